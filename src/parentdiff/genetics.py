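"""Small shared toolkit: standard genetic code, complements, codon lookups.

The genetic code is taken from Biopython's standard table (NCBI table 1);
stop codons are represented by ``"*"``.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon (upper-case DNA) -> one-letter amino acid, stops as "*"
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_standard.stop_codons)
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; ``"*"`` for a stop."""
    try:
        return CODON_TO_AA[codon.upper()]
    except KeyError:  # ambiguous base
        raise ValueError(f"cannot translate codon {codon!r}") from None


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return {a.upper(), b.upper()} in ({"A", "G"}, {"C", "T"})
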