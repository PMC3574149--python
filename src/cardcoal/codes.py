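"""Genetic code tables (standard and vertebrate mitochondrial).

Thin wrapper over Biopython's NCBI codon tables exposing plain dicts that
map codons to one-letter amino acids, with '*' for stop codons.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

__all__ = ["get_code", "sense_codons", "CODE_NAMES"]

CODE_NAMES = {
    "standard": 1,
    "vertebrate-mitochondrial": 2,
}


@lru_cache(maxsize=None)
def get_code(name: str) -> dict:
    """Codon -> amino acid (one letter, '*' = stop) for a named code."""
    if name not in CODE_NAMES:
        raise ValueError(
            f"unknown genetic code {name!r}; choose from {sorted(CODE_NAMES)}")
    table = CodonTable.unambiguous_dna_by_id[CODE_NAMES[name]]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    # every one of the 64 codons must be covered
    for codon in ("".join(p) for p in product("ACGT", repeat=3)):
        assert codon in code, codon
    return code


@lru_cache(maxsize=None)
def sense_codons(name: str) -> tuple:
    """All non-stop codons under the named code, in lexicographic order."""
    code = get_code(name)
    return tuple(c for c in sorted(code) if code[c] != "*")
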