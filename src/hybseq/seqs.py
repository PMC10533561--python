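"""Small nucleotide/protein helpers shared across the pipeline.

Thin wrappers around Biopython plus a fixed one-codon-per-residue table used
wherever a protein sequence has to be turned back into DNA deterministically
(fragment design, the plate simulator).
"""

from __future__ import annotations

from Bio.Seq import Seq

#: One high-usage mouse codon per amino acid. Deliberately CpG-poor so that
#: reverse-translated V regions do not pick up NotI/AscI/BssHII sites by accident.
CODON_TABLE: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
    "*": "TGA",
}


def revcomp(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def translate(nt: str) -> str:
    """Translate, ignoring a trailing partial codon."""
    n = len(nt) - len(nt) % 3
    return str(Seq(nt[:n]).translate())


def reverse_translate(aa: str, codon_table: dict[str, str] | None = None) -> str:
    """Deterministic one-codon-per-residue expansion; translate(result) == aa.

    Raises ``ValueError`` on residues missing from the table.
    """
    table = CODON_TABLE if codon_table is None else codon_table
    try:
        return "".join(table[r] for r in aa)
    except KeyError as exc:
        raise ValueError(f"no codon for residue {exc.args[0]!r}") from None


def hamming(a: str, b: str) -> int:
    """Hamming distance; defined only for equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
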