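"""Standard genetic code tables shared across the package.

Everything is kept in the DNA alphabet (T, not U): GtRNAdb names anticodons
with T, and keeping a single alphabet avoids conversions at every boundary.
Amino acids are referred to by their three-letter names (Gly, not G), matching
tRNA nomenclature.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Special tRNA isotypes that are not plain amino-acid carriers: initiator
#: methionine, selenocysteine, and suppressor tRNAs reading stop codons.
SPECIAL_ISOTYPES = frozenset({"iMet", "SeC", "Sup"})

_table = CodonTable.unambiguous_dna_by_name["Standard"]

#: codon -> three-letter amino acid, for the 61 sense codons.
CODON_TO_AA: dict[str, str] = {
    codon: seq3(aa) for codon, aa in _table.forward_table.items()
}

STOP_CODONS: tuple[str, ...] = tuple(sorted(_table.stop_codons))  # TAA, TAG, TGA

#: The 61 sense codons in lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: All 20 amino acids, three-letter, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

#: amino acid -> tuple of its synonymous codons (lexicographic).
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AMINO_ACIDS
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_nt(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def anticodon_to_codon(anticodon: str) -> str:
    """The Watson-Crick codon read by an anticodon (pairing 34<->3, 36<->1)."""
    return reverse_complement(anticodon)


#: The 61 anticodons whose Watson-Crick codon is a sense codon.
SENSE_ANTICODONS: tuple[str, ...] = tuple(
    sorted(reverse_complement(c) for c in SENSE_CODONS)
)

#: anticodon -> three-letter amino acid of its Watson-Crick codon.
ANTICODON_TO_AA: dict[str, str] = {
    ac: CODON_TO_AA[anticodon_to_codon(ac)] for ac in SENSE_ANTICODONS
}
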