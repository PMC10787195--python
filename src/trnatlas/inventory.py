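"""tRNA reference inventory: name parsing, sequence collapsing, grouping.

tRNA gene sets (GtRNAdb for nuclear genes, mitotRNAdb for mitochondrial ones)
contain many gene copies transcribing the exact same mature sequence. A
sequencing read cannot distinguish such copies, so quantification operates on
*isodecoders*: unique-sequence transcripts. Isodecoders sharing an anticodon
form an *isoacceptor*; isoacceptors charging the same amino acid form an
*isotype*. This module parses reference headers, collapses identical
sequences, and builds the isodecoder -> isoacceptor -> isotype grouping used
by every downstream analysis.

Initiator methionine (iMet), selenocysteine (SeC), and suppressor (Sup) tRNAs
are kept as groups of their own, distinct from the standard isoacceptors, even
where they share an anticodon with a standard tRNA (iMet-CAT vs Met-CAT).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .genetic_code import (
    ANTICODON_TO_AA,
    SPECIAL_ISOTYPES,
    anticodon_to_codon,
    normalize_nt,
)

CYTOSOLIC = "cytosolic"
MITOCHONDRIAL = "mitochondrial"

_ANTICODON_RE = re.compile(r"^[ACGT]{3}$")


class TrnaParseError(ValueError):
    """Raised when a tRNA reference header cannot be interpreted."""


class AnnotationError(ValueError):
    """Raised when reference annotations are internally inconsistent."""


@dataclass
class IsodecoderRecord:
    """One unique-sequence tRNA after collapsing identical gene copies."""

    id: str
    member_names: list[str]
    sequence: str
    isotype: str
    anticodon: str
    compartment: str

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3:
            raise ValueError(f"anticodon must be length 3: {self.anticodon!r}")
        if not self.member_names:
            raise ValueError("member_names must be non-empty")

    @property
    def isoacceptor_key(self) -> tuple[str, str]:
        return (self.isotype, self.anticodon)

    @property
    def is_special(self) -> bool:
        return self.isotype in SPECIAL_ISOTYPES


def anticodon_to_isotype(anticodon: str, declared_isotype: str | None = None) -> str:
    """Resolve the isotype of an anticodon under the standard genetic code.

    The anticodon is reverse-complemented to its Watson-Crick codon and
    decoded. A declared special isotype (iMet, SeC, Sup) always wins; an
    anticodon decoding a stop codon with no declared isotype is a suppressor.
    A declared non-special isotype that disagrees with the decoded amino acid
    triggers a warning and the decoded value is used.
    """
    anticodon = normalize_nt(anticodon)
    if not _ANTICODON_RE.match(anticodon):
        raise TrnaParseError(f"invalid anticodon {anticodon!r}")
    if declared_isotype in SPECIAL_ISOTYPES:
        return declared_isotype
    derived = ANTICODON_TO_AA.get(anticodon)
    if derived is None:
        # decodes a stop codon: suppressor unless declared special above
        return "Sup"
    if declared_isotype is not None and declared_isotype != derived:
        warnings.warn(
            f"declared isotype {declared_isotype!r} disagrees with anticodon "
            f"{anticodon} (codon {anticodon_to_codon(anticodon)} -> {derived}); "
            f"using {derived}",
            stacklevel=2,
        )
    return derived


def parse_trna_name(name: str, compartment: str = CYTOSOLIC) -> IsodecoderRecord:
    """Parse a GtRNAdb-style tRNA name into an (un-sequenced) record.

    Accepts names like ``Gly-CCC-4-1``, ``tRNA-iMet-CAT-1-1`` or
    ``mt-tRNA-Leu-TAA``: an optional ``tRNA``/``mt`` prefix, an isotype token,
    and a 3-letter anticodon token, hyphen-separated.
    """
    tokens = [t for t in name.strip().split("-") if t]
    while tokens and tokens[0].lower() in {"trna", "mt", "nmt"}:
        tokens.pop(0)
    if len(tokens) < 2:
        raise TrnaParseError(f"cannot parse tRNA name {name!r}: too few tokens")
    declared = tokens[0]
    anticodon = normalize_nt(tokens[1])
    if not _ANTICODON_RE.match(anticodon):
        raise TrnaParseError(
            f"cannot parse tRNA name {name!r}: anticodon token {tokens[1]!r} "
            f"is not a 3-mer over ACGT/U"
        )
    isotype = (
        declared
        if declared in SPECIAL_ISOTYPES
        else anticodon_to_isotype(anticodon, declared)
    )
    return IsodecoderRecord(
        id=name,
        member_names=[name],
        sequence="",
        isotype=isotype,
        anticodon=anticodon,
        compartment=compartment,
    )


def collapse_identical(records: list[IsodecoderRecord]) -> list[IsodecoderRecord]:
    """Merge records with identical sequences into one isodecoder each.

    Gene copies transcribing the same sequence are indistinguishable to
    sequencing, so they are collapsed; the lexicographically first member name
    becomes the isodecoder id. Identical sequences carrying conflicting
    anticodon annotations indicate a broken reference and raise.

    Collapsing is idempotent. Sequences are compared after uppercasing and
    U->T normalization; any CCA-tail trimming is expected to have happened
    upstream (read processing removes 3'-CCA before mapping).
    """
    by_seq: dict[tuple[str, str], list[IsodecoderRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (normalize_nt(rec.sequence), rec.compartment)
        if key not in by_seq:
            by_seq[key] = []
            order.append(key)
        by_seq[key].append(rec)

    collapsed: list[IsodecoderRecord] = []
    for key in order:
        group = by_seq[key]
        anticodons = {r.anticodon for r in group}
        isotypes = {r.isotype for r in group}
        if len(anticodons) > 1 or len(isotypes) > 1:
            names = sorted(n for r in group for n in r.member_names)
            raise AnnotationError(
                f"identical sequence annotated with conflicting labels "
                f"(anticodons {sorted(anticodons)}, isotypes {sorted(isotypes)}) "
                f"for members {names}"
            )
        members = sorted({n for r in group for n in r.member_names})
        first = group[0]
        collapsed.append(
            IsodecoderRecord(
                id=members[0],
                member_names=members,
                sequence=key[0],
                isotype=first.isotype,
                anticodon=first.anticodon,
                compartment=first.compartment,
            )
        )
    return collapsed


@dataclass
class GroupingMap:
    """Isodecoder -> isoacceptor -> isotype partition with group sizes."""

    isoacceptor_of: dict[str, tuple[str, str]] = field(default_factory=dict)
    isotype_of: dict[str, str] = field(default_factory=dict)

    @property
    def isodecoders(self) -> list[str]:
        return list(self.isoacceptor_of)

    def group_sizes(self, level: str) -> dict:
        """Number of isodecoders n_i in each group at the requested level."""
        mapping = self._mapping(level)
        sizes: dict = {}
        for g in mapping.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def _mapping(self, level: str) -> dict:
        if level == "isodecoder":
            return {i: i for i in self.isoacceptor_of}
        if level == "isoacceptor":
            return self.isoacceptor_of
        if level == "isotype":
            return self.isotype_of
        raise ValueError(f"unknown grouping level {level!r}")

    def n_groups(self, level: str) -> int:
        return len(set(self._mapping(level).values()))


def build_grouping(records: list[IsodecoderRecord]) -> GroupingMap:
    """Build the anticodon- and isotype-level partitions of the isodecoders.

    Isoacceptor keys are (isotype, anticodon) pairs, so iMet-CAT is a group
    distinct from Met-CAT and the suppressor/SeC groups never merge with
    standard isoacceptors sharing their anticodon.
    """
    if not records:
        raise ValueError("cannot build a grouping from an empty record list")
    gm = GroupingMap()
    for rec in records:
        if rec.id in gm.isoacceptor_of:
            raise AnnotationError(f"duplicate isodecoder id {rec.id!r}")
        # mt-tRNAs are distinct molecular species: never merge them into a
        # cytosolic isoacceptor that happens to share the anticodon
        prefix = "mt-" if rec.compartment == MITOCHONDRIAL else ""
        gm.isoacceptor_of[rec.id] = (prefix + rec.isotype, rec.anticodon)
        gm.isotype_of[rec.id] = prefix + rec.isotype
    return gm


def read_trna_fasta(path: str | Path, compartment: str) -> list[IsodecoderRecord]:
    """Read a tRNA reference FASTA, parsing each header into a record."""
    if compartment not in (CYTOSOLIC, MITOCHONDRIAL):
        raise ValueError(f"unknown compartment {compartment!r}")
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        rec = parse_trna_name(sr.id, compartment)
        rec.sequence = normalize_nt(str(sr.seq))
        records.append(rec)
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def load_reference(
    cytosolic_fasta: str | Path, mitochondrial_fasta: str | Path | None = None
) -> list[IsodecoderRecord]:
    """Read, merge, and collapse the cytosolic (+ optional mt) references."""
    records = read_trna_fasta(cytosolic_fasta, CYTOSOLIC)
    if mitochondrial_fasta is not None:
        records += read_trna_fasta(mitochondrial_fasta, MITOCHONDRIAL)
    return collapse_identical(records)


def write_collapsed_fasta(records: list[IsodecoderRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def write_grouping_tsv(records: list[IsodecoderRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "id\tmembers\tisotype\tanticodon\tcompartment\t"
            "isoacceptor_key\tisotype_key\n"
        )
        for rec in records:
            fh.write(
                f"{rec.id}\t{','.join(rec.member_names)}\t{rec.isotype}\t"
                f"{rec.anticodon}\t{rec.compartment}\t"
                f"{rec.isotype}-{rec.anticodon}\t{rec.isotype}\n"
            )
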