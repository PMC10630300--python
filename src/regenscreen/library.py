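"""Reference assets for a pooled shRNA screen: the hairpin library and the
sample manifest.

The library is the ground truth every downstream stage consults: each record
carries the unique guide sequence used for exact-match read assignment, the
target gene symbol, and an explicit control class. Control classes are
annotations, never inferred from naming conventions, so that QC verdicts are
deterministic:

``targeting``
    ordinary hairpin against a candidate gene.
``non_targeting``
    no transcript target (shNC); expected neutral under selection.
``sentinel_depletion``
    targets a gene essential for the selected phenotype (e.g. c-Met for
    liver regeneration); expected to drop out, validating selection pressure.

The manifest maps 8-bp sample barcodes to sample ids and roles. Exactly one
sample plays the ``reference_pool`` role — the plasmid pool sequenced before
injection, the denominator of every fold change.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CONTROL_CLASSES",
    "ShRNARecord",
    "ShRNALibrary",
    "SampleEntry",
    "SampleManifest",
    "LibraryValidationError",
    "ManifestValidationError",
    "read_library",
    "write_library",
    "read_manifest",
    "write_manifest",
]

CONTROL_CLASSES = ("targeting", "non_targeting", "sentinel_depletion")
ROLES = ("reference_pool", "replicate")

_DNA = set("ACGT")

LIBRARY_COLUMNS = ["shrna_id", "gene", "guide_seq", "control_class"]
MANIFEST_COLUMNS = ["barcode", "sample_id", "role"]


class LibraryValidationError(ValueError):
    """Raised when a library violates its invariants."""


class ManifestValidationError(ValueError):
    """Raised when a sample manifest violates its invariants."""


@dataclass(frozen=True)
class ShRNARecord:
    """One hairpin: identifier, target gene, guide sequence, control class."""

    shrna_id: str
    gene: str
    guide_seq: str
    control_class: Literal["targeting", "non_targeting", "sentinel_depletion"] = "targeting"

    def validate(self, guide_length: int | None = None) -> None:
        if not self.shrna_id:
            raise LibraryValidationError("shrna_id must be non-empty")
        if self.control_class not in CONTROL_CLASSES:
            raise LibraryValidationError(
                f"{self.shrna_id}: control_class {self.control_class!r} not one of {CONTROL_CLASSES}"
            )
        seq = self.guide_seq
        if not seq or seq != seq.upper() or not set(seq) <= _DNA:
            raise LibraryValidationError(
                f"{self.shrna_id}: guide_seq must be uppercase A/C/G/T, got {seq!r}"
            )
        if guide_length is not None and len(seq) != guide_length:
            raise LibraryValidationError(
                f"{self.shrna_id}: guide length {len(seq)} != library guide length {guide_length}"
            )
        if self.control_class == "non_targeting" and self.gene:
            raise LibraryValidationError(
                f"{self.shrna_id}: non_targeting record must have an empty gene, got {self.gene!r}"
            )


@dataclass
class ShRNALibrary:
    """Ordered, validated collection of :class:`ShRNARecord`.

    Guide length is a library-wide constant (default 22 nt, a typical miR30
    guide); all guides are pairwise distinct so that guide -> record lookup
    is a bijection.
    """

    records: list[ShRNARecord]
    guide_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise LibraryValidationError("library is empty")
        self.guide_length = len(self.records[0].guide_seq)
        seen_ids: dict[str, str] = {}
        seen_guides: dict[str, str] = {}
        for rec in self.records:
            rec.validate(self.guide_length)
            if rec.shrna_id in seen_ids:
                raise LibraryValidationError(f"duplicate shrna_id {rec.shrna_id!r}")
            seen_ids[rec.shrna_id] = rec.shrna_id
            if rec.guide_seq in seen_guides:
                raise LibraryValidationError(
                    f"duplicate guide sequence shared by {seen_guides[rec.guide_seq]!r} "
                    f"and {rec.shrna_id!r}"
                )
            seen_guides[rec.guide_seq] = rec.shrna_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def shrna_ids(self) -> list[str]:
        return [r.shrna_id for r in self.records]

    @property
    def guide_to_id(self) -> dict[str, str]:
        return {r.guide_seq: r.shrna_id for r in self.records}

    def record(self, shrna_id: str) -> ShRNARecord:
        for r in self.records:
            if r.shrna_id == shrna_id:
                return r
        raise KeyError(shrna_id)

    def by_gene(self) -> dict[str, list[ShRNARecord]]:
        """Targeting/sentinel records grouped by gene (non-targeting excluded)."""
        out: dict[str, list[ShRNARecord]] = {}
        for r in self.records:
            if r.gene:
                out.setdefault(r.gene, []).append(r)
        return out

    def controls(self, control_class: str) -> list[ShRNARecord]:
        return [r for r in self.records if r.control_class == control_class]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.shrna_id, r.gene, r.guide_seq, r.control_class) for r in self.records],
            columns=LIBRARY_COLUMNS,
        )


@dataclass(frozen=True)
class SampleEntry:
    barcode: str
    sample_id: str
    role: Literal["reference_pool", "replicate"]


@dataclass
class SampleManifest:
    """Barcode -> sample mapping with exactly one reference pool."""

    entries: list[SampleEntry]
    barcode_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ManifestValidationError("manifest is empty")
        self.barcode_length = len(self.entries[0].barcode)
        barcodes: set[str] = set()
        sample_ids: set[str] = set()
        n_pool = 0
        for e in self.entries:
            if e.role not in ROLES:
                raise ManifestValidationError(
                    f"{e.sample_id}: role {e.role!r} not one of {ROLES}"
                )
            bc = e.barcode
            if not bc or bc != bc.upper() or not set(bc) <= _DNA:
                raise ManifestValidationError(
                    f"{e.sample_id}: barcode must be uppercase A/C/G/T, got {bc!r}"
                )
            if len(bc) != self.barcode_length:
                raise ManifestValidationError(
                    f"{e.sample_id}: barcode {bc!r} has length {len(bc)}, "
                    f"expected {self.barcode_length}"
                )
            if bc in barcodes:
                raise ManifestValidationError(f"duplicate barcode {bc!r}")
            barcodes.add(bc)
            if e.sample_id in sample_ids:
                raise ManifestValidationError(f"duplicate sample_id {e.sample_id!r}")
            sample_ids.add(e.sample_id)
            if e.role == "reference_pool":
                n_pool += 1
        if n_pool != 1:
            raise ManifestValidationError(
                f"manifest must contain exactly one reference_pool sample, found {n_pool}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def pool_id(self) -> str:
        return next(e.sample_id for e in self.entries if e.role == "reference_pool")

    @property
    def replicate_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries if e.role == "replicate"]

    @property
    def barcode_to_sample(self) -> dict[str, str]:
        return {e.barcode: e.sample_id for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.barcode, e.sample_id, e.role) for e in self.entries],
            columns=MANIFEST_COLUMNS,
        )


def _records_from_frame(df: pd.DataFrame) -> list[ShRNARecord]:
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryValidationError(f"library TSV missing columns: {missing}")
    df = df.fillna({"gene": ""})
    return [
        ShRNARecord(
            shrna_id=str(row.shrna_id),
            gene=str(row.gene) if row.gene else "",
            guide_seq=str(row.guide_seq),
            control_class=str(row.control_class),
        )
        for row in df.itertuples()
    ]


def read_library(path: str | Path, format: str = "tsv") -> ShRNALibrary:
    """Read and validate an shRNA library from TSV (canonical) or FASTA.

    TSV needs header columns ``shrna_id, gene, guide_seq, control_class``.
    FASTA record ids encode the metadata as ``shrna_id|gene|control_class``
    (empty gene allowed) with the guide as the sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise LibraryValidationError(f"{path}: empty library file") from None
        records = _records_from_frame(df)
    elif format == "fasta":
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 3:
                raise LibraryValidationError(
                    f"{path}: FASTA id {rec.id!r} is not shrna_id|gene|control_class"
                )
            records.append(
                ShRNARecord(
                    shrna_id=parts[0],
                    gene=parts[1],
                    guide_seq=str(rec.seq).upper(),
                    control_class=parts[2],
                )
            )
    else:
        raise ValueError(f"unknown library format {format!r}")
    if not records:
        raise LibraryValidationError(f"{path}: empty library file")
    return ShRNALibrary(records)


def write_library(library: ShRNALibrary, path: str | Path, format: str = "tsv") -> None:
    """Write a library as TSV or FASTA; round-trips field-by-field."""
    path = Path(path)
    if format == "tsv":
        library.to_frame().to_csv(path, sep="\t", index=False)
    elif format == "fasta":
        seq_records = [
            SeqRecord(
                Seq(r.guide_seq),
                id=f"{r.shrna_id}|{r.gene}|{r.control_class}",
                description="",
            )
            for r in library
        ]
        with open(path, "w") as fh:
            SeqIO.write(seq_records, fh, "fasta")
    else:
        raise ValueError(f"unknown library format {format!r}")


def read_manifest(path: str | Path) -> SampleManifest:
    """Read and validate a sample manifest TSV (barcode, sample_id, role)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ManifestValidationError(f"{path}: empty manifest file") from None
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestValidationError(f"manifest TSV missing columns: {missing}")
    entries = [
        SampleEntry(barcode=str(r.barcode), sample_id=str(r.sample_id), role=str(r.role))
        for r in df.itertuples()
    ]
    return SampleManifest(entries)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)
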