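"""Demultiplex amplicon reads by sample barcode and count exact guide matches.

The screen readout is amplicon sequencing of the integrated hairpin cassette:
each read starts with an 8-bp sample barcode followed by a constant primer
region and the variable guide. Assignment is maximally strict — a read counts
for an shRNA only if the guide region is a 100% match to a library guide, and
for a sample only if its leading bases equal a manifest barcode exactly.
Everything else is tallied (per-sample ``unassigned``, global ``undemuxed``)
so that reads are conserved:

    sum(counts) + sum(unassigned) + undemuxed == total_reads

Quality scores are ignored: exact matching subsumes quality filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .library import SampleManifest, ShRNALibrary

__all__ = ["CountMatrix", "demultiplex_read", "count_shrnas", "write_counts", "read_counts"]

UNASSIGNED_ROW = "__unassigned__"

_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class CountMatrix:
    """Integer reads per shRNA x sample, plus the unassigned/undemuxed tallies.

    ``counts`` is indexed by shrna_id (rows, in library order) and sample_id
    (columns, in manifest order); ``unassigned`` is a per-sample Series of
    demultiplexed reads whose guide region matched no library guide;
    ``undemuxed`` counts reads whose barcode matched no sample.
    """

    counts: pd.DataFrame
    unassigned: pd.Series
    undemuxed: int
    total_reads: int

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any() or (self.unassigned < 0).any():
            raise ValueError("negative counts")
        if not self.counts.columns.equals(self.unassigned.index):
            raise ValueError("counts columns and unassigned index disagree")
        assigned = int(self.counts.to_numpy().sum()) + int(self.unassigned.sum())
        if assigned + self.undemuxed != self.total_reads:
            raise ValueError(
                f"read conservation violated: {assigned} assigned + "
                f"{self.undemuxed} undemuxed != {self.total_reads} total"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.unassigned.equals(other.unassigned)
            and self.undemuxed == other.undemuxed
            and self.total_reads == other.total_reads
        )


def demultiplex_read(read_seq: str, manifest: SampleManifest) -> str | None:
    """Assign a read to the sample whose barcode equals its leading bases.

    Zero mismatches are allowed. Returns the sample_id, or None if the read
    is shorter than the barcode or no barcode matches (tallied as undemuxed
    by the caller).
    """
    blen = manifest.barcode_length
    if len(read_seq) < blen:
        return None
    return manifest.barcode_to_sample.get(read_seq[:blen].upper())


def _find_guide(
    seq: str,
    guide_to_id: dict[str, str],
    guide_length: int,
    guide_offset: int,
    scan: bool,
) -> str | None:
    if scan:
        # leftmost exact occurrence of any guide, anywhere in the read
        for start in range(0, len(seq) - guide_length + 1):
            hit = guide_to_id.get(seq[start : start + guide_length])
            if hit is not None:
                return hit
        return None
    if len(seq) < guide_offset + guide_length:
        return None
    return guide_to_id.get(seq[guide_offset : guide_offset + guide_length])


def count_shrnas(
    fastq_path: str | Path,
    library: ShRNALibrary,
    manifest: SampleManifest,
    guide_offset: int = 30,
    scan: bool = False,
    match_revcomp: bool = False,
) -> CountMatrix:
    """Count exact guide matches per (shRNA, sample) from a FASTQ stream.

    Parameters
    ----------
    fastq_path
        FASTQ or FASTQ.gz file of single-end amplicon reads.
    guide_offset
        0-based position of the guide within the read (barcode + constant
        primer region; the amplicon layout is configuration, not inference).
        Ignored when ``scan`` is set.
    scan
        Search each read for any exact guide occurrence instead of using a
        fixed offset; ties broken by leftmost position.
    match_revcomp
        Also try the reverse complement of the read (off by default;
        single-orientation amplicon sequencing).

    Each read contributes exactly one count: to a (shRNA, sample) cell, to
    that sample's unassigned tally, or to the undemuxed tally. Counting is
    order-independent and deterministic for a fixed input.
    """
    fastq_path = Path(fastq_path)
    guide_to_id = library.guide_to_id
    barcode_to_sample = manifest.barcode_to_sample
    blen = manifest.barcode_length
    L = library.guide_length

    shrna_ids = library.shrna_ids
    sample_ids = manifest.sample_ids
    row_index = {s: i for i, s in enumerate(shrna_ids)}
    col_index = {s: j for j, s in enumerate(sample_ids)}

    counts = np.zeros((len(shrna_ids), len(sample_ids)), dtype=np.int64)
    unassigned = np.zeros(len(sample_ids), dtype=np.int64)
    undemuxed = 0
    total = 0

    with pysam.FastxFile(str(fastq_path)) as fh:
        for record_index, rec in enumerate(fh):
            seq = (rec.sequence or "").upper()
            if rec.sequence is None:
                raise ValueError(f"{fastq_path}: unreadable FASTQ record {record_index}")
            total += 1
            candidates = [seq, _revcomp(seq)] if match_revcomp else [seq]
            sample = None
            shrna = None
            for cand in candidates:
                if len(cand) < blen:
                    continue
                s = barcode_to_sample.get(cand[:blen])
                if s is None:
                    continue
                sample = s
                shrna = _find_guide(cand, guide_to_id, L, guide_offset, scan)
                if shrna is not None:
                    break
            if sample is None:
                undemuxed += 1
            elif shrna is None:
                unassigned[col_index[sample]] += 1
            else:
                counts[row_index[shrna], col_index[sample]] += 1

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(shrna_ids, name="shrna_id"), columns=sample_ids),
        unassigned=pd.Series(unassigned, index=pd.Index(sample_ids), name=UNASSIGNED_ROW),
        undemuxed=undemuxed,
        total_reads=total,
    )
    cm.validate()
    return cm


def counts_from_arrays(
    counts: pd.DataFrame | np.ndarray,
    shrna_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> CountMatrix:
    """Wrap a plain count table (no unassigned/undemuxed reads) as a CountMatrix."""
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(
            np.asarray(counts), index=pd.Index(shrna_ids, name="shrna_id"), columns=sample_ids
        )
    counts = counts.astype(np.int64)
    counts.index.name = "shrna_id"
    cm = CountMatrix(
        counts=counts,
        unassigned=pd.Series(0, index=counts.columns, name=UNASSIGNED_ROW, dtype=np.int64),
        undemuxed=0,
        total_reads=int(counts.to_numpy().sum()),
    )
    cm.validate()
    return cm


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as TSV; re-reading reproduces it exactly.

    Layout: a ``#undemuxed=N  #total_reads=N`` metadata line, the header,
    one row per shRNA, and a trailing ``__unassigned__`` row. All-zero
    sample columns are preserved.
    """
    cm.validate()
    path = Path(path)
    table = pd.concat([cm.counts, cm.unassigned.rename(UNASSIGNED_ROW).to_frame().T])
    table.index.name = "shrna_id"
    with open(path, "w") as fh:
        fh.write(f"#undemuxed={cm.undemuxed}\t#total_reads={cm.total_reads}\n")
        table.to_csv(fh, sep="\t")


def read_counts(path: str | Path) -> CountMatrix:
    """Read a counts TSV written by :func:`write_counts`."""
    path = Path(path)
    with open(path) as fh:
        meta = fh.readline().strip()
        fields = dict(part.lstrip("#").split("=") for part in meta.split("\t"))
        table = pd.read_csv(fh, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    unassigned = table.loc[UNASSIGNED_ROW].astype(np.int64)
    unassigned.name = UNASSIGNED_ROW
    counts = table.drop(index=UNASSIGNED_ROW).astype(np.int64)
    counts.index.name = "shrna_id"
    cm = CountMatrix(
        counts=counts,
        unassigned=unassigned,
        undemuxed=int(fields["undemuxed"]),
        total_reads=int(fields["total_reads"]),
    )
    cm.validate()
    return cm
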