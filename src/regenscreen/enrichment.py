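"""Relative abundance, per-replicate log2 fold change versus the starting
pool, replicate aggregation and consistency scoring.

Enrichment is measured as the change in an shRNA's relative read share
between each liver replicate and the sequenced starting pool:

    lfc[s, r] = log2( freq[s, r] / freq[s, pool] )

with frequencies computed over library shRNAs only (unassigned reads are
excluded from the denominator) after adding a pseudocount to raw counts.
The per-shRNA score is the arithmetic mean of the per-replicate log2 fold
changes — averaging the plotted per-animal log2 values, not the log of the
mean frequency. Replicate consistency formalizes "enriched in every mouse"
prioritization: the fraction of replicates whose lfc agrees in sign with the
mean and clears a magnitude floor (default 0, i.e. sign agreement only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .library import SampleManifest, ShRNALibrary
from .quantify import CountMatrix

__all__ = [
    "AbundanceTable",
    "FoldChangeTable",
    "relative_abundance",
    "log2_fold_change",
    "replicate_consistency",
    "write_foldchange",
    "read_foldchange",
]


@dataclass
class AbundanceTable:
    """Per-sample relative abundances; every column sums to 1 (within 1e-9)."""

    freq: pd.DataFrame
    pseudocount: float

    def validate(self) -> None:
        colsums = self.freq.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = colsums[~np.isclose(colsums, 1.0, atol=1e-9)]
            raise ValueError(f"abundance columns do not sum to 1: {dict(bad)}")
        if self.pseudocount > 0 and (self.freq.to_numpy() <= 0).any():
            raise ValueError("zero frequency despite positive pseudocount")


@dataclass
class FoldChangeTable:
    """Per-shRNA, per-replicate log2 fold change versus the reference pool.

    ``lfc`` is shrna_id x replicate_id; ``mean_lfc`` the arithmetic mean over
    replicates; ``consistency`` (filled by :func:`replicate_consistency`) the
    fraction of replicates agreeing in sign with the mean and clearing the
    magnitude floor.
    """

    lfc: pd.DataFrame
    mean_lfc: pd.Series
    n_replicates: int
    consistency: pd.Series | None = None

    @property
    def shrna_ids(self) -> list[str]:
        return list(self.lfc.index)


def relative_abundance(cm: CountMatrix, pseudocount: float = 0.5) -> AbundanceTable:
    """Normalize counts to per-sample frequencies after adding a pseudocount.

    freq[s, j] = (counts[s, j] + pseudocount) / sum_s' (counts[s', j] + pseudocount)

    The default pseudocount of 0.5 keeps all downstream log fold changes
    finite when an shRNA drops to zero reads in a sample.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = cm.counts.astype(float) + pseudocount
    totals = shifted.sum(axis=0)
    zero_total = totals[totals == 0]
    if len(zero_total):
        raise ValueError(
            f"sample(s) with zero total counts and pseudocount 0: {list(zero_total.index)}"
        )
    ab = AbundanceTable(freq=shifted / totals, pseudocount=pseudocount)
    ab.validate()
    return ab


def log2_fold_change(ab: AbundanceTable, manifest: SampleManifest) -> FoldChangeTable:
    """Per-replicate log2(freq_replicate / freq_pool) and its replicate mean."""
    pool = manifest.pool_id
    if pool not in ab.freq.columns:
        raise ValueError(f"reference pool sample {pool!r} not present in abundance table")
    replicates = [s for s in manifest.replicate_ids if s in ab.freq.columns]
    if not replicates:
        raise ValueError("no replicate samples present in abundance table")
    pool_freq = ab.freq[pool]
    if (pool_freq == 0).any():
        zero = list(pool_freq.index[pool_freq == 0])
        raise ValueError(f"zero pool frequency for {zero}; use a positive pseudocount")
    lfc = np.log2(ab.freq[replicates].div(pool_freq, axis=0))
    lfc.columns.name = "replicate_id"
    return FoldChangeTable(lfc=lfc, mean_lfc=lfc.mean(axis=1), n_replicates=len(replicates))


def replicate_consistency(fc: FoldChangeTable, consistency_floor: float = 0.0) -> FoldChangeTable:
    """Fill the consistency column: fraction of replicates agreeing with the mean.

    A replicate agrees when sign(lfc) == sign(mean_lfc) and |lfc| >= floor.
    shRNAs with mean_lfc exactly 0 get consistency 0.
    """
    if fc.n_replicates < 1:
        raise ValueError("need at least one replicate")
    mean_sign = np.sign(fc.mean_lfc)
    agree = (
        np.sign(fc.lfc).eq(mean_sign, axis=0) & (fc.lfc.abs() >= consistency_floor)
    ).sum(axis=1)
    consistency = (agree / fc.n_replicates).where(mean_sign != 0, 0.0)
    return replace(fc, consistency=consistency)


def write_foldchange(
    fc: FoldChangeTable, library: ShRNALibrary, path: str | Path
) -> None:
    """Write the fold-change table as TSV with library annotations.

    Columns: shrna_id, gene, control_class, lfc_<replicate>..., mean_lfc,
    consistency (empty if not computed).
    """
    lib = library.to_frame().set_index("shrna_id")[["gene", "control_class"]]
    out = lib.join(fc.lfc.add_prefix("lfc_"), how="right")
    out["mean_lfc"] = fc.mean_lfc
    out["consistency"] = fc.consistency if fc.consistency is not None else np.nan
    out.index.name = "shrna_id"
    out.to_csv(path, sep="\t")


def read_foldchange(path: str | Path) -> tuple[FoldChangeTable, pd.DataFrame]:
    """Read a TSV written by :func:`write_foldchange`.

    Returns the FoldChangeTable and the annotation frame (gene,
    control_class per shrna_id).
    """
    df = pd.read_csv(path, sep="\t", index_col="shrna_id", keep_default_na=False)
    df.index = df.index.astype(str)
    lfc_cols = [c for c in df.columns if c.startswith("lfc_")]
    lfc = df[lfc_cols].astype(float)
    lfc.columns = [c[len("lfc_"):] for c in lfc_cols]
    lfc.columns.name = "replicate_id"
    consistency = pd.to_numeric(df["consistency"], errors="coerce")
    fc = FoldChangeTable(
        lfc=lfc,
        mean_lfc=pd.to_numeric(df["mean_lfc"]),
        n_replicates=len(lfc_cols),
        consistency=None if consistency.isna().all() else consistency,
    )
    annotations = df[["gene", "control_class"]].copy()
    return fc, annotations
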