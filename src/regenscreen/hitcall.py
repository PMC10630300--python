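"""Two-fold shRNA classification, gene-level hit calling and control QC.

An shRNA is *enriched* when its mean log2 fold change clears +1 (a two-fold
change, inclusive boundary — "at least two-fold") with sufficient replicate
consistency, *depleted* symmetrically at -1, and *neutral* otherwise. A gene
becomes a hit only when at least two independent shRNAs score in the same
direction, guarding against single-hairpin off-target effects. Controls give
the screen its QC verdict: non-targeting hairpins must stay inside the
two-fold band, depletion sentinels (hairpins against a gene required for the
selected phenotype) must drop out. A QC failure is reported, never fatal —
screens are exploratory and controls are confidence checks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .enrichment import FoldChangeTable
from .library import ShRNALibrary

__all__ = [
    "ShRNACall",
    "GeneHitTable",
    "ControlQCReport",
    "classify_shrnas",
    "call_gene_hits",
    "control_qc",
    "write_hit_tables",
]

CALLS = ("enriched", "depleted", "neutral")


@dataclass(frozen=True)
class ShRNACall:
    shrna_id: str
    gene: str
    control_class: str
    mean_lfc: float
    consistency: float
    call: str  # enriched | depleted | neutral


@dataclass
class GeneHitTable:
    """Per-gene hit calls under the >=2-independent-shRNA rule.

    ``table`` has one row per gene: n_shrnas_total, n_enriched, n_depleted,
    gene_call (hit_enriched | hit_depleted | none), discordant flag, the
    supporting shrna ids and the mean lfc of the supporters; rows are ranked
    by n_enriched then supporter mean lfc, descending.
    """

    table: pd.DataFrame
    min_shrnas_per_gene: int = 2

    @property
    def hits(self) -> pd.DataFrame:
        return self.table[self.table["gene_call"] != "none"]


@dataclass
class ControlQCReport:
    """Pass/fail per control shRNA; overall_pass iff every control passes.

    Non-targeting controls pass when |mean_lfc| < lfc_threshold (neither
    enriched nor depleted); depletion sentinels pass when
    mean_lfc <= -lfc_threshold.
    """

    non_targeting: pd.DataFrame
    sentinels: pd.DataFrame
    lfc_threshold: float
    overall_pass: bool = field(init=False)

    def __post_init__(self) -> None:
        self.overall_pass = bool(
            self.non_targeting["pass"].all() and self.sentinels["pass"].all()
        )

    def to_dict(self) -> dict:
        return {
            "lfc_threshold": self.lfc_threshold,
            "overall_pass": self.overall_pass,
            "non_targeting": self.non_targeting.to_dict(orient="records"),
            "sentinels": self.sentinels.to_dict(orient="records"),
        }


def classify_shrnas(
    fc: FoldChangeTable,
    library: ShRNALibrary,
    lfc_threshold: float = 1.0,
    min_consistency: float = 0.8,
) -> list[ShRNACall]:
    """Give every library shRNA exactly one call at the two-fold threshold.

    enriched  iff mean_lfc >= +lfc_threshold and consistency >= min_consistency
    depleted  iff mean_lfc <= -lfc_threshold and consistency >= min_consistency
    neutral   otherwise

    The boundary is inclusive ("at least two-fold"). min_consistency defaults
    to 0.8 — with 5 replicates, at least 4 of 5 agreeing in sign with the
    mean — and may be lowered to 0 to disable the consistency gate.
    """
    if lfc_threshold <= 0:
        raise ValueError("lfc_threshold must be > 0")
    if fc.consistency is None:
        raise ValueError("run replicate_consistency before classify_shrnas")
    calls = []
    for rec in library:
        if rec.shrna_id not in fc.mean_lfc.index:
            raise ValueError(f"library shRNA {rec.shrna_id!r} missing from fold-change table")
        m = float(fc.mean_lfc[rec.shrna_id])
        c = float(fc.consistency[rec.shrna_id])
        if m >= lfc_threshold and c >= min_consistency:
            call = "enriched"
        elif m <= -lfc_threshold and c >= min_consistency:
            call = "depleted"
        else:
            call = "neutral"
        calls.append(
            ShRNACall(
                shrna_id=rec.shrna_id,
                gene=rec.gene,
                control_class=rec.control_class,
                mean_lfc=m,
                consistency=c,
                call=call,
            )
        )
    return calls


def call_gene_hits(
    calls: list[ShRNACall],
    library: ShRNALibrary,
    min_shrnas_per_gene: int = 2,
) -> GeneHitTable:
    """Aggregate shRNA calls to gene-level hits.

    A gene is hit_enriched when >= min_shrnas_per_gene of its shRNAs are
    enriched (hit_depleted symmetrically). Opposite-direction support never
    combines; a gene clearing the bar in both directions is called none and
    flagged discordant. Non-targeting records carry no gene and are excluded.
    Rows are ranked by n_enriched, then the mean mean_lfc of the supporting
    shRNAs, descending.
    """
    by_gene = library.by_gene()
    call_by_id = {c.shrna_id: c for c in calls}
    missing = [r.shrna_id for r in library if r.shrna_id not in call_by_id]
    if missing:
        raise ValueError(f"calls do not cover the library; missing {missing[:5]}")
    rows = []
    for gene, recs in by_gene.items():
        gene_calls = [call_by_id[r.shrna_id] for r in recs]
        enriched = [c for c in gene_calls if c.call == "enriched"]
        depleted = [c for c in gene_calls if c.call == "depleted"]
        up = len(enriched) >= min_shrnas_per_gene
        down = len(depleted) >= min_shrnas_per_gene
        discordant = up and down
        if discordant:
            gene_call, supporters = "none", []
        elif up:
            gene_call, supporters = "hit_enriched", enriched
        elif down:
            gene_call, supporters = "hit_depleted", depleted
        else:
            gene_call, supporters = "none", []
        support_lfc = (
            sum(c.mean_lfc for c in supporters) / len(supporters) if supporters else float("nan")
        )
        rows.append(
            {
                "gene": gene,
                "n_shrnas_total": len(recs),
                "n_enriched": len(enriched),
                "n_depleted": len(depleted),
                "gene_call": gene_call,
                "discordant": discordant,
                "supporting_shrnas": ",".join(c.shrna_id for c in supporters),
                "support_mean_lfc": support_lfc,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["n_enriched", "support_mean_lfc", "gene"],
        ascending=[False, False, True],
        na_position="last",
    ).reset_index(drop=True)
    return GeneHitTable(table=table, min_shrnas_per_gene=min_shrnas_per_gene)


def control_qc(
    calls: list[ShRNACall],
    library: ShRNALibrary,
    lfc_threshold: float = 1.0,
) -> ControlQCReport:
    """QC the screen on its internal controls.

    Warns (and passes trivially) when the library annotates no controls.
    """
    call_by_id = {c.shrna_id: c for c in calls}
    nt = library.controls("non_targeting")
    sent = library.controls("sentinel_depletion")
    if not nt and not sent:
        warnings.warn("library annotates no control shRNAs; QC is trivially empty-pass")
    nt_rows = [
        {
            "shrna_id": r.shrna_id,
            "mean_lfc": call_by_id[r.shrna_id].mean_lfc,
            "pass": abs(call_by_id[r.shrna_id].mean_lfc) < lfc_threshold,
        }
        for r in nt
    ]
    sent_rows = [
        {
            "shrna_id": r.shrna_id,
            "mean_lfc": call_by_id[r.shrna_id].mean_lfc,
            "pass": call_by_id[r.shrna_id].mean_lfc <= -lfc_threshold,
        }
        for r in sent
    ]
    cols = ["shrna_id", "mean_lfc", "pass"]
    return ControlQCReport(
        non_targeting=pd.DataFrame(nt_rows, columns=cols),
        sentinels=pd.DataFrame(sent_rows, columns=cols),
        lfc_threshold=lfc_threshold,
    )


def calls_to_frame(calls: list[ShRNACall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def write_hit_tables(
    calls: list[ShRNACall],
    gene_hits: GeneHitTable,
    qc: ControlQCReport,
    out_dir: str | Path,
) -> None:
    """Write shrna_calls.tsv, gene_hits.tsv, qc_report.tsv and qc_report.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls_to_frame(calls).to_csv(out_dir / "shrna_calls.tsv", sep="\t", index=False)
    gene_hits.table.to_csv(out_dir / "gene_hits.tsv", sep="\t", index=False)
    qc_long = pd.concat(
        [
            qc.non_targeting.assign(control_class="non_targeting"),
            qc.sentinels.assign(control_class="sentinel_depletion"),
        ],
        ignore_index=True,
    )
    qc_long.to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    with open(out_dir / "qc_report.json", "w") as fh:
        json.dump(qc.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
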