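"""Cross-species differential-expression concordance.

Mouse and human knockdown experiments are analyzed separately (upstream, by
any DE engine producing gene / log2fc / pvalue / padj tables); this module
implements the downstream concordance procedure: prefilter low-count genes
(mean raw count < 10 across samples removed), keep significant genes
(adjusted p < 0.1 by default, or raw p < 0.05 as the alternate variant, with
|log2FC| > 1 — all inequalities strict as worded), map mouse symbols to
human orthologs, and partition the ortholog pairs significant in both
species into same-direction (counted) and discordant (reported, excluded)
sets. A seeded generator plants a known concordant structure into synthetic
DE tables so the whole procedure is testable without any real dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DE_COLUMNS",
    "OverlapResult",
    "validate_de_table",
    "read_de_table",
    "read_ortholog_map",
    "prefilter_counts",
    "filter_deg",
    "overlap_orthologs",
    "generate_synthetic_de",
]

DE_COLUMNS = ["gene", "log2fc", "pvalue", "padj"]
ORTHOLOG_COLUMNS = ["mouse_symbol", "human_symbol"]


def validate_de_table(de: pd.DataFrame, require_padj: bool = False) -> pd.DataFrame:
    """Check a DE result table: required columns, unique genes, finite log2fc."""
    missing = [c for c in ("gene", "log2fc", "pvalue") if c not in de.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if require_padj and "padj" not in de.columns:
        raise ValueError("DE table has no padj column but use_padj was requested")
    if de["gene"].duplicated().any():
        dups = de.loc[de["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene symbols in DE table: {dups[:5]}")
    if not np.isfinite(de["log2fc"]).all():
        raise ValueError("non-finite log2fc in DE table")
    return de


def read_de_table(path: str | Path) -> pd.DataFrame:
    return validate_de_table(pd.read_csv(path, sep="\t"))


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ortholog map missing columns: {missing}")
    return df


def prefilter_counts(count_table: pd.DataFrame, min_mean: float = 10.0) -> pd.DataFrame:
    """Drop genes whose mean raw count across samples is below min_mean.

    The cut is strict — a gene at exactly the threshold is retained ("less
    than ten" removes only means < 10). Rows index genes, columns samples.
    """
    if count_table.shape[1] == 0:
        raise ValueError("count table has no sample columns")
    if (count_table.to_numpy() < 0).any():
        raise ValueError("negative raw counts")
    return count_table[count_table.mean(axis=1) >= min_mean]


def filter_deg(
    de: pd.DataFrame,
    alpha: float = 0.1,
    lfc_cut: float = 1.0,
    use_padj: bool = True,
) -> pd.DataFrame:
    """Keep significant rows and annotate direction.

    A row survives iff (padj if use_padj else pvalue) < alpha and
    |log2fc| > lfc_cut — both strict. Direction is up for positive log2fc,
    down for negative. Idempotent: filtering a filtered table is a no-op.
    The defaults are the adjusted-p variant (padj < 0.1, |log2FC| > 1); pass
    use_padj=False with alpha=0.05 for the raw-p variant.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if lfc_cut <= 0:
        raise ValueError("lfc_cut must be > 0")
    de = validate_de_table(de, require_padj=use_padj)
    p = de["padj"] if use_padj else de["pvalue"]
    keep = (p < alpha) & (de["log2fc"].abs() > lfc_cut)
    out = de.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


@dataclass
class OverlapResult:
    """Concordant ortholog pairs between a mouse and a human DE table.

    ``pairs`` lists one (mouse_symbol, human_symbol, direction) row per
    overlapping mouse gene; ``discordant`` lists pairs significant in both
    species with opposite direction (excluded from n_overlap);
    ``collapsed`` logs alternative human symbols dropped by the
    one-pair-per-mouse-gene tie-break. n_overlap == n_up + n_down always.
    """

    pairs: pd.DataFrame
    discordant: pd.DataFrame
    collapsed: pd.DataFrame
    n_overlap: int = field(init=False)
    n_up: int = field(init=False)
    n_down: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_up = int((self.pairs["direction"] == "up").sum())
        self.n_down = int((self.pairs["direction"] == "down").sum())
        self.n_overlap = len(self.pairs)
        assert self.n_overlap == self.n_up + self.n_down

    def summary(self) -> dict:
        return {
            "n_overlap": self.n_overlap,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_discordant": len(self.discordant),
        }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(out_dir / "overlap.tsv", sep="\t", index=False)
        self.discordant.to_csv(out_dir / "discordant.tsv", sep="\t", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


_PAIR_COLUMNS = ["mouse_symbol", "human_symbol", "direction"]


def overlap_orthologs(
    de_mouse_sig: pd.DataFrame,
    de_human_sig: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    mouse_col: str = "mouse_symbol",
    human_col: str = "human_symbol",
) -> OverlapResult:
    """Partition ortholog pairs significant in both species by direction.

    Inputs must already be filtered by :func:`filter_deg` (they need the
    ``direction`` column). A pair contributes iff the genes are orthologs,
    both significant, and the directions agree; many-to-many orthology
    contributes at most one pair per mouse gene, tie-broken to the
    lexicographically smallest human symbol with the alternatives logged in
    ``collapsed``. Opposite-direction pairs are reported separately.
    """
    for name, de in (("mouse", de_mouse_sig), ("human", de_human_sig)):
        if "direction" not in de.columns:
            raise ValueError(f"{name} table lacks a direction column; run filter_deg first")
    m = de_mouse_sig[["gene", "direction"]].rename(
        columns={"gene": mouse_col, "direction": "direction_mouse"}
    )
    h = de_human_sig[["gene", "direction"]].rename(
        columns={"gene": human_col, "direction": "direction_human"}
    )
    joint = ortholog_map[[mouse_col, human_col]].merge(m, on=mouse_col).merge(h, on=human_col)

    concordant = joint[joint["direction_mouse"] == joint["direction_human"]].copy()
    discordant = joint[joint["direction_mouse"] != joint["direction_human"]].copy()
    concordant["direction"] = concordant["direction_mouse"]

    # one pair per mouse gene: lexicographically smallest human symbol wins
    concordant = concordant.sort_values([mouse_col, human_col], kind="stable")
    first = concordant.drop_duplicates(subset=mouse_col, keep="first")
    collapsed = concordant.loc[~concordant.index.isin(first.index)]

    pairs = (
        first.rename(columns={mouse_col: "mouse_symbol", human_col: "human_symbol"})[
            _PAIR_COLUMNS
        ].reset_index(drop=True)
    )
    discordant = discordant.rename(
        columns={mouse_col: "mouse_symbol", human_col: "human_symbol"}
    )[["mouse_symbol", "human_symbol", "direction_mouse", "direction_human"]].reset_index(
        drop=True
    )
    collapsed = collapsed.rename(
        columns={mouse_col: "mouse_symbol", human_col: "human_symbol"}
    )[_PAIR_COLUMNS].reset_index(drop=True)
    return OverlapResult(pairs=pairs, discordant=discordant, collapsed=collapsed)


def _mouse_symbol(i: int) -> str:
    return f"Gene{i:05d}"


def _human_symbol(i: int) -> str:
    return f"GENE{i:05d}"


def generate_synthetic_de(
    n_genes: int = 1000,
    n_up_concordant: int = 25,
    n_down_concordant: int = 83,
    n_mouse_only: int = 40,
    n_human_only: int = 40,
    effect_size: float = 2.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired synthetic mouse/human DE tables with a planted overlap structure.

    Planted concordant genes are significant in both species with matching
    sign (|log2fc| > 1, padj < 0.1 and pvalue < 0.05, so both threshold
    variants recover them); species-specific genes are significant in one
    table only; the remaining background genes are null in both. The
    ortholog map is 1:1 with the usual symbol-case conventions
    (mouse "Gene00001" <-> human "GENE00001").

    Returns (mouse table, human table, ortholog map, truth) where truth
    labels every gene's planted category.
    """
    n_planted = n_up_concordant + n_down_concordant + n_mouse_only + n_human_only
    if n_planted > n_genes:
        raise ValueError("planted subsets exceed n_genes")
    rng = np.random.default_rng(seed)

    categories = (
        ["up_concordant"] * n_up_concordant
        + ["down_concordant"] * n_down_concordant
        + ["mouse_only"] * n_mouse_only
        + ["human_only"] * n_human_only
        + ["null"] * (n_genes - n_planted)
    )
    order = rng.permutation(n_genes)
    truth = pd.DataFrame(
        {
            "mouse_symbol": [_mouse_symbol(i) for i in range(n_genes)],
            "human_symbol": [_human_symbol(i) for i in range(n_genes)],
            "category": [categories[j] for j in order],
        }
    )

    def _sig_lfc(n: int, sign: int | np.ndarray) -> np.ndarray:
        # strictly beyond the |log2fc| > 1 cut
        return sign * (1.0 + 0.05 + rng.exponential(effect_size - 1.0, size=n))

    def _sig_p(n: int) -> tuple[np.ndarray, np.ndarray]:
        padj = rng.uniform(1e-6, 0.04, size=n)
        pvalue = padj * rng.uniform(0.2, 1.0, size=n)
        return pvalue, padj

    def _null_stats(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lfc = np.clip(rng.normal(0.0, 0.3, size=n), -0.9, 0.9)
        padj = rng.uniform(0.2, 1.0, size=n)
        pvalue = padj * rng.uniform(0.3, 1.0, size=n)
        return lfc, pvalue, padj

    def _table(species: str) -> pd.DataFrame:
        cat = truth["category"].to_numpy()
        own = "mouse_only" if species == "mouse" else "human_only"
        n = n_genes
        lfc, pvalue, padj = _null_stats(n)
        sig = np.isin(cat, ["up_concordant", "down_concordant", own])
        n_sig = int(sig.sum())
        # species-specific genes get a random direction; concordant genes
        # share their planted sign between species
        signs = np.where(
            cat[sig] == "up_concordant",
            1,
            np.where(cat[sig] == "down_concordant", -1, rng.choice([-1, 1], size=n_sig)),
        )
        lfc[sig] = _sig_lfc(n_sig, signs)
        pvalue[sig], padj[sig] = _sig_p(n_sig)
        col = "mouse_symbol" if species == "mouse" else "human_symbol"
        return pd.DataFrame(
            {"gene": truth[col], "log2fc": lfc, "pvalue": pvalue, "padj": padj}
        )

    de_mouse = _table("mouse")
    de_human = _table("human")
    ortho = truth[["mouse_symbol", "human_symbol"]].copy()
    return de_mouse, de_human, ortho, truth
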