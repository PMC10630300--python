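import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import regenscreen as rs
from regenscreen.enrichment import FoldChangeTable
from regenscreen.hitcall import call_gene_hits, classify_shrnas, control_qc
from regenscreen.library import ShRNALibrary, ShRNARecord


def _fc_from_means(means: dict[str, float], consistency: float = 1.0) -> FoldChangeTable:
    """Fold-change table where every replicate equals the desired mean."""
    ids = list(means)
    lfc = pd.DataFrame(
        {f"rep_{i}": [means[s] for s in ids] for i in range(5)},
        index=pd.Index(ids, name="shrna_id"),
    )
    fc = FoldChangeTable(lfc=lfc, mean_lfc=lfc.mean(axis=1), n_replicates=5)
    fc.consistency = pd.Series(consistency, index=fc.mean_lfc.index)
    return fc


def _library(genes: dict[str, str], classes: dict[str, str] | None = None) -> ShRNALibrary:
    classes = classes or {}
    base = "ACGT" * 6
    records = []
    for i, (sid, gene) in enumerate(genes.items()):
        suffix = "ACGT"[i % 4] + "ACGT"[(i // 4) % 4] + "ACGT"[(i // 16) % 4]
        records.append(
            ShRNARecord(sid, gene, base[:19] + suffix, classes.get(sid, "targeting"))
        )
    return ShRNALibrary(records)


@pytest.mark.parametrize(
    "mean_lfc, consistency, expected",
    [
        (1.2, 1.0, "enriched"),
        (-1.2, 1.0, "depleted"),
        (0.99, 1.0, "neutral"),  # strict boundary at the two-fold threshold
        (1.0, 1.0, "enriched"),  # inclusive ("at least two-fold")
        (-1.0, 1.0, "depleted"),
        (1.5, 0.6, "neutral"),  # consistency gate
    ],
)
def test_shrna_classification_rules(mean_lfc, consistency, expected):
    lib = _library({"sh_X": "GeneX"})
    fc = _fc_from_means({"sh_X": mean_lfc}, consistency=consistency)
    (call,) = classify_shrnas(fc, lib, lfc_threshold=1.0, min_consistency=0.8)
    assert call.call == expected


@given(means=st.lists(st.floats(-4, 4, allow_nan=False), min_size=1, max_size=30))
@settings(deadline=None, max_examples=50)
def test_every_shrna_gets_exactly_one_call(means):
    lib = _library({f"sh_{i}": f"G{i}" for i in range(len(means))})
    fc = _fc_from_means({f"sh_{i}": m for i, m in enumerate(means)})
    calls = classify_shrnas(fc, lib, min_consistency=0.0)
    assert len(calls) == len(lib)
    assert all(c.call in ("enriched", "depleted", "neutral") for c in calls)


def test_raising_threshold_never_adds_calls():
    means = {f"sh_{i}": v for i, v in enumerate(np.linspace(-3, 3, 25))}
    lib = _library({s: f"G{i}" for i, s in enumerate(means)})
    fc = _fc_from_means(means)
    previous = None
    for threshold in (0.5, 1.0, 1.5, 2.0):
        calls = classify_shrnas(fc, lib, lfc_threshold=threshold, min_consistency=0.0)
        n_called = sum(c.call != "neutral" for c in calls)
        if previous is not None:
            assert n_called <= previous
        previous = n_called


def test_gene_needs_two_supporting_shrnas():
    lib = _library({"sh_1": "GeneA", "sh_2": "GeneA", "sh_3": "GeneA", "sh_4": "GeneB"})
    fc = _fc_from_means({"sh_1": 1.5, "sh_2": 1.2, "sh_3": 0.1, "sh_4": 3.0})
    calls = classify_shrnas(fc, lib, min_consistency=0.0)
    hits = call_gene_hits(calls, lib).table.set_index("gene")
    assert hits.loc["GeneA", "gene_call"] == "hit_enriched"
    assert hits.loc["GeneA", "n_enriched"] == 2
    assert hits.loc["GeneA", "supporting_shrnas"] == "sh_1,sh_2"
    # a single shRNA at +3 is never enough
    assert hits.loc["GeneB", "gene_call"] == "none"


def test_opposite_directions_never_combine():
    lib = _library({f"sh_{i}": "GeneA" for i in range(4)})
    fc = _fc_from_means({"sh_0": 1.5, "sh_1": 1.4, "sh_2": -1.5, "sh_3": -1.4})
    calls = classify_shrnas(fc, lib, min_consistency=0.0)
    row = call_gene_hits(calls, lib).table.set_index("gene").loc["GeneA"]
    assert row["gene_call"] == "none"
    assert bool(row["discordant"])


def test_planted_screen_ranks_hit_gene_first():
    """Default simulated scenario: the 4-hairpin advantaged gene tops the
    ranking with all four hairpins enriched."""
    cfg = rs.SimConfig(seed=11)
    cm, lib, manifest, _ = rs.simulate_counts(cfg)
    fc = rs.replicate_consistency(rs.log2_fold_change(rs.relative_abundance(cm), manifest))
    calls = rs.classify_shrnas(fc, lib)
    table = rs.call_gene_hits(calls, lib).table
    assert table.iloc[0]["gene"] == "Mfap4"
    assert table.iloc[0]["n_enriched"] == 4
    assert table.iloc[0]["gene_call"] == "hit_enriched"


def test_control_qc_rules():
    lib = _library(
        {"sh_nc1": "", "sh_nc2": "", "sh_s1": "Met", "sh_s2": "Met", "sh_s3": "Met"},
        classes={
            "sh_nc1": "non_targeting",
            "sh_nc2": "non_targeting",
            "sh_s1": "sentinel_depletion",
            "sh_s2": "sentinel_depletion",
            "sh_s3": "sentinel_depletion",
        },
    )
    fc = _fc_from_means(
        {"sh_nc1": 0.1, "sh_nc2": -0.2, "sh_s1": -1.5, "sh_s2": -2.0, "sh_s3": -1.2}
    )
    calls = classify_shrnas(fc, lib, min_consistency=0.0)
    qc = control_qc(calls, lib, lfc_threshold=1.0)
    assert qc.non_targeting["pass"].all()
    assert qc.sentinels["pass"].all()
    assert qc.overall_pass


def test_sentinel_that_fails_to_deplete_fails_qc():
    lib = _library({"sh_s1": "Met"}, classes={"sh_s1": "sentinel_depletion"})
    fc = _fc_from_means({"sh_s1": 0.5})
    qc = control_qc(classify_shrnas(fc, lib, min_consistency=0.0), lib)
    assert not qc.sentinels["pass"].any()
    assert not qc.overall_pass


def test_qc_without_controls_warns_and_passes():
    lib = _library({"sh_1": "GeneA"})
    fc = _fc_from_means({"sh_1": 0.0})
    calls = classify_shrnas(fc, lib, min_consistency=0.0)
    with pytest.warns(UserWarning, match="no control"):
        qc = control_qc(calls, lib)
    assert qc.overall_pass
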