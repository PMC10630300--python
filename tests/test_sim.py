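import dataclasses

import numpy as np
import pytest

import regenscreen as rs
from regenscreen.library import SampleEntry, SampleManifest
from regenscreen.quantify import count_shrnas, counts_from_arrays
from regenscreen.sim import (
    SimConfig,
    default_fitness,
    emit_fastq,
    expected_log2_enrichment,
    initialize_population,
    make_default_library,
    make_manifest,
    run_damage_cycles,
    sample_sequencing,
    simulate_counts,
)


def _det(**kw) -> SimConfig:
    return SimConfig(stochastic=False, **kw)


def test_default_library_structure(rng):
    cfg = SimConfig()
    lib = make_default_library(cfg, rng)
    assert len(lib) == 253
    by_gene = lib.by_gene()
    assert len(by_gene["Mfap4"]) == 4
    assert len(by_gene["Met"]) == 3
    assert len(lib.controls("non_targeting")) == 2
    background = {g: len(v) for g, v in by_gene.items() if g not in ("Mfap4", "Met")}
    assert all(2 <= n <= 4 for n in background.values())
    w = default_fitness(lib, cfg)
    assert {w[r.shrna_id] for r in by_gene["Mfap4"]} == {1.1}
    assert {w[r.shrna_id] for r in by_gene["Met"]} == {0.9}
    assert all(w[r.shrna_id] == 1.0 for r in lib.controls("non_targeting"))


@pytest.mark.parametrize(
    "pool_freq, n_cells, expected",
    [([0.5, 0.5], 100, [50, 50]), ([0.9, 0.1], 1000, [900, 100])],
)
def test_deterministic_initialization_is_proportional(rng, pool_freq, n_cells, expected):
    cfg = _det(n_shrnas=2, n_hit_shrnas=1, n_non_targeting=0, n_sentinel_shrnas=1,
               n_cells=n_cells, guide_length=8)
    lib = make_default_library(cfg, rng)
    pop = initialize_population(cfg, lib, rng, np.array(pool_freq))
    assert np.allclose(pop.cell_counts, expected)


def test_stochastic_initialization_reproducible():
    cfg = SimConfig(n_cells=1000)
    lib = make_default_library(cfg, np.random.default_rng(7))
    a = initialize_population(cfg, lib, np.random.default_rng(42))
    b = initialize_population(cfg, lib, np.random.default_rng(42))
    assert np.array_equal(a.cell_counts, b.cell_counts)


def test_one_deterministic_cycle_closed_form(rng):
    cfg = _det(n_shrnas=2, n_hit_shrnas=1, n_non_targeting=0, n_sentinel_shrnas=1,
               n_cycles=1, n_cells=1000, guide_length=8)
    lib = make_default_library(cfg, rng)
    pop = initialize_population(cfg, lib, rng, np.array([0.5, 0.5]))
    out = run_damage_cycles(pop, cfg, np.array([2.0, 1.0]), rng)
    assert np.allclose(out.frequencies, [2 / 3, 1 / 3])


def test_neutral_fitness_leaves_frequencies_unchanged(rng):
    cfg = _det(n_shrnas=5, n_hit_shrnas=1, n_non_targeting=1, n_sentinel_shrnas=1,
               n_cycles=17, kill_fraction=0.45, guide_length=8)
    lib = make_default_library(cfg, rng)
    start = np.array([0.4, 0.3, 0.15, 0.1, 0.05])
    pop = initialize_population(cfg, lib, rng, start)
    out = run_damage_cycles(pop, cfg, np.ones(5), rng)
    assert np.allclose(out.frequencies, start, atol=1e-12)


def test_deterministic_cycles_match_closed_form_everywhere(rng):
    """freq_s(c) proportional to freq_s(0) * w_s**c, to 1e-12, for random
    fitness maps and several cycle counts."""
    for n_cycles in (1, 5, 24):
        n = 20
        cfg = _det(n_shrnas=n, n_hit_shrnas=2, n_non_targeting=2, n_sentinel_shrnas=2,
                   n_cycles=n_cycles, guide_length=10)
        lib = make_default_library(cfg, rng)
        w = rng.uniform(0.8, 1.25, size=n)
        f0 = rng.dirichlet(np.ones(n))
        pop = initialize_population(cfg, lib, rng, f0)
        out = run_damage_cycles(pop, cfg, w, rng)
        closed = f0 * w**n_cycles
        closed /= closed.sum()
        assert np.allclose(out.frequencies, closed, atol=1e-12)
        # the same closed form expressed as log2 enrichment
        lfc = expected_log2_enrichment(w, n_cycles, f0)
        assert np.allclose(np.log2(out.frequencies / f0), lfc, atol=1e-9)


def test_extinction_raises_helpful_error(rng):
    cfg = SimConfig(n_shrnas=3, n_hit_shrnas=1, n_non_targeting=1, n_sentinel_shrnas=1,
                    n_cells=5, n_cycles=50, kill_fraction=0.99, guide_length=8)
    lib = make_default_library(cfg, rng)
    pop = initialize_population(cfg, lib, np.random.default_rng(0))
    with pytest.raises(ValueError, match="n_cells"):
        run_damage_cycles(pop, cfg, np.ones(3), np.random.default_rng(0))


def test_sample_sequencing_modes():
    assert np.array_equal(
        sample_sequencing(np.array([0.5, 0.5]), 10, stochastic=False), [5, 5]
    )
    assert np.array_equal(
        sample_sequencing(np.array([0.3, 0.7]), 0, stochastic=False), [0, 0]
    )
    a = sample_sequencing(np.array([0.2, 0.8]), 1000, np.random.default_rng(5))
    b = sample_sequencing(np.array([0.2, 0.8]), 1000, np.random.default_rng(5))
    assert np.array_equal(a, b)


def test_deterministic_sequencing_sums_to_depth(rng):
    for _ in range(20):
        f = rng.dirichlet(np.ones(rng.integers(2, 40)))
        depth = int(rng.integers(1, 10_000))
        counts = sample_sequencing(f, depth, stochastic=False)
        assert counts.sum() == depth
        assert (counts >= 0).all()


def test_replicates_are_independent_in_stochastic_mode():
    cfg = SimConfig(n_cells=2000, pool_depth=5000, replicate_depth=5000, seed=9)
    cm, _, manifest, _ = simulate_counts(cfg)
    reps = cm.counts[manifest.replicate_ids]
    assert not reps["mouse_1"].equals(reps["mouse_2"])


def test_deterministic_replicates_are_identical():
    cfg = SimConfig(stochastic=False, pool_depth=5000, replicate_depth=5000, seed=9)
    cm, _, manifest, _ = simulate_counts(cfg)
    reps = cm.counts[manifest.replicate_ids]
    for rep in manifest.replicate_ids[1:]:
        assert reps[rep].equals(reps["mouse_1"])


def test_same_seed_reproduces_whole_screen():
    a = simulate_counts(SimConfig(pool_depth=3000, replicate_depth=3000, seed=123))[0]
    b = simulate_counts(SimConfig(pool_depth=3000, replicate_depth=3000, seed=123))[0]
    assert a == b


def test_fastq_round_trip_small(tmp_path, tiny_library, small_manifest):
    cm = counts_from_arrays(
        np.array([[3, 0, 0], [0, 2, 0], [0, 0, 1]]),
        tiny_library.shrna_ids,
        small_manifest.sample_ids,
    )
    fq = tmp_path / "reads.fq"
    emit_fastq(cm, tiny_library, small_manifest, fq, rng=np.random.default_rng(1))
    recovered = count_shrnas(fq, tiny_library, small_manifest, guide_offset=30)
    assert recovered.counts.equals(cm.counts)
    assert recovered.undemuxed == 0 and recovered.unassigned.sum() == 0


def test_fastq_with_certain_errors_goes_unassigned(tmp_path, tiny_library, small_manifest):
    cm = counts_from_arrays(
        np.array([[5, 0, 0], [0, 0, 0], [0, 0, 0]]),
        tiny_library.shrna_ids,
        small_manifest.sample_ids,
    )
    fq = tmp_path / "reads.fq"
    emit_fastq(
        cm, tiny_library, small_manifest, fq, error_rate=1.0, rng=np.random.default_rng(2)
    )
    recovered = count_shrnas(fq, tiny_library, small_manifest, guide_offset=30)
    assert recovered.counts.to_numpy().sum() == 0
    assert recovered.total_reads == 5


def test_end_to_end_truth_equals_quantification(tmp_path):
    """Generator bookkeeping is the oracle: at error rate 0 the counts
    recovered from FASTQ equal the emitted composition exactly."""
    cfg = SimConfig(n_shrnas=30, n_hit_shrnas=4, n_non_targeting=2, n_sentinel_shrnas=3,
                    n_cells=2000, pool_depth=2000, replicate_depth=2000,
                    n_replicates=3, seed=5)
    rng = np.random.default_rng(cfg.seed)
    cm, lib, manifest, _ = simulate_counts(cfg, rng=rng)
    fq = tmp_path / "reads.fq.gz"
    emit_fastq(cm, lib, manifest, fq, guide_offset=cfg.guide_offset, rng=rng)
    recovered = count_shrnas(fq, lib, manifest, guide_offset=cfg.guide_offset)
    assert recovered.counts.equals(cm.counts)


def test_config_yaml_round_trip(tmp_path):
    p = tmp_path / "sim.yaml"
    p.write_text("n_shrnas: 40\nn_cycles: 6\nkill_fraction: 0.2\nseed: 77\n")
    cfg = SimConfig.from_yaml(p)
    assert cfg.n_shrnas == 40 and cfg.n_cycles == 6 and cfg.seed == 77
    assert cfg.n_replicates == 5  # untouched defaults


@pytest.mark.parametrize(
    "field, value",
    [("kill_fraction", 1.0), ("transduced_fraction", 0.0), ("n_cells", 0),
     ("pool_depth", -1)],
)
def test_invalid_config_rejected(field, value):
    with pytest.raises(ValueError):
        dataclasses.replace(SimConfig(), **{field: value}).validate()
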