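"""Synthetic chimeric-liver screen: clonal competition under damage and
regeneration cycles, with sequencing readout down to FASTQ.

The generator emulates a pooled in vivo RNAi screen in a chronically damaged
liver. A transposon library is delivered hydrodynamically so that ~10% of
hepatocytes stably integrate one hairpin each; repeated hepatotoxin dosing
(three damage events per week for eight weeks, hence the 24-cycle default)
kills a fraction of hepatocytes per cycle and the surviving clones
repopulate the organ. Selection acts at regrowth: a clone's share of the
repopulated compartment is proportional to survivors x fitness w, so a
hairpin whose knockdown enhances regeneration (w > 1) expands and one that
impairs it (w < 1) drops out. In deterministic mode this has the closed form

    freq_s(c)  proportional to  freq_s(0) * w_s**c

after c cycles — the oracle for the stochastic mode, which uses binomial
thinning and multinomial repopulation/sequencing throughout.

The default scenario mirrors the structure of the screen it emulates:
253 hairpins, 5 replicate mice plus the sequenced starting pool, one
4-hairpin hit gene at fitness 1.1, two neutral non-targeting controls, and
a 3-hairpin depletion-sentinel gene at fitness 0.9.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .library import (
    SampleEntry,
    SampleManifest,
    ShRNALibrary,
    ShRNARecord,
    write_library,
    write_manifest,
)
from .quantify import CountMatrix, counts_from_arrays, write_counts

__all__ = [
    "SimConfig",
    "ClonePopulation",
    "make_default_library",
    "make_manifest",
    "default_fitness",
    "initialize_population",
    "run_damage_cycles",
    "sample_sequencing",
    "expected_log2_enrichment",
    "simulate_counts",
    "emit_fastq",
    "simulate_to_dir",
]

HIT_GENE = "Mfap4"
SENTINEL_GENE = "Met"

# constant amplicon flanks (miR30-like context); sliced to fill the read
# between barcode and guide and after the guide
_CONSTANT_5P = "TGCTGTTGACAGTGAGCGACTGTAAACATCCTACACTCAG"
_CONSTANT_3P = "TAGTGAAGCCACAGATGTAGCTGTCTGTGGAAG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of the simulated screen; defaults are the study conditions.

    n_cells is the number of transduced hepatocytes per mouse (the ~10%
    compartment is the only one sequencing sees, so untransduced cells are
    absorbed into the normalization); kill_fraction is the per-cycle loss to
    hepatotoxin damage; n_cycles = 3 damage events/week x 8 weeks.
    """

    n_shrnas: int = 253
    n_hit_shrnas: int = 4
    n_non_targeting: int = 2
    n_sentinel_shrnas: int = 3
    shrnas_per_gene: tuple[int, int] = (2, 4)
    n_replicates: int = 5
    transduced_fraction: float = 0.10
    n_cells: int = 100_000
    n_cycles: int = 24
    kill_fraction: float = 0.3
    hit_fitness: float = 1.1
    sentinel_fitness: float = 0.9
    pool_depth: int = 1_000_000
    replicate_depth: int = 1_000_000
    guide_length: int = 22
    barcode_length: int = 8
    guide_offset: int = 30
    error_rate: float = 0.0
    stochastic: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.transduced_fraction <= 1):
            raise ValueError("transduced_fraction must be in (0, 1]")
        if not (0 <= self.kill_fraction < 1):
            raise ValueError("kill_fraction must be in [0, 1)")
        if self.pool_depth < 0 or self.replicate_depth < 0:
            raise ValueError("sequencing depths must be >= 0")
        if self.n_cells <= 0 or self.n_shrnas <= 0:
            raise ValueError("n_cells and n_shrnas must be positive")
        lo, hi = self.shrnas_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("shrnas_per_gene must be an increasing positive range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "shrnas_per_gene" in data:
            data["shrnas_per_gene"] = tuple(data["shrnas_per_gene"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class ClonePopulation:
    """Per-hairpin clone sizes in one liver; counts are expected (float) in
    deterministic mode, integer cells in stochastic mode."""

    shrna_ids: list[str]
    cell_counts: np.ndarray
    cycle_index: int = 0

    @property
    def frequencies(self) -> np.ndarray:
        total = self.cell_counts.sum()
        if total <= 0:
            raise ValueError("population is extinct")
        return self.cell_counts / total


def _random_guides(n: int, length: int, rng: np.random.Generator) -> list[str]:
    guides: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        g = bytes(_BASES[rng.integers(0, 4, size=length)]).decode()
        if g not in guides:
            guides.add(g)
            out.append(g)
    return out


def make_default_library(cfg: SimConfig, rng: np.random.Generator) -> ShRNALibrary:
    """Build the default 253-hairpin library with planted controls.

    One hit gene with ``n_hit_shrnas`` hairpins, ``n_non_targeting`` shNC
    controls, one sentinel gene with ``n_sentinel_shrnas`` hairpins, and the
    remaining hairpins spread over background genes with 2-4 hairpins each.
    """
    cfg.validate()
    guides = iter(_random_guides(cfg.n_shrnas, cfg.guide_length, rng))
    records: list[ShRNARecord] = []
    for i in range(cfg.n_hit_shrnas):
        records.append(
            ShRNARecord(f"sh{HIT_GENE}.{i + 1}", HIT_GENE, next(guides), "targeting")
        )
    for i in range(cfg.n_non_targeting):
        records.append(ShRNARecord(f"shNC.{i + 1}", "", next(guides), "non_targeting"))
    for i in range(cfg.n_sentinel_shrnas):
        records.append(
            ShRNARecord(
                f"sh{SENTINEL_GENE}.{i + 1}", SENTINEL_GENE, next(guides), "sentinel_depletion"
            )
        )
    remaining = cfg.n_shrnas - len(records)
    if remaining < 0:
        raise ValueError("n_shrnas smaller than the planted controls")
    lo, hi = cfg.shrnas_per_gene
    gene_idx = 0
    while remaining > 0:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, remaining)
        if remaining - k == 1 and remaining - k < lo:  # avoid orphan singleton at the end
            k = remaining
        gene_idx += 1
        gene = f"Gene{gene_idx:03d}"
        for i in range(k):
            records.append(ShRNARecord(f"sh{gene}.{i + 1}", gene, next(guides), "targeting"))
        remaining -= k
    return ShRNALibrary(records)


def make_manifest(cfg: SimConfig, rng: np.random.Generator) -> SampleManifest:
    """Starting pool plus ``n_replicates`` mice, each with a random barcode."""
    n = cfg.n_replicates + 1
    barcodes = _random_guides(n, cfg.barcode_length, rng)
    entries = [SampleEntry(barcodes[0], "pool", "reference_pool")]
    for i in range(cfg.n_replicates):
        entries.append(SampleEntry(barcodes[i + 1], f"mouse_{i + 1}", "replicate"))
    return SampleManifest(entries)


def default_fitness(library: ShRNALibrary, cfg: SimConfig) -> dict[str, float]:
    """Planted fitness map: hit gene advantaged, sentinels disadvantaged,
    everything else (including non-targeting) neutral."""
    w = {}
    for r in library:
        if r.gene == HIT_GENE:
            w[r.shrna_id] = cfg.hit_fitness
        elif r.control_class == "sentinel_depletion":
            w[r.shrna_id] = cfg.sentinel_fitness
        else:
            w[r.shrna_id] = 1.0
    return w


def _fitness_array(library: ShRNALibrary, fitness: dict[str, float]) -> np.ndarray:
    unknown = set(fitness) - set(library.shrna_ids)
    if unknown:
        raise ValueError(f"fitness keys not in library: {sorted(unknown)[:5]}")
    w = np.array([fitness.get(s, 1.0) for s in library.shrna_ids], dtype=float)
    if (w < 0).any():
        raise ValueError("fitness must be >= 0")
    return w


def initialize_population(
    cfg: SimConfig,
    library: ShRNALibrary,
    rng: np.random.Generator,
    pool_freq: np.ndarray | None = None,
) -> ClonePopulation:
    """Seed one mouse's transduced compartment from the pool frequencies.

    Multinomial draw of n_cells in stochastic mode; exact proportional split
    in deterministic mode.
    """
    cfg.validate()
    if pool_freq is None:
        pool_freq = np.full(len(library), 1.0 / len(library))
    pool_freq = np.asarray(pool_freq, dtype=float)
    if pool_freq.shape != (len(library),):
        raise ValueError("pool_freq length must match library size")
    if cfg.stochastic:
        counts = rng.multinomial(cfg.n_cells, pool_freq).astype(float)
    else:
        counts = cfg.n_cells * pool_freq
    return ClonePopulation(shrna_ids=library.shrna_ids, cell_counts=counts)


def run_damage_cycles(
    pop: ClonePopulation,
    cfg: SimConfig,
    fitness: np.ndarray | dict[str, float],
    rng: np.random.Generator,
) -> ClonePopulation:
    """Apply n_cycles of damage (nonselective kill) and fitness-weighted
    regeneration back to the pre-kill total.

    Stochastic: binomial thinning with survival 1 - kill_fraction, then a
    multinomial repopulation with clone probabilities proportional to
    survivors x w. Deterministic: exact scaling, which telescopes to
    freq_s(c) proportional to freq_s(0) * w_s**c (the kill cancels).
    """
    if isinstance(fitness, dict):
        ids = pop.shrna_ids
        fitness = np.array([fitness.get(s, 1.0) for s in ids], dtype=float)
    w = np.asarray(fitness, dtype=float)
    counts = pop.cell_counts.astype(float).copy()
    total = counts.sum()
    if total <= 0:
        raise ValueError("population is extinct before cycling")
    for _ in range(cfg.n_cycles):
        if cfg.stochastic:
            survivors = rng.binomial(counts.astype(np.int64), 1.0 - cfg.kill_fraction)
            weights = survivors * w
            wsum = weights.sum()
            if wsum <= 0:
                raise ValueError(
                    "all clones went extinct during damage cycles; "
                    "increase n_cells or lower kill_fraction"
                )
            counts = rng.multinomial(int(total), weights / wsum).astype(float)
        else:
            weights = counts * w
            counts = total * weights / weights.sum()
    return ClonePopulation(
        shrna_ids=pop.shrna_ids,
        cell_counts=counts if not cfg.stochastic else counts.astype(float),
        cycle_index=pop.cycle_index + cfg.n_cycles,
    )


def sample_sequencing(
    frequencies: np.ndarray,
    depth: int,
    rng: np.random.Generator | None = None,
    stochastic: bool = True,
) -> np.ndarray:
    """Sequence a population: multinomial reads at the given depth.

    Deterministic mode returns the rounded expectation with largest-remainder
    rounding so the counts always sum exactly to depth.
    """
    f = np.asarray(frequencies, dtype=float)
    if depth == 0:
        return np.zeros(len(f), dtype=np.int64)
    if stochastic:
        if rng is None:
            raise ValueError("stochastic sequencing needs an rng")
        return rng.multinomial(depth, f / f.sum()).astype(np.int64)
    expected = depth * f / f.sum()
    base = np.floor(expected).astype(np.int64)
    shortfall = depth - int(base.sum())
    if shortfall > 0:
        remainder = expected - base
        # largest remainders get the leftover reads; ties to the lowest index
        top = np.argsort(-remainder, kind="stable")[:shortfall]
        base[top] += 1
    return base


def expected_log2_enrichment(
    fitness: np.ndarray, n_cycles: int, pool_freq: np.ndarray | None = None
) -> np.ndarray:
    """Closed-form per-hairpin log2 fold change after n_cycles of
    deterministic selection: log2(w**c / Z), Z = sum_s f0_s * w_s**c."""
    w = np.asarray(fitness, dtype=float)
    if pool_freq is None:
        pool_freq = np.full(len(w), 1.0 / len(w))
    growth = w**n_cycles
    z = float((pool_freq * growth).sum())
    return np.log2(growth / z)


def simulate_counts(
    cfg: SimConfig,
    library: ShRNALibrary | None = None,
    manifest: SampleManifest | None = None,
    fitness: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, ShRNALibrary, SampleManifest, pd.DataFrame]:
    """Run the whole in-silico screen and return sequenced counts.

    The starting pool is sequenced directly from the (uniform) plasmid pool
    frequencies at pool_depth; each replicate mouse is seeded independently,
    run through the damage-regeneration cycles, and sequenced at
    replicate_depth. Each replicate uses an independent child generator, so
    replicate trajectories are independent given the master seed.

    Returns (counts, library, manifest, truth) where truth carries per-shRNA
    fitness and the planted role of every hairpin.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if library is None:
        library = make_default_library(cfg, rng)
    if manifest is None:
        manifest = make_manifest(cfg, rng)
    if len(manifest.replicate_ids) != cfg.n_replicates:
        raise ValueError("manifest replicate count disagrees with config")
    if fitness is None:
        fitness = default_fitness(library, cfg)
    w = _fitness_array(library, fitness)

    pool_freq = np.full(len(library), 1.0 / len(library))
    columns = {}
    pool_rng = rng.spawn(1)[0]
    columns[manifest.pool_id] = sample_sequencing(
        pool_freq, cfg.pool_depth, pool_rng, cfg.stochastic
    )
    for rep_id, rep_rng in zip(manifest.replicate_ids, rng.spawn(cfg.n_replicates)):
        pop = initialize_population(cfg, library, rep_rng, pool_freq)
        pop = run_damage_cycles(pop, cfg, w, rep_rng)
        columns[rep_id] = sample_sequencing(
            pop.frequencies, cfg.replicate_depth, rep_rng, cfg.stochastic
        )

    counts = pd.DataFrame(columns, index=pd.Index(library.shrna_ids, name="shrna_id"))
    cm = counts_from_arrays(counts[manifest.sample_ids])
    truth = library.to_frame()
    truth["fitness"] = [fitness.get(s, 1.0) for s in truth["shrna_id"]]
    return cm, library, manifest, truth


def _mutate(read: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    hits = rng.random(len(read)) < error_rate
    if hits.any():
        read = read.copy()
        # substitute with a uniformly random *different* base
        idx = np.nonzero(hits)[0]
        for i in idx:
            choices = _BASES[_BASES != read[i]]
            read[i] = rng.choice(choices)
    return read


def emit_fastq(
    cm: CountMatrix,
    library: ShRNALibrary,
    manifest: SampleManifest,
    path: str | Path,
    guide_offset: int = 30,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    shuffle: bool = True,
) -> None:
    """Write one amplicon read per count: barcode + constant + guide + constant.

    Reads use constant Phred 'I' qualities; substitution errors are applied
    per base at ``error_rate``. Output is gzipped when the path ends in .gz
    (with a fixed mtime so identical inputs give identical bytes). The
    emitted composition is exactly ``cm.counts`` (unassigned/undemuxed
    tallies are not materialized as reads).
    """
    path = Path(path)
    blen = manifest.barcode_length
    filler5 = _CONSTANT_5P[: guide_offset - blen]
    if len(filler5) < guide_offset - blen:
        raise ValueError("guide_offset too large for the constant region")
    bc = manifest.barcode_to_sample
    sample_to_bc = {v: k for k, v in bc.items()}
    guide_by_id = {r.shrna_id: r.guide_seq for r in library}

    templates = []
    reps = []
    for sample in cm.sample_ids:
        barcode = sample_to_bc[sample]
        for shrna_id, n in cm.counts[sample].items():
            if n > 0:
                seq = barcode + filler5 + guide_by_id[shrna_id] + _CONSTANT_3P
                templates.append(seq)
                reps.append(int(n))
    order = np.repeat(np.arange(len(templates)), reps)
    if shuffle:
        if rng is None:
            rng = np.random.default_rng(0)
        order = rng.permutation(order)
    if error_rate > 0 and rng is None:
        rng = np.random.default_rng(0)

    opener = (
        (lambda p: gzip.GzipFile(p, "wb", mtime=0))
        if path.suffix == ".gz"
        else (lambda p: open(p, "wb"))
    )
    with opener(str(path)) as fh:
        for i, t_idx in enumerate(order):
            seq = templates[t_idx]
            if error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8)
                seq = bytes(_mutate(arr, error_rate, rng)).decode()
            qual = "I" * len(seq)
            fh.write(f"@read_{i}\n{seq}\n+\n{qual}\n".encode())


def write_truth(cm: CountMatrix, truth: pd.DataFrame, path: str | Path) -> None:
    """Long-format truth table: planted fitness plus the exact emitted
    per-(shRNA, sample) read composition."""
    long = (
        cm.counts.reset_index()
        .melt(id_vars="shrna_id", var_name="sample_id", value_name="reads")
        .merge(truth[["shrna_id", "gene", "control_class", "fitness"]], on="shrna_id")
    )
    long.to_csv(path, sep="\t", index=False)


def simulate_to_dir(
    cfg: SimConfig, out_dir: str | Path, write_fastq: bool = True
) -> dict[str, Path]:
    """Run the default scenario and write library.tsv, manifest.tsv,
    counts.tsv, truth.tsv and (optionally) reads.fq.gz under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    cm, library, manifest, truth = simulate_counts(cfg, rng=rng)
    paths = {
        "library": out_dir / "library.tsv",
        "manifest": out_dir / "manifest.tsv",
        "counts": out_dir / "counts.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_library(library, paths["library"])
    write_manifest(manifest, paths["manifest"])
    write_counts(cm, paths["counts"])
    write_truth(cm, truth, paths["truth"])
    if write_fastq:
        paths["reads"] = out_dir / "reads.fq.gz"
        emit_fastq(
            cm,
            library,
            manifest,
            paths["reads"],
            guide_offset=cfg.guide_offset,
            error_rate=cfg.error_rate,
            rng=rng,
        )
    return paths
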