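# Methods

## Screen readout model

The pipeline quantifies a pooled shRNA screen from single-end amplicon
reads laid out as `barcode (8 bp) | constant primer region | guide (22 nt)`.
Assignment is maximally strict: a read is demultiplexed only when its
leading bases equal a manifest barcode with zero mismatches, and counted
only when the guide region is a 100% match to a library guide. Strictness
is the design choice everywhere ambiguity existed — it makes counting
deterministic, order-independent and trivially conservative (every read
lands in exactly one cell, a per-sample unassigned tally, or the undemuxed
tally, and these sum to the total). Quality scores are ignored because a
sequencing error anywhere in the matched region already voids the match.
The guide's position in the read is configuration (default offset 30 =
8 bp barcode + 22 nt constant region), not inference; a scan mode that
accepts an exact guide occurrence anywhere in the read (leftmost wins) is
available for amplicon designs with variable spacers. Reverse-complement
matching is off by default since amplicon sequencing is single-orientation.

Enrichment of shRNA *s* in replicate *r* versus the sequenced starting
pool is

    lfc[s, r] = log2( f[s, r] / f[s, pool] )

with `f[s, j] = (n[s, j] + c) / Σ_s' (n[s', j] + c)` computed over library
shRNAs only — unassigned reads are excluded from the denominator because
relative abundance is defined among detected hairpins. The pseudocount
defaults to `c = 0.5`, standard screen practice that keeps every log fold
change finite when a hairpin drops to zero reads; at the default depth of
10⁶ reads over 253 hairpins (~4,000 reads each) its bias is negligible.
The per-shRNA score is the arithmetic mean of the per-replicate log2
values, i.e. the average of the per-animal log fold changes rather than
the log of a pooled frequency; this weights animals equally regardless of
depth. Replicate consistency is the fraction of replicates whose lfc
agrees in sign with the mean and clears a magnitude floor (default 0:
sign agreement only); shRNAs with mean exactly 0 get consistency 0.

## Hit calling

* shRNA call: enriched iff `mean_lfc ≥ +1` and `consistency ≥ 0.8`
  (≥ 4 of 5 replicates agreeing in sign); depleted symmetrically; neutral
  otherwise. The two-fold boundary is inclusive ("at least two-fold"),
  applied to the mean with the consistency gate as a separate criterion —
  the alternative reading (each replicate individually two-fold) is
  stricter and can be emulated with `consistency_floor = 1.0` and
  `min_consistency = 1.0`.
* Gene call: `hit_enriched` iff ≥ 2 independent shRNAs are enriched
  (`hit_depleted` symmetrically). Opposite-direction support never
  combines; a gene clearing the bar both ways is called `none` and
  flagged discordant. Genes are ranked by number of enriched hairpins,
  then the mean lfc of the supporters.
* QC: non-targeting controls pass when `|mean_lfc| < 1`; depletion
  sentinels pass when `mean_lfc ≤ −1`. QC failure is reported, never
  aborts hit calling — controls are confidence checks on the selection
  pressure, not gates.

## Clonal-competition simulator

The generator emulates the chimeric-liver experiment: hydrodynamic
delivery stably transduces ~10% of hepatocytes (only this compartment is
modeled — sequencing sees only integrated cassettes, so untransduced
cells cancel out of the normalization), and repeated hepatotoxin dosing
drives damage–regeneration cycles. Defaults are the study conditions:
253 hairpins (one 4-hairpin hit gene at fitness 1.1, two non-targeting
controls at 1.0, one 3-hairpin sentinel gene at 0.9, background genes
with 2–4 hairpins each), 5 replicate mice, 10⁵ transduced hepatocytes
per mouse, 24 cycles (3 damage events/week × 8 weeks), 30% of cells
killed per cycle, 10⁶ reads per sample. The per-cycle kill fraction and
effective population size in a real damaged liver are unknown; these are
order-of-magnitude choices exposed in `SimConfig`, and the tests are
phrased as parameter-recovery properties rather than matches to in vivo
numbers.

Each cycle kills cells nonselectively (binomial thinning at the kill
fraction) and regrows the compartment to its pre-kill size with clone
shares drawn multinomially with probability ∝ survivors × fitness — i.e.
selection acts at regeneration, matching the biology of nonselective
toxin injury followed by competitive repopulation. In deterministic mode
the kill cancels exactly and the model telescopes to the closed form

    freq_s(c) ∝ freq_s(0) · w_s^c ,

asserted to 1e-12 in tests and used as the oracle for the stochastic
mode (which adds multinomial transduction, drift across cycles and
multinomial sequencing noise). Deterministic sequencing resolves rounding
by largest remainder so counts always sum to the requested depth.
FASTQ emission writes one read per sequenced count with constant
miR30-like flanks and Phred 'I' qualities, optional per-base substitution
errors, and gzip output with fixed mtime so equal inputs give equal
bytes; the emitted composition is recorded as the ground truth.

What the simulator does not emulate: PCR amplification bias and jackpot
effects, sequencing quality degradation (errors are uniform
substitutions), spatial structure of liver lobules, variable transduction
efficiency between animals, and barcode cross-talk. Passing tests
therefore demonstrate correctness of the deconvolution and calling logic
under multinomial noise, not robustness to every artifact of real
amplicon data — the strict exact-match design deliberately shifts such
artifacts into the unassigned tally rather than into the counts.

At the default conditions the planted hit's expected signal is
`24·log2(1.1) − log2 Z ≈ 3.1` log2 units (Z the pool normalization),
roughly 12 standard deviations of the null drift of a replicate mean, so
planted-hit recovery is expected in essentially every seed while
all-neutral screens yield no gene-level hits; both properties are checked
over 20 seeds in the acceptance tests.

## Cross-species concordance

DE fitting itself is out of scope — the module consumes finished result
tables (gene, log2fc, pvalue, padj) from any upstream engine. Count
prefiltering removes genes with mean raw count below 10 across samples
(strict: a mean of exactly 10 is retained). Significance filtering keeps
rows with adjusted *p* < 0.1 and |log2FC| > 1 (all strict, as worded);
a raw *p* < 0.05 variant is supported because both conventions are in
circulation for the same analysis, and the choice is left to the caller.
Ortholog overlap counts mouse genes whose human ortholog is significant
in the same direction; many-to-many orthology contributes at most one
pair per mouse gene (tie-break: lexicographically smallest human symbol,
alternatives logged) so the tally is per-gene, not per-pair.
Opposite-direction pairs are reported separately and never counted. The
synthetic generator plants concordant genes that pass both threshold
variants simultaneously (padj < 0.04, p < 0.04 · U(0.2, 1), |lfc| > 1.05)
and clips null genes to |lfc| ≤ 0.9 with p ≥ 0.05·…, so planted-structure
recovery is exact by construction and deterministic per seed.

## Numerical and degenerate-input choices

* Validation is fail-fast with offender-naming errors: duplicate guides
  or ids, mixed guide lengths, zero/duplicate reference pools, barcode
  length mismatches, zero-total samples at pseudocount 0.
* Abundance columns are checked to sum to 1 within 1e-9.
* An all-extinct stochastic population raises with advice to increase
  `n_cells` rather than silently renormalizing.
* All randomness flows from one `numpy` Generator; replicates use
  `Generator.spawn`, so trajectories are independent but fully
  reproducible from the master seed, and stochastic/deterministic modes
  share every other code path.
* Problem sizes in the test and acceptance runs: 200 randomized counting
  instances (≤ 50 reads × ≤ 20 guides), 20-seed batches of the default
  253-hairpin screen at depth 10⁶, and 1,000-gene DE tables — sizes at
  which every check completes in seconds while the statistics (drift
  null, planted recovery) are already in their asymptotic regime.
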