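# Methods

## The effort statistic

For a gene × sample matrix with nonnegative entries, each sample column is
scaled to a total of 10⁶ ("per-million" units). The transcription effort of
gene g in sample s is `100 · x_gs / total`, with `total = 10⁶` for a full
matrix. Per-million scaling is plain count scaling: no gene-length term is
applied, because the statistic asks what share of the sequenced
transcription a gene absorbs, not how many molecules per kilobase it
produces. A classic length-normalised variant is available
(`normalize_per_million(..., gene_lengths=...)`) and off by default.

Partial matrices (e.g. a printed top-10 table) are admitted behind an
explicit `partial=True` flag that suspends the column-sum invariant; every
effort computation against a partial matrix takes the true total as an
explicit argument. A threshold that the provided genes cannot reach raises
`InsufficientDataError` rather than returning a misleading answer.

Rounding policy: efforts are reported to 2 decimals and catalog fractions
to 1 decimal (matching how such tables are conventionally printed); all
internal computation and all test comparisons use full precision.

## Concentration curves and the logarithmic fit

Genes are ranked by descending expression, ties broken by ascending gene ID
so reports are reproducible. The cumulative effort over ranks is fitted by
ordinary least squares to `a·ln(rank) + b`. Natural log is used; the base
only rescales `a` and leaves R² — the quantity of interest — unchanged. By
default only ranks with nonzero expression enter the fit: trailing
zero-expression ranks add no cumulative mass and a long flat tail against
`ln(rank)` would distort R²; the rank window is configurable for anyone who
wants the full-catalog fit. A constant curve (zero total sum of squares) is
returned as `a = 0, R² = 1` with a `degenerate` flag instead of dividing by
zero.

The concentration summary reports, per sample: the minimal top-k gene count
for each threshold in a ladder (default 10/75/80 %), the expressed-gene
count and catalog fraction ("expressed" = strictly above a detection
threshold, default 0 — the data motivating the package report detection
without a stated cutoff, so the cutoff is an exposed parameter), and the
gene count and catalog fraction at 80 % effort (the Pareto summary).

## KOG and gene-set decomposition

KOG categories use the standard 25-letter vocabulary (A–Z without X);
unknown letters are rejected at parse time. Two semantics coexist
deliberately:

* **counts** — a gene annotated with several classes is tallied once per
  class, the way category bar charts are drawn;
* **effort** — a gene's effort is split equally across its classes, so
  class efforts plus the unannotated remainder form a true partition
  summing to 100.

Gene sets are overlays, not partitions: a gene in two sets contributes its
full effort to both (e.g. succinate dehydrogenase belongs to both the TCA
and electron-transport-chain sets; a class V alcohol dehydrogenase to both
glycolysis and the aroma panel). Set members absent from a matrix are
reported (`members_present` vs `member_count`), never an error.

## Condition comparison

Pairwise Pearson correlation is computed on linear per-million values by
default; with heavy-tailed expression this is dominated by the top genes,
which is the desired behaviour when asking whether two cultures allocate
their transcription the same way (a log-scale option exists). Both r and r²
are always reported side by side — conflating them is a common error in
this literature and the package refuses to participate.

The outlier rule: gene g is an outlier between samples a, b when
`|log2((x_ga + p)/(x_gb + p))| > log2(fold_limit)` with strict inequality
(a gene at exactly twofold is not an outlier) and pseudocount `p = 1`
per-million unit by default, which absorbs the zero-vs-trace flips at the
detection boundary. With `p = 0`, a zero against a nonzero value is flagged
as an infinite ratio rather than overflowing. Zero variance in a
correlation yields a defined result with `r_defined = False`.

## The synthetic generator

The generator exists so every pipeline stage can be tested offline against
known truth. It emulates a four-condition bulk transcriptome of a
12,346-gene catalog: per-condition expressed fractions of 84.6–88.6 %,
~46 % of genes KOG-annotated, nested gene sets of sizes 43/25/11/3/92 plus
a 13-gene secondary-metabolite pool, one pair of same-medium conditions
correlated at r ≈ 0.996 and cross-media correlations around 0.65, and the
concentration profile described above.

**Magnitude law.** The top `tail_mass` (default 0.85) fraction of ranks is
laid down at the quantiles of a shifted Pareto law,
`value ∝ (rank + shift)^(-1/shape)` with shape 1 — a shifted-Zipf profile
whose cumulative sum is logarithmic in rank by construction. The remaining
ranks are an i.i.d. lognormal body (log-mean 3.0, log-sd 1.2) scaled to
continue below the tail, and every gene receives lognormal dispersion
(σ = 0.2). The tail is placed at quantiles rather than drawn i.i.d.
because i.i.d. draws from a unit-shape Pareto make the top-gene share
Fréchet-unstable: the share of the single largest draw swings by an order
of magnitude across seeds, and no fixed parameterization can then keep the
top-3 share inside a [8, 14] % band on ~90 % of seeds. Quantile placement
keeps the law's shape while making the concentration statistics
reproducible — the property the generator exists to provide.

**Calibration.** The Pareto shift is the concentration dial: the top-3
share is monotone decreasing in it. `calibrate_tail` bisects the shift
(common random numbers across evaluations keep the objective monotone)
until the mean top-3 effort over 20 simulated conditions hits the target
(default 11 %), then verifies the companion targets: cumulative effort at
10 % of the catalog inside [70, 80] %, fewer than 2000 genes at 80 %, and
log-fit R² ≥ 0.97. The shipped default `pareto_shift = 1.42` is the value
this procedure solves for the default targets, so the stock generator is
already calibrated. Infeasible targets raise `CalibrationError` carrying
the last achieved statistics — a pure-lognormal tail (`tail_mass = 0`)
cannot put ≥8 % of the budget on three genes of a 12,346-gene catalog and
fails exactly this way, which is the quantitative argument for the heavy
tail.

**Condition structure.** Same-medium pairs share a latent profile and
differ by multiplicative lognormal noise whose σ is solved numerically
(bisection on the realized Pearson r) from the target correlation; the
noise normals are truncated at ±3σ, so at the solved σ ≈ 0.06 background
within-pair ratios stay below e^{6σ} ≈ 1.5 — strictly inside the twofold
limit, which is what makes planted-outlier recovery clean. Different media
are coupled by rank: each medium reorders the shared value multiset using
a noisy log-magnitude score whose coupling strength is likewise solved
numerically from the target cross-media r. Rank coupling, unlike
multiplicative noise, lowers the correlation to ~0.65 without disturbing
any single medium's concentration profile — and it reproduces the
qualitative signature of real media shifts, where a top gene of one medium
drops 30-fold in another while both media keep the same rank-abundance
shape. Multiplicative noise large enough to reach r ≈ 0.65 on the linear
scale would inflate the top-3 share unpredictably.

**Outliers, zeros, counts.** Planted outliers set the target condition's
value to exactly `value/fold` after noise, on a gene drawn from ranks
50–500 (well above the pseudocount floor), so the realized per-million fold
matches the configured fold to within rounding (~1 %). Unexpressed genes
are the weakest `(1 − frac_expressed)·N` genes per condition — differing
slightly between paired conditions, as real detection boundaries do.
Raw counts are produced by scaling magnitudes to a 5×10⁷-read library and
rounding (expressed genes are floored at one count), so per-million
normalization is exercised as a genuine pipeline step. Gene sets are
sampled from expression windows of the realized matrix: central-metabolism
sets from the 100–700 per-million band, secondary clusters below 60
per-million (past rank 2000 on the full catalog, giving a pooled effort of
~0.02–0.08 %), and the aroma panel spanning the range with a configured
7 of 92 members unexpressed somewhere. All randomness flows from one
seeded generator; identical config + seed gives bit-identical bundles.

**What the simulator does not emulate.** No biological replicates or
overdispersion model (each condition is one library, as in the motivating
study); no gene-length, GC or mappability structure; no correlation between
function and expression level beyond the set-placement windows; zero masks
are deterministic low-expression truncations rather than dropout. Passing
tests therefore demonstrate that the statistics recover planted structure
of the right shape and scale — not that any particular organism's values
will be reproduced.

## Parameter recovery

`parameter_recovery_suite` regenerates ≥20 bundles under derived seeds,
runs the full pipeline on each, and scores: expressed fractions within ±1
percentage point; top-3 effort in band; <2000 genes at 80 %; log-fit
R² ≥ 0.97; paired r in [0.99, 1]; planted-outlier precision = recall = 1
(with nothing planted: no false positives within pairs); secondary-cluster
effort ≤ 0.1 %; and the aroma expressed-in-all count. A check passes when
≥90 % of replicates satisfy it; failures are report entries, never
exceptions.

## Problem sizes and tolerances in the tests

The suite runs the full 12,346-gene generator where structure is under
test (single-seed fixtures, a 20-seed calibration check, a 20-replicate
recovery run) and 2,000-gene bundles where only plumbing is exercised;
random-instance oracle checks use 1000 matrices of ≤200 genes. Numerical
tolerances: column sums and normalization 1e-9 relative; effort
conservation and partitions 1e-6 absolute; least-squares recovery 1e-8;
correlation oracles 1e-10; the r² = r² identity 1e-12.

## Known limitations

* The twofold rule is deliberately rough — no dispersion model, no
  multiple-testing control — matching its role as a screening criterion;
  it should not be read as differential expression.
* Linear-scale Pearson r is top-gene dominated; for catalogs without a
  heavy tail the log-scale option is more informative.
* The log fit's support (expressed ranks only) is a choice; fits over the
  full catalog give slightly different (a, b) with essentially unchanged R²
  on heavy-tailed data.
* `gene_effort`'s default `total` of 10⁶ is only correct for per-million
  matrices; for partial tables drawn from other totals the caller must
  supply the total explicitly.
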