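# Methods

## Model

Relative gene expression measured by qPCR is treated as lognormally
distributed, so all estimation and testing happens on the log10 scale,
where it is approximately normal. The observable for one well is the pair
(E, Cq): amplification efficiency (fold-amplification per cycle,
theoretical maximum 2) and quantification cycle. The starting template
quantity is proportional to `E^(−Cq)`, so `log10(E)·Cq` — the
efficiency-weighted Cq, written `Cq(w)` — is the (negated) log10 quantity,
and wells with unequal efficiencies become directly comparable.

The pipeline is a chain of linear operations on `Cq(w)`:

1. **Technical aggregation.** The arithmetic mean of `log10(E_i)·Cq_i`
   over a sample's technical-replicate wells, computed in weighted (log)
   space — never by averaging raw Cq first. Unequal replicate counts per
   gene are allowed; the mean is per group.
2. **Normalization.** `ΔCq(w) = Cq(w)_GOI − (1/n) Σ_j Cq(w)_REF_j`.
   The arithmetic mean of the reference genes' log-scale values is
   identical to normalizing by their geometric mean in linear scale
   (verified as a property test at relative 1e−12), so any number of
   reference genes combine without special-casing.
3. **Contrast.** `ΔΔCq(w)` is a difference of group means (unpaired) or a
   mean of within-pair differences (paired); on balanced complete data the
   two coincide.
4. **Back-transformation.** The ratio `R = 10^(−ΔΔCq(w))` and its
   confidence interval `(10^(−upper), 10^(−lower))` are computed last.
   Because `x ↦ 10^(−x)` is decreasing, interval bounds swap, and the
   ratio-scale interval is asymmetric about R — correctly so.

The log base (default 10) is configurable; R and all test statistics,
degrees of freedom and p-values are base-invariant (the base cancels in
`base^(−ΔΔ)`), while log-scale estimates and intervals are base-specific
and are always reported together with the base.

## Inference

- **Unpaired:** two-sample t-test on ΔCq(w), Welch–Satterthwaite by
  default (conservative; pooled variance available). The Welch df is kept
  as a real number, never floored.
- **Paired:** one-sample t-test of the within-pair differences against 0;
  df = n − 1. Pairing acts as an implicit block on the biological
  replicate.
- **ANOVA with blocking:** one-factor additive fixed-effects model with
  plates and/or individuals as randomized complete blocks, no interaction
  terms. The decomposition is delegated to an ordinary least-squares fit
  with type-II (marginal) sums of squares, which equals the textbook
  sequential decomposition on balanced data; unbalanced data trigger a
  warning that the marginal decomposition is in use. Block F and p values
  are reported but are not inferential — blocking exists to partition
  nuisance variation out of the error term. A factor level missing
  entirely from a block is a design error naming the cell; a constant
  response yields a zero decomposition with F reported as undefined (NaN),
  not as an error.
- **Post-hoc:** pairwise t-contrasts using the pooled error mean square,
  `se = sqrt(2·MS_error/n)` on the error df (harmonic-mean n, flagged,
  when level sizes differ). P-values are Bonferroni-multiplied by the
  number of pairs and capped at 1; confidence intervals use the
  *unadjusted* t quantile. This mixed convention (adjusted p, unadjusted
  CI) is deliberate and matches standard reporting practice for these
  designs.
- **Intervals:** always Student-t quantiles at the stated confidence
  (default 95%). The large-sample z-quantile 1.96 is a common shorthand in
  write-ups but is not used anywhere: at the sample sizes typical of qPCR
  (3–6 biological replicates) the difference is material.
- Two-tailed tests only, null fixed at ΔΔCq(w) = 0 (ratio 1). A Shapiro
  screen on each group issues an advisory `AssumptionWarning` when
  log-scale normality looks doubtful; it never blocks an analysis and can
  be disabled (`check_assumptions=False`), which the Monte-Carlo loops do.

### Why not test ratios directly

`misuse.improper_ratio_test` implements, on purpose, the invalid
procedure of back-transforming each pair's ΔΔCq to a ratio and t-testing
the ratios against 1. Ratios are right-skewed, so the arithmetic mean and
the t-statistic depend on which group is the numerator; the two directions
of the same comparison can disagree about significance. The log-scale
method passes a strict reciprocity check (p identical, statistic negated,
ratio inverted) for any input; the test suite demonstrates both facts on
fixed and random data. The misuse path always emits a warning and exists
only under the demonstration API/CLI subcommand.

## Synthetic data generator

`simulate.simulate_experiment` draws per-well tables from the assumed
model so that every pipeline stage can be verified against known truth:

- true normalized log10 expression per biological sample =
  condition offset + biological noise + plate shift, all Gaussian in
  log10;
- the plate shift is shared by every well on a plate — exactly the
  structure a randomized complete block removes; plate assignment is by
  replicate index, so every plate is a complete block;
- per-well efficiencies are truncated-Gaussian on (1, 2.2]; per-well
  quantification cycles invert the weighting, `Cq = w / log10(E)` with
  `w` the target weighted value plus technical noise, so the pipeline's
  estimand equals the configured truth exactly (the noise-free case
  recovers the configured ratio to floating-point precision);
- reference genes are unaffected by condition (technical noise only)
  unless `ref_response` is raised to probe normalization failure.

Defaults: two conditions with true log10 offsets (0, −0.546) — a true
ratio of 10^0.546 ≈ 3.52, the effect size of the worked examples — 4
biological replicates, 3 technical replicates, 2 reference genes, 1
plate, sd_biological = 0.15, sd_plate = 0.15, sd_technical = 0.05 (log10
units), E ~ N(1.9, 0.03) truncated. The variance magnitudes are
illustrative choices of plausible bench values (≈1.4-fold biological
scatter, small technical jitter); no published variance components back
them. Seeding is explicit everywhere (`SimulationConfig.seed`); there is
no global random state.

What the generator does *not* emulate: amplification-curve shape and
efficiency-estimation error (E values are taken as given inputs),
between-gene efficiency correlation, pipetting dropouts/missing wells,
inhibition, and biological replicate effects shared across conditions
beyond the plate shift. Passing Monte-Carlo checks therefore certify the
statistical machinery under the assumed lognormal model, not robustness
to real-world artifacts.

## Monte-Carlo operating characteristics (test-suite sizes)

- Type-I error: 2000 simulated null experiments (true ratio 1, 4
  replicates/group). The empirical level is required to stay below the
  99% binomial envelope above the nominal 0.05 and to agree (two-sample
  binomial bound) with the Welch test's own level measured on ideal iid
  Gaussian samples of the same size — that reference level is ≈0.043, not
  0.05, because the Satterthwaite approximation is slightly conservative
  at n = 4 per group.
- CI coverage: 1000 simulated experiments per design (unpaired, paired);
  95% intervals must cover the true ratio within the 99% binomial
  envelope. The same runs check unbiasedness of the mean log-scale
  estimate.
- Blocking power: 400 simulated three-condition experiments on two plates
  with sd_plate = 0.3, sd_biological = 0.1 and a true log10 offset of
  −0.25 for the middle condition — values chosen once to make the
  blocked/unblocked contrast visible. The blocked ANOVA must show a
  smaller mean error mean-square and a higher rejection rate than the
  one-way analysis of the same data (measured: roughly 0.85 vs 0.30).

These sizes keep the whole suite under ~2 minutes on one CPU while
leaving the binomial envelopes meaningful.

## Numerical conventions and edge cases

- All arithmetic at full double precision; no intermediate rounding.
  Published worked-example tables round the weighted column to 3 decimals,
  so tests compare at the printed precision (and at a looser 2e−3 where a
  chain starts from raw (E, Cq) pairs rather than the printed weighted
  column).
- Efficiency must satisfy E > 1 (the log-weight must be positive);
  E ≤ 1 and E above a configurable 2.2 threshold (percent-efficiency or
  E−1 unit mistakes) are rejected at input, never silently converted.
- Result CSVs are written with 17 significant digits and re-read with
  round-trip float parsing, so write→read is lossless.
- Validation errors name 1-based data-row numbers (header excluded).
- Degenerate inputs: zero variance in both groups, all-identical pair
  differences, zero residual df, and post-hoc testing on a zero error
  mean square are explicit errors; a constant response in ANOVA is a
  defined result with undefined F.

## Known limitations

- Efficiencies are inputs; the package does not estimate E from
  fluorescence curves, nor parse instrument-native formats (RDML etc.).
- Blocking is additive only; crossed multi-block designs beyond a simple
  additive model (e.g. plate × individual with interactions) are out of
  scope, as are ANCOVA/regression-style formulations.
- The classical-formula cross-checks support a single reference gene by
  construction; they are oracles for testing, not analysis entry points.
- One gene of interest per experiment table; run several tables for
  several targets.
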