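# Methods

## Score model

A DMS experiment reports one raw score per variant on an arbitrary assay
scale. `dmsbench` reduces every score set to a common representation in two
steps:

1. **Anchoring and orientation.** With `wt_score` the raw score of the
   unmutated protein and the assay's `orientation` stating whether higher
   raw scores mean higher fitness, the signed score is
   `signed = ±(raw − wt_score)`, with the sign chosen so that negative
   always means loss of fitness (deleterious) and positive means gain
   (beneficial). Wild type sits exactly at 0.
2. **Per-side unit interpolation.** Deleterious and beneficial variants
   are normalized separately — selection assays are not symmetric around
   wild type, and pooling the sides would let one tail distort the other.
   Within a side, `normalized = |signed| / max(|signed|)`, so 0 is
   wild-type-like and 1 is the strongest observed effect *on that side of
   that dataset*. The map is strictly monotone in |signed|, so per-side
   rank statistics (Spearman ρ, AUC) are provably unchanged by it; the
   test suite asserts this to 1e−12.

No cross-dataset calibration is attempted: scales of independent assays are
not commensurable, and all evaluation is per dataset (per side).

## Neutral/effect labels from synonymous variants

Synonymous variants do not change the protein, so their signed-score
distribution is a direct estimate of measurement noise around wild type.
The neutral interval for scheme *synC* (C ∈ {90, 95, 99}) is the pair of
empirical quantiles at (1−C)/2 and 1−(1−C)/2 of the synonymous signed
scores. Numerical choices, pinned for reproducibility:

* quantiles use linear interpolation between order statistics (the
  `numpy.quantile` default);
* thresholding operates on **signed, pre-interpolation** scores, because
  synonymous variants span both sides of 0 and the interval must be
  two-sided;
* the interval is **closed** at both bounds — the synonymous variants that
  define the bounds are themselves neutral;
* datasets with fewer than 10 synonymous variants (configurable) are
  refused rather than thresholded unreliably, and their label columns read
  `unlabeled`.

Nested coverages give nested intervals, so syn90 effect calls always
contain syn99's; this monotonicity is property-tested.

## Predictor harmonization

Each external method is described by data, not code: a YAML registry entry
with theoretical score bounds `[raw_min, raw_max]`, a `reversed` flag (true
when lower raw score means more effect, as for SIFT), a default binary
threshold in raw units, and an optional beneficial-side target interval.
Harmonization maps oriented scores linearly onto [0, 1] using those
theoretical bounds (values outside them are clamped with a logged count).
Binary calls use strict `>` at the oriented default threshold, applied
uniformly; a score exactly at the cutoff is neutral.

The **naive conservation** baseline needs no external predictor: from a
PSI-BLAST ASCII PSSM, the predicted effect of substituting amino acid *a*
at position *p* is `−log_odds[p][a]` — substitutions rarely tolerated among
homologs score as high effect, and the binary cutoff is 0 on this flipped
scale. PSSM log-odds have no published theoretical bounds; the registry
pins the unit-rescaling bounds at ±17 (integer log-odds emitted by
PSI-BLAST stay well inside this in practice). This is a recorded
convention, configurable per run.

Two null baselines calibrate expectations: **shuffled scores** (a
predictor's own unit scores permuted across variants — same distribution,
no association) and **Gaussian around the experimental mean** (normal draws
with the experimental score vector's mean and SD, clamped to [0, 1]). For a
predictor whose score distribution matches the experiment's, the expected
MSE of the shuffled null equals that of independent draws from the two
marginals (2·Var for identical marginals); the acceptance suite verifies
this to 2%, which is what makes "low MSE" interpretable: distribution
matching alone achieves it.

## Evaluation

All comparisons run on the largest common SAV subset of experiment and
prediction, in a deterministic key order (position, then mutant residue);
missing predictions shrink the subset and are never imputed.

* Spearman ρ (average ranks for ties) and Pearson R via `scipy.stats`;
  MSE as the plain mean of squared differences. Undefined statistics
  (constant vectors) propagate as refusals, never as 0.
* 95% confidence intervals use the percentile bootstrap: resample index
  pairs with replacement (default 1000 reps), recompute, take the
  2.5th/97.5th percentiles. The same bootstrap backs the AUC CI, for
  internal consistency across metrics. A vectorized path (rank/moment
  algebra over a resample index matrix) handles the three core metrics and
  is tested bit-identical against the generic per-resample loop. A
  calibration test (500 simulations of copula pairs with known population
  ρ = 0.4 at n = 1000) checks empirical coverage lands in [0.92, 0.98].
* ROC sweeps all distinct thresholds with "effect" as the positive class
  and trapezoidal AUC (scikit-learn); single-class inputs are refused. AUC
  is verified against the exhaustive pairwise statistic
  P(s_eff > s_neut) + ½·P(tie) to 1e−12, ties included.
* Precision-recall points come from every distinct threshold; the
  zero-predicted-positive endpoint (undefined precision) is omitted.
* **Binned recall**: SAVs sorted by experimental score are split into 20
  contiguous equal-count bins (the remainder of n/20 is spread over the
  lowest bins, so bin sizes differ by at most one; ties at borders follow
  the deterministic key order). Recall per bin is the fraction called
  "effect"; `adjusted_recall` subtracts bin 1's recall to remove each
  method's over-prediction floor. Equal-count bins keep per-bin estimates
  comparable; an equal-width alternative is a selectable flag.

### Agreement between experiments

For two experiments x₁, x₂ on one protein and a predictor p aligned on
their common SAV set:

    Δρ   = ½(ρ(x₁,p₁) + ρ(x₂,p₂)) − ρ(x₁,x₂)
    ΔMSE = MSE(x₁,x₂) − ½(MSE(x₁,p₁) + MSE(x₂,p₂))

Negative values mean the experiments agree more with each other than with
the prediction. Since a single harmonized predictor restricted to the
common set gives p₁ = p₂, the two prediction vectors coincide; the
machinery keeps them separate so per-experiment predictor variants remain
expressible. Pairs sharing a provenance tag (same publication) are
excluded; beneficial-side pairs with n < 10 are reported but flagged low-n.

## Synthetic data generator

The generator emulates the statistical signatures the pipeline depends on,
with these defaults as the study conditions:

| parameter | default | rationale |
|---|---|---|
| protein_length | 500 | mid-sized scanned protein; 9500 SAVs |
| SAV coverage | all 19·N | complete scans exist; subsampling is a flag away via missingness |
| fraction deleterious / beneficial | 0.55 / 0.15 | deleterious-skewed effect mix (~3.7:1), remainder near-neutral |
| effect magnitudes | Gamma(2, 1.0) del., Gamma(2, 0.4) ben. | heavy-tailed, strictly positive, deleterious tail dominates |
| n_synonymous | 300 | a few percent of variants, enough to fit syn intervals |
| syn_noise_sd | 0.1 | tight noise around wild type relative to effect sizes of O(1) |
| predictor_target_rho | 0.4 | mid-range predictor performance |
| replicate_target_rho | 0.93 | strong same-assay reproducibility |

Rank-correlation targeting uses a Gaussian copula. For a bivariate normal
with latent Pearson correlation r, the population Spearman correlation is
ρ_S = (6/π)·arcsin(r/2); the mixing weight is therefore solved in closed
form, r = 2·sin(π·ρ_S/6), with no iteration, and the realized sample
correlation matches the target up to O(n^−1/2) sampling error (verified at
±0.03 for n ≈ 10,000). Replicates additionally quantile-map the perturbed
ranks back onto the original score values, so a replicate has *exactly* the
same marginal distribution as its source and only the rank agreement is
controlled. Synthetic PSSMs assign integer log-odds decreasing linearly in
true effect magnitude (plus optional Gaussian blur, rounded and clipped to
±16), so the naive-conservation baseline recovers true effect ranks up to
integer quantization.

What the generator does **not** emulate: real assays' bimodality or
censoring, position-level effect correlation (each SAV's effect is drawn
independently), sequencing-count noise models, and any specific published
study's empirical score distribution. Passing tests therefore demonstrate
correctness and calibration of the *machinery*, not performance claims
about real predictors on real scans.

## Reproducibility and problem sizes

Everything is reproducible bit-for-bit from (config, seed). The pipeline
derives one seed per (stage, dataset, method) from the global seed via
SHA-256, so adding or removing a combination never shifts another's
randomness, and refusals become status rows rather than aborts.

Simulation sizes in the test and acceptance suites are chosen so sampling
noise sits well below the tolerances being asserted: n = 1000 pairs × 500
simulations for bootstrap coverage, ~10,000 SAVs for correlation-target
recovery (Spearman SE ≈ 0.01), 100 simulated proteins for the agreement
and binned-recall rate checks, and 5000 SAVs per bin (n = 100,000) for
bin-level recall monotonicity, where adjacent-bin differences of O(0.02)
must exceed binomial noise.

## Known limitations

* Per-side normalization divides by the side maximum, so a single extreme
  variant compresses the rest of its side; robust alternatives (quantile
  scaling) are deliberately not offered, to keep scores interpretable as
  "fraction of strongest observed effect".
* Score sets with categorical (non-numeric) effect annotations are rejected
  at parse time rather than coerced.
* The beneficial-side mapping onto a target interval (for
  regression-style methods whose gain-of-function scores live elsewhere on
  their scale) is a min–max map of the *observed* subset, hence
  dataset-dependent by construction.
* The ASCII PSSM dialect carries no protein identifier; the pipeline
  rebinds a profile to the dataset's protein when unambiguous, and a wrong
  pairing degrades to an empty key intersection (a refusal), not a silent
  mis-evaluation.
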