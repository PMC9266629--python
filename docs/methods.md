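# Methods

## The relative ferroptosis level

Ferroptosis regulation is two-sided: driver genes push a cell toward
iron-dependent lipid-peroxidation death, suppressor genes hold it back. A
single-signature score conflates the two, so `ferroscore` scores each side
separately with single-sample gene-set enrichment and takes their ratio:

    drive_s    = ssGSEA(x_·s, D)        suppress_s = ssGSEA(x_·s, S)
    RFL_s      = drive_s / suppress_s

RFL is unit-free, invariant to rescaling both activities by a common
positive constant, and — because ssGSEA depends on expression only through
within-sample ranks — invariant to any strictly increasing per-sample
transform of expression (log, quantile, library-size scaling).

**Signature hygiene.** Before scoring, genes annotated as both driver and
suppressor are excluded from both lists (they carry no directional
information), and the lists may be intersected with a protein-coding
whitelist. All exclusions are recorded on the resulting `GeneSetPair`.
Mutation rates are not a filter; they can be reported descriptively.

**ssGSEA.** For a sample with genes ranked ascending (ranks 1..N, average
ties), walking genes by decreasing rank (ties broken lexicographically by
gene id for determinism),

    P_in(i)  = Σ_{j≤i, g_j∈S} r_{g_j}^α / Σ_{g∈S} r_g^α
    P_out(i) = #{j≤i, g_j∉S} / (N − |S|)
    ES       = Σ_{i=1}^{N} (P_in(i) − P_out(i)).

α ≥ 0 weights the contribution of highly ranked genes; the default 0.25 is
the conventional ssGSEA choice. An optional cohort-range normalization
(divide every score in a call by max ES − min ES) is off by default: the
RFL ratio is provably invariant to it, and raw scores keep interpretable
signs. Set genes absent from the matrix are intersected out and logged; a
set covering every measured gene is rejected (the out-of-set fraction would
be undefined).

**Undefined RFL.** A raw enrichment score can be non-positive. Where
suppress activity ≤ 0 the ratio is flagged undefined (NaN), the sample is
excluded from downstream stages, and the count is logged. Cohorts are only
analyzed further if RFL correlates with its components in the expected
directions (r > +0.2 with drive, r < −0.2 with suppress activity, Pearson);
this is the same rule used to exclude cohorts where the score is not a
usable read-out.

## Survival analysis

Kaplan–Meier estimation, the two-group log-rank test and Cox
proportional-hazards fits (Breslow tie handling) are delegated to
`lifelines`; ROC AUC to `scikit-learn`.

**Cutoff scan.** Candidate cutoffs are every distinct observed RFL value
within the 10th–90th percentile window (linear-interpolation quantiles).
Each candidate splits the cohort at `rfl > cutoff`; the candidate with the
smallest log-rank P wins, ties broken toward the cutoff closest to the
median. The minimum-P scan mirrors common practice but inflates type I
error; `scan_cutoff(n_permutations=...)` computes a permutation-adjusted P
for the selected minimum (off by default, reported alongside, never
substituted). The hazard ratio at the best cutoff comes from a univariate
Cox fit; if that fit diverges (monotone likelihood at an extreme split) it
is refit with a small L2 penalty (0.1) and a warning.

**Risk score.** Given a fitted multivariate Cox model, RS is the linear
predictor centered at the fitting-cohort covariate means, so mean RS = 0 on
the fitting cohort and RS > 0 reads as above-average modeled risk; groups
are RS > 0 vs RS ≤ 0. Significance conventions: HR > 1 & P < 0.05 = poor
survival; HR < 1 & P < 0.05 = favorable. In the pipeline's risk stage the
gene panel is fit with penalizer 0.1 because recurrent RFL-correlated genes
all track the same latent signal and are therefore collinear.

**ROC.** The AUC uses the end-of-follow-up event indicator as the binary
label (ties count ½). A fixed-horizon time-dependent AUC is a possible
alternative; it is deliberately not implemented.

## Gene screen

Per cohort, each gene's expression is Pearson-correlated with RFL
(two-sided P from t = r·√(n−2)/√(1−r²)); calls use strict thresholds
r > +0.3 / r < −0.3 and P < 0.05. No multiple-testing correction is applied
by default, matching the marginal-threshold design of the screen; a
Benjamini–Hochberg option exists. Constant genes are class `none`.
A gene is *recurrent* when called in the same direction in at least
`min_cohorts` (default 7) cohorts and never in the other direction — sign
consistency is required. Jaccard matrices J(A,B) = |A∩B|/|A∪B| are computed
separately for the positive and negative set collections; an empty-union
pair is 0 with a warning. In the pipeline, the screen's candidate universe
excludes the driver/suppressor signature genes themselves: the screen's
purpose is finding *new* RFL-correlated genes, and the signature genes
correlate with RFL by construction.

## Pseudobulk

For single-cell data, the per-patient profile is the arithmetic gene-wise
mean of that patient's cells, on the values as provided (no
re-normalization); RFL is then computed on the pseudobulk matrix exactly as
for bulk cohorts.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, with
ground truth for recovery tests:

- latent ferroptosis activity f_s ~ Normal(0, 1) per sample;
- log-expression x_gs = b_g + β_g f_s + ε_gs, ε ~ Normal(0, noise_sd²),
  with β = +effect_b (drivers), −effect_b (suppressors), ±effect_c
  (planted RFL-correlates), 0 (background);
- per-gene baselines b_g ~ Normal(baseline_mean, baseline_gene_sd²), plus
  `signature_boost` for driver/suppressor genes. The boost keeps both
  enrichment scores bounded away from zero so the ratio is well behaved —
  the regime real validated cohorts show (activities stably positive, RFL
  smooth); without it, a near-zero denominator makes RFL heavy-tailed, a
  known pathology of ratio statistics rather than a property of the data
  being emulated;
- survival times Exponential with hazard baseline_hazard·exp(−γ f_s); γ > 0
  encodes "high ferroptosis favorable". Censoring is Exponential and
  independent of f, its single global rate solved (Brent) so the expected
  censored fraction matches `censor_rate`;
- a treatment design shifts f by `treatment_delta` in the treated arm
  (inducer-like > 0, inhibitor-like < 0);
- single-cell data draw per-cell noise around the patient profile, so
  pseudobulk converges to the patient mean as cells grow.

Defaults (n=300 samples, 2000 genes, 40+40 signature genes, 30+30 planted
correlates, effect_b=1, noise_sd=0.5, effect_c=0.29 giving planted true
r ≈ 0.5 with f, γ=0.8, 30% censoring, baseline hazard 0.002/day) are the
reference study conditions: large enough for stable Pearson screens at the
0.3 threshold, small enough that the full multi-cohort analysis runs in
seconds per cohort. The population correlation of a planted gene with f is
c/√(c²+noise_sd²), which the tests verify empirically at large n.

What the generator does **not** emulate: negative-binomial count noise,
library-size and batch effects, correlated gene modules beyond the single
latent factor, informative censoring, and competing risks. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability under the assumed model, not robustness to real RNA-seq
artifacts.

## Numerical and design choices

- Gene identifiers are upper-cased and whitespace-trimmed on ingest.
- Group boundary: `rfl > cutoff` is high; a sample equal to the cutoff is
  low. The cutoff must lie strictly inside the observed RFL range.
- Expression rows with any missing value are dropped at ingest (logged).
- All generators and the pipeline are pure functions of (params, seed); a
  single `SeedSequence` feeds per-stage child streams. The run log contains
  stage names, counts, the config echo and the package version but no
  timestamps, so rerunning a configuration reproduces the report bundle
  byte for byte.
- Exact small-sample behavior (hand-computable Kaplan–Meier products, the
  O−E/V log-rank statistic, closed-form Pearson P-values, pair-counting
  AUC) is pinned by tests against independent oracles written before the
  implementations they check.

## Known limitations

- The min-P cutoff is anticonservative without the permutation adjustment.
- The unpenalized Cox fit can diverge under perfect separation; the
  penalized fallback biases the HR toward 1 and is flagged in the log.
- RFL is undefined for samples with non-positive suppress activity; cohorts
  where that is common (weakly expressed suppressor signature) will lose
  samples and may fail validation — by design, not silently.
- The screen's strict thresholds control false positives but are not
  calibrated for dependent tests across genes.
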