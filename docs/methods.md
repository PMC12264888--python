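# Methods

## Scope

`lesionpls` implements a region-level multimodal lesion–symptom mapping
analysis: modality-specific PLS regression of four WAB-R language subtest
scores on neuroimaging features, VIP-based identification of shared
anatomical substrates, coefficient-threshold calling of subtest-unique
regions, LOOCV-validated prediction, and a two-stage shared/unique
variance decomposition. Voxel-level MRI preprocessing (segmentation,
normalization, tractography, GLM estimation) is out of scope; the package
starts from region-level matrices, optionally extracting regional lesion
load from NIfTI masks against a labelled parcellation.

## PLS regression core

Both blocks are column-centred and unit-variance scaled by default
(`scale=False` available). Z-scoring is what makes VIP scores comparable
across regions and across modalities with different physical units;
constant columns are centred only and flagged. Components are extracted
by NIPALS in regression mode: the weight vector is the leading singular
vector of the deflated cross-covariance (computed by dense SVD of the
p × 4 matrix X'Y, which is exact and cheap at k = 4), X is deflated by
its score regression, and Y is left undeflated — for PLS2 regression the
extracted sequence and predictions are identical under either convention
because deflated X is orthogonal to earlier scores. Each weight vector's
sign is fixed so its largest-magnitude entry is positive, making output
deterministic; predictions and VIP are invariant to these sign choices.
Extraction stops early, truncating the model, if the residual
cross-covariance vanishes (rank exhausted); exactly-orthogonal Y is an
error rather than a zero model.

Regression coefficients are computed as B = W (P'W)⁻¹ Q' on the
standardized scale for any leading component count, then back-transformed
to original units. At full rank the PLS solution equals ordinary least
squares, which the tests exploit as an oracle, along with an independent
reference implementation (scikit-learn's `PLSRegression`) for predictions
and VIP inputs.

SSY_a, the Y sum-of-squares explained by component a on the standardized
scale, is (t_a't_a)·‖q_a‖². VIP uses the standard Wold formula weighted
by SSY_a, so mean-square VIP is exactly 1. "Explained brain–behaviour
covariance" per component is the squared leading singular value of the
deflated cross-covariance at that step, relative to ‖X'Y‖²_F of the
standardized blocks; the per-modality report includes the smallest
component count whose cumulative value reaches 50%.

Components computed/retained default to 20/5. Components are ranked by
explained Y sum-of-squares for retention (ranking by X-variance would be
the alternative reading; both orderings are present in the
explained-covariance table).

## Cross-validation and selection

LOOCV refits everything inside each fold, including centring/scaling.
Accuracy is the Pearson correlation between the n out-of-fold predictions
and the observed scores per subtest, with the exact t-transform p-value
(n − 2 df); a Benjamini–Hochberg column is added in the run report as
supplementary information, matching the per-model reporting convention of
the field. Constant observed columns are flagged, never silently zeroed.

VIP-restricted regression supports two protocols. `paper` selects the
high-VIP features once on the full data and cross-validates the
restricted matrix; `nested` re-selects within every training fold. The
nested protocol is the default headline because the paper-style protocol
lets the held-out subject influence its own feature set; on pure-noise
responses the paper protocol's mean r exceeds the nested protocol's,
which the test suite measures directly. Selection keeps the top-N
features with VIP > 1.5 over the retained components, N = 50 for the two
connectivity modalities and 30 otherwise, ties broken by feature index.

For pairwise (connectivity) modalities, features are edges (strict upper
triangle of the symmetrized 384 × 384 matrix). Edge-level VIP selections
are summarized to regions by marking both endpoints of each selected
edge; this aggregation rule is a package choice, as is summarizing edge
coefficient maps to regions by the maximum |β| over incident edges.

## Shared and unique anatomy

The shared substrate is a count-based consensus: a region counts once per
modality model in which it passed VIP selection; ≥ 4 of 11 models is the
reporting consensus and ≥ 6 the core set. Consensus sets shrink
monotonically in the threshold.

Unique calling takes |standardized β| per region and subtest (from the
full 20-component model, whose coefficients best resolve weak
single-subtest directions), min–max rescales to [0, 1] within each
modality × subtest, and applies the 0.2 threshold. Rescaling before
thresholding makes the cut comparable across modalities with different
units, which is the point of the rescaling; the reverse order (threshold
raw standardized β at 0.2 first) is available via a flag. Magnitude, not
sign, is thresholded: damage can impair while perfusion in the same
region can facilitate, so involvement is what is called. A region unique
to one subtest in ≥ 2 modality models (consistent subtest) enters the
map; regions reaching the ≥ 2-modality bar for two different subtests are
conflicts and dropped with a report, and regions in the ≥ 6-model core
consensus are excluded from the unique map (reported as overlap) — the
core set, not the looser ≥ 4 consensus, because at ≥ 4 most of the
stroke territory qualifies and the exclusion would be vacuous.

The variance decomposition regresses each subtest on lesion % of the top
4 consensus regions (ranked by model count, ties by mean regional VIP),
then the residuals on MD of that subtest's unique regions — capped at the
8 with broadest modality support, since an uncapped map can carry dozens
of regions and saturate R² at n = 86. Ill-conditioned designs (condition
number > 1e8) fall back to a pseudoinverse fit with a warning. Both
stages use ordinary least squares with exact per-predictor two-sided
p-values.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated.

**Behaviour.** Scores are drawn from a clipped Gaussian copula: a latent
multivariate normal per subject, transformed to each subtest's scale and
clipped to [0, max] (20/10/10/10). Clipping biases moments, so the latent
margins are pre-calibrated by closed-form censored-normal moment matching
(fixed-point, ≤ 25 iterations, tolerance 1e-3), and each latent pairwise
correlation is solved by root-finding so the *post-clipping* correlation
hits its target, with post-clipping moments evaluated by 48-node 2-D
Gauss–Hermite quadrature. Targets default to the published cohort: means
11.4/5.4/5.2/7.7, SDs 4.9/3.0/2.9/1.8, correlations 0.63–0.84. The
calibrated matrix is repaired to the nearest positive-definite
correlation matrix by eigenvalue clipping when needed. Two quantities are
deliberately *not* calibrated and serve as emergent consistency checks:
the SD of the Aphasia Quotient AQ = 2·(SS+N+R+AC) (published 23.0) and
r(SS, AQ) (published 0.96).

**Severity and lesions.** A single latent severity factor — the negated
mean of the latent behaviour factors, mixed 1:1 with an independent
normal component (`severity_noise=1`) and probability-transformed to
[0, 1] — links behaviour to anatomy. The independent component reflects
that lesion extent tracks impairment imperfectly; without it the shared
regressions explain an unrealistic ~80–90% of score variance, versus the
~15–50% band the mixed factor produces. Damage occupies a contiguous
window of an ordered 60-region left-hemisphere "territory" around a
random seed region; window length grows with severity until it covers
the territory, and the damage level approaches 100% with a bounded
multiplicative texture (≥ 90% everywhere at full severity for the default
lesion noise). Rare low-grade stray damage (rate 0.01) outside the
territory emulates secondary lesions — and, deliberately, the
chance lesion–behaviour correlations that produce spurious unique calls
in any finite cohort.

**Derived modalities.** Each regional modality is a monotone link of
damage around a healthy baseline (FA 0.45 and CBF 50 fall, MD 0.80
rises, TIV-normalized volumes, pALF and task-fMRI contrast fall), with
additive Gaussian noise at 25% of the healthy dynamic range; i3mT1 is the
damage fraction plus blur, clipped to [0, 1]. Connectivity starts from
one fixed healthy connectome (lognormal streamline counts; tanh-normal
correlations) and attenuates each edge by (1 − 0.95·d) per endpoint
damage fraction d, so a fully damaged endpoint leaves ≤ 5% of the edge.

**Planted effects.** The four shared regions sit at the territory centre;
their cohort-standardized mean damage is added to all four subtests with
slopes 0.65/0.50/0.50/0.35 (SS/N/R/AC), matching the observed dominance
of spontaneous speech and weak loading of auditory comprehension on the
severity axis. Unique regions (1/3/3/4 per subtest, outside the
territory, both hemispheres) each carry an independent standard-normal
integrity deviation per subject that is orthogonalized in-sample against
the other three subtests' (provisional final) scores and the shared
component — realizing "perturbs exactly one subtest's residual" — and is
injected into four imaging channels (MD up; FA, CBF, pALF down) at
amplitudes well above the channel noise floors. Four channels satisfy the
≥ 2-modality support rule while keeping planted unique regions below the
6-model consensus core. Auditory comprehension carries the widest and
strongest unique component (4 regions, slope 0.45) and spontaneous speech
the weakest (1 region, slope 0.25, half channel amplitude), which is what
makes the ΔR² ordering across subtests testable. Score variance is
approximately preserved during injection by shrinking the pre-existing
residual to absorb the added variance.

**What the generator does not emulate.** Spatial smoothness within
regions, hemodynamic or acquisition artefacts, lesion-volume
distributions in cc, non-MCA stroke topographies, and the attenuation of
subtest inter-correlations after planting (the planted cohort's pairwise
correlations run ~0.35–0.65, below the published 0.63–0.84, because the
unique components are made large enough to be recoverable at n = 86 —
detectability and faithfulness to the published covariance trade off
directly at this sample size, and the calibration targets are asserted on
the pre-planting behaviour draw). LOOCV accuracies on the synthetic
cohort (r ≈ 0.5–0.9) exceed the published real-data range (≤ 0.45)
because region-level severity signal is cleaner than real data. Passing
recovery tests therefore demonstrates that the pipeline's machinery
identifies what was planted under favourable, known conditions — not that
it would achieve the same sensitivity on real cohorts.

## Determinism and problem sizes

Every stochastic step flows from one seeded `numpy` generator; a fixed
seed reproduces cohorts bit for bit, and all ranking ties break
deterministically. The test suite validates full-scale replicates (86
subjects, 384 regions, 11 modalities) and uses 10 fixed-seed replicates
for the parameter-recovery checks; smaller fixtures (40 subjects, 48
regions) cover the remaining behaviour. The acceptance script draws
n = 5000 behaviour samples for calibration checks. These sizes keep the
whole validation run in minutes on a single CPU while leaving every
full-scale code path exercised.

## Known limitations

* The paper-style selection protocol is reported for comparability but is
  optimistic by construction; use the nested protocol for accuracy
  claims.
* Unique-region calling inherits the noise of coefficient estimates at
  p ≫ n: spurious single-subtest calls occur (the stray-lesion mechanism
  reproduces this honestly), which is why calls require multi-modality
  support and the variance stage caps predictors.
* Edge-to-region aggregation rules for connectivity models are package
  choices; other reasonable rules (count-weighted, mean |β|) would shift
  region-level results.
* The multi-component Y-loading profile is diluted by overfit later
  components at p ≫ n; subtest dominance should be read off the leading
  latent variable.
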