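# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `senesurv`. It is written for users who need to judge what
the package's validation on synthetic cohorts does and does not establish
about real tissue-microarray (TMA) data.

## Survival machinery

`survival_stats` implements the Kaplan-Meier product-limit estimator and
the k-group log-rank (Mantel-Cox) test directly on numpy arrays.

* KM: S(t) = prod over distinct event times t_i <= t of (1 - d_i / n_i),
  with n_i the number at risk just before t_i. Ties between an event and
  a censoring at the same time follow the standard convention that the
  event precedes the censoring (the censored subject is still at risk).
* Log-rank: per distinct event time, observed minus expected events per
  group with the multiplicity-corrected hypergeometric variance
  d (n - d) / (n - 1); the statistic is z' V^-1 z over the first k-1
  groups, chi-square with k-1 df. If V is singular the pseudo-inverse is
  used.

Both are cross-checked in the test suite against `lifelines`
(KaplanMeierFitter, multivariate_logrank_test) to ~1e-9 relative
agreement, and against hand-computed fixtures. The in-house
implementation exists because the cutpoint search below needs thousands
of log-rank evaluations per second in a vectorizable form; `lifelines`
serves as the independent oracle, never the implementation.

No Greenwood confidence bands are part of the core contract; KM output
tables carry times, survival, at-risk and event counts only.

## Maximally selected cutpoints

For scores X_1..X_n with survival (T_i, delta_i):

* Candidates are midpoints between consecutive distinct order statistics
  of X, restricted so both sides keep at least ceil(min_group_frac * n)
  subjects. `min_group_frac` defaults to 0.10; this prevents degenerate
  tail splits and is a common choice for maximally selected statistics.
* Two-tier: minimize the 2-group log-rank p over candidates; ties go to
  the smaller cutoff.
* Three-tier: exhaustive search over ordered candidate pairs (c1 < c2)
  with all three groups feasible; the objective is the global 3-group
  log-rank (df = 2), matching a three-curve Kaplan-Meier comparison
  rather than the minimum of pairwise tests. Ties resolve to the pair
  with the largest smallest group, then the smaller c1, then c2. A joint
  exhaustive search is used (not a sequential/greedy one): it is exactly
  optimal, and the test suite verifies equality with brute-force
  enumeration; a greedy variant would save little here since the whole
  search is O(K^2) on precomputed prefix sums.

### Implementation

Because candidate groups are nested along the score order, the search is
computed with prefix sums: per-subject log-rank scores
l_j = delta_j - Lambda_hat(T_j) (martingale residuals at the
Nelson-Aalen estimate) give every candidate's observed-minus-expected by
a cumulative sum; prefix at-risk counts per event time give every
candidate's hypergeometric variance. One full scan costs O(T x n) for T
distinct event times, and the three-tier pair search reduces to one
K x K Gram matrix. Exact equality with naive enumeration via the plain
log-rank test is asserted over hundreds of random instances.

### Selection bias

The minimum p over a search grid is anti-conservative. On null cohorts
(no score-survival association, n = 400, min_group_frac = 0.10) the
selected p has a null median near 0.05-0.06 and falls below 0.05 in
roughly 45% of replicates — the familiar inflation of "optimal" cutoffs.
`permutation_adjusted_p` therefore reruns the full search on B
permutations of the score-survival pairing (B >= 100 enforced; default
199) and reports (1 + #{permuted min-p <= observed}) / (B + 1), which is
exact under the null and verified uniform by KS test in the acceptance
suite. Both p values are always reported; p_raw should never be quoted
alone.

## Registration

Consecutive sections are aligned per patient (all cores of a section
move together, mimicking sectioning physics) by least-squares orthogonal
Procrustes on matched fiducial landmarks — the Kabsch construction with
the determinant correction so reflections are disallowed (sections are
never mirrored). Optionally a similarity fit (isotropic scale) is
available. The RMS residual is reported with every transform so users
can judge whether a rigid model is adequate; deformable registration is
out of scope. An ICP refinement (`icp_refine`) alternates
nearest-neighbor matching with Procrustes re-fits, with a divergence
guard that reverts the last step if the RMS residual increases.

With landmark noise sigma the translation error scales ~ sigma / sqrt(n)
(verified empirically over sigma in {0.5, 1, 2, 4} um). At sigma = 2 um
and 20+ landmarks, single-replicate translation errors are
Rayleigh-distributed with scale ~0.45 um, so a small percentage of
replicates exceed 1 um by chance even for the exact least-squares
optimum; accuracy statements in the acceptance suite are therefore about
mean errors over replicates.

## Quantification

Per-cell compartment classification stands in for the trained classifier
of a digital-pathology platform: a random forest (scikit-learn, seeded)
on three generic per-cell features — mean stain intensity across the
panel, local density (neighbors within 50 um in the same core), and
radial distance from the core center. In the synthetic pipeline the
annotation used for training is a stratified 20% sample of the
generator's true labels. The per-patient score is
100 x (positive epithelial cells) / (epithelial cells), pooled across
the patient's cores; pooling weights cores by their evaluable cells and
is robust to sparse cores (per-core averaging is available via
`per_core=True`). Unclassified cells enter neither numerator nor
denominator. Positivity thresholds are per-marker configuration values
applied to intensities (`apply_positivity_threshold`); threshold
calibration itself is out of scope.

## Proximity

Two patient-level statistics, computed in the registered section-1 frame
and pooled over cores (cross-core pairs are never formed):

* mean nearest-neighbor distance, by default from each p21+ tumor cell
  to the nearest CD8+ cell. The direction is configurable
  (`cd8_to_p21`) and always recorded in the output, since "average
  distance between two populations" is inherently directional for
  nearest-neighbor estimators.
* percent of CD8+ cells with at least one p21+ epithelial cell within
  r = 100 um (closed ball; center-to-center distances).

p21 positivity is restricted to classified tumor epithelium; CD8 counts
in all compartments. No edge correction is applied for source cells near
the 1-mm core rim, whose true nearest neighbor may lie outside the core;
this biases nearest-neighbor distances upward near the boundary. A
border-margin option excludes source cells within m um of the rim for
sensitivity analyses. Patients lacking either population in every core
get missing statistics, a logged warning, and are excluded from survival
splits on these metrics.

## Synthetic cohort generator

The generator produces the structure the analysis assumes, with known
latent truth for recovery tests. All randomness descends from one seed;
per-patient child streams are spawned deterministically, and survival
draws are separated from cell draws so survival tables are identical
with or without cell generation. Same seed, same bytes.

Geometry. Per patient, 3 cores of 1 mm diameter. Cells are homogeneous
Poisson in the core disc; tumor epithelium is the central disc holding
60% of the core area, stroma the rim — the simplest architecture that
makes the classifier stage meaningful. Real tumors are not radially
organized; nothing downstream depends on this layout.

Markers. Latent per-patient percent positivity is drawn from per-marker
Gaussian mixtures on the percent scale, clipped to (0.5, 99.5):

* wide tri-modal (means 15/50/85, sds 10, weights 0.3/0.4/0.3) for
  NTAL, ARMCX3, EBP50, gH2AX — populating all three expression tiers;
* a low, tight mixture for p21 (means 8/12/17, sds 1.5/2/2.5): p21 marks
  scattered senescent cells, and the p21+ cells also serve as spatial
  anchors for CD8 attraction. Keeping their counts low and comparable
  across patients keeps the baseline probability that a random CD8 cell
  falls within 100 um of some p21+ cell well below saturation and with
  small between-patient variance — otherwise the percent-within
  statistic would measure p21 abundance rather than attraction. With
  ~120 epithelial cells per core this yields ~10-20 anchors per core and
  a baseline coverage around 0.3-0.5.

Cell-level positivity is Bernoulli(latent percent / 100) in epithelium
and Bernoulli(0.02) background in stroma; intensities are drawn from
class-separated Gaussians (positive N(3.0, 0.5), negative N(1.0, 0.4),
clipped at 0) so the configured threshold 2.0 is recoverable.

Immune section. CD8 counts are Poisson(80) per core. A per-patient
attraction fraction q ~ Beta(2, 2) of CD8 cells is placed uniformly
within 100 um of a randomly chosen p21+ epithelial cell (radially
clipped to the core); the rest are uniform in the disc. Section-2
coordinates are the section-1 frame pushed through a per-patient rigid
transform (rotation uniform in +/-5 deg, shifts uniform in +/-50 um),
and 8 rim landmarks per core are emitted with N(0, 2 um) jitter on the
second section.

Survival. Exponential event times (the minimal model with closed-form
properties; the analysis itself is nonparametric) with hazard

    lambda_i = lambda_0 x HR(tier_i) x exp(beta x (1 - q_i))

where tier_i is the true tier of the driver marker (NTAL by default,
boundaries 30/70), HR = (2.0, 1.0, 2.5) for low/moderate/excessive — the
U-shaped profile in which moderate expression carries the best
prognosis — and beta = 1.5 links poor CD8-p21 contact (small q) to
higher hazard, a strong effect of about 4.5-fold hazard across the full
q range. The hazard uses the latent q, not the realized spatial
statistic, so recovery tests compare pipeline estimates against exactly
known truth. DSS and PFS are drawn independently with the same hazard;
censoring is administrative, uniform on (0, 120] months. The paper this
design emulates states no censoring rates or follow-up length, so these
are invented defaults: lambda_0 = 0.005/month was chosen so that with
the tier and proximity multipliers averaged in, overall censoring lands
at ~35-45%, inside the 30-50% design band. Scenario overrides that zero
the effect multipliers (null cohorts) must compensate by raising the
baseline (0.02/month keeps ~38% censoring); otherwise the cohort drifts
to ~75% censored and stops resembling the design conditions.

What the generator does not emulate: tissue morphology and stain
artifacts, non-exponential baseline hazards, informative censoring,
competing risks, correlated markers within a patient, spatial clustering
of tumor cells beyond the radial mask, and imperfect landmark
correspondence. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the stated model,
not robustness to these real-data features.

## Validation study sizes

The acceptance suite and `scripts/acceptance.py` run (sizes chosen to
make each quantity's Monte-Carlo error small relative to its acceptance
band while keeping a full run in minutes on one CPU):

* oracle equality of spatial statistics, tier binning and both cutpoint
  finders vs brute-force enumeration: 200 random instances each;
* hand-computed KM and log-rank fixtures; chi-square p vs a 10,000-draw
  permutation on 40 subjects (agreement within 0.02);
* null calibration: 1000 replicate cohorts (n = 400) for the
  prespecified-split type-I error (0.05 +/- 0.02 band and KS
  uniformity), 200 replicates x B = 199 for permutation-p uniformity
  (the script reports 400 and 100 replicates respectively);
* three-tier recovery: 100 replicates at n = 600 under the default
  U-shaped hazard; both boundaries within +/-10 points in >= 80% of
  replicates and moderate-tier-best KM checked at t = 60 months;
* proximity recovery: 100 replicates at n = 400 (p21-only panel, tier
  HRs flattened so the proximity effect acts alone); Spearman of
  percent-within-100-um vs latent q > 0.9 and permutation-significant
  optimal split in >= 80% of replicates (the script runs 30 replicates);
* registration: 100 replicates of a 30 deg / (50, -20) um transform
  with 24 landmarks at sigma = 2 um; mean errors within 0.5 deg / 1 um.

## Known limitations

* The three-tier search is O(K^2) in distinct scores; at n ~ 10^4+ a
  coarsened candidate grid would be advisable.
* The permutation p treats patients as exchangeable; stratified
  permutation (e.g., within stage) is not implemented.
* Proximity statistics ignore core-edge effects (documented bias) and
  assume registration residuals are small relative to r = 100 um; the
  per-patient RMS residual in transforms.csv should be checked.
* Cox or multivariable adjustment is deliberately out of scope; the
  package tests marginal associations only.
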