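# senesurv

Cellular senescence is a double-edged sword in colorectal cancer: senescent
tumor cells have stopped dividing, but whether that benefits the patient
depends on whether the immune system can find and clear them. `senesurv`
implements the quantitative analysis stack for studying this on tissue
microarrays (TMAs): per-patient scoring of senescence-marker positivity in
classified tumor epithelium, co-registration of consecutive sections so
that CD8+ cytotoxic T cells and p21+ senescent tumor cells can be related
spatially, nearest-neighbor proximity statistics, and survival
stratification by *optimal* cutpoints — including a three-tier
low / moderate / excessive split whose hallmark finding is a U-shaped risk
profile (moderate expression best).

It is aimed at digital-pathology and biostatistics users who have
cell-level export tables (any platform that emits per-cell coordinates,
compartments and marker intensities) plus right-censored DSS/PFS survival
data, and at methodologists who want a fully synthetic, truth-known
test bed for maximally selected survival statistics.

## The statistics at the core

**Kaplan-Meier / log-rank.** Survival is compared between groups with the
product-limit estimator S(t) = prod over event times t_i <= t of (1 - d_i/n_i)
and the k-group log-rank (Mantel-Cox) test: for each distinct event time,
observed minus expected events per group under the hypergeometric
distribution; chi-square with k-1 df.

**Optimal cutpoints.** For a per-patient score X (a marker's percent
positive, or a proximity statistic), the two-tier cutoff c* minimizes the
log-rank p over all midpoints between consecutive distinct scores that
leave both groups at least `min_group_frac` (default 10%) of the cohort:

    c* = argmin_c  p_logrank( {X <= c} vs {X > c} )

The three-tier extension searches all ordered pairs c1 < c2 exhaustively
with the global 3-group log-rank (df = 2), producing
low (X <= c1) / moderate (c1 < X <= c2) / excessive (X > c2) tiers.
Because the reported minimum p is selection-biased, `senesurv` always
accompanies it with a permutation family-wise p: shuffle the
score-survival pairing B times, rerun the *entire* search, and report
(1 + #{permuted min-p <= observed}) / (B + 1).

**Proximity.** After rigid (Kabsch/Procrustes, reflections disallowed)
co-registration of consecutive sections from matched landmarks, per
patient: the mean nearest-neighbor distance between p21+ tumor cells and
CD8+ cells, and the percent of CD8+ cells within 100 um of a p21+ cell.
Pairs are never formed across cores.

**Synthetic cohorts.** A generator emulates the study design (up to 598
patients, 3 cores of 1 mm per patient, markers NTAL / ARMCX3 / p21 /
EBP50 / gH2AX on one section, CD8 on the consecutive one) with known
latent truth: per-patient marker positivity, a CD8 attraction fraction q
toward p21+ cells, a per-patient rigid section transform, and exponential
survival whose hazard is driven by the driver marker's true tier
(U-shaped) and by q. Every downstream stage is therefore testable against
exact ground truth. See `docs/methods.md` for the model and defaults.

## Worked example

```python
from senesurv.config import RunConfig, SimConfig
from senesurv.pipeline import run_pipeline

cfg = RunConfig(sim=SimConfig(n_patients=200, seed=7), seed=7)
results = run_pipeline(cfg, "demo_out")
print(results["cutpoints"]["pct_within_r"]["DSS"]["k2"])
```

prints (abridged)

```
{'cutoffs': [82.37818732643272], 'chi2': 23.854752795214665, 'df': 1,
 'p_raw': 1.0388506637606515e-06, 'p_adjusted': 0.005,
 'group_sizes': [152, 48], ...}
```

meaning: on this simulated 200-patient cohort the optimal two-tier split
of "percent of CD8+ cells within 100 um of a p21+ tumor cell" falls at
82.4%, separating 152 low-contact from 48 high-contact patients with
log-rank chi2 = 23.9; the selection-corrected permutation p is 0.005
(its floor at B = 199 permutations), i.e. the proximity effect built
into the generator is recovered as a significant survival split. The
same run reports, e.g., for the NTAL three-tier DSS split cutoffs
(76.6, 85.8) with p_adjusted = 0.04 — a single n=200 cohort localizes
U-shaped boundaries only coarsely; the replicate studies below do it
properly at n=600.

The same pipeline is scriptable from the shell:

```bash
senesurv simulate --n 200 --seed 7 --out cohort/
senesurv run --config run.yaml --out results/
```

All intermediate artifacts (cells.csv, scores.csv, transforms.csv,
proximity.csv, tiers.csv, km/*.csv, results.json) are plain CSV/JSON;
rerunning with the same config and seed reproduces results.json byte for
byte.

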