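# Methods

This note records the models, conventions and numerical choices behind
`cirs`, including every place where the design was genuinely open.

## Data model and conventions

An immune profile is 20 features per blood draw: counts in 10⁹/L (wbc,
neut, eos, baso, mono, lymph and the six derived subset counts) and
fractions as proportions in [0, 1] (mono/lymph fractions of nucleated
cells; NK, T, CD4, CD8, Treg, B fractions of lymphocytes). Derived
counts are defined as lymphocyte count × subset fraction and the loader
enforces that identity to 1e-6 relative. Day 1 is the first day
post-transplant; all period intervals are closed (days 91–180 includes
both endpoints). `lymph ≤ wbc` and `cd4 + cd8 ≤ t` are warn-only on
loaded data (laboratory round-off violates them), hard by construction
in simulated data. Profiles with missing features are excluded from
embedding and scanning rather than imputed. Multiple draws of one
patient on one day are all kept.

Min–max rescaling is fitted once on the full profile set under analysis
and frozen; new data are transformed with the frozen map and clipped to
[0, 1]. A constant feature maps to 0 with a warning.

## Phase-space embedding

t-SNE (scikit-learn, Barnes–Hut) with perplexity 30, 1000 iterations,
PCA initialization, fixed seed, single-threaded; coordinates are
centered per axis so the discovery grid is reproducible. These
hyperparameters are package defaults, chosen for reproducibility —
reproduction of any particular published map geometry is not attempted,
and all downstream inference is invariant to the map's arbitrary
rotation/scale because the grid and radius are defined relative to the
embedding's own bounding box.

Axis gradients are ordinary least squares of each feature on (1, x, y).
The bootstrap average trajectory at time t uses the closed window
[t − δt/2, t + δt/2] with δt = 30/90/180 days for 0 < t ≤ 90,
90 < t ≤ 360, t > 360 respectively (boundaries: t = 90 → 30, t = 360 →
90); each of 100 bootstrap samples resamples in-window profiles with
replacement and the reported point is the mean (and sd) of the sample
means. Window rows are canonically sorted first so results are invariant
to input row order. Between-patient variance at t is the sample
variance (n − 1 denominator, summed over the two axes) of per-patient
mean in-window locations; a single-patient window reports 0. The n − 1
convention was fixed by the package's worked example (two patients at
(0,0) and (2,0) give variance 2).

## Anchor discovery

Grid: 121 × 121 equally spaced points spanning the bounding box of the
embedded profiles, inclusive. Distances for nearness are computed after
rescaling each axis by its span, so a radius of r *grid steps* equals
r/120 of each axis and the neighborhood is elliptical in raw units.

**Nearness radius (open design point).** The source analysis never
defines "near". The default here is 5 grid steps (≈ 4.2 % of each axis
span). The choice is driven by test power, not geometry: at cohort scale
(~1000 in-window patients) a 2-step neighborhood holds a median of ~4
patients, so no grid point can reach p < .01 whatever the effect size,
while 5 steps put a few tens of patients in a dense-region neighborhood
— enough for a univariate Cox fit to resolve a threefold hazard. The
radius is exposed in every API and config.

Per grid point, patients are labeled near (any in-window profile within
the radius) or far, and a univariate Cox model of all-cause death is
fitted on the label. Survival is clocked from a landmark at the
period's last day (e.g. day 180 for days 91–180); patients dead or
censored by the landmark are excluded, avoiding immortal-time bias. Ties
use the Efron approximation. The p-value is the likelihood-ratio test:
with small near-groups the Wald statistic collapses under near-monotone
likelihoods (Hauck–Donner), which would silently erase true anchors and
distort the permutation null. Grid points where either group has fewer
than 5 patients are untestable (p := 1). The 14 641 tests are
deliberately uncorrected, matching the discovery design; the safeguard
is validation on untouched splits, which the pipeline enforces
structurally (a leakage guard raises if a discovery stage receives
non-training outcomes).

**Anchor direction.** An anchor is a grid point with p < α (default .01)
*and hazard ratio > 1*. A two-sided p alone would also flag protective
regions — neighborhoods depleted of high-risk patients, e.g. the healthy
core of the map — and patients near those would absurdly be labeled
high-risk. Restricting to the harmful direction makes the signature mean
what its name says.

The per-grid-point Cox fits are computed by a vectorized Newton solver
specialized to a binary covariate (the partial likelihood then depends
only on group-wise risk-set and death counts per distinct event time),
which fits all grid columns simultaneously; it is cross-checked against
lifelines and against direct partial-likelihood maximization in the
tests.

Period screening uses k-fold (default 10) cross-validation within the
training split: anchors discovered on k−1 folds, held-out patients'
signature labels pooled, one post-landmark Cox test on the pooled
labels. The pooled CV p-value is a *screening heuristic*: its null
distribution mixes an atom at 1 (runs where no fold finds an anchor)
with mild anti-conservatism at small values (label selection and the
pooled test share outcomes through the risk-set averages, as is typical
of pooled-CV significance testing). The tests therefore assert
approximate calibration (rejection rate at .05 within a small factor of
nominal), and confirmatory inference rests on the held-out splits.

## Risk score

The published Composite Immune Risk Score is an intercept-free weighted
sum of eight features with the printed coefficients, applied verbatim;
the printed cutoff 2.50 is applied to that bare sum with strict
inequality (score = 2.50 is low-risk). Inputs are proportions; a
fraction outside [0, 1] raises rather than being rescaled silently (the
CLI offers `--percent` for 0–100 inputs). Patient-level scoring averages
the per-profile scores over the period's in-window draws, then
thresholds; patients without in-window data are excluded, not labeled.

Refitted scores use bidirectional stepwise logistic selection by AIC
from the empty model over all 20 profile features (entry/exit rule was
unspecified in the source; AIC was chosen over p-value stepping for
stability, and the greedy search is verified against exhaustive
best-subset AIC on small instances). Ties in AIC break by candidate
order, making the fit deterministic given input order. Quasi-separation
(runaway coefficients) triggers a warning and an L2-stabilized refit
(alpha 1e-3). The fitted model keeps its intercept internally but
reports an intercept-free linear predictor with a threshold chosen to
maximize Youden's J against the signature labels, for interface parity
with the published score.

## Survival validation

Kaplan–Meier curves (Greenwood variance) and two-sided log-rank tests,
and multivariate landmark Cox fits (Efron ties, Wald 95 % CIs on the
log-HR scale) are delegated to lifelines; the landmark exclusion rule is
shared with anchor discovery. The Cox solver is asked for full Newton
steps at 1e-12 precision (lifelines' damped default stalls ~1e-6 short
of the optimum on tiny datasets), falling back to library defaults on
convergence failure.

Cumulative incidence is Aalen–Johansen, implemented directly so that
Σ_cause CIF(t) + KM survival(t) = 1 holds to machine precision at every
event time; it is cross-checked against lifelines. Fine–Gray
subdistribution hazards use the IPCW formulation: subjects failing from
a competing cause remain in the risk set with weights G(t−)/G(T_i−)
from the Kaplan–Meier estimate of the censoring distribution, the data
are expanded to counting-process form at the target-cause event times,
and the weighted Cox fit is delegated to lifelines'
CoxTimeVaryingFitter. On a seeded fixture the coefficients agree with R
`cmprsk::crr` to ~2e-5 (frozen oracle values in the tests).

The logistic model for predictors of a high score uses severe aGVHD in
days 1–90, infection episodes in days 1–90 and age by default, with Wald
CIs on the log-OR scale.

## Synthetic cohort generator

The generator is the package's study condition, not a tuning knob. Each
lineage (neut, eos, baso, mono, NK, CD4, CD8, B, other-T, other-lymph)
recovers as mean(t) = plateau × (1 − exp(−t/rise_time)) on the natural
scale with multiplicative log-normal observation noise (sd 0.35–0.45)
and two per-patient, per-lineage log-normal random effects: level
(sd 0.25) and recovery rate (sd 0.6). Rate heterogeneity makes patients
fan out mid-recovery and re-converge at plateau — the source of the
early between-patient variance peak. Default plateaus and rise times
follow adult post-transplant kinetics: neutrophils/monocytes engraft in
weeks (rise 15–20 d), CD8 recovers fastest among lymphocytes (60 d),
CD4 and B slowest (180 d). Visits at nominal days 30, 60, 90, 135, 180,
270, 360 with Gaussian jitter (sd 4 d); no profile is emitted after a
patient's event/censoring day.

A latent fraction (default 0.15) of patients is *derailed*: lymphoid
plateaus are multiplied by exp(−derail_shift) with myeloid lineages
untouched, and the all-cause hazard is multiplied by exp(derail_log_hr)
(default log 3). derail_shift defaults to 2.0 — profound lymphoid
failure (plateaus at ~14 %) — because the planted-recovery design
presumes a displacement large relative to noise: min–max scaling of
right-skewed count distributions compresses log-scale shifts, and a
shift of ~1 leaves the derailed region overlapping the healthy mass so
that no location-based classifier (the signature included) can be
simultaneously sensitive and specific. Survival is exponential
(baseline 2e-4/day ≈ 20 % three-year mortality for non-derailed
patients), causes drawn from a fixed mix (relapse .45, infection-NRM
.25, other-NRM .30) independent of time, administrative censoring at
day 1095. Derailment also raises the severe-aGVHD probability
(.08 → .20) and the early-infection Poisson rate (.25 → .60), giving
the risk-factor regression planted structure. Splits are random
50/25/25 (a date-threshold split, as used for real data, is supported
via the outcomes table).

**What the generator does not emulate.** Cause of death is independent
of time and of lineage specifics; there are no center/batch effects, no
GVHD–infection feedback, and no late re-convergence: derailed survivors
stay displaced, so between-patient variance does not fall after day 90
the way the real cohort's does (it plateaus high instead). Passing
tests therefore demonstrate that the pipeline recovers planted structure
of this kind, not that the clinical effect sizes transfer.

## Problem sizes and determinism

Tests run the full discovery at the default n = 2000 (≈13 500 profiles;
t-SNE is the dominant cost), the permutation null at a 41 × 41 grid with
50 permutations, Cox calibration with 200 replicates of n = 2000, and
the end-to-end determinism check at n = 400 with a 61 × 61 grid — sizes
chosen so the whole suite runs on one CPU in minutes while keeping every
statistical property at a scale where it is actually informative. All
randomness flows from explicit seeds; pipeline outputs are written with
fixed float formatting, and two runs with the same config are
byte-identical.

## Known limitations

- t-SNE has no out-of-sample projection; new data are embedded by
  re-running on the union or assessed through the score only.
- The published coefficients cannot be re-derived here (that requires
  the restricted patient data and the original stepwise path); they are
  applied as printed and verified as constants.
- The Fine–Gray expansion is O(n × events of target cause) rows; fine at
  cohort scale, not tuned for very large registries.
- The pooled CV screening p-value is approximately, not exactly,
  calibrated (see above).
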