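# Methods

## Scope and model

`ntcpkit` implements data-driven normal tissue complication probability
(NTCP) modelling for late gastrointestinal (GI) toxicity of the rectum after
external-beam prostate radiotherapy. The core model is multivariate
logistic:

    NTCP(x) = e^{g(x)} / (1 + e^{g(x)}),
    g(x)    = β0 + β1 x1 + … + βn xn,

where the covariates x mix dosimetric summaries of the rectal dose–volume
histogram (DVH) — Vx (percent volume receiving ≥ x Gy), Dmean, Dmax — and
binary clinical factors coded yes = 1 / no = 0 (antihypertensive/
anticoagulant use, prior acute GI toxicity, diabetes, smoking, …). A
traditional Lyman–Kutcher–Burman (LKB) model serves as comparator: the DVH
is reduced to the generalised equivalent uniform dose
gEUD = (Σ v_i D_i^{1/n})^n and NTCP = Φ((gEUD − TD50)/(m·TD50)).

The binary endpoint is crude incidence of grade 1–2 late GI toxicity
(RTOG/EORTC scale); no time-to-event structure is modelled.

## Dose–volume histograms

Curves are stored in cumulative (volume ≥ dose, non-increasing) or
differential (point masses) form, volumes exclusively as percent of organ
volume; absolute-volume input is rejected. Conversion differential →
cumulative places each mass as a step, encoded as paired grid points 1e-9 Gy
apart so that linear interpolation on the converted grid reproduces the
exact suffix-sum step function. Consequently:

- Vx on cumulative curves = linear interpolation at x (fine grids ≤ 1 Gy in
  practice); on differential curves = exact sum of masses at doses ≥ x.
- Dmean = mass-weighted mean dose over the *whole* organ; volume not
  accounted for by the histogram is assumed unirradiated (0 Gy). Cumulative
  curves are differenced onto bin centres first.
- Dmax = largest grid dose carrying positive volume (grid resolution; no
  tail extrapolation).
- gEUD normalises fractional volumes over the *irradiated* organ (Σv_i) and
  is evaluated in log space (logsumexp) so strongly serial behaviour
  (n → 0, exponent 1/n large) stays finite; Φ is evaluated through the
  error function rather than by numerical integration of the Lyman
  integral — mathematically identical and exact to machine precision.
- A Vx threshold above the grid maximum yields 0 with a logged note, since
  exported planning DVHs legitimately end at the prescription maximum.

No fractionation (EQD2) correction is applied to DVH bins; LKB parameters
(n, m, TD50) are endpoint-specific configuration inputs applied to physical
dose. The shipped `DEMO_PARAMETERS` set is a synthetic placeholder for
tests and demonstrations, not a fitted or published parameter set.

## Logistic fitting

Maximum likelihood by Newton–Raphson with step halving (log-likelihood is
non-decreasing across iterations); convergence when max |score| < 1e-8,
cap 100 iterations. Standard errors come from the inverse observed
information; p-values are two-sided Wald (stated in the summary output,
since score/likelihood-ratio variants would differ in small samples).
Covariates enter on their natural scales — V-type covariates in percent
(0–100), so an odds ratio of 1.03 means "per percentage point of rectal
volume". No penalisation. Perfect separation is detected both by a direct
pre-check on binary covariates and by coefficient divergence (|β| > 40)
during iteration, and raises an error naming the offending covariate.

## Variable selection

1. **Univariate screen.** Spearman rank correlation (average ranks for
   ties) of every candidate covariate with the outcome; p-values from the
   t-approximation. Constant covariates report rs = 0 with a degeneracy
   flag.
2. **Pruning.** Pairwise Spearman > 0.75 in absolute value drops the member
   with the weaker outcome correlation. Candidates are visited in
   decreasing |rs| (ties by name), so the result is deterministic and
   independent of input ordering; of k mutually correlated covariates
   exactly the strongest survives.
3. **Bootstrap selection.** 500 resamples of n patients drawn with
   replacement; the same resamples are reused across model orders. For each
   resample and each order k ≤ max_order, *every* k-subset of the pruned
   pool is fitted by logistic regression (the pool is small, ≤ ~13, so
   exhaustive search is tractable and deterministic) and the subset with
   the highest Spearman Rs between predicted NTCP and outcome on the
   resample wins. Ranking subsets by win frequency (ties: higher mean Rs,
   then lexicographic names) gives the model ranking; the chosen order is
   the smallest k whose mean best-subset Rs gain at k+1 falls below 0.01
   (defaulting to the Rs-maximising order when the gain never saturates).
   In-sample Rs on the resample is the default criterion; `oob=True`
   scores the fitted subsets on out-of-bag patients instead, which is the
   honest choice for order selection (in-sample Rs grows mechanically with
   order through overfitting, so the plateau rule cannot detect a null
   pool in-sample).

   Single-class resamples are skipped and counted; non-convergent subset
   fits within a resample are excluded from that resample only. For speed
   all subsets of one order are fitted simultaneously by a batched Newton
   solver (ridge 1e-8 guards resample-induced singularity); it is
   numerically equivalent to the public single-model fit and cross-checked
   against it in the test suite.

   Randomness derives from a single master seed through per-bootstrap
   `SeedSequence` substreams: reports are bit-stable across runs and under
   any parallel split of the resamples.

## Evaluation

- **ROC/AUC**: trapezoid over all unique prediction thresholds; equals the
  Mann–Whitney concordance probability with ties counted ½ (verified
  against brute-force pair counting in tests).
- **Youden cut-point**: threshold maximising J = sensitivity +
  specificity − 1; ties are broken toward higher specificity (the more
  conservative cut-off, fewer false positives). For a single-covariate
  model the probability threshold is mapped back to the covariate scale
  through the monotone link.
- **Calibration**: patients sorted by predicted risk and split into
  equal-count bins (sizes differ by ≤ 1; default 5 bins for n ≈ 57,
  configurable), reporting mean predicted NTCP vs observed event rate.
- **Model Rs**: Spearman correlation between predicted NTCP and the binary
  outcome — the conventional predictive-power summary of this modelling
  tradition. All AUCs are apparent (in-sample) and labelled as such; no
  optimism correction or DeLong testing.

## Synthetic cohort

The generator emulates the reference study population (n = 57) so the whole
pipeline is testable without patient data:

- **Clinical covariates**: independent Bernoulli draws at the reference
  prevalences (e.g. AH/AC 0.649, acute GI toxicity 0.368, hormonal therapy
  0.93). Acute toxicity is exogenous by default; an optional mode links it
  to the dosimetric severity through a logistic in the latent severity
  (slope 1.5 around the marginal logit), preserving its prevalence.
- **Dosimetry**: one latent per-patient severity s ~ Beta(1.2, b) with b
  solved so the scaled median matches V65 = 27.0% on [0.4, 98.2]. The
  cumulative DVH is logistic in dose, V(d) = 100(1+u)/(1+u e^{d/w}), with
  the free parameter u solved in closed form so V(65) hits the patient's
  target exactly; the width w = 16 Gy with ±2σ-clipped lognormal jitter
  (σ = 0.15) makes the Vx family strongly but not perfectly rank-correlated
  (adjacent Vx > 0.99, V50–V70 pairwise > 0.75, triggering the pruning
  rule), as one anatomy/plan drives the whole real DVH. Dmean integrates
  the curve; Dmax ~ 73 + 6.7·Beta(2,2) Gy is drawn independently of the
  severity because in practice it is hotspot-driven and nearly
  uncorrelated with outcome, and it caps all curves below 80 Gy
  (76 Gy prescription + margin). The study's single low-Dmax outlier
  (47 Gy) is not emulated: a cutoff below 65 Gy would contradict V65 > 0
  for every patient.
- **Outcome**: late_gi ~ Bernoulli(NTCP(x)) under a supplied coefficient
  set, by default the reference three-variable model (β0 = −1.283,
  βV65 = 0.028, βAH/AC = −1.442, βacute = 1.458).

What the generator does **not** emulate: real treatment-planning dose
distributions, correlations among clinical covariates, time-to-event
censoring, or inter-fraction variation. Passing tests therefore demonstrate
correctness of the statistical machinery under a faithful marginal/
correlation structure, not clinical validity on real cohorts.

## Problem sizes used in verification

The shipped verification runs use cohorts of n = 2000 (100 replicates) for
coefficient recovery, 20 replicate cohorts at the study size n = 57 with
500 bootstraps each for the selection replica, and 200 study-size cohorts
for the performance summaries; these sizes give stable estimates of each
quantity while keeping a full run in the minutes range.

## Known limitations

- At the study sample size (n = 57) the identity of the "best" model is
  intrinsically unstable: chance correlations of noise covariates are
  properties of a cohort, persist across all bootstrap resamples, and
  routinely rival true effects of the magnitude implied by the reference
  coefficients (population Spearman ≈ 0.22–0.28). Replicate simulations
  show the generating variable trio tops the order-3 ranking only in a
  minority of cohorts, and only ~1 in 5 cohorts reproduces a univariate
  table with all three true predictors above every noise covariate. The
  bootstrap ranking should therefore be read as a stability diagnostic,
  not as evidence that the top-ranked model is the true one.
- Near-collinear Vx metrics (pairwise rank correlation > 0.95) make the
  choice of the surviving dosimetric representative essentially arbitrary
  at this sample size; the pruning rule is deterministic but its winner
  varies between replicate cohorts.
- Wald standard errors and p-values are first-order approximations; with
  19 events and 3 covariates they are at the edge of their comfort zone.
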