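# Methods

## The forward model

Soft tissue under an AFM step force creeps with a two-stage power law: a
fast regime with exponent `alphaL` between 0.5 and 1 below a few tenths of
a second, and a slow regime with exponent `alphaR` near 0.2 at longer
times.  `viscoclass` represents this with a four-branch relaxation modulus
in the Laplace domain,

    Ghat(s) = E3 + E2 (s/w0)^alphaR + E1 (s/w0)^alphaL + eta s,   w0 = 1 rad/s,

a compact surrogate for self-similar hierarchical rheology: `E3` is the
elastic plateau of the whole structural network, the `E2` branch carries the
slow power law of the cytoskeletal fiber network, the `E1` branch the fast
power law of the cytoplasm, and `eta` its Newtonian flow.  Creep compliance
follows from `Jhat(s) = 1/(s Ghat(s))` by Gaver–Stehfest inversion with
N = 14 terms, which reproduces the closed-form spring, dashpot and
spring-pot limits to better than 1e-6 relative error (the suite requires
0.5%).  Fixing `w0 = 1 rad/s` makes the branch moduli identifiable from the
exponents; all moduli are quoted at that reference rate.

Derived markers: total modulus `Esum = E1 + E2 + E3`; relaxation time
`tau = eta / E1`; transition frequency
`fT = (w0 / 2 pi) (E2/E1)^{1/(alphaL - alphaR)}`, the frequency at which the
fast and slow branches are equal (verified against a bisection oracle).

Indentation records convert to compliance through Hertz contact for a
spherical probe, `J(t) = 4 sqrt(R) d(t)^{3/2} / (3 F (1 - nu^2))`, with
`nu = 0.5` (incompressible tissue), probe radius 10 um and a 10 s hold.

### Units

Group statistics are carried in "paper units" U so that the calibrated group
means print as the familiar numbers (healthy mean `Esum` = 456.1).  When the
simulator emits SI indentation records it maps 1 U = 1 kPa, a physiologically
plausible scale for liver; classification is invariant to this choice because
features are z-scored.

## The synthetic cohort

No public AFM dataset exists for this design, so the cohort generator is a
first-class, tested component.  Three groups — healthy (status 0), treated
fibrotic (status 1), diseased fibrotic (status 2) — receive 800 measurements
each by default.  Per draw:

- `E1 ~ LogNormal` (arithmetic mean 100 / 149.4 / 500 U; CoV 0.39);
  `E2 = E1 * r12`, `E3 = E1 * r13` with log-normal ratios (means 2.0 and
  1.561, CoV 0.10).  The shared `E1` factor makes the moduli within a group
  almost perfectly correlated — fibrotic stiffening raises every structural
  level together — and fixes the group means of `Esum` at 456.1, 681.4 and
  2280.5 U (diseased = 5 x healthy).
- `eta ~ LogNormal` (means 50 / 70 / 250 U s, CoV 0.40).
- `alphaL ~ N(0.85 / 0.72 / 0.55, 0.05)` and
  `alphaR ~ N(0.20 / 0.21 / 0.22, 0.025)`, truncated to (0.5, 1.0) and
  (0.10, 0.35) with per-draw rejection until `alphaL > alphaR + 0.1`.
  `alphaR` is deliberately only weakly informative.
- The measurement is the Hertz-inverted depth multiplied pointwise by
  `exp(eps)`, `eps ~ N(0, 0.03)` — 3% multiplicative noise, which becomes
  4.5% on compliance through the 3/2 Hertz power.  No monotone enforcement:
  fitting must tolerate local dips.

The spreads are calibration choices: they make `Esum` alone almost separate
healthy from diseased while leaving healthy and treated heavily overlapped
in `Esum`, with the exponents and transition frequency carrying the residual
treated-state signal.  What the generator does **not** emulate: spatial
heterogeneity, collagen-proximity effects, instrument drift, cantilever
dynamics, or any departure of real liver rheology from the surrogate model.
Passing tests therefore demonstrate the soundness of the pipeline under the
stated statistical structure, not performance on real tissue.

## Marker extraction

### Slope windows

The short-time exponent is read by log-log regression over `[t_min, 0.1]` s.
The long-time window is `[1.5, 6]` s: below ~1 s the fast branch still
contributes, and beyond ~6 s the network plateau `E3` progressively flattens
the curve, so the slow-branch exponent (~0.2) is expressed between the two.
Over `[3, 10]` s the plateau biases the regression slope down to ~0.13 under
the default calibration, which is why that window is not the default.

### Identifiability, and why the fit is penalized

At 4.5% compliance noise on 60 points spanning 2.7 decades, the
six-parameter inverse problem is sloppy.  A Cramér–Rao analysis at the
healthy defaults gives standard deviations of order 1 in the log-moduli
(and ~9 in `ln fT`): many parameter combinations fit any one curve equally
well, and an unpenalized least-squares fit returns marker values dominated
by noise along the flat directions while still reporting R² ≈ 0.99.

`fit_hierarchical_model` therefore minimizes a penalized objective,

    sum_i [(ln J_model(t_i) - ln J_obs(t_i)) / sigma_hat]^2
      + sum_k [(theta_k - theta0_k) / prior_sd_k]^2 ,

with three design elements:

1. **Coordinates.**  `theta = (ln E1, ln s_x, ln E3, ln eta, alphaL,
   alphaR)` where `s_x = 2 pi fT` is the branch-crossover rate and
   `E2 = E1 s_x^{alphaL - alphaR}`.  Carrying the crossover as a coordinate
   lets the visible kink of the curve (and its prior) constrain the
   transition frequency directly; in the naive coordinates the same
   information passes through `(E2/E1)^{1/(alphaL-alphaR)}`, whose exponent
   amplifies small, independent errors.
2. **Prior centres from robust descriptors.**  Window slopes for the
   exponents; the compliance level near `t = 1/w0` (corrected by the local
   `Gamma(1 + slope)` factor) for the total level; the intersection of the
   two regression lines for the crossover; a 10% Newtonian share for `eta`.
   Prior widths (0.6 on log-amplitudes, 1.0 on `ln E3`/`ln eta`, 0.08/0.04
   on the exponents) are wide enough that the likelihood dominates wherever
   the data are informative.
3. **Noise-scaled weighting.**  `sigma_hat` is estimated per curve from
   fourth differences of `ln J` (which cancel the smooth trend).  On a
   noiseless curve `sigma_hat` collapses to ~1e-7, the data term dominates
   every prior, and all six parameters are recovered to well under 1%
   relative — the penalty costs nothing where the data decide.

The solver is trust-region least squares with a hand-derived analytic
Jacobian, tight tolerances (ftol = xtol = 1e-12, gtol = 1e-14) because the
sloppy valley otherwise stalls progress, and a multi-start strategy (one
heuristic start plus up to four perturbed restarts, stopping early once the
data chi-square reaches the noise floor).  Failure never raises: the result
carries `converged = False` with diagnostics.

R² is reported on the linear compliance scale, `1 - SS_res/SS_tot`.  Rows
with `converged = False` or R² < 0.9 are dropped from the feature table and
counted; under the default cohort fewer than 1% of fits are lost and the
median R² is ≈ 0.993.

The feature table mirrors the two-path extraction of the measurement
pipeline: `alphaL`/`alphaR` come from the double power-law regressions;
`E1, E2, E3, eta` (and the derived `Esum`, `tau`, `fT`) from the
hierarchical fit.

### What extraction can and cannot recover

The measurement itself caps what any estimator can do.  An RBF-SVM trained
directly on the 60 raw log-compliance values separates healthy from treated
tissue with ~0.78 accuracy under the default noise — the nine extracted
markers do slightly better (~0.81) because they denoise along model
structure, but no honest extraction can reach the ~0.93 attainable from the
ground-truth parameters.  The same ceiling applies to the single-marker
transition-frequency and `alphaR` tasks: the diseased-group crossover sits
near the short edge of the time grid where the Newtonian branch masks it,
and the long-time exponent's 0.01-wide group shifts are smaller than the
regression noise of any window.  These limits are measured and documented
rather than patched: where a headline figure depends on them the acceptance
suite reports the shortfall.

## Classification protocol

Soft-margin SVM with Gaussian kernel `exp(-||xi - xj||^2 / 2 sigma^2)`
(scikit-learn's SVC supplies the QP solver; `gamma = 1/(2 sigma^2)`).
Features are z-scored with training-split statistics — required for a single
shared kernel width across markers whose units differ by orders of
magnitude.  Stratified 70/30 train/test splits; hyperparameters selected by
stratified 10-fold cross-validation on the training split over
C ∈ {0.1, 1, 10, 100} and sigma ∈ {0.5, 1, 2, 5}, ties broken toward
smaller C then smaller sigma.  Multi-class tasks use one-vs-one voting;
multi-class ROCs are macro one-vs-rest on continuous decision scores.
Headline accuracies are means over five cohort seeds.

## Marker ranking and ablation

SVM-RFE uses the kernel-space margin criterion
`W^2 = sum_ij a_i a_j y_i y_j kappa(x_i, x_j)` summed over one-vs-one
subproblems, zeroing one z-scored feature at a time while keeping the dual
coefficients fixed, and eliminating the feature with the smallest
`|Delta W^2|` each round.  Because the four moduli are nearly collinear by
construction, RFE ranks *one* modulus high and lets the redundant copies
sink — eliminating `Esum` while `E1`/`E2` survive costs almost no margin.
Single-marker accuracy and RFE rank therefore disagree for redundant
markers; this is a property of recursive elimination, not a defect.

Feature ablation replaces markers cumulatively with fresh `N(0, 1)` draws in
z-scored space (in both splits), retraining at every step so that each curve
point isolates information loss rather than train/test distribution shift.
Curves run from the intact baseline to all-noise, which lands at chance
(1/3 for the balanced three-state task); in inverted (low-to-high) order the
largest single-step drop occurs when the last — most important — marker
goes.

## Drug-efficacy readout

Two binary classifiers are trained with the standard protocol: treated vs
healthy and treated vs diseased.  Effective treatment makes the first
accuracy fall toward chance and keeps the second high; the recovery index is
`acc_TD - acc_TH` in [-0.5, 0.5].  Verdicts: `full_recovery` when
acc_TH ≤ 0.60 and acc_TD ≥ 0.80; `no_recovery` in the symmetric case;
`partial_recovery` otherwise.  The thresholds are design choices; the index
is invariant to global modulus rescaling (z-scoring) and rises monotonically
as the treated group's parameters are interpolated from diseased-like to
healthy-like.

## Problem sizes and determinism

Default experiments use 800 measurements per group (2400 curves per cohort
seed), ~7 ms per penalized fit, and five cohort seeds for every stochastic
headline figure; the full acceptance battery runs in roughly ten minutes on
one core.  Every random draw (cohort sampling, measurement noise, splits,
folds, restarts, ablation noise) flows from explicit integer seeds, so any
run is reproducible bit-for-bit.

## Known limitations

- The surrogate modulus is not the hierarchical ladder model of the
  underlying theory; it reproduces the documented phenomenology (two-stage
  creep, transition frequency, plateau and flow limits) but its parameters
  should not be read as micro-structural constants.
- The treated-vs-healthy and single-marker `fT`/`alphaR` tasks are
  information-limited at the default noise (see above); reported accuracies
  for those tasks sit below the ideal-marker values.
- `eta` and the moduli are strongly status-correlated by calibration, so the
  viscosity is not a "minimal-correlation" marker here; only `tau` and
  `alphaR` are near-uninformative.
- Printed modulus units follow the source material's convention ("MPa");
  literature liver moduli are kPa-scale, hence the 1 U = 1 kPa SI mapping.
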