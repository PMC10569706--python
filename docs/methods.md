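# Methods

This note documents the models implemented in `petkin`, the conventions and
defaults behind them, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter when reading results.

## Time base and units

Time is minutes post-injection throughout. Frames are `(t_start, t_end)`
pairs; the representative time of a frame is its midpoint, and model
predictions that are compared with frame data are *frame averages* computed
from analytic antiderivatives, not midpoint samples. This matters for the
early 30–60 s frames, which are short relative to the ~5-min fast blood
half-life. Activity concentrations are kBq/ml, decay-corrected to injection
time; rate constants are 1/min; the physical half-life of ⁸⁹Zr is 78.4 h.

SUV uses the universal water-equivalent convention (1 kg body weight ≡
1000 ml distribution volume), so `SUV = conc · weight / dose` with
concentration in kBq/ml, weight in kg, dose in MBq. SUVpeak is the mean of
the 8 hottest voxels; at 2.344-mm isotropic voxels that support is
8 · 0.2344³ ≈ 0.103 ml.

## Input function

Whole blood is modeled as `Cp(t) = Σⱼ Aⱼ e^(−λⱼ t)` with three non-negative
components. Triexponential fitting is multimodal, so the fit is staged:
amplitudes are solved by non-negative least squares at each rate triplet from
an 8-point log-spaced grid over [1/2000, 1] min⁻¹ (all 56 triplets), and the
best candidates are refined jointly by bounded least squares on the weighted,
frame-averaged objective. Degenerate solutions — a component with zero
amplitude, a zero rate carrying amplitude, or two indistinguishable rates —
are flagged rather than hidden: a triexponential fitted to fewer-exponential
data is not uniquely parameterized even when it reproduces the curve
exactly.

The reference synthetic curve uses the half-lives 5.1 min / 55.9 min /
22.1 h with amplitude fractions (0.6, 0.3, 0.1) and a 4 kBq/ml scale
(≈18.5 MBq injected into a ~5-liter blood pool); the fractions and scale are
scenario choices, since only half-lives are constrained by the study the
protocol emulates.

## Compartment models

The serial two-tissue model is used: free compartment C₁ exchanges with
blood (K₁ in, k₂ out), binds into C₂ (k₃), and returns (k₄):

    dC₁/dt = K₁·Cp − (k₂+k₃)·C₁ + k₄·C₂
    dC₂/dt = k₃·C₁ − k₄·C₂

with eigenvalues `α₁,₂ = [(k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄)]/2`. The
impulse response is a sum of at most two exponentials, and its convolution
with the triexponential input is evaluated in closed form (confluent
`t·e^(−rt)` terms are used when two rates coincide within 10⁻⁹). Model TACs
are therefore exact exponential mixtures — evaluation, integration, and
frame-averaging are analytic, and the closed form is verified against an
ODE-solver oracle at 10⁻⁶ relative in the tests. With k₃ = 0 the model
reduces exactly to the one-tissue response `K₁e^(−k₂t)`.

**Blood-fraction convention.** The measured signal is modeled as

    C_model(t) = C_tissue(t) + v_b · C_wb(t)

with image-derived *whole-blood* concentration (not metabolite-corrected
plasma) as both the input and the vascular term. The alternative convention
with a `(1 − v_b)` complement on the tissue term is equally common; the
no-complement form is used here because it makes the macroparameter
`Kᵢ = K₁k₃/(k₂+k₃)` exactly the late-time Patlak slope of the measured TAC
for irreversible kinetics, so compartmental Kᵢ, Patlak slopes, and late TBRs
are mutually consistent estimates of the same influx quantity. Under the
complement convention every Patlak slope would carry an extra (1 − v_b)
factor relative to the fitted Kᵢ. Fitted v_b values are convention-dependent
and should not be compared across software without checking this.

**Weights.** `wᵢ = Δtᵢ · e^(−λ_phys·t_mid,i)`, i.e. variance proportional to
the decay-uncorrected count rate on the decay-corrected scale; frames of the
late sessions (start ≥ 120 min, in practice the 6-h and 48-h scans) are
divided by 10 (configurable) to reflect the much noisier late input-function
measurement and the single data point per session; weights are normalized to
sum to the number of frames (AICc differences are invariant to that overall
scale, which the tests assert).

**Fitting.** Bounded trust-region least squares (`scipy.optimize.
least_squares`) on the weighted residuals, with physiologic bounds
v_b ∈ [0, 0.6], K₁ ∈ [0, 2] ml/cm³/min, k₂,k₃,k₄ ∈ [0, 1] min⁻¹, multi-start
from a conservative default (v_b=0.05, K₁=0.01, k₂=0.01, k₃=10⁻³, k₄=10⁻⁴)
plus log-uniform random starts (5 by default, seeded). Parameters can be
fixed (e.g. v_b = 0.4 for spleen, where v_b and K₁ are too correlated to
separate); fixed parameters are excluded from the AICc parameter count and
from sensitivity/correlation analyses. Parameters ending at a bound are
flagged, not treated as errors. Convergence tolerances are 10⁻¹² on cost,
step, and gradient with 2000 function evaluations per start; noiseless
round-trips recover parameters to ≪0.1%.

## Model selection

`AICc = n·ln(WRSS/n) + 2k + 2k(k+1)/(n−k−1)` with n the number of fitted
frames (48 for the full protocol, late frames counted as full observations)
and k the number of *free* parameters; the Gaussian noise variance is
profiled out. Ties below 10⁻⁹ go to the smaller model. Fits are only
comparable on identical data and weights, which is enforced via a data
fingerprint.

## Graphical analysis

Patlak x and y use the *fitted* triexponential (analytic integral and
denominator), not raw blood frames, so late points are not corrupted by the
noisy late blood measurement. The equilibrium window cannot be determined
from two late time points, so the window is an explicit argument (default:
frame midpoints ≥ 30 min) and never auto-selected. For k₄ = 0 the late-window
slope equals Kᵢ (tested at 5%); k₄ > 0 biases the slope downward.

## Identifiability

Sensitivities are normalized central finite differences
`S_j(t) = (∂C/∂θ_j)·θ_j/C` with relative step 10⁻³ (forward at the
non-negativity boundary). Correlations come from `cov ∝ (JᵀWJ)⁻¹` at the
parameter point, with a pseudo-inverse and a degeneracy flag when the
information matrix is rank-deficient.

The frame-noise model is Gaussian with

    σᵢ² = Sc² · C_model(tᵢ) · e^(λ_phys·t_mid,i) / Δtᵢ

a standard PET TAC noise form (variance tracking the decay-uncorrected count
rate); the variance function is pluggable for other noise assumptions. The
scale Sc is estimated per subject by making the mean standardized squared
residual equal one. Monte-Carlo bias/SD/RMSE refits each of n (default 100)
noisy replicates starting from the truth plus one random start — a
cost-bounded probe of local minima, not a global search. Negative simulated
concentrations are clipped to zero (negligible at the noise scales used —
the per-frame SD calibration test shows the clipped empirical SD matches σᵢ
within 5%). Percentages are relative to the generating value; a parameter
whose true value is 0 reports NaN. SD uses the population normalization so
RMSE² = bias² + SD² holds exactly. Reports with >20% failed refits are
flagged unreliable.

## Group statistics

The exact Mann-Whitney null is computed by the standard counting recursion
(equivalent to enumerating all C(n₁+n₂, n₁) assignments); the two-tailed p is
the doubled smaller tail capped at 1. Under complete separation this gives
the minimum attainable values 2/56 ≈ 0.036 (5 vs 3), 2/35 ≈ 0.057 (4 vs 3),
and 2/20 = 0.1 (3 vs 3). No tie correction is implemented — tied pooled
values raise an error (the intended measurements are continuous); the
cohort-level wrapper can instead report NaN for tied metrics (this happens
naturally when a 1T region yields identically zero Kᵢ). Spearman ρ is
computed from ranks, with exact permutation p for n ≤ 9 (mid-ranks plus a
warning, and the t-approximation, when ties occur). Bonferroni-adjusted
p-values are reported as a sensitivity column but do not drive the
significance flag, mirroring an uncorrected-primary-analysis design.

## Synthetic data generator

The generator emulates: the exact dynamic framing (6×60, 16×30, 2×60,
12×120, 10×300 s) plus 60-min frames at 6 h and 48 h; triexponential blood
curves with minute/hour half-lives; tissue TACs from the compartment models;
and the frame-based noise model above. Region archetypes are *scenario
parameters* chosen to exhibit the qualitative organ behaviors the analysis
is designed around, not measurements:

| archetype    | v_b | K₁ (ml/cm³/min) | k₂ (1/min) | k₃ (1/min) | k₄ (1/min) | true model |
|--------------|-----|------|------|------|-------|------|
| spleen       | 0.40| 1.5  | 0.85 | 0.10 | 0.001 | 2T5P |
| bone marrow  | 0.15| 0.25 | 0.20 | 0.05 | 0.001 | 2T5P |
| lung         | 0.15| 0.03 | 0.08 | 0.01 | 0     | 2T4P |
| lymph node   | 0.03| 0.02 | 0.01 | 0    | 0     | 1T3P |

The spleen
regime's fast free-compartment exchange makes v_b and K₁ >90% correlated —
the reason spleen fits fix v_b = 0.4 — and both two-tissue regimes place the
bound-compartment peak at ~19–20 h before declining, consistent with
trafficking-driven efflux. Cohorts draw per-subject parameters log-normally
(unit mean, default CV 15%; blood half-lives CV 10%) and give the case group
a ×1.5 bone-marrow k₃ (elevated net influx). The default noise scale
Sc = 0.05 yields ~2% relative noise on early dynamic frames.

What the generator does **not** emulate: voxel-level images and VOI
segmentation, motion, scatter/randoms residuals, air-fraction effects in
lung, cell-trafficking compartments distinct from ordinary rate constants,
dual blood supply (liver), or plasma-metabolite kinetics. Passing tests
therefore show the estimation machinery is correct under the stated model,
not that the model is adequate for any particular real organ.

## Problem sizes

The test suite and acceptance checks use the full 48-frame protocol; the
Monte-Carlo suites use 100 replicates (matching the identifiability design),
the convolution oracle 100 random parameter draws, and cohort demonstrations
5-vs-3 subjects with 1–2 regions — sizes chosen so the whole suite runs in
a couple of minutes on one CPU while exercising every code path at the
design's native scale.

## Known limitations

* Exit from local minima is only as good as the multi-start budget; pathological
  TACs can converge to boundary solutions (flagged via `at_bounds`).
* The exact Mann-Whitney test has no tie handling by design; discretized
  metrics need a different test.
* The noise model's late-time behavior is optimistic when the model itself is
  fitted from only two late points (possible overfitting of the late frames
  is not detected by the residual-based Sc estimate).
* `fit_triexponential` assumes data spanning both early (<90 min) and late
  (>300 min) times; single-session data are rejected rather than
  extrapolated.
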