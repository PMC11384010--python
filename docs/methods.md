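# Methods

This note documents the models implemented in `akdyn`, the conventions chosen
where the science left the design open, and what the synthetic-data tests do
and do not demonstrate.

## The conformational–kinetic network

**States.** Six ligation states — apo (E), binary complexes ET (ATP) and EM
(AMP), misaligned ternary complexes ETMᵢ ("ATP first" order) and EMTᵢ
("AMP first"), and the catalytically competent ETM — each present as an open
and a closed conformer: 12 states. The fixed enumeration (ligation order
E, ET, EM, ETMᵢ, EMTᵢ, ETM; open before closed) makes every matrix
reproducible bit for bit.

**Edges.**

* *Binding.* Ligand association/dissociation connects open conformers only:
  the closed active site is shielded from solvent. On-rates are
  pseudo-first-order k_on·[ligand] with k_on = 1×10⁸ M⁻¹s⁻¹ (diffusion
  limited) for both nucleotides; off-rates follow mass action,
  k_off = k_on·Kd. Note that k_on is *not* a nuisance parameter in this
  topology: because binding runs through open conformers only, association
  flux competes with the conformational exchange, and turnover rises with
  k_on until binding exchange outruns the relaxation (the suite documents
  this monotone, saturating dependence over five decades). The
  diffusion-limited value sits in the physically expected intermediate
  regime and reproduces the measured turnover optimum.
* *Conformational exchange* k_open/k_close within every ligation state.
* *Rearrangement* ETMᵢ(open) → ETM(open) at k_r^T and EMTᵢ(open) → ETM(open)
  at k_r^M, irreversible. Substrates cannot reorient while enclosed, so
  rearrangement is open-only; irreversibility reflects that the reverse
  step is unobservable in the fitted data.
* *Catalysis* ETM(closed) → E(open) + products at k_cat, irreversible; the
  forward assay regenerates substrates and removes products, so the reverse
  chemical step is not modeled. The recycling edge keeps the generator
  conservative, so the stationary distribution of the full matrix directly
  yields turnover v₀/[E] = k_cat · p_ss(ETM, closed).

**Generator convention.** Column generator, dp/dt = G p; off-diagonal G[j,i]
is the i→j rate, diagonals are minus the column sums (exact to one rounding
ulp of the largest rate; with rates of order 10⁵ s⁻¹, float64 cannot do
better than ~10⁻¹⁰ absolute).

**Solvers.** The stationary state solves the bordered system {G p = 0,
Σp = 1} by least squares with a rank check; independently, stiff BDF
integration (rtol 10⁻⁸, atol 10⁻¹², steady state declared at
‖dp/dt‖∞ < 10⁻¹⁰ s⁻¹) provides a cross-check, and `cross_check=True`
enforces agreement to relative 10⁻⁶. Degenerate networks (e.g. catalysis and
rearrangement both switched off, which disconnects ETM) are reported as a
rank error rather than silently resolved.

**Parameter values.** The wild-type preset carries k_cat = 3.1×10³ s⁻¹,
k_r^T = 4.2×10³ s⁻¹, k_r^M = 370 s⁻¹, Kd(ATP) = 50 µM and Kd(AMP) =
332/522/758 µM at 0/0.4/0.8 M urea. Urea enters the model *only* through
Kd(AMP) and the conformational equilibria; the catalytic and rearrangement
constants are urea-independent (shielded active site).

**Conformational rates per species.** smFRET provides equilibrium
coefficients K_C per condition, not per species, so a mapping is needed:
E and EM take the apo/AMP-only value (K_C = 0.16; AMP binding alone does not
shift the equilibrium), ET takes the 1 mM ATP value (1.28 without urea, 0.85
at 0.8 M), and the ternary species take the 1 mM ATP + 5 mM AMP value (1.65
and 1.10) — each species paired with the measurement condition in which it
dominates. The condition-matched mapping reproduces the measured turnover
optimum (~400 vs ~370 s⁻¹ observed); mapping all ATP-bound species to the
ATP-only value overshoots it (~430 s⁻¹).

The total relaxation rate k_open + k_close defaults to 4×10⁴ s⁻¹ for every
species: domain opening and closing complete within tens of microseconds,
about two orders of magnitude faster than maximal turnover. At steady state
only K_C matters provided relaxation stays far above k_cat and k_r, which
the K_C-preserving scan (`kc_scan`, mode `both`) verifies directly: scaling
both rates upward changes turnover by <1%, scaling 100× down makes the
exchange itself rate-limiting.

## Global activity fitting

Datasets are v₀-versus-substrate tables with standard errors. The shared
rate constants (k_cat, k_r^T, k_r^M) are optimized in log₁₀ space
(positivity by construction) by trust-region least squares on
(v_model − v_obs)/σ, restarted from 16 points log-uniform within ±2 decades
of the seed guess (deterministic RNG, default seed 1234), followed by an
unbounded Levenberg–Marquardt polish; per-urea inputs (Kd(AMP),
conformational rates) stay fixed. Non-convergence is flagged on the result,
not raised.

Confidence intervals are profile likelihood: the parameter is clamped on a
grid, the remaining free parameters re-optimized, and the interval is where
χ²_red ≤ χ²_red,min + Δ with Δ defaulting to 1/dof (Δχ² = 1 on the profiled
parameter, a 1σ interval; the threshold is configurable). Crossings are
interpolated linearly between grid points; a profile that never crosses the
threshold inside the grid returns an open bound — the natural outcome for a
rate far from limiting, where only a lower bound is identifiable.

Identifiability caveat: with AMP scans alone, k_cat (≫ the observed maximal
turnover) is weakly determined; joint AMP- and ATP-dependence across several
urea levels — the design the recovery tests use — pins it to ~10%.

## Assay fits

* Initial velocities: least-squares slope over the first 10% of the time
  course or the first 60 s, whichever is shorter (minimizes
  product-inhibition bias); absorbance traces convert with ε₃₄₀ =
  6220 M⁻¹cm⁻¹, 1 cm path.
* Product-inhibited reverse time courses fit
  [P](t) = (v₀/η)(1 − e^(−ηt)) (evaluated via expm1 for small ηt) with
  early-slope/plateau-based initial guesses; when η is indistinguishable
  from zero the linear fit is returned with an explicit flag.
* Michaelis–Menten and 1:1 isotherm fits are weighted when standard errors
  are supplied. Isotherms carry amplitude and baseline nuisance parameters;
  ligand depletion is not corrected (titrations assume enzyme ≪ Kd) but a
  warning fires if [E] > Kd/10. A 1:1 site model is used throughout — the
  titration data give no reason for a Hill coefficient. Non-monotone
  titrations beyond a robust (MAD-based) noise estimate are flagged.

## Photon-by-photon HMM

**Likelihood.** For each burst's donor-excitation photons, the forward
algorithm propagates the two-state distribution between photons with the
analytic 2×2 matrix P(j|i,Δt) = π_j + (δ_ij − π_j)e^(−ΛΔt) (Λ = k_open +
k_close) and multiplies per-photon emission probabilities (acceptor: E_state;
donor: 1 − E_state), with per-photon normalization for numerical stability.
No time binning is involved; the likelihood is exact for arbitrary interval
structure, and the test suite verifies it against exhaustive 2^N path
enumeration (independent scipy expm transition matrices) on bursts up to 10
photons.

**Fitting.** Direct maximum likelihood: L-BFGS-B on (logit E_open, logit
E_closed, log k_open, log k_close), multi-start with dispersed initial rates
(fixed seeds). The state efficiencies may be shared across condition sets
("global E": one pair of efficiencies, rates per set) or fixed to known
values (perturbation series). The high-FRET state is labeled "closed" after
fitting. A fit is flagged degenerate when the two-state likelihood fails to
beat a single-state binomial description by more than 5 log units or the
efficiencies collapse — single-state data leave the rates unidentifiable,
and the flag says so instead of reporting noise. The number of restarts
(default 4) and the rate bounds (10–10⁷ s⁻¹) cover the microsecond-to-second
range of interest.

**Rates at the information limit.** Interconversion rates are recoverable
while they stay below the in-burst photon rate; the recovery sweep in the
tests (0.5–50 × 10³ s⁻¹ at 200 kHz) bounds the regime. K_C, a ratio, is more
robust than either rate individually.

**Validation tools.** Viterbi decoding (same emission/transition structure,
max-product) yields per-photon state paths; dwells run from the first photon
of a state to the first photon of the next, so they tile the burst span.
Dwell-time means are censored by burst edges (bursts are ~1 ms, dwells
100 µs–1 ms), so dwell *fractions*, not means, are the quantity that
converges to the equilibrium populations. The recoloring test keeps observed
photon times, redraws hidden paths and colors from the fitted model, and
compares per-burst E distributions by the two-sample Kolmogorov–Smirnov
distance: the statistic is the median observed-vs-recoloring distance, the
null envelope the 95th percentile of distances between independent
recoloring pairs (200 draws by default). Burst variance analysis compares
the standard deviation of E over consecutive photon windows (default 8–10
photons) with the binomial shot-noise level √(E(1−E)/n); because the
per-burst sample SD is biased low with few windows, calibration checks
compare RMS values.

**Corrections.** Leakage l is estimated from the mean raw E of donor-only
bursts (stoichiometry S > 0.85), l = E_DO/(1 − E_DO); direct excitation d
from the mean raw S of acceptor-only bursts (S < 0.15), d = S_AO/(1 − S_AO).
The corrected acceptor signal is F_A = A_Dexc − l·D_Dexc − d·A_Aexc; the
donor signal is rescaled by (1 + l), the spectral complement of the photons
the donor lost to the acceptor channel, so a static population's corrected E
equals its generating value exactly in expectation. No γ (detection
efficiency/quantum yield) correction is applied. Double-labeled selection
keeps corrected S ∈ [0.3, 0.7].

**Burst search** smooths inter-photon *intervals* (the smoothed quantity
must be declared; intervals are the natural choice for a rate-threshold
criterion) with a centered 15-photon running average and keeps maximal runs
below the 5 µs cut-off with at least 50 photons. The output is independent
of how the stream was chunked before concatenation.

## Synthetic data

The generators produce every input the analysis consumes, deterministic
given their seed:

* *Photon streams.* Hidden two-state paths by Gillespie sampling inside each
  burst; photons as a uniform Poisson process over the burst (constant
  in-burst rate, 200 kHz default); burst durations exponential (1 ms mean)
  — the simplest stand-in for diffusion transits. Colors are drawn per
  photon from the state's E; leakage misdirects donor photons with
  probability l/(1+l) (so the estimator recovers l); direct excitation adds
  acceptor-channel photons in the donor-excitation slot at rate d × the
  acceptor-excitation rate; donor-only/acceptor-only species and uniform
  background emulate real label statistics. Ground-truth paths are returned
  for recovery tests.
* *Activity curves*: model velocities with relative Gaussian noise
  v(1 + σ_rel·N(0,1)), σ_rel = 5% default — the replicate-scatter scale of
  coupled assays — and SEM = σ_rel·v. Titrations use the same relative-noise
  convention (an absolute option exists).
* *Time courses*: the closed-form product-inhibition curve plus absolute
  noise.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: photophysics (blinking, bleaching, acceptor dark
states), diffusion through a 3-D Gaussian focus (burst-size/brightness
correlations, re-entries), detector dead time and afterpulsing, more than
two conformational states, and assay-side systematics (coupled-enzyme lags,
instrument drift). Recovery results quantify estimator correctness under the
model's own assumptions, not robustness to these artifacts.

## Numerical conventions and edge cases

* Timestamps are integer nanoseconds; all rates s⁻¹, concentrations molar;
  unit conversion happens only at I/O boundaries.
* Likelihood evaluations guard log(0) with 10⁻³⁰⁰ floors; HMM fits operate
  on transformed (log/logit) parameters, so positivity and [0,1] constraints
  hold by construction.
* Fit optima are reproducible: fixed multi-start seeds everywhere; dataset
  or burst reordering moves optima only within optimizer termination slack
  (exactly zero effect on the objective itself).
* Degenerate inputs fail loudly: empty photon streams yield empty burst
  lists; bursts without donor-excitation photons, non-finite times, empty
  scans and non-positive rates raise; missing single-label populations
  default the corrections to zero with a warning.
* The pipeline records a config hash, seeds and package version in every
  artifact; reruns with the same configuration are byte-identical.

## Scale of the shipped studies

The test suite and the reproduction script run simulation sizes chosen to
keep the estimators' Monte-Carlo error comfortably inside the tolerances
they are checked against: 3000 bursts (~6×10⁵ photons) per condition for
K_C recovery, 3×1000 bursts for the shared-efficiency fit, 12–20 replicates
for noisy-recovery medians, 100 random networks for the solver
cross-checks. Larger runs sharpen nothing qualitative; the recovery errors
scale as expected with sample size.
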