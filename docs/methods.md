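# Methods

## Structural model and conventions

The parent drug follows two-compartment disposition with linear
elimination; the glucuronide metabolite occupies a single compartment fed
by a fixed fraction Fm of parent elimination. All amounts are carried in
nmol/kg of parent-molar equivalents, so metabolite formation conserves
moles and Fm has its literal meaning; concentrations are amounts divided by
the respective volumes (nmol/L). The mass-to-molar bridge uses a CBG
molecular weight of 316.48 g/mol and is applied only at configuration
boundaries — inside the pipeline every quantity is molar (h, nmol/L,
nmol/kg).

Oral absorption is a Weibull depot: the depot is loaded with F·D at dose
time and empties with survival exp(−(ka·t)^β). Two conventions deserve
emphasis:

* **F scales the depot load**, not the transfer rate. A transfer-rate
  factor would cancel from the mass balance and leave total exposure
  independent of F; loading the depot with F·D makes oral AUC∞ equal
  F·D/Cl, which is the behaviour the bioavailability estimate of 28% must
  have to mean anything.
* **The depot is propagated through its analytic survival**, never by
  evaluating the instantaneous rate at t = 0 — for β < 1 (the oil
  formulation, β = 0.70) that rate is power-law singular at zero, but the
  integrated input over any panel is finite and closed-form in
  u = (ka·t)^β.

IV doses are zero-order infusions of 5 min by default (the study's
administration procedure); a flag selects a true bolus.

## Solver

The disposition matrix is lower block-triangular, so its spectrum is
available in closed form: the two parent eigenvalues from the standard
two-compartment quadratic and −Clm/Vm for the metabolite. The system is
solved in modal coordinates y with y′ = λy + u·r(t):

* IV bolus/infusion responses are exact exponentials.
* The Weibull input is convolved per mode with 8-point Gauss–Legendre
  panels in u-space, which absorbs the t → 0 singularity; panel lengths are
  capped by Δu ≤ 1 (graded near the origin, where no power substitution
  can make a non-integer-β input smooth) and by |λ|·Δt ≤ 3 while the depot
  is active. Once the depot survival falls below 1e−13 the recursion is a
  pure decay and steps jump directly between output times.
* Interval AUCs are exact given the modal states at the endpoints
  (∫y = (Δy − u·∫r)/λ with ∫r closed-form), so no quadrature error enters
  reported exposures.

Against a reference `solve_ivp` integration (Radau/LSODA, rtol 1e−11) the
solution agrees to ~1e−9 relative; eigenvalue near-collisions with the
metabolite mode are guarded by a 1e−6 relative nudge of Clm/Vm. The kernel
is JIT-compiled with numba when available and runs as plain Python
otherwise.

## Population model

Individual parameters: θᵢ = inverse-transform(transform(θ_typ) + cov + η_IIV
+ η_IOV), log scale for all parameters, logit for F. IIV is subject-level;
IOV applies to F, ka and β on the two oral occasions only (the IV occasion
has no depot and F ≡ 1 there). The formulation covariate shifts ka and β on
the log scale with micellar as reference; the published oil coefficients
are ln(0.31/0.99) and ln(0.70/1.59). Random effects are uncorrelated (no
off-diagonal covariances are reported).

Reported variability percentages are interpreted as CV% for log-normal
parameters (ω = √ln(1 + (pct/100)²)) and as 100·SD of the logit-scale η for
F. CV% is the dominant reporting convention in the field; at these
magnitudes the difference from an SD×100 reading is second order.

Residual error is proportional per analyte, b₁ = 0.29 (parent) and
b₂ = 0.41 (metabolite), observations truncated at zero. Additive error is
available behind a switch; combined error is not implemented.

## Synthetic data

The generator emulates the study design: 8 subjects (configurable), body
weight ~ N(451, 49.4²) kg truncated positive, three occasions (IV 1 mg/kg
over 5 min; oral micellar and oil at 10 mg/kg) with complete washout,
sampling at 0 (pre-dose), 5, 10, 15, 30, 45 min and 1, 2, 4, 6, 8, 12, 24,
36, 48, 72 h, LOQ flags at 0.0004/0.0008 nmol/L. Doses are per-kg, so body
weight is a covariate column only. Generating parameters are returned in a
separate truth structure that never enters a fitting table.

What it does **not** emulate: assay drift or between-day analytical error,
dropout or missed samples, incomplete washout, within-formulation batch
effects, and any misspecification of the structural model itself — passing
recovery tests therefore demonstrates internal consistency of the
estimator under the assumed model, not robustness to the ways real equine
data deviate from it.

The printed LOQs are orders of magnitude below any simulated
concentration (likely a units artifact in the source values); they are kept
as defaults, configurable, and flagged rows are simply excluded from
fitting (likelihood-based censoring is out of scope).

## Estimation

SAEM with Metropolis-within-Gibbs over two latent blocks per subject:
η̃ᵢ ∈ R⁹ (location-absorbed transformed parameters, prior N(μ, Ω)) and
κ̃ᵢₖ ∈ R³ per oral occasion (prior mean = covariate shift, variance Γ).
With this parameterization the complete-data model is Gaussian in
(μ, covariate coefficients, Ω, Γ) and the M-step is closed form, as is the
residual-proportion update. Three details matter in practice:

* **Location recentring.** The mean reference-category κ̃ is moved into η̃
  each iteration. Because F/ka/β play no role on the IV occasion, the shift
  is exactly likelihood-neutral, and it removes a degenerate direction that
  otherwise lets the occasion shifts absorb location that belongs to the
  typical values.
* **Population group moves.** The 5-minute first sample barely observes the
  fast distribution phase (its half-life is ~4.6 min), leaving a shallow
  ridge through (Q, Vc, Vp). During the exploration phase, Metropolis
  proposals shift one latent coordinate (or a correlated set) for the whole
  population together with μ — prior-invariant, accepted on the summed data
  likelihood with a mild annealed temperature (4 → 1) — which carries the
  population along the ridge far faster than subject-level moves can.
  Two exploration chains are run (`n_starts`) and the one with the better
  complete likelihood continues into the stochastic-approximation phase.
* **Working variability.** Parameters with no random effect (Q) receive an
  annealed working SD (0.35 → 0.05) during sampling so their typical value
  also has a closed-form update; it is an algorithmic device, never
  reported as IIV. Variance and residual updates carry a 0.95 annealing
  floor during exploration to prevent premature collapse.

Defaults: 400 exploration + 200 stochastic-approximation iterations, SA
step 1/k^0.8, two MH sweeps per block per iteration with subset-of-3
coordinate proposals and Robbins–Monro scale adaptation toward 0.3
acceptance. Initial values come from non-compartmental heuristics (Cl from
IV dose/AUC, Vc from the IV peak, Vss from Cl·MRT, curve-peeled
biexponential micro-constants where resolvable, F from dose-normalized AUC
ratios, per-formulation ka from 1/Tmax, Clm from the IV metabolite AUC with
Fm fixed), followed by a coarse likelihood screen over multiplier grids for
Q, Vc and Vm — the three quantities the schedule leaves nearly invisible to
moment-based starts.

The marginal −2LL is computed after convergence by a Laplace approximation
at the per-subject joint modes, found by L-BFGS in prior-standardized
coordinates (batched finite differences across subjects; forward step 1e−4,
Hessian step 1e−3, jittered Cholesky for the log-determinant).
AIC = −2LL + 2p; BIC = −2LL + p·ln(N) with N = number of subjects (the
convention is declared because the source does not state one). A covariate
is retained when ΔBIC ≥ 10. Convergence is flagged from the drift of the
transformed typical values over the last quarter of the SA phase; an ω
below 1e−3 is collapsed to zero with a warning. The reported standard
errors are the between-subject first-order approximation ω/√n
(delta-method back-transformed) — a deliberate simplification; the
non-parametric bootstrap (subjects resampled with replacement, percentile
2.5/97.5 intervals, non-converged replicates counted and excluded) is the
reference uncertainty measure.

Empirical Bayes estimates are the conditional modes; shrinkage is
1 − sd(η̂)/ω in percent, undefined (NaN) for parameters without estimated
IIV. A subject with no observations sits at the typical values.

## Secondary parameters

Two AUC pathways are deliberately exposed: exact modal integrals when
structural parameters are known, and linear-up/log-down trapezoid with
C_last/λz tail extrapolation for sampled curves. λz is chosen by best
adjusted R² over the last 3–6 points after Cmax (the common NCA
convention); profiles whose terminal phase is not resolvable return NaN
rather than a fabricated value. Vss is Vc + Vp from the model, or
D·AUMC/AUC² for observed IV profiles. Cmax/Tmax ties break to the earliest
time. NCA on a sampled schedule prepends C(0) = 0 since every
administration here is an infusion or depot, never an instantaneous bolus.

## Regimen simulation

For identical doses every τ hours, superposition reduces each subject to a
single-dose solve: the first-interval AUC is the single-dose AUC over
[0, τ]; the last-interval (steady-state) AUC over [(n−1)τ, nτ] equals the
single-dose AUC over [0, nτ] because the n shifted windows tile that range;
steady-state concentrations are lattice sums of the single-dose curve.
Interval AUCs are exact modal integrals (the defaults integrate
[312, 336] h of a 14-dose q24h regimen). Subjects are drawn from the
population distribution with one IOV draw per subject (the regimen is one
treatment occasion); externally supplied individual parameters (e.g. EBEs)
are accepted instead. The summary statistic is the median: the typical
subject's closed-form exposure sits within ~1.5% of the reported
steady-state table value, whereas a mean over the log-normal spread would
sit several percent above.

Under this model the two formulations must converge to near-identical
steady-state parent AUC (same F and Cl once the depot has emptied); the
simulated oil arm lands ~1% below micellar (slower Weibull input pushes
exposure beyond the truncation horizon), not the ~12% difference in the
source simulation, which drew from eight specific animals' individual
estimates rather than the population distribution. Time to stationarity is
defined as the first dose whose interval AUC reaches a threshold (default
90%) of the last-interval AUC: day 4 for typical micellar parameters at
90%, day 5–6 at 95% — the latter matching the qualitative "fifth or sixth
day" description.

## Diagnostics

The VPC simulates replicate studies on the dataset's own design (one bin
per nominal time — appropriate for nominal-time rich sampling), reporting
observed 10/50/90th percentiles against the 5th–95th band of each simulated
percentile, stratified by analyte and formulation. The band holds the
observed median at its nominal level on average over replicate studies,
with substantial between-study spread because bins within one study share
subjects; the calibration test therefore averages coverage over replicate
studies rather than asserting a single study's bin count. IWRES uses conditional-mode predictions,
(obs − ipred)/(b·ipred); note the −log(b·f) term of the proportional
likelihood biases the conditional mode by O(b), so IWRES on noise-free data
vanishes only in the small-b limit. PWRES standardizes each observation
against the marginal mean and SD of its design point, approximated by Monte
Carlo simulation from the population model (chosen over the first-order
expansion for accuracy at equal code complexity; the two agree to first
order). Plots are conveniences; the numbers are the tested surface.

## Problem sizes

Defaults used by the test suite and the reproduction script, chosen to
give stable statistics at interactive runtimes: recovery fits use 50
subjects (ten replicates for bias assessment); covariate-decision fits use
10 subjects, where the generating formulation effect (a 3.2-fold ka ratio)
clears the retention threshold by a wide margin; Monte Carlo regimens use the full n = 5000 per arm;
VPCs use 200–500 simulated replicates; bootstrap and
convergence-assessment defaults (200 replicates / 20 runs) are exercised at
reduced counts in tests, full size being a production setting.

## Known limitations

* Fm is fixed, not estimable (no IV metabolite dosing); misfixing it
  propagates into Clm and Vm, which is demonstrated in the tests.
* Ω and Γ are diagonal; correlated random effects are out of scope.
* BLOQ rows are discarded, not integrated into the likelihood.
* The Laplace −2LL inherits the approximation's bias for small subjects ×
  occasions; ΔBIC decisions at the scale tested are far from the boundary,
  but borderline comparisons (|ΔBIC| near 10) deserve the bootstrap.
* Saturable elimination, enterohepatic recirculation and phase-I metabolite
  kinetics are intentionally absent from the model.
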