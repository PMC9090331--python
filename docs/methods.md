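# Methods

This note documents the models implemented in `osmovol`, their assumptions,
the default parameter choices, the synthetic-data generators, and the
numerical decisions, in enough detail to judge what the package's passing
tests do and do not establish about real cells.

## Pump-and-leak steady state

The cell interior contains three permeant ion species (Na⁺, K⁺, Cl⁻) and
impermeant osmolytes: an amount `nX` (mM·µm³) of mean valence `zX < 0` and
a neutral amount `nY`.  Passive fluxes are linear (Ohmic),
`J_i ∝ −g_i (Vm − E_i)` with Nernst potentials `E_i`; a full
Goldman–Hodgkin–Katz treatment is deliberately omitted because every result
used downstream (steady-state composition, small-signal mechanosensitivity,
sign structure) is flux-law agnostic in the linear regime.  The Na/K pump
is electrogenic with fixed 3:2 stoichiometry at rate `pump_rate`.

At a given membrane potential the three zero-flux conditions fix the
interior concentrations in closed form; internal electroneutrality
(`cNa + cK − cCl + zX nX/Vw = 0`) then fixes the water volume `Vw`, and the
osmotic-balance residual becomes a scalar function of the potential,
bracketed on [−250, 100] mV and solved with Brent's method.  The returned
state is verified against all five conditions with a combined relative
residual below 1e-8.  Two classical degeneracies are raised as explicit
errors rather than returned silently: `nX = 0` (volume undetermined) and a
disabled pump (no finite-volume solution — the Donnan swelling
catastrophe).

`default_hela_params()` *constructs* conductance ratios and pump rate
analytically so that the steady state sits exactly at cNa = 15, cK = 120,
cCl = 65 mM with 100 mM impermeant osmolyte of valence −0.7 against a
145/5/150 mM medium — interior ion total 200 mM versus 300 mM outside.
This composition was chosen over the alternative "≈150 mM inside" rounding
because the package's order-of-magnitude pressure estimates (10⁵ Pa of
trapped-osmolyte pressure from ~100 mM) rely on it.

Units: µm³, µm², mM, minutes, mV, Pa; `RT = 2577 Pa/mM` and Nernst scale
`RT/F = 26.71 mV` at 310 K.  The osmotically inactive volume is a constant
offset `b`, with `excluded_fraction = b/V` at the isosmotic state
defaulting to 0.33 — the Ponder-intercept convention.

## Osmotic shocks

State variables are the water volume and the three ion amounts; trapped
amounts `nX`, `nY` are conserved exactly (constant dry mass).  Water flux is
`dV/dt = Lp A RT (Π_int − Π_ext)` with separate permeabilities for swelling
(`Lp_in = 1.5e-5 µm·min⁻¹·Pa⁻¹`) and shrinking (`Lp_out = Lp_in/2`); the
asymmetry is an empirical observation without an agreed mechanism, so it is
exposed as two parameters rather than modelled.  Defaults give a passive
water-equilibration time of roughly 10–20 s for a 2000 µm³ cell, against
minutes-scale ion regulation — the timescale separation that makes the
immediate response purely passive (Ponder's relation).

Regulatory volume decrease/increase is phenomenological: the ion content
relaxes at rate `k_reg` (default 0.1 min⁻¹) toward the content that would
restore the isosmotic water volume under the current medium, with species
amounts scaled proportionally.  An optional cap on the total regulatory
flux (`reg_flux_cap`) saturates the response and reproduces the partial
recovery seen after large hypo-osmotic shocks.  The true transporter
network (VRAC, NKCC, KCC, …) is out of scope; only the relaxation
phenomenology is represented, so fitted `k_reg` values carry no molecular
interpretation.

Integration uses SciPy's stiff-capable LSODA piecewise between protocol
events (rtol 1e-9).  The output grid is decoupled from the solver's
internal steps, but a uniform grid coarser than ~5 water-flux time
constants raises a `StabilityError` instead of returning an aliased passive
phase; callers needing mixed cadences (100 ms passive / 30 s adaptation)
pass explicit sample times.  A volume reaching the inactive floor raises
with the collapse time.  The post-shock volume extremum is located as the
discrete argmin/argmax within 3 min of the shock (earliest index on ties),
and the adaptation rate is the least-squares slope of the following 5-min
window.

## Spherical-cap geometry

A spreading cell is a truncated sphere over its contact disc.  Given
measured (V, Ac) the cap height is the unique positive root of the
monotone cubic `h³ + 3a²h = 6V/π` (Newton with bisection safeguard,
residual below 1e-12 relative).  The tension drive uses the exact
logarithmic sensitivities `f1 = (1/Atot) ∂Atot/∂V|Ac = 4h/((a²+h²) Atot)`
and `f2 = (1/Atot) ∂Atot/∂Ac|V = 2a²/((a²+h²) Atot)`, verified against
central finite differences in the tests.  The measured observable is the
contact area (RICM); the total area is always derived through the cap.
Sphere and cylinder area formulas cover detached and confined cells, and
`volume_ratio^(2/3)` converts a rupture volume ratio into the implied
membrane-area reserve (no averaging-order correction is attempted).

## Mechanosensitive coupling

Three linear blocks: (i) `α = d ln V / d(δγ/γ_iso)` from the steady state
with conductances `g_i (1 + β_i δγ/γ_iso)` — computed by central
differences with one Richardson halving used both for extrapolation and
step-size control, because no closed form for the three-species α is
assumed; (ii) Maxwell tension `(1 + τ d/dt) x = (kτ/γ_iso) dAtot/dt`;
(iii) the cap geometry closing `dAtot/dt` on `dV/dt` and `dAc/dt`.
Combining them with constant effective stiffness `ξ = −Atot k α/γ_iso`
(referenced to the detached spherical area) gives the volume equation
quoted in the README, with `τ_eff = τ (1 + ξ V_iso f1)`; `τ_eff ≤ 0` is
rejected as unphysical.  Growth enters as a constant volumetric source
`V_iso·r_growth` (default 5 %/hr; 7 %/hr for the non-adherent preset).

Integration is a fixed-step predictor–corrector built on per-step
exponential updates (exact for piecewise-constant forcing), dt = 0.1 min by
default; halving the step is the convergence check used in the tests.
Tension output: when α is set and nonzero, `x = u/α` (exact under the
linear coupling); for α = 0 the Maxwell law is integrated directly from the
realized area history.  The with/without-coupling tension difference runs
the simulation twice (given α; α = 0) and is non-negative for ξ > 0: the
coupled cell sheds volume, grows less total area, and therefore reaches
lower tension.

Because ξ is referenced to the spherical area while the instantaneous
coupling scales with `Atot(t)`, the constant-ξ equation and the raw
tension→volume chain agree exactly only near the spherical reference; the
dual-route consistency test therefore runs in the small-deformation
quasi-static regime.

## Migration fluctuations

A cell crawling at speed `v` through obstacles with effective spacing `λ`
experiences a sinusoidal area strain of amplitude ε at
`ω = 2π v/λ`; the steady-state response of the volume transfer function
gives `CV = ξ ω τ ε / (√2 √(1 + (ω τ_eff)²))`, monotone in speed and
saturating at `ξ ε τ/(√2 τ_eff)`.  Only the lumped parameters `B = ξ ε τ`
and `τ_eff` are identifiable from CV-versus-speed data, and only those are
fitted — the ε/ξ degeneracy is explicit, not hidden.  Defaults: ε = 0.05,
λ = 20 µm (an effective constriction spacing of order the cell's own
length in a loose collagen gel — volume-relevant squeezing events occur
when the whole cell body passes an obstacle, not at every collagen pore),
ξ = 1, τ = 15 min, τ_eff = 20 min; these give few-percent volume
fluctuations at ~1 µm/min, in the observed range.

The empirical statistic is the CV of 10-min windowed least-squares volume
slopes.  For a signed flux with near-zero mean, std/|mean| is ill-defined,
so the default normalization divides the slope standard deviation by the
natural flux scale `mean(V)/window`; the plain variant is available behind
a flag.  Finite windows low-pass the slopes: for a sinusoid the windowed
slope amplitude carries the factor `6(sin x − x cos x)/x²`, `x = ωW/2`,
which the end-to-end tests account for explicitly rather than pretending
the windowed CV equals the instantaneous one.

## Trajectory-fitting pipeline

Records are re-zeroed at spreading onset — the first sample with
detectable contact area, which must not exceed 100 µm² (otherwise the
onset was missed and the cell is excluded with an explicit error; there is
no silent pass-through and no manual curation anywhere in the pipeline:
missing samples stay missing and no interpolation is performed).

The contact-area kinetics `Ac(t) = A_init + (A0 − A_init)(1 − e^(−t/τa))`
is fitted with `A_init` pinned to the onset sample (two free parameters;
bounds A0 ≤ 10⁴ µm², τa ∈ [0.5, 500] min, with bound hits flagged).  The
volume trace, normalized by the mean of its first three samples (the same
convention defines the fit's reference volume, and the forward model is
normalized identically so the convention cancels rather than biasing ξ),
is then fitted for (ξ, τ) with bounds ξ ∈ [0, 10], τ ∈ [0.5, 200] min from
four starting points spanning the weak/strong-coupling and fast/slow
corners; the forward model runs at dt = 0.5 min inside the fit, which is
ample for the minutes-scale dynamics.  ξ pinned at 0 for a flat trace is a
valid result.  (ξ, τ) estimates from 1-min-sampled single cells are
strongly correlated along a ξτ ridge — the recovery studies therefore
evaluate cohort medians, and per-cell values should be interpreted
accordingly.  Fitting group-averaged traces is supported by averaging
upstream; the per-cell route is the default here.

Initial fluxes are OLS slopes of area and volume over the first 10 min;
speed terciles are a rank-based split (stable sort: tied speeds fall to the
lower group) with remainder-1 going to the middle group, so n = 127 yields
42/43/42; all-equal speeds are flagged degenerate.  All regressions are
ordinary least squares; the Ponder regression additionally reports whether
slope + intercept is compatible with 1, a self-check of the
fixed-content passive model.

## Synthetic data

The generators emulate the measurement designs the pipeline expects, with
per-cell draws: reference volume log-normal (mean 2000 µm³, CV 10% — an
invented baseline, as no absolute volume is prescribed), spreading
timescale log-normal (median 15 min, log-sd 0.5, matching an initial
spreading phase of ~15±10 min), saturating contact area log-normal (median
1000 µm²), and a shared coupling truth per condition.  Measurement noise is
multiplicative log-normal: 1% per sample (single-cell tracking accuracy)
plus a 10% per-cell scale offset (chamber-to-chamber absolute precision).
(τa, ξ) are drawn independently; any real covariance between spreading
speed and coupling is unknown and not modelled.

Condition presets encode qualitative phenotypes as generator targets:
control (τa = 15 min, ξ = 1), fast/contractility-inhibited (τa = 6 min),
slow/actin-perturbed (τa = 40 min), uncoupled (τa = 6 min, ξ = 0.05) and
non-adherent (no spreading, 7 %/hr growth).  With the cap geometry and
these ansatz scales, a bare tension-relaxation time τ = 1.5 min reproduces
the characteristic peak losses (~3% slow, ~7% control, ~16% fast, <1%
uncoupled); the "mean 20-min volume loss" statistic used for the ordering
checks is the largest relative loss attained within 20 min of onset.
Shock experiments jitter the impermeant amount (10% CV), which rescales
the resting volume without changing composition, and sample at 100 ms
during the passive minute and 30 s elsewhere.  Migration tracks
superimpose the single-frequency model response (random phase per cell) on
measurement noise.

What passing tests show — and what they do not: the pipeline recovers the
generators' own structure under the stated noise model; real FXm/RICM data
have correlated noise, segmentation artefacts, missing stretches, and
shape families (blebs, lamellipodia) outside the spherical-cap model, none
of which the generators emulate.  Recovery results are statements about
estimator correctness, not about biological effect sizes.

## Known limitations

- No GHK electrodiffusion, explicit cotransporters, pH or calcium dynamics;
  transporter inhibitions are represented only through parameter changes.
- The regulatory model is a single-rate relaxation; it cannot represent
  overshoot or biphasic recovery.
- The constant-ξ volume equation is a small-deformation linearization; at
  a 3-fold total-area increase the instantaneous coupling differs from the
  spherical-reference ξ by the same factor.
- Millisecond-scale confinement volume loss is intentionally out of scope:
  the required transport rates are orders of magnitude beyond the model's
  regime.
- Problem sizes in the test suite (cohorts of 25–50 cells, 30 regression
  replicates, 3-hr migration tracks) were chosen as the smallest designs
  whose statistics are stable under the fixed seeds.
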