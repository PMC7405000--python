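# Methods

This note documents the models implemented in `gutdial`, their
assumptions, the numerical choices, and what the synthetic data do and do
not establish.

## Generation kinetics

Starch hydrolysis by α-amylase is represented by the saturating
first-order law `rs(t) = rs∞(1 − e^(−kt))` for the cumulative mass of
reducing sugars.  This is a phenomenological lump: it captures the
decelerating release as accessible substrate depletes, but not
Michaelis–Menten saturation or product inhibition, both of which are out
of scope.  Its derivative `rs∞·k·e^(−kt)` is the instantaneous generation
rate that feeds the membrane balance.

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) on unweighted residuals, with `k ∈ (0, ∞)` and
`rs∞ ∈ (0, M0]` when the starch load `M0` is known — generated sugars
cannot exceed substrate.  Starting values are closed-form:
`rs∞₀ = 1.05 × max observed mass` and `k₀` from a through-origin
regression of `ln(1 − rs/rs∞₀)` on `t` over the rising phase
(`rs < 0.9·rs∞₀`), falling back to a half-rise heuristic if that
regression is unusable.  Standard errors come from the Gauss–Newton
covariance `s²(JᵀJ)⁻¹`.  At least two distinct time points are required
(two exact points determine both parameters); all-zero curves are
rejected.

A deliberate modelling point: the *fitted plateau* `rs∞` is the model's
asymptote, not the last observation of a 60-min run.  With
`k = 0.037 1/min` the law reaches only ~89% of its plateau at 60 min, so
the final sample and the plateau differ by design; both are exposed
(`generation_mass(params, t_end)` vs `params.rs_inf`) and should not be
conflated.

## Membrane transfer

Transport across the hollow-fiber membrane is the sum of a diffusive term
(concentration gradient) and a convective term (transmembrane pressure),
lumped as a volumetric conductance `c = K·A_T + K_UF·ΔP` in m³/min.  All
internal computation is SI-consistent (g, m³, Pa, min); mg/mL ↔ g/m³
(×1000) and mmHg ↔ Pa (×133.322) conversions happen only at I/O
boundaries.

Fouling — deposits of undigested starch and large dextrins on the fiber
wall — is modelled as a dimensionless, time-varying resistance dividing
the conductance: `N_rs = (c/R_MT)(C_F − C_D)`.  The division form (rather
than multiplication) is forced by resistance semantics: larger `R_MT`
must reduce flux, and it makes the forward scheme and the `R_MT`
estimator exact inverses of each other.  Correspondingly, the estimator
uses `R_MT = (C_F − C_D)·Δt·c / Δrs`, whose sign is positive whenever the
feed exceeds the dialysate — the physically meaningful orientation.

Two forward schemes:

* **quasi-steady** — per sampling interval, the transferred mass equals
  the generated mass, and the feed concentration follows algebraically:
  `C_F = C_D + (Δrs/Δt)·R_MT/c`.  Volumes are constant.  With `R_MT = 1`
  this reduces bit-for-bit to the resistance-free balance (the
  multiplication by 1.0 is exact in IEEE arithmetic and the expression
  order is shared).
* **two-compartment** — explicit accumulation balances
  `dM_F/dt = gen − N_rs`, `dM_D/dt = N_rs`, with the water flux
  `K_UF·ΔP` drifting the volumes (`dV_F/dt = −K_UF·ΔP`).  Integration is
  explicit Euler at `dt = 0.1 min` by default; the generation increment
  per step is taken from the closed form (exact), so only the transfer
  term carries discretization error, and total mass minus cumulative
  generation is conserved to rounding (~1e−13 g over a run).  A
  stability precheck rejects steps for which the per-step transferred
  fraction of the gradient, `c·dt/R_min·(1/V_F + 1/V_D)`, exceeds 1.
  Step-refinement tests show end-of-run concentrations converged to
  <0.1% at the default step.

Negative ΔP (dialysate pressurised above the feed) reduces the lumped
conductance in the literal model; an optional switch
(`clip_negative_convection`) floors the convective term at zero for users
who prefer that incoming water carry no solute out.  The literal form is
the default.  If the convective term drives `c ≤ 0` the lumped model has
no valid regime and an error is raised rather than a negative flux
silently reversing.

**Conductance calibration.**  With no generation, the balance integrates
to `ln((C_F−C_D)/(C_0−C_D)) = −c·t/V_F`; a pure-solute run therefore
identifies `c` from a straight-line fit (exact on synthetic data to
<1e−6 relative).  A quadratic-curvature check on the residuals flags runs
whose transfer coefficient is drifting — fouling — as unsuitable for
clean-membrane calibration.  The membrane constants `K` and `K_UF` of any
physical module are supplier/calibration data and are required
configuration inputs; nothing in the package presumes particular values.

**Fouling estimation.**  Per sampling interval,
`R_MT = (C_F−C_D)·Δt·c/Δrs`, with the generation increment from the
fitted kinetics.  Intervals whose increment falls below 1e−9 g are
flagged *indeterminate* (NaN, `defined=False`) instead of dividing by
~0; defined intervals with non-positive estimates (zero gradient despite
generation) are flagged *degenerate*.  The estimator inverts the
quasi-steady balance, so it is exact on quasi-steady data and
approximate (to the pseudo-steady-state error, a few percent at the
default rates) on two-compartment data.  Between estimate knots a
profile is interpolated stepwise by default — matching the per-interval
semantics — with linear interpolation optional.

## Efficiencies and scale-up

Run summaries take *final-sample* masses `M_rsF = C_F·V_F`,
`M_rsD = C_D·V_D` (not time-integrals), and report starch digested,
membrane efficiency and expected overall efficiency as defined in the
README.  Membrane efficiency and its feed complement sum to 100 exactly.

Scale-up uses human-intestine reference values (transfer fraction 0.964,
volume 0.5 L, area 30 m², feed flow 3 mL/min, digestion time 180 min,
initial starch 2.2 mg/mL) to fix the absorbed-mass target
`N_rs = C_starch,0·V·f ≈ 1.06 g`, then asks the forward simulator for the
first time the cumulative transferred mass (dialysate mass) reaches that
target, linearly interpolating between steps.  The answer is monotone in
the fouling resistance and in the target; an unreachable target (beyond
the generation plateau, or blocked by compartment equilibration) raises
an error carrying the asymptotic transferred mass.  Because the operating
time depends on the unpublished membrane constants of any specific
module, it is validated by step-refinement and monotonicity properties
rather than against fixed numbers.

## Synthetic data

The generator emulates the bench campaign: aliquots every 2 min to
20 min then every 5 min to 60 min; DNS-assay measurement as a linear
glucose calibration (default slope 0.5 AU·mL/mg, an invented instrument
setting) with multiplicative Gaussian noise of CV 5% floored at zero (the
assay's triplicate scatter is reported only qualitatively, so the noise
law is a stand-in); and a detection limit (default 0.02 mg/mL) below
which a measurement reads zero.  The detection limit is what produces the
characteristic *dialysate lag*: the receiving tank is 10× larger than the
feed, so early transferred mass sits below detectability for tens of
minutes despite a nonzero gradient.

Three operating presets carry the campaign conditions: feed/dialysate
flow ratios 250/400, 400/400, 400/250 with transmembrane pressures
−7.25, 19.66 and 59.73 mmHg and generation plateaus 2.92, 2.86 and 4.9 g
over a 20 g load (batch: 6.7 g, k = 0.037 1/min).  The shared membrane
fixture (K = 1.5e−4 m/min, A_T = 1.7 m², K_UF = 2e−9 m³/(Pa·min)) and the
per-condition piecewise-linear fouling ramps are synthetic values chosen
once so that the simulated runs reproduce the qualitative phenomenology —
feed concentration rising to a maximum then declining, dialysate
detection beginning at ~25 min for 400/400, feed-tank overflow truncating
the 250/400 run at 25 min (water flows dialysate→feed under negative ΔP),
and volume-drift direction following the sign of ΔP.  They are not
measurements, and quantitative agreement of simulated efficiencies with
any particular bench campaign is neither claimed nor tested; tests assert
the qualitative features and the internal consistency (conservation,
round-trip recovery of kinetics and fouling).  Quasi-steady generation is
evaluated directly on the aliquot times (the bench Δt), which keeps the
fouling estimator an exact inverse of the generator.

What passing tests show: the estimators recover generating parameters
under the stated noise; the schemes are mutually consistent; conservation
holds.  What they do not show: that real membranes foul like the fixture
ramps, that assay noise is exactly multiplicative-Gaussian, or that the
first-order law extrapolates beyond 60 min.

## Problem sizes

Defaults throughout are sized to the bench campaign: 18-point schedules,
60-min horizons, 0.1-min integration steps, and 200-replicate recovery
studies for the Monte-Carlo validation (chosen to make the mean estimate's
Monte-Carlo error well below the tolerances being checked).
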