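# Methods

## Model

The shoot apical meristem (SAM) is represented as a two-dimensional disc
of radius `R(t)`; the organizing center (OC), the WUS-producing cell
population beneath the stem cells, as a concentric disc of radius `r(t)`.
Four diffusible signals live on the meristem: WUSCHEL (`u0`), CLAVATA3
(`u1`), cytokinin (`u2`) and HECATE (`u3`). Their kinetics encode the
core regulatory logic of the niche:

- WUS is produced at rate `k1` inside the OC and induces CLV3 through a
  steep sigmoid `k2 / (1 + exp(-(u0 - k3) k4))` — with `k4 = 100` an
  effective switch at the WUS threshold `k3 = 0.6`;
- CK production `(1 + k9 u3/(1 + k10 u3)) · k11 u0/(1 + k12 u0)` requires
  WUS and is amplified (but not created) by HEC;
- HEC production `k13 / (1 + k14 u0)` is repressed by WUS;
- all species degrade linearly and are diluted by domain growth.

The radii obey ordinary differential equations. The meristem radius
grows with a proliferation term `k21 / (1 + k23 ∫u0)` (total WUS enlarges
the slowly dividing stem-cell pool and slows net cell production) and
shrinks with a differentiation term
`pp · (1 + R²)/(1 + R0²) · g(∫u2)` (organ formation scales with meristem
area; the piecewise-linear gate `g ∈ [0.9, 1.1]` lowers the outflux at
high total CK and raises it at low CK). The OC radius grows with
`∫_OC k77/(1 + k7 u1) · f(u2, u3) dx − pdbasic`: CLV3 represses OC
expansion (closing the WUS–CLV3 negative feedback), while CK and HEC
promote it through the gate `f = max(min(aa·u2 + ab, k16·u3 + k15), k17)`
— the CK arm capped by a HEC-dependent ceiling, with floor `k17` so the
OC persists without either signal. A smoothstep factor `s(R − r)`
(width `0.05·R`) freezes OC growth as `r` approaches `R`; the integrator
additionally clamps `r ≤ R`, the discrete counterpart of the physical
constraint that the OC cannot outgrow the meristem.

All quantities are dimensionless; with the unit-cell-area convention the
cell count of the modelled layer is `N = πR²`.

## Numerics

Rotational symmetry of the geometry, sources and initial data makes the
problem one-dimensional in the radius. On the reference coordinate
`ξ = ρ/R(t) ∈ [0, 1]` the moving-domain advection term combines with the
coordinate motion into a pure dilution term, giving

    dU/dt = (D/R²) (1/ξ) ∂ξ(ξ ∂ξ U) − 2 (Ṙ/R) U + reaction(U, ξR)

with zero-flux conditions at both ends. Space is discretized by a
conservative finite volume scheme on the measure `ξ dξ` (`n_r = 200`
cells by default); disc integrals use the exact cell volumes, so the
discrete mass of a reaction-free species is conserved to machine
precision on any growing domain (verified to < 1e-9 relative under 50%
growth). Integrals over the OC sub-disc use the trapezoid rule with the
cut radius interpolated between nodes. The sharp OC indicator is
replaced by a linear ramp of physical width `w = 0.025` (two grid cells
at the default resolution), which also makes the equilibrium maps
`F(R, r)`, `G(R, r)` smooth enough for finite differencing.

Time stepping (`Δt = 0.01`) is a first-order splitting: explicit Euler
for the radii with sub-stepping whenever a radius would move more than
2% in one step, an exact dilution update `U ← U (R_old/R_new)²`, then
implicit (banded) diffusion + degradation with explicit nonlinear
productions. The implicit treatment of degradation matters because CLV3
degrades at `d1 = 64`. Observed convergence is first order in `Δt` on
the full nonlinear system and second order in `Δξ` on smooth elliptic
problems; the stationary WUS equation with a sharp source matches its
modified-Bessel closed form to < 1% in max norm at `n_r = 400`.

## Calibration

Following the published procedure, the two differentiation rates are
estimated from a prescribed steady-state geometry: at the target
`(R*, r*)` the four stationary PDEs are solved sequentially (WUS; then
CLV3 and HEC, each linear given WUS; then CK), and `pdbasic` and `pp`
are set so both radius brackets vanish there exactly, with `R0 := R*` so
the size-dependent differentiation factor is 1 at equilibrium. The
central zone (CZ) is defined as the area where CLV3 exceeds a threshold
frozen at calibration to half the wild-type CLV3 maximum and reused
unchanged across all scenarios.

The published constants do not pin `(R*, r*)`. The shipped default,
`R* = 2.5`, `r* = 0.95`, was frozen once from two requirements: the CZ
fraction at equilibrium is ≈ 10% of the meristem area (the one
numerically stated wild-type property), and the equilibrium is locally
stable with the documented phase-plane signs (`∂F/∂r < 0`, `∂F/∂R > 0`,
both partials of `G` negative, trace < 0, det > 0). The stability
requirement is restrictive: at geometries large enough for the WUS dome
to saturate at its plateau `k1/d0 = 1.2`, the CLV3 switch simply tracks
the OC edge and the OC bracket `F` becomes structurally *increasing* in
`r` (the perimeter gain dominates), turning the 10%-CZ equilibrium into
a saddle. The stable regime is the curvature-limited one, where the WUS
maximum (~0.9 here) responds globally to `r` and the CLV3 zone reacts
superlinearly. A consequence of this choice is that the re-calibrated
`pdbasic` (0.49) and `pp` (1.60) differ from the published magnitudes,
which are themselves strongly discretization-dependent (the original
calibration notes different values for every mesh size); the qualitative
structure, not those magnitudes, is what the analysis and the experiment
suite rely on.

The quasi-steady phase-plane reduction is used for the stability
analysis only; all simulations integrate the fully coupled system. The
reduction is qualitatively but not quantitatively faithful here: the
predicted slow decay rate (−0.26/time) overestimates the observed
relaxation (−0.040/time) because HEC (`d3 = 0.6`) and CK (`d2 = 1.1`)
relax on the same timescale as the radii. Jacobians use central
differences with step `10⁻³ ×` each radius; the entries are stable under
halving the step.

## Perturbation scenarios

Each in-silico genotype is an exact substitution in the equations (see
`samdyn.scenarios`). Strengths the source material states are used as
stated: HEC over-expression `c = 3` for the flat-state run and
`c = 0.05` for the direct-vs-indirect contrast pair; the WUS
over-expression transient uses `c = 2.9`. Strengths left open were
frozen once at values that produce the documented phenotypes and are
exposed as configuration:

- suite WUS over-expression `c = 5`: the far-field WUS floor is `c/d0`,
  and full-meristem CLV3 activation needs it above the switch threshold
  0.6, hence `c > 3`;
- CLV3 over-expression `c = 2`: with the strong OC repression
  (`k7 = 500`) a ten-fold induction overshoots the feedback so far that
  even peak CLV3 ends below wild type; a two-fold induction yields the
  documented phenotype (higher CLV3 peak, slightly reduced WUS, mild
  size change);
- reduced CK degradation `d2_factor = 0.65`: strong reductions (≤ 0.6)
  collapse to the uniform all-CZ state, while 0.65 gives the documented
  moderate phenotype (OC +8%, meristem +6%, CZ up ~1 percentage point);
- the "no direct HEC effect" variant freezes the HEC argument of the OC
  gate `f` at the wild-type central HEC level, removing the direct arm
  while HEC still drives CK production (substituting zero instead would
  silence the CK arm too, since `f` would pin at its floor).

One documented direction is *not* reproduced and is reported as a
failure by the suite: under HEC over-expression the meristem radius
settles ~3% below wild type instead of above. Once the WUS source fills
the meristem, total WUS rises ~6-fold and the proliferation bracket
falls by ~27%, more than the ≤ 10% outflux reduction available through
`g`; within this parameter set the effect is calibration-independent
(geometries small enough to avoid it break the reduced-CK-degradation
direction instead). All other 26 direction checks pass.

## Synthetic inputs and scope

There are no external data; every input is either a published constant
or generated by the model itself. The shipped fixture
(`src/samdyn/data/`) is the calibrated wild-type equilibrium at the
default resolution and is bit-reproducible from `samdyn calibrate` /
`MeristemModel().fit()`. What the passing suite shows is internal
consistency of the model and agreement with the qualitative experimental
directions it was built to reproduce — not quantitative agreement with
measured expression levels, which the dimensionless formulation cannot
address.

## Known limitations

- One meristem layer, strict rotational symmetry: azimuthal patterning
  (e.g. discrete primordia) is outside the formulation.
- The splitting integrator is first order in time; runs shown use
  `Δt = 0.01`, where the equilibrium radii are converged to < 0.5%
  against a run with doubled resolution and halved step.
- The `(R*, r*)` geometry is an inference (see Calibration); absolute
  cell counts (~20 cells per layer at the default) are smaller than real
  inflorescence meristems, a known consequence of requiring the stable
  branch with the published constants.
- Sensitivity sweeps re-march the full system and flag, rather than
  resolve, non-converged perturbations.
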