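# Methods

## Scope and assumptions

`spiderstat` is a *static* model of a cage-and-elastic-cord
rehabilitation device. The body is a rigid mass; all belt-routed cord
forces act at a single point, the centre of gravity (COG), at the
measured COG height above the floor; ground contact is at two points
(left/right foot). Dynamics, balance control, multi-segment body
mechanics, belt torque and cord viscoelasticity (hysteresis, creep,
temperature) are out of scope. Cords transmit tension only.

The frame is right-handed and anatomical: Z up, X anterior, Y toward
the subject's left, origin on the floor midway between the feet. A
cord's *COG-level angle* is its elevation above the horizontal
(transverse) plane through the COG: positive angles (anchor above the
waist) unweight, negative load, zero is neutral.

## Cord tension model

Tension is a three-term sum of sines of elongation in percent of rest
length, T(x) = Σₖ aₖ sin(bₖ x + cₖ), evaluated on 0–100 % only and
floored at 0 N. Outside behaviour: negative elongation means a slack
cord (0 N, with a warning); above 100 % is an error rather than an
extrapolation, because an oscillatory basis extrapolates meaninglessly.
Rest lengths default to the middle of each catalogue band (thick
0.6175 m from [0.605, 0.630]; thin 0.6375 m from [0.620, 0.655]);
values outside the band warn but are accepted.

### Fitting

The sum-of-sines objective is multimodal in the frequencies, so
`fit_sum_of_sines` runs seeded multi-start bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective): amplitudes in
(0, 2·max force], frequencies in (0, π/50] per percent — every term's
half-period at least spans the domain — phases in [−π, π]; 20 restarts
by default, best residual sum of squares wins; bit-reproducible for a
fixed seed. R² is 1 − SS_res/SS_tot about the observed mean.
Preconditions: ≥ 10 points spanning ≥ 50 percentage points, non-constant
forces. On noiseless samples of a physical (nonnegative) three-term
characteristic the fit recovers R² ≥ 0.9999; on 21-point benches with
1 % multiplicative noise it attains ≈ 0.9997, comfortably above the
0.9926/0.9982 bench-quality floors asserted in the tests.

The *working range* of a characteristic is the sub-interval of the
recommended 20–80 % elongation band on which tension strictly
increases, determined by a dense-grid scan at 0.1 % steps anchored at
20 %.

## Statics

COG resultant **F** = Σ Tᵢ**dᵢ** (plain summation); unweighting
fraction u = F_z/(m g) with g = 9.81 m/s². Vertical foot reactions
(L_z, R_z) solve

    L_z + R_z = m g − F_z
    y_L L_z + y_R R_z = h · F_y

where y_L, y_R are foot offsets from the COG's floor projection and h
is COG height: a horizontal pull at waist height tips load toward the
pulled side. The fore-aft (about-Y) moment is not balanced by the
point-foot pair — a real foot is an extended contact, and that within-
foot distribution is exactly what the heel/toe classification reports.
The 2×2 solve is written in a sign-symmetric closed form so that
mirroring a scenario through the sagittal plane swaps the feet and
negates Y components *bit-exactly* (IEEE negation is exact). The net
horizontal cord force is reacted at the feet as friction split in
proportion to vertical load, preserving equilibrium and symmetry.

Lift-off: when the cords carry ≥ 100 % of body weight both reactions
are zero and a flag is raised (unilateral contact cannot pull). A
single-foot stance assigns the whole load to the contact foot. Feet at
identical lateral positions cannot balance a lateral moment; the load
splits evenly with a warning.

Heel/toe classification operates on the *cord-imposed* force at each
foot — the cord-free baseline reaction minus the actual reaction, i.e.
the change the cords cause there. Z > 0 unweights the heel, Z < 0 loads
it; Y > 0 moves load toward the toe mound, Y < 0 away. Components
within 1e−9 N of zero classify as neutral, absorbing floating-point
residue of symmetric configurations.

`perturb_tension` scales all tensions by a factor (the usual
therapeutic adjustment band is 0.8–1.2; outside it warns but applies),
and unweighting scales linearly with it.

## Inverse planning

`solve_configuration` finds either a shared elongation (angles fixed)
or a shared anchor height (horizontal radii fixed) meeting a signed
target unweighting. The forward map is sampled on the bracket (241
points) to assert monotonicity — guaranteeing uniqueness — then solved
with Brent's method at 1e−9 tolerance on the free variable; the
achieved value is forward-verified (error ≪ 1e−6). Targets outside the
bracket raise an error carrying the achievable interval. A zero target
returns zero elongation directly.

## Synthetic bench data and reference characteristics

The generator emulates the bench protocol (a cord stretched step by
step with the force read at each step; default grid every 5 % over
0–100 %, the percent equivalent of 0.05 m steps on these rest lengths
being ≈ 8 %). Ground truth is a stretched-exponential saturation

    F(x) = F_sat · (1 − exp(−(x/s)^p)),

strictly increasing with F(0) = 0: `p` ≥ 1 softens the toe region, `s`
sets where the curve bends, `F_sat` the saturation force. Readings are
truth × (1 + ε), ε ~ N(0, cv²), floored at 0, seeded.

The two packaged reference characteristics are three-term fits to
noiseless curves of this family, each *calibrated* through one anchor
point derived by inverting the static model for a standard worked
configuration:

| fixture | anchor | implied by |
|---|---|---|
| `reference_adult_thick` | 39.02 N at 40.49 % | 0.15 · 75 kg · g / (4 sin 45°), 250 mm on 0.6175 m |
| `reference_child_thin` | 27.12 N at 15.69 % | 0.16 · 12 kg · g / (4 sin 10°), 100 mm on 0.6375 m |

Saturation levels (150 N thick, 80 N thin, p = 1.1) were chosen once as
plausible expander scales; the closed-form calibration then fixes `s`.
Both fits are strictly increasing on 5–95 % and reproduce their anchor
within 0.1 N, so the worked cases land at 15.0 % and 15.9 %. The
recipes (parameters + fit seed) are recorded in
`spiderstat.fixtures`; `scripts/regenerate_fixtures.py` rebuilds the
JSONs bit-exactly.

What the generator does *not* emulate: loading/unloading hysteresis,
cord aging, grip slippage, temperature, or correlated dynamometer
error. Passing tests therefore demonstrate correctness of the fitting
and statics machinery under clean monotone curves, not fidelity to any
physical cord's absolute stiffness.

## Numerical choices

- g = 9.81 m/s² (module constant).
- Tension floor at 0 N; domain clamp tolerates ≤ 1e−9 % overshoot at
  the 100 % edge (pure round-off) before erroring.
- Neutral classification tolerance 1e−9 N; equilibrium closure asserted
  to 1e−9 relative to body weight.
- Fit: xtol = ftol = gtol = 1e−14, max 2000 residual evaluations per
  restart.
- Default azimuths for four-cord sets: 45°, 135°, 225°, 315°
  (symmetric about both vertical planes); cage drawings do not fix
  them, so they are a declared convention, configurable per cord.
- Elongations quoted in mm are absolute stretch beyond rest length,
  converted to percent with the cord's rest length.
- Belt modelled as a point at COG height (zero belt radius).
- Subject mass above 110 kg (the device limit) is a hard error; mass
  outside the 70–80 kg adult utility band produces an advisory note in
  the report rather than an exception, since children are legitimate
  users.
- COG height defaults to 0.56 · stature (adult) or 0.58 (young child)
  when not measured.

## Test problem sizes

Randomised invariant suites run 1000 equilibrium-closure scenarios, 300
moment-balance-oracle and 300 mirror-symmetry scenarios, 100 planner
inverse-forward targets and 200 polar↔Cartesian round-trips; fit checks
use 21-point benches with 20 restarts. The whole suite completes in a
few minutes on one core.

## Known limitations

- All cords are routed through the belt/COG; setups that strap a cord
  directly to a limb are not represented — their forces would bypass
  the COG reduction entirely.
- The left/right partition assumes both feet on one floor plane and a
  COG fixed over the origin; shifted postures need explicit foot
  coordinates.
- Per-foot vertical reactions can go negative under extreme lateral
  pull (the model reports them rather than modelling partial foot
  lift-off).
- The sum-of-sines basis is the device's established characteristic
  form; it fits smooth monotone curves excellently but is not a
  physical elasticity model.
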