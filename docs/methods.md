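# Methods

## Damage model and stress formulation

Blood damage is modelled with the empirical power law `D = C τ^α t^β`.
Three constant sets ship with the package, interpreted with stress in Pa
and time in s:

| set      | kind | C         | α      | β      |
|----------|------|-----------|--------|--------|
| HO       | HI % | 1.800e-4  | 1.9910 | 0.7650 |
| TZ       | HI % | 1.228e-5  | 1.9918 | 0.6606 |
| Ding-PAI | PAI  | 4.08e-5   | 1.56   | 0.8    |

HI is returned in percent, PAI as a dimensionless index — the calibration
convention of the underlying Couette-flow correlations. The registry is
closed; user-defined sets are accepted everywhere but flagged as
non-registry in reports so results stay auditable.

The stress argument is the energy-dissipation effective stress
`τ = √(ε μ ρ)` with ε the **total** specific dissipation rate (W/kg). The
caller supplies ε as the sum of resolved viscous and turbulence-model
parts; the field layer keeps the two components separate in its containers
and sums them at evaluation time. Blood defaults: ρ = 1055 kg/m³,
μ = 0.0035 Pa·s, Newtonian.

## Eulerian evaluation

Linearizing `DI = D^{1/β}` makes the damage rate a pure source
`σ = C^{1/β} τ^{α/β}` (per second). Unsteady effects are dropped —
evaluation is steady-state throughout — so integrating the transport
balance over the device volume and the flux over its outlet reduces
single-pass damage to `D = (S/Q)^β` with `S = Σ_cells σ(τ_cell) V_cell`.

Two conventions to note:

* `S` carries the `C^{1/β}` factor inside it (it is the integral of σ), so
  no further model constant appears in `D`. This keeps the composition rule
  `D_{p+v} = ((S_p+S_v)/Q)^β` free of bookkeeping.
* Only cell volumes and dissipation rates enter; velocity fields and mesh
  connectivity are never needed, which is why a flat CSV is an adequate
  exchange format for CFD exports.

`S` is exactly invariant under dissipation-preserving cell subdivision, and
on a uniform-stress field `D` collapses to `C τ^α (V/Q)^β` — the power law
with the mean residence time. Both identities are enforced by tests, as is
agreement with an independent Lagrangian oracle that integrates σ along a
stress history with the trapezoidal rule (adequate because test histories
are smooth or piecewise constant; tolerances are stated per test). No
wall-region exclusion is applied to the integral — every cell counts.

## Composition and comparison statistics

Series composition attributes to the valve its marginal damage
`D_v = ((S_p+S_v)/Q)^β − (S_p/Q)^β`, which for β < 1 is strictly below the
valve's stand-alone damage (concavity) — the valve "hides" behind the pump.
The valve-to-pump ratio `R = (1+S_v/S_p)^β − 1` depends only on the
integral ratio and β. Multi-pass loop experiments scale both integrals by
the pass count and leave R unchanged; this is documented rather than
parameterized. The degenerate case S_p = 0 with S_v > 0 returns
(0, (S_v/Q)^β) with a warning instead of failing, since a valve-only
configuration is meaningful in sensitivity studies.

Hemolysis ratios are averaged over the HO and TZ sets (arithmetic mean,
sample SD; SD = 0 for a single set) to reduce model uncertainty; PAI has a
single set and is reported as-is. The attenuation
`Δ = (η_{p+v}−1)/(η_p−1) − 1` is undefined at η_p = 1 and rejected there.
Reference reproductions of published Δ values feed the *printed, rounded* η
inputs through this formula; for one row the η rounding alone shifts Δ by
up to 0.34 percentage points, so those checks compare at the table's
printed precision (one decimal) within 0.3 points, while the first row
agrees exactly.

## Throat geometry

The clamp is idealized as a stadium cross-section under a conserved
inner-wall perimeter. The perimeter constant is held at the *exact*
uncompressed circumference π·9.525 mm = 29.9228 mm rather than the rounded
29.92: this reproduces the full published (d → L) sizing family to 0.01 mm
and makes the uncompressed limit (d = 9.525 mm → L = 0, a circle) exact.
Axial assembly: 95.25 mm (10 D) straight extensions, 16 mm throat, and —
since the transition lengths are not individually specified — a symmetric
10 + 10 mm contraction/expansion split, the minimal assumption that closes
the 226.5 mm total. Transitions interpolate d(z) linearly (cosine easing
optional) with L(z) always from the perimeter constraint, so the perimeter
is conserved at every station; exact conservation through the transitions
is an assumption of this model, not a measured property of clamped tubing.
Coordinates: z along the axis from the inlet face, parallel sides normal to
the clamping direction (y).

The swept surface (default 256 boundary points per ring, 181 rings) is
closed with end-cap fans, watertight and consistently oriented; exported
binary STL is byte-deterministic and its re-measured cross-section areas
match the analytic stadium area to well under 0.5%. Throats below 1 µm are
rejected as degenerate.

## Reduced-flow surrogates

The pressure drop of the tubing model is a quasi-1D loss model: sharp
contraction (K = 0.5(1 − A_throat/A_tube)) on the throat velocity head,
Borda–Carnot expansion loss, and Darcy friction (laminar 64/Re below
Re = 2300, Blasius above) integrated along the swept profile with the local
hydraulic diameter. Its contract is qualitative — positive, smooth,
strictly decreasing in throat thickness and increasing in flow — because it
stands in for full CFD only to exercise the matching workflows; its heads
for the shipped throats land within a factor of two of the matched loop
conditions, which is all the tests claim. Conversions are fixed at
1 mmHg = 133.322 Pa and 1 L/min = 1/60000 m³/s.

Both matching loops are bisection on the quantization grid — 1 µm in d for
valve sizing, 5 rpm in speed for pump matching — terminating when the
relative head error is ≤ 0.75%, with the smaller grid point preferred when
both neighbours qualify and every trial logged. Bisection (not Newton) is
chosen because monotonicity then guarantees convergence in ≤ 60 steps over
the full d bracket. Targets outside the achievable bracket, or so steep
that adjacent grid points straddle the tolerance, raise an explicit error
naming the achievable range or the best grid error.

The pump surrogate collapses reference (flow, speed, head) triples to a
head-coefficient-vs-flow-coefficient curve (`H ∝ n²` at fixed Q/n, the
affinity scaling) interpolated piecewise-linearly, so reference points are
reproduced exactly and head is strictly increasing in speed for a falling
curve.

`distribute_dissipation` builds the valve's field by slicing the tubing
model axially, weighting dissipation uniformly-low in the straights, high
in the throat, and exponentially decaying (5 mm decay length) over a 20 mm
downstream jet, then rescaling so total dissipated power equals Q·ΔP
*exactly* — energy closure is an identity of the construction, not an
approximation. The jet books 80% of its dissipation as turbulent, laminar
straights 100% viscous (configurable). The spatial shape of valve
dissipation is a declared modelling choice: no data constrains it, so
valve-to-pump ratios computed from these synthetic fields characterize the
pipeline, not any physical loop.

## Synthetic fields: what they emulate and what they don't

* **uniform** — every cell at one stress τ*; analytic
  `S = C^{1/β} τ*^{α/β} V` attached. Exercises exactness of the integral
  and the closed-form damage equivalence (tolerance 1e-10), and stress
  recovery by inversion (1e-8).
* **poiseuille** — annular cells with the parabolic profile's dissipation
  `(μ/ρ)(4Ur/R²)²` at annulus mid-radii; Reynolds numbers ≥ 2100 are
  rejected. Midpoint quadrature converges to the Hagen–Poiseuille power
  Q·ΔP from below, within 0.5% at 64 rings.
* **pump_like** — log-normal per-cell dissipation (default median
  500 W/kg, log-SD 1.5, 20 mL volume) reproducing the qualitative feature
  that damage is dominated by a small high-stress volume fraction;
  bit-identical under a fixed seed. Any heavy-tailed distribution would
  serve; the defaults put effective stresses in the tens-of-Pa range
  typical of rotary pumps.

None of these carry velocity fields, spatial correlation, near-wall
structure, or real impeller stress statistics. Passing tests therefore
demonstrate the correctness of the damage arithmetic, the composition
algebra, the geometry, and the matching loops — not the absolute damage
levels of any physical pump, which require real CFD exports as input. The
published headline valve-to-pump ratios (tens of percent) derive from such
exports and are deliberately not reproduction targets here.

## Numerical choices and degenerate inputs

* Field validation rejects empty fields, non-positive volumes, negative
  dissipation (with the offending cell index) and non-positive flow rates.
* CSV/VTU writers format floats at 17 significant digits and readers parse
  with exact round-tripping, so both dialects are bit-stable and lossless.
  A missing `eps_turb` column reads as zero with a logged warning.
* Streamline histories must start at t = 0 with strictly increasing times;
  discontinuous (piecewise-constant) histories are represented with closely
  spaced double samples.
* The end-to-end sizing-plus-comparison pipeline over all eight shipped
  operating points runs in about a second at the default problem sizes
  (hundreds of cells per field, ~100 axial stations for the loss model),
  which are ample for the exact identities being verified.

## Known limitations

Rigid tubing and exact perimeter conservation under clamping; steady-state
damage only (the Eulerian treatment of exposure time is known to err for
strongly accelerating flows like the valve jet); power-law models
calibrated in laminar shear, applied here to dissipation-dominated flow;
the loss model is not a CFD replacement and its absolute heads carry no
validation claim; no thrombosis transport, no normal-stress-specific
damage, no pulsatility.
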