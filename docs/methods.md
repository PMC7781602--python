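# Methods

## Model and scope

`relaywave` implements single-component diffusive relays: every cell
measures the local concentration `c` of one molecule and contributes to
its emission at rate `a·f(c)`, with `f` either a Heaviside switch at
`Cth` or a Hill function of order `n` (the switch is the n→∞ limit).  The
cells are static and treated in the continuum limit; the molecule
diffuses freely with constant `D` and, optionally, decays at rate `γ`
(numerics only).  Supported dimensionalities are (cells, diffusion) =
(1,1), (1,2), (2,2), (2,3), (3,3); when the dimensions differ the medium
is semi-infinite on one side of the cell manifold and the kernels carry a
single image factor of two.  Out of scope: pulsed-emission and decay
*asymptotics*, discrete-cell corrections beyond the `d·v/4D` validity
check, bistable/uptake-dominated activation, non-axisymmetric fronts, and
chemotaxis–wave coupling (cell migration at ~0.3 µm/s is negligible
against wave speeds of ~2 µm/s; the constant is kept in
`swarming.NEUTROPHIL_SPEED_U` for documentation).

## Nondimensionalization

All engines work in natural units — length `D/v`, time `D/v²`,
concentration `Cth`, with `v` the Heaviside asymptotic speed for the given
parameters — and convert at the API boundary.  This gives a single
well-conditioned code path across parameter magnitudes, makes the
threshold condition exactly `ĉ = 1`, and renders the D-independence of
the mismatched-dimension speed structural: the nondimensional front
problem for cells-2D/diffusion-3D contains no free parameter besides the
colony radius.  Dimensional runs at different `D` therefore test the unit
plumbing and the transient (through the rescaled colony size), not the
speed law itself — which is exactly the point of the law.

## Green's-function machinery

The concentration due to an emission history is assembled from ring/shell
kernels derived from the heat kernel `(4πDτ)^(−m/2) exp(−x²/4Dτ)`.  The
R-integral of each kernel over a source band [0, b] has a closed form:
error functions for cells in 1D and 3D, and the Rician CDF (equivalently
the Marcum Q-function, evaluated through `scipy.stats.ncx2`) for cells in
2D.  Above SNR² = ν²/σ² = 10⁴ the Rician CDF switches to a Gaussian
approximation with mean `ν + σ²/2ν` (verified against brute quadrature to
< 1e-6 absolute).  The spherical-shell band integral switches to a
point-source series expansion for `τ > 25 (r+b)²`, where the closed
antiderivative loses all precision to cancellation.  Bessel factors are
always exponentially scaled (`ive`) so nothing overflows.

Time integrals use the substitution `u = √(t−T)`, which removes the
`τ^(−1/2)` endpoint singularity of the half-space kernels exactly, and
fixed Gauss–Legendre panels (order 6): geometrically refined toward
`u = 0`, growing geometrically for old history (panel ratio 1.15–1.25),
capped at unit width, and — for front histories — exact per grid segment
over the most recent 64 steps.  Steady states (3D environments only)
split the integral at `t₀ = (r+ri)² + 1` and map the tail through
`τ = 1/w²`, whose transformed integrand is smooth at `w = 0`.  Against
independent adaptive quadrature these panel schemes agree to ~1e-8
relative; against closed-form oracles (uniform sources, the emitting
ball's `aρri²/3D` surface value, the emitting disk's `2aρri/πD` rim
value) to better than 1e-6.

## Front finder

The information front solves `Cth = aρ ∫₀ᵗ dT ∫ dR G(r_c(t), t; R, T)`
with the emitting region bounded by `max(ri, r_c(T))` (the target emits
from t = 0 regardless of threshold, which is also the swarming variant).
After computing the initiation time, the front is advanced on a uniform
grid of step `Δt = D/10v²` (the default; halving it moves end radii by
< 0.5%).  At each step the radius is found by bracketed Brent root
finding, with the candidate point included as the final trajectory
segment inside the root solve — so the self-consistency constraint holds
exactly at every accepted point rather than up to a separate fixed-point
tolerance.  Concentration is monotone decreasing in r beyond the emitting
region, so the root is unique; the bracket `[r_prev, r_prev + 10 v Δt]`
expands outward if needed.

The simple-diffusion front is the threshold level set of the colony-only
field.  Its points carry no history dependence, so its grid is capped at
400 steps regardless of `D/10v²`; in 3D environments it approaches the
finite steady-state level set, and it is empty when the threshold exceeds
the steady-state maximum.

Measured transients, for orientation: the relay front slope reaches the
asymptotic speed within 1.2% by t = 100 D/v² for (1,1), (2,2) and (2,3).
For (3,3) the spherical curvature correction (≈ −2D/vr) leaves the slope
2.4% low at t = 100 D/v²; it passes 2% only around t ≈ 200 D/v², which is
where the convergence test checks it.

## Initiation

`t_init` solves `Cth = c(ri, t)` by doubling-bracket plus Brent (relative
tolerance 1e-4 by default).  In 3D environments "never initiates" is
decided against the dedicated steady-state quadrature, not a finite
horizon, eliminating false negatives from slow saturation; in 1D/2D a
finite `t_max` raises instead, since initiation always occurs eventually.
Critical radii are bisected on the steady state: exactly `D/v` for cells
in 2D under 3D diffusion and `√3·D/v` for cells in 3D (from
`c_ss(ri) = aρri²/3D`); the near-critical divergence is implemented as
`t_init ∝ ri⁶ [(v²ri²/3D²) − 1]^(−2)`.  The closed-form small/large-colony
limits are provided for cross-validation only; the 2D small-colony law is
order-of-magnitude (its exponent, not its prefactor, is asserted in
tests).  One caveat documented deliberately: the mismatched-dimension
plateau `4D/πv²` carries a finite-colony correction
`t_init ≈ (4/π)(1 + 2/(π·ri v/D)) D/v²`, i.e. still +6.4% at
`ri = 10 D/v` — the plateau is a genuine `ri → ∞` limit, unlike the
matched-dimension `2D/v²` which is reached super-exponentially fast.

## PDE oracle

The direct solver discretizes the radial Laplacian with conservative
finite volumes (cell centers at `(j+½)Δr`, no-flux boundaries) and steps
with Crank–Nicolson diffusion (sparse LU factorized once) plus an
explicit source with one corrector pass; decay enters the implicit
operator.  The singular cell layer of mismatched geometries is never
discretized: it becomes the flux condition `−D ∂c/∂z = aρ f(c_surf)` at
`z = 0`, on a geometrically stretched z grid (first spacing `D/20v`,
ratio 1.08, extent `6√(D·t_end)`).  Activation at the layer is decided on
the reconstructed surface value (center value plus half-cell flux
correction), ties counting as active; this converges to the
Green's-function front from above (+2.0% at `Δr = D/20v`, +0.5% at
`D/40v`).  Defaults: `Δr = D/20v`, `Δt = D/20v²`, radial extent
`1.3 v t_end + ri + 12 D/v`.  Mass is conserved to machine precision by
construction; the bookkeeping arrays let tests assert it.

The Hill-prefactor measurement runs this solver for cells-2D/diffusion-3D
with Hill n = 2 to `t = 40 D/v²` and fits the level-set slope over
[32, 40] D/v² (grid-converged: refining to `D/40v` moves α by 0.1%).  The
measured `α = v·Cth/aρ` is 0.662, about 4% above 2/π — consistent with
2/π being the Heaviside value and an approximation for low Hill orders.

## Swarming application

The target is idealized as a permanently emitting disk of `ri = 100 µm`
(the physical targets are smaller, oblong objects).  The thick-medium
model has exactly two parameters, `Cth/aρ` (s/m) and `D`; fitting to
observed front points is weighted least squares on radial residuals in
log-parameter space (Levenberg–Marquardt), replacing the by-eye fit such
data is usually given — hence recovery tolerances of ±10%.  Parameter
sets whose horizon exceeds 100 D/v² are rejected as inadmissible during
fitting (they are far outside the regime the data constrains and would
cost thousands of front steps).  The matched simple-diffusion threshold
at `t_match` is found by Brent on the log-threshold; it *decreases* with
`t_match`, since matching the receding relay front requires ever more
sensitive cells.

The synthetic generator emulates the chemotactic-index data product:
`⟨cos θ⟩ = 0.95` inside the true relay front and 0 outside, on 25 µm ×
25 s bins out to 600 µm and 500 s, plus i.i.d. Gaussian noise of σ = 0.05
(the default study condition), clipped to [−1, 1]; fronts are extracted
per time bin as the outermost crossing of half the directed value.  It
does **not** emulate finite-cell counting statistics, correlated tracking
errors, target asphericity, or the gradual rise of the index behind the
front — so passing recovery tests demonstrate identifiability under
binning and additive noise, not robustness to all real-data pathologies.
Extraction quantizes radii at the bin scale, which induces a small
systematic bias in the fit (~+4% in `Cth/aρ`, ~−6% in `D` at the default
binning) that is included in, and dominates, the ±10% recovery band.
The recovery property is checked across 20 seeded replicates.

## Validity criteria and conventions

The dimensionless checks `d·v/4D ≪ 1` (continuum), `h·v/D` (≪1 thin, ≫1
thick), `H·v/D ≪ 1` (cell layer), `γD/v² ≪ 1` (decay) and `τv²/D ≫ 1`
(pulse) are reported with package cutoffs 0.25 for "≪" and 4 for "≫"
(configurable; the theory states only the inequalities).  Concentrations
are molecule number densities (molecules/m³) throughout; molar conversion
is a documented helper.  The (1,1) channel convention uses cross-section
h², so its speed is `√(aρD/h²Cth)`.

## Known limitations

- The thick-medium comoving profile is returned only in its two closed
  limits, with an explicit unreliability flag for `|r̃| ≲ D/v`; no
  interpolation is invented for the crossover zone.
- Decay is supported numerically (PDE) but the Green's-function kernels
  omit it (the extension is a factor `e^(−γτ)`, documented but untested).
- Front propagation assumes axisymmetry and a monotone (non-receding)
  relay front.
- Hill activation is available in the PDE path only; the Green's-function
  front finder requires the sharp-threshold structure.
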