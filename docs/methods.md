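# Methods

This note records the model assumptions, numerical choices and known
limitations of the package, in the order the pipeline uses them.

## Coarse-grained filament model

The filament is an inextensible elastic rod confined to the inner surface of
a rigid cylinder (the turgor-pressed membrane is treated as undeformable; a
flat membrane is the `r → ∞` limit). Its state is the pitch-angle field
`θ(s)` and the twist field `ψ(s)`; the energy functional is quadratic in the
curvature and twist-rate mismatches plus a single-welled binding potential
`2V sin²(ψ/2)`, minimal only at `ψ = 0` because MreB has one membrane-binding
face. Energies are in `kBT` (≡ 1), lengths in nm, angles in radians
internally and degrees at every public interface.

Default (wild-type) parameters, with provenance:

| parameter | default | meaning / origin |
|---|---|---|
| `K` | 4.6·10³ kBT·nm | torsional modulus from the twist-angle SD, `K = Δl/σ²` with σ = 1.88°/monomer |
| `C` | 4.6·10³ kBT·nm | bending modulus; set to `K`'s magnitude (the direction-wise bending SDs needed to pin it are not separately published). See "sensitivity" below. |
| `V` | 4 kBT/nm | 10 kBT membrane-binding energy per monomer × 2 protofilaments / 5 nm rise |
| `µ0` | 2 kBT/nm | 5 kBT polymerization free energy per monomer × 2 / 5 nm |
| `k0` | 2.3·10⁻³ rad/nm | intrinsic curvature from the mean bending angle |
| `ω0` | 0.03595 rad/nm | intrinsic twist, 10.3° (ATP-state doublet twist) per 5 nm rise |
| `Δl` | 5 nm | monomer rise, used in every per-monomer ↔ per-length conversion |

## Flat-membrane analytics

The first integral of the Euler–Lagrange equation gives
`ψ′ = √(ω0² + (2V/K)(sin²(ψ/2) − sin²(ψm/2)))` with free-end boundary
conditions `ψ(±L/2) = ±ψm`, `ψ′(±L/2) = ω0`; the solution is antisymmetric
about the filament midpoint. `L(ψm)` and `E(ψm)` are evaluated by adaptive
quadrature (the normative path) and, as a validated fast path, by incomplete
elliptic integrals using scipy's parameter-`m` convention with
`m = −2/(2·lm² + cos ψm − 1)`, `lm = √(K/2V)·ω0`; the two paths agree to
better than 10⁻⁶ relative and the quadrature is what the energy–length curve
uses. The branch exists for `sin(ψm/2) < lm`; at the bound the boundary
layer detaches and `L` diverges, which the code reports as an explicit
`PsiBoundError` rather than a NaN.

The energy–length profile sweeps `ψm` on a grid geometrically clustered
toward the bound, restricts to the monotone `L(ψm)` branch, fits a monotone
(PCHIP) spline to `(L, E)` and differentiates it for `dE/dL`. The limit
length is the first `dE/dL = µ0` crossing located by linear interpolation;
`math.inf` encodes "unbounded" (no crossing up to `L_max`, default
2,000 nm). `dE/dL` saturates at the fully-bound interior density
`e0 + Kω0²/2` with `e0 = Ck0²/2`, so the limit length is finite exactly when
that density exceeds `µ0`.

### Zero-winding restriction

Both the analytics and the Monte Carlo are deliberately restricted to the
zero-winding sector (`n = 0`: no full 360° twist anywhere along the
filament), on the physical ground that a protein filament breaks before
accumulating a full turn against its binding interface. The restriction is
load-bearing, not cosmetic: with the default parameters the freely twisting
*unbound* state (density `V/2 = 2 kBT/nm`) undercuts the untwisted bound
state (`Kω0²/2 ≈ 2.97 kBT/nm`), so an unconstrained minimizer escapes
through 2π twist walls at large `L` (we measured ~27% lower energy at
`L = 400 nm`) and no limit length would exist at all. Concretely, Monte
Carlo proposals reject `|ψ| > π` and the brute-force oracle minimizes inside
the same box, so all routes describe the same sector. Winding solutions with
`n ≥ 1` are exposed in the analytical API for completeness but are untested
against published behaviour.

## Monte Carlo minimization

The Hamiltonian is discretized by the midpoint rule on `N = L/Δl` segments
(angle values at the `N+1` nodes; gradient terms from nearest-neighbour
differences, pointwise terms from nearest-neighbour means), which reproduces
constant-density configurations exactly and converges at O(Δs²). Starting
from `θ = 90°, ψ = 0`, each step perturbs one randomly chosen node angle
(θ or ψ with probability ½) by a uniform draw in `[−δ, δ]`; uphill moves are
accepted with probability `exp(−ΔE/kBT)`. `δ` is auto-tuned every 10³ steps
toward a 30–50% acceptance rate; θ proposals leaving `[0, π]` and ψ
proposals leaving `[−π, π]` are rejected outright. Ends are free; boundary
derivatives are one-sided by construction of the interval sum.

A literal fixed-temperature Metropolis walk cannot serve as a *minimizer*
here: at `kBT = 1` the equilibrium thermal excess is ~`n_dof/2 kBT`
(comparable to the whole minimum energy for short filaments), and the
1%/10⁴-step fluctuation rule never triggers when `E_min` is small. The
default schedule therefore runs 30% of the budget at the working temperature
(exploration), cools geometrically to `10⁻⁴ kBT` over the remainder, applies
the fluctuation criterion (with a 0.05 kBT absolute floor for near-zero
minima) in the cold phase, and finishes with a deterministic L-BFGS-B polish
of the best-found state using the analytic gradient. A `pure` mode retains
the un-cooled, un-polished algorithm for detailed-balance checks, where the
realized uphill acceptance frequency is verified against the mean Boltzmann
factor of uphill proposals. Every run is bit-reproducible from its seed
(replicate seeds are spawned from the base seed via `SeedSequence`), the
result energy is always recomputed with the reference numpy Hamiltonian, and
non-convergence is returned as a flag, never silently. The inner loop is
numba-compiled (~10⁶ steps/s), which is what makes replicate radius sweeps
affordable on one CPU.

Problem sizes used in the shipped analyses and checks: 10⁶ steps and 3
replicates per (radius, length) for the radius sweep over lengths
100–1,000 nm; 2–4·10⁵ steps for single-point comparisons; 20 replicates
remain the library default.

## Pitch angle on a cylinder

On a cylinder the helical geometry contributes `sin(2θ)/(2r)` to the frame
rotation rate, so a tilted filament (`θ > 90°` for left-handed `ω0 > 0`)
absorbs part of the intrinsic twist; the `C(sin²θ/r − k0)²` term opposes
tilting (and pins `|sin θ| = √(k0·r)` when `k0·r ≤ 1`). The reported pitch is
the length-weighted mean of θ with deviation `|θ̄ − 90°|`. The geometric
relief saturates at `θ = 135°` (where `|sin 2θ|` is maximal), so with the
default `C` the equilibrium pitch deviation is large (~40°) and grows only
slowly with `ω0`; the *trends* — more twist → more deviation, more `k0` or
`C` → closer to 90°, `K`/`V` nearly pitch-neutral — are robust and are what
the tests assert. A quasi-1D shortcut (uniform tilt, flat boundary-layer
problem at the tilt-renormalized twist rate `ω_eff = ω0 + sin2θ/(2r)`)
reproduces the Monte Carlo pitch to within a degree at a small fraction of
the cost and is what the synthetic mutant panel uses for its predictions.

## Sensitivity of the headline numbers (and an honest discrepancy)

The flat limit length is steeply sensitive to `ω0` near the default value,
because `Kω0²/2` sits close above `µ0`: `ω0 = 10.3°/5 nm` gives
`L* = 120 nm`, `9.0°/5 nm` gives 176 nm, and below `8.4°/5 nm` growth is
unbounded. Independently reported limit lengths around 160 nm therefore
correspond to an effective `ω0` a few percent below the 10.3° ATP-state
doublet twist used here; the same shift moves the critical membrane radius
(largest radius with `dE/dL < µ0` everywhere) from the ~60 nm computed here
to ~80–120 nm. We keep the directly derived `ω0` rather than back-fitting
it, and report the computed numbers as they fall. `C` cannot repair this:
on a flat membrane it enters only through `e0 = Ck0²/2 ≈ 0.01 kBT/nm`.

## Trajectory geometry

Opening angle: mean of the two subdomain-centroid angles (at IIA between
IIA→IIB and IIA→IA, and at IA between IA→IB and IA→IIA); dihedral: absolute
angle between the (IA, IB, IIA) and (IIB, IIA, IA) plane normals, reported
in [0°, 180°] (signed trends live in the time series, not the sign).
Centroids are unweighted over the labelled heavy atoms (a weighted mode is
available); the N-terminal amphipathic helix (residues 1–8) is always
excluded and the frame type enforces that.

Body frames: `d3` points from a subunit's centroid toward its partner's,
`d2` is the membrane normal orthogonalized against `d3`, and `d1 = d3 × d2`
as in the source convention — note that this ordered triple has determinant
−1, so the Euler decomposition conjugates by the (improper) basis matrix and
flips the angle signs by its determinant, making planted-rotation
round-trips exact. Frame triads are carried from the reference structure by
the rotation part of a Kabsch superposition, which makes all angle operators
invariant to global rigid motion. The decomposition order is twist about
`d3` first, then bending about `d2`, then about `d1`; at the ≤20° angles of
interest order effects are below 0.1° (asserted by test), and `|θ2| > 80°`
triggers a gimbal warning. The membrane normal for water-only systems is
inherited from the reference configuration.

SASA is Shrake–Rupley with 960 Fibonacci-sphere points per atom and a
1.40 Å water probe, implemented directly on (position, radius) sphere sets so
the generators can exercise it without structure files; it is cross-checked
in the tests against an independent library implementation and against
closed-form sphere/cap values. Buried area between two molecules is
`(A1 + A2 − A1+2)/2`, clipped at zero (with a warning) when sampling noise
makes it marginally negative. Membrane-patch curvature fits
`z = ax² + bxy + cy² + dx + ey + f` in the cloud's principal-axes frame and
returns the largest-magnitude principal curvature of the shape operator at
the fitted-surface centre; the sign is positive toward a caller-supplied
protein-side direction (without it the normal orientation, hence the sign,
is arbitrary).

## Parameter estimation

Equilibrium windows (default: last 40 ns) are histogrammed at 0.5° and fit
with a least-squares Gaussian, falling back (flagged) to sample moments for
degenerate distributions. Conversions: `K = Δl/σ²` and `C` as the average of
the two direction-wise bending moduli (warning above 5% disagreement);
`ω0 = θ̄3/Δl`, `k0 = √(θ̄1² + θ̄2²)/Δl`; `V` and `µ0` from per-monomer
energies times two protofilaments per rise (`ΔG = −ln Kc` helper included).
σ is interpreted per monomer step; degrees convert to radians exactly once
at estimator entry. A single 200-frame window determines σ only to ~5%
(iid) or far worse under realistic autocorrelation, so `K` (∝ σ⁻²) from one
window carries tens of percent of uncertainty; quantitative recovery checks
therefore pool the fitted SDs of several replicate windows in quadrature,
mirroring how replicate simulations are pooled in practice. Pearson
correlations carry two-tailed Student-t p-values
(`t = r√((n−2)/(1−r²))`, `df = n−2`); constant input raises rather than
returning NaN. The 10 kBT per-monomer binding energy is an *input* — the
mapping from interface-burial dynamics to an energy is not modelled.

## Patch quantification

Flattened-surface images (rows = long cell axis) are min–max normalized and
binarized at a fixed 0.5 level (mirroring the cited routine's default; a
constant non-zero image is an error, a blank one yields an empty table);
8-connected components below the 0.02 µm² structured-illumination resolution
limit are discarded; each component's second-moment ellipse gives the length
(major-axis length × pixel size) and the pitch (major-axis orientation vs.
the long axis, folded into [0°, 90°]). The default pixel size is 0.032 µm
(configurable — the true reconstructed pixel size is not published).
Length and pitch estimates are exactly equivariant under 90° image rotation
and invariant under intensity scaling; note that a 300 × 60 nm band has a
true area (~0.014 µm²) *below* the resolution filter, so measuring such a
band requires relaxing `min_area_um2`. Pooled summaries: empirical CDFs,
the 99th length percentile (linear interpolation; refused below n = 100),
and mean ± SEM pitch.

## Synthetic data: what it does and does not emulate

Angle series are discrete Ornstein–Uhlenbeck processes (default correlation
time 2 ns, frames 0.2 ns apart, 60 ns burn-in relaxing from zero to the
target mean) with stationary N(mean, sd) tails — they emulate the
*statistics* of equilibrated trajectory observables, not any underlying
dynamics, so passing recovery tests validates the estimators, not the MD.
Rigid pairs plant exact bend/twist rotations on an asymmetric four-subdomain
pseudo-atom cloud with optional positional noise. Membrane clouds are
jittered lattices on exact cylinders. Surface images render solid-ellipse
bands (half-max thresholding then recovers the planted axes), blurred by a
Gaussian PSF and degraded by Poisson shot noise plus Gaussian read noise —
no structured-illumination reconstruction artefacts. Every generator emits
its ground truth alongside the data (JSON sidecars on disk), and recovery
tests read truth only from there.

The mutant panel composes the model end to end: per planted twist, the flat
analytics predict the limit length — capped at 800 nm (≈ half the periphery
of a 0.8 µm-wide cell) for strains whose growth the model leaves unbounded,
standing in for the cell-geometry ceiling seen in vivo — and the quasi-1D
cylinder model predicts the pitch at a fixed 200 nm reference length (so
strains differ through twist, not through the cap). Planted per-strain patch
lengths are log-normal with their 99th percentile at the predicted limit
plus a constant 0.2 µm resolution offset (the apparent-size floor of
diffraction-limited imaging); pitches are Gaussian (SD 3°) around the
prediction. The panel supports *sign-level* correlation checks only — the
published correlation coefficients depend on real data and are not
reproduced.

## Known limitations

* The membrane is rigid: no membrane deformation energetics, although the
  trajectory-geometry module measures induced curvature in membrane clouds.
* No polymerization kinetics — the limit length is a purely energetic
  balance point.
* `C` and the per-mutant `ω0` are the least constrained inputs; the
  sensitivity section above quantifies the consequences.
* Monte Carlo "minimization" finds local minima within the zero-winding
  sector; the 20-replicate default guards against basin-trapping but cannot
  prove global optimality.
* The SIM image model is a Gaussian-PSF cartoon; segmentation behaviour on
  real reconstructions (ringing, channel misalignment) is out of scope.
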