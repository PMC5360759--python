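# Methods

## The deformation model

The simulator generates longitudinal brain images whose voxel-wise volume
change is known exactly, for use as ground truth when validating atrophy
estimation (e.g. tensor-based morphometry) pipelines. The input is a baseline
scan, a three-regime segmentation, and an atrophy map `a` giving the
fractional volume loss per time step at each voxel, `a = (V0 − V1)/V0`
(positive = shrinkage, negative = growth).

Tissue is modelled as a quasi-static creep flow: prescribed volume change
creates internal stress which the tissue relieves by deforming, and each
step's strain energy is fully released before the next step. With
displacement `u` (mm) and a pressure-like multiplier `p` (kPa) the system
solved per step is

| Regime | Equations |
| --- | --- |
| Label 0 (skull, background) | `u = 0` (Dirichlet, unknowns eliminated) |
| Label 1 (CSF, ventricles) | `μ Δu − ∇p = 0`, `∇·u + k p = 0` |
| Label 2 (parenchyma) | `μ Δu − ∇p = (μ+λ) ∇a`, `∇·u = −a` |

Incompressibility is strict in Label 2 (the prescribed divergence) and
relaxed in Label 1, whose compliance `k` lets the CSF compartment absorb
exactly the volume lost by the parenchyma: with zero boundary displacement
the divergence integral vanishes, so Label-1 expansion equals Label-2 loss
by construction. For small steps `∇·u = −a ≈ J − 1`, where `J = det(I+∇u)`
is the local ratio of warped to original voxel volume.

Parameter defaults are `μ = 1 kPa`, `λ = 0 kPa`, `k = 1 kPa⁻¹`. Only the
ratio structure matters for the displacement: scaling `(μ, λ) → (cμ, cλ)`
and `k → k/c` leaves `u` unchanged and scales `p` by `c` (asserted to 1e-8
in the tests). Different `(μ, λ, k)` trade off where the compensating
deformation concentrates, not whether the constraint holds.

## Discretisation

Velocity components live on cell faces (staggered/MAC layout), pressure and
atrophy at cell centers; this avoids pressure checkerboarding. Momentum rows
use the canonical 7-point second-difference Laplacian per face component
with spacing-aware coefficients; `∇p` and `∇a` are face-centered differences
of cell values, making the discrete gradient and divergence adjoint up to
the `k` term and yielding a well-posed saddle-point system.

Two divergence stencils are supported for the constraint rows:

* **6-point** (per cell, its own six faces): the natural staggered stencil.
* **12-point**: the centered difference of face-averaged center values,
  algebraically identical to applying the standard centered-difference
  divergence to the center-sampled output field.

The output displacement image holds face averages at centers, so external
tools measuring divergence or Jacobians with centered differences only see
the 12-point view. Solving with the 6-point stencil therefore leaves an
apparent constraint error in external measurements, largest within a couple
of voxels of atrophy discontinuities; solving with the 12-point stencil
(the default) makes the external measurement agree with the prescription to
solver precision. Ground-truth Jacobians are computed with the same centered
stencil for the same reason: ground truth must be scheme-matched to the
measurement that consumes it.

Face handling: a face is a zero (Dirichlet) face when it lies on the domain
boundary or either adjacent cell is Label 0; such faces are eliminated, so
Label-0 displacement is exactly zero, not merely small. A mixed
Label-1/Label-2 face keeps the standard momentum row with the forcing term
evaluated from the adjacent cells' `a` values (`a = 0` on the Label-1 side);
this keeps the operator symmetric and the constraint rows untouched.
Label-2 connected components with no path to a Label-1 cell have a
constant-pressure nullspace (all their boundary faces are Dirichlet); their
mass rows receive a tiny diagonal `ε = 1e-8` with a logged warning.
Prescribing nonzero atrophy outside Label 2, or without any Label-1 voxel to
compensate, is a hard error.

### Linear solver

Unknowns are ordered faces-by-component then pressures, lexicographically.
Two backends:

* **direct** — sparse LU of the full saddle-point matrix; used by default
  below 25 000 unknowns, where it is fast and bit-deterministic.
* **schur** — factor the (component-decoupled, definite) velocity Laplacian
  once, then GMRES on the pressure Schur complement `K − D A⁻¹ G`. The MAC
  Stokes Schur complement is spectrally close to a scaled mass matrix, so
  unpreconditioned GMRES converges in a few dozen iterations; a 32³ phantom
  solves in under ten seconds on one core.

The achieved relative residual, the worst violation of the divergence
constraint over Label 2 (measured with the solve's own stencil), and the
flux-form conservation residual are reported in the diagnostics of every
solve. The default verification tolerance is 1e-8; direct solves typically
achieve 1e-14.

## Field calculus and warping

* `divergence_centered` and the Jacobian use centered differences in the
  interior and first-order one-sided differences at the domain edge
  (comparisons restrict to interior voxels; the edge rule is a convention).
* Composition `Φ_outer ∘ Φ_inner` samples the outer field trilinearly at the
  inner-displaced positions. Out-of-domain samples extend by zero, which is
  exact for solver fields (they vanish at the boundary by the Dirichlet
  condition); the count of such samples is logged.
* Inversion iterates the fixed point `v ← −u(y + v)` from `v = 0` until the
  largest update is below `1e-3 · min(spacing)` mm (cap 100 iterations,
  error on non-convergence). Convergence requires `‖∇u‖ < 1`, amply true for
  single-step atrophy fields.
* Images are warped by pulling through the inverse field with B-spline
  interpolation (order 0–5, default 3); segmentations use nearest-neighbor
  pulls with round-half-toward-lower-index tie-breaking for platform
  determinism. Order-3 interpolation can overshoot near edges by design;
  bounds are preserved only up to that ringing.

## Longitudinal sequences and intensity resampling

For `n` time points the solver runs once per step. Before step `t`, the
previous step's atrophy map and the *original* labels are warped with the
accumulated composed field (trilinear for atrophy, nearest-neighbor for
labels), and the warped atrophy is masked to the warped Label-2 support so
interpolation bleed at region edges cannot violate the zero-outside-
prescribed-region invariant. Because the atrophy map is re-warped each step,
the total prescribed atrophy drifts slightly over a sequence; this is a
property of the procedure, left uncorrected by default (a rescale hook
exists, default off). Images for every time point are warped from the
original baseline through the accumulated field, never by chaining warps of
warped images, to avoid compounding interpolation blur.

Intensity variants per time point: resampling the baseline gives `I_s0`;
resampling a same-session repeat scan through the same simulated field gives
`I_s1` (same morphology, the other scan's noise and bias); resampling a
later-time scan `I_r` through `Φ_sim ∘ Φ_reg`, with `Φ_reg` the registration
of `I_r` onto the baseline, gives `I_s2`. All variants share one simulated
field, so their ground-truth volume change is identical by construction.
The registration itself is out of scope — any tool that emits a displacement
field can supply `Φ_reg`.

## Phantoms

The synthetic generator stands in for preprocessed real scans: concentric
spheres give background+skull (Label 0), a CSF shell and central ventricle
(Label 1), and a parenchyma shell with embedded ROI blobs (Label 2).
Defaults scale with grid size (`for_shape`): outer CSF radius 0.42, parenchyma
0.30, ventricle 0.12 of the grid extent, one ROI blob of radius 0.07 offset
from center — proportions chosen so that even an 8³ grid retains all three
regimes. Intensities are per-tissue means (parenchyma 110, CSF 30, skull 40,
background 0) plus Gaussian noise (default sd 5); a Rician option (magnitude
of complex Gaussian) exists for comparison studies. Repeat scans redraw the
noise and can multiply in a smooth random polynomial bias field of order 2
and amplitude 0.2, emulating inter-scan inhomogeneity differences. Follow-up
scans warp the noiseless anatomy by a known field and return the exact
inverse as ground-truth `Φ_reg`, so registration error can be injected in
controlled amounts. All randomness flows from explicit seeds; identical
specs produce bit-identical phantoms.

What the phantoms do **not** emulate: cortical folding and anatomical
detail, partial-volume mixtures, MR acquisition physics (k-space, motion,
Gibbs ringing), and realistic noise correlation structure. Tests passing on
phantoms demonstrate the numerical contracts of the pipeline — constraint
satisfaction, conservation, scheme consistency, round trips, resampling
structure — not anatomical realism of the simulated images.

## Problem sizes and numerical checks

Tests and the acceptance script use 8³ phantoms for dense-oracle and
parameter-scaling checks (small enough for dense LAPACK factorization), 16³
for round trips, 24³ for first-order volume accounting and the 3-step
sequence, and 32³ for the Dirichlet, scheme-consistency, conservation and
resampling experiments; each completes in seconds on one core. Key
tolerances: solver verification 1e-8; inversion `1e-3·min(spacing)` mm;
metadata agreement 1e-4 mm; scheme-consistency checks compare against
`10 × 1e-8`; the first-order volume relation is checked against the Taylor
bound `2·(max a)²` and sequence compounding against `2·n·a²`.

## Known limitations

* Homogeneous, isotropic `μ, λ` per regime; no hyperelasticity, anisotropy,
  or skull contact mechanics.
* Single-grid operation: all inputs must be pre-aligned on one grid
  (enforced, tolerance 1e-4 mm); no resampling between spaces.
* The fixed-point inverse is approximate near `‖∇u‖ → 1` and not a
  diffeomorphic guarantee.
* Nearest-neighbor label warping over many accumulated steps can produce
  stair-casing; long sequences inherit that instability.
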