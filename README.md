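# atrophysim

Biophysical simulation of longitudinal brain MR images with **known,
prescribed voxel-wise volume change** and realistic intensity variation.

Validating atrophy-estimation pipelines (registration-based morphometry,
tensor-based morphometry) requires ground truth that real longitudinal data
cannot provide: nobody knows the true voxel-wise volume change in a
patient's scans. This package generates that ground truth. Given a baseline
image, a three-regime segmentation and an atrophy map
`a = (V0 − V1)/V0` (fractional volume loss per step, positive = shrinkage),
it solves

```
Label 0 (skull/background):  u = 0
Label 1 (CSF):               μ Δu − ∇p = 0,          ∇·u + k p = 0
Label 2 (parenchyma):        μ Δu − ∇p = (μ+λ) ∇a,   ∇·u = −a
```

on a staggered (MAC) grid, producing a displacement field whose divergence
equals `−a` at every parenchyma voxel while the CSF compartment expands to
compensate (`∇·u = −a ≈ J − 1`, with `J = det(I + ∇u)` the Jacobian
determinant, the local V1/V0). Warping the baseline through the field gives
a follow-up image whose volume change is known exactly; resampling the
intensities from other co-registered scans of the same subject — directly
for a same-session repeat scan, through a composed field
`Φ_sim ∘ Φ_reg` for a later scan — adds the noise/bias variation of real
repeat acquisitions without modelling MR physics. Multi-time-point
sequences warp the atrophy map and labels forward with accumulated composed
fields and re-solve per step.

Two divergence stencils are available for the solver's constraint rows: the
natural 6-point face stencil and a 12-point stencil consistent with the
centered differences external morphometry tools apply to the center-sampled
output field. With the 12-point scheme (default) the externally measured
`∇·u + a` is zero to solver precision; with the 6-point scheme it is not,
with the error concentrated at atrophy discontinuities — choose the scheme
to match the measurement that will consume the ground truth. See
`docs/methods.md` for the discretisation, solver and design details.

A synthetic phantom generator (concentric skull/CSF/parenchyma geometry,
per-tissue intensities, seeded noise, smooth bias fields, follow-up scans
with exact registration ground truth) makes the whole pipeline testable
without any real MRI.

## Worked example

```python
import numpy as np
from atrophysim import (PhantomSpec, make_phantom, atrophy_from_table,
                        RoiAtrophyTable, simulate_step, jacobian_determinant,
                        divergence_centered)

spec = PhantomSpec.for_shape((32, 32, 32), seed=1)
baseline, labels, rois = make_phantom(spec)

# 5 % volume loss per step in the parenchyma (ROI 1) and the blob (ROI 17)
a = atrophy_from_table(rois, RoiAtrophyTable({1: 0.05, 17: 0.05}), labels)
step = simulate_step(baseline, labels, a)

print("max |u| in rigid region :", np.abs(step.displacement.values[labels.values == 0]).max())
print("max |div u + a| (L2)    :", np.abs(divergence_centered(step.displacement).values
                                          + a.values)[labels.values == 2].max())
J = jacobian_determinant(step.displacement).values
print("measured volume loss    : %.3f %%" % (100 * (1 - J[labels.values == 2].mean())))
```

prints

```
max |u| in rigid region : 0.0
max |div u + a| (L2)    : 1.3490195072130007e-11
measured volume loss    : 4.927 %
```

— the skull/background never moves (those unknowns are eliminated, so the
zero is exact), the divergence constraint holds to solver precision, and
integrating the Jacobian over the parenchyma recovers the prescribed 5 %
loss up to the first-order `J − 1 ≈ −a` approximation.

The same pipeline is scriptable from the shell:

```
atrophysim phantom --shape 32,32,32 --seed 1 --out-dir work/
atrophysim atrophy-map --labels work/labels.nii.gz --rois work/rois.nii.gz \
    --table table.csv --out work/atrophy.nii.gz
atrophysim simulate --baseline work/baseline.nii.gz --labels work/labels.nii.gz \
    --atrophy work/atrophy.nii.gz --out-dir work/sim/
atrophysim divergence --field work/sim/displacement.nii.gz \
    --atrophy work/atrophy.nii.gz --labels work/labels.nii.gz --out work/div.nii.gz
```

Every run writes a provenance JSON (options, seeds, versions, solver
diagnostics) beside its outputs.

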