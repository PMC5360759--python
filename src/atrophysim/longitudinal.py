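"""Single- and multi-time-point simulation, and intensity resampling from
alternate scans through composed deformation fields.

A single step solves the deformation model for the prescribed atrophy and
warps the baseline: ``I_s = Φ_sim ⋆ I_b``.  Multi-step sequences re-solve at
each step on the anatomy transported so far: the atrophy map of the previous
step and the *original* segmentation are warped with the accumulated field
``u_{t-1} ∘ … ∘ u_0`` before solving step ``t``.  Because the atrophy map is
itself re-warped every step, the globally prescribed atrophy rate is not
necessarily preserved across steps — this is a property of the procedure,
reported in the per-step diagnostics rather than corrected for.

The key trick for realistic intensities: any other co-registered scan of the
same subject can replace the baseline as the intensity source.  A
same-session repeat scan is resampled through ``Φ_sim`` alone; a later-time
scan ``I_r`` with its own morphological change is resampled through
``Φ_sim ∘ Φ_reg``, where ``Φ_reg`` registers ``I_r`` onto the baseline.  All
variants share the same simulated field, so their ground-truth volume change
is identical by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atrophy import AtrophyMap
from .fields import compose_fields, invert_field
from .images import (
    DisplacementField,
    LabelImage,
    ScalarImage,
    assert_same_space,
)
from .solver import ModelParams, PressureField, SolverDiagnostics, solve_deformation
from .warp import warp_image, warp_labels

__all__ = [
    "SequenceSpec",
    "SimulationStep",
    "SequenceResult",
    "simulate_step",
    "simulate_sequence",
    "resample_intensity",
]


@dataclass
class SimulationStep:
    image: ScalarImage
    displacement: DisplacementField
    pressure: PressureField
    diagnostics: SolverDiagnostics


@dataclass
class SequenceSpec:
    """Configuration of a multi-time-point simulation.

    ``rescale_atrophy`` optionally renormalises each warped atrophy map so its
    total prescribed volume change matches the initial one; it defaults off,
    leaving the drift introduced by warping in place.
    """

    n_steps: int = 1
    params: ModelParams = field(default_factory=ModelParams)
    rescale_atrophy: bool = False
    interpolation_order: int = 3

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class SequenceResult:
    """Per-step fields, accumulated per-time-point fields, and images."""

    step_fields: list[DisplacementField]
    accumulated_fields: list[DisplacementField]
    images: list[ScalarImage]
    pressures: list[PressureField]
    diagnostics: list[SolverDiagnostics]
    atrophy_maps: list[AtrophyMap]
    label_maps: list[LabelImage]


def simulate_step(
    baseline: ScalarImage,
    labels: LabelImage,
    a: AtrophyMap,
    params: ModelParams | None = None,
    interpolation_order: int = 3,
) -> SimulationStep:
    """One model solve plus baseline warp: returns I_s, u, p and diagnostics."""
    assert_same_space(baseline, labels)
    u, p, diag = solve_deformation(labels, a, params)
    image = warp_image(
        baseline, u, field_is_inverse=False, interpolation_order=interpolation_order
    )
    return SimulationStep(image, u, p, diag)


def _mask_to_label2(a: AtrophyMap, labels: LabelImage) -> AtrophyMap:
    values = a.values.copy()
    values[labels.values != 2] = 0.0
    return AtrophyMap(a.grid, values)


def simulate_sequence(
    baseline: ScalarImage,
    labels: LabelImage,
    a0: AtrophyMap,
    spec: SequenceSpec | None = None,
) -> SequenceResult:
    """Simulate ``n_steps`` time points from one baseline.

    Step 0 solves on ``(a_0, L_0)``.  For each later step ``t`` the previous
    atrophy map and the original labels are warped with the accumulated field
    (trilinear for atrophy, nearest-neighbor for labels), the warped atrophy
    is masked to the warped Label-2 support, and the model is re-solved.
    Accumulated fields compose left-to-right (``u_t ∘ … ∘ u_0``) and images
    are always warped from the original baseline through the accumulated
    field, never by chaining warps of warped images.
    """
    spec = spec or SequenceSpec()
    assert_same_space(baseline, labels)
    assert_same_space(baseline, a0)

    target_total = float(a0.values.sum())
    step_fields: list[DisplacementField] = []
    accumulated: list[DisplacementField] = []
    images: list[ScalarImage] = []
    pressures: list[PressureField] = []
    diags: list[SolverDiagnostics] = []
    amaps: list[AtrophyMap] = []
    lmaps: list[LabelImage] = []

    a_t, l_t = a0, labels
    for t in range(spec.n_steps):
        if t > 0:
            acc = accumulated[-1]
            l_t = warp_labels(labels, acc, field_is_inverse=False)
            a_warp = warp_image(
                amaps[-1], acc, field_is_inverse=False, interpolation_order=1
            )
            a_t = _mask_to_label2(AtrophyMap(a_warp.grid, a_warp.values), l_t)
            if spec.rescale_atrophy and a_t.values.sum() != 0:
                a_t = AtrophyMap(
                    a_t.grid, a_t.values * (target_total / a_t.values.sum())
                )
        try:
            u, p, diag = solve_deformation(l_t, a_t, spec.params)
        except Exception as err:
            raise RuntimeError(f"sequence aborted at step {t}: {err}") from err
        acc = u if t == 0 else compose_fields(u, accumulated[-1])
        step_fields.append(u)
        accumulated.append(acc)
        pressures.append(p)
        diags.append(diag)
        amaps.append(a_t)
        lmaps.append(l_t)
        images.append(
            warp_image(
                baseline,
                acc,
                field_is_inverse=False,
                interpolation_order=spec.interpolation_order,
            )
        )
    return SequenceResult(step_fields, accumulated, images, pressures, diags, amaps, lmaps)


def resample_intensity(
    sim_field: DisplacementField,
    source: ScalarImage,
    reg_field: DisplacementField | None = None,
    interpolation_order: int = 3,
) -> ScalarImage:
    """Resample a simulated time point's intensities from an alternate scan.

    ``reg_field=None`` treats ``source`` as a same-anatomy scan (baseline or
    same-session repeat): output is ``Φ_sim ⋆ source``.  Otherwise
    ``reg_field`` must map the source scan's anatomy onto the baseline (the
    output of registering source → baseline) and the result is
    ``(Φ_sim ∘ Φ_reg) ⋆ source``.
    """
    assert_same_space(sim_field, source)
    if reg_field is None:
        total = sim_field
    else:
        assert_same_space(sim_field, reg_field)
        total = compose_fields(sim_field, reg_field)
    return warp_image(
        source, total, field_is_inverse=False, interpolation_order=interpolation_order
    )
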