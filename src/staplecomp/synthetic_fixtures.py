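"""Seeded synthetic stand-ins for unpublished reference data.

The ex vivo force-compression measurements used to validate the original
compression model are not publicly deposited, so validation runs against a
*synthetic* reference curve: the closed-form uniform-engine force response
perturbed by multiplicative log-normal noise.  Multiplicative noise keeps
forces positive and mimics the roughly scale-proportional scatter of soft
tissue mechanical tests.  Every generator here is a pure function of its
parameters and the seed, so fixtures regenerate bit-identically.

``make_toy_stress_field`` builds small hand-specified stress fields in the
shape of a solved load step, letting the band classifier be exercised
without running a solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import OgdenMaterial
from .geometry_mesh import TissueStack
from .solver import LayerStats, StepResult, _layer_stats, run_uniform, LoadProgram

__all__ = ["SyntheticReference", "make_reference_curve", "make_toy_stress_field"]


@dataclass(frozen=True)
class SyntheticReference:
    """Synthetic force-compression reference curve with full provenance."""

    ratios: np.ndarray  # compression ratios, dimensionless
    forces: np.ndarray  # N, after noise
    clean_forces: np.ndarray  # N, closed-form curve before noise
    sigma_log: float
    seed: int


def make_reference_curve(
    mat: OgdenMaterial,
    stack: TissueStack,
    seed: int,
    sigma_log: float = 0.15,
    max_ratio: float = 0.75,
    n_points: int = 15,
) -> SyntheticReference:
    """Noisy closed-form force curve on a uniform compression-ratio grid.

    ``forces[i] = F_closed(ratios[i]) * exp(sigma_log * z_i)`` with
    ``z_i ~ N(0, 1)`` drawn from ``numpy.random.default_rng(seed)``.
    """
    if not (0.0 <= sigma_log <= 0.5):
        raise ValueError(f"sigma_log must be in [0, 0.5], got {sigma_log}")
    ratios = np.linspace(max_ratio / n_points, max_ratio, n_points)
    program = LoadProgram(
        total_travel=max_ratio * stack.total_thickness,
        step_size=max_ratio * stack.total_thickness / n_points,
    )
    clean = np.array([s.reaction_force for s in run_uniform(mat, stack, program)[1:]])
    rng = np.random.default_rng(seed)
    noise = np.exp(sigma_log * rng.standard_normal(n_points))
    return SyntheticReference(
        ratios=ratios,
        forces=clean * noise,
        clean_forces=clean,
        sigma_log=sigma_log,
        seed=seed,
    )


def make_toy_stress_field(
    spec: list[tuple[float, float]],
    layer: str = "lower",
    d: float = 0.0,
    total: float = 1.0,
) -> StepResult:
    """Fixture step with one pseudo-element per ``(volume, von_mises)`` pair.

    All elements are tagged with ``layer``; stress tensors are uniaxial
    states whose von Mises equals the requested value.
    """
    if any(v <= 0 for v, _ in spec):
        raise ValueError("element volumes must be positive")
    n = len(spec)
    vol = np.array([v for v, _ in spec], dtype=float)
    vm = np.array([s for _, s in spec], dtype=float)
    stress = np.zeros((n, 4))
    stress[:, 1] = -vm  # compressive uniaxial state with |sigma| = vm
    tags = np.full(n, layer)
    return StepResult(
        index=0,
        d=d,
        ratio=0.0 if total <= 0 else d / total,
        stress=stress,
        von_mises=vm,
        current_volume=vol,
        ref_volume=vol.copy(),
        layer_tag=tags,
        layer_stats=_layer_stats(vm, vol, tags) if n else {},
        reaction_force=0.0,
    )
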