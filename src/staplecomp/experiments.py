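"""Study pipelines: thickness sweep, mesh convergence, force validation.

These reproduce the three study designs around the compression model:

* :func:`thickness_sweep` — run the load program for each tissue-thickness
  pair (default: the five clinically motivated pairs 2.5-2.5, 2.0-2.0,
  1.5-1.5, 2.5-1.5 and 1.5-2.5 mm), accumulate per-step layer statistics
  and stress-band fractions, and derive the safe distance/ratio/gap table.
* :func:`mesh_convergence` — refine the element size over a ladder of
  meshes and select the first size whose monitored mean equivalent stress
  changes by less than the criterion (default 3%) from the preceding size.
  The monitor state is the 2.5-2.5 mm stack compressed until the platen
  gap reaches 1 mm.
* :func:`validation_curve` — compare the model's force-compression curve
  against a reference curve (normally a synthetic stand-in, see
  :mod:`staplecomp.synthetic_fixtures`); the contract is agreement within
  an order of magnitude everywhere, and within a factor of two below 60%
  compression where soft-tissue models and bench data track each other
  closely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band_safety import BandFractions, SafetyTable, Thresholds, band_fractions, safety_table
from .constitutive import OgdenMaterial
from .geometry_mesh import ContactFootprint, TissueStack, build_mesh, default_footprints
from .solver import (
    LoadProgram,
    NonConvergenceError,
    SolverOptions,
    StepResult,
    run_fem,
    run_uniform,
)

__all__ = [
    "PAPER_THICKNESS_PAIRS",
    "PAPER_MESH_SIZES",
    "SweepConfig",
    "PairResult",
    "ConvergenceReport",
    "ValidationReport",
    "thickness_sweep",
    "mesh_convergence",
    "select_converged_size",
    "validation_curve",
    "layer_stats_frame",
    "band_fraction_frame",
    "safety_table_frame",
]

logger = logging.getLogger("staplecomp.experiments")

#: the five upper/lower thickness pairs of the study design (mm)
PAPER_THICKNESS_PAIRS: tuple[tuple[float, float], ...] = (
    (2.5, 2.5),
    (2.0, 2.0),
    (1.5, 1.5),
    (2.5, 1.5),
    (1.5, 2.5),
)

#: mesh-refinement ladder for the convergence study (mm)
PAPER_MESH_SIZES: tuple[float, ...] = (2.0, 1.6, 1.2, 0.8, 0.4)


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of the thickness sweep."""

    pairs: tuple[tuple[float, float], ...] = PAPER_THICKNESS_PAIRS
    engine: str = "uniform"  # "uniform" | "fem"
    thresholds: Thresholds = field(default_factory=Thresholds)
    r_inner: float = 10.0
    r_outer: float = 16.0
    element_size: float = 0.8
    max_ratio: float = 0.8
    step_size: float = 0.1
    footprints: tuple[ContactFootprint, ContactFootprint] | None = None
    solver_options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.engine not in ("uniform", "fem"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not (0.0 < self.max_ratio <= 0.95):
            raise ValueError(f"max_ratio must be in (0, 0.95], got {self.max_ratio}")


@dataclass
class PairResult:
    """Everything computed for one thickness pair."""

    stack: TissueStack
    results: list[StepResult]
    fractions: list[BandFractions]
    table: SafetyTable
    error: str | None = None


def _run_pair(cfg: SweepConfig, mat: OgdenMaterial, t_u: float, t_l: float) -> PairResult:
    stack = TissueStack(t_upper=t_u, t_lower=t_l, r_inner=cfg.r_inner, r_outer=cfg.r_outer)
    program = LoadProgram.for_stack(stack, max_ratio=cfg.max_ratio, step_size=cfg.step_size)
    fps = cfg.footprints or default_footprints(stack)
    if cfg.engine == "uniform":
        results = run_uniform(mat, stack, program, anvil=fps[0])
    else:
        mesh = build_mesh(stack, cfg.element_size)
        results = run_fem(mat, stack, fps, program, mesh, cfg.solver_options)
    fractions = [band_fractions(s, cfg.thresholds) for s in results]
    table = safety_table(results, cfg.thresholds, stack)
    return PairResult(stack=stack, results=results, fractions=fractions, table=table)


def thickness_sweep(
    cfg: SweepConfig, mat: OgdenMaterial | None = None
) -> dict[tuple[float, float], PairResult]:
    """Run the full load program for every thickness pair in the config.

    A solver failure on one pair is recorded in that pair's
    ``PairResult.error`` (with results up to the failing step empty) and
    does not abort the sweep.  Deterministic given the configuration.
    """
    mat = mat or OgdenMaterial.from_pa()
    out: dict[tuple[float, float], PairResult] = {}
    for t_u, t_l in cfg.pairs:
        try:
            out[(t_u, t_l)] = _run_pair(cfg, mat, t_u, t_l)
            logger.info(
                "sweep pair %.1f-%.1f: joint safe gaps %s",
                t_u, t_l, out[(t_u, t_l)].table.joint_safe_gaps,
            )
        except NonConvergenceError as err:
            stack = TissueStack(t_upper=t_u, t_lower=t_l, r_inner=cfg.r_inner, r_outer=cfg.r_outer)
            out[(t_u, t_l)] = PairResult(
                stack=stack,
                results=[],
                fractions=[],
                table=safety_table({"upper": [], "lower": []}, cfg.thresholds, stack),
                error=str(err),
            )
            logger.warning("sweep pair %.1f-%.1f failed: %s", t_u, t_l, err)
    return out


def select_converged_size(
    sizes: tuple[float, ...], means: tuple[float, ...], criterion_pct: float
) -> tuple[tuple[float, ...], float, bool]:
    """Convergence selection: percent changes, chosen size, converged flag.

    The chosen size is the first whose monitored value changed by less
    than ``criterion_pct`` percent of the preceding value; if none
    qualifies the smallest size is returned flagged as not converged.
    """
    changes = tuple(100.0 * abs(b - a) / abs(a) for a, b in zip(means, means[1:]))
    for i, ch in enumerate(changes):
        if ch < criterion_pct:
            return changes, sizes[i + 1], True
    return changes, sizes[-1], False


@dataclass(frozen=True)
class ConvergenceReport:
    """Mesh-refinement ladder with the monitored mean equivalent stress."""

    element_sizes: tuple[float, ...]
    mean_vm: tuple[float, ...]  # MPa, monitored quantity per size
    rel_change_pct: tuple[float, ...]  # |delta| vs preceding size, percent
    selected_size: float
    converged: bool


def mesh_convergence(
    stack: TissueStack,
    mat: OgdenMaterial,
    sizes: tuple[float, ...] = PAPER_MESH_SIZES,
    criterion_pct: float = 3.0,
    gap_target: float = 1.0,
    footprints: tuple[ContactFootprint, ContactFootprint] | None = None,
    options: SolverOptions | None = None,
) -> ConvergenceReport:
    """Refine the mesh until the monitored stress stabilises.

    The monitored quantity is the volume-weighted mean von Mises stress of
    the whole tissue with the anvil advanced until the platen gap equals
    ``gap_target`` (default 1 mm).  The selected size is the first whose
    change from the preceding size is below ``criterion_pct``; if no size
    qualifies the smallest is returned with ``converged=False``.
    """
    if len(sizes) < 2:
        raise ValueError("need at least two element sizes")
    if not all(a > b for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"element sizes must be strictly decreasing, got {sizes}")
    if gap_target < 0:
        raise ValueError("gap target must be non-negative")
    d_total = stack.total_thickness - gap_target
    if d_total <= 0:
        raise ValueError("gap target exceeds the undeformed thickness")
    program = LoadProgram(total_travel=d_total)
    fps = footprints or default_footprints(stack)
    means: list[float] = []
    for h in sizes:
        mesh = build_mesh(stack, h)
        results = run_fem(mat, stack, fps, program, mesh, options or SolverOptions())
        final = results[-1]
        means.append(float(np.average(final.von_mises, weights=final.current_volume)))
        logger.info("convergence size %.2f mm: mean vM %.4f MPa", h, means[-1])
    changes, selected, converged = select_converged_size(
        tuple(sizes), tuple(means), criterion_pct
    )
    return ConvergenceReport(
        element_sizes=tuple(sizes),
        mean_vm=tuple(means),
        rel_change_pct=changes,
        selected_size=selected,
        converged=converged,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Ratio-wise comparison of model force against a reference curve."""

    ratios: np.ndarray
    model_forces: np.ndarray  # N
    reference_forces: np.ndarray  # N
    quotients: np.ndarray  # model / reference
    within_order_of_magnitude: bool  # all quotients in [0.1, 10]
    close_below_60pct: bool  # quotients in [0.5, 2] for ratios < 0.60


def validation_curve(
    mat: OgdenMaterial,
    reference_ratios: np.ndarray,
    reference_forces: np.ndarray,
    stack: TissueStack | None = None,
    engine: str = "uniform",
    element_size: float = 0.8,
) -> ValidationReport:
    """Evaluate the model force at each reference compression ratio.

    The default stack is the symmetric 2.0-2.0 mm validation geometry.
    Model forces at the reference ratios are interpolated from the engine's
    step curve.  Flags report the order-of-magnitude contract ([0.1, 10])
    and the tighter low-compression closeness ([0.5, 2] below 60%).
    """
    stack = stack or TissueStack(t_upper=2.0, t_lower=2.0)
    ratios = np.asarray(reference_ratios, dtype=float)
    ref = np.asarray(reference_forces, dtype=float)
    if ratios.size == 0 or ratios.min() <= 0 or ratios.max() > 0.75 + 1e-9:
        raise ValueError("reference ratios must lie in (0, 0.75]")
    total_travel = float(ratios.max()) * stack.total_thickness
    program = LoadProgram(total_travel=total_travel, step_size=total_travel / 60.0)
    if engine == "uniform":
        results = run_uniform(mat, stack, program)
    elif engine == "fem":
        mesh = build_mesh(stack, element_size)
        results = run_fem(mat, stack, default_footprints(stack), program, mesh)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    curve_r = np.array([s.ratio for s in results])
    curve_f = np.array([s.reaction_force for s in results])
    model = np.interp(ratios, curve_r, curve_f)
    quot = model / ref
    return ValidationReport(
        ratios=ratios,
        model_forces=model,
        reference_forces=ref,
        quotients=quot,
        within_order_of_magnitude=bool(np.all((quot >= 0.1) & (quot <= 10.0))),
        close_below_60pct=bool(
            np.all((quot[ratios < 0.60] >= 0.5) & (quot[ratios < 0.60] <= 2.0))
        ),
    )


# ---------------------------------------------------------------------------
# Tabular exports (CSV-ready frames)
# ---------------------------------------------------------------------------

def layer_stats_frame(results: list[StepResult], total: float) -> pd.DataFrame:
    """Per-step, per-layer max/mean von Mises and reaction force."""
    rows = []
    for s in results:
        row: dict[str, float] = {
            "step": s.index,
            "d_mm": s.d,
            "ratio": s.ratio,
            "force_N": s.reaction_force,
            "newton_iters": s.newton_iters,
        }
        for layer, st in s.layer_stats.items():
            row[f"max_vm_{layer}_MPa"] = st.max_vm
            row[f"mean_vm_{layer}_MPa"] = st.mean_vm
        rows.append(row)
    return pd.DataFrame(rows)


def band_fraction_frame(fractions: list[BandFractions]) -> pd.DataFrame:
    """Per-step stress-band fractions per layer (figure-shaped table)."""
    rows = []
    for bf in fractions:
        row = {"d_mm": bf.d, "ratio": bf.ratio}
        for layer, b in bf.layers.items():
            row[f"f_fix_{layer}"] = b.f_fix
            row[f"f_dmg_{layer}"] = b.f_dmg
            row[f"v_total_{layer}_mm3"] = b.v_total
        rows.append(row)
    return pd.DataFrame(rows)


def safety_table_frame(tables: dict[tuple[float, float], SafetyTable]) -> pd.DataFrame:
    """Long-format safe distance/ratio/gap summary across thickness pairs."""
    rows = []
    for (t_u, t_l), tab in tables.items():
        for layer in ("upper", "lower"):
            rows.append(
                {
                    "pair": f"{t_u:.1f}-{t_l:.1f}",
                    "layer": layer,
                    "safe_distances_mm": ", ".join(
                        f"{d:.1f}" for d in tab.safe_distances[layer]
                    ),
                    "safe_ratios": ", ".join(f"{r:.2f}" for r in tab.safe_ratios[layer]),
                    "joint_safe_gaps_mm": ", ".join(
                        f"{g:.1f}" for g in tab.joint_safe_gaps
                    ),
                }
            )
    return pd.DataFrame(rows)
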