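"""Volumetric stress-band statistics and the safe-compression tabulation.

The safety criterion works on the distribution of element volume over von
Mises stress bands, per tissue layer:

* *fixed-tissue volume* ``V_total``: element volume with equivalent stress
  strictly above ``tau_low`` (default 0.1 MPa);
* *effective-fixation volume* ``V_fix``: equivalent stress inside the
  fixation band (default 0.3-0.6 MPa, both ends inclusive);
* *damage volume* ``V_dmg``: equivalent stress strictly above ``tau_dmg``
  (default 0.6 MPa).

A layer at a given compression step is *safe* when the fixation fraction
``V_fix / V_total`` strictly exceeds ``f_fix_min`` (20%) and the damage
fraction ``V_dmg / V_total`` does not exceed ``f_dmg_max`` (5%).  The three
bands (low, fixation, damage) partition the fixed-tissue volume exactly.

The band boundaries are interpreted so the three defining phrases are
mutually exclusive and exhaustive: a stress of exactly 0.3 MPa counts as
fixation, exactly 0.6 MPa counts as fixation (not damage), and damage
starts strictly above 0.6 MPa.

``safety_table`` scans a solved load program and reports, per layer, the
set of safe compression distances (multiples of the step size), the
corresponding two-decimal compression ratios, and the *joint* safe staple
gaps ``t_u + t_l - d`` over the intersection of the two layers' safe sets.
Ratios are computed in exact decimal arithmetic with half-up rounding:
2.3 mm / 4.0 mm must print as 0.58, which naive binary floating point
(0.57499...) would miss.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .geometry_mesh import TissueStack
from .solver import StepResult

__all__ = [
    "Thresholds",
    "LayerBands",
    "BandFractions",
    "SafetyTable",
    "band_fractions",
    "classify",
    "compression_ratio",
    "safety_table",
    "SAFE",
    "NOT_FIXED",
    "DAMAGED",
    "DAMAGED_AND_NOT_FIXED",
]

SAFE = "safe"
NOT_FIXED = "not_fixed"
DAMAGED = "damaged"
DAMAGED_AND_NOT_FIXED = "damaged_and_not_fixed"


@dataclass(frozen=True)
class Thresholds:
    """Stress thresholds (MPa) and volume-fraction decision constants."""

    tau_low: float = 0.1
    fix_band: tuple[float, float] = (0.3, 0.6)
    tau_dmg: float = 0.6
    f_fix_min: float = 0.20
    f_dmg_max: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.fix_band
        if not (0.0 < self.tau_low < lo < hi):
            raise ValueError(
                f"need 0 < tau_low < fix_band[0] < fix_band[1], got "
                f"{self.tau_low}, {self.fix_band}"
            )
        if hi != self.tau_dmg:
            raise ValueError(
                f"fix_band upper bound ({hi}) must equal tau_dmg ({self.tau_dmg})"
            )
        if not (0.0 < self.f_dmg_max < self.f_fix_min < 1.0):
            raise ValueError(
                f"need 0 < f_dmg_max < f_fix_min < 1, got "
                f"{self.f_dmg_max}, {self.f_fix_min}"
            )


@dataclass(frozen=True)
class LayerBands:
    """Band volumes (mm^3) and fractions for one layer at one step.

    ``no_fixation`` flags the V_total = 0 case where fractions are
    undefined (returned as 0.0 but must not be read as a real fraction).
    """

    v_total: float
    v_fix: float
    v_dmg: float

    @property
    def no_fixation(self) -> bool:
        return self.v_total <= 0.0

    @property
    def f_fix(self) -> float:
        return 0.0 if self.no_fixation else self.v_fix / self.v_total

    @property
    def f_dmg(self) -> float:
        return 0.0 if self.no_fixation else self.v_dmg / self.v_total

    @property
    def f_low(self) -> float:
        """Fraction in the sub-fixation band (tau_low, fix_band[0])."""
        if self.no_fixation:
            return 0.0
        return (self.v_total - self.v_fix - self.v_dmg) / self.v_total


@dataclass(frozen=True)
class BandFractions:
    """Per-layer and whole-tissue band volumes for one load step."""

    d: float
    ratio: float
    layers: dict[str, LayerBands]
    tissue: LayerBands


def band_fractions(step: StepResult, thr: Thresholds) -> BandFractions:
    """Sum element volumes into stress bands by centroid von Mises.

    Uses the current (deformed) element volumes — Cauchy stress pairs with
    deformed volume; pass ``step.ref_volume`` based results through a
    custom ``StepResult`` if reference volumes are wanted instead.
    """
    vm = step.von_mises
    vol = step.current_volume
    lo, hi = thr.fix_band

    def bands(mask) -> LayerBands:
        v = vol[mask]
        s = vm[mask]
        total = float(v[s > thr.tau_low].sum())
        fix = float(v[(s >= lo) & (s <= hi)].sum())
        dmg = float(v[s > thr.tau_dmg].sum())
        return LayerBands(v_total=total, v_fix=fix, v_dmg=dmg)

    layers = {
        layer: bands(step.layer_tag == layer)
        for layer in ("upper", "lower")
        if (step.layer_tag == layer).any()
    }
    tissue = bands(slice(None))
    return BandFractions(d=step.d, ratio=step.ratio, layers=layers, tissue=tissue)


def classify(bands: LayerBands, thr: Thresholds) -> str:
    """Classify one layer's band fractions.

    Fixation requires the fixation fraction to *strictly* exceed
    ``f_fix_min``; damage occurs when the damage fraction *strictly*
    exceeds ``f_dmg_max``.  With no fixed-tissue volume at all the layer is
    ``not_fixed``.
    """
    if bands.no_fixation:
        return NOT_FIXED
    fixed = bands.f_fix > thr.f_fix_min
    damaged = bands.f_dmg > thr.f_dmg_max
    if fixed and not damaged:
        return SAFE
    if fixed and damaged:
        return DAMAGED
    if damaged:
        return DAMAGED_AND_NOT_FIXED
    return NOT_FIXED


def compression_ratio(d: float, total: float) -> float:
    """Two-decimal compression ratio d/total with half-up decimal rounding.

    Distances live on a 0.1 mm grid, so the quotient is formed from exact
    tenths-of-a-millimetre integers before rounding.
    """
    if total <= 0.0:
        raise ValueError(f"total thickness must be positive, got {total}")
    if not (0.0 <= d <= total + 1e-9):
        raise ValueError(f"distance {d} outside [0, {total}]")
    d10 = Decimal(round(d * 10)) if abs(d * 10 - round(d * 10)) < 1e-6 else Decimal(repr(d)) * 10
    t10 = Decimal(round(total * 10)) if abs(total * 10 - round(total * 10)) < 1e-6 else Decimal(repr(total)) * 10
    ratio = (d10 / t10).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(ratio)


@dataclass(frozen=True)
class SafetyTable:
    """Safe compression distances, ratios and joint staple gaps for a pair.

    Distances are multiples of the load-program step size; gaps are
    ``total - d`` over the *intersection* of the layers' safe distance
    sets, ordered by increasing distance (so decreasing gap).
    """

    t_upper: float
    t_lower: float
    safe_distances: dict[str, tuple[float, ...]]
    safe_ratios: dict[str, tuple[float, ...]]
    joint_safe_gaps: tuple[float, ...]

    @property
    def total_thickness(self) -> float:
        return self.t_upper + self.t_lower


def _to_tenths(d: float) -> int:
    return round(d * 10)


def safety_table(
    results_or_safe: list[StepResult] | dict[str, list[float]],
    thr: Thresholds,
    stack: TissueStack,
) -> SafetyTable:
    """Tabulate safe distances/ratios per layer and joint safe gaps.

    Accepts either a solved load program (list of :class:`StepResult`,
    classified per layer with :func:`band_fractions`/:func:`classify`) or a
    pre-computed mapping ``{"upper": [d...], "lower": [d...]}`` of safe
    distances (used to regression-test the table logic in isolation).
    """
    total = stack.total_thickness
    if isinstance(results_or_safe, dict):
        safe: dict[str, list[float]] = {
            layer: sorted(results_or_safe.get(layer, []))
            for layer in ("upper", "lower")
        }
    else:
        safe = {"upper": [], "lower": []}
        for step in results_or_safe:
            if step.d <= 0.0:
                continue
            bf = band_fractions(step, thr)
            for layer, bands in bf.layers.items():
                if classify(bands, thr) == SAFE:
                    safe[layer].append(step.d)

    ratios = {
        layer: tuple(compression_ratio(d, total) for d in ds)
        for layer, ds in safe.items()
    }
    upper10 = {_to_tenths(d) for d in safe["upper"]}
    lower10 = {_to_tenths(d) for d in safe["lower"]}
    joint = sorted(upper10 & lower10)
    gaps = tuple(round((_to_tenths(total) - d10) / 10.0, 10) for d10 in joint)
    return SafetyTable(
        t_upper=stack.t_upper,
        t_lower=stack.t_lower,
        safe_distances={k: tuple(v) for k, v in safe.items()},
        safe_ratios=ratios,
        joint_safe_gaps=gaps,
    )
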