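"""Annular two-layer tissue geometry, contact footprints, and meshing.

The tissue clamped in a circular stapler is idealised as two stacked annular
disks (upper layer against the anvil, lower layer against the staple
cartridge) sharing the same inner/outer radii.  The device's contact
surfaces are reduced to axisymmetric *footprints*: sets of annular bands,
each with an ``area_fraction`` in (0, 1] standing in for staple holes and
the cutting-washer clearance.  The physically load-bearing fact preserved by
this surrogate is that the cartridge presents a smaller effective contact
area than the anvil, which is what concentrates stress in the lower layer.

Coordinates: ``z`` is the compression axis, ``r`` the radial direction.
``z = 0`` is the cartridge-side (bottom) face; the layer interface sits at
``z = t_lower`` and the anvil-side face at ``z = t_lower + t_upper``.

Meshing is a structured grid of 4-node quadrilaterals (axisymmetric ring
elements); the reference volume of an element is ``2*pi*r_centroid*area``,
which sums exactly to the analytic annulus volume for rectangular cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueStack",
    "ContactFootprint",
    "AxisymMesh",
    "build_mesh",
    "default_footprints",
    "effective_area",
    "DEFAULT_R_INNER",
    "DEFAULT_R_OUTER",
]

# Default annulus radii consistent with a 34 mm-class circular stapler
# (configurable; the true device contact radii are proprietary).
DEFAULT_R_INNER = 10.0
DEFAULT_R_OUTER = 16.0


@dataclass(frozen=True)
class TissueStack:
    """Two-layer annular tissue stack (all lengths in mm)."""

    t_upper: float
    t_lower: float
    r_inner: float = DEFAULT_R_INNER
    r_outer: float = DEFAULT_R_OUTER

    def __post_init__(self) -> None:
        if not (0.0 < self.r_inner < self.r_outer):
            raise ValueError(
                f"need 0 < r_inner < r_outer, got {self.r_inner}, {self.r_outer}"
            )
        if not (self.t_upper > 0.0 and self.t_lower > 0.0):
            raise ValueError("layer thicknesses must be positive")

    @property
    def total_thickness(self) -> float:
        return self.t_upper + self.t_lower

    @property
    def annulus_volume(self) -> float:
        """Undeformed tissue volume in mm^3."""
        return np.pi * (self.r_outer**2 - self.r_inner**2) * self.total_thickness


@dataclass(frozen=True)
class ContactFootprint:
    """Axisymmetric contact surface of one platen side.

    ``bands`` is a list of ``(r_in, r_out, area_fraction)`` annuli; the
    fraction discounts the geometric annulus area for staple holes and
    machining clearances.
    """

    side: str  # "anvil" | "cartridge"
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.side not in ("anvil", "cartridge"):
            raise ValueError(f"side must be 'anvil' or 'cartridge', got {self.side!r}")
        prev_out = -np.inf
        for r_in, r_out, frac in sorted(self.bands):
            if not (0.0 <= r_in < r_out):
                raise ValueError(f"band ({r_in}, {r_out}) has r_in >= r_out")
            if r_in < prev_out:
                raise ValueError("footprint bands overlap")
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"area_fraction must be in (0, 1], got {frac}")
            prev_out = r_out

    def validate_within(self, stack: TissueStack, tol: float = 1e-9) -> None:
        for r_in, r_out, _ in self.bands:
            if r_in < stack.r_inner - tol or r_out > stack.r_outer + tol:
                raise ValueError(
                    f"{self.side} band ({r_in}, {r_out}) lies outside the tissue "
                    f"annulus [{stack.r_inner}, {stack.r_outer}]"
                )


def effective_area(fp: ContactFootprint) -> float:
    """Effective contact area in mm^2: sum of pi*(r_out^2 - r_in^2)*fraction."""
    return float(
        sum(np.pi * (r_out**2 - r_in**2) * frac for r_in, r_out, frac in fp.bands)
    )


def default_footprints(stack: TissueStack) -> tuple[ContactFootprint, ContactFootprint]:
    """Default anvil/cartridge footprints for the tissue annulus.

    The tissue annulus extends beyond the device's contact lands on both
    rims — essential, because with the outer tissue surface held radially
    the nearly incompressible material squeezed under the lands must be
    able to extrude into free rim tissue.  Each face carries three narrow
    annular lands; the cartridge lands are narrower and perforated
    (``area_fraction = 0.8``, staple holes), giving an effective area of
    about 60% of the anvil's.  Positions scale linearly with the annulus
    extent so custom radii keep the same layout.
    """
    ri, ro = stack.r_inner, stack.r_outer
    w = ro - ri

    def at(f: float) -> float:
        return ri + f * w

    # Narrow lands with relief gaps on both faces: the gaps stand in for
    # the staple holes, forming pockets and cutting clearance through which
    # nearly incompressible tissue extrudes.  Keeping every land narrow
    # bounds the no-slip squeeze pressure; the cartridge lands are narrower
    # and perforated (fraction 0.8), so its effective area is ~60% of the
    # anvil's and the lower layer sees the harsher contact.
    anvil = ContactFootprint(
        "anvil",
        (
            (at(0.7 / 6.0), at(1.9 / 6.0), 1.0),
            (at(2.9 / 6.0), at(4.1 / 6.0), 1.0),
            (at(5.1 / 6.0), at(5.9 / 6.0), 1.0),
        ),
    )
    cartridge = ContactFootprint(
        "cartridge",
        (
            (at(0.9 / 6.0), at(1.8 / 6.0), 0.8),
            (at(3.1 / 6.0), at(3.9 / 6.0), 0.8),
            (at(5.2 / 6.0), at(5.8 / 6.0), 0.8),
        ),
    )
    anvil.validate_within(stack)
    cartridge.validate_within(stack)
    return anvil, cartridge


@dataclass
class AxisymMesh:
    """Structured axisymmetric quad mesh of the two-layer stack.

    nodes: (N, 2) array of (r, z) coordinates in mm.
    elements: (E, 4) int array, counter-clockwise node ids per quad.
    layer_tag: (E,) array of "upper"/"lower".
    ref_volume: (E,) reference ring volume per element, mm^3.
    """

    nodes: np.ndarray
    elements: np.ndarray
    layer_tag: np.ndarray
    ref_volume: np.ndarray
    stack: TissueStack
    element_size: float
    n_radial: int = field(default=0)
    n_axial: int = field(default=0)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def top_nodes(self) -> np.ndarray:
        """Node ids on the anvil-side face z = t_lower + t_upper."""
        z_top = self.stack.total_thickness
        return np.flatnonzero(np.isclose(self.nodes[:, 1], z_top))

    def bottom_nodes(self) -> np.ndarray:
        """Node ids on the cartridge-side face z = 0."""
        return np.flatnonzero(np.isclose(self.nodes[:, 1], 0.0))

    def outer_nodes(self) -> np.ndarray:
        """Node ids on the outer lateral surface r = r_outer."""
        return np.flatnonzero(np.isclose(self.nodes[:, 0], self.stack.r_outer))


def build_mesh(stack: TissueStack, element_size: float) -> AxisymMesh:
    """Structured quad mesh with at least two element rows per layer.

    The layer interface is a shared node row (the bonded tissue-tissue
    contact), so no tying is needed there.  Raises if ``element_size``
    exceeds the thinner layer — such a mesh could not resolve the layer.
    """
    tmin = min(stack.t_upper, stack.t_lower)
    if element_size > tmin + 1e-12:
        raise ValueError(
            f"element_size={element_size} mm exceeds the thinnest layer "
            f"({tmin} mm); refine the mesh to at most {tmin} mm"
        )
    n_r = max(2, int(np.ceil((stack.r_outer - stack.r_inner) / element_size)))
    n_zl = max(2, int(np.ceil(stack.t_lower / element_size)))
    n_zu = max(2, int(np.ceil(stack.t_upper / element_size)))

    r = np.linspace(stack.r_inner, stack.r_outer, n_r + 1)
    z_lower = np.linspace(0.0, stack.t_lower, n_zl + 1)
    z_upper = np.linspace(stack.t_lower, stack.total_thickness, n_zu + 1)
    z = np.concatenate([z_lower, z_upper[1:]])
    n_z = n_zl + n_zu

    rr, zz = np.meshgrid(r, z, indexing="ij")
    nodes = np.column_stack([rr.ravel(), zz.ravel()])

    def nid(i: int, j: int) -> int:
        return i * (n_z + 1) + j

    elems = []
    tags = []
    for i in range(n_r):
        for j in range(n_z):
            elems.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
            tags.append("lower" if j < n_zl else "upper")
    elements = np.asarray(elems, dtype=np.int64)
    layer_tag = np.asarray(tags)

    # ring volume 2*pi*r_bar*A is exact for rectangles with midpoint r_bar
    quad = nodes[elements]  # (E, 4, 2)
    r_bar = quad[:, :, 0].mean(axis=1)
    dr = quad[:, 1, 0] - quad[:, 0, 0]
    dz = quad[:, 3, 1] - quad[:, 0, 1]
    ref_volume = 2.0 * np.pi * r_bar * dr * dz

    mesh = AxisymMesh(
        nodes=nodes,
        elements=elements,
        layer_tag=layer_tag,
        ref_volume=ref_volume,
        stack=stack,
        element_size=element_size,
        n_radial=n_r,
        n_axial=n_z,
    )
    total = float(ref_volume.sum())
    if abs(total - stack.annulus_volume) > 0.005 * stack.annulus_volume:
        raise AssertionError(
            f"mesh volume {total:.4f} deviates from analytic "
            f"{stack.annulus_volume:.4f} by more than 0.5%"
        )
    return mesh
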