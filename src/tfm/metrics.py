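"""Per-cell scalar readouts from masked displacement and traction fields.

The standard single-cell outputs of a traction force microscopy
experiment are the projected cell area, the summed substrate
deformation, the strain energy

    U = 1/2 * integral( d . f ) dA,

the force epicenter (the point the traction field is maximally directed
toward, defined here as the torque-balance point), and the contractility
(the sum of the projections of all traction forces toward the
epicenter).  Area-normalized variants allow comparison across cells of
different sizes.

Internally everything is computed in SI units; the reporting layer
converts to um^2, pJ, nN, J/m^2 and N/m^2 as conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .displacement import DisplacementField
from .traction import TractionField


class DegenerateEpicenterError(RuntimeError):
    """All in-mask forces are parallel: the torque objective has no unique minimum."""

    def __init__(self, fallback: tuple[float, float]):
        super().__init__(
            "all traction vectors are parallel; epicenter undefined "
            f"(|f|-weighted centroid fallback: {fallback})"
        )
        self.fallback = fallback


@dataclass(frozen=True)
class CellMask:
    """Image-resolution masks attributing tractions to one cell.

    ``cell_boundary`` marks the cell outline interior (area readout);
    ``traction_area`` marks the usually larger region whose tractions and
    deformations are attributed to the cell.  Both are boolean rasters at
    image resolution.
    """

    cell_boundary: np.ndarray
    traction_area: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        cb = np.asarray(self.cell_boundary, dtype=bool)
        ta = np.asarray(self.traction_area, dtype=bool)
        if cb.shape != ta.shape:
            raise ValueError("cell_boundary and traction_area must share a shape")
        if not cb.any() or not ta.any():
            raise ValueError("masks must be non-empty")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "cell_boundary", cb)
        object.__setattr__(self, "traction_area", ta)

    @classmethod
    def from_labels(
        cls,
        labels: np.ndarray,
        label: int,
        pixel_size: float,
        traction_margin: float = 15.0,
    ) -> "CellMask":
        """Build a mask from a labeled raster (one integer per cell).

        ``traction_margin`` (um) dilates the cell footprint to form the
        traction-attribution area, so that stresses smeared outward by
        the finite PIV window are still credited to the cell.
        """
        cell = np.asarray(labels) == label
        if not cell.any():
            raise ValueError(f"label {label} not present in mask")
        dist = ndimage.distance_transform_edt(~cell, sampling=pixel_size)
        area = dist <= traction_margin
        return cls(cell_boundary=cell, traction_area=area, pixel_size=pixel_size)


@dataclass(frozen=True)
class TractionMetrics:
    """Scalar per-cell outputs, in conventionally reported units."""

    cell_area: float  # um^2
    deformation_sum: float  # um
    strain_energy: float  # pJ
    strain_energy_normalized: float  # J/m^2
    contractility: float  # nN
    contractility_normalized: float  # N/m^2
    epicenter: tuple[float, float]  # um
    epicenter_degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "cell area (um^2)": self.cell_area,
            "sum of deformations (um)": self.deformation_sum,
            "strain energy (pJ)": self.strain_energy,
            "strain energy normalized (J/m^2)": self.strain_energy_normalized,
            "contractility (nN)": self.contractility,
            "contractility normalized (N/m^2)": self.contractility_normalized,
            "epicenter x (um)": self.epicenter[0],
            "epicenter y (um)": self.epicenter[1],
        }


def _grid_membership(mask_raster: np.ndarray, x: np.ndarray, y: np.ndarray, pixel_size: float) -> np.ndarray:
    """Rasterize an image-resolution mask onto grid nodes.

    A node belongs to the mask when the pixel containing the node center
    does; nodes falling outside the image raster are outside the mask.
    """
    rows = np.round(np.asarray(y) / pixel_size).astype(int)
    cols = np.round(np.asarray(x) / pixel_size).astype(int)
    inside = (
        (rows >= 0)
        & (rows < mask_raster.shape[0])
        & (cols >= 0)
        & (cols < mask_raster.shape[1])
    )
    member = np.zeros(np.shape(x), dtype=bool)
    member[inside] = mask_raster[rows[inside], cols[inside]]
    return member


def cell_area(mask: CellMask) -> float:
    """Projected cell area in um^2 (interior pixel count x pixel area)."""
    n = int(np.count_nonzero(mask.cell_boundary))
    if n == 0:
        raise ValueError("empty cell mask")
    return n * mask.pixel_size**2


def deformation_sum(displacement: DisplacementField, mask: CellMask) -> float:
    """Sum of deformation magnitudes (um) over grid nodes inside the traction area."""
    member = _grid_membership(mask.traction_area, displacement.x, displacement.y, mask.pixel_size)
    if not member.any():
        raise ValueError("traction area does not overlap the displacement grid")
    return float(np.hypot(displacement.u, displacement.v)[member].sum())


def strain_energy(displacement: DisplacementField, traction: TractionField, mask: CellMask) -> float:
    """Strain energy U = 1/2 sum (d . f) dA over the traction area, in pJ."""
    if displacement.u.shape != traction.tx.shape:
        raise ValueError("displacement and traction grids differ in shape")
    member = _grid_membership(mask.traction_area, traction.x, traction.y, mask.pixel_size)
    if not member.any():
        raise ValueError("traction area does not overlap the grid")
    da = (traction.grid_spacing * 1e-6) ** 2  # m^2
    dot = (
        displacement.u[member] * 1e-6 * traction.tx[member]
        + displacement.v[member] * 1e-6 * traction.ty[member]
    )
    return float(0.5 * dot.sum() * da * 1e12)  # J -> pJ


def force_epicenter(traction: TractionField, mask: CellMask) -> tuple[tuple[float, float], bool]:
    """Torque-balance point of the in-mask traction field, in um.

    Minimizes ``sum_i [(x_i - xc) f_yi - (y_i - yc) f_xi]^2`` (each node's
    force treated as a point force; the summand is its torque about the
    candidate point) via the 2x2 normal equations.  For a radially
    symmetric inward field this is the symmetry center.

    Returns ``((x, y), degenerate)``.  When all forces are parallel the
    normal matrix is singular; the |f|-weighted centroid is returned with
    ``degenerate=True``.
    """
    member = _grid_membership(mask.traction_area, traction.x, traction.y, mask.pixel_size)
    fx = traction.tx[member]
    fy = traction.ty[member]
    px = traction.x[member]
    py = traction.y[member]
    if fx.size < 2 or not np.any(np.hypot(fx, fy) > 0):
        raise ValueError("need at least two nonzero in-mask force vectors")

    # normal equations of the torque objective
    sxx = np.sum(fy * fy)
    syy = np.sum(fx * fx)
    sxy = np.sum(fx * fy)
    m = np.array([[sxx, -sxy], [-sxy, syy]])
    rhs_val = px * fy - py * fx
    rhs = np.array([np.sum(rhs_val * fy), -np.sum(rhs_val * fx)])
    # parallel forces make the normal matrix rank-deficient: the epicenter
    # coordinate along the common force axis is then pure noise
    eigs = np.linalg.eigvalsh(m)
    if eigs[0] <= 1e-9 * eigs[1]:
        w = np.hypot(fx, fy)
        fallback = (float(np.sum(px * w) / np.sum(w)), float(np.sum(py * w) / np.sum(w)))
        return fallback, True
    xc, yc = np.linalg.solve(m, rhs)
    return (float(xc), float(yc)), False


def contractility(
    traction: TractionField,
    mask: CellMask,
    epicenter: tuple[float, float] | None = None,
) -> float:
    """Sum of traction-force projections toward the epicenter, in nN.

    Each node contributes ``f_i . e_i`` where ``f_i`` is the node force
    (traction times cell area of one grid node) and ``e_i`` the unit
    vector from the node toward the epicenter; a node exactly at the
    epicenter contributes zero.  Coordinated inward contraction gives a
    large positive value; a purely circulating field gives zero.
    """
    member = _grid_membership(mask.traction_area, traction.x, traction.y, mask.pixel_size)
    if not member.any():
        raise ValueError("traction area does not overlap the grid")
    if epicenter is None:
        epicenter, _ = force_epicenter(traction, mask)
    da = (traction.grid_spacing * 1e-6) ** 2  # m^2
    fx = traction.tx[member] * da  # N
    fy = traction.ty[member] * da
    dx = epicenter[0] - traction.x[member]
    dy = epicenter[1] - traction.y[member]
    r = np.hypot(dx, dy)
    nz = r > 0
    proj = np.zeros_like(r)
    proj[nz] = (fx[nz] * dx[nz] + fy[nz] * dy[nz]) / r[nz]
    return float(proj.sum() * 1e9)  # N -> nN


def summarize(
    displacement: DisplacementField,
    traction: TractionField,
    mask: CellMask,
) -> TractionMetrics:
    """Assemble all per-cell metrics from consistent fields and masks."""
    area = cell_area(mask)  # um^2
    dsum = deformation_sum(displacement, mask)
    u_pj = strain_energy(displacement, traction, mask)
    epi, degenerate = force_epicenter(traction, mask)
    c_nn = contractility(traction, mask, epicenter=epi)
    area_m2 = area * 1e-12
    return TractionMetrics(
        cell_area=area,
        deformation_sum=dsum,
        strain_energy=u_pj,
        strain_energy_normalized=u_pj * 1e-12 / area_m2,  # pJ -> J, / m^2
        contractility=c_nn,
        contractility_normalized=c_nn * 1e-9 / area_m2,  # nN -> N, / m^2
        epicenter=epi,
        epicenter_degenerate=degenerate,
    )
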