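"""Fourier-transform traction cytometry (FTTC).

A cell adhering to a linearly elastic substrate exerts an in-plane
traction stress field f(x) on the surface.  For a substrate much thicker
than the cell footprint the surface response is that of an elastic
half-space (the Boussinesq solution), which in Fourier space reduces to
a per-mode 2x2 linear map between traction and displacement,

    u(k) = G(k) f(k),
    G(k) = 2 (1 + nu) / (E k^3) *
           [[(1 - nu) k^2 + nu ky^2,  -nu kx ky],
            [-nu kx ky,               (1 - nu) k^2 + nu kx^2]],

with k = |k|, E the Young's modulus and nu the Poisson ratio.  FTTC
inverts this relation mode by mode, optionally with Tikhonov
regularization, which makes the otherwise ill-posed deconvolution a
cheap FFT computation.  The forward map is exposed as well: it is the
natural oracle for validating the inversion and the engine behind the
synthetic scene generator.

Unit policy: wavevectors are rad/m, kernel entries m/Pa; displacements
convert um -> m on entry and tractions are returned in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft

from .displacement import DisplacementField


@dataclass(frozen=True)
class SubstrateProperties:
    """Elastic substrate parameters.

    ``thickness`` is carried for provenance only: the half-space kernel is
    valid when the analysed cell is small compared to the substrate
    thickness, in which case no finite-thickness correction is applied.
    """

    youngs_modulus: float  # Pa
    poisson_ratio: float = 0.5
    thickness: float = 70.0  # um
    pixel_size: float = 0.46  # um

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class TractionField:
    """Traction stress vectors (Pa) on the PIV grid."""

    x: np.ndarray  # um
    y: np.ndarray  # um
    tx: np.ndarray  # Pa
    ty: np.ndarray  # Pa
    grid_spacing: float  # um
    regularization: float = 0.0
    substrate: SubstrateProperties | None = None

    def __post_init__(self) -> None:
        shapes = {np.shape(a) for a in (self.x, self.y, self.tx, self.ty)}
        if len(shapes) != 1:
            raise ValueError("x, y, tx, ty must share one grid shape")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x_um": self.x.ravel(),
                "y_um": self.y.ravel(),
                "tx_pa": self.tx.ravel(),
                "ty_pa": self.ty.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid_spacing: float | None = None, **kwargs) -> "TractionField":
        import pandas as pd

        df = pd.read_csv(path)
        nx = df["x_um"].nunique()
        ny = df["y_um"].nunique()
        shp = (ny, nx)
        x = df["x_um"].to_numpy().reshape(shp)
        if grid_spacing is None:
            grid_spacing = float(x[0, 1] - x[0, 0]) if nx > 1 else 1.0
        return cls(
            x=x,
            y=df["y_um"].to_numpy().reshape(shp),
            tx=df["tx_pa"].to_numpy().reshape(shp),
            ty=df["ty_pa"].to_numpy().reshape(shp),
            grid_spacing=grid_spacing,
            **kwargs,
        )


def boussinesq_kernel(kx, ky, substrate: SubstrateProperties) -> np.ndarray:
    """Half-space surface Green's function in Fourier space.

    Returns G(k) as an array of shape ``(..., 2, 2)`` in m/Pa; for scalar
    wavevector components this is a plain 2x2 symmetric positive-definite
    matrix.  The zero wavevector is outside the domain (the mean
    displacement of a half-space under a net force diverges) and raises.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k = np.hypot(kx, ky)
    if np.any(k == 0):
        raise ValueError("zero wavevector: kernel undefined at k=0")
    e = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    pre = 2.0 * (1.0 + nu) / (e * k**3)
    g = np.empty(k.shape + (2, 2))
    g[..., 0, 0] = pre * ((1.0 - nu) * k**2 + nu * ky**2)
    g[..., 1, 1] = pre * ((1.0 - nu) * k**2 + nu * kx**2)
    g[..., 0, 1] = -pre * nu * kx * ky
    g[..., 1, 0] = g[..., 0, 1]
    return g


def _kernel_components(shape: tuple[int, int], spacing_m: float, substrate: SubstrateProperties):
    """Gxx, Gxy, Gyy over the FFT frequency grid, with G(0) := 0."""
    ky = 2.0 * np.pi * fft.fftfreq(shape[0], d=spacing_m)
    kx = 2.0 * np.pi * fft.fftfreq(shape[1], d=spacing_m)
    kxg, kyg = np.meshgrid(kx, ky)
    k = np.hypot(kxg, kyg)
    k[0, 0] = 1.0  # placeholder; zero mode overwritten below
    e = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    pre = 2.0 * (1.0 + nu) / (e * k**3)
    gxx = pre * ((1.0 - nu) * k**2 + nu * kyg**2)
    gyy = pre * ((1.0 - nu) * k**2 + nu * kxg**2)
    gxy = -pre * nu * kxg * kyg
    gxx[0, 0] = gyy[0, 0] = gxy[0, 0] = 0.0
    return gxx, gxy, gyy


def _padded_shape(shape: tuple[int, int], pad_factor: float) -> tuple[int, int]:
    return tuple(fft.next_fast_len(int(np.ceil(n * pad_factor))) for n in shape)


def forward_displacement(
    traction: TractionField,
    substrate: SubstrateProperties | None = None,
    pad_factor: float = 2.0,
) -> DisplacementField:
    """Surface displacement produced by a traction field (forward model).

    The tractions are zero-padded (default to at least twice the linear
    grid size, to keep the periodic images of the FFT from interacting),
    transformed, multiplied per mode by G(k) and transformed back.  The
    zero-frequency mode is set to zero, i.e. the displacement field is
    reported relative to its spatial mean.
    """
    if substrate is None:
        substrate = traction.substrate
    if substrate is None:
        raise ValueError("substrate properties required")
    tx = np.asarray(traction.tx, dtype=float)
    ty = np.asarray(traction.ty, dtype=float)
    if not (np.isfinite(tx).all() and np.isfinite(ty).all()):
        raise ValueError("traction field contains non-finite values")
    ny, nx = tx.shape
    h = traction.grid_spacing * 1e-6  # m
    pshape = _padded_shape((ny, nx), pad_factor)
    gxx, gxy, gyy = _kernel_components(pshape, h, substrate)
    ftx = fft.fft2(tx, s=pshape)
    fty = fft.fft2(ty, s=pshape)
    fu = gxx * ftx + gxy * fty
    fv = gxy * ftx + gyy * fty
    u = fft.ifft2(fu).real[:ny, :nx] * 1e6  # m -> um
    v = fft.ifft2(fv).real[:ny, :nx] * 1e6
    return DisplacementField(
        x=traction.x,
        y=traction.y,
        u=u,
        v=v,
        valid=np.ones_like(u, dtype=bool),
        window_size=2.0 * traction.grid_spacing,
        overlap=traction.grid_spacing,
        pixel_size=substrate.pixel_size,
    )


def fttc_invert(
    displacement: DisplacementField,
    substrate: SubstrateProperties,
    regularization: float = 0.0,
    pad_factor: float = 2.0,
) -> TractionField:
    """Recover the traction field from a complete displacement grid.

    Per Fourier mode the traction solves

        f(k) = [G(k)^T G(k) + lambda^2 I]^{-1} G(k)^T u(k),

    which for ``regularization`` (lambda) equal to zero is the direct
    inverse ``G^{-1} u``.  lambda carries the units of G (m/Pa); a value
    of zero reproduces the unregularized FTTC scheme, while noisy
    experimental fields benefit from a small positive value.  The k=0
    mode is forced to zero traction, so the recovered field is balanced
    (zero net force) by construction.

    The grid must be complete: run ``validate_and_fill`` first.
    """
    u = np.asarray(displacement.u, dtype=float) * 1e-6  # um -> m
    v = np.asarray(displacement.v, dtype=float) * 1e-6
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("displacement grid has invalid values; run validate_and_fill first")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    ny, nx = u.shape
    hs = displacement.grid_spacing
    h = hs * 1e-6
    pshape = _padded_shape((ny, nx), pad_factor)
    gxx, gxy, gyy = _kernel_components(pshape, h, substrate)
    fu = fft.fft2(u, s=pshape)
    fv = fft.fft2(v, s=pshape)
    lam2 = float(regularization) ** 2
    if lam2 == 0.0:
        det = gxx * gyy - gxy**2
        det[0, 0] = 1.0
        ftx = (gyy * fu - gxy * fv) / det
        fty = (-gxy * fu + gxx * fv) / det
    else:
        # G symmetric: G^T G = G^2
        axx = gxx**2 + gxy**2 + lam2
        ayy = gyy**2 + gxy**2 + lam2
        axy = gxy * (gxx + gyy)
        bx = gxx * fu + gxy * fv
        by = gxy * fu + gyy * fv
        det = axx * ayy - axy**2
        det[0, 0] = 1.0
        ftx = (ayy * bx - axy * by) / det
        fty = (-axy * bx + axx * by) / det
    ftx[0, 0] = 0.0
    fty[0, 0] = 0.0
    tx = fft.ifft2(ftx).real[:ny, :nx]
    ty = fft.ifft2(fty).real[:ny, :nx]
    # zeroing the k=0 mode balances the padded grid; re-balance the crop so
    # the reported field is force-free (the cell exerts no net force)
    tx -= tx.mean()
    ty -= ty.mean()
    return TractionField(
        x=displacement.x,
        y=displacement.y,
        tx=tx,
        ty=ty,
        grid_spacing=hs,
        regularization=regularization,
        substrate=substrate,
    )


def render_traction_map(traction: TractionField, path, cmap: str = "inferno", dpi: int = 150) -> None:
    """Write a color-mapped |t| raster (Pa) with a labeled color scale."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    mag = traction.magnitude
    extent = (
        float(traction.x.min()),
        float(traction.x.max()),
        float(traction.y.max()),
        float(traction.y.min()),
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mag, origin="upper", extent=extent, cmap=cmap)
    fig.colorbar(im, ax=ax, label="traction stress (Pa)")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
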