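"""Substrate deformation fields from bead-image pairs.

The deformation of an elastic substrate is measured by comparing a
fluorescent-bead image taken while the cell is attached (stressed state)
with a reference image taken after the cell has been removed (relaxed
state).  The workflow is the standard one for 2D traction force
microscopy: correct the global stage drift between the two frames, then
run windowed cross-correlation particle image velocimetry (PIV) with
subpixel peak localization, and finally validate and fill outlier
vectors so the grid is complete for the elastic inversion downstream.

Coordinates follow the image convention: the origin is the center of the
top-left pixel, x runs rightward along columns, y runs downward along
rows.  Displacements (u, v) use the same axes and are expressed in
micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import tifffile
from scipy import fft, ndimage


class DriftCorrectionError(RuntimeError):
    """Raised when a rigid shift cannot be estimated (e.g. featureless frame)."""


class ValidationError(RuntimeError):
    """Raised when a displacement field has no valid vectors to work from."""


@dataclass(frozen=True)
class BeadImage:
    """Single-channel grayscale image of fluorescent marker beads.

    Parameters
    ----------
    pixels
        2-D nonnegative intensity raster (any float or integer dtype).
    pixel_size
        Physical size of one pixel in micrometers.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("bead image must be 2-D")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("bead image must be at least 64x64 pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_tiff(cls, path, pixel_size: float) -> "BeadImage":
        """Load a single-channel 8/16-bit grayscale TIFF."""
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[0] == 1:
            arr = arr[0]
        return cls(pixels=np.asarray(arr, dtype=float), pixel_size=pixel_size)


@dataclass
class DisplacementField:
    """Gridded substrate deformation vectors on PIV window centers.

    ``x``/``y`` are 2-D arrays of window-center coordinates (um), ``u``/``v``
    the displacement components (um) on the same grid.  ``valid`` marks
    vectors that came straight from a trustworthy correlation peak;
    vectors replaced during validation keep ``valid=False``.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    window_size: float  # um
    overlap: float  # um
    pixel_size: float  # um
    s2n: np.ndarray | None = None  # peak-to-second-peak ratio per vector

    def __post_init__(self) -> None:
        shapes = {np.shape(a) for a in (self.x, self.y, self.u, self.v, self.valid)}
        if len(shapes) != 1:
            raise ValueError("x, y, u, v, valid must share one grid shape")
        if self.overlap >= self.window_size:
            raise ValueError("overlap must be smaller than window_size")

    @property
    def grid_spacing(self) -> float:
        """Grid step in micrometers (window size minus overlap, px-rounded)."""
        if self.x.shape[1] > 1:
            return float(self.x[0, 1] - self.x[0, 0])
        return self.window_size - self.overlap

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x_um": self.x.ravel(),
                "y_um": self.y.ravel(),
                "u_um": self.u.ravel(),
                "v_um": self.v.ravel(),
                "valid": self.valid.ravel().astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window_size: float, overlap: float, pixel_size: float) -> "DisplacementField":
        import pandas as pd

        df = pd.read_csv(path)
        nx = df["x_um"].nunique()
        ny = df["y_um"].nunique()
        shp = (ny, nx)
        return cls(
            x=df["x_um"].to_numpy().reshape(shp),
            y=df["y_um"].to_numpy().reshape(shp),
            u=df["u_um"].to_numpy().reshape(shp),
            v=df["v_um"].to_numpy().reshape(shp),
            valid=df["valid"].to_numpy().reshape(shp).astype(bool),
            window_size=window_size,
            overlap=overlap,
            pixel_size=pixel_size,
        )


class PeakFit(NamedTuple):
    """Result of subpixel correlation-peak localization (offsets in pixels)."""

    dx: float
    dy: float
    on_border: bool


def subpixel_peak(correlation_map: np.ndarray) -> PeakFit:
    """Locate the correlation peak with subpixel precision.

    The integer peak is refined by a three-point Gaussian fit per axis
    (log-parabola through the peak and its two axis neighbors); when any
    of the three samples is non-positive the fit falls back to a plain
    parabola.  Offsets are reported relative to the map center
    ``(rows // 2, cols // 2)``, i.e. the zero-lag position of an
    ``fftshift``-ed correlation.

    If the integer peak sits on the map border no refinement is possible
    and the integer offset is returned with ``on_border=True``.
    """
    c = np.asarray(correlation_map, dtype=float)
    if c.ndim != 2 or c.shape[0] < 3 or c.shape[1] < 3:
        raise ValueError("correlation map must be 2-D and at least 3x3")
    iy, ix = np.unravel_index(np.nanargmax(c), c.shape)
    cy, cx = c.shape[0] // 2, c.shape[1] // 2
    if iy == 0 or ix == 0 or iy == c.shape[0] - 1 or ix == c.shape[1] - 1:
        return PeakFit(float(ix - cx), float(iy - cy), True)

    def _refine(cm1: float, c0: float, cp1: float) -> float:
        if cm1 > 0 and c0 > 0 and cp1 > 0:
            lm1, l0, lp1 = np.log(cm1), np.log(c0), np.log(cp1)
        else:
            lm1, l0, lp1 = cm1, c0, cp1
        denom = lm1 - 2.0 * l0 + lp1
        if denom >= 0 or not np.isfinite(denom):
            return 0.0  # flat or degenerate: keep the integer peak
        delta = 0.5 * (lm1 - lp1) / denom
        return float(np.clip(delta, -0.999, 0.999))

    sub_x = _refine(c[iy, ix - 1], c[iy, ix], c[iy, ix + 1])
    sub_y = _refine(c[iy - 1, ix], c[iy, ix], c[iy + 1, ix])

    # re-take each axis triplet through the refined apex (quadratic
    # interpolation across the 3x3 block); sampling the transverse triplet
    # at the integer column leaks up to ~0.1 px of cross-axis error when
    # the peak is not separable
    def _interp3(cm1: float, c0: float, cp1: float, t: float) -> float:
        return c0 + 0.5 * t * (cp1 - cm1) + 0.5 * t * t * (cp1 - 2.0 * c0 + cm1)

    block = c[iy - 1 : iy + 2, ix - 1 : ix + 2]
    row = [_interp3(*block[k], sub_x) for k in range(3)]
    col = [_interp3(*block[:, k], sub_y) for k in range(3)]
    sub_y = _refine(*row)
    sub_x = _refine(*col)
    return PeakFit(float(ix - cx + sub_x), float(iy - cy + sub_y), False)


def _xcorr_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mean-subtracted circular cross-correlation of window stacks.

    ``a``, ``b``: shape (m, h, w).  Returns fftshift-ed correlation maps of
    shape (m, P, P) with zero lag at (P//2, P//2), normalized to the
    correlation-coefficient scale.  Windows with no texture get all-NaN maps.
    """
    m, h, w = a.shape
    p = (fft.next_fast_len(2 * max(h, w) - 1),) * 2
    a0 = a - a.mean(axis=(1, 2), keepdims=True)
    b0 = b - b.mean(axis=(1, 2), keepdims=True)
    sa = a0.std(axis=(1, 2))
    sb = b0.std(axis=(1, 2))
    fa = fft.rfft2(a0, s=p)
    fb = fft.rfft2(b0, s=p)
    c = fft.irfft2(np.conj(fa) * fb, s=p)
    c = fft.fftshift(c, axes=(-2, -1))
    # unbiased estimator: divide by the overlap count per lag, not by h*w.
    # The raw sum carries a triangular envelope that pulls the fitted
    # subpixel peak toward zero lag by ~sigma_peak^2/(window - |lag|) px.
    ly = np.abs(np.arange(c.shape[-2]) - c.shape[-2] // 2)
    lx = np.abs(np.arange(c.shape[-1]) - c.shape[-1] // 2)
    oy = np.clip(h - ly, 1, None).astype(float)
    ox = np.clip(w - lx, 1, None).astype(float)
    c /= oy[:, None] * ox[None, :]
    norm = sa * sb
    bad = norm <= 0
    norm[bad] = 1.0
    c /= norm[:, None, None]
    c[bad] = np.nan
    return c


def correct_drift(reference: BeadImage, deformed: BeadImage) -> tuple[tuple[float, float], BeadImage]:
    """Estimate and remove the global rigid drift between two frames.

    The shift ``(dx, dy)`` (pixels, subpixel precision) maximizes the
    full-frame mean-subtracted cross-correlation; the deformed image is
    resampled by ``-shift`` with a Fourier phase ramp so that a second
    pass returns a shift of approximately zero.
    """
    if reference.shape != deformed.shape:
        raise ValueError("images must have the same shape")
    if reference.pixel_size != deformed.pixel_size:
        raise ValueError("images must have the same pixel size")
    ra = reference.pixels
    rb = deformed.pixels
    if ra.std() == 0 or rb.std() == 0:
        raise DriftCorrectionError("featureless image: drift correlation undefined")
    c = _xcorr_batch(ra[None], rb[None])[0]
    # restrict the search to modest drifts; stage drift is a few pixels
    cy, cx = c.shape[0] // 2, c.shape[1] // 2
    r = min(64, cy - 1, cx - 1)
    crop = c[cy - r : cy + r + 1, cx - r : cx + r + 1]
    pk = subpixel_peak(crop)
    dx, dy = pk.dx, pk.dy
    aligned = ndimage.fourier_shift(np.fft.fft2(rb), shift=(-dy, -dx))
    aligned = np.fft.ifft2(aligned).real
    return (dx, dy), BeadImage(pixels=aligned, pixel_size=deformed.pixel_size)


def _zncc_batch(a: np.ndarray, regions: np.ndarray, w: int) -> np.ndarray:
    """Zero-normalized cross-correlation of templates against search regions.

    ``a``: reference windows, shape (m, w, w).  ``regions``: search crops of
    the deformed frame, shape (m, Ws, Ws) with Ws = w + 2*search.  Returns
    correlation-coefficient maps of shape (m, 2*search+1, 2*search+1); lag
    (i, j) correlates the template against the patch starting at (i, j) in
    the region.  Featureless templates yield all-NaN maps.

    Per-lag normalization (by the local mean and variance of each candidate
    patch, computed with integral images) is what makes this the true
    correlation coefficient; a single global normalization leaves residual
    edge-content bias of order several hundredths of a pixel in the fitted
    subpixel peak.
    """
    m, ws, _ = regions.shape
    nlag = ws - w + 1
    a0 = a - a.mean(axis=(1, 2), keepdims=True)
    sa = a0.std(axis=(1, 2))

    p = (fft.next_fast_len(ws + w - 1),) * 2
    fa = fft.rfft2(a0[:, ::-1, ::-1], s=p)  # flip: convolution -> correlation
    fb = fft.rfft2(regions, s=p)
    full = fft.irfft2(fa * fb, s=p)
    num = full[:, w - 1 : w - 1 + nlag, w - 1 : w - 1 + nlag]

    # integral images for local patch sums of B and B^2
    def _patch_sums(x: np.ndarray) -> np.ndarray:
        s = np.zeros((m, ws + 1, ws + 1))
        np.cumsum(x, axis=1, out=s[:, 1:, 1:])
        np.cumsum(s[:, 1:, 1:], axis=2, out=s[:, 1:, 1:])
        return (
            s[:, w:, w:] - s[:, :-w, w:] - s[:, w:, :-w] + s[:, :-w, :-w]
        )

    n = float(w * w)
    sum_b = _patch_sums(regions)
    sum_b2 = _patch_sums(regions**2)
    var_b = np.clip(sum_b2 / n - (sum_b / n) ** 2, 0.0, None)
    denom = n * sa[:, None, None] * np.sqrt(var_b)
    bad_t = sa <= 0
    out = np.full_like(num, np.nan)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    out[bad_t] = np.nan
    return out


def compute_piv(
    reference: BeadImage,
    deformed: BeadImage,
    window_size: float = 20.0,
    overlap: float = 18.0,
    search_radius: int | None = None,
    chunk: int = 256,
) -> DisplacementField:
    """Windowed cross-correlation PIV between a reference and a deformed frame.

    ``window_size`` and ``overlap`` are physical lengths in micrometers and
    are rounded to integer pixel counts (e.g. 20 um at 0.46 um/px -> 43 px
    windows on a 4 px step grid).  Windows that would overlap the image
    border are dropped.  Each reference window is matched against the
    deformed frame by zero-normalized cross-correlation over lags up to
    ``search_radius`` pixels (default: a quarter window); the correlation
    peak is refined by a three-point Gaussian fit and converted to
    micrometers.  The per-vector peak-to-second-peak ratio is stored in
    ``s2n`` for downstream validation.
    """
    if reference.shape != deformed.shape:
        raise ValueError("images must have the same shape")
    ps = reference.pixel_size
    win = int(round(window_size / ps))
    step = int(round((window_size - overlap) / ps))
    if overlap >= window_size:
        raise ValueError("overlap must be smaller than window_size")
    if win < 8:
        raise ValueError("window smaller than 8 px: increase window_size")
    if step < 1:
        raise ValueError("overlap too close to window_size: zero-pixel step")
    H, W = reference.shape
    if win > H or win > W:
        raise ValueError("window larger than image")
    search = int(search_radius) if search_radius is not None else max(4, win // 4)
    ws = win + 2 * search

    # windows (including their search margin) must fit inside the frame;
    # border windows are dropped rather than padded
    rows = np.array([r for r in range(0, H - win + 1, step)
                     if r - search >= 0 and r + win + search <= H])
    cols = np.array([c for c in range(0, W - win + 1, step)
                     if c - search >= 0 and c + win + search <= W])
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("window plus search margin larger than image")
    ny, nx = len(rows), len(cols)

    from numpy.lib.stride_tricks import sliding_window_view

    swa = sliding_window_view(reference.pixels, (win, win))
    swb = sliding_window_view(deformed.pixels, (ws, ws))
    idx = [(r, c) for r in rows for c in cols]

    u = np.zeros(ny * nx)
    v = np.zeros(ny * nx)
    valid = np.ones(ny * nx, dtype=bool)
    s2n = np.full(ny * nx, np.inf)

    for start in range(0, len(idx), chunk):
        block = idx[start : start + chunk]
        a = np.stack([swa[r, c] for r, c in block])
        b = np.stack([swb[r - search, c - search] for r, c in block])
        maps = _zncc_batch(a, b, win)
        for j in range(maps.shape[0]):
            cm = maps[j]
            k = start + j
            if not np.isfinite(cm).any():
                valid[k] = False
                continue
            pk = subpixel_peak(cm)
            if pk.on_border:
                valid[k] = False
            u[k] = pk.dx * ps
            v[k] = pk.dy * ps
            s2n[k] = _peak_ratio(cm)

    xg, yg = np.meshgrid((cols + (win - 1) / 2.0) * ps, (rows + (win - 1) / 2.0) * ps)
    return DisplacementField(
        x=xg,
        y=yg,
        u=u.reshape(ny, nx),
        v=v.reshape(ny, nx),
        valid=valid.reshape(ny, nx),
        window_size=window_size,
        overlap=overlap,
        pixel_size=ps,
        s2n=s2n.reshape(ny, nx),
    )


def _peak_ratio(cm: np.ndarray) -> float:
    """Primary-to-secondary correlation peak ratio (3x3 exclusion zone)."""
    iy, ix = np.unravel_index(np.nanargmax(cm), cm.shape)
    peak = cm[iy, ix]
    masked = cm.copy()
    masked[max(iy - 1, 0) : iy + 2, max(ix - 1, 0) : ix + 2] = -np.inf
    second = np.nanmax(masked)
    if second <= 0:
        return np.inf
    return float(peak / second)


def compensate_window_response(field: DisplacementField, alpha: float = 0.05) -> DisplacementField:
    """Compensate the PIV window's moving-average frequency response.

    Cross-correlation over an interrogation window reports (approximately)
    the top-hat average of the true displacement over the window, which
    attenuates spatial frequencies by W(k) = sinc(kx w / 2) sinc(ky w / 2)
    (w the window side).  Because the traction inversion multiplies by
    E k, this attenuation propagates into a systematic underestimate of
    traction magnitude, contractility and especially strain energy.

    This step applies the Wiener-style inverse gain

        H(k) = W(k) / (W(k)^2 + alpha)

    on the zero-padded FFT of the field: frequencies the window resolves
    (W ~ 1) are restored with gain ~ 1/W, while frequencies near and
    beyond the window cutoff (W -> 0), where the data carry no signal,
    are rolled off instead of amplified.  ``alpha`` bounds the maximum
    gain at 1/(2 sqrt(alpha)); the default 0.05 (max gain ~2.2) restores
    most of the resolvable band without blowing up estimator noise.
    Set ``alpha`` to 0 to disable (identity).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return field
    u, v = field.u, field.v
    ny, nx = u.shape
    h = field.grid_spacing * 1e-6
    # effective window is the integer pixel count actually correlated
    w = round(field.window_size / field.pixel_size) * field.pixel_size * 1e-6
    pshape = tuple(fft.next_fast_len(2 * n) for n in (ny, nx))
    ky = 2.0 * np.pi * fft.fftfreq(pshape[0], d=h)
    kx = 2.0 * np.pi * fft.fftfreq(pshape[1], d=h)
    kxg, kyg = np.meshgrid(kx, ky)
    wk = np.sinc(kxg * w / (2.0 * np.pi)) * np.sinc(kyg * w / (2.0 * np.pi))
    gain = wk / (wk**2 + alpha)
    fu = fft.fft2(u, s=pshape) * gain
    fv = fft.fft2(v, s=pshape) * gain
    return DisplacementField(
        x=field.x,
        y=field.y,
        u=fft.ifft2(fu).real[:ny, :nx],
        v=fft.ifft2(fv).real[:ny, :nx],
        valid=field.valid,
        window_size=field.window_size,
        overlap=field.overlap,
        pixel_size=field.pixel_size,
        s2n=field.s2n,
    )


def validate_and_fill(
    field: DisplacementField,
    s2n_threshold: float = 1.3,
    neighborhood: int = 3,
) -> DisplacementField:
    """Flag untrustworthy PIV vectors and fill them from their neighbors.

    A vector is invalidated when its peak-to-second-peak ratio falls below
    ``s2n_threshold`` or when it deviates from the local median vector by
    more than three times the local median absolute residual (a normalized
    median test over a ``neighborhood x neighborhood`` stencil, with a
    small absolute floor so noise-free uniform fields pass untouched).
    Invalid vectors are replaced by the median of valid neighbors,
    iterating outward until the grid is complete; replaced vectors keep
    ``valid=False`` so downstream consumers can see what was interpolated.
    """
    u = field.u.copy()
    v = field.v.copy()
    valid = field.valid.copy()
    if field.s2n is not None:
        valid &= field.s2n >= s2n_threshold
    finite = np.isfinite(u) & np.isfinite(v)
    valid &= finite
    if not valid.any():
        raise ValidationError("no valid vectors in displacement field")

    k = max(int(neighborhood), 3)
    if k % 2 == 0:
        k += 1
    # normalized local median test (vector residual magnitude)
    med_u = ndimage.median_filter(np.where(finite, u, 0.0), size=k, mode="nearest")
    med_v = ndimage.median_filter(np.where(finite, v, 0.0), size=k, mode="nearest")
    res = np.hypot(u - med_u, v - med_v)
    res_med = ndimage.median_filter(np.where(np.isfinite(res), res, 0.0), size=k, mode="nearest")
    floor = 0.1 * field.pixel_size  # absolute noise floor, um
    outlier = res > 3.0 * res_med + floor
    valid &= ~outlier
    if not valid.any():
        raise ValidationError("all vectors rejected during validation")

    filled = valid.copy()
    u[~filled] = np.nan
    v[~filled] = np.nan
    while not filled.all():
        progress = False
        targets = np.argwhere(~filled)
        new_u = u.copy()
        new_v = v.copy()
        newly = np.zeros_like(filled)
        for iy, ix in targets:
            y0, y1 = max(iy - 1, 0), min(iy + 2, u.shape[0])
            x0, x1 = max(ix - 1, 0), min(ix + 2, u.shape[1])
            nb = filled[y0:y1, x0:x1]
            if nb.any():
                new_u[iy, ix] = np.median(u[y0:y1, x0:x1][nb])
                new_v[iy, ix] = np.median(v[y0:y1, x0:x1][nb])
                newly[iy, ix] = True
                progress = True
        u, v = new_u, new_v
        filled |= newly
        if not progress:  # disconnected region: fall back to global median
            u[~filled] = np.median(u[filled])
            v[~filled] = np.median(v[filled])
            break

    return DisplacementField(
        x=field.x,
        y=field.y,
        u=u,
        v=v,
        valid=valid,
        window_size=field.window_size,
        overlap=field.overlap,
        pixel_size=field.pixel_size,
        s2n=field.s2n,
    )
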