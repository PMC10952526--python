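"""AFM substrate characterization with the Hertz-Sneddon contact model.

The Young's modulus of the elastic substrate enters the traction
reconstruction directly, so it has to be measured.  With a colloidal
(spherical) AFM probe the force-indentation relation on an elastic
half-space is

    F = (4/3) * sqrt(Rc) * E / (1 - nu^2) * delta^(3/2),

with Rc the probe radius, E the Young's modulus, nu the Poisson ratio
and delta the indentation depth.  This module detects the contact point
on an approach force curve, fits the model by bounded nonlinear least
squares (jointly estimating E, the contact point and a force baseline),
and provides a forward simulator used to verify the fit by parameter
recovery.

Position convention: the ``position`` series of a :class:`ForceCurve`
increases as the probe approaches and indents the sample, so the
indentation past contact is ``position - contact_point`` (minus the
cantilever deflection when the curve carries raw piezo height rather
than tip-sample separation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares


class ContactDetectionError(RuntimeError):
    """The force curve never rises above the baseline noise band."""


class HertzFitError(RuntimeError):
    """The Hertz fit cannot be performed or did not converge."""


@dataclass(frozen=True)
class ForceCurve:
    """An AFM approach (or retract) force-vs-position record.

    ``position`` is in nm and increases toward/into the sample;
    ``force`` is in nN.  When the record stems from raw piezo height and
    cantilever deflection, pass ``spring_constant`` (N/m) and set
    ``deflection_corrected=False`` so that the fit subtracts the
    cantilever bending from the indentation; curves already expressed as
    force versus tip-sample separation use the default
    ``deflection_corrected=True``.
    """

    position: np.ndarray  # nm
    force: np.ndarray  # nN
    segment: str = "approach"
    spring_constant: float | None = None  # N/m
    deflection_corrected: bool = True

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        frc = np.asarray(self.force, dtype=float)
        if pos.shape != frc.shape or pos.ndim != 1:
            raise ValueError("position and force must be 1-D arrays of equal length")
        if pos.size < 16:
            raise ValueError("force curve needs at least 16 samples")
        d = np.diff(pos)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("position must be strictly monotonic within a segment")
        if self.segment not in ("approach", "retract"):
            raise ValueError("segment must be 'approach' or 'retract'")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "force", frc)

    @classmethod
    def from_deflection(
        cls,
        position: np.ndarray,
        deflection_nm: np.ndarray,
        spring_constant: float,
        segment: str = "approach",
    ) -> "ForceCurve":
        """Build a curve from raw deflection (nm) and spring constant (N/m).

        force [nN] = deflection [nm] * k [N/m]  (1 nm * 1 N/m = 1 nN).
        """
        force = np.asarray(deflection_nm, dtype=float) * spring_constant
        return cls(
            position=position,
            force=force,
            segment=segment,
            spring_constant=spring_constant,
            deflection_corrected=False,
        )

    def __len__(self) -> int:
        return self.position.size


@dataclass(frozen=True)
class HertzFit:
    """Result of fitting the spherical-indenter contact model to a curve."""

    youngs_modulus: float  # Pa
    contact_point: float  # nm
    probe_radius: float  # m
    poisson_ratio: float
    baseline_offset: float  # nN
    rms_residual: float  # nN
    n_points_fit: int

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be nonnegative")


def evaluate_hertz(
    youngs_modulus: float,
    probe_radius: float,
    poisson_ratio: float,
    indentation,
):
    """Hertz-Sneddon force (N) of a sphere of radius ``probe_radius`` (m)
    indenting an elastic half-space by ``indentation`` (m).

    Vectorized over ``indentation``; strictly increasing and convex in
    the indentation depth.
    """
    delta = np.asarray(indentation, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be nonnegative")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if poisson_ratio >= 1:
        raise ValueError("poisson_ratio must be < 1")
    out = (
        (4.0 / 3.0)
        * np.sqrt(probe_radius)
        * youngs_modulus
        / (1.0 - poisson_ratio**2)
        * delta**1.5
    )
    return float(out) if np.isscalar(indentation) else out


def detect_contact_point(
    curve: ForceCurve,
    noise_window: int = 64,
    threshold: float = 3.0,
    min_consecutive: int = 3,
) -> float:
    """Initial contact-point estimate (nm) by baseline threshold crossing.

    Baseline mean and SD are computed over the first ``noise_window``
    samples (the probe is far from the surface there); contact is the
    first position where the force exceeds mean + ``threshold`` x SD for
    ``min_consecutive`` consecutive samples, which makes the detector
    robust to isolated noise excursions.  This is an initializer: the
    Hertz fit re-estimates the contact point as a free parameter.
    """
    n = len(curve)
    if noise_window >= n:
        raise ValueError("noise_window must be smaller than the curve length")
    if noise_window < 4:
        raise ValueError("noise_window too small to estimate baseline statistics")
    base = curve.force[:noise_window]
    mu = base.mean()
    sd = base.std()
    thr = mu + threshold * sd
    above = curve.force > thr
    run = 0
    for i in range(noise_window, n):
        run = run + 1 if above[i] else 0
        if run >= min_consecutive:
            return float(curve.position[i - min_consecutive + 1])
    raise ContactDetectionError("force never exceeds the baseline noise band")


def _indentation_nm(curve: ForceCurve, contact_nm: float, baseline_nn: float) -> np.ndarray:
    """Modeled indentation (nm, clipped at 0) at each sample."""
    delta = curve.position - contact_nm
    if not curve.deflection_corrected:
        if curve.spring_constant is None:
            raise HertzFitError("raw-height curve requires a spring constant")
        delta = delta - (curve.force - baseline_nn) / curve.spring_constant
    return np.clip(delta, 0.0, None)


def fit_hertz(
    curve: ForceCurve,
    probe_radius: float = 10e-6,
    poisson_ratio: float = 0.5,
    noise_window: int = 64,
) -> HertzFit:
    """Fit the Hertz-Sneddon model to an approach curve.

    Jointly estimates the Young's modulus E (Pa), contact point (nm) and
    a constant force baseline (nN) by bounded nonlinear least squares
    over the full curve: pre-contact points constrain the baseline,
    post-contact points the power law.  E is initialized from a
    closed-form two-point estimate at the deepest indentation and the
    contact point from the threshold detector.
    """
    if curve.segment != "approach":
        raise HertzFitError("Hertz fit requires the approach segment")
    z0_init = detect_contact_point(curve, noise_window=noise_window)
    base_init = float(curve.force[:noise_window].mean())

    delta0 = _indentation_nm(curve, z0_init, base_init)
    post = delta0 > 0
    if post.sum() < 8:
        raise HertzFitError("fewer than 8 post-contact points")

    # closed-form initial E from the deepest point
    dmax = delta0.max() * 1e-9
    fmax = float(curve.force[np.argmax(delta0)] - base_init) * 1e-9
    if dmax <= 0 or fmax <= 0:
        raise HertzFitError("no usable post-contact force rise")
    e_init = fmax * (1.0 - poisson_ratio**2) / ((4.0 / 3.0) * np.sqrt(probe_radius) * dmax**1.5)
    e_init = float(np.clip(e_init, 1.0, 1e9))

    span = float(curve.position.max() - curve.position.min())

    def model(params: np.ndarray) -> np.ndarray:
        e, z0, b = params
        delta = _indentation_nm(curve, z0, b) * 1e-9  # m
        f_n = evaluate_hertz(e, probe_radius, poisson_ratio, delta)
        return f_n * 1e9 + b  # nN

    def residuals(params: np.ndarray) -> np.ndarray:
        return model(params) - curve.force

    lo = [1.0, float(curve.position.min()) - span, -np.inf]
    hi = [1e9, float(curve.position.max()), np.inf]
    res = least_squares(
        residuals,
        x0=[e_init, z0_init, base_init],
        bounds=(lo, hi),
        x_scale=[max(e_init, 1.0), max(span / 10.0, 1.0), 1.0],
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise HertzFitError(f"Hertz fit did not converge: {res.message}")
    e_fit, z0_fit, b_fit = res.x
    delta_fit = _indentation_nm(curve, z0_fit, b_fit)
    n_fit = int((delta_fit > 0).sum())
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return HertzFit(
        youngs_modulus=float(e_fit),
        contact_point=float(z0_fit),
        probe_radius=probe_radius,
        poisson_ratio=poisson_ratio,
        baseline_offset=float(b_fit),
        rms_residual=rms,
        n_points_fit=n_fit,
    )


def simulate_force_curve(
    youngs_modulus: float,
    probe_radius: float = 10e-6,
    poisson_ratio: float = 0.5,
    contact_point: float = 500.0,
    max_force: float = 5.0,
    speed_samples: int = 1024,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_fraction: float = 0.4,
) -> ForceCurve:
    """Forward-simulate an approach force curve for parameter-recovery tests.

    The probe travels at constant speed (uniform position sampling): a
    force-free baseline spanning ``baseline_fraction`` of the ramp is
    followed by a Hertzian rise that terminates at the ``max_force``
    setpoint (nN).  Zero-mean Gaussian noise of SD ``noise_sd`` (nN) is
    added to the force channel; the curve is deterministic given the seed.
    """
    if youngs_modulus <= 0 or probe_radius <= 0 or max_force <= 0:
        raise ValueError("youngs_modulus, probe_radius and max_force must be positive")
    if speed_samples < 16:
        raise ValueError("speed_samples must be at least 16")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    coeff = (4.0 / 3.0) * np.sqrt(probe_radius) * youngs_modulus / (1.0 - poisson_ratio**2)
    delta_max_m = (max_force * 1e-9 / coeff) ** (2.0 / 3.0)
    delta_max = delta_max_m * 1e9  # nm
    z_start = contact_point - baseline_fraction / (1.0 - baseline_fraction) * delta_max
    z_end = contact_point + delta_max
    position = np.linspace(z_start, z_end, speed_samples)
    delta = np.clip(position - contact_point, 0.0, None) * 1e-9
    force = evaluate_hertz(youngs_modulus, probe_radius, poisson_ratio, delta) * 1e9
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    return ForceCurve(position=position, force=force, segment="approach")


# ---------------------------------------------------------------------------
# file I/O

def read_force_curve(path) -> ForceCurve:
    """Read a two-column delimited force curve with an optional header block.

    Header lines start with ``#`` and may carry ``key: value`` metadata:
    ``spring_constant`` (N/m), ``segment`` and ``force_column`` (``force``
    for force in nN, ``deflection`` for raw deflection in nm).  The data
    body is two whitespace- or comma-delimited columns: position (nm) and
    force (nN) or deflection (nm).
    """
    meta: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip().lower()] = val.strip()
            continue
        rows.append([float(tok) for tok in line.replace(",", " ").split()])
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns")
    position, second = data[:, 0], data[:, 1]
    segment = meta.get("segment", "approach")
    k = float(meta["spring_constant"]) if "spring_constant" in meta else None
    if meta.get("force_column", "force") == "deflection":
        if k is None:
            raise ValueError(f"{path}: deflection data requires a spring_constant header")
        return ForceCurve.from_deflection(position, second, k, segment=segment)
    return ForceCurve(
        position=position,
        force=second,
        segment=segment,
        spring_constant=k,
        deflection_corrected=True,
    )


def write_fit_table(fits: dict[str, HertzFit], path) -> None:
    """Write one row per curve: E (Pa), contact point (nm), residual (nN)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "curve": list(fits),
            "youngs_modulus_pa": [f.youngs_modulus for f in fits.values()],
            "contact_point_nm": [f.contact_point for f in fits.values()],
            "baseline_offset_nn": [f.baseline_offset for f in fits.values()],
            "rms_residual_nn": [f.rms_residual for f in fits.values()],
            "n_points_fit": [f.n_points_fit for f in fits.values()],
        }
    )
    df.to_csv(path, index=False)
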