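"""End-to-end TFM workflow: images -> drift correction -> PIV -> FTTC -> metrics.

One configuration object drives the whole chain, its defaults matching a
typical soft-silicone single-cell experiment (0.46 um pixels, 20 um PIV
windows with 18 um overlap, 9 kPa substrate, Poisson ratio 0.5, 70 um
gel, unregularized FTTC).  Every run writes a manifest that reproduces
it and a log that records per-stage parameters and vector counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .displacement import (
    BeadImage,
    compensate_window_response,
    compute_piv,
    correct_drift,
    validate_and_fill,
)
from .metrics import CellMask, summarize
from .traction import SubstrateProperties, fttc_invert, render_traction_map


class ConfigurationError(RuntimeError):
    """Missing or mutually inconsistent pipeline inputs."""


class PipelineError(RuntimeError):
    """A computation stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Inputs and parameters of one TFM run.

    The relaxed (post cell removal) bead image is the PIV reference, so
    displacements describe the deformation present in the stressed
    state and point along the traction forces that caused it.
    """

    reference_image: str | Path | None = None  # relaxed beads
    deformed_image: str | Path | None = None  # stressed beads
    mask_image: str | Path | None = None  # labeled raster, one int per cell
    membrane_image: str | Path | None = None  # optional, passthrough
    output_dir: str | Path = "tfm_out"
    pixel_size: float = 0.46  # um
    window_size: float = 20.0  # um
    overlap: float = 18.0  # um
    youngs_modulus: float = 9000.0  # Pa
    poisson_ratio: float = 0.5
    thickness: float = 70.0  # um
    regularization: float = 0.0
    traction_margin: float = 15.0  # um
    window_compensation: float = 0.05  # Wiener alpha; 0 disables
    s2n_threshold: float = 1.3
    drift_correction: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("reference_image", "deformed_image", "mask_image", "membrane_image", "output_dir"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


@dataclass
class PipelineResult:
    """Artifacts of a completed run."""

    metrics: pd.DataFrame
    displacement: "object"
    traction: "object"
    drift: tuple[float, float]
    output_dir: Path
    excluded_labels: list[int] = field(default_factory=list)


def _load_image(path, pixel_size: float, what: str) -> BeadImage:
    if path is None:
        raise ConfigurationError(f"missing {what} image")
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"{what} image not found: {p}")
    return BeadImage.from_tiff(p, pixel_size)


def run_tfm(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write the results bundle.

    Stages: drift correction, PIV, vector validation and filling, FTTC
    inversion, then per-cell metrics for every label in the mask raster.
    Cells whose mask touches the field-of-view border are excluded (their
    traction field extends beyond the image) and the exclusion logged.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("tfm.pipeline")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        return _run(config, out, log)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path, log: logging.Logger) -> PipelineResult:
    reference = _load_image(config.reference_image, config.pixel_size, "reference")
    deformed = _load_image(config.deformed_image, config.pixel_size, "deformed")
    if reference.shape != deformed.shape:
        raise ConfigurationError(
            f"image shape mismatch: {reference.shape} vs {deformed.shape}"
        )
    if config.mask_image is None:
        raise ConfigurationError("missing mask image")
    mask_path = Path(config.mask_image)
    if not mask_path.exists():
        raise ConfigurationError(f"mask image not found: {mask_path}")
    labels = np.asarray(tifffile.imread(mask_path))
    if labels.shape != reference.shape:
        raise ConfigurationError(
            f"mask shape {labels.shape} does not match images {reference.shape}"
        )
    log.info("inputs: reference=%s deformed=%s mask=%s", config.reference_image,
             config.deformed_image, config.mask_image)
    log.info("parameters: pixel=%g um window=%g um overlap=%g um E=%g Pa nu=%g "
             "thickness=%g um lambda=%g", config.pixel_size, config.window_size,
             config.overlap, config.youngs_modulus, config.poisson_ratio,
             config.thickness, config.regularization)

    if config.drift_correction:
        drift, deformed = correct_drift(reference, deformed)
        log.info("drift correction: shift=(%.3f, %.3f) px", drift[0], drift[1])
    else:
        drift = (0.0, 0.0)
        log.info("drift correction: skipped")

    disp = compute_piv(reference, deformed, config.window_size, config.overlap)
    n_total = disp.valid.size
    log.info("PIV: %d vectors (%d raw-valid)", n_total, int(disp.valid.sum()))
    try:
        disp = validate_and_fill(disp, s2n_threshold=config.s2n_threshold)
    except Exception as exc:
        raise PipelineError(f"PIV validation failed: {exc}") from exc
    n_replaced = n_total - int(disp.valid.sum())
    log.info("validation: %d vectors replaced (%.1f%%)", n_replaced, 100.0 * n_replaced / n_total)
    if config.window_compensation > 0:
        disp = compensate_window_response(disp, alpha=config.window_compensation)
        log.info("window-response compensation: alpha=%g", config.window_compensation)

    substrate = SubstrateProperties(
        youngs_modulus=config.youngs_modulus,
        poisson_ratio=config.poisson_ratio,
        thickness=config.thickness,
        pixel_size=config.pixel_size,
    )
    try:
        trac = fttc_invert(disp, substrate, regularization=config.regularization)
    except Exception as exc:
        raise PipelineError(f"FTTC inversion failed: {exc}") from exc
    log.info("FTTC: grid %s, peak |t|=%.1f Pa", trac.tx.shape, float(trac.magnitude.max()))

    rows = []
    excluded: list[int] = []
    cell_labels = sorted(int(v) for v in np.unique(labels) if v != 0)
    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for lab in cell_labels:
        region = labels == lab
        if (region & border).any():
            excluded.append(lab)
            log.warning("cell %d touches the field-of-view border: excluded", lab)
            continue
        cm = CellMask.from_labels(labels, lab, config.pixel_size,
                                  traction_margin=config.traction_margin)
        m = summarize(disp, trac, cm)
        row = {"cell": lab, **m.as_dict()}
        rows.append(row)
        log.info("cell %d: area=%.0f um^2 U=%.4g pJ C=%.4g nN", lab,
                 m.cell_area, m.strain_energy, m.contractility)
    metrics = pd.DataFrame(rows)

    disp.to_csv(out / "displacement.csv")
    trac.to_csv(out / "traction.csv")
    metrics.to_csv(out / "metrics.csv", index=False)
    render_traction_map(trac, out / "traction_map.png")
    manifest = {
        "config": config.to_dict(),
        "drift_px": [float(drift[0]), float(drift[1])],
        "excluded_labels": excluded,
        "format_version": 1,
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    log.info("outputs written to %s", out)
    return PipelineResult(
        metrics=metrics,
        displacement=disp,
        traction=trac,
        drift=drift,
        output_dir=out,
        excluded_labels=excluded,
    )
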