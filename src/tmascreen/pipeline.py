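"""Pipeline orchestration: deconvolution -> detection -> smoothing ->
classification -> dearray -> certification -> evaluation, behind one
configuration object.

The whole slide is dearrayed first (on a downsampled tissue mask); cell
detection then runs per core on cropped full-resolution tiles, which
bounds memory regardless of slide size. All randomness flows from named
seeds in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_tma as sim
from .agreement_stats import (
    DEFAULT_POSITIVE_CLASS,
    AgreementReport,
    agreement_report,
    confusion,
)
from .cell_detection import DetectionParams, detect_and_measure
from .core_certification import CertificationParams, certify_all
from .stain_tools import StainMatrix, deconvolve, rgb_to_od
from .tissue_classifier import (
    ClassifierModel,
    TrainingRegion,
    add_smoothed_features,
    classify,
    compose_training_image,
    label_cells_by_annotations,
    train_classifier,
)
from .tma_dearray import TMAGrid, apply_overrides, assign_cells_to_cores, dearray, tissue_mask

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "train_from_regions",
           "train_synthetic_model", "evaluate_calls"]

log = logging.getLogger("tmascreen")


@dataclass
class DearrayConfig:
    core_diameter: float = 900.0
    density_threshold: float = 5.0
    bounds_scale: float = 105.0
    rows: int = 9
    cols: int = 18
    od_floor: float = 0.1


@dataclass
class SmoothingConfig:
    fwhm: float = 25.0
    same_base_class: bool = True


@dataclass
class ClassifierConfig:
    n_estimators: int = 100
    seed: int = 0


@dataclass
class PipelineConfig:
    """Every default equals the calibrated study value where one exists
    (stain vectors, detection table, FWHM 25 um, dearray 0.9 mm / 5.0 /
    105.0, certification threshold 75%)."""

    pixel_size: float = 0.5
    stains: StainMatrix = field(default_factory=StainMatrix)
    detection: DetectionParams = field(default_factory=DetectionParams)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    dearray: DearrayConfig = field(default_factory=DearrayConfig)
    certification: CertificationParams = field(default_factory=CertificationParams)
    positive_class: str = DEFAULT_POSITIVE_CLASS
    overrides_path: str | None = None
    log_level: str = "INFO"

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "stains": self.stains.to_dict(),
            "detection": self.detection.to_dict(),
            "smoothing": asdict(self.smoothing),
            "classifier": asdict(self.classifier),
            "dearray": asdict(self.dearray),
            "certification": asdict(self.certification),
            "positive_class": self.positive_class,
            "overrides_path": self.overrides_path,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        required = {"pixel_size", "stains", "detection", "smoothing",
                    "classifier", "dearray", "certification"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"config missing required fields: {sorted(missing)}")
        return cls(
            pixel_size=d["pixel_size"],
            stains=StainMatrix.from_dict(d["stains"]),
            detection=DetectionParams.from_dict(d["detection"]),
            smoothing=SmoothingConfig(**d["smoothing"]),
            classifier=ClassifierConfig(**d["classifier"]),
            dearray=DearrayConfig(**d["dearray"]),
            certification=CertificationParams(**d["certification"]),
            positive_class=d.get("positive_class", DEFAULT_POSITIVE_CLASS),
            overrides_path=d.get("overrides_path"),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    grid: TMAGrid
    cells: pd.DataFrame
    calls: pd.DataFrame
    tallies: dict
    manifest: dict
    report: AgreementReport | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.grid.to_csv(out / "grid.csv")
        self.cells.to_csv(out / "cells.csv", index=False)
        self.calls.to_csv(out / "calls.csv", index=False)
        summary = dict(self.manifest, tallies=self.tallies)
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
        if self.report is not None:
            (out / "agreement.txt").write_text(self.report.to_text() + "\n")


def _detect_core_tile(
    image: np.ndarray, core, config: PipelineConfig
) -> pd.DataFrame:
    """Run detection on the cropped tile of one core and return measured
    cells in slide coordinates."""
    px = config.pixel_size
    half = 0.5 * core.diameter_um * config.dearray.bounds_scale / 100.0 + 20.0
    h, w = image.shape[:2]
    x0 = max(0, int((core.x_um - half) / px))
    x1 = min(w, int((core.x_um + half) / px) + 1)
    y0 = max(0, int((core.y_um - half) / px))
    y1 = min(h, int((core.y_um + half) / px) + 1)
    if x0 >= x1 or y0 >= y1:
        return pd.DataFrame()
    tile = image[y0:y1, x0:x1]
    od = rgb_to_od(tile, config.stains.background_rgb)
    conc = deconvolve(od, config.stains)
    cells, _, _ = detect_and_measure(
        conc[..., 0], conc[..., 1], config.detection, px
    )
    if cells.empty:
        return cells
    cells["x_um"] += x0 * px
    cells["y_um"] += y0 * px
    return cells


def run_pipeline(
    image: np.ndarray,
    model: ClassifierModel,
    config: PipelineConfig,
    reference: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on a whole-slide RGB image.

    Stages: dearray -> per-core (colour deconvolution -> positive cell
    detection) -> smoothed features -> tissue classification -> per-core
    certification -> optional evaluation against ``reference`` (a frame
    with ``core_label`` and ``call`` columns). Deterministic for a fixed
    config and model.
    """
    logging.basicConfig(level=config.log_level)
    dz = config.dearray
    log.info("dearraying %dx%d grid", dz.rows, dz.cols)
    grid = dearray(
        image,
        pixel_size=config.pixel_size,
        core_diameter=dz.core_diameter,
        density_threshold=dz.density_threshold,
        bounds_scale=dz.bounds_scale,
        rows=dz.rows,
        cols=dz.cols,
        background_rgb=config.stains.background_rgb,
        od_floor=dz.od_floor,
    )
    if config.overrides_path:
        mask = tissue_mask(
            image[::8, ::8], config.stains.background_rgb,
            od_floor=dz.od_floor, pixel_size=config.pixel_size * 8,
        )
        grid = apply_overrides(
            grid, pd.read_csv(config.overrides_path),
            mask=mask, mask_pixel_size=config.pixel_size * 8,
        )
    frames = []
    for core in grid.valid_cores:
        cells = _detect_core_tile(image, core, config)
        if len(cells):
            frames.append(cells)
    if frames:
        cells = pd.concat(frames, ignore_index=True)
        cells["cell_id"] = np.arange(1, len(cells) + 1)
    else:
        cells = pd.DataFrame(columns=["cell_id", "x_um", "y_um", "base_class"])
    log.info("detected %d cells in %d valid cores", len(cells), len(grid.valid_cores))
    cells = assign_cells_to_cores(grid, cells, bounds_scale=dz.bounds_scale)
    cells = add_smoothed_features(
        cells, fwhm=config.smoothing.fwhm,
        same_base_class=config.smoothing.same_base_class,
    ) if len(cells) else cells
    cells = classify(model, cells) if len(cells) else cells
    calls, tallies = certify_all(
        cells, config.certification,
        core_labels=[c.label for c in grid.valid_cores],
    )
    report = None
    if reference is not None and len(calls):
        # agreement is assessed on the cores the reference labels; cores
        # without a reference diagnosis (e.g. consensus-unresolved) are
        # outside the comparison
        scored = calls[calls["core_label"].isin(reference["core_label"])]
        table = confusion(scored, reference, config.positive_class)
        report = agreement_report(table)
    manifest = {
        "config_hash": config.config_hash(),
        "classifier_seed": model.seed,
        "n_valid_cores": len(grid.valid_cores),
        "n_cells": len(cells),
    }
    result = PipelineResult(
        grid=grid, cells=cells, calls=calls, tallies=tallies,
        manifest=manifest, report=report,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def train_from_regions(
    regions: list[TrainingRegion], config: PipelineConfig
) -> ClassifierModel:
    """Train the tissue classifier from annotated training regions:
    montage -> deconvolution -> detection -> smoothed features -> labels
    from annotations -> random forest."""
    mosaic = compose_training_image(regions)
    od = rgb_to_od(mosaic.image, config.stains.background_rgb)
    conc = deconvolve(od, config.stains)
    cells, _, _ = detect_and_measure(
        conc[..., 0], conc[..., 1], config.detection, mosaic.pixel_size
    )
    cells = add_smoothed_features(
        cells, fwhm=config.smoothing.fwhm,
        same_base_class=config.smoothing.same_base_class,
    )
    labels = label_cells_by_annotations(cells, mosaic.annotations)
    return train_classifier(
        cells, labels,
        n_estimators=config.classifier.n_estimators,
        seed=config.classifier.seed,
    )


def train_synthetic_model(
    config: PipelineConfig, seed: int = 0, density: float = 2000.0
) -> ClassifierModel:
    """Train on the generator's 14 single-class 500 um training regions
    (the no-external-data training path)."""
    from shapely.geometry import box

    regions = []
    for k, (cls, pos) in enumerate(sim.default_training_regions()):
        rng = np.random.default_rng([seed, 1000 + k])
        tile, _ = sim.render_training_region(
            cls, pos, stains=config.stains,
            pixel_size=config.pixel_size, rng=rng, density=density,
        )
        size_um = tile.shape[0] * config.pixel_size
        regions.append(
            TrainingRegion(
                image=tile,
                annotations=[(box(0, 0, size_um, size_um), cls)],
                pixel_size=config.pixel_size,
            )
        )
    return train_from_regions(regions, config)


def evaluate_calls(
    calls: pd.DataFrame,
    reference: pd.DataFrame,
    positive_class: str = DEFAULT_POSITIVE_CLASS,
) -> AgreementReport:
    """Agreement between a call table and reference labels."""
    return agreement_report(confusion(calls, reference, positive_class))
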