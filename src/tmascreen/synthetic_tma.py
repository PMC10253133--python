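"""Synthetic brightfield TMA images with per-cell and per-core ground truth.

The generator emulates an MLH1-immunostained colorectal tissue microarray:
0.6 mm tissue cores on a 0.9 mm grid (default 9x18, some positions blank),
rendered at 0.5 um/pixel. Staining follows the Beer-Lambert mixing model:
every nucleus deposits haematoxylin optical density, marker-positive nuclei
additionally deposit DAB, and the resulting OD image is composed into 8-bit
RGB against the calibrated white point. Four tissue classes with distinct
nucleus morphology are modelled:

* normal epithelium — medium, fairly round nuclei;
* tumour — large, eccentric, hyperchromatic nuclei;
* immune infiltrate — small, dense, round lymphocyte nuclei;
* stroma — spindle-shaped fibroblast nuclei.

A faint uniform haematoxylin "tissue wash" is rendered over the tissue disc
(cytoplasm and extracellular matrix take up counterstain in real sections);
it is what makes cores visible to area-based tissue detection.

Scenario factories encode both unambiguous cores and the five ambiguity
patterns a core-level certification step must flag: scant tissue, atypical
tumour morphology, heavy immune infiltrate, normal-only mucosa, and
weak/patchy marker staining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stain_tools import DEFAULT_BACKGROUND, StainMatrix

__all__ = [
    "TISSUE_CLASSES",
    "CoreScenario",
    "TMASimSpec",
    "compose_pixel",
    "render_core",
    "render_tma",
    "render_training_region",
    "default_training_regions",
    "default_tma_spec",
    "match_cells",
    "write_tma",
    "scenario_blank",
    "scenario_normal_proficient",
    "scenario_tumour_proficient",
    "scenario_tumour_deficient",
    "scenario_scant_tissue",
    "scenario_atypical_tumour",
    "scenario_immune_rich",
    "scenario_normal_only",
    "scenario_patchy_stain",
    "AMBIGUOUS_SCENARIOS",
]

TISSUE_CLASSES = ("NormalEpithelium", "Tumour", "ImmuneInfiltrate", "Stroma")

# axis ratio of the rendered nuclear ellipse, per tissue class
_CLASS_ELONGATION = {
    "NormalEpithelium": 1.3,
    "Tumour": 1.8,
    "ImmuneInfiltrate": 1.1,
    "Stroma": 3.0,
}

_DEFAULT_RADIUS = {
    "NormalEpithelium": (3.5, 0.40),
    "Tumour": (5.0, 0.70),
    "ImmuneInfiltrate": (2.4, 0.25),
    "Stroma": (3.8, 0.50),
}
_DEFAULT_H_OD = {
    "NormalEpithelium": 0.60,
    "Tumour": 0.75,
    "ImmuneInfiltrate": 0.90,
    "Stroma": 0.50,
}
_DEFAULT_DAB_OD = {c: 0.60 for c in TISSUE_CLASSES}

# wavelength of the sinusoidal patchiness field, um
_PATCH_WAVELENGTH_UM = 250.0


@dataclass
class CoreScenario:
    """Ground-truth recipe for one tissue core.

    ``composition`` gives the per-class cell fractions (sum 1);
    ``marker_positive`` the fraction of each class's nuclei that express
    the marker; ``dab_od``/``h_od`` the mean nuclear OD amplitudes;
    ``radius_um`` the (mean, sd) nuclear radius per class.  ``tissue_fill``
    shrinks the tissue disc to that fraction of the nominal core area
    (scant-tissue cores); ``patchiness`` is the amplitude of a
    low-frequency sinusoidal multiplier on DAB OD (weak/patchy staining).
    ``expected_call`` is the certification outcome the scenario is
    designed to produce.
    """

    name: str
    composition: dict[str, float] = field(
        default_factory=lambda: {"NormalEpithelium": 1.0}
    )
    marker_positive: dict[str, float] = field(default_factory=dict)
    dab_od: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DAB_OD))
    h_od: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_H_OD))
    radius_um: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RADIUS)
    )
    density: float = 2000.0  # cells / mm^2
    tissue_fill: float = 1.0
    patchiness: float = 0.0
    blank: bool = False
    expected_call: str = "Flagged"

    def __post_init__(self) -> None:
        if self.blank:
            return
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, not 1")
        for cls, frac in self.composition.items():
            if cls not in TISSUE_CLASSES:
                raise ValueError(f"unknown tissue class {cls!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"composition fraction out of [0,1]: {frac}")
        for frac in self.marker_positive.values():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"marker fraction out of [0,1]: {frac}")
        if not 0.0 <= self.tissue_fill <= 1.0:
            raise ValueError("tissue_fill must lie in [0,1]")


# ---------------------------------------------------------------------------
# scenario factories
# ---------------------------------------------------------------------------


def scenario_blank() -> CoreScenario:
    """Empty grid position (orientation blank): background only."""
    return CoreScenario(name="blank", composition={}, blank=True, expected_call="Invalid")


def scenario_normal_proficient() -> CoreScenario:
    """Unambiguous MLH1-proficient normal colonic mucosa."""
    return CoreScenario(
        name="normal_proficient",
        composition={"NormalEpithelium": 0.85, "Stroma": 0.12, "ImmuneInfiltrate": 0.03},
        marker_positive={
            "NormalEpithelium": 0.96,
            "Stroma": 0.40,
            "ImmuneInfiltrate": 0.30,
        },
        expected_call="MLH1ProficientNormal",
    )


def scenario_tumour_proficient() -> CoreScenario:
    """Unambiguous MLH1-proficient tumour."""
    return CoreScenario(
        name="tumour_proficient",
        composition={"Tumour": 0.85, "Stroma": 0.08, "ImmuneInfiltrate": 0.07},
        marker_positive={"Tumour": 0.95, "Stroma": 0.40, "ImmuneInfiltrate": 0.30},
        expected_call="MLH1ProficientTumour",
    )


def scenario_tumour_deficient() -> CoreScenario:
    """Unambiguous MLH1-deficient tumour: tumour nuclei unstained while
    stromal/immune nuclei retain expression (the internal positive
    control seen in real MLH1-lost cancers)."""
    return CoreScenario(
        name="tumour_deficient",
        composition={"Tumour": 0.85, "Stroma": 0.08, "ImmuneInfiltrate": 0.07},
        marker_positive={"Tumour": 0.03, "Stroma": 0.70, "ImmuneInfiltrate": 0.70},
        expected_call="MLH1DeficientTumour",
    )


def scenario_scant_tissue() -> CoreScenario:
    """Ambiguous: small quantity of tissue with mixed histology."""
    return CoreScenario(
        name="scant_tissue",
        composition={"Tumour": 0.50, "NormalEpithelium": 0.30, "Stroma": 0.20},
        marker_positive={"Tumour": 0.60, "NormalEpithelium": 0.95, "Stroma": 0.40},
        tissue_fill=0.25,
        expected_call="Flagged",
    )


def scenario_atypical_tumour() -> CoreScenario:
    """Ambiguous: atypical/diverse tumour morphology mixed with other
    compartments; tumour nuclei shrunk towards the normal range."""
    s = CoreScenario(
        name="atypical_tumour",
        composition={
            "Tumour": 0.55,
            "NormalEpithelium": 0.20,
            "ImmuneInfiltrate": 0.10,
            "Stroma": 0.15,
        },
        marker_positive={
            "Tumour": 0.90,
            "NormalEpithelium": 0.95,
            "ImmuneInfiltrate": 0.30,
            "Stroma": 0.40,
        },
        expected_call="Flagged",
    )
    s.radius_um = dict(s.radius_um, Tumour=(4.2, 0.8))
    return s


def scenario_immune_rich() -> CoreScenario:
    """Ambiguous: heavy inflammatory/immune infiltrate."""
    return CoreScenario(
        name="immune_rich",
        composition={"ImmuneInfiltrate": 0.45, "Tumour": 0.35, "Stroma": 0.20},
        marker_positive={"ImmuneInfiltrate": 0.35, "Tumour": 0.90, "Stroma": 0.40},
        expected_call="Flagged",
    )


def scenario_normal_only() -> CoreScenario:
    """Ambiguous: normal mucosa with abundant stroma, no tumour."""
    return CoreScenario(
        name="normal_only",
        composition={"NormalEpithelium": 0.60, "Stroma": 0.35, "ImmuneInfiltrate": 0.05},
        marker_positive={
            "NormalEpithelium": 0.95,
            "Stroma": 0.40,
            "ImmuneInfiltrate": 0.30,
        },
        expected_call="Flagged",
    )


def scenario_patchy_stain() -> CoreScenario:
    """Ambiguous: weak/patchy marker staining on an otherwise clean
    tumour core — the marker fraction sits mid-range and spatial
    patchiness pushes weakly stained nuclei below threshold."""
    return CoreScenario(
        name="patchy_stain",
        composition={"Tumour": 0.85, "Stroma": 0.08, "ImmuneInfiltrate": 0.07},
        marker_positive={"Tumour": 0.55, "Stroma": 0.40, "ImmuneInfiltrate": 0.30},
        patchiness=0.5,
        expected_call="Flagged",
    )


AMBIGUOUS_SCENARIOS = (
    scenario_scant_tissue,
    scenario_atypical_tumour,
    scenario_immune_rich,
    scenario_normal_only,
    scenario_patchy_stain,
)


# ---------------------------------------------------------------------------
# TMA layout spec
# ---------------------------------------------------------------------------


@dataclass
class TMASimSpec:
    """Layout and physics parameters for a whole synthetic TMA."""

    scenarios: list[CoreScenario]
    rows: int = 9
    cols: int = 18
    pixel_size: float = 0.5  # um / pixel
    core_spacing: float = 900.0  # um, grid pitch
    tissue_core_diameter: float = 600.0  # um
    background_rgb: tuple[float, float, float] = DEFAULT_BACKGROUND
    noise_sd: float = 0.02  # OD units
    tissue_od: float = 0.15  # haematoxylin wash over the tissue disc
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.scenarios) != self.rows * self.cols:
            raise ValueError(
                f"need {self.rows * self.cols} scenarios (blanks included), "
                f"got {len(self.scenarios)}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.tissue_core_diameter >= self.core_spacing:
            raise ValueError("tissue core diameter must be below the grid pitch")


def core_label(row: int, col: int) -> str:
    """Grid label, rows A.. top-to-bottom, columns 1.. left-to-right."""
    return f"{chr(ord('A') + row)}{col + 1}"


def default_tma_spec(
    seed: int = 0,
    rows: int = 9,
    cols: int = 18,
    n_deficient: int = 17,
    n_proficient_tumour: int = 29,
    n_proficient_normal: int = 28,
    n_per_ambiguous: int = 5,
    pixel_size: float = 0.5,
) -> TMASimSpec:
    """Study-scale layout: 74 unambiguous cores (17 MLH1-deficient tumours,
    29 proficient tumours, 28 proficient normals), 25 ambiguous cores
    (5 per ambiguity pattern), remaining positions blank; positions
    shuffled deterministically by ``seed``."""
    scenarios: list[CoreScenario] = []
    scenarios += [scenario_tumour_deficient() for _ in range(n_deficient)]
    scenarios += [scenario_tumour_proficient() for _ in range(n_proficient_tumour)]
    scenarios += [scenario_normal_proficient() for _ in range(n_proficient_normal)]
    for factory in AMBIGUOUS_SCENARIOS:
        scenarios += [factory() for _ in range(n_per_ambiguous)]
    n_blank = rows * cols - len(scenarios)
    if n_blank < 0:
        raise ValueError("more scenarios than grid positions")
    scenarios += [scenario_blank() for _ in range(n_blank)]
    order = np.random.default_rng(seed).permutation(len(scenarios))
    return TMASimSpec(
        scenarios=[scenarios[i] for i in order],
        rows=rows,
        cols=cols,
        pixel_size=pixel_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def compose_pixel(concentrations: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Compose stain concentrations into 8-bit RGB (Beer-Lambert).

    ``concentrations`` has last axis of length 2 (stain1, stain2) or 3
    (plus residual).  Channel value = background * 10**(-sum_s v_s c_s),
    rounded and clamped to [0, 255].  Negative concentrations are
    rejected: absorbance cannot be negative.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative stain concentration")
    if conc.shape[-1] == 2:
        m = stains._matrix[:2]
    elif conc.shape[-1] == 3:
        m = stains._matrix
    else:
        raise ValueError("concentrations must have 2 or 3 stain channels")
    od = (conc.astype(np.float32) @ m.astype(np.float32)) * np.float32(math.log(10.0))
    rgb = np.asarray(stains.background_rgb, np.float32) * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def _hardcore_points(
    rng: np.random.Generator,
    sampler,
    n_target: int,
    min_dist: float,
    max_attempts_factor: int = 10,
) -> np.ndarray:
    """Dart-throwing hard-core point process: candidates from ``sampler``
    are accepted unless within ``min_dist`` of an accepted point; at most
    ``max_attempts_factor * n_target`` darts are thrown."""
    if n_target == 0:
        return np.empty((0, 2))
    # bucket edge = min_dist so conflicting points are always within the
    # 3x3 bucket neighbourhood
    cell = min_dist
    buckets: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []
    md2 = min_dist * min_dist
    attempts = max_attempts_factor * n_target
    cands = sampler(rng, attempts)
    for x, y in cands:
        bi, bj = int(x // cell), int(y // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in buckets.get((bi + di, bj + dj), ()):
                    px, py = pts[k]
                    if (px - x) ** 2 + (py - y) ** 2 < md2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            buckets.setdefault((bi, bj), []).append(len(pts))
            pts.append((x, y))
            if len(pts) >= n_target:
                break
    if len(pts) < 0.9 * n_target:
        raise ValueError(
            f"hard-core placement infeasible: placed {len(pts)} of {n_target} "
            f"nuclei at minimum spacing {min_dist:.2f} um; lower the density"
        )
    return np.asarray(pts)


def _draw_ellipse(arr: np.ndarray, cx: float, cy: float, a: float, b: float,
                  theta: float, amplitude: float) -> None:
    """Add ``amplitude`` inside the ellipse (px coordinates) to ``arr``."""
    h, w = arr.shape
    r = max(a, b)
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    mask = u * u + v * v <= 1.0
    sub = arr[y0:y1, x0:x1]
    sub[mask] += amplitude


def _patch_multiplier(x_um: np.ndarray, y_um: np.ndarray, patchiness: float) -> np.ndarray:
    if patchiness == 0:
        return np.ones_like(np.asarray(x_um, float))
    w = 2.0 * math.pi / _PATCH_WAVELENGTH_UM
    m = 1.0 + patchiness * np.sin(w * np.asarray(x_um)) * np.sin(w * np.asarray(y_um))
    return np.maximum(m, 0.0)


def _render_tissue(
    od_h: np.ndarray,
    od_d: np.ndarray,
    scenario: CoreScenario,
    rng: np.random.Generator,
    pixel_size: float,
    sampler,
    area_mm2: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Place and draw nuclei for one tissue region; returns truth records
    with coordinates in um relative to the OD array origin."""
    classes = [c for c in TISSUE_CLASSES if scenario.composition.get(c, 0) > 0]
    probs = np.array([scenario.composition[c] for c in classes])
    mean_r = float(sum(scenario.composition[c] * scenario.radius_um[c][0] for c in classes))
    n_target = int(rng.poisson(scenario.density * area_mm2))
    pts = _hardcore_points(rng, sampler, n_target, 1.5 * mean_r)
    n = len(pts)
    cols = {"x_um": pts[:, 0] if n else np.empty(0), "y_um": pts[:, 1] if n else np.empty(0)}
    if n == 0:
        return pd.DataFrame(cols | {"tissue_class": [], "marker_status": []})
    idx = rng.choice(len(classes), size=n, p=probs)
    cls = np.array(classes, dtype=object)[idx]
    pos_p = np.array([scenario.marker_positive.get(c, 0.0) for c in classes])[idx]
    marker = rng.random(n) < pos_p
    patch = _patch_multiplier(pts[:, 0] + origin_um[0], pts[:, 1] + origin_um[1],
                              scenario.patchiness)
    for i in range(n):
        c = cls[i]
        r_mean, r_sd = scenario.radius_um[c]
        r = max(1.0, rng.normal(r_mean, r_sd))
        e = _CLASS_ELONGATION[c]
        a, b = r * math.sqrt(e), r / math.sqrt(e)
        theta = rng.uniform(0, math.pi)
        h_amp = max(0.1, rng.normal(scenario.h_od[c], 0.12 * scenario.h_od[c]))
        cx, cy = pts[i, 0] / pixel_size, pts[i, 1] / pixel_size
        _draw_ellipse(od_h, cx, cy, a / pixel_size, b / pixel_size, theta, h_amp)
        if marker[i]:
            d_amp = rng.normal(scenario.dab_od[c], 0.15 * scenario.dab_od[c])
            d_amp = max(0.0, d_amp * patch[i])
            if d_amp > 0:
                _draw_ellipse(od_d, cx, cy, a / pixel_size, b / pixel_size, theta, d_amp)
    return pd.DataFrame(
        {
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "tissue_class": cls,
            "marker_status": np.where(marker, "Positive", "Negative"),
        }
    )


def render_core(
    scenario: CoreScenario,
    stains: StainMatrix | None = None,
    pixel_size: float = 0.5,
    rng: np.random.Generator | None = None,
    core_spacing: float = 900.0,
    tissue_core_diameter: float = 600.0,
    noise_sd: float = 0.02,
    tissue_od: float = 0.15,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one grid cell (``core_spacing`` square) containing a tissue
    core, returning the RGB tile and tile-local truth records (um).

    Nuclei are placed by a dart-throwing hard-core process (no two
    centres closer than 1.5x the composition-weighted mean radius) inside
    the tissue disc; each is an ellipse with class-dependent shape.  DAB
    is deposited only in marker-positive nuclei.  Gaussian OD noise is
    added before composition to RGB.
    """
    stains = stains or StainMatrix()
    rng = rng if rng is not None else np.random.default_rng()
    tile_px = int(round(core_spacing / pixel_size))
    od_h = np.zeros((tile_px, tile_px), dtype=float)
    od_d = np.zeros_like(od_h)
    if scenario.blank or scenario.tissue_fill == 0:
        cells = pd.DataFrame(
            {"x_um": [], "y_um": [], "tissue_class": [], "marker_status": []}
        )
    else:
        r_t = 0.5 * tissue_core_diameter * math.sqrt(scenario.tissue_fill)
        c_um = 0.5 * core_spacing
        yy, xx = np.mgrid[0:tile_px, 0:tile_px]
        disc = (xx * pixel_size - c_um) ** 2 + (yy * pixel_size - c_um) ** 2 <= r_t**2
        od_h[disc] += tissue_od

        def sampler(rg, k):
            rad = r_t * np.sqrt(rg.random(k))
            ang = rg.uniform(0, 2 * math.pi, k)
            return np.column_stack([c_um + rad * np.cos(ang), c_um + rad * np.sin(ang)])

        area_mm2 = math.pi * r_t**2 / 1e6
        cells = _render_tissue(od_h, od_d, scenario, rng, pixel_size, sampler, area_mm2)
    if noise_sd > 0:
        od_h += rng.normal(0.0, noise_sd, od_h.shape)
        od_d += rng.normal(0.0, noise_sd, od_d.shape)
        np.maximum(od_h, 0.0, out=od_h)
        np.maximum(od_d, 0.0, out=od_d)
    tile = compose_pixel(np.stack([od_h, od_d], axis=-1), stains)
    return tile, cells


def render_training_region(
    tissue_class: str,
    marker_positive: float,
    stains: StainMatrix | None = None,
    pixel_size: float = 0.5,
    rng: np.random.Generator | None = None,
    size_um: float = 500.0,
    density: float = 2000.0,
    noise_sd: float = 0.02,
    tissue_od: float = 0.15,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a square training tile fully occupied by one tissue class.

    Mirrors how representative 500 um x 500 um regions of a single
    histology are annotated to train the object classifier.
    """
    stains = stains or StainMatrix()
    rng = rng if rng is not None else np.random.default_rng()
    scenario = CoreScenario(
        name=f"train_{tissue_class}",
        composition={tissue_class: 1.0},
        marker_positive={tissue_class: marker_positive},
        density=density,
    )
    tile_px = int(round(size_um / pixel_size))
    od_h = np.full((tile_px, tile_px), tissue_od, dtype=float)
    od_d = np.zeros_like(od_h)
    margin = scenario.radius_um[tissue_class][0]

    def sampler(rg, k):
        return rg.uniform(margin, size_um - margin, (k, 2))

    cells = _render_tissue(
        od_h, od_d, scenario, rng, pixel_size, sampler, (size_um / 1000.0) ** 2
    )
    if noise_sd > 0:
        od_h += rng.normal(0.0, noise_sd, od_h.shape)
        od_d += rng.normal(0.0, noise_sd, od_d.shape)
        np.maximum(od_h, 0.0, out=od_h)
        np.maximum(od_d, 0.0, out=od_d)
    tile = compose_pixel(np.stack([od_h, od_d], axis=-1), stains)
    return tile, cells


def default_training_regions() -> list[tuple[str, float]]:
    """14 training-region recipes (tissue class, marker-positive fraction)
    spanning the four classes and both base classes."""
    return (
        [("NormalEpithelium", 0.7)] * 4
        + [("Tumour", 0.7)] * 4
        + [("ImmuneInfiltrate", 0.3)] * 3
        + [("Stroma", 0.3)] * 3
    )


def render_tma(
    spec: TMASimSpec, stains: StainMatrix | None = None
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Render a whole synthetic TMA slide.

    Returns ``(image, cells, cores)``: the 8-bit RGB slide of shape
    ``(rows * spacing / px, cols * spacing / px, 3)``, per-cell truth
    (slide coordinates in um, grid label, tissue class, marker status)
    and per-core truth (label, centre, scenario name, expected call).
    Deterministic for a fixed spec: every core draws from its own
    seed-and-position derived RNG stream.
    """
    if stains is None:
        stains = StainMatrix(background_rgb=tuple(spec.background_rgb))
    tile_px = int(round(spec.core_spacing / spec.pixel_size))
    image = np.empty((spec.rows * tile_px, spec.cols * tile_px, 3), dtype=np.uint8)
    cell_frames: list[pd.DataFrame] = []
    core_rows: list[dict] = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            k = r * spec.cols + c
            scenario = spec.scenarios[k]
            rng = np.random.default_rng([spec.seed, k])
            tile, cells = render_core(
                scenario,
                stains=stains,
                pixel_size=spec.pixel_size,
                rng=rng,
                core_spacing=spec.core_spacing,
                tissue_core_diameter=spec.tissue_core_diameter,
                noise_sd=spec.noise_sd,
                tissue_od=spec.tissue_od,
            )
            image[r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px] = tile
            label = core_label(r, c)
            if len(cells):
                cells = cells.copy()
                cells["x_um"] += c * spec.core_spacing
                cells["y_um"] += r * spec.core_spacing
                cells["core_label"] = label
                cell_frames.append(cells)
            core_rows.append(
                {
                    "label": label,
                    "x_um": (c + 0.5) * spec.core_spacing,
                    "y_um": (r + 0.5) * spec.core_spacing,
                    "scenario": scenario.name,
                    "expected_call": scenario.expected_call,
                    "blank": scenario.blank,
                    "n_cells": len(cells),
                }
            )
    if cell_frames:
        cells_df = pd.concat(cell_frames, ignore_index=True)
    else:
        cells_df = pd.DataFrame(
            {"x_um": [], "y_um": [], "tissue_class": [], "marker_status": [], "core_label": []}
        )
    cores_df = pd.DataFrame(core_rows)
    return image, cells_df, cores_df


def write_tma(
    out_dir: str | Path,
    image: np.ndarray,
    cells: pd.DataFrame,
    cores: pd.DataFrame,
) -> dict[str, Path]:
    """Write the rendered slide (TIFF) and truth tables (CSV)."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "tma.tiff",
        "cells": out / "truth_cells.csv",
        "cores": out / "truth_cores.csv",
        "reference": out / "reference.csv",
    }
    tifffile.imwrite(paths["image"], image, photometric="rgb")
    cells.to_csv(paths["cells"], index=False)
    cores.to_csv(paths["cores"], index=False)
    # reference call table for evaluation: cores with a definite
    # expected diagnosis (blanks and designed-ambiguous cores have none)
    ref = cores[~cores["blank"] & ~cores["expected_call"].isin(["Flagged", "Invalid"])]
    ref = ref.rename(columns={"label": "core_label", "expected_call": "call"})
    ref[["core_label", "call"]].to_csv(paths["reference"], index=False)
    return paths


def match_cells(
    truth: pd.DataFrame, detected: pd.DataFrame, max_dist_um: float = 6.0
) -> pd.DataFrame:
    """Greedily match detected cells to ground-truth cells by mutual
    nearest centroid within ``max_dist_um``; returns the matched truth
    rows joined with the detected rows (suffix ``_det``)."""
    from scipy.spatial import cKDTree

    if truth.empty or detected.empty:
        return pd.DataFrame()
    t_xy = truth[["x_um", "y_um"]].to_numpy()
    d_xy = detected[["x_um", "y_um"]].to_numpy()
    tree = cKDTree(d_xy)
    dist, j = tree.query(t_xy, distance_upper_bound=max_dist_um)
    ok = np.isfinite(dist)
    # enforce one-to-one: keep the closest truth cell per detection
    order = np.argsort(dist[ok])
    t_idx = np.flatnonzero(ok)[order]
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for ti in t_idx:
        dj = int(j[ti])
        if dj not in used:
            used.add(dj)
            pairs.append((int(ti), dj))
    if not pairs:
        return pd.DataFrame()
    ti, dj = map(list, zip(*pairs))
    left = truth.iloc[ti].reset_index(drop=True)
    right = detected.iloc[dj].reset_index(drop=True).add_suffix("_det")
    return pd.concat([left, right], axis=1)
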