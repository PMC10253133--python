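"""Neighbourhood-smoothed features and random-forest tissue classification.

Each detected cell receives, alongside its raw measurements, Gaussian
distance-weighted averages of those measurements over neighbouring cells
(FWHM 25 um by default, restricted to neighbours sharing the cell's
Positive/Negative base class). A random forest trained on annotated
regions then assigns one of four tissue classes — normal epithelium,
tumour, immune infiltrate, stroma — while the marker base class is
carried through unchanged. The (tissue, marker) pair forms the composite
class used for core-level certification.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestClassifier

from .cell_detection import UNSCORED

__all__ = [
    "TISSUE_CLASSES",
    "FWHM_TO_SIGMA",
    "TrainingRegion",
    "ClassifierModel",
    "RAW_FEATURES",
    "add_smoothed_features",
    "compose_training_image",
    "label_cells_by_annotations",
    "train_classifier",
    "classify",
    "composite_class",
]

from .synthetic_tma import TISSUE_CLASSES

#: FWHM = 2 sqrt(2 ln 2) sigma
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: measurement columns smoothed and fed to the forest
RAW_FEATURES = (
    "nucleus_area_um2",
    "nucleus_circularity",
    "nucleus_h_od_mean",
    "nucleus_dab_od_mean",
    "cell_dab_od_mean",
    "cytoplasm_dab_od_mean",
)


@dataclass
class TrainingRegion:
    """A training tile plus its polygon annotations.

    ``annotations`` is a list of ``(polygon, tissue_class)`` pairs with
    polygon coordinates in um, tile-local.
    """

    image: np.ndarray
    annotations: list[tuple[object, str]]
    pixel_size: float


def add_smoothed_features(
    cells: pd.DataFrame,
    fwhm: float = 25.0,
    same_base_class: bool = True,
    features: tuple[str, ...] = RAW_FEATURES,
) -> pd.DataFrame:
    """Append Gaussian neighbourhood averages of the raw features.

    For cell i, smoothed_f(i) = sum_j w_ij f(j) / sum_j w_ij with
    w_ij = exp(-d_ij^2 / (2 sigma^2)), sigma = fwhm / 2.3548, summing
    over cells j (including i itself) within 3 sigma, restricted to
    neighbours sharing i's base class when ``same_base_class``. A cell
    with no eligible neighbours keeps its raw value. NaN feature values
    are ignored in the averages (and fall back to the raw value when no
    neighbour has the feature).
    """
    df = cells.copy()
    present = [f for f in features if f in df.columns]
    for f in present:
        df[f"smoothed_{f}"] = df[f].to_numpy(dtype=float)
    if df.empty or fwhm <= 0:
        return df
    sigma = fwhm / FWHM_TO_SIGMA
    cutoff = 3.0 * sigma
    if same_base_class and "base_class" in df.columns:
        groups = [g.index.to_numpy() for _, g in df.groupby("base_class", sort=False)]
    else:
        groups = [df.index.to_numpy()]
    for gidx in groups:
        sub = df.loc[gidx]
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        tree = cKDTree(xy)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        n = len(gidx)
        rows = np.concatenate([np.arange(n), pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([np.arange(n), pairs[:, 1], pairs[:, 0]])
        d2 = np.sum((xy[rows] - xy[cols]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * sigma * sigma))
        for f in present:
            vals = sub[f].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            vw = np.where(finite[cols], w, 0.0)
            num = np.bincount(rows, weights=vw * np.where(finite[cols], vals[cols], 0.0), minlength=n)
            den = np.bincount(rows, weights=vw, minlength=n)
            sm = np.where(den > 0, num / np.where(den > 0, den, 1.0), vals)
            df.loc[gidx, f"smoothed_{f}"] = sm
    return df


def compose_training_image(
    regions: list[TrainingRegion], gutter_um: float = 50.0
) -> TrainingRegion:
    """Montage training tiles row-major with blank gutters.

    Annotation coordinates are remapped into the montage frame. The
    gutters (background white) exceed the feature-smoothing reach, so
    detections and neighbourhood features never mix across tiles.
    """
    from shapely.affinity import translate

    if not regions:
        raise ValueError("no training regions")
    px = regions[0].pixel_size
    if any(abs(r.pixel_size - px) > 1e-9 for r in regions):
        raise ValueError("training regions have mixed pixel sizes")
    if len(regions) == 1:
        return regions[0]
    n = len(regions)
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    gut = int(round(gutter_um / px))
    tile_h = max(r.image.shape[0] for r in regions)
    tile_w = max(r.image.shape[1] for r in regions)
    H = nrows * tile_h + (nrows - 1) * gut
    W = ncols * tile_w + (ncols - 1) * gut
    mosaic = np.full((H, W, 3), 255, dtype=np.uint8)
    # background colour from the first tile's corner pixel
    mosaic[:] = regions[0].image[0, 0]
    annotations: list[tuple[object, str]] = []
    for k, reg in enumerate(regions):
        ri, ci = divmod(k, ncols)
        y0 = ri * (tile_h + gut)
        x0 = ci * (tile_w + gut)
        h, w = reg.image.shape[:2]
        mosaic[y0 : y0 + h, x0 : x0 + w] = reg.image
        for poly, cls in reg.annotations:
            annotations.append((translate(poly, xoff=x0 * px, yoff=y0 * px), cls))
    return TrainingRegion(image=mosaic, annotations=annotations, pixel_size=px)


def label_cells_by_annotations(
    cells: pd.DataFrame, annotations: list[tuple[object, str]]
) -> pd.Series:
    """Tissue-class label for each cell whose centroid falls inside an
    annotation polygon (first containing polygon wins); NaN elsewhere."""
    from shapely.geometry import Point
    from shapely.prepared import prep

    labels = pd.Series(np.nan, index=cells.index, dtype=object)
    prepared = [(prep(poly), cls) for poly, cls in annotations]
    xs = cells["x_um"].to_numpy()
    ys = cells["y_um"].to_numpy()
    for i, idx in enumerate(cells.index):
        p = Point(xs[i], ys[i])
        for pr, cls in prepared:
            if pr.contains(p):
                labels.at[idx] = cls
                break
    return labels


@dataclass
class ClassifierModel:
    """Fitted random-forest tissue classifier with its feature manifest."""

    feature_names: list[str]
    classes: list[str]
    forest: RandomForestClassifier
    seed: int
    n_estimators: int
    oob_accuracy: float | None = None
    training_hash: str | None = None
    version: str = "1"
    extra: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """Store the forest as a binary with a sidecar text manifest."""
        import joblib

        path = Path(path)
        joblib.dump(self.forest, path)
        manifest = {
            "version": self.version,
            "feature_names": self.feature_names,
            "classes": self.classes,
            "seed": self.seed,
            "n_estimators": self.n_estimators,
            "oob_accuracy": self.oob_accuracy,
            "training_hash": self.training_hash,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(manifest, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        import joblib

        path = Path(path)
        manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            feature_names=manifest["feature_names"],
            classes=manifest["classes"],
            forest=joblib.load(path),
            seed=manifest["seed"],
            n_estimators=manifest["n_estimators"],
            oob_accuracy=manifest.get("oob_accuracy"),
            training_hash=manifest.get("training_hash"),
            version=manifest.get("version", "1"),
        )


def _feature_matrix(cells: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing = [f for f in feature_names if f not in cells.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = cells[feature_names].to_numpy(dtype=float)
    # forests cannot ingest NaN; impute with the column median
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            med = np.nanmedian(col) if np.isfinite(col).any() else 0.0
            col[bad] = med
    return X


def train_classifier(
    cells: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_estimators: int = 100,
    seed: int = 0,
    min_cells_per_class: int = 10,
    features: list[str] | None = None,
) -> ClassifierModel:
    """Fit the tissue random forest on all raw + smoothed features.

    Requires at least two classes; classes with fewer than
    ``min_cells_per_class`` cells raise a warning. Out-of-bag accuracy
    is recorded in the model manifest.
    """
    import warnings

    y = pd.Series(labels).reset_index(drop=True)
    cells = cells.reset_index(drop=True)
    keep = y.notna()
    cells, y = cells[keep.to_numpy()], y[keep]
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("training set contains fewer than two classes")
    small = counts[counts < min_cells_per_class]
    if len(small):
        warnings.warn(
            f"classes with < {min_cells_per_class} training cells: "
            f"{dict(small)}", stacklevel=2
        )
    if features is None:
        features = [f for f in RAW_FEATURES if f in cells.columns]
        features += [f"smoothed_{f}" for f in RAW_FEATURES if f"smoothed_{f}" in cells.columns]
    X = _feature_matrix(cells, list(features))
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y.to_numpy())
    digest = hashlib.sha256(
        np.ascontiguousarray(X).tobytes() + "".join(sorted(y)).encode()
    ).hexdigest()[:16]
    return ClassifierModel(
        feature_names=list(features),
        classes=[c for c in TISSUE_CLASSES if c in set(y)] +
                sorted(set(y) - set(TISSUE_CLASSES)),
        forest=forest,
        seed=seed,
        n_estimators=n_estimators,
        oob_accuracy=float(forest.oob_score_),
        training_hash=digest,
    )


def classify(model: ClassifierModel, cells: pd.DataFrame) -> pd.DataFrame:
    """Assign each cell its tissue class (forest majority vote, ties
    broken by the fixed tissue-class order) and carry the marker base
    class through unchanged."""
    df = cells.copy()
    if df.empty:
        df["tissue_class"] = pd.Series(dtype=object)
        return df
    X = _feature_matrix(df, model.feature_names)
    proba = model.forest.predict_proba(X)
    forest_classes = list(model.forest.classes_)
    order = [c for c in TISSUE_CLASSES if c in forest_classes]
    order += [c for c in forest_classes if c not in order]
    cols = [forest_classes.index(c) for c in order]
    pick = np.argmax(proba[:, cols], axis=1)  # argmax takes the first max: fixed order
    df["tissue_class"] = np.array(order, dtype=object)[pick]
    return df


def composite_class(cells: pd.DataFrame) -> pd.Series:
    """Composite (tissue, marker) label, e.g. ``Tumour:Positive``;
    unscored cells yield NaN."""
    out = cells["tissue_class"].astype(str) + ":" + cells["base_class"].astype(str)
    out[cells["base_class"] == UNSCORED] = np.nan
    return out
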