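"""Optical density transform, stain vectors and colour deconvolution.

Brightfield immunohistochemistry follows the Beer-Lambert law: each stain
attenuates transmitted light exponentially, so stain amounts combine
*additively* in optical density, OD = -log10(I / I0), per RGB channel.
Colour deconvolution inverts the resulting 3x3 linear mixing model to
recover per-stain concentration images (haematoxylin counterstain, DAB
chromogen, and a residual channel) from an RGB image.

The default stain matrix is the H-DAB calibration used throughout this
package: haematoxylin (0.67253, 0.56452, 0.47856), DAB
(0.25141, 0.41193, 0.87585), background white point (235, 232, 239).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_HEMATOXYLIN",
    "DEFAULT_DAB",
    "DEFAULT_BACKGROUND",
    "StainMatrix",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "estimate_stain_vectors",
]

DEFAULT_HEMATOXYLIN = (0.67253, 0.56452, 0.47856)
DEFAULT_DAB = (0.25141, 0.41193, 0.87585)
DEFAULT_BACKGROUND = (235.0, 232.0, 239.0)

_UNIT_NORM_TOL = 1e-4


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


@dataclass(frozen=True)
class StainMatrix:
    """Unit OD vectors for two stains plus an orthogonal residual.

    Rows of :attr:`matrix` are (stain1, stain2, residual); a pixel with
    concentrations ``c`` has OD vector ``c @ matrix``.
    """

    stain1: tuple[float, float, float] = DEFAULT_HEMATOXYLIN
    stain2: tuple[float, float, float] = DEFAULT_DAB
    residual: tuple[float, float, float] | None = None
    background_rgb: tuple[float, float, float] = DEFAULT_BACKGROUND
    stain_names: tuple[str, str] = ("hematoxylin", "dab")
    _matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        s1 = np.asarray(self.stain1, dtype=float)
        s2 = np.asarray(self.stain2, dtype=float)
        for name, v in (("stain1", s1), ("stain2", s2)):
            if abs(np.linalg.norm(v) - 1.0) > _UNIT_NORM_TOL:
                raise ValueError(f"{name} is not unit-norm: {v}")
        if self.residual is None:
            res = _unit(np.cross(s1, s2))
            object.__setattr__(self, "residual", tuple(float(v) for v in res))
        else:
            res = np.asarray(self.residual, dtype=float)
            if abs(np.linalg.norm(res) - 1.0) > _UNIT_NORM_TOL:
                raise ValueError(f"residual is not unit-norm: {res}")
        bg = np.asarray(self.background_rgb, dtype=float)
        if np.any(bg <= 0) or np.any(bg > 255):
            raise ValueError(f"background channels must lie in (0, 255]: {bg}")
        m = np.stack([s1, s2, res])
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "_matrix", m)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 array, rows = (stain1, stain2, residual)."""
        return self._matrix.copy()

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stain1": [float(v) for v in self.stain1],
            "stain2": [float(v) for v in self.stain2],
            "residual": [float(v) for v in self.residual],
            "background_rgb": [float(v) for v in self.background_rgb],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainMatrix":
        return cls(
            stain1=tuple(d["stain1"]),
            stain2=tuple(d["stain2"]),
            residual=tuple(d["residual"]) if d.get("residual") else None,
            background_rgb=tuple(d.get("background_rgb", DEFAULT_BACKGROUND)),
        )


def rgb_to_od(image: np.ndarray, background_rgb=DEFAULT_BACKGROUND) -> np.ndarray:
    """Convert an 8-bit RGB image to per-channel optical density.

    OD = -log10(max(I, 1) / I0) per channel, clamped at zero for pixels
    brighter than the white point. Intensity is clamped at 1 before the
    log so a zero pixel maps to the finite value log10(I0).
    """
    bg = np.asarray(background_rgb, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background channels must be positive")
    img = np.asarray(image, dtype=float)
    od = -np.log10(np.maximum(img, 1.0) / bg)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, background_rgb=DEFAULT_BACKGROUND) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`: intensity = I0 * 10**(-OD), as uint8."""
    bg = np.asarray(background_rgb, dtype=float)
    rgb = bg * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Unmix a 3-channel OD image into per-stain concentrations.

    Solves ``od = c @ M`` for ``c`` per pixel (M rows are the unit stain
    vectors) and clamps negative concentrations to zero — concentrations
    are physically non-negative; small negatives arise from noise and
    8-bit quantisation.

    Returns an array shaped like ``od`` with the last axis ordered
    (stain1, stain2, residual).
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValueError("deconvolve expects a 3-channel OD image")
    inv = np.linalg.inv(stains._matrix)
    conc = od @ inv
    return np.maximum(conc, 0.0)


def estimate_stain_vectors(
    image: np.ndarray,
    background_rgb=DEFAULT_BACKGROUND,
    od_floor: float = 0.15,
    percentile: float = 1.0,
    min_foreground: int = 100,
) -> StainMatrix:
    """Estimate the two dominant stain vectors from an RGB image.

    Angular-percentile method: foreground OD pixels (vector norm >=
    ``od_floor``) are projected onto the plane of their top two principal
    components; the directions at the ``percentile``-th and
    ``(100 - percentile)``-th angular percentiles are taken as the two
    stain vectors (the extreme directions of the OD point cloud belong to
    the purest pixels of each stain). The residual is their normalised
    cross product.

    The vector with the larger red-channel OD component is reported as
    haematoxylin (blue stains absorb red light most strongly), the other
    as DAB.

    Raises ``ValueError`` when there are fewer than ``min_foreground``
    foreground pixels, or when the foreground is effectively
    single-stain (angular spread < 3 degrees) so the second vector is
    ill-defined.
    """
    od = rgb_to_od(image, background_rgb).reshape(-1, 3)
    norms = np.linalg.norm(od, axis=1)
    fg = od[norms >= od_floor]
    if fg.shape[0] < min_foreground:
        raise ValueError(
            f"only {fg.shape[0]} foreground pixels above OD {od_floor}; "
            f"need at least {min_foreground}"
        )
    # principal plane of the OD cloud (directions through the origin)
    _, _, vt = np.linalg.svd(fg, full_matrices=False)
    basis = vt[:2]
    if np.sum(basis[0]) < 0:  # orient towards positive OD octant
        basis = -basis
    proj = fg @ basis.T
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [percentile, 100.0 - percentile])
    if np.degrees(hi - lo) < 3.0:
        raise ValueError(
            "angular spread of OD directions < 3 degrees: "
            "image appears to contain a single stain"
        )
    v_lo = np.cos(lo) * basis[0] + np.sin(lo) * basis[1]
    v_hi = np.cos(hi) * basis[0] + np.sin(hi) * basis[1]
    vecs = []
    for v in (v_lo, v_hi):
        if np.sum(v) < 0:
            v = -v
        vecs.append(_unit(np.maximum(v, 0.0)))
    # haematoxylin absorbs red more strongly than DAB does
    vecs.sort(key=lambda v: -v[0])
    return StainMatrix(
        stain1=tuple(vecs[0]), stain2=tuple(vecs[1]), background_rgb=tuple(np.asarray(background_rgb, float))
    )
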