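"""Receptor-space facial colorimetry.

Camera RGB measurements are mapped into modeled long-wave (LW) and
medium-wave (MW) receptor captures of a dichromatic-channel macaque
observer via an affine calibration fitted on a reflectance chart imaged
under the session's exposure.  Two outcomes summarize each face photo: the
red-green opponency ratio (LW-MW)/(LW+MW) and the achromatic luminance
(LW+MW)/2.

Note on the luminance formula: published shorthand sometimes prints it as
"MW+LW/2"; the mean capture (MW+LW)/2 is the standard achromatic channel
of the receptor-noise framework and is what this module computes.

Receptor sensitivities and the illuminant are user-supplied band weights;
the shipped default is a synthetic stand-in for testing only and encodes
no real macaque photoreceptor data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ReceptorModel:
    """Band-weight receptor model (3 camera bands: R, G, B).

    Weights are non-negative and normalized to unit peak.  Expected patch
    captures are sum_band reflectance * illuminant * sensitivity.
    """

    lw_weights: np.ndarray
    mw_weights: np.ndarray
    illuminant: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.lw_weights = np.asarray(self.lw_weights, dtype=float)
        self.mw_weights = np.asarray(self.mw_weights, dtype=float)
        self.illuminant = np.asarray(self.illuminant, dtype=float)
        for w in (self.lw_weights, self.mw_weights, self.illuminant):
            if (w < 0).any():
                raise ValueError("receptor/illuminant weights must be non-negative")
        self.lw_weights = self.lw_weights / self.lw_weights.max()
        self.mw_weights = self.mw_weights / self.mw_weights.max()

    def expected_captures(self, reflectance: np.ndarray) -> np.ndarray:
        """(n_patches, 2) LW/MW captures from per-band reflectances in [0,1]."""
        refl = np.asarray(reflectance, dtype=float)
        rad = refl * self.illuminant
        return np.column_stack([rad @ self.lw_weights, rad @ self.mw_weights])


#: Synthetic test model — NOT biological sensitivities.
SYNTHETIC_RECEPTOR_MODEL = ReceptorModel(
    lw_weights=np.array([1.0, 0.35, 0.05]),
    mw_weights=np.array([0.25, 1.0, 0.20]),
)


@dataclass
class ChartReference:
    """Calibration chart: known reflectances plus measured camera RGB."""

    patch_ids: list[str]
    reflectance: np.ndarray  # (n_patches, 3) in [0, 1]
    rgb: np.ndarray  # (n_patches, 3) measured under the session exposure

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.rgb = np.asarray(self.rgb, dtype=float)
        if len(self.patch_ids) < 4:
            raise ValueError("calibration needs at least 4 chart patches")
        if ((self.reflectance < 0) | (self.reflectance > 1)).any():
            raise ValueError("reflectances must lie in [0, 1]")
        if self.reflectance.shape != self.rgb.shape:
            raise ValueError("reflectance and rgb must have matching shapes")


def synthetic_colorchecker(n_patches: int = 24) -> tuple[list[str], np.ndarray]:
    """Deterministic synthetic 24-patch chart (ids, reflectance triples).

    A stand-in for a physical reflectance chart: a neutral ramp plus
    saturated and mixed chromatic patches spanning the RGB cube.  Synthetic;
    no real chart's reflectance data are reproduced.
    """
    greys = [[v, v, v] for v in np.linspace(0.05, 0.95, 6)]
    prim = [
        [0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8],
        [0.8, 0.8, 0.1], [0.8, 0.1, 0.8], [0.1, 0.8, 0.8],
    ]
    rng = np.random.default_rng(20130126)  # fixed: chart is a constant fixture
    mixed = rng.uniform(0.05, 0.95, size=(n_patches - len(greys) - len(prim), 3))
    refl = np.vstack([greys, prim, mixed])[:n_patches]
    ids = [f"patch{i + 1:02d}" for i in range(len(refl))]
    return ids, refl


@dataclass
class CalibrationMap:
    """Affine map camera RGB -> (LW, MW): captures = rgb @ A + b."""

    A: np.ndarray  # (3, 2)
    b: np.ndarray  # (2,)
    residual_rms: float

    def apply(self, rgb: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(rgb, dtype=float)) @ self.A + self.b


def fit_calibration(chart: ChartReference, model: ReceptorModel) -> CalibrationMap:
    """Ordinary-least-squares affine fit of chart RGB onto expected captures.

    Raises on a rank-deficient patch set (e.g. all-grey charts, which
    cannot pin down a 3-channel map).
    """
    target = model.expected_captures(chart.reflectance)
    X = np.column_stack([chart.rgb, np.ones(len(chart.rgb))])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("chart patch set is rank-deficient; add chromatic patches")
    coef, _, _, _ = np.linalg.lstsq(X, target, rcond=None)
    fitted = X @ coef
    rms = float(np.sqrt(np.mean((fitted - target) ** 2)))
    return CalibrationMap(A=coef[:3], b=coef[3], residual_rms=rms)


@dataclass
class ColorMeasurement:
    """One photo's modeled captures and derived color outcomes."""

    lw: float
    mw: float

    def __post_init__(self) -> None:
        if self.lw <= 0 or self.mw <= 0:
            raise ValueError("LW and MW captures must be positive")

    @property
    def rg_ratio(self) -> float:
        return (self.lw - self.mw) / (self.lw + self.mw)

    @property
    def luminance(self) -> float:
        return (self.lw + self.mw) / 2.0


def measure_face(region_rgb: np.ndarray, calibration: CalibrationMap) -> ColorMeasurement:
    """Map a face-region mean RGB through the session calibration."""
    lw, mw = calibration.apply(region_rgb)[0]
    if lw <= 0 or mw <= 0:
        raise ValueError(
            f"calibrated captures non-positive (LW={lw:.4g}, MW={mw:.4g}); "
            "check that the chart was imaged under the same exposure"
        )
    return ColorMeasurement(lw=float(lw), mw=float(mw))


def extract_region(image: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Mean linear RGB over a polygonal face region.

    ``image`` is (H, W, 3) linear RGB; ``polygon`` is (n, 2) vertices as
    (row, col).  Pixels inside the polygon are averaged arithmetically.
    """
    from skimage.draw import polygon as sk_polygon

    image = np.asarray(image, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if (poly < 0).any() or (poly[:, 0] > image.shape[0]).any() or (
        poly[:, 1] > image.shape[1]
    ).any():
        raise ValueError("polygon extends outside the image bounds")
    rr, cc = sk_polygon(poly[:, 0], poly[:, 1], shape=image.shape[:2])
    if rr.size == 0:
        raise ValueError("polygon mask is empty")
    return image[rr, cc].mean(axis=0)


def color_outcomes(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-photo analysis outcomes: log luminance and (untransformed) R/G.

    Input needs columns lw, mw (plus any id/period columns, carried
    through).  Luminance is log-transformed (it fits a lognormal well);
    the R/G ratio can be negative, so it is modeled on its natural scale.
    """
    df = measurements.copy()
    lw = df["lw"].to_numpy(dtype=float)
    mw = df["mw"].to_numpy(dtype=float)
    if (lw <= 0).any() or (mw <= 0).any():
        raise ValueError("non-positive LW/MW captures in measurements")
    df["rg_ratio"] = (lw - mw) / (lw + mw)
    df["luminance"] = (lw + mw) / 2.0
    df["log_luminance"] = np.log(df["luminance"])
    return df
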