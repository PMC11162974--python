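"""Per-seed trait extraction: morphometrics, UPOV size/shape/color classes,
RGB and mean-reflectance summaries, spectral transforms (logR, dR) and
pigment-sensitive vegetation indices (NDVI, ARI2, TCARI).

The vegetation indices read reflectance at fixed wavelengths (nearest band):

    NDVI  = (R800 - R680) / (R800 + R680)
    ARI2  = R800 * (1/R550 - 1/R700)
    TCARI = 3 * [(R700 - R670) - 0.2 * (R700 - R550) * (R700 / R670)]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_envi import Hypercube, RgbImage
from .segmentation import GRAY_WEIGHTS, SeedRegion
from .spectral_similarity import Spectrum

__all__ = [
    "SeedFeatures",
    "FeatureTable",
    "morphometrics",
    "classify_size",
    "classify_shape",
    "classify_color",
    "mean_rgb",
    "mean_reflectance",
    "log_transform",
    "first_derivative",
    "vegetation_indices",
    "build_feature_table",
    "SIZE_CLASSES",
    "SHAPE_CLASSES",
    "DEFAULT_COLOR_CENTROIDS",
]

SIZE_CLASSES = ("small", "medium", "large")
SHAPE_CLASSES = ("spherical", "spherical_flattened", "elongated",
                 "elongated_flattened")

# Synthetic reference centroids for the seven UPOV coat-color categories,
# chosen as representative RGB triplets (the published table reports only the
# two brown classes: medium brown [0.41, 0.32, 0.26], dark brown
# [0.39, 0.29, 0.24]). Users with rated collections should pass their own.
DEFAULT_COLOR_CENTROIDS = {
    "yellow": (0.82, 0.72, 0.45),
    "yellow_green": (0.70, 0.72, 0.42),
    "green": (0.45, 0.60, 0.35),
    "light_brown": (0.60, 0.45, 0.32),
    "medium_brown": (0.41, 0.32, 0.26),
    "dark_brown": (0.39, 0.29, 0.24),
    "black": (0.12, 0.10, 0.10),
}


@dataclass
class SeedFeatures:
    """Feature bundle for one segmented seed."""

    accession: str
    seed_id: int
    area_mm2: float
    height_mm: float
    width_mm: float
    thickness_mm: float | None = None
    weight_g: float | None = None
    rgb: tuple[float, float, float] | None = None
    gray: float | None = None
    mean_reflectance: Spectrum | None = None
    ndvi: float | None = None
    ari2: float | None = None
    tcari: float | None = None
    size_class: str | None = None
    shape_class: str | None = None
    color_class: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def wl_ratio(self) -> float:
        """Width/length (minor over major axis)."""
        return self.width_mm / self.height_mm

    @property
    def tw_ratio(self) -> float | None:
        """Thickness/width; needs a lateral-view measurement."""
        if self.thickness_mm is None:
            return None
        return self.thickness_mm / self.width_mm


def morphometrics(region: SeedRegion, mm_per_px: float) -> tuple[float, float, float]:
    """(area_mm2, height_mm, width_mm) from pixel measurements.

    Height is the major-axis length, width the minor-axis length; area scales
    with the square of the pixel pitch.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    area = region.area_px * mm_per_px ** 2
    height = region.major_axis_px * mm_per_px
    width = region.minor_axis_px * mm_per_px
    return float(area), float(height), float(width)


def classify_size(weight_g: float) -> str:
    """UPOV size class from single-seed weight: small < 0.13 g,
    medium 0.13-0.24 g (inclusive), large > 0.24 g."""
    if weight_g <= 0:
        raise ValueError("seed weight must be positive")
    if weight_g < 0.13:
        return "small"
    if weight_g <= 0.24:
        return "medium"
    return "large"


def classify_shape(wl_ratio: float, tw_ratio: float) -> str:
    """UPOV shape class from width/length and thickness/width ratios.

    spherical: W/L > 0.90 and T/W > 0.85; spherical_flattened: W/L > 0.90 and
    T/W <= 0.84 is the corrected flattened rule, extended to T/W <= 0.85 so the
    rules partition; elongated: W/L <= 0.90 and T/W > 0.85;
    elongated_flattened otherwise.
    """
    if wl_ratio <= 0 or tw_ratio <= 0:
        raise ValueError("ratios must be positive")
    round_seed = wl_ratio > 0.90
    tall = tw_ratio > 0.85
    if round_seed:
        return "spherical" if tall else "spherical_flattened"
    return "elongated" if tall else "elongated_flattened"


def classify_color(rgb: tuple[float, float, float],
                   centroids: dict[str, tuple[float, float, float]] | None = None
                   ) -> str:
    """Nearest-centroid coat-color naming in RGB space (a convenience; the
    reference workflow is majority vote of human raters)."""
    centroids = centroids or DEFAULT_COLOR_CENTROIDS
    rgb = np.asarray(rgb, dtype=np.float64)
    names = list(centroids)
    d = [np.linalg.norm(rgb - np.asarray(centroids[n])) for n in names]
    return names[int(np.argmin(d))]


def mean_rgb(rgb: RgbImage | np.ndarray, mask: np.ndarray
             ) -> tuple[tuple[float, float, float], float]:
    """Channel means over a mask plus the grayscale of the mean triplet."""
    data = rgb.data if isinstance(rgb, RgbImage) else np.asarray(rgb, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    triplet = tuple(float(v) for v in data[mask].mean(axis=0))
    gray = float(np.dot(GRAY_WEIGHTS, triplet))
    return triplet, gray


def mean_reflectance(cube: Hypercube, mask: np.ndarray) -> Spectrum:
    """Per-band mean reflectance over masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    return Spectrum(values=cube.data[mask].mean(axis=0),
                    wavelengths=cube.wavelengths.copy())


def log_transform(s, base: str | float = 10) -> np.ndarray:
    """Elementwise log reflectance (logR); base 10 by default."""
    v = s.values if isinstance(s, Spectrum) else np.asarray(s, dtype=np.float64)
    if np.any(v <= 0):
        raise ValueError("logR requires strictly positive reflectance")
    if base in (10, "10"):
        return np.log10(v)
    if base in ("e", np.e):
        return np.log(v)
    return np.log(v) / np.log(float(base))


def first_derivative(s, central: bool = False) -> np.ndarray:
    """First-derivative spectrum dR_i = (r_{i+2} - r_i) / dlam, length n-2.

    The divisor is the band interval dlam (set ``central=True`` for the
    conventional 2*dlam central difference). Band spacing must be uniform to
    within 1%.
    """
    if isinstance(s, Spectrum):
        v, wl = s.values, s.wavelengths
    else:
        v, wl = np.asarray(s, dtype=np.float64), None
    if v.size < 3:
        raise ValueError("need at least 3 bands for a derivative spectrum")
    if wl is not None:
        steps = np.diff(wl)
        dlam = float(steps.mean())
        if np.any(np.abs(steps - dlam) > 0.01 * dlam):
            raise ValueError("band spacing non-uniform beyond 1% tolerance")
    else:
        dlam = 1.0
    denom = 2.0 * dlam if central else dlam
    return (v[2:] - v[:-2]) / denom


def _reflectance_at(s: Spectrum, nm: float) -> float:
    if s.wavelengths is None:
        raise ValueError("spectrum needs a wavelength axis for index lookup")
    lo, hi = s.wavelengths[0], s.wavelengths[-1]
    if not (lo <= nm <= hi):
        raise ValueError(f"required wavelength {nm} nm outside span [{lo}, {hi}]")
    return float(s.values[int(np.argmin(np.abs(s.wavelengths - nm)))])


def vegetation_indices(s: Spectrum) -> tuple[float, float, float]:
    """(NDVI, ARI2, TCARI) from nearest-band reflectance."""
    r550 = _reflectance_at(s, 550.0)
    r670 = _reflectance_at(s, 670.0)
    r680 = _reflectance_at(s, 680.0)
    r700 = _reflectance_at(s, 700.0)
    r800 = _reflectance_at(s, 800.0)
    if r800 + r680 == 0:
        raise ValueError("zero denominator in NDVI")
    if r550 == 0 or r700 == 0 or r670 == 0:
        raise ValueError("zero reflectance at an index wavelength")
    ndvi = (r800 - r680) / (r800 + r680)
    ari2 = r800 * (1.0 / r550 - 1.0 / r700)
    tcari = 3.0 * ((r700 - r670) - 0.2 * (r700 - r550) * (r700 / r670))
    return float(ndvi), float(ari2), float(tcari)


@dataclass
class FeatureTable:
    """Seeds x predictors matrix with class labels and a layout manifest."""

    frame: pd.DataFrame
    predictor_names: list[str]
    class_labels: np.ndarray
    manifest: dict = field(default_factory=dict)

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)

    def matrix(self) -> np.ndarray:
        return self.frame[self.predictor_names].to_numpy(dtype=np.float64)


def build_feature_table(seeds: list[SeedFeatures], *, include_logR: bool = False,
                        include_dR: bool = False) -> FeatureTable:
    """Assemble the predictor table.

    Default layout: morphology (area, height, width, thickness, wl_ratio,
    tw_ratio, weight when present) + RGB triplet + gray + one column per
    retained band of the mean reflectance + the three vegetation indices.
    Optional logR / dR blocks append transformed spectra. Missing thickness or
    weight columns are NaN-marked and dropped from the predictor list if
    absent for every seed.
    """
    if not seeds:
        raise ValueError("empty seed list")
    wl = None
    for s in seeds:
        if s.mean_reflectance is not None:
            w = s.mean_reflectance.wavelengths
            if wl is None:
                wl = w
            elif w is None or w.size != wl.size or not np.allclose(w, wl):
                raise ValueError("seeds do not share one wavelength grid")

    rows = []
    for s in seeds:
        row: dict[str, float] = {
            "area_mm2": s.area_mm2, "height_mm": s.height_mm,
            "width_mm": s.width_mm,
            "thickness_mm": np.nan if s.thickness_mm is None else s.thickness_mm,
            "wl_ratio": s.wl_ratio,
            "tw_ratio": np.nan if s.tw_ratio is None else s.tw_ratio,
            "weight_g": np.nan if s.weight_g is None else s.weight_g,
        }
        if s.rgb is not None:
            row.update(R=s.rgb[0], G=s.rgb[1], B=s.rgb[2])
            row["gray"] = s.gray
        if s.mean_reflectance is not None:
            spec = s.mean_reflectance
            for w, v in zip(spec.wavelengths, spec.values):
                row[f"refl_{w:.0f}nm"] = v
            if include_logR:
                for w, v in zip(spec.wavelengths, log_transform(spec)):
                    row[f"logR_{w:.0f}nm"] = v
            if include_dR:
                dr = first_derivative(spec)
                for w, v in zip(spec.wavelengths[1:-1], dr):
                    row[f"dR_{w:.0f}nm"] = v
        for name, val in (("ndvi", s.ndvi), ("ari2", s.ari2), ("tcari", s.tcari)):
            if val is not None:
                row[name] = val
        rows.append(row)

    frame = pd.DataFrame(rows)
    frame.insert(0, "accession", [s.accession for s in seeds])
    frame.insert(1, "seed_id", [s.seed_id for s in seeds])
    predictors = [c for c in frame.columns if c not in ("accession", "seed_id")
                  and not frame[c].isna().all()]
    manifest = {
        "n_predictors": len(predictors),
        "blocks": {
            "morphology": [p for p in predictors if p in (
                "area_mm2", "height_mm", "width_mm", "thickness_mm",
                "wl_ratio", "tw_ratio", "weight_g")],
            "rgb": [p for p in predictors if p in ("R", "G", "B", "gray")],
            "reflectance": [p for p in predictors if p.startswith("refl_")],
            "logR": [p for p in predictors if p.startswith("logR_")],
            "dR": [p for p in predictors if p.startswith("dR_")],
            "indices": [p for p in predictors if p in ("ndvi", "ari2", "tcari")],
        },
        "wavelengths_nm": [] if wl is None else [float(w) for w in wl],
    }
    return FeatureTable(frame=frame, predictor_names=predictors,
                        class_labels=frame["accession"].to_numpy(),
                        manifest=manifest)
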