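"""AFM topography quantification: plane flattening, feature segmentation,
per-feature morphometry and oligomer/fibril/amorphous classification.

Heights are reported as the per-feature maximum for compact features (caps,
blobs) and as the crest mean (mean of the per-transect maxima along the major
axis) for elongated fibrils.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage import measure as skmeasure

__all__ = [
    "Topograph",
    "Feature",
    "ClassifierConfig",
    "flatten",
    "segment",
    "measure",
    "classify",
    "analyze_topograph",
    "timecourse_summary",
]


@dataclass
class Topograph:
    """2-D height grid (nm) with a pixel size (nm/px) and free-form metadata
    (condition, incubation-time label, ...)."""

    heights: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class Feature:
    """One segmented surface feature; lengths in nm, area in nm²."""

    area: float
    max_height: float
    mean_height: float
    crest_height: float  # mean of per-transect maxima along the major axis
    length: float
    width: float
    aspect_ratio: float
    feature_class: str = ""
    centroid: tuple[float, float] = (np.nan, np.nan)  # (row, col) px

    @property
    def representative_height(self) -> float:
        """Crest mean for fibrils, per-feature maximum otherwise."""
        return self.crest_height if self.feature_class == "fibril" else self.max_height


@dataclass(frozen=True)
class ClassifierConfig:
    """Morphology class thresholds (kept in config, not code, so they can be
    tuned per data set)."""

    fibril_min_aspect: float = 5.0
    fibril_min_length_nm: float = 100.0
    amorphous_min_height_nm: float = 6.0
    amorphous_min_area_nm2: float = 1.0e4


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------

def flatten(topo: Topograph, order: int = 1) -> Topograph:
    """Remove the background plane (order 1) or offset (order 0).

    The background is fitted by least squares on pixels below
    median + 1 SD — a feature-exclusion mask that avoids pulling the plane up
    over aggregates — and refined once on the residual background. After
    subtraction the background mean is ≈ 0.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    h = topo.heights
    ny, nx = h.shape
    Y, X = np.mgrid[0:ny, 0:nx]

    def fit_plane(mask):
        if order == 0:
            return np.full_like(h, np.mean(h[mask]))
        A = np.column_stack([X[mask], Y[mask], np.ones(mask.sum())])
        coef, *_ = np.linalg.lstsq(A, h[mask], rcond=None)
        return coef[0] * X + coef[1] * Y + coef[2]

    mask = h < np.median(h) + np.std(h)
    bg = fit_plane(mask)
    resid = h - bg
    # refine on background only: a 3-sigma (robust) cut keeps essentially all
    # background pixels, so the plane is not biased by noise truncation
    sd_bg = 1.4826 * np.median(np.abs(resid[mask] - np.median(resid[mask])))
    mask = resid < np.median(resid) + 3.0 * max(sd_bg, 1e-12)
    bg = fit_plane(mask)
    out = h - bg
    return Topograph(out, topo.pixel_size, dict(topo.metadata))


def background_sd(topo: Topograph) -> float:
    """Robust (MAD) noise SD of the flattened background."""
    h = topo.heights
    med = np.median(h)
    return float(1.4826 * np.median(np.abs(h - med)))


# ---------------------------------------------------------------------------
# Segmentation and measurement
# ---------------------------------------------------------------------------

def segment(topo: Topograph, threshold_nm: float | None = None,
            min_pixels: int = 4) -> list[np.ndarray]:
    """Connected components above the height threshold, as boolean masks.

    Default threshold: 3 × background SD, but at least 0.5 nm. Components with
    fewer than ``min_pixels`` pixels are discarded.
    """
    if threshold_nm is None:
        threshold_nm = max(3.0 * background_sd(topo), 0.5)
    if threshold_nm <= 0:
        raise ValueError("threshold must be positive")
    labels = skmeasure.label(topo.heights > threshold_nm, connectivity=2)
    masks = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if m.sum() >= min_pixels:
            masks.append(m)
    return masks


def _crest_height(mask: np.ndarray, heights: np.ndarray,
                  orientation: float) -> float:
    """Mean of the per-transect maxima along the feature's major axis.

    Pixels are projected onto the major axis (skimage orientation convention:
    angle of the major axis from the vertical/row axis), binned per pixel of
    arc length, and the maximum height per bin averaged.
    """
    rows, cols = np.nonzero(mask)
    # unit vector along the major axis in (row, col) coordinates
    ur, uc = np.cos(orientation), np.sin(orientation)
    t = rows * ur + cols * uc
    bins = np.round(t - t.min()).astype(int)
    hvals = heights[rows, cols]
    out = np.full(bins.max() + 1, -np.inf)
    np.maximum.at(out, bins, hvals)
    return float(np.mean(out[np.isfinite(out)]))


def _despeckled_max(mask: np.ndarray, h: np.ndarray) -> float:
    """Peak height read from a 3×3-median despeckled crop.

    A raw max over the mask rides on the upper tail of the pixel noise; the
    median filter suppresses that bias with minimal peak attenuation. Features
    smaller than the filter window fall back to the raw maximum.
    """
    if mask.sum() < 9:
        return float(np.max(h[mask]))
    rows, cols = np.nonzero(mask)
    r0, r1 = max(rows.min() - 1, 0), min(rows.max() + 2, h.shape[0])
    c0, c1 = max(cols.min() - 1, 0), min(cols.max() + 2, h.shape[1])
    med = median_filter(h[r0:r1, c0:c1], size=3)
    return float(np.max(med[mask[r0:r1, c0:c1]]))


def measure(mask: np.ndarray, topo: Topograph,
            classifier: ClassifierConfig | None = None) -> Feature:
    """Morphometry of one segmented feature: heights, principal-axis length
    and width, aspect ratio, and class."""
    if not np.any(mask):
        raise ValueError("empty feature mask")
    px = topo.pixel_size
    h = topo.heights
    props = skmeasure.regionprops(mask.astype(np.uint8), intensity_image=h)[0]
    # end-to-end (max Feret) length; the moment-based major axis overshoots
    # rod-like shapes by ~15 %
    length = max(props.feret_diameter_max, 1.0) * px
    width = max(props.axis_minor_length, 1.0) * px
    feat = Feature(
        area=float(props.area) * px * px,
        max_height=_despeckled_max(mask, h),
        mean_height=float(np.mean(h[mask])),
        crest_height=_crest_height(mask, h, props.orientation),
        length=float(length),
        width=float(width),
        aspect_ratio=float(length / width),
        centroid=tuple(props.centroid),
    )
    feat.feature_class = classify(feat, classifier)
    return feat


def classify(feature: Feature,
             config: ClassifierConfig | None = None) -> str:
    """Deterministic, total three-way morphology rule.

    fibril: elongated (aspect ratio ≥ 5) and long (≥ 100 nm);
    amorphous: tall (≥ 6 nm), compact, and large (≥ 1e4 nm²);
    oligomer: everything else.
    """
    c = config or ClassifierConfig()
    if (feature.aspect_ratio >= c.fibril_min_aspect
            and feature.length >= c.fibril_min_length_nm):
        return "fibril"
    if (feature.max_height >= c.amorphous_min_height_nm
            and feature.aspect_ratio < c.fibril_min_aspect
            and feature.area >= c.amorphous_min_area_nm2):
        return "amorphous"
    return "oligomer"


def analyze_topograph(topo: Topograph, threshold_nm: float | None = None,
                      classifier: ClassifierConfig | None = None,
                      flatten_order: int = 1) -> list[Feature]:
    """flatten → segment → measure/classify for one image."""
    flat = flatten(topo, order=flatten_order)
    return [measure(m, flat, classifier) for m in segment(flat, threshold_nm)]


# ---------------------------------------------------------------------------
# Time course
# ---------------------------------------------------------------------------

def timecourse_summary(labeled: list[tuple[str, str, Topograph]],
                       threshold_nm: float | None = None,
                       classifier: ClassifierConfig | None = None
                       ) -> pd.DataFrame:
    """Per-(condition, time) class counts and mean representative heights.

    ``labeled`` is a list of (condition, time_label, topograph). Returns a
    DataFrame with one row per label pair and columns n_<class> and
    mean_height_<class>_nm.
    """
    classes = ("oligomer", "fibril", "amorphous")
    rows = []
    keys = sorted({(c, t) for c, t, _ in labeled})
    for cond, time in keys:
        feats: list[Feature] = []
        for c, t, topo in labeled:
            if (c, t) == (cond, time):
                feats.extend(analyze_topograph(topo, threshold_nm, classifier))
        row: dict = {"condition": cond, "time": time}
        for cls in classes:
            sel = [f for f in feats if f.feature_class == cls]
            row[f"n_{cls}"] = len(sel)
            row[f"mean_height_{cls}_nm"] = (
                float(np.mean([f.representative_height for f in sel]))
                if sel else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
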