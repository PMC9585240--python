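"""Myelinated-fiber segmentation and morphometry of cross-section images.

The segmentation follows threshold-based particle analysis: contrast
normalization, a three-level intensity partition (dark myelin / light
axoplasm / mid background), hole-filling of the myelin annuli, connected
components, and area/circularity filters.  Per fiber we measure the
area-equivalent outer diameter (myelin included — the convention is
recorded in the output column name), the centroid, and the Euclidean
distance from the centroid to the epineurium boundary polygon.  A
Table-1-style summary and the diameter-vs-distance ordinary least
squares regression complete the pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import Point, Polygon
from skimage import measure
from skimage.filters import threshold_multiotsu

__all__ = [
    "SegmentationParams",
    "MorphometrySummary",
    "segment_fibers",
    "measure_fibers",
    "classify_size",
    "summarize",
    "diameter_distance_regression",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the particle-analysis segmentation."""

    contrast_percentiles: tuple[float, float] = (1.0, 99.0)
    min_area_px: int = 3
    max_area_px: Optional[int] = None  # default: 1% of the image
    # digital perimeters overestimate circularity for few-pixel disks
    # (a 3x3 disk measures ~1.8), so no upper bound by default
    circularity: tuple[float, float] = (0.3, float("inf"))
    thresholds: Optional[tuple[float, float]] = None  # normalized; None = multi-Otsu


@dataclass
class MorphometrySummary:
    """Morphometric parameters of one nerve cross-section."""

    nerve_area_um2: float
    nerve_diameter_um: float
    myelinated_count: int
    density_per_mm2: float
    median_diameter_um: float
    large_count: int
    large_density_per_mm2: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def segment_fibers(
    image: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> np.ndarray:
    """Label myelinated fibers (filled outer profiles) in a grayscale image.

    Returns an integer label map; 0 is background.  A blank or saturated
    image yields zero labels with a warning.
    """
    import warnings

    if image.ndim != 2:
        raise ValueError("expected a single-channel image")
    img = image.astype(float)
    lo, hi = np.percentile(img, params.contrast_percentiles)
    if hi <= lo:
        warnings.warn("blank or saturated image; no fibers found")
        return np.zeros(image.shape, dtype=np.int32)
    img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)

    if params.thresholds is not None:
        t_dark, _ = params.thresholds
    else:
        try:
            t_dark, _ = threshold_multiotsu(img, classes=3)
        except ValueError:
            # degenerate (two-level) image: fall back to binary Otsu
            from skimage.filters import threshold_otsu

            t_dark = threshold_otsu(img)
    myelin = img <= t_dark

    max_area = params.max_area_px or int(0.01 * image.size)
    # drop oversized dark structures (epineurium rim) BEFORE hole filling,
    # otherwise the filled rim swallows the whole nerve interior
    lab0, n0 = ndimage.label(myelin)
    if n0:
        sizes = np.bincount(lab0.ravel())
        big = np.where(sizes > max_area)[0]
        big = big[big != 0]
        if big.size:
            myelin[np.isin(lab0, big)] = False
    # bridge 1-px rasterization breaks in thin annuli before filling;
    # 4-connected (cross) closing avoids fusing fibers across tight gaps
    myelin = ndimage.binary_closing(
        myelin, structure=ndimage.generate_binary_structure(2, 1)
    )
    filled = ndimage.binary_fill_holes(myelin)

    labels = measure.label(filled, connectivity=2)
    props = measure.regionprops(labels)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for p in props:
        if p.area < params.min_area_px or p.area > max_area:
            continue
        per = p.perimeter if p.perimeter > 0 else 1.0
        circ = 4.0 * math.pi * p.area / per**2
        if not (params.circularity[0] <= circ <= params.circularity[1]):
            continue
        keep[p.label] = True
    out = np.where(keep[labels], labels, 0)
    return measure.label(out > 0, connectivity=2).astype(np.int32)


def measure_fibers(
    labels: np.ndarray,
    pixel_size: float,
    boundary: np.ndarray,
    origin: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Per-fiber morphometrics from a label map.

    ``boundary`` is the epineurium polygon in µm; ``origin`` maps pixel
    indices to the polygon's coordinate frame (µm of pixel (0,0) corner).
    Diameters are area-equivalent outer diameters d = 2·√(area/π), in µm.
    """
    if boundary is None:
        raise ValueError("boundary polygon is required")
    ring = Polygon(boundary).exterior
    props = measure.regionprops(labels)
    rows = []
    for p in props:
        cx = origin[0] + (p.centroid[0] + 0.5) * pixel_size
        cy = origin[1] + (p.centroid[1] + 0.5) * pixel_size
        d = 2.0 * math.sqrt(p.area / math.pi) * pixel_size
        rows.append(
            {
                "id": p.label,
                "x_um": cx,
                "y_um": cy,
                "diameter_um": d,
                "distance_to_epineurium_um": float(ring.distance(Point(cx, cy))),
                "size_class": "unset",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "x_um", "y_um", "diameter_um",
            "distance_to_epineurium_um", "size_class",
        ],
    )


def classify_size(
    records: pd.DataFrame, threshold: Union[float, str] = "median"
) -> pd.DataFrame:
    """Label fibers large/small by a diameter threshold.

    ``threshold="median"`` uses the table's own median; large means
    strictly greater than the threshold (ties are small).
    """
    if records.empty:
        raise ValueError("empty fiber table")
    thr = (
        float(records["diameter_um"].median())
        if isinstance(threshold, str) and threshold == "median"
        else float(threshold)
    )
    out = records.copy()
    out["size_class"] = np.where(out["diameter_um"] > thr, "large", "small")
    return out


def summarize(
    records: pd.DataFrame, boundary: np.ndarray, pixel_size: float
) -> MorphometrySummary:
    """Table-style summary: nerve area/diameter, counts, densities, median."""
    poly = Polygon(boundary)
    area = float(poly.area)
    if area <= 0:
        raise ValueError("degenerate boundary polygon")
    area_mm2 = area * 1e-6
    n = len(records)
    if "size_class" in records and (records["size_class"] != "unset").any():
        n_large = int((records["size_class"] == "large").sum())
    else:
        n_large = 0
    return MorphometrySummary(
        nerve_area_um2=area,
        nerve_diameter_um=2.0 * math.sqrt(area / math.pi),
        myelinated_count=n,
        density_per_mm2=n / area_mm2,
        median_diameter_um=float(records["diameter_um"].median()) if n else float("nan"),
        large_count=n_large,
        large_density_per_mm2=n_large / area_mm2,
    )


def diameter_distance_regression(records: pd.DataFrame, ci: float = 0.95) -> dict:
    """OLS of diameter on distance-to-epineurium with a t-based slope CI."""
    if len(records) < 3:
        raise ValueError("need at least 3 fibers")
    x = records["distance_to_epineurium_um"].to_numpy(float)
    y = records["diameter_um"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in distance")
    res = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.5 + ci / 2.0, dof)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "slope_ci95": (
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        "stderr": float(res.stderr),
        "r_value": float(res.rvalue),
        "n": int(len(x)),
    }
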