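"""Section-based morphometry: volumetry, cortical thickness, cell density.

Volume follows the serial-section (Cavalieri-style) estimator: the summed
cross-sectional area (mm^2) times the slice thickness (40 um) times the
sampling interval (every 5th section).  Cortical thickness is averaged
over three measurement points (dorsal, lateral, ventral) per hemisphere
across seven consecutive slices.  Cell counting thresholds the grayscale
image to an inclusive [low, high] band, optionally separates touching
particles with a distance-transform watershed (the 1-pixel divide-line
approach), and filters connected components by pixel area and circularity
4*pi*A/P^2 before counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, measure, segmentation
from skimage.color import rgb2gray

__all__ = [
    "SectionSet",
    "ParticleCountResult",
    "estimate_volume",
    "mean_section_area",
    "impute_missing_sections",
    "aggregate_thickness",
    "count_particles",
    "cell_density",
    "ROI_AREAS_MM2",
]

#: Standard cortical ROI areas (mm^2) for density normalisation.
ROI_AREAS_MM2 = {"dorsal": 0.352, "lateral": 0.30}

#: Expected section counts per structure under the standard protocol.
_EXPECTED_SECTIONS = {"cortex": 8, "dhpc": 4}

#: A brain with this many missing sections or more is rejected.
MAX_MISSING_SECTIONS = 3


@dataclass
class SectionSet:
    """Ordered per-section areas (mm^2, post-shrinkage) for one structure.

    Missing/damaged sections are NaN; ``structure`` ('cortex' or 'dhpc')
    only drives the expected-count warning.
    """

    areas_mm2: np.ndarray
    slice_thickness_um: float = 40.0
    sampling_interval: int = 5
    structure: Optional[str] = None
    bregma_range_mm: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        if self.areas_mm2.ndim != 1 or len(self.areas_mm2) == 0:
            raise ValueError("areas must be a non-empty 1-D sequence")
        if np.nanmin(self.areas_mm2, initial=0.0) < 0:
            raise ValueError("section areas must be non-negative")
        if self.slice_thickness_um <= 0 or self.sampling_interval <= 0:
            raise ValueError("thickness and sampling interval must be positive")
        if self.structure is not None:
            expected = _EXPECTED_SECTIONS.get(self.structure.lower())
            if expected is not None and len(self.areas_mm2) != expected:
                warnings.warn(
                    f"{self.structure}: {len(self.areas_mm2)} sections "
                    f"(protocol uses {expected})",
                    stacklevel=2,
                )


def impute_missing_sections(sections: SectionSet) -> SectionSet:
    """Fill missing sections with the mean of their flanking sections.

    Only isolated interior gaps can be imputed (the flanking mean is
    undefined for runs or edge sections), and a brain missing
    ``MAX_MISSING_SECTIONS`` or more sections is rejected outright.
    """
    areas = sections.areas_mm2.copy()
    missing = np.isnan(areas)
    n_missing = int(missing.sum())
    if n_missing == 0:
        return sections
    if n_missing >= MAX_MISSING_SECTIONS:
        raise ValueError(
            f"{n_missing} missing sections; at most "
            f"{MAX_MISSING_SECTIONS - 1} can be tolerated"
        )
    for i in np.nonzero(missing)[0]:
        if i == 0 or i == len(areas) - 1:
            raise ValueError(f"cannot impute edge section {i} (no flanking pair)")
        if missing[i - 1] or missing[i + 1]:
            raise ValueError(
                "cannot impute consecutive missing sections "
                f"around index {i}"
            )
        areas[i] = (areas[i - 1] + areas[i + 1]) / 2.0
    return SectionSet(
        areas_mm2=areas,
        slice_thickness_um=sections.slice_thickness_um,
        sampling_interval=sections.sampling_interval,
        structure=sections.structure,
        bregma_range_mm=sections.bregma_range_mm,
    )


def estimate_volume(sections: SectionSet) -> float:
    """Structure volume in mm^3: sum(areas) x slice thickness x interval."""
    filled = impute_missing_sections(sections)
    thickness_mm = filled.slice_thickness_um / 1000.0
    return float(np.sum(filled.areas_mm2)) * thickness_mm * filled.sampling_interval


def mean_section_area(sections: SectionSet) -> float:
    """Average cross-sectional area (mm^2) after imputation."""
    filled = impute_missing_sections(sections)
    return float(np.mean(filled.areas_mm2))


# ---------------------------------------------------------------------------
# cortical thickness


def aggregate_thickness(records: pd.DataFrame, by: str = "overall") -> pd.Series | float:
    """Mean cortical thickness (mm) at the requested grouping.

    ``records`` is tidy with columns ``slice``, ``hemisphere``, ``point``
    (dorsal/lateral/ventral) and ``thickness_mm``; up to six measurements
    per section (three points per hemisphere).  Missing cells are simply
    absent rows and are excluded from the means.  ``by`` is one of
    'overall', 'point', 'hemisphere'.
    """
    required = {"thickness_mm"}
    if not required.issubset(records.columns):
        raise ValueError("records need a thickness_mm column")
    vals = records["thickness_mm"].dropna()
    if (vals <= 0).any():
        raise ValueError("thickness values must be positive")
    if by == "overall":
        return float(vals.mean())
    if by in ("point", "hemisphere"):
        return records.dropna(subset=["thickness_mm"]).groupby(by)[
            "thickness_mm"
        ].mean()
    raise ValueError("by must be 'overall', 'point', or 'hemisphere'")


# ---------------------------------------------------------------------------
# particle counting


@dataclass
class ParticleCountResult:
    """Cell count and density for one ROI image."""

    count: int
    roi_area_mm2: Optional[float] = None
    filter_settings: dict = field(default_factory=dict)
    labels: Optional[np.ndarray] = None

    @property
    def density_per_mm2(self) -> Optional[float]:
        if self.roi_area_mm2 is None:
            return None
        return self.count / self.roi_area_mm2


def _to_grayscale_8bit(image: np.ndarray) -> np.ndarray:
    """RGB -> grayscale, rescaled to the 0-255 threshold scale."""
    img = np.asarray(image)
    if img.ndim == 3:
        if img.shape[2] not in (3, 4):
            raise ValueError("expected an RGB(A) or single-channel image")
        img = rgb2gray(img[:, :, :3]) * 255.0
    elif img.ndim != 2:
        raise ValueError("expected a 2-D or 3-D image array")
    img = np.asarray(img, dtype=float)
    if img.max() > 255.0:  # 16-bit input: rescale onto the 8-bit band scale
        img = img / 257.0
    return img


def _watershed_split(mask: np.ndarray) -> np.ndarray:
    """Label particles, splitting touching ones by watershed.

    Markers are the local maxima of the (lightly smoothed) Euclidean
    distance transform — one per convex blob core — and the watershed
    carves a 1-pixel divide line between merged particles.  Returns the
    watershed label image (the divide line itself is background).
    """
    eight = np.ones((3, 3), dtype=int)
    labels, _ = ndi.label(mask, structure=eight)
    dist = ndi.distance_transform_edt(mask)
    # smoothing removes plateau/ridge ties so a lone disk keeps one maximum
    dist_s = ndi.gaussian_filter(dist, sigma=1.0)
    coords = feature.peak_local_max(dist_s, min_distance=5, labels=labels,
                                    exclude_border=False)
    marker_mask = np.zeros_like(mask, dtype=bool)
    marker_mask[tuple(coords.T)] = True
    markers, _ = ndi.label(marker_mask, structure=eight)
    return segmentation.watershed(-dist, markers, mask=mask, watershed_line=True)


def count_particles(
    image: np.ndarray,
    low: float = 90.0,
    high: float = 180.0,
    size_px: tuple[float, float] = (0.0, math.inf),
    circularity: tuple[float, float] = (0.0, 1.0),
    watershed: bool = True,
    roi_area_mm2: Optional[float] = None,
) -> ParticleCountResult:
    """Count stained particles in a grayscale (or RGB) ROI image.

    Pixels with intensity inside the inclusive ``[low, high]`` band form
    the particle mask; ``watershed=True`` separates merged particles;
    components are then filtered by pixel area and circularity
    (4*pi*A/P^2, clamped at 1.0 as digital perimeters can overshoot).
    """
    if low > high:
        raise ValueError("low threshold exceeds high threshold")
    img = _to_grayscale_8bit(image)
    mask = (img >= low) & (img <= high)
    if watershed and mask.any():
        labels = _watershed_split(mask)
    else:
        labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    count = 0
    kept = []
    for region in measure.regionprops(labels):
        area = region.area
        if not (size_px[0] <= area <= size_px[1]):
            continue
        perim = region.perimeter
        circ = 1.0 if perim == 0 else min(4.0 * math.pi * area / perim ** 2, 1.0)
        if not (circularity[0] <= circ <= circularity[1]):
            continue
        count += 1
        kept.append(region.label)
    out_labels = np.where(np.isin(labels, kept), labels, 0)
    return ParticleCountResult(
        count=count,
        roi_area_mm2=roi_area_mm2,
        filter_settings={
            "low": low, "high": high, "size_px": tuple(size_px),
            "circularity": tuple(circularity), "watershed": watershed,
        },
        labels=out_labels,
    )


def cell_density(result: ParticleCountResult, roi_area_mm2: Optional[float] = None) -> float:
    """Cells per mm^2 for a counted ROI."""
    area = roi_area_mm2 if roi_area_mm2 is not None else result.roi_area_mm2
    if area is None or area <= 0:
        raise ValueError("a positive ROI area is required")
    return result.count / area
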