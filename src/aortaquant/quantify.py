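"""Per-cross-section measurements, profile smoothing, regional summaries,
dilation detection, and measurement calibration.

Maximal diameter is the Feret diameter of the largest 4-connected
component of a slice — the largest pairwise distance between boundary
pixel centers, computed with a convex hull plus rotating calipers.
Profiles are smoothed with a Savitzky-Golay filter (least-squares
polynomial fit per window, solved from the normal equations) before
summary statistics are taken.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .straighten import StraightenedVolume

__all__ = [
    "CrossSectionProfile", "SegmentSpec", "QuantReport", "Calibration",
    "slice_area", "slice_max_diameter", "profile_from_straightened",
    "smooth_profile", "subdivide_segments", "summarize_segments",
    "detect_dilation", "calibrate_measurements", "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = {"ascending": 40.0, "arch": 35.0, "descending": 30.0}

SEGMENTS = ("ascending", "arch", "descending")

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class CrossSectionProfile:
    """Raw and smoothed diameter/area sequences indexed by arc length."""

    arclength: np.ndarray        # (N,) mm
    diameter_raw: np.ndarray     # (N,) mm
    diameter_smooth: np.ndarray  # (N,) mm
    area_raw: np.ndarray         # (N,) mm^2
    area_smooth: np.ndarray      # (N,) mm^2
    truncated: np.ndarray        # (N,) bool, endpoint-truncated slices

    def __post_init__(self):
        lengths = {len(self.arclength), len(self.diameter_raw),
                   len(self.diameter_smooth), len(self.area_raw),
                   len(self.area_smooth), len(self.truncated)}
        if len(lengths) != 1:
            raise ValueError("profile channel lengths differ")

    def __len__(self):
        return len(self.arclength)

    def to_csv(self, path, segments=None) -> None:
        import pandas as pd

        df = pd.DataFrame({
            "arclength_mm": self.arclength,
            "diameter_raw": self.diameter_raw,
            "diameter_smooth": self.diameter_smooth,
            "area_raw": self.area_raw,
            "area_smooth": self.area_smooth,
            "segment": segments if segments is not None else [""] * len(self),
            "truncated": self.truncated.astype(int),
        })
        df.to_csv(path, index=False, float_format="%.6f")


@dataclass(frozen=True)
class SegmentSpec:
    """Arc-length positions of the two landmark branch origins.

    Convention: ascending = [0, s_bct), arch = [s_bct, s_lsa],
    descending = (s_lsa, end].
    """

    s_bct: float
    s_lsa: float

    def __post_init__(self):
        if not 0 < self.s_bct < self.s_lsa:
            raise ValueError(
                f"need 0 < s_bct < s_lsa, got s_bct={self.s_bct}, s_lsa={self.s_lsa}")


@dataclass
class QuantReport:
    """Per-segment summary statistics and dilation flags."""

    segments: dict               # name -> {max/mean/median diameter & area}
    dilated: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"segments": self.segments, "dilated": self.dilated,
                "thresholds": self.thresholds}

    def to_json(self, path=None, extra=None) -> str:
        doc = self.to_dict()
        if extra:
            doc.update(extra)
        payload = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _largest_component(slice_mask: np.ndarray) -> np.ndarray | None:
    mask = np.asarray(slice_mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("slice mask must be 2D")
    if not mask.any():
        return None
    labels, n = ndimage.label(mask, structure=_STRUCT4)
    if n == 1:
        return mask
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def slice_area(slice_mask, pixel_mm: float = 1.0) -> float:
    """Area (mm^2) of the largest 4-connected component; 0 if empty."""
    comp = _largest_component(slice_mask)
    if comp is None:
        return 0.0
    return float(comp.sum()) * float(pixel_mm) ** 2


def _boundary_pixels(comp: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(comp, structure=_STRUCT4, border_value=0)
    return np.argwhere(comp & ~eroded)


def _hull_vertices(pts: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull, QhullError

    if len(pts) < 3:
        return pts
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear input
        return pts
    return pts[hull.vertices]  # counterclockwise


def _rotating_calipers_max(hull: np.ndarray) -> float:
    """Max pairwise distance over CCW-ordered convex polygon vertices."""
    m = len(hull)
    if m == 1:
        return 0.0
    if m == 2:
        return float(np.linalg.norm(hull[0] - hull[1]))

    def area2(a, b, c):
        return abs((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    best = 0.0
    k = 1
    for i in range(m):
        j = (i + 1) % m
        while area2(hull[i], hull[j], hull[(k + 1) % m]) > area2(hull[i], hull[j], hull[k]):
            k = (k + 1) % m
        best = max(best,
                   float(np.linalg.norm(hull[i] - hull[k])),
                   float(np.linalg.norm(hull[j] - hull[k])))
    return best


def slice_max_diameter(slice_mask, pixel_mm: float = 1.0) -> float:
    """Maximal Feret diameter (mm) of the largest 4-connected component.

    Distances are between boundary pixel centers (a single pixel has
    diameter 0), found via convex hull + rotating calipers; degenerate
    (collinear) boundaries fall back to a direct pairwise maximum.
    """
    comp = _largest_component(slice_mask)
    if comp is None:
        return 0.0
    pts = _boundary_pixels(comp).astype(float)
    hull = _hull_vertices(pts)
    if len(hull) <= 2 or len(pts) == len(hull):
        d = 0.0
        for i in range(len(hull)):
            d = max(d, float(np.max(np.linalg.norm(hull - hull[i], axis=1))))
        return d * float(pixel_mm)
    return _rotating_calipers_max(hull) * float(pixel_mm)


def _savgol_kernel(window: int, order: int) -> np.ndarray:
    """Center-point Savitzky-Golay weights from the normal equations."""
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    a = np.vander(x, order + 1, increasing=True)        # (window, order+1)
    ata = a.T @ a
    # center-point estimate is the constant coefficient of the local fit
    coeffs = np.linalg.solve(ata, a.T)                   # (order+1, window)
    return coeffs[0]


def smooth_profile(values, window: int = 11, order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing with interpolating edge handling.

    The interior uses the closed-form center-point kernel solved from
    the least-squares normal equations; each edge is handled by fitting
    the terminal window's polynomial and evaluating it at the edge
    positions, so any polynomial sequence of degree <= *order* is
    reproduced exactly everywhere.  Sequences shorter than *window* are
    returned unchanged with a warning.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if order >= window:
        raise ValueError(f"order ({order}) must be < window ({window})")
    n = len(values)
    if n < window:
        warnings.warn(f"sequence length {n} < window {window}; returning input "
                      "unchanged", stacklevel=2)
        return values.copy()

    kernel = _savgol_kernel(window, order)
    out = np.convolve(values, kernel[::-1], mode="same")
    half = window // 2
    # interpolating edges: evaluate the terminal windows' polynomial fits
    x = np.arange(window, dtype=float)
    a = np.vander(x, order + 1, increasing=True)
    proj = a @ np.linalg.solve(a.T @ a, a.T)   # fit-and-evaluate on a window
    out[:half] = (proj @ values[:window])[:half]
    out[n - half:] = (proj @ values[n - window:])[window - half:]
    return out


def profile_from_straightened(sv: StraightenedVolume, window: int = 11,
                              order: int = 2) -> CrossSectionProfile:
    """Per-slice raw and smoothed diameter/area profiles of a straightened mask."""
    vals = np.unique(sv.volume.data)
    if not set(vals.tolist()).issubset({0, 1}):
        raise ValueError("straightened volume must be a binary mask")
    n = sv.n_slices
    diam = np.empty(n)
    area = np.empty(n)
    any_fg = False
    for k in range(n):
        sl = sv.slice_mask(k)
        diam[k] = slice_max_diameter(sl, 1.0)
        area[k] = slice_area(sl, 1.0)
        any_fg = any_fg or area[k] > 0
    if not any_fg:
        raise ValueError("no foreground in any straightened slice")
    arclength = np.arange(n, dtype=float) * sv.source_centerline.step_mm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        diam_s = smooth_profile(diam, window, order)
        area_s = smooth_profile(area, window, order)
    return CrossSectionProfile(arclength, diam, np.maximum(diam_s, 0.0),
                               area, np.maximum(area_s, 0.0),
                               sv.truncated_flags())


def subdivide_segments(profile: CrossSectionProfile, seg: SegmentSpec) -> dict:
    """Map each non-truncated slice index to exactly one anatomical segment."""
    total = float(profile.arclength[-1])
    if not seg.s_lsa < total:
        raise ValueError(f"s_lsa ({seg.s_lsa}) must be < total length ({total})")
    s = profile.arclength
    keep = ~profile.truncated
    idx = np.arange(len(profile))
    return {
        "ascending": idx[keep & (s < seg.s_bct)],
        "arch": idx[keep & (s >= seg.s_bct) & (s <= seg.s_lsa)],
        "descending": idx[keep & (s > seg.s_lsa)],
    }


def _stats(values: np.ndarray) -> dict:
    return {"max": float(np.max(values)), "mean": float(np.mean(values)),
            "median": float(np.median(values))}


def summarize_segments(profile: CrossSectionProfile, seg: SegmentSpec) -> QuantReport:
    """Max/mean/median diameter and area per segment, on smoothed channels.

    Only non-truncated slices contribute; the whole-aorta row aggregates
    all non-truncated slices.
    """
    ranges = subdivide_segments(profile, seg)
    for name, idx in ranges.items():
        if len(idx) == 0:
            raise ValueError(f"segment {name!r} contains no usable slices")
    segments = {}
    for name, idx in ranges.items():
        segments[name] = {
            "diameter": _stats(profile.diameter_smooth[idx]),
            "area": _stats(profile.area_smooth[idx]),
            "n_slices": int(len(idx)),
        }
    keep = ~profile.truncated
    segments["whole"] = {
        "diameter": _stats(profile.diameter_smooth[keep]),
        "area": _stats(profile.area_smooth[keep]),
        "n_slices": int(keep.sum()),
    }
    return QuantReport(segments=segments)


def detect_dilation(report: QuantReport,
                    thresholds: dict = DEFAULT_THRESHOLDS) -> dict:
    """Flag segments whose max diameter strictly exceeds its threshold."""
    flags = {}
    for name in report.segments:
        if name == "whole":
            continue
        if name not in thresholds:
            raise KeyError(f"no dilation threshold configured for segment {name!r}")
        flags[name] = bool(report.segments[name]["diameter"]["max"]
                           > thresholds[name])
    flags["any"] = any(flags.values())
    report.dilated = flags
    report.thresholds = {k: float(v) for k, v in thresholds.items()}
    return flags


@dataclass(frozen=True)
class Calibration:
    """Linear correction mapping measured values onto a reference scale."""

    intercept: float
    slope: float

    def apply(self, measured):
        return self.intercept + self.slope * np.asarray(measured, dtype=float)


def calibrate_measurements(pairs) -> Calibration:
    """OLS fit ``reference = intercept + slope * measured`` from paired data."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (measured, reference) pairs")
    m, ref = arr[:, 0], arr[:, 1]
    var = np.var(m)
    if var < 1e-15:
        raise ValueError("degenerate predictor: measured values are all identical")
    slope = float(np.cov(m, ref, bias=True)[0, 1] / var)
    intercept = float(ref.mean() - slope * m.mean())
    return Calibration(intercept, slope)
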