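"""Voxelized tubular phantoms with exact analytic ground truth.

Geometries are defined by an analytic centerline curve and an
arc-length-dependent lumen radius; voxelization is a center-inclusion
test against the distance to that curve, so the truth (centerline,
radius profile, landmarks, dilation flags) is exact and voxelization
error is quantifiable.

The ``candy_cane`` shape is a simplified thoracic aorta: straight
ascending limb, half-torus arch, straight descending limb, with
optional branch stubs on the arch standing in for the brachiocephalic
trunk and left subclavian artery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .volume_io import ImageVolume

__all__ = [
    "PhantomSpec", "PhantomTruth", "PairedCase",
    "make_phantom", "add_wall", "make_paired_cohort",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = {"ascending": 40.0, "arch": 35.0, "descending": 30.0}

_CURVE_STEP_MM = 0.5  # analytic centerline sampling pitch


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a tubular phantom.

    ``bulge`` is an optional ``(s0_mm, amplitude_mm, width_mm)`` Gaussian
    radius bump; ``branch_stubs`` is a tuple of
    ``(arclength_mm, stub_radius_mm, stub_length_mm)`` entries.
    """

    shape_kind: str = "straight_tube"
    tube_radius_mm: float | Callable[[np.ndarray], np.ndarray] = 12.0
    length_mm: float = 100.0            # straight/curved tube length (arc length)
    ring_radius_mm: float = 40.0        # torus ring radius (curved tube / arch)
    ascending_mm: float = 60.0          # candy cane: ascending limb length
    descending_mm: float = 90.0         # candy cane: descending limb length
    wall_mm: float = 0.0
    bulge: Optional[tuple] = None
    branch_stubs: tuple = ()
    spacing: tuple = (1.0, 1.0, 1.0)
    noise_flip_fraction: float = 0.0    # seeded boundary label noise, off by default
    seed: int = 0

    def __post_init__(self):
        if self.shape_kind not in ("straight_tube", "curved_tube", "candy_cane"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if not callable(self.tube_radius_mm) and self.tube_radius_mm <= 0:
            raise ValueError("tube_radius_mm must be positive")
        if self.wall_mm < 0:
            raise ValueError("wall_mm must be nonnegative")
        if self.bulge is not None and self.bulge[1] < 0:
            raise ValueError("bulge amplitude must be nonnegative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")


@dataclass
class PhantomTruth:
    """Exact analytic ground truth for a generated phantom."""

    centerline_points: np.ndarray       # (N, 3) mm, ordered by arc length
    arclength: np.ndarray               # (N,) cumulative mm from the start
    radius_profile: np.ndarray          # (N,) lumen radius (mm) at each sample
    landmark_arclengths: np.ndarray     # branch-stub origins (mm), increasing
    landmark_points: np.ndarray         # (L, 3) mm positions of the landmarks
    dilated: Optional[dict]             # per-segment flags, or None
    spec: PhantomSpec

    @property
    def total_length_mm(self) -> float:
        return float(self.arclength[-1])

    @property
    def max_lumen_diameter_mm(self) -> float:
        return float(2.0 * self.radius_profile.max())

    def segment_max_diameters(self) -> dict:
        """True max lumen diameter per anatomical segment (requires 2 landmarks)."""
        if len(self.landmark_arclengths) < 2:
            raise ValueError("segment breakdown needs two landmark arc lengths")
        s_bct, s_lsa = self.landmark_arclengths[:2]
        s, r = self.arclength, self.radius_profile
        return {
            "ascending": float(2 * r[s < s_bct].max()),
            "arch": float(2 * r[(s >= s_bct) & (s <= s_lsa)].max()),
            "descending": float(2 * r[s > s_lsa].max()),
        }


@dataclass
class PairedCase:
    """One synthetic patient: contrast and non-contrast arms plus truth."""

    contrast_mask: ImageVolume
    noncontrast_mask: ImageVolume
    truth: PhantomTruth


def _analytic_curve(spec: PhantomSpec):
    """Densely sampled centerline points and arc lengths for the spec."""
    ds = _CURVE_STEP_MM
    if spec.shape_kind == "straight_tube":
        s = np.arange(0.0, spec.length_mm + ds / 2, ds)
        pts = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
        return pts, s
    if spec.shape_kind == "curved_tube":
        # quarter torus in the x-z plane, ring radius R
        R = spec.ring_radius_mm
        length = (np.pi / 2) * R
        s = np.arange(0.0, length + ds / 2, ds)
        theta = s / R
        pts = np.column_stack([R * np.cos(theta), np.zeros_like(s), R * np.sin(theta)])
        return pts, s
    # candy cane: up, over the half-torus arch, and down (longer) on the far side
    R = spec.ring_radius_mm
    la, ld = spec.ascending_mm, spec.descending_mm
    total = la + np.pi * R + ld
    s = np.arange(0.0, total + ds / 2, ds)
    pts = np.empty((len(s), 3))
    asc = s <= la
    pts[asc] = np.column_stack([np.zeros(asc.sum()), np.zeros(asc.sum()), s[asc]])
    arch = (s > la) & (s <= la + np.pi * R)
    phi = (s[arch] - la) / R
    pts[arch] = np.column_stack([R - R * np.cos(phi), np.zeros(arch.sum()),
                                 la + R * np.sin(phi)])
    desc = s > la + np.pi * R
    t = s[desc] - la - np.pi * R
    pts[desc] = np.column_stack([np.full(desc.sum(), 2 * R), np.zeros(desc.sum()),
                                 la - t])
    return pts, s


def _radius_profile(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    if callable(spec.tube_radius_mm):
        r = np.asarray(spec.tube_radius_mm(s), dtype=float)
    else:
        r = np.full_like(s, float(spec.tube_radius_mm))
    if spec.bulge is not None:
        s0, amp, width = spec.bulge
        r = r + amp * np.exp(-0.5 * ((s - s0) / width) ** 2)
    return r


def _default_landmarks(spec: PhantomSpec, total: float):
    """Arc lengths of landmark stand-ins: stub origins, else arch quartiles."""
    if spec.branch_stubs:
        return np.sort(np.asarray([st[0] for st in spec.branch_stubs], dtype=float))
    if spec.shape_kind == "candy_cane":
        la, R = spec.ascending_mm, spec.ring_radius_mm
        return np.asarray([la + 0.25 * np.pi * R, la + 0.75 * np.pi * R])
    return np.asarray([], dtype=float)


def _segment_flags(s, r, landmarks, thresholds) -> Optional[dict]:
    if len(landmarks) < 2:
        return None
    s_bct, s_lsa = landmarks[:2]
    seg_max = {
        "ascending": 2 * r[s < s_bct].max(),
        "arch": 2 * r[(s >= s_bct) & (s <= s_lsa)].max(),
        "descending": 2 * r[s > s_lsa].max(),
    }
    flags = {k: bool(seg_max[k] > thresholds[k]) for k in seg_max}
    flags["any"] = any(flags.values())
    return flags


def make_phantom(spec: PhantomSpec, thresholds: dict = DEFAULT_THRESHOLDS,
                 extra_radius_mm: float = 0.0, bbox=None):
    """Voxelize a phantom; returns ``(lumen_mask, truth)``.

    A voxel is foreground iff its center lies within ``radius(s)`` of the
    analytic centerline (s taken at the nearest curve sample), or within a
    branch stub.  ``extra_radius_mm`` inflates the lumen radius uniformly
    (used to build exact lumen+wall masks).  ``bbox`` optionally pins the
    world bounding box ``(lo, hi)`` so related phantoms share a grid
    origin.  Deterministic given the spec; the seed only drives optional
    boundary label noise.
    """
    pts, s = _analytic_curve(spec)
    radius = _radius_profile(spec, s)
    if np.any(radius <= 0):
        raise ValueError("tube radius must be positive everywhere")

    spacing = np.asarray(spec.spacing, dtype=float)
    min_feature = radius.min()
    if spec.branch_stubs:
        min_feature = min(min_feature, min(st[1] for st in spec.branch_stubs))
    if min_feature < 2.0 * spacing.max():
        raise ValueError(
            f"unresolvable geometry: min radius {min_feature:.2f} mm < "
            f"2 voxels ({2 * spacing.max():.2f} mm) at spacing {tuple(spacing)}")

    eff_radius = radius + extra_radius_mm
    if bbox is None:
        margin = eff_radius.max() + 2 * spacing.max()
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin
        for st_s, st_r, st_len in spec.branch_stubs:
            hi[2] = max(hi[2], pts[np.searchsorted(s, st_s)][2] + st_len + st_r
                        + extra_radius_mm + 2 * spacing.max())
    else:
        lo = np.asarray(bbox[0], dtype=float)
        hi = np.asarray(bbox[1], dtype=float)
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo

    tree = cKDTree(pts)
    # flat tube ends: clip by the terminal tangent planes so the phantom
    # is a finite tube, not a capsule with spherical caps
    t_start = pts[1] - pts[0]
    t_start /= np.linalg.norm(t_start)
    t_end = pts[-1] - pts[-2]
    t_end /= np.linalg.norm(t_end)
    mask = np.zeros(shape, dtype=bool)
    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    r_bound = float(eff_radius.max()) * 1.0001
    plane = np.empty((shape[0] * shape[1], 3))
    plane[:, 0] = np.repeat(xs, shape[1])
    plane[:, 1] = np.tile(ys, shape[0])
    for k in range(shape[2]):
        plane[:, 2] = zs[k]
        d, idx = tree.query(plane, workers=-1, distance_upper_bound=r_bound)
        hit = np.isfinite(d)
        if not hit.any():
            continue
        inside = np.zeros(len(plane), dtype=bool)
        ih, dh, ph = idx[hit], d[hit], plane[hit]
        ok = dh <= eff_radius[ih]
        # clip the spherical end caps (points whose nearest sample is a
        # terminal one and that lie beyond the end plane) -> flat tube ends
        ok &= ~((ih == 0) & ((ph - pts[0]) @ t_start < -1e-6))
        ok &= ~((ih == len(pts) - 1) & ((ph - pts[-1]) @ t_end > 1e-6))
        inside[hit] = ok
        mask[:, :, k] = inside.reshape(shape[0], shape[1])

    for st_s, st_r, st_len in spec.branch_stubs:
        i = int(np.searchsorted(s, st_s))
        base = pts[min(i, len(pts) - 1)]
        tip = base + np.array([0.0, 0.0, st_len])  # stubs point superiorly
        mask |= _capsule_mask(shape, origin, spacing, base, tip,
                              st_r + extra_radius_mm)

    if spec.noise_flip_fraction > 0:
        mask = _flip_boundary(mask, spec.noise_flip_fraction, spec.seed)

    landmarks = _default_landmarks(spec, s[-1])
    lm_pts = np.asarray([pts[min(int(np.searchsorted(s, L)), len(pts) - 1)]
                         for L in landmarks]).reshape(-1, 3)
    truth = PhantomTruth(
        centerline_points=pts,
        arclength=s,
        radius_profile=radius,
        landmark_arclengths=landmarks,
        landmark_points=lm_pts,
        dilated=_segment_flags(s, radius, landmarks, thresholds),
        spec=spec,
    )
    vol = ImageVolume(mask.astype(np.uint8), spacing, origin)
    return vol, truth


def _capsule_mask(shape, origin, spacing, a, b, radius):
    """Voxels whose centers lie within *radius* of segment a-b."""
    lo = np.minimum(a, b) - radius - spacing
    hi = np.maximum(a, b) + radius + spacing
    i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, shape)
    out = np.zeros(shape, dtype=bool)
    if np.any(i0 >= i1):
        return out
    ax = [origin[d] + np.arange(i0[d], i1[d]) * spacing[d] for d in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    p = np.stack([gx, gy, gz], axis=-1)
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
    closest = a + t[..., np.newaxis] * ab
    d = np.linalg.norm(p - closest, axis=-1)
    out[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = d <= radius
    return out


def _flip_boundary(mask, fraction, seed):
    from scipy.ndimage import binary_dilation, binary_erosion

    boundary = binary_dilation(mask) ^ binary_erosion(mask)
    idx = np.flatnonzero(boundary.ravel())
    rng = np.random.default_rng(seed)
    pick = rng.choice(idx, size=int(len(idx) * fraction), replace=False)
    flat = mask.ravel().copy()
    flat[pick] = ~flat[pick]
    return flat.reshape(mask.shape)


def add_wall(lumen_mask: ImageVolume, wall_mm: float) -> ImageVolume:
    """Dilate a binary lumen by a spherical element of physical radius *wall_mm*.

    Implemented as a threshold on the spacing-aware Euclidean distance to
    the lumen, which is the exact continuous-space dilation evaluated at
    voxel centers.  The output is always a superset of the input.
    """
    from scipy.ndimage import distance_transform_edt

    if wall_mm < 0:
        raise ValueError(f"wall_mm must be nonnegative, got {wall_mm}")
    fg = lumen_mask.data.astype(bool)
    if not set(np.unique(lumen_mask.data)).issubset({0, 1}):
        raise ValueError("add_wall expects a binary mask")
    if wall_mm == 0:
        out = fg
    else:
        dist = distance_transform_edt(~fg, sampling=lumen_mask.spacing)
        out = fg | (dist <= wall_mm)
    return ImageVolume(out.astype(np.uint8), lumen_mask.spacing.copy(),
                       lumen_mask.origin.copy(), lumen_mask.direction.copy())


def make_geometry_cohort(n: int, seed: int, radius_range=(10.0, 20.0),
                         spacing=(0.65, 0.65, 1.0)) -> list:
    """Seeded lumen-only candy-cane phantoms for geometric-recovery checks.

    Tube radii are drawn from *radius_range*; half the cases carry an
    ascending bulge (amplitude up to 8 mm).  The arch ring radius is kept
    >= 3x the tube radius and large enough that the opposite limb stays
    outside an 80 mm reformation plane.  Returns ``[(mask, truth), ...]``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        base_r = rng.uniform(*radius_range)
        amp = rng.uniform(2.0, 8.0) if rng.random() < 0.5 else 0.0
        asc = rng.uniform(50.0, 65.0)
        desc = asc + rng.uniform(15.0, 30.0)
        # keep the far limb clear of an 80 mm plane: 2*ring >= 45 + r_max
        ring = max(3.0 * base_r, (45.0 + base_r + amp) / 2.0) + rng.uniform(0, 5)
        bulge = (asc * rng.uniform(0.4, 0.6), amp, rng.uniform(8.0, 12.0)) \
            if amp > 0 else None
        spec = PhantomSpec(shape_kind="candy_cane", tube_radius_mm=base_r,
                           ascending_mm=asc, descending_mm=desc,
                           ring_radius_mm=ring, bulge=bulge,
                           spacing=tuple(spacing), seed=seed)
        out.append(make_phantom(spec))
    return out


CONTRAST_SPACING = (0.65, 0.65, 1.0)
NONCONTRAST_SPACING = (0.65, 0.65, 3.0)


def make_paired_cohort(n: int, seed: int, dilated_fraction: float = 0.5,
                       thresholds: dict = DEFAULT_THRESHOLDS,
                       wall_mm: float = 2.0) -> list:
    """Generate *n* synthetic patients with paired acquisition arms.

    Each case is a random candy-cane phantom.  The contrast arm is the
    lumen voxelized at 1 mm slice thickness; the non-contrast arm is the
    lumen plus a *wall_mm* wall voxelized at 3 mm slices (both 0.65 mm
    in-plane).  Exactly ``round(n * dilated_fraction)`` cases carry an
    ascending-aorta bulge whose true max lumen diameter exceeds the
    ascending threshold by >= 5 mm; the rest stay >= 5 mm below it.
    Reproducible: the same seed yields an identical cohort.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= dilated_fraction <= 1.0:
        raise ValueError("dilated_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_dil = int(round(n * dilated_fraction))
    flags = np.zeros(n, dtype=bool)
    flags[:n_dil] = True
    rng.shuffle(flags)

    t_asc = thresholds["ascending"]
    cases = []
    for i in range(n):
        base_r = rng.uniform(10.0, 14.0)
        asc = rng.uniform(50.0, 65.0)
        desc = asc + rng.uniform(15.0, 30.0)
        ring = rng.uniform(max(3.0 * base_r, 37.0), 46.0)
        if flags[i]:
            target = rng.uniform(t_asc + 5.0, t_asc + 15.0)  # separable margin
            amp = target / 2.0 - base_r
        else:
            amp = rng.uniform(0.0, max(0.0, (t_asc - 5.0) / 2.0 - base_r))
        bulge = (asc * rng.uniform(0.4, 0.6), amp, rng.uniform(8.0, 12.0)) \
            if amp > 0 else None
        common = dict(shape_kind="candy_cane", tube_radius_mm=base_r,
                      ascending_mm=asc, descending_mm=desc, ring_radius_mm=ring,
                      bulge=bulge, seed=seed + i)
        spec_c = PhantomSpec(spacing=CONTRAST_SPACING, **common)
        spec_n = PhantomSpec(spacing=NONCONTRAST_SPACING, wall_mm=wall_mm, **common)
        # shared world bbox so the two arms sit on aligned grids
        pts, s = _analytic_curve(spec_c)
        rmax = _radius_profile(spec_c, s).max() + wall_mm
        margin = rmax + 2 * max(NONCONTRAST_SPACING)
        bbox = (pts.min(axis=0) - margin, pts.max(axis=0) + margin)
        contrast, truth = make_phantom(spec_c, thresholds, bbox=bbox)
        # exact continuous-space lumen+wall: voxelize at radius + wall
        noncontrast, _ = make_phantom(spec_n, thresholds,
                                      extra_radius_mm=wall_mm, bbox=bbox)
        assert truth.dilated is not None and truth.dilated["ascending"] == flags[i]
        cases.append(PairedCase(contrast, noncontrast, truth))
    return cases
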