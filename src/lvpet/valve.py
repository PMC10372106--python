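"""Atrioventricular (mitral) valve-plane detection.

The valve ring is below PET resolution but depresses the blood-pool activity
between left ventricle and left atrium, producing a waist ("indentation") in
the long-axis activity profile. The detector:

1. estimates the LV long axis from the activity-weighted principal axis of
   the LEFT blood pool;
2. for many rotations about that axis, resamples the image on a thin slab
   through the axis, masks low-activity voxels, and measures the width of
   the high-activity pool across the slab at each long-axis position; local
   width minima of sufficient prominence are indentation candidates;
3. fits a robust consensus 3D plane through the candidates (exhaustive /
   sampled triple search with inlier refit), oriented so the apical side has
   positive signed distance;
4. exposes a user adjustment (translation along the normal plus a bounded
   tilt), mirroring the interactive fine-tuning step of the clinical
   workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage, signal

from .imaging import VoxelGrid3D

__all__ = [
    "LongAxis",
    "IndentationCandidate",
    "Plane3D",
    "DegenerateMaskError",
    "estimate_long_axis",
    "find_indentations",
    "select_and_fit_plane",
    "adjust_plane",
]


class DegenerateMaskError(RuntimeError):
    """The LEFT pool is too small or too isotropic for a long axis."""


@dataclass(frozen=True)
class LongAxis:
    """Unit direction (oriented base -> apex) and activity-weighted centroid."""

    direction: np.ndarray  # (3,) unit vector, world mm
    centroid: np.ndarray  # (3,) world mm

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=np.float64)
        if d.shape != (3,) or not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise ValueError("direction must be a 3D unit vector")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=np.float64))


@dataclass(frozen=True)
class IndentationCandidate:
    """A width minimum at one rotation angle about the long axis."""

    angle_deg: float
    point: np.ndarray  # (3,) world mm
    width_mm: float
    prominence_mm: float

    def __post_init__(self) -> None:
        if self.width_mm < 0:
            raise ValueError("width must be non-negative")
        if self.prominence_mm <= 0:
            raise ValueError("prominence must be positive")
        object.__setattr__(self, "point", np.asarray(self.point, dtype=np.float64))


@dataclass(frozen=True)
class Plane3D:
    """A 3D plane; the apical side is the positive-signed-distance side."""

    point: np.ndarray
    normal: np.ndarray
    inlier_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    low_confidence: bool = False

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64)
        if n.shape != (3,) or not np.isclose(np.linalg.norm(n), 1.0, atol=1e-6):
            raise ValueError("normal must be a 3D unit vector")
        object.__setattr__(self, "normal", n / np.linalg.norm(n))
        object.__setattr__(self, "point", np.asarray(self.point, dtype=np.float64))
        object.__setattr__(self, "inlier_points", np.asarray(self.inlier_points, dtype=np.float64))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return (points - self.point) @ self.normal

    def to_dict(self) -> dict:
        return {
            "point": self.point.tolist(),
            "normal": self.normal.tolist(),
            "n_inliers": int(len(self.inlier_points)),
            "low_confidence": bool(self.low_confidence),
        }


# ---------------------------------------------------------------------------
# Long axis
# ---------------------------------------------------------------------------

def estimate_long_axis(
    left_mask: np.ndarray,
    image: VoxelGrid3D,
    min_voxels: int = 20,
    min_anisotropy: float = 1.2,
) -> LongAxis:
    """Activity-weighted principal axis of the LEFT pool, oriented base->apex.

    The LEFT pool (ventricle + atrium) holds most of its activity in the
    ventricle, so the activity-weighted centroid sits on the ventricular
    side of the pool's extent midpoint; the apex is the extreme on that
    side. Raises :class:`DegenerateMaskError` for tiny or near-isotropic
    pools, for which a manual axis must be supplied.
    """
    mask = np.asarray(left_mask, dtype=bool)
    idx = np.argwhere(mask)
    if len(idx) < min_voxels:
        raise DegenerateMaskError(f"LEFT pool has only {len(idx)} voxels (< {min_voxels})")
    coords = image.index_to_world(idx)
    weights = np.clip(image.values[mask], 0.0, None)
    if weights.sum() <= 0:
        weights = np.ones(len(idx))
    centroid = np.average(coords, axis=0, weights=weights)
    centred = coords - centroid
    cov = (centred * weights[:, None]).T @ centred / weights.sum()
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    if eigvals[-1] <= 0 or np.sqrt(eigvals[-1] / max(eigvals[-2], 1e-12)) < min_anisotropy:
        raise DegenerateMaskError(
            "LEFT pool is near-isotropic; supply the long axis manually"
        )
    direction = eigvecs[:, -1]

    # orient base -> apex: t is centred on the weighted centroid, so a
    # positive extent midpoint means the heavy (ventricular) half - and with
    # it the apex - lies on the negative side
    t = centred @ direction
    if t.min() + t.max() > 0:
        direction = -direction
    return LongAxis(direction=direction, centroid=centroid)


def _orthonormal_frame(w: np.ndarray):
    w = w / np.linalg.norm(w)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v


# ---------------------------------------------------------------------------
# Indentation search
# ---------------------------------------------------------------------------

def _sample_world(image: VoxelGrid3D, points: np.ndarray) -> np.ndarray:
    ijk = image.world_to_index(points)
    return ndimage.map_coordinates(image.values, ijk.reshape(-1, 3).T, order=1, cval=0.0).reshape(
        points.shape[:-1]
    )


def find_indentations(
    image: VoxelGrid3D,
    axis: LongAxis,
    n_angles: int = 36,
    low_fraction: float = 0.5,
    reference: float | None = None,
    left_mask: np.ndarray | None = None,
    prominence_min_mm: float = 2.0,
    s_margin: float = 0.2,
) -> list[IndentationCandidate]:
    """Find activity-waist candidates at ``n_angles`` rotations about the axis.

    ``reference`` is the activity against which "low" is judged; by default it
    is the median of the LEFT-pool voxels (when ``left_mask`` is given) or of
    voxels above half the image maximum, which is insensitive to hot-spot
    noise. A slab position is low-activity when below
    ``low_fraction * reference``; at each long-axis position the width of the
    high-activity run around the axis is measured, and local width minima
    with prominence >= ``prominence_min_mm`` become candidates located at the
    run's midpoint.
    """
    if n_angles < 8:
        raise ValueError("n_angles must be >= 8")
    if not 0 < low_fraction < 1:
        raise ValueError("low_fraction must be in (0, 1)")
    if reference is None:
        if left_mask is not None and np.any(left_mask):
            reference = float(np.median(image.values[np.asarray(left_mask, dtype=bool)]))
        else:
            vmax = image.values.max()
            blood = image.values[image.values >= 0.5 * vmax]
            reference = float(np.median(blood))
    if reference <= 0:
        raise ValueError("reference activity must be positive")
    threshold = low_fraction * reference

    w = axis.direction
    u, v = _orthonormal_frame(w)
    step = float(min(image.spacing))

    # long-axis sampling range: LEFT-pool extent (plus margin) if available
    if left_mask is not None and np.any(left_mask):
        coords = image.index_to_world(np.argwhere(left_mask))
        t = (coords - axis.centroid) @ w
        s_lo, s_hi = t.min(), t.max()
        pad = s_margin * (s_hi - s_lo)
        s_lo, s_hi = s_lo - pad, s_hi + pad
        r_max = float(np.max(np.linalg.norm((coords - axis.centroid) - np.outer(t, w), axis=1)))
        r_max *= 1.0 + s_margin
    else:
        half_diag = 0.5 * float(np.linalg.norm(np.asarray(image.shape) * np.asarray(image.spacing)))
        s_lo, s_hi, r_max = -half_diag, half_diag, half_diag

    s_grid = np.arange(s_lo, s_hi + step / 2, step)
    r_grid = np.arange(-r_max, r_max + step / 2, step)
    i_center = int(np.argmin(np.abs(r_grid)))
    slab_offsets = np.array([-step, 0.0, step])  # slab thickness ~= 2 voxels

    candidates: list[IndentationCandidate] = []
    for angle in np.linspace(0.0, 180.0, n_angles, endpoint=False):
        theta = np.deg2rad(angle)
        d = np.cos(theta) * u + np.sin(theta) * v
        e = np.cross(w, d)
        # (ns, nr, n_off, 3) sample points
        pts = (
            axis.centroid[None, None, None, :]
            + s_grid[:, None, None, None] * w
            + r_grid[None, :, None, None] * d
            + slab_offsets[None, None, :, None] * e
        )
        slab = _sample_world(image, pts).mean(axis=2)  # (ns, nr)
        high = slab >= threshold

        widths = np.full(len(s_grid), np.nan)
        mids = np.zeros(len(s_grid))
        for i in range(len(s_grid)):
            row = high[i]
            if not row[i_center]:
                continue  # axis itself outside the pool at this position
            j_hi = i_center
            while j_hi + 1 < len(row) and row[j_hi + 1]:
                j_hi += 1
            j_lo = i_center
            while j_lo - 1 >= 0 and row[j_lo - 1]:
                j_lo -= 1
            widths[i] = r_grid[j_hi] - r_grid[j_lo] + step
            mids[i] = 0.5 * (r_grid[j_hi] + r_grid[j_lo])

        # local minima of the width profile within each finite run
        finite = np.isfinite(widths)
        for run in _finite_runs(finite):
            seg = widths[run]
            if len(seg) < 3:
                continue
            peaks, props = signal.find_peaks(-seg, prominence=prominence_min_mm)
            for p, prom in zip(peaks, props["prominences"]):
                i = run.start + p
                point = axis.centroid + s_grid[i] * w + mids[i] * d
                candidates.append(
                    IndentationCandidate(
                        angle_deg=float(angle),
                        point=point,
                        width_mm=float(widths[i]),
                        prominence_mm=float(prom),
                    )
                )
    return candidates


def _finite_runs(finite: np.ndarray):
    runs = []
    start = None
    for i, f in enumerate(finite):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append(slice(start, i))
            start = None
    if start is not None:
        runs.append(slice(start, len(finite)))
    return runs


# ---------------------------------------------------------------------------
# Plane selection and fitting
# ---------------------------------------------------------------------------

def select_and_fit_plane(
    candidates: list[IndentationCandidate],
    axis: LongAxis,
    inlier_tol_mm: float = 2.0,
    max_triples: int = 20000,
    max_obliquity_deg: float = 45.0,
    seed: int = 0,
) -> Plane3D:
    """Robust consensus plane through the indentation candidates.

    Searches candidate triples (exhaustively when feasible, else a seeded
    random sample), keeps the plane with the most candidates within
    ``inlier_tol_mm``, breaking ties toward the most basal mean long-axis
    position (the mitral waist is the basal-most consistent ring), and
    refits by total least squares on the inliers. Planes tilted more than
    ``max_obliquity_deg`` from transverse are rejected as implausible valve
    orientations. The normal is oriented toward the apex, so apical points
    have positive signed distance.
    """
    if len(candidates) < 3:
        raise ValueError(f"need >= 3 indentation candidates, got {len(candidates)}")
    angles = np.array([c.angle_deg for c in candidates])
    if angles.max() - angles.min() < 90.0:
        raise ValueError("candidates must span >= 90 degrees of rotation angles")
    pts = np.array([c.point for c in candidates])
    w = axis.direction
    t_axis = (pts - axis.centroid) @ w  # long-axis coordinate (apex = +)
    min_dot = np.cos(np.deg2rad(max_obliquity_deg))

    n = len(pts)
    triples = list(combinations(range(n), 3))
    if len(triples) > max_triples:
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(triples), size=max_triples, replace=False)
        triples = [triples[i] for i in picks]

    best = None  # (n_inliers, -mean_t, inlier_mask)
    for i, j, k in triples:
        normal = np.cross(pts[j] - pts[i], pts[k] - pts[i])
        norm = np.linalg.norm(normal)
        if norm < 1e-9:
            continue
        normal = normal / norm
        if abs(normal @ w) < min_dot:
            continue
        dist = np.abs((pts - pts[i]) @ normal)
        inliers = dist <= inlier_tol_mm
        n_in = int(inliers.sum())
        mean_t = float(t_axis[inliers].mean())
        key = (n_in, -mean_t)  # more inliers; then more basal (smaller t)
        if best is None or key > best[0]:
            best = (key, inliers)
    if best is None:
        raise ValueError("no admissible plane found among candidate triples")

    inliers = best[1]
    in_pts = pts[inliers]
    centroid = in_pts.mean(axis=0)
    _, _, vt = np.linalg.svd(in_pts - centroid)
    normal = vt[-1]
    if normal @ w < 0:
        normal = -normal  # apical side positive
    low_confidence = inliers.sum() / n < 0.5
    return Plane3D(point=centroid, normal=normal, inlier_points=in_pts,
                   low_confidence=low_confidence)


def adjust_plane(
    plane: Plane3D,
    offset_mm: float = 0.0,
    tilt_deg: float = 0.0,
    tilt_azimuth_deg: float = 0.0,
) -> Plane3D:
    """User adjustment: translate along the normal and/or tilt it.

    ``offset_mm`` moves the plane along its normal (positive = apical).
    ``tilt_deg`` rotates the normal about the horizontal world axis at
    ``tilt_azimuth_deg`` (a fixed axis, so equal and opposite tilts cancel
    exactly); tilts beyond 45 degrees are rejected as implausible.
    """
    if abs(tilt_deg) > 45.0:
        raise ValueError(f"|tilt| must be <= 45 degrees, got {tilt_deg}")
    point = plane.point + offset_mm * plane.normal
    normal = plane.normal
    if tilt_deg != 0.0:
        az = np.deg2rad(tilt_azimuth_deg)
        k = np.array([np.cos(az), np.sin(az), 0.0])  # rotation axis, world xy-plane
        t = np.deg2rad(tilt_deg)
        normal = (
            normal * np.cos(t)
            + np.cross(k, normal) * np.sin(t)
            + k * (k @ normal) * (1.0 - np.cos(t))
        )
        normal /= np.linalg.norm(normal)
    return Plane3D(point=point, normal=normal, inlier_points=plane.inlier_points,
                   low_confidence=plane.low_confidence)
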