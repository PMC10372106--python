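"""Image containers and NIfTI / timing-sidecar I/O.

Images are treated as activity-concentration volumes (Bq/mL) on a regular
orthonormal grid. World coordinates are RAS millimetres; voxel indices are
0-based. NIfTI-1 is the canonical on-disk format; frame timing and gating
metadata live in a JSON sidecar (BIDS-PET-style ``FrameTimesStart`` /
``FrameDuration`` fields, or ``NumberOfGates`` + ``GateWindow`` for gated
series) because the NIfTI header carries no usable timing.

No decay correction is applied anywhere in this package: input is assumed to
be reconstruction-corrected, as is standard for clinical PET.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid3D",
    "DynamicSeries",
    "GatedSeries",
    "TimingInfo",
    "ImageLoadError",
    "read_image",
    "write_image",
    "read_timing",
    "expand_schedule",
    "load_dynamic",
    "load_gated",
    "DEFAULT_FRAME_SCHEDULE",
]

#: The default non-gated dynamic framing: 22 frames spanning 0-360 s.
DEFAULT_FRAME_SCHEDULE = "1x10,8x5,4x10,2x15,3x20,2x30,2x60"


class ImageLoadError(RuntimeError):
    """Raised when a volumetric image cannot be loaded safely."""


def _as_float_array(values: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(values, dtype=np.float64))


@dataclass(frozen=True)
class VoxelGrid3D:
    """A 3D scalar field with geometry.

    Parameters
    ----------
    values
        Voxel values, shape ``(nx, ny, nz)``, interpreted as Bq/mL.
    spacing
        Per-axis voxel size in mm, all positive.
    origin
        World position (mm) of the centre of voxel (0, 0, 0).
    axes
        3x3 orthonormal direction matrix; column ``k`` is the world direction
        of voxel axis ``k``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        values = _as_float_array(self.values)
        if values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {values.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        axes = np.asarray(self.axes, dtype=np.float64)
        if axes.shape != (3, 3) or not np.allclose(axes.T @ axes, np.eye(3), atol=1e-4):
            raise ValueError("axes must be a 3x3 orthonormal direction matrix")
        n_bad = int(np.count_nonzero(~np.isfinite(values)))
        if n_bad:
            raise ValueError(f"non-finite voxel values: {n_bad} voxels affected")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "axes", axes)

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.axes * np.asarray(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices ``(..., 3)`` to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=np.float64)
        return ijk * np.asarray(self.spacing) @ self.axes.T + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates ``(..., 3)`` to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=np.float64)
        return (xyz - np.asarray(self.origin)) @ self.axes / np.asarray(self.spacing)

    def with_values(self, values: np.ndarray) -> "VoxelGrid3D":
        """Same geometry, new voxel values."""
        return VoxelGrid3D(values, self.spacing, self.origin, self.axes)

    def same_geometry(self, other: "VoxelGrid3D", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=atol)
        )


def _check_shared_geometry(grids: Sequence[VoxelGrid3D], what: str) -> None:
    if not grids:
        raise ValueError(f"{what} needs at least one volume")
    first = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if not first.same_geometry(g):
            raise ValueError(f"{what}: volume {i} geometry differs from volume 0")


@dataclass(frozen=True)
class DynamicSeries:
    """An ordered non-gated dynamic series with frame timing in seconds."""

    frames: tuple[VoxelGrid3D, ...]
    frame_start: np.ndarray
    frame_end: np.ndarray

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        _check_shared_geometry(frames, "DynamicSeries")
        start = np.asarray(self.frame_start, dtype=np.float64)
        end = np.asarray(self.frame_end, dtype=np.float64)
        if start.shape != end.shape or start.ndim != 1 or len(start) != len(frames):
            raise ValueError("frame_start/frame_end must match the number of frames")
        if np.any(end <= start):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame start times must be strictly increasing")
        if not np.allclose(start[1:], end[:-1], atol=1e-6):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def mid_times(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    def voxel_tacs(self) -> np.ndarray:
        """Stack frame values into a 4D array (nx, ny, nz, n_frames)."""
        return np.stack([f.values for f in self.frames], axis=-1)


@dataclass(frozen=True)
class GatedSeries:
    """Cardiac-gated blood-pool bins over a fixed post-injection window."""

    bins: tuple[VoxelGrid3D, ...]
    window: tuple[float, float] = (10.0, 50.0)

    def __post_init__(self) -> None:
        bins = tuple(self.bins)
        if len(bins) < 2:
            raise ValueError("a gated series needs at least 2 bins")
        _check_shared_geometry(bins, "GatedSeries")
        t0, t1 = (float(t) for t in self.window)
        if t1 <= t0:
            raise ValueError(f"gating window end must exceed start, got {self.window}")
        object.__setattr__(self, "bins", bins)
        object.__setattr__(self, "window", (t0, t1))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def bin_phase(self) -> np.ndarray:
        """Fractional cardiac-cycle interval covered by each bin."""
        edges = np.linspace(0.0, 1.0, self.n_bins + 1)
        return np.stack([edges[:-1], edges[1:]], axis=1)

    def time_average(self) -> VoxelGrid3D:
        """Mean over bins; approximates the non-gated first-pass image."""
        mean = np.mean([b.values for b in self.bins], axis=0)
        return self.bins[0].with_values(mean)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _geometry_from_affine(affine: np.ndarray):
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ImageLoadError("degenerate voxel spacing in image header")
    axes = lin / spacing
    if not np.allclose(axes.T @ axes, np.eye(3), atol=1e-3):
        raise ImageLoadError("non-orthonormal direction matrix in image header")
    origin = affine[:3, 3]
    return tuple(spacing), tuple(origin), axes


def read_image(path: str | Path):
    """Read a 3D or 4D NIfTI image.

    Returns a :class:`VoxelGrid3D` for 3D inputs, or a list of
    :class:`VoxelGrid3D` (one per volume, shared geometry) for 4D inputs.
    NaN/Inf voxels are rejected with a count of affected voxels.
    """
    path = Path(path)
    if not path.exists():
        raise ImageLoadError(f"image file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ImageLoadError(f"{path}: non-finite voxel values ({n_bad} voxels)")
    spacing, origin, axes = _geometry_from_affine(img.affine)
    if data.ndim == 3:
        return VoxelGrid3D(data, spacing, origin, axes)
    if data.ndim == 4:
        return [VoxelGrid3D(data[..., t], spacing, origin, axes) for t in range(data.shape[3])]
    raise ImageLoadError(f"{path}: expected 3D or 4D image, got {data.ndim}D")


def write_image(image: VoxelGrid3D | Sequence[VoxelGrid3D], path: str | Path) -> None:
    """Write a 3D grid or a sequence of grids (as one 4D volume) to NIfTI."""
    if isinstance(image, VoxelGrid3D):
        data = image.values
        affine = image.affine
    else:
        grids = list(image)
        _check_shared_geometry(grids, "write_image")
        data = np.stack([g.values for g in grids], axis=-1)
        affine = grids[0].affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# Frame timing / gating sidecars
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimingInfo:
    """Frame timing (dynamic) or gating (gated) metadata from a sidecar."""

    kind: str  # "dynamic" or "gated"
    frame_start: np.ndarray | None = None
    frame_end: np.ndarray | None = None
    n_bins: int | None = None
    window: tuple[float, float] | None = None

    @property
    def n_frames(self) -> int:
        if self.kind == "dynamic":
            return len(self.frame_start)  # type: ignore[arg-type]
        return int(self.n_bins)  # type: ignore[arg-type]


def expand_schedule(schedule: str | Sequence[str] | Sequence[float]) -> np.ndarray:
    """Expand a framing schedule into per-frame durations (seconds).

    Accepts a comma/space separated string like ``"1x10,8x5"`` (count x
    duration), a sequence of such tokens, or a plain sequence of durations.
    """
    if isinstance(schedule, str):
        tokens = [t for t in schedule.replace(",", " ").split() if t]
    else:
        tokens = list(schedule)
    durations: list[float] = []
    for tok in tokens:
        if isinstance(tok, str) and "x" in tok:
            count_s, dur_s = tok.split("x")
            count, dur = int(count_s), float(dur_s)
            durations.extend([dur] * count)
        else:
            durations.append(float(tok))
    out = np.asarray(durations, dtype=np.float64)
    if out.size == 0 or np.any(out <= 0):
        raise ValueError(f"schedule must expand to positive durations, got {schedule!r}")
    return out


def _starts_ends(durations: np.ndarray, t0: float = 0.0):
    ends = t0 + np.cumsum(durations)
    starts = np.concatenate([[t0], ends[:-1]])
    return starts, ends


def read_timing(path: str | Path) -> TimingInfo:
    """Read a JSON timing sidecar.

    Dynamic sidecars carry ``FrameTimesStart`` + ``FrameDuration`` or a
    ``FrameSchedule`` string; gated sidecars carry ``NumberOfGates`` and
    ``GateWindow`` ([t0, t1] seconds post injection).
    """
    with open(path) as fh:
        meta = json.load(fh)
    return timing_from_dict(meta)


def timing_from_dict(meta: dict) -> TimingInfo:
    if "NumberOfGates" in meta:
        n_bins = int(meta["NumberOfGates"])
        window = tuple(float(t) for t in meta.get("GateWindow", (10.0, 50.0)))
        if n_bins < 2:
            raise ValueError("NumberOfGates must be >= 2")
        if window[1] <= window[0]:
            raise ValueError("GateWindow end must exceed start")
        return TimingInfo(kind="gated", n_bins=n_bins, window=window)  # type: ignore[arg-type]
    if "FrameSchedule" in meta:
        durations = expand_schedule(meta["FrameSchedule"])
        starts, ends = _starts_ends(durations, float(meta.get("ScanStart", 0.0)))
        return TimingInfo(kind="dynamic", frame_start=starts, frame_end=ends)
    if "FrameTimesStart" in meta and "FrameDuration" in meta:
        starts = np.asarray(meta["FrameTimesStart"], dtype=np.float64)
        durations = np.asarray(meta["FrameDuration"], dtype=np.float64)
        if np.any(durations <= 0):
            raise ValueError("FrameDuration entries must be positive")
        return TimingInfo(kind="dynamic", frame_start=starts, frame_end=starts + durations)
    raise ValueError(
        "sidecar must contain NumberOfGates, FrameSchedule, or FrameTimesStart+FrameDuration"
    )


def load_dynamic(image_path: str | Path, sidecar_path: str | Path) -> DynamicSeries:
    frames = read_image(image_path)
    if isinstance(frames, VoxelGrid3D):
        frames = [frames]
    timing = read_timing(sidecar_path)
    if timing.kind != "dynamic":
        raise ValueError("sidecar describes a gated series, expected dynamic framing")
    if timing.n_frames != len(frames):
        raise ValueError(
            f"sidecar lists {timing.n_frames} frames but image has {len(frames)} volumes"
        )
    return DynamicSeries(tuple(frames), timing.frame_start, timing.frame_end)


def load_gated(image_path: str | Path, sidecar_path: str | Path) -> GatedSeries:
    bins = read_image(image_path)
    if isinstance(bins, VoxelGrid3D):
        raise ValueError("gated image must be 4D (one volume per cardiac bin)")
    timing = read_timing(sidecar_path)
    if timing.kind != "gated":
        raise ValueError("sidecar describes a dynamic series, expected gating metadata")
    if timing.n_bins != len(bins):
        raise ValueError(f"sidecar lists {timing.n_bins} gates but image has {len(bins)} volumes")
    return GatedSeries(tuple(bins), timing.window)  # type: ignore[arg-type]
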