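"""Steepest-path seeding of the blood pool and left/right chamber assignment.

Every foreground voxel follows, step by step, the 26-neighbour with the
greatest positive spacing-normalised value increase until no neighbour is
higher; all voxels terminating at the same local maximum form one *seed*.
The cardiac valves, though below scanner resolution, depress the local
activity, so voxels on either side of a valve reach different maxima and end
up in different seeds. Each seed is then assigned to the left or right heart
from the arterial (V_A) and venous (V_V) spill-over fractions sampled at the
voxel holding the seed's maximum.

Determinism: ties between equally steep neighbours break to the lowest
linear (C-order) voxel index; plateaus (connected equal-value components
with no higher neighbour) collapse to a single representative maximum at
their lowest linear index.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .imaging import VoxelGrid3D
from .kinetics import ParametricMaps

__all__ = [
    "Side",
    "SeedMap",
    "ChamberLabels",
    "steepest_path_seeds",
    "assign_chambers",
    "chamber_mask",
]


class Side(Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    NONE = "NONE"


@dataclass(frozen=True)
class SeedMap:
    """Voxel -> seed labelling (0 = background, 1..K = seed ids)."""

    labels: np.ndarray
    maxima: dict  # seed id -> (voxel index tuple, value)
    grid: VoxelGrid3D

    @property
    def n_seeds(self) -> int:
        return len(self.maxima)

    def seed_ids(self) -> list[int]:
        return sorted(self.maxima)


@dataclass(frozen=True)
class ChamberLabels:
    """Seed -> {LEFT, RIGHT, NONE} with the (V_A, V_V) evidence used."""

    assignment: dict  # seed id -> Side
    evidence: dict  # seed id -> (va, vv)

    def seeds_on(self, side: Side) -> list[int]:
        return sorted(s for s, a in self.assignment.items() if a == side)


def _neighbor_offsets_sorted(shape):
    """All 26 neighbour offsets, sorted by linear-index delta (ascending).

    Sorting makes a first-argmax tie-break pick the neighbour with the lowest
    linear index.
    """
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    strides = (shape[1] * shape[2], shape[2], 1)
    offsets.sort(key=lambda o: o[0] * strides[0] + o[1] * strides[1] + o[2] * strides[2])
    return offsets, strides


def _shifted(values, off, fill):
    """values[i + off] with out-of-bounds filled."""
    out = np.full_like(values, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(off):
        if d == 1:
            src[ax], dst[ax] = slice(1, None), slice(None, -1)
        elif d == -1:
            src[ax], dst[ax] = slice(None, -1), slice(1, None)
    out[tuple(dst)] = values[tuple(src)]
    return out


def steepest_path_seeds(
    image: VoxelGrid3D,
    background_fraction: float = 0.10,
    min_seed_voxels: int = 8,
) -> SeedMap:
    """Partition foreground voxels into steepest-ascent basins (seeds).

    Voxels below ``background_fraction * max(image)`` are background (label
    0). Ascent steepness is (neighbour - centre) / centre-to-centre distance
    in mm, so anisotropic voxels do not bias the path. Seeds smaller than
    ``min_seed_voxels`` are merged into the neighbouring seed sharing the
    largest boundary (0 disables the merge).
    """
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must be in [0, 1)")
    values = image.values
    vmax = values.max()
    fg = values >= background_fraction * vmax if vmax > 0 else np.zeros_like(values, bool)
    fg &= values > 0
    if not np.any(fg):
        return SeedMap(np.zeros(values.shape, dtype=np.int32), {}, image)

    shape = values.shape
    offsets, strides = _neighbor_offsets_sorted(shape)
    spacing = np.asarray(image.spacing)

    best_steep = np.full(shape, 0.0)
    best_off = np.full(shape, 0, dtype=np.int64)  # linear-index delta of chosen neighbour
    for off in offsets:
        dist = float(np.linalg.norm(spacing * np.asarray(off)))
        nb = _shifted(values, off, -np.inf)
        steep = (nb - values) / dist
        take = steep > best_steep  # strict: keeps the earlier (lower-index) tie winner
        off_lin = off[0] * strides[0] + off[1] * strides[1] + off[2] * strides[2]
        best_steep[take] = steep[take]
        best_off[take] = off_lin

    n = values.size
    idx = np.arange(n, dtype=np.int64)
    pointer = idx.copy()
    fg_flat = fg.reshape(-1)
    ascends = (best_steep.reshape(-1) > 0) & fg_flat
    pointer[ascends] = idx[ascends] + best_off.reshape(-1)[ascends]

    # Plateau collapse: local maxima (no strictly higher neighbour) that touch
    # each other necessarily share a value; label their connected components
    # and point every member at the component's lowest-linear-index voxel.
    maxima_mask = fg & ~ascends.reshape(shape)
    plateau_lab, n_plateau = ndimage.label(maxima_mask, structure=np.ones((3, 3, 3)))
    plateau_flat = plateau_lab.reshape(-1)
    reps = np.zeros(n_plateau + 1, dtype=np.int64)
    order = np.argsort(plateau_flat, kind="stable")
    lab_sorted = plateau_flat[order]
    first = np.searchsorted(lab_sorted, np.arange(1, n_plateau + 1))
    reps[1:] = order[first]  # lowest linear index per component (C-order scan)
    member = plateau_flat > 0
    pointer[member] = reps[plateau_flat[member]]

    # Pointer jumping to the basin root.
    while True:
        nxt = pointer[pointer]
        if np.array_equal(nxt, pointer):
            break
        pointer = nxt

    roots = np.unique(pointer[fg_flat])
    labels_flat = np.zeros(n, dtype=np.int32)
    root_to_label = {int(r): i + 1 for i, r in enumerate(np.sort(roots))}
    lut = np.zeros(n, dtype=np.int32)
    for r, l in root_to_label.items():
        lut[r] = l
    labels_flat[fg_flat] = lut[pointer[fg_flat]]
    labels = labels_flat.reshape(shape)

    if min_seed_voxels > 0:
        labels = _merge_small_seeds(labels, min_seed_voxels)

    maxima = {}
    flat_vals = values.reshape(-1)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        lin = np.flatnonzero(labels.reshape(-1) == lab)
        best = lin[np.argmax(flat_vals[lin])]
        maxima[int(lab)] = (np.unravel_index(best, shape), float(flat_vals[best]))
    # relabel contiguously 1..K (merging may have removed ids)
    remap = {old: new for new, old in enumerate(sorted(maxima), start=1)}
    out_labels = np.zeros_like(labels)
    out_maxima = {}
    for old, new in remap.items():
        out_labels[labels == old] = new
        out_maxima[new] = maxima[old]
    return SeedMap(out_labels, out_maxima, image)


def _merge_small_seeds(labels: np.ndarray, min_voxels: int) -> np.ndarray:
    """Merge seeds with < min_voxels into the neighbour sharing most boundary."""
    labels = labels.copy()
    offsets, _ = _neighbor_offsets_sorted(labels.shape)
    n_labels = int(labels.max())
    if n_labels == 0:
        return labels
    for _ in range(n_labels):  # bounded; every pass removes >= 1 small seed
        counts = np.bincount(labels.reshape(-1), minlength=n_labels + 1)
        small = np.flatnonzero((counts > 0) & (counts < min_voxels))
        small = small[small > 0]
        if len(small) == 0:
            break
        # boundary-contact counts between every ordered label pair (a -> b)
        contact = np.zeros((n_labels + 1, n_labels + 1), dtype=np.int64)
        is_small = np.zeros(n_labels + 1, dtype=bool)
        is_small[small] = True
        for off in offsets:
            nb = _shifted(labels, off, 0)
            sel = is_small[labels] & (nb != labels)
            if np.any(sel):
                np.add.at(contact, (labels[sel], nb[sel]), 1)
        for lab in small:
            row = contact[lab].copy()
            row[0] = 0  # prefer any seed neighbour over background
            target = int(np.argmax(row)) if row.max() > 0 else 0
            labels[labels == lab] = target
    return labels


def assign_chambers(
    seeds: SeedMap,
    maps: ParametricMaps,
    min_fraction: float = 0.25,
) -> ChamberLabels:
    """Assign each seed to the left or right heart from V_A/V_V evidence.

    A seed is LEFT if the arterial spill-over fraction at its maximum exceeds
    both the venous fraction and ``min_fraction``; RIGHT symmetrically; NONE
    otherwise (including exact ties).
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    va = np.asarray(maps.va)
    vv = np.asarray(maps.vv)
    if va.shape != seeds.grid.shape:
        raise ValueError(
            f"parametric maps shape {va.shape} does not match seeded image {seeds.grid.shape}"
        )
    assignment, evidence = {}, {}
    for sid, (vox, _val) in seeds.maxima.items():
        a, v = float(va[vox]), float(vv[vox])
        if a > v and a > min_fraction:
            side = Side.LEFT
        elif v > a and v > min_fraction:
            side = Side.RIGHT
        else:
            side = Side.NONE
        assignment[sid] = side
        evidence[sid] = (a, v)
    return ChamberLabels(assignment, evidence)


def chamber_mask(seeds: SeedMap, labels: ChamberLabels, side: Side) -> np.ndarray:
    """Boolean union of the voxels of all seeds assigned to ``side``."""
    if side not in (Side.LEFT, Side.RIGHT):
        raise ValueError("side must be Side.LEFT or Side.RIGHT")
    ids = labels.seeds_on(side)
    return np.isin(seeds.labels, ids)
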