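"""Synthetic gated blood-pool and dynamic water-PET phantom with known truth.

The phantom emulates the first-pass gated acquisition this package analyses:
a prolate-ellipsoid LV cavity whose volume follows a cosine curve over the
cardiac cycle, a left atrium basal to a known valve plane and joined to the
LV by a narrow neck (the activity waist the valve-plane detector looks for),
a laterally offset right-ventricular pool, and a low-activity myocardial
shell. Images are voxelised with supersampling (so analytic truth volumes
carry < 0.5% voxelisation error), blurred with a Gaussian scanner
point-spread function, and optionally Poisson-sampled on expected counts -
gated bins are count-starved, which is exactly why only a handful of gates
are practical clinically.

Gate bins are *phase-window averages* of the volume curve (a gate integrates
counts over its phase window), so per-bin truth volumes are attenuated
toward the mean by the known factor sin(pi/B)/(pi/B); coarser gating
attenuates more, which reproduces the ESV overestimation expected when few
gates are used.

A matching non-gated dynamic series is driven by gamma-variate venous and
arterial blood curves (venous bolus first) and the single-tissue water
model in the myocardium.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .imaging import (
    DEFAULT_FRAME_SCHEDULE,
    DynamicSeries,
    GatedSeries,
    VoxelGrid3D,
    expand_schedule,
)
from .kinetics import InputFunctions, ParametricMaps, simulate_tac
from .valve import Plane3D

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "gated_volume_curve",
    "make_gated_phantom",
    "make_dynamic_phantom",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, activity and noise settings of the synthetic heart.

    Defaults describe a normal resting heart imaged with a clinical protocol:
    EDV 150 mL, EF 0.60, 8 gates over the 10-50 s first-pass window, 2 mm
    isotropic voxels, 6 mm FWHM resolution, blood at 30 kBq/mL.
    """

    edv_ml: float = 150.0
    ef: float = 0.60
    n_bins: int = 8
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 2.0
    blur_fwhm_mm: float = 6.0
    blood_activity_bq_ml: float = 30_000.0
    #: detector sensitivity scale: expected counts = Bq/mL * mL * s * sensitivity
    sensitivity: float = 0.05
    noise: bool = True
    seed: int = 0
    window_s: tuple[float, float] = (10.0, 50.0)
    frame_schedule: str = DEFAULT_FRAME_SCHEDULE
    # geometry
    lv_elongation: float = 1.8
    la_volume_ml: float = 40.0
    la_elongation: float = 1.2
    rv_volume_ml: float = 140.0
    rv_gap_mm: float = 12.0
    neck_radius_mm: float = 5.0
    neck_half_length_mm: float = 4.0
    myo_thickness_mm: float = 9.0
    myo_activity_fraction: float = 0.08
    valve_z_mm: float = 35.0
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    include_rv: bool = True
    include_la: bool = True
    include_myocardium: bool = True
    supersample: int = 4
    # dynamic blood-curve parameters (gamma variates; venous bolus first)
    venous_t0_s: float = 5.0
    venous_alpha: float = 3.0
    venous_beta_s: float = 3.3
    arterial_t0_s: float = 13.0
    arterial_alpha: float = 3.0
    arterial_beta_s: float = 4.0
    recirculation_fraction: float = 0.12
    myo_mbf: float = 0.9
    myo_vt: float = 0.91

    def __post_init__(self) -> None:
        if not 0 < self.ef < 1:
            raise ValueError("EF must be a fraction in (0, 1)")
        if self.edv_ml <= 0:
            raise ValueError("EDV must be positive")
        if self.blur_fwhm_mm < 0:
            raise ValueError("blur FWHM must be non-negative")
        if self.n_bins < 2:
            raise ValueError("need at least 2 gate bins")

    @property
    def esv_ml(self) -> float:
        return self.edv_ml * (1.0 - self.ef)

    @property
    def rotation(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a phantom image."""

    config: PhantomConfig
    volumes_ml: np.ndarray  # per-bin phase-averaged LV volume
    edv_ml: float  # continuous-curve extremes
    esv_ml: float
    ef: float
    plane: Plane3D
    lv_mask: np.ndarray  # at the end-diastolic bin
    la_mask: np.ndarray
    rv_mask: np.ndarray
    myo_mask: np.ndarray
    maps: ParametricMaps  # blurred V_A / V_V truth


def gated_volume_curve(edv_ml: float, esv_ml: float, n_bins: int) -> np.ndarray:
    """Phase-window-averaged LV volume per gate bin.

    The continuous curve is V(phi) = ESV + (EDV-ESV) (1 + cos 2 pi phi) / 2
    (single end-diastole at phi=0, single end-systole at phi=0.5). Bin b
    averages V over the window of width 1/B centred on phi = b/B, giving

        V_b = ESV + (EDV-ESV)/2 * (1 + cos(2 pi b / B) * sinc(1/B))

    where sinc(1/B) = sin(pi/B)/(pi/B) < 1 is the gating attenuation: the
    fewer the bins, the more the extremes are washed toward the mean (ESV is
    overestimated, EDV underestimated).
    """
    b = np.arange(n_bins)
    attenuation = np.sinc(1.0 / n_bins)  # numpy sinc(x) = sin(pi x)/(pi x)
    return esv_ml + 0.5 * (edv_ml - esv_ml) * (1.0 + np.cos(2 * np.pi * b / n_bins) * attenuation)


# ---------------------------------------------------------------------------
# Geometry rasterisation
# ---------------------------------------------------------------------------

def _semiaxis_from_volume(volume_ml: float, elongation: float) -> float:
    """Transverse semi-axis of a prolate ellipsoid (a, a, elongation*a)."""
    return float((3.0 * volume_ml * 1000.0 / (4.0 * np.pi * elongation)) ** (1.0 / 3.0))


def _make_grid(config: PhantomConfig) -> VoxelGrid3D:
    shape = tuple(config.shape)
    spacing = (config.spacing_mm,) * 3
    origin = tuple(-(n - 1) / 2.0 * config.spacing_mm for n in shape)
    return VoxelGrid3D(np.zeros(shape), spacing, origin, np.eye(3))


class _Rasteriser:
    """Supersampled fractional-occupancy rasterisation in phantom-local coords."""

    def __init__(self, grid: VoxelGrid3D, rotation: np.ndarray, supersample: int):
        self.grid = grid
        self.rot = rotation  # local -> world
        n = supersample
        # supersample offsets within a voxel, in voxel-index units
        edges = (np.arange(n) + 0.5) / n - 0.5
        ox, oy, oz = np.meshgrid(edges, edges, edges, indexing="ij")
        self.offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)

    def occupancy(self, membership, bbox_local) -> np.ndarray:
        """Fractional occupancy of ``membership(local_points)`` on the grid.

        ``bbox_local`` is ((x0,y0,z0), (x1,y1,z1)) in local mm bounding the
        structure; only voxels intersecting it are evaluated.
        """
        lo, hi = (np.asarray(b, dtype=np.float64) for b in bbox_local)
        corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
        )
        world = corners @ self.rot.T
        ijk = self.grid.world_to_index(world)
        i_lo = np.maximum(np.floor(ijk.min(axis=0)).astype(int) - 1, 0)
        i_hi = np.minimum(np.ceil(ijk.max(axis=0)).astype(int) + 2, self.grid.shape)
        out = np.zeros(self.grid.shape)
        if np.any(i_hi <= i_lo):
            return out
        ii, jj, kk = [np.arange(i_lo[a], i_hi[a]) for a in range(3)]
        centres = np.stack(np.meshgrid(ii, jj, kk, indexing="ij"), axis=-1).reshape(-1, 3)
        sub = centres[:, None, :] + self.offsets[None, :, :]  # voxel-index units
        pts_world = self.grid.index_to_world(sub.reshape(-1, 3))
        pts_local = pts_world @ self.rot  # world -> local (rot orthonormal)
        inside = membership(pts_local).reshape(len(centres), -1)
        frac = inside.mean(axis=1)
        out[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]] = frac.reshape(
            len(ii), len(jj), len(kk)
        )
        return out


def _ellipsoid(centre, semiaxes):
    centre = np.asarray(centre, dtype=np.float64)
    semiaxes = np.asarray(semiaxes, dtype=np.float64)

    def member(p):
        q = (p - centre) / semiaxes
        return np.einsum("ij,ij->i", q, q) <= 1.0

    bbox = (centre - semiaxes, centre + semiaxes)
    return member, bbox


def _cylinder_z(centre_xy, radius, z_lo, z_hi):
    cx, cy = centre_xy

    def member(p):
        r2 = (p[:, 0] - cx) ** 2 + (p[:, 1] - cy) ** 2
        return (r2 <= radius**2) & (p[:, 2] >= z_lo) & (p[:, 2] <= z_hi)

    bbox = ((cx - radius, cy - radius, z_lo), (cx + radius, cy + radius, z_hi))
    return member, bbox


def _phantom_occupancies(config: PhantomConfig):
    """Per-structure fractional occupancies; LV per bin, the rest static."""
    grid = _make_grid(config)
    ras = _Rasteriser(grid, config.rotation, config.supersample)
    zv = config.valve_z_mm
    vols = gated_volume_curve(config.edv_ml, config.esv_ml, config.n_bins)

    occ_lv = []
    for v in vols:
        a = _semiaxis_from_volume(v, config.lv_elongation)
        c = config.lv_elongation * a
        member, bbox = _ellipsoid((0.0, 0.0, zv - c), (a, a, c))
        occ_lv.append(ras.occupancy(member, bbox))

    zero = np.zeros(grid.shape)
    occ_la = zero
    occ_neck = zero
    if config.include_la:
        a_la = _semiaxis_from_volume(config.la_volume_ml, config.la_elongation)
        c_la = config.la_elongation * a_la
        member, bbox = _ellipsoid((0.0, 0.0, zv + c_la), (a_la, a_la, c_la))
        occ_la = ras.occupancy(member, bbox)
        member, bbox = _cylinder_z(
            (0.0, 0.0), config.neck_radius_mm,
            zv - config.neck_half_length_mm, zv + config.neck_half_length_mm,
        )
        occ_neck = ras.occupancy(member, bbox)

    occ_rv = zero
    a_ed = _semiaxis_from_volume(config.edv_ml, config.lv_elongation)
    c_ed = config.lv_elongation * a_ed
    if config.include_rv:
        # prolate-ish RV with semi-axes ratios (0.7, 1.0, 1.5)
        s = float((3.0 * config.rv_volume_ml * 1000.0 / (4.0 * np.pi * 0.7 * 1.0 * 1.5)) ** (1 / 3))
        semi = np.array([0.7 * s, 1.0 * s, 1.5 * s])
        centre = (-(a_ed + config.rv_gap_mm + semi[0]), 0.0, zv - semi[2] - 2.0)
        member, bbox = _ellipsoid(centre, semi)
        occ_rv = ras.occupancy(member, bbox)

    occ_myo = None
    if config.include_myocardium:
        th = config.myo_thickness_mm
        outer_member, outer_bbox = _ellipsoid(
            (0.0, 0.0, zv - c_ed), (a_ed + th, a_ed + th, c_ed + th)
        )

        def outer_clipped(p):
            return outer_member(p) & (p[:, 2] <= zv)

        occ_outer = ras.occupancy(outer_clipped, outer_bbox)
        occ_myo = [np.clip(occ_outer - lv - occ_neck, 0.0, 1.0) for lv in occ_lv]

    return grid, vols, occ_lv, occ_la, occ_neck, occ_rv, occ_myo


def _blur(values: np.ndarray, config: PhantomConfig) -> np.ndarray:
    if config.blur_fwhm_mm <= 0:
        return values
    sigma = config.blur_fwhm_mm * _FWHM_TO_SIGMA / config.spacing_mm
    return gaussian_filter(values, sigma)


def _truth_plane(config: PhantomConfig) -> Plane3D:
    rot = config.rotation
    point = rot @ np.array([0.0, 0.0, config.valve_z_mm])
    normal = rot @ np.array([0.0, 0.0, -1.0])  # apex at -z: apical side positive
    return Plane3D(point=point, normal=normal)


def make_gated_phantom(config: PhantomConfig | None = None):
    """Build the gated blood-pool series and its ground truth.

    Returns ``(GatedSeries, PhantomTruth)``. With the same config (and seed)
    the output is bit-identical.
    """
    config = config or PhantomConfig()
    grid, vols, occ_lv, occ_la, occ_neck, occ_rv, occ_myo = _phantom_occupancies(config)
    a0 = config.blood_activity_bq_ml

    rng = np.random.default_rng(config.seed)
    bin_dur = (config.window_s[1] - config.window_s[0]) / config.n_bins
    scale = grid.voxel_volume_ml * bin_dur * config.sensitivity

    bins = []
    blood_left_sum = np.zeros(grid.shape)
    for b in range(config.n_bins):
        blood_left = np.maximum(np.maximum(occ_lv[b], occ_la), occ_neck)
        blood_left_sum += blood_left
        act = a0 * np.maximum(blood_left, occ_rv)
        if occ_myo is not None:
            act = act + a0 * config.myo_activity_fraction * occ_myo[b]
        act = _blur(act, config)
        if config.noise:
            counts = rng.poisson(act * scale)
            act = counts / scale
        bins.append(grid.with_values(act))

    va_map = _blur(np.clip(blood_left_sum / config.n_bins, 0.0, 1.0), config)
    vv_map = _blur(occ_rv, config)
    total = va_map + vv_map
    over = total > 1.0
    if np.any(over):  # guard against blur overlap
        va_map[over] /= total[over]
        vv_map[over] /= total[over]

    truth = PhantomTruth(
        config=config,
        volumes_ml=vols,
        edv_ml=config.edv_ml,
        esv_ml=config.esv_ml,
        ef=config.ef,
        plane=_truth_plane(config),
        lv_mask=occ_lv[0] >= 0.5,
        la_mask=occ_la >= 0.5,
        rv_mask=occ_rv >= 0.5,
        # strict > so a 50/50 cavity/wall boundary voxel counts as cavity only
        myo_mask=(occ_myo[0] > 0.5) if occ_myo is not None else np.zeros(grid.shape, bool),
        maps=ParametricMaps.from_blood_fractions(va_map, vv_map),
    )
    return GatedSeries(tuple(bins), config.window_s), truth


# ---------------------------------------------------------------------------
# Dynamic phantom
# ---------------------------------------------------------------------------

def _gamma_variate(t, t0, alpha, beta, amplitude, recirc_fraction):
    tau = np.clip(np.asarray(t, dtype=np.float64) - t0, 0.0, None)
    peak_tau = alpha * beta
    bolus = (tau / peak_tau) ** alpha * np.exp(alpha - tau / beta)
    recirc = recirc_fraction * (1.0 - np.exp(-tau / 30.0)) * np.exp(-tau / 250.0)
    return amplitude * (bolus + recirc)


def blood_curves(config: PhantomConfig, times: np.ndarray):
    """Ground-truth arterial and venous blood curves at the given times."""
    a0 = config.blood_activity_bq_ml
    cv = _gamma_variate(
        times, config.venous_t0_s, config.venous_alpha, config.venous_beta_s,
        a0, config.recirculation_fraction,
    )
    ca = _gamma_variate(
        times, config.arterial_t0_s, config.arterial_alpha, config.arterial_beta_s,
        a0, config.recirculation_fraction,
    )
    return ca, cv


def make_dynamic_phantom(config: PhantomConfig | None = None):
    """Build the non-gated dynamic series, its input functions and truth maps.

    Geometry is static at the cycle-averaged LV volume. Left-heart blood
    voxels carry the arterial curve, RV voxels the venous curve, myocardial
    voxels the single-tissue model response; frames are time-averages over
    the schedule and are blurred and (optionally) Poisson-sampled like the
    gated data.
    """
    config = config or PhantomConfig()
    durations = expand_schedule(config.frame_schedule)
    ends = np.cumsum(durations)
    starts = np.concatenate([[0.0], ends[:-1]])
    mids = 0.5 * (starts + ends)

    mean_vol = float(np.mean(gated_volume_curve(config.edv_ml, config.esv_ml, config.n_bins)))
    static = replace(config, edv_ml=mean_vol, ef=1e-6, n_bins=2)  # quasi-static geometry
    grid, _, occ_lv, occ_la, occ_neck, occ_rv, occ_myo = _phantom_occupancies(static)
    occ_left = np.maximum(np.maximum(occ_lv[0], occ_la), occ_neck)
    occ_m = occ_myo[0] if occ_myo is not None else np.zeros(grid.shape)

    # fine-grid blood curves drive the frame averages
    fine_t = np.arange(0.0, ends[-1] + 0.5, 0.5)
    ca_fine, cv_fine = blood_curves(config, fine_t)
    inputs_fine = InputFunctions(times=fine_t[1:], ca=ca_fine[1:], cv=cv_fine[1:])
    tac_left = simulate_tac(0.0, 1.0, 1.0, 0.0, inputs_fine, starts, ends)
    tac_rv = simulate_tac(0.0, 1.0, 0.0, 1.0, inputs_fine, starts, ends)
    tac_myo = simulate_tac(config.myo_mbf, config.myo_vt, 0.0, 0.0, inputs_fine, starts, ends)

    rng = np.random.default_rng(config.seed + 1)
    frames = []
    for f in range(len(durations)):
        act = occ_left * tac_left[f] + occ_rv * tac_rv[f] + occ_m * tac_myo[f]
        act = _blur(act, config)
        if config.noise:
            scale = grid.voxel_volume_ml * durations[f] * config.sensitivity
            act = rng.poisson(act * scale) / scale
        frames.append(grid.with_values(act))
    dynamic = DynamicSeries(tuple(frames), starts, ends)

    inputs = InputFunctions(
        times=mids,
        ca=simulate_tac(0.0, 1.0, 1.0, 0.0, inputs_fine, starts, ends),
        cv=simulate_tac(0.0, 1.0, 0.0, 1.0, inputs_fine, starts, ends),
    )
    va = _blur(occ_left, config)
    vv = _blur(occ_rv, config)
    total = va + vv
    over = total > 1.0
    if np.any(over):
        va[over] /= total[over]
        vv[over] /= total[over]
    maps = ParametricMaps(
        mbf=config.myo_mbf * _blur(occ_m, config),
        vt=np.full(grid.shape, config.myo_vt),
        va=va,
        vv=vv,
        rss=np.zeros(grid.shape),
        fitted=np.ones(grid.shape, dtype=bool),
    )
    return dynamic, inputs, maps
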