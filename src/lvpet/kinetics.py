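"""Single-tissue-compartment kinetics for freely diffusible water PET.

A voxel's activity is modelled as perfused tissue plus arterial and venous
blood spill-over:

    C_PET(t) = (1 - V_A - V_V) * MBF * [C_A(t) (x) exp(-(MBF/V_T) t)]
               + V_A * C_A(t) + V_V * C_V(t)

with MBF the myocardial blood flow (mL.min^-1.mL^-1), V_T the partition
(distribution) volume of water (mL.mL^-1), and V_A / V_V the arterial and
venous spill-over fractions. The fit is the classic basis-function
linearisation: for each clearance rate k2 = MBF/V_T on a fixed grid the model
is linear in (alpha, V_A, V_V) with alpha = (1 - V_A - V_V) * MBF, and the
non-negativity-constrained least-squares solution is found exactly by
enumerating the support subsets of the three columns. The voxelwise V_A and
V_V maps are what the chamber-assignment step consumes: a seed whose maximum
is mostly arterial blood belongs to the left heart, mostly venous to the
right.

Convolution is carried out on a uniform sub-second grid (reconstruction
frames are >= 5 s) and model frame values are time-averages over each frame
interval.
No delay or dispersion correction is applied to the input functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .imaging import DynamicSeries

__all__ = [
    "InputFunctions",
    "ParametricMaps",
    "simulate_tac",
    "fit_voxelwise",
    "fit_tacs",
    "extract_input_functions",
    "default_k2_grid",
    "NoBolusError",
]

#: Floor on (1 - V_A - V_V) when recovering MBF from the tissue coefficient.
MIN_TISSUE_FRACTION = 0.05


class NoBolusError(RuntimeError):
    """Raised when a dynamic series shows no first-pass bolus."""


@dataclass(frozen=True)
class InputFunctions:
    """Arterial and venous (right-ventricular) whole-blood input curves.

    Values are activity concentrations (Bq/mL) at the given sample times
    (seconds post injection, typically frame mid-times). The venous bolus
    transits the right heart first, so its peak must not come after the
    arterial peak.
    """

    times: np.ndarray
    ca: np.ndarray
    cv: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        ca = np.asarray(self.ca, dtype=np.float64)
        cv = np.asarray(self.cv, dtype=np.float64)
        if not (times.shape == ca.shape == cv.shape) or times.ndim != 1:
            raise ValueError("times, ca, cv must be 1D arrays of equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(ca < 0) or np.any(cv < 0):
            raise ValueError("input functions must be non-negative")
        if cv.max() > 0 and times[int(np.argmax(cv))] > times[int(np.argmax(ca))]:
            raise ValueError("venous peak must not come after the arterial peak")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ca", ca)
        object.__setattr__(self, "cv", cv)


@dataclass(frozen=True)
class ParametricMaps:
    """Voxelwise single-tissue fit results.

    ``fitted`` is False where the voxel TAC was empty (all-zero); parameter
    invariants (0 <= V_A, V_V, V_A+V_V <= 1; MBF >= 0) hold on fitted voxels.
    """

    mbf: np.ndarray
    vt: np.ndarray
    va: np.ndarray
    vv: np.ndarray
    rss: np.ndarray
    fitted: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.mbf, self.vt, self.va, self.vv, self.rss, self.fitted]
        shape = np.asarray(self.mbf).shape
        if any(np.asarray(a).shape != shape for a in arrays):
            raise ValueError("all parametric maps must share one shape")
        m = np.asarray(self.fitted, dtype=bool)
        va, vv = np.asarray(self.va), np.asarray(self.vv)
        if np.any(va[m] < -1e-9) or np.any(vv[m] < -1e-9) or np.any(va[m] + vv[m] > 1 + 1e-9):
            raise ValueError("spill-over fractions must satisfy 0 <= V_A, V_V, V_A+V_V <= 1")
        if np.any(np.asarray(self.mbf)[m] < -1e-9):
            raise ValueError("MBF must be non-negative")

    @classmethod
    def from_blood_fractions(cls, va: np.ndarray, vv: np.ndarray) -> "ParametricMaps":
        """Maps carrying only spill-over fractions (e.g. precomputed inputs)."""
        zeros = np.zeros_like(np.asarray(va, dtype=np.float64))
        return cls(
            mbf=zeros,
            vt=zeros,
            va=np.asarray(va, dtype=np.float64),
            vv=np.asarray(vv, dtype=np.float64),
            rss=zeros,
            fitted=np.ones(zeros.shape, dtype=bool),
        )


def default_k2_grid(k2_min: float = 0.01, k2_max: float = 8.0, n: int = 64) -> np.ndarray:
    """Log-spaced clearance-rate grid (min^-1) covering plausible MBF/V_T."""
    if k2_min <= 0 or k2_max <= k2_min or n < 2:
        raise ValueError("k2 grid must be positive, increasing, with n >= 2")
    return np.geomspace(k2_min, k2_max, n)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _fine_grid(times, values, t_end, dt):
    """Resample an input curve to a uniform grid on [0, t_end].

    Linear interpolation, zero before the first sample (pre-arrival blood is
    tracer-free), last value held after the final sample.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        values = np.concatenate([[0.0], values])
    return t, np.interp(t, times, values)


def _frame_average(t, fine, frame_start, frame_end):
    """Trapezoidal time-average of a fine-grid curve over each frame."""
    integral = np.concatenate([[0.0], cumulative_trapezoid(fine, t)])
    start_i = np.interp(frame_start, t, integral)
    end_i = np.interp(frame_end, t, integral)
    return (end_i - start_i) / (np.asarray(frame_end) - np.asarray(frame_start))


def _convolve_exp(t, ca_fine, k2_per_s, dt):
    """C_A (x) exp(-k2 t) on the fine grid (trapezoidal discrete convolution,
    per second): the endpoint correction makes the quadrature second-order."""
    kernel = np.exp(-k2_per_s * t)
    conv = np.convolve(ca_fine, kernel)[: len(t)]
    conv = conv - 0.5 * (ca_fine[0] * kernel + ca_fine * kernel[0])
    return conv * dt


def simulate_tac(
    mbf: float,
    vt: float,
    va: float,
    vv: float,
    inputs: InputFunctions,
    frame_start: np.ndarray,
    frame_end: np.ndarray,
    dt: float = 0.25,
) -> np.ndarray:
    """Frame-averaged single-tissue model TAC (Bq/mL per frame)."""
    if va < 0 or vv < 0 or va + vv > 1 + 1e-12:
        raise ValueError(f"spill-over fractions invalid: V_A={va}, V_V={vv}")
    if mbf < 0:
        raise ValueError("MBF must be non-negative")
    if mbf > 0 and vt <= 0:
        raise ValueError("V_T must be positive when MBF > 0")
    frame_start = np.asarray(frame_start, dtype=np.float64)
    frame_end = np.asarray(frame_end, dtype=np.float64)
    t_end = float(frame_end[-1])
    t, ca_fine = _fine_grid(inputs.times, inputs.ca, t_end, dt)
    _, cv_fine = _fine_grid(inputs.times, inputs.cv, t_end, dt)

    tac_fine = va * ca_fine + vv * cv_fine
    if mbf > 0 and (1.0 - va - vv) > 0:
        k2_per_s = (mbf / vt) / 60.0
        conv = _convolve_exp(t, ca_fine, k2_per_s, dt)
        tac_fine = tac_fine + (1.0 - va - vv) * (mbf / 60.0) * conv
    return _frame_average(t, tac_fine, frame_start, frame_end)


# ---------------------------------------------------------------------------
# Basis-function fit
# ---------------------------------------------------------------------------

def _basis_matrix(inputs, frame_start, frame_end, k2_grid, dt):
    """Frame-averaged regressors: per-k2 tissue basis, C_A and C_V columns."""
    t_end = float(frame_end[-1])
    t, ca_fine = _fine_grid(inputs.times, inputs.ca, t_end, dt)
    _, cv_fine = _fine_grid(inputs.times, inputs.cv, t_end, dt)
    ca_bar = _frame_average(t, ca_fine, frame_start, frame_end)
    cv_bar = _frame_average(t, cv_fine, frame_start, frame_end)
    basis = np.empty((len(k2_grid), len(frame_start)))
    for j, k2 in enumerate(k2_grid):
        conv = _convolve_exp(t, ca_fine, k2 / 60.0, dt)
        basis[j] = _frame_average(t, conv, frame_start, frame_end)
    return basis, ca_bar, cv_bar


def _ls_candidate(cols: np.ndarray, Y: np.ndarray):
    """Unconstrained LS coefficients of ``cols`` (n_obs, k) against Y; None
    if the Gram matrix is ill-conditioned."""
    gram = cols.T @ cols
    if gram.size and np.linalg.cond(gram) > 1e12:
        return None
    return np.linalg.solve(gram, cols.T @ Y)


def _nnls_enumerate(X: np.ndarray, Y: np.ndarray):
    """Exact constrained least squares for the 3-column kinetic design.

    Minimises ||Y - X beta||^2 subject to beta >= 0 and beta[1] + beta[2]
    (the blood fractions V_A + V_V) <= 1, per column of Y, by enumerating
    every active set: the 2^3 coordinate supports with the sum constraint
    inactive, plus all supports restricted to the boundary V_A + V_V = 1.
    Primal-feasible candidates of minimum RSS are exact constrained optima
    (the global QP minimiser is feasible for its own active set).

    Returns (beta (3, n), rss (n,)).
    """
    n = Y.shape[1]
    best_rss = np.einsum("ij,ij->j", Y, Y)  # empty support: beta = 0
    best_beta = np.zeros((3, n))

    def consider(beta_full: np.ndarray, feasible: np.ndarray) -> None:
        nonlocal best_rss, best_beta
        if not np.any(feasible):
            return
        resid = Y - X @ beta_full
        rss = np.einsum("ij,ij->j", resid, resid)
        better = feasible & (rss < best_rss - 1e-12)
        if np.any(better):
            best_rss[better] = rss[better]
            best_beta[:, better] = beta_full[:, better]

    tol = 1e-12
    # interior of the sum constraint: plain coordinate supports
    for k in range(1, 4):
        for support in combinations(range(3), k):
            beta_s = _ls_candidate(X[:, support], Y)
            if beta_s is None:
                continue
            beta_full = np.zeros((3, n))
            for row, col in enumerate(support):
                beta_full[col] = beta_s[row]
            feasible = np.all(beta_s >= -tol, axis=0)
            feasible &= (beta_full[1] + beta_full[2]) <= 1.0 + tol
            consider(np.clip(beta_full, 0.0, None), feasible)

    # boundary V_A + V_V = 1: substitute vv = 1 - va, regress Y - cv on the
    # remaining free directions
    b_col, ca, cv = X[:, 0], X[:, 1], X[:, 2]
    Yb = Y - cv[:, None]
    d = (ca - cv)[:, None]
    cases = [
        ((b_col[:, None], d), ("alpha", "va")),
        ((d,), ("va",)),
        ((b_col[:, None],), ("alpha",)),  # va = 0, vv = 1
        ((), ()),  # beta = (0, 0, 1)
    ]
    for cols, names in cases:
        beta_full = np.zeros((3, n))
        beta_full[2] = 1.0
        if cols:
            mat = np.hstack(cols)
            beta_s = _ls_candidate(mat, Yb)
            if beta_s is None:
                continue
            feasible = np.ones(n, dtype=bool)
            for row, name in enumerate(names):
                if name == "alpha":
                    beta_full[0] = beta_s[row]
                    feasible &= beta_s[row] >= -tol
                else:  # va
                    beta_full[1] = beta_s[row]
                    beta_full[2] = 1.0 - beta_s[row]
                    feasible &= (beta_s[row] >= -tol) & (beta_s[row] <= 1.0 + tol)
        else:
            feasible = np.ones(n, dtype=bool)
        consider(np.clip(beta_full, 0.0, None), feasible)
    # va = 1, vv = 0 boundary corner with free alpha
    Ya = Y - ca[:, None]
    beta_s = _ls_candidate(b_col[:, None], Ya)
    if beta_s is not None:
        beta_full = np.zeros((3, n))
        beta_full[0] = beta_s[0]
        beta_full[1] = 1.0
        consider(np.clip(beta_full, 0.0, None), beta_s[0] >= -tol)
    return best_beta, best_rss


def fit_tacs(
    tacs: np.ndarray,
    inputs: InputFunctions,
    frame_start: np.ndarray,
    frame_end: np.ndarray,
    k2_grid: np.ndarray | None = None,
    dt: float = 0.25,
):
    """Fit the single-tissue model to TACs of shape (n_tacs, n_frames).

    Returns a dict of 1D arrays: mbf, vt, va, vv, rss, fitted. For each TAC
    the returned parameters attain the minimum RSS over the k2 grid among
    non-negativity-constrained linear solutions.
    """
    tacs = np.atleast_2d(np.asarray(tacs, dtype=np.float64))
    if k2_grid is None:
        k2_grid = default_k2_grid()
    k2_grid = np.asarray(k2_grid, dtype=np.float64)
    if np.any(k2_grid <= 0):
        raise ValueError("k2 grid must be positive")
    basis, ca_bar, cv_bar = _basis_matrix(inputs, frame_start, frame_end, k2_grid, dt)

    n = tacs.shape[0]
    fitted = np.any(tacs != 0, axis=1)
    Y = tacs[fitted].T  # (n_frames, n_fit)
    n_fit = Y.shape[1]
    out = {k: np.zeros(n) for k in ("mbf", "vt", "va", "vv", "rss")}
    out["fitted"] = fitted
    if n_fit == 0:
        return out

    best_rss = np.full(n_fit, np.inf)
    best_beta = np.zeros((3, n_fit))
    best_k2 = np.zeros(n_fit)
    for j, k2 in enumerate(k2_grid):
        X = np.column_stack([basis[j], ca_bar, cv_bar])
        beta, rss = _nnls_enumerate(X, Y)
        better = rss < best_rss - 1e-12
        if np.any(better):
            best_rss[better] = rss[better]
            best_beta[:, better] = beta[:, better]
            best_k2[better] = k2

    alpha, va, vv = best_beta  # alpha = (1 - V_A - V_V) * MBF / 60 on the 1 s grid
    tissue_frac = np.maximum(1.0 - va - vv, MIN_TISSUE_FRACTION)
    mbf = 60.0 * alpha / tissue_frac
    vt = np.where(mbf > 0, mbf / best_k2, 0.0)

    out["mbf"][fitted] = mbf
    out["vt"][fitted] = vt
    out["va"][fitted] = np.clip(va, 0.0, 1.0)
    out["vv"][fitted] = np.clip(vv, 0.0, 1.0)
    out["rss"][fitted] = best_rss
    return out


def fit_voxelwise(
    dynamic: DynamicSeries,
    inputs: InputFunctions,
    k2_grid: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    dt: float = 0.25,
) -> ParametricMaps:
    """Voxelwise basis-function fit of the dynamic series.

    ``mask`` optionally restricts the fit (e.g. to foreground voxels); voxels
    outside it are left unfitted. All-zero voxel TACs are flagged unfitted.
    """
    tacs4d = dynamic.voxel_tacs()
    shape = tacs4d.shape[:3]
    flat = tacs4d.reshape(-1, dynamic.n_frames)
    if mask is not None:
        mask_flat = np.asarray(mask, dtype=bool).reshape(-1)
    else:
        mask_flat = np.ones(flat.shape[0], dtype=bool)

    sub = fit_tacs(
        flat[mask_flat], inputs, dynamic.frame_start, dynamic.frame_end, k2_grid, dt
    )
    full = {}
    for key in ("mbf", "vt", "va", "vv", "rss"):
        arr = np.zeros(flat.shape[0])
        arr[mask_flat] = sub[key]
        full[key] = arr.reshape(shape)
    fitted = np.zeros(flat.shape[0], dtype=bool)
    fitted[mask_flat] = sub["fitted"]
    return ParametricMaps(
        mbf=full["mbf"], vt=full["vt"], va=full["va"], vv=full["vv"],
        rss=full["rss"], fitted=fitted.reshape(shape),
    )


# ---------------------------------------------------------------------------
# Input-function extraction
# ---------------------------------------------------------------------------

def extract_input_functions(
    dynamic: DynamicSeries,
    n_clusters: int = 4,
    first_pass_end_s: float = 60.0,
    percentile: float = 95.0,
    seed: int = 0,
) -> InputFunctions:
    """Estimate arterial and venous blood curves from the dynamic series.

    High-amplitude voxels of the first pass are clustered (k-means on
    L2-normalised TACs); the venous curve is the earliest-peaking first-pass
    cluster and the arterial curve the latest-peaking one. Each cluster's
    curve is the mean TAC of its highest-amplitude members, which keeps edge
    (partial-volume) voxels from depressing the amplitude.
    """
    from sklearn.cluster import KMeans

    tacs4d = dynamic.voxel_tacs()
    if tacs4d.max() <= 0:
        raise NoBolusError("no activity above zero in the dynamic series")
    mids = dynamic.mid_times
    early = mids <= first_pass_end_s
    if not np.any(early):
        raise NoBolusError("no frames within the first-pass window")
    early_max = tacs4d[..., early].max(axis=-1)
    thresh = np.percentile(early_max, percentile)
    if thresh <= 0:
        raise NoBolusError("first-pass activity indistinguishable from background")
    sel = early_max >= thresh
    tacs = tacs4d[sel]  # (n_sel, n_frames)

    norms = np.linalg.norm(tacs, axis=1, keepdims=True)
    normed = tacs / np.maximum(norms, 1e-12)
    k = min(n_clusters, len(tacs))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(normed)

    curves, peaks = [], []
    for c in range(k):
        members = tacs[labels == c]
        if len(members) == 0:
            continue
        amp = members.max(axis=1)
        top = members[amp >= np.percentile(amp, 90.0)]
        curve = top.mean(axis=0)
        peak_t = mids[int(np.argmax(curve))]
        if peak_t <= first_pass_end_s and curve.max() >= 0.5 * tacs.max():
            curves.append(curve)
            peaks.append(peak_t)
    if len(curves) < 2:
        raise NoBolusError("could not separate venous and arterial first-pass pools")
    # earliest peak = venous (right heart), latest = arterial (left heart /
    # aorta); ties between clusters peaking in the same frame go to the
    # higher-amplitude (purer-blood) cluster
    amps = [c.max() for c in curves]
    i_cv = min(range(len(curves)), key=lambda i: (peaks[i], -amps[i]))
    i_ca = max(range(len(curves)), key=lambda i: (peaks[i], amps[i]))
    cv = curves[i_cv]
    ca = curves[i_ca]
    return InputFunctions(times=mids, ca=ca, cv=cv)
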