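"""Agreement statistics for paired measurements (method vs reference,
observer vs observer): Bland-Altman with the repeatability coefficient,
relative bias, intraclass correlation, Pearson correlation, and the paired
Wilcoxon signed-rank test.

The ICC is the two-way random-effects, absolute-agreement, single-measurement
form, commonly written ICC(2,1). This choice matters: consistency-type ICCs
ignore systematic bias between the two measurements and would be higher
whenever one method reads systematically high. The 95% CI follows the
McGraw & Wong F-distribution construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "BlandAltmanResult",
    "ICCResult",
    "bland_altman",
    "relative_bias",
    "icc_absolute",
    "pearson_r",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class PairedSeries:
    """Two equal-length measurement series in the same units.

    By convention ``b`` is the reference (e.g. CMR) when one exists.
    """

    a: np.ndarray
    b: np.ndarray
    labels: tuple | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
            raise ValueError("paired series must be equal-length 1D arrays with n >= 2")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("paired series must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n(self) -> int:
        return len(self.a)

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    rpc: float  # repeatability coefficient, 1.96 * SD of differences
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float


def bland_altman(pairs: PairedSeries) -> BlandAltmanResult:
    """Mean bias, SD of differences, RPC = 1.96*SD, and limits of agreement."""
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rpc = 1.96 * sd
    return BlandAltmanResult(bias=bias, sd=sd, rpc=rpc, loa_low=bias - rpc, loa_high=bias + rpc)


def relative_bias(pairs: PairedSeries) -> tuple[float, float]:
    """Mean and SD of the per-subject percent difference 100*(a-b)/b."""
    if np.any(pairs.b == 0):
        raise ValueError("reference series contains zeros; percent bias undefined")
    pct = 100.0 * pairs.differences / pairs.b
    return float(pct.mean()), float(pct.std(ddof=1))


def icc_absolute(pairs: PairedSeries, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares over n subjects x k=2
    raters; the CI uses the McGraw & Wong F-based construction.
    """
    if pairs.n < 3:
        raise ValueError("ICC needs n >= 3 subjects")
    data = np.column_stack([pairs.a, pairs.b])
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise ValueError("zero total variance; ICC undefined")

    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_rater

    msr = ss_subj / (n - 1)  # between-subjects ("rows")
    msc = ss_rater / (k - 1)  # between-raters ("columns")
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 0.0

    # McGraw & Wong CI for ICC(A,1)
    alpha = 1.0 - confidence
    if icc >= 1.0 - 1e-12:
        return ICCResult(icc=float(icc), ci_low=1.0, ci_high=1.0)
    a_coef = k * icc / (n * (1.0 - icc))
    b_coef = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
    denom_ab = a_coef * msc + b_coef * mse
    if np.isfinite(denom_ab) and denom_ab > 0:
        v = denom_ab**2 / (
            (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        ci_low = ci_high = icc
    return ICCResult(icc=float(icc), ci_low=float(ci_low), ci_high=float(ci_high))


def pearson_r(pairs: PairedSeries) -> float:
    """Pearson product-moment correlation between the two series."""
    if pairs.n < 3:
        raise ValueError("Pearson r needs n >= 3")
    if pairs.a.std() == 0 or pairs.b.std() == 0:
        raise ValueError("zero variance in one series; r undefined")
    return float(stats.pearsonr(pairs.a, pairs.b).statistic)


def wilcoxon_signed_rank(pairs: PairedSeries, exact_max_n: int = 25):
    """Paired Wilcoxon signed-rank test: (statistic, two-sided p).

    Zero differences are dropped; ties get mid-ranks. The exact null
    distribution is used for n <= ``exact_max_n`` (and no tied absolute
    differences), the normal approximation with continuity correction above.
    """
    d = pairs.differences
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= exact_max_n and not has_ties) else "approx"
    res = stats.wilcoxon(d, correction=True, method=method)
    return float(res.statistic), float(res.pvalue)
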