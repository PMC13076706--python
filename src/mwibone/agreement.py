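"""Method-comparison statistics for paired volume measurements.

Conventions (chosen to be explicit, since they change the numbers):

* Lin's CCC uses **sample** (n−1) moments; the bias-correction factor is
  Cb = CCC / r.
* Bland–Altman works on percent differences with the **reference** as
  denominator: d_i = 100 (est_i − ref_i)/ref_i; LoA = bias ± 1.96 SD.
* Deming regression uses error-variance ratio λ = 1 (orthogonal regression)
  with sample moments.
* The Wilcoxon signed-rank test is exact (full sign-enumeration) at the
  small n used here.
* Bootstrap CIs are percentile intervals over specimen-level resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "PairedVolumes",
    "AgreementReport",
    "pearson_fisher",
    "lins_ccc",
    "bland_altman_percent",
    "deming",
    "paired_tests",
    "mape",
    "bootstrap_ci",
    "icc_2_1",
    "compare",
]


@dataclass
class PairedVolumes:
    """Reference and estimated volumes for the same specimens."""

    specimens: list
    reference_ul: np.ndarray
    estimate_ul: np.ndarray

    def __post_init__(self):
        self.reference_ul = np.asarray(self.reference_ul, dtype=float)
        self.estimate_ul = np.asarray(self.estimate_ul, dtype=float)
        if self.reference_ul.shape != self.estimate_ul.shape:
            raise ValueError("reference and estimate must align")
        if self.reference_ul.size < 3:
            raise ValueError("need at least 3 paired specimens")
        if np.any(self.reference_ul <= 0) or np.any(self.estimate_ul <= 0):
            raise ValueError("volumes must be positive")


@dataclass
class AgreementReport:
    r: float
    r_p: float
    r_fisher_ci: tuple
    r_boot_ci: tuple
    ccc: float
    cb: float
    ccc_boot_ci: tuple
    bias_percent: float
    sd_percent: float
    loa_percent: tuple
    bias_boot_ci: tuple
    mean_diff_ul: float
    mean_diff_boot_ci: tuple
    t_stat: float
    t_df: int
    t_p: float
    wilcoxon_p: float
    mape_percent: float
    deming_slope: float
    deming_intercept: float
    deming_slope_boot_ci: tuple

    def to_dict(self) -> dict:
        return asdict(self)


def _check_variance(x, y):
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the inputs")


def pearson_fisher(x, y):
    """Pearson r with the Fisher-z 95% CI and two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Fisher CI needs n >= 4")
    _check_variance(x, y)
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(n - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half)), float(res.pvalue)


def lins_ccc(x, y):
    """Lin's concordance correlation (sample moments) and accuracy factor Cb."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    _check_variance(x, y)
    sx = np.var(x, ddof=1)
    sy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    ccc = 2 * sxy / (sx + sy + (x.mean() - y.mean()) ** 2)
    r = sxy / np.sqrt(sx * sy)
    return float(ccc), float(ccc / r)


def bland_altman_percent(reference, estimate):
    """Bias, SD, and 95% limits of agreement of percent differences vs reference."""
    reference = np.asarray(reference, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference values must be positive")
    d = 100.0 * (estimate - reference) / reference
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def deming(x, y, lambda_ratio: float = 1.0):
    """Deming (errors-in-both-variables) regression with variance ratio λ."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    sx = np.var(x, ddof=1)
    sy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        raise ValueError("zero covariance: Deming slope undefined")
    lam = lambda_ratio
    slope = (sy - lam * sx + np.sqrt((sy - lam * sx) ** 2 + 4 * lam * sxy**2)) / (2 * sxy)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def paired_tests(x, y):
    """Paired t and exact Wilcoxon signed-rank on d = y − x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    d = y - x
    if np.all(d == 0):
        raise ValueError("all differences zero: Wilcoxon undefined")
    t_res = stats.ttest_rel(y, x)
    w_res = stats.wilcoxon(y, x, method="exact")
    return (
        float(t_res.statistic),
        int(x.size - 1),
        float(t_res.pvalue),
        float(w_res.pvalue),
        float(d.mean()),
    )


def mape(reference, estimate) -> float:
    """Mean absolute percent error relative to the reference."""
    reference = np.asarray(reference, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference values must be positive")
    return float(np.mean(100.0 * np.abs(estimate - reference) / reference))


def bootstrap_ci(statistic, x, y, n_boot: int = 10000, seed: int = 0):
    """Percentile 95% CI of ``statistic(x*, y*)`` over paired resamples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    import warnings

    rng = np.random.default_rng(seed)
    n = x.size
    vals = []
    failures = 0
    with warnings.catch_warnings():
        # degenerate resamples (all pairs identical) are expected at small n
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                val = statistic(x[idx], y[idx])
            except Exception:
                failures += 1
                continue
            if np.isfinite(val):
                vals.append(val)
            else:
                failures += 1
    if failures > n_boot / 2:
        raise RuntimeError(f"statistic failed on {failures}/{n_boot} bootstrap resamples")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def icc_2_1(matrix) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete 2-D matrix with >= 2 rows and columns")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be complete (no missing values)")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        raise ValueError("no variance: ICC undefined")
    return float((ms_r - ms_e) / denom)


def compare(pairs: PairedVolumes, n_boot: int = 10000, seed: int = 0) -> AgreementReport:
    """Run the full agreement panel on one reference/estimate pairing."""
    x, y = pairs.reference_ul, pairs.estimate_ul
    r, rlo, rhi, r_p = pearson_fisher(x, y)
    ccc, cb = lins_ccc(x, y)
    bias, sd, loa_lo, loa_hi = bland_altman_percent(x, y)
    slope, intercept = deming(x, y)
    t_stat, t_df, t_p, w_p, mean_diff = paired_tests(x, y)
    mape_val = mape(x, y)

    r_bci = bootstrap_ci(lambda a, b: stats.pearsonr(a, b).statistic, x, y, n_boot, seed)
    ccc_bci = bootstrap_ci(lambda a, b: lins_ccc(a, b)[0], x, y, n_boot, seed + 1)
    bias_bci = bootstrap_ci(lambda a, b: bland_altman_percent(a, b)[0], x, y, n_boot, seed + 2)
    md_bci = bootstrap_ci(lambda a, b: float(np.mean(b - a)), x, y, n_boot, seed + 3)
    slope_bci = bootstrap_ci(lambda a, b: deming(a, b)[0], x, y, n_boot, seed + 4)

    return AgreementReport(
        r=r, r_p=r_p, r_fisher_ci=(rlo, rhi), r_boot_ci=r_bci,
        ccc=ccc, cb=cb, ccc_boot_ci=ccc_bci,
        bias_percent=bias, sd_percent=sd, loa_percent=(loa_lo, loa_hi),
        bias_boot_ci=bias_bci,
        mean_diff_ul=mean_diff, mean_diff_boot_ci=md_bci,
        t_stat=t_stat, t_df=t_df, t_p=t_p, wilcoxon_p=w_p,
        mape_percent=mape_val,
        deming_slope=slope, deming_intercept=intercept,
        deming_slope_boot_ci=slope_bci,
    )
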