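"""Two-sample MR estimators: Wald ratio, fixed-effects IVW, Cochran's Q,
weighted median, and Egger regression."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedSet

__all__ = [
    "MrEstimate",
    "QResult",
    "wald_ratio",
    "wald_ratios",
    "ivw_fixed",
    "cochran_q",
    "weighted_median",
    "weighted_median_point",
    "mr_egger",
    "write_estimates_tsv",
]

Z95 = float(stats.norm.ppf(0.975))  # 1.959964...

METHODS = ("wald", "ivw_fe", "weighted_median", "egger_slope", "egger_intercept")


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate with normal/t-based uncertainty."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
        }


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity test over per-SNP estimates."""

    q: float
    df: int
    pval: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("Q must be non-negative")
        if self.df < 1:
            raise ValueError("df must be at least 1")

    def to_dict(self) -> dict:
        return {"q": self.q, "df": self.df, "pval": self.pval}


def _normal_estimate(method: str, theta: float, se: float, n_snps: int) -> MrEstimate:
    z = theta / se
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return MrEstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        pval=pval,
        n_snps=n_snps,
    )


def wald_ratio(
    beta_x: float,
    se_x: float,
    beta_y: float,
    se_y: float,
    se_order: str = "first",
) -> MrEstimate:
    """Per-SNP causal estimate beta_y / beta_x.

    ``se_order="first"`` uses the first-order delta-method SE se_y/|beta_x|
    (exposure uncertainty ignored); ``"second"`` adds the beta_y²·se_x²
    term.
    """
    if beta_x == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_x = 0")
    if not se_y > 0:
        raise ValueError("se_y must be positive")
    theta = beta_y / beta_x
    if se_order == "first":
        se = se_y / abs(beta_x)
    elif se_order == "second":
        se = np.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4)
    else:
        raise ValueError(f"se_order must be 'first' or 'second', got {se_order!r}")
    return _normal_estimate("wald", theta, se, 1)


def wald_ratios(hset: HarmonizedSet, se_order: str = "first") -> list[MrEstimate]:
    """Wald ratio for every pair in the set, in set order."""
    return [wald_ratio(p.beta_x, p.se_x, p.beta_y, p.se_y, se_order=se_order) for p in hset.pairs]


def ivw_fixed(estimates: Sequence[MrEstimate]) -> MrEstimate:
    """Fixed-effects inverse-variance-weighted combination of per-SNP estimates."""
    if not estimates:
        raise ValueError("ivw_fixed requires at least one estimate")
    theta = np.array([e.theta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return _normal_estimate("ivw_fe", pooled, se, len(estimates))


def cochran_q(estimates: Sequence[MrEstimate]) -> QResult:
    """Heterogeneity of per-SNP estimates around their IVW mean."""
    if len(estimates) < 2:
        raise ValueError("cochran_q requires at least two estimates")
    theta = np.array([e.theta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    pooled = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(estimates) - 1
    pval = float(stats.chi2.sf(q, df))
    return QResult(q=q, df=df, pval=pval)


def weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative weight at 0.5."""
    theta = np.asarray(theta, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, t))


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    se_order: str = "first",
) -> MrEstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Per-SNP Wald ratios are weighted by their inverse variance; the SE is
    the standard deviation of the estimate over ``n_boot`` replicates in
    which both betas are resampled from their reported sampling
    distributions. ``seed`` makes the bootstrap reproducible.
    """
    if len(hset) < 3:
        raise ValueError("weighted_median requires at least 3 SNPs")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if seed is None:
        raise ValueError("a bootstrap seed is required for reproducibility")

    bx = np.array([p.beta_x for p in hset.pairs])
    sx = np.array([p.se_x for p in hset.pairs])
    by = np.array([p.beta_y for p in hset.pairs])
    sy = np.array([p.se_y for p in hset.pairs])

    ests = wald_ratios(hset, se_order=se_order)
    theta = np.array([e.theta for e in ests])
    w = np.array([1.0 / e.se**2 for e in ests])
    point = weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, len(bx)))
    by_b = rng.normal(by, sy, size=(n_boot, len(by)))
    bx_b = np.where(bx_b == 0.0, np.finfo(float).tiny, bx_b)
    theta_b = by_b / bx_b
    if se_order == "first":
        se_b = sy / np.abs(bx_b)
    else:
        se_b = np.sqrt(sy**2 / bx_b**2 + by_b**2 * sx**2 / bx_b**4)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = weighted_median_point(theta_b[i], 1.0 / se_b[i] ** 2)
    se = float(np.std(reps, ddof=1))
    return _normal_estimate("weighted_median", point, se, len(hset))


def mr_egger(
    hset: HarmonizedSet,
    fit_intercept: bool = True,
) -> tuple[MrEstimate, MrEstimate] | MrEstimate:
    """Egger regression of outcome on exposure effects, weighted by 1/se_y².

    Returns ``(slope, intercept)`` estimates; the intercept measures average
    directional pleiotropy. SEs carry a multiplicative residual-dispersion
    factor floored at 1, and p-values/CIs use a t distribution with J-2
    degrees of freedom (J-1 when the intercept is constrained to zero, in
    which case only the slope estimate is returned).
    """
    j = len(hset)
    if j < 3:
        raise ValueError("mr_egger requires at least 3 SNPs")
    bx = np.array([p.beta_x for p in hset.pairs])
    by = np.array([p.beta_y for p in hset.pairs])
    sy = np.array([p.se_y for p in hset.pairs])
    if np.ptp(bx) == 0.0:
        raise np.linalg.LinAlgError("singular design: all exposure effects identical")

    weights = 1.0 / sy**2
    exog = sm.add_constant(bx) if fit_intercept else bx[:, None]
    fit = sm.WLS(by, exog, weights=weights).fit()
    df = j - exog.shape[1]
    # no under-dispersion credit: residual variance scaling floored at 1
    infl = max(1.0, np.sqrt(fit.scale))
    bse = fit.bse / np.sqrt(fit.scale) * infl
    tcrit = float(stats.t.ppf(0.975, df))

    def make(method: str, est: float, se: float) -> MrEstimate:
        pval = float(2.0 * stats.t.sf(abs(est / se), df))
        return MrEstimate(
            method=method,
            theta=float(est),
            se=float(se),
            ci_low=float(est - tcrit * se),
            ci_high=float(est + tcrit * se),
            pval=pval,
            n_snps=j,
        )

    if not fit_intercept:
        return make("egger_slope", fit.params[0], bse[0])
    slope = make("egger_slope", fit.params[1], bse[1])
    intercept = make("egger_intercept", fit.params[0], bse[0])
    return slope, intercept


def write_estimates_tsv(estimates: Iterable[MrEstimate], path: str | Path) -> None:
    """Export estimates as TSV (method, theta, se, ci_low, ci_high, pval, n_snps)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["method", "theta", "se", "ci_low", "ci_high", "pval", "n_snps"])
        for e in estimates:
            w.writerow([e.method, repr(e.theta), repr(e.se), repr(e.ci_low), repr(e.ci_high), repr(e.pval), e.n_snps])
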