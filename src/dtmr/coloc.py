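"""Bayesian colocalization of two traits' regional association signals.

Per-SNP approximate Bayes factors (shrinkage form) are combined over the
five standard hypotheses: no association (H0), association with one trait
only (H1/H2), two distinct causal variants (H3), one shared causal variant
(H4). All hypothesis sums are evaluated in log space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .gwas_io import GwasTable

__all__ = [
    "ColocPriors",
    "ColocResult",
    "log_abf",
    "coloc_posteriors",
    "prior_sd_for_scale",
]

#: Effect-scale prior SD per trait measurement scale.
PRIOR_SD_BY_SCALE = {
    "continuous": 0.15,
    "log_continuous": 0.15,
    "absolute_risk": 0.15,
    "log_odds": 0.2,
}


def prior_sd_for_scale(trait_scale: str) -> float:
    """Default prior effect SD for a trait's measurement scale."""
    try:
        return PRIOR_SD_BY_SCALE[trait_scale]
    except KeyError:
        raise ValueError(f"no prior SD convention for scale {trait_scale!r}") from None


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of causality for each trait and jointly."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2) <= max(self.p1, self.p2) < 1.0):
            raise ValueError(
                f"priors must satisfy 0 < p12 <= min(p1, p2) < 1, got {self}"
            )


@dataclass(frozen=True)
class ColocResult:
    """Per-SNP log Bayes factors and posterior probabilities over H0..H4."""

    log_abf1: np.ndarray
    log_abf2: np.ndarray
    pp: tuple[float, float, float, float, float]
    n_snps: int
    priors: ColocPriors

    def __post_init__(self) -> None:
        if abs(sum(self.pp) - 1.0) > 1e-12:
            raise ValueError("posterior probabilities must sum to 1")
        if any(p < 0 or p > 1 for p in self.pp):
            raise ValueError("posterior probabilities must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "pp0": self.pp[0],
            "pp1": self.pp[1],
            "pp2": self.pp[2],
            "pp3": self.pp[3],
            "pp4": self.pp[4],
            # the two probabilities the source analysis reports, under its own labels
            "paper_pp1": self.pp[3],
            "paper_pp2": self.pp[4],
            "n_snps": self.n_snps,
            "priors": {"p1": self.priors.p1, "p2": self.priors.p2, "p12": self.priors.p12},
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def log_abf(beta: float | np.ndarray, se: float | np.ndarray, prior_sd: float) -> float | np.ndarray:
    """Log approximate Bayes factor for one association estimate.

    With V = se², W = prior_sd², r = W/(V+W) and z = beta/se, returns
    0.5·log(1−r) + z²·r/2. Accepts scalars or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * z**2 * r
    return float(out) if out.ndim == 0 else out


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b; -inf when the difference vanishes."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_posteriors(
    region1: GwasTable,
    region2: GwasTable,
    priors: ColocPriors = ColocPriors(),
    prior_sd1: Optional[float] = None,
    prior_sd2: Optional[float] = None,
) -> ColocResult:
    """Five-hypothesis colocalization posteriors for two regional tables.

    SNPs are matched by rsid (region1 order); both tables must overlap.
    ``prior_sd1``/``prior_sd2`` default from each table's trait scale.
    A single-SNP region cannot support two distinct causal variants, so
    PP3 is exactly zero there.
    """
    if prior_sd1 is None:
        prior_sd1 = prior_sd_for_scale(region1.trait_scale)
    if prior_sd2 is None:
        prior_sd2 = prior_sd_for_scale(region2.trait_scale)

    shared = [r.rsid for r in region1.records if region2.get(r.rsid) is not None]
    if not shared:
        raise ValueError("regions share no SNPs")

    rec1 = [region1.get(r) for r in shared]
    rec2 = [region2.get(r) for r in shared]
    l1 = log_abf(np.array([r.beta for r in rec1]), np.array([r.se for r in rec1]), prior_sd1)
    l2 = log_abf(np.array([r.beta for r in rec2]), np.array([r.se for r in rec2]), prior_sd2)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    lsum1 = float(logsumexp(l1))
    lsum2 = float(logsumexp(l2))
    lsum12 = float(logsumexp(l1 + l2))

    log_s = np.empty(5)
    log_s[0] = 0.0
    log_s[1] = math.log(priors.p1) + lsum1
    log_s[2] = math.log(priors.p2) + lsum2
    # H3: sum over ordered pairs of distinct SNPs = sum1*sum2 - sum12
    log_s[3] = math.log(priors.p1) + math.log(priors.p2) + _log_diff_exp(lsum1 + lsum2, lsum12)
    log_s[4] = math.log(priors.p12) + lsum12

    with np.errstate(under="ignore"):
        shifted = np.exp(log_s - np.max(log_s))
    pp = shifted / shifted.sum()
    return ColocResult(
        log_abf1=l1,
        log_abf2=l2,
        pp=tuple(float(p) for p in pp),
        n_snps=len(shared),
        priors=priors,
    )
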