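"""Synthetic GWAS summary statistics with known ground truth.

Everything here is summary-level: per-SNP effects are drawn directly and
observed with sampling noise ``se = 1/sqrt(2·n·maf·(1−maf))``, the SE of a
per-allele regression coefficient for a standardized continuous trait.
Binary outcomes reuse the same form with an effective-n reading — only the
relative calibration matters for exercising the pipeline.

Three generators are provided: AR(1) LD matrices, multi-biomarker
instrument panels with a known causal effect and optional directional
pleiotropy, and paired regional z-score panels for the five colocalization
scenarios. A fourth helper writes a complete, deterministic study fixture
(tables, LD matrix, YAML config) shaped like the source analysis's
selection cascade: 28 in-window candidates, 15 with any biomarker
association, 8 concordant, 1 palindromic exclusion, 7 combined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .gwas_io import GwasTable, SnpRecord, write_gwas_table
from .instruments import LdMatrix, write_ld_matrix

__all__ = [
    "SimConfig",
    "ColocScenario",
    "InstrumentPanel",
    "simulate_ld_matrix",
    "simulate_instrument_panel",
    "simulate_coloc_region",
    "write_study_fixture",
]

NON_PALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("G", "T"), ("C", "T"))
PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


def _ar1_corr(n_snps: int, rho: float) -> np.ndarray:
    """Signed AR(1) correlation matrix r_ij = rho^|i-j| (positive definite)."""
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    idx = np.arange(n_snps)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld_matrix(n_snps: int, rho: float, seed: int = 0, rsids: Optional[list[str]] = None) -> LdMatrix:
    """AR(1)-structured LD: r²_ij = rho^(2|i-j|).

    Deterministic given its arguments; ``seed`` only names SNPs when no
    rsids are supplied.
    """
    if rsids is None:
        rsids = [f"rs{seed}_{j:04d}" for j in range(n_snps)]
    if len(rsids) != n_snps:
        raise ValueError("rsids length must equal n_snps")
    return LdMatrix(rsids=tuple(rsids), r2=_ar1_corr(n_snps, rho) ** 2)


def _se_per_allele(n: float, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of an instrument-panel simulation."""

    n_snps: int = 20
    theta_true: float = 0.0
    n_exposure: float = 21_758.0
    n_outcome: float = 377_673.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    ld_rho: float = 0.0
    seed: int = 0
    palindromic_frac: float = 0.0
    biomarker_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        if not (0.0 <= self.palindromic_frac <= 1.0):
            raise ValueError("palindromic_frac must lie in [0, 1]")


@dataclass(frozen=True)
class InstrumentPanel:
    """Simulated biomarker/outcome tables plus the generating truth."""

    exposures: tuple[GwasTable, GwasTable, GwasTable]
    outcome: GwasTable
    truth: dict

    @property
    def exposure(self) -> GwasTable:
        """The primary exposure table (first biomarker)."""
        return self.exposures[0]


def _make_table(
    trait_name: str,
    trait_scale: str,
    rsids: list[str],
    alleles: list[tuple[str, str]],
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: float,
    chrom: str = "12",
    pos0: int = 6_313_757,
) -> GwasTable:
    pvals = _pvals(beta, se)
    records = tuple(
        SnpRecord(
            rsid=rsids[j],
            chrom=chrom,
            pos=pos0 + 1500 * j,
            ea=alleles[j][0],
            nea=alleles[j][1],
            eaf=float(maf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pvals[j]),
            n=n,
        )
        for j in range(len(rsids))
    )
    return GwasTable(trait_name=trait_name, trait_scale=trait_scale, records=records)


def simulate_instrument_panel(config: SimConfig) -> InstrumentPanel:
    """Simulate three concordant biomarker GWAS plus one outcome GWAS.

    Per SNP j the true exposure effect is inhibition-signed,
    b_j = −|N(0.05, 0.02)|; the second and third biomarkers scale it by
    fixed positive constants (0.8, 0.6) plus noise; the outcome's true
    effect is ``theta_true·b_j + α_j`` with α_j = ``pleiotropy_mean`` on a
    seeded random subset of size ``pleiotropy_frac·n_snps`` and zero
    elsewhere. Observed effects add Normal(0, se_j) noise with the
    standard per-allele SE for each trait's sample size.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_snps
    rsids = [f"rs{config.seed}_{j:04d}" for j in range(k)]
    maf = rng.uniform(*config.maf_range, size=k)

    alleles: list[tuple[str, str]] = []
    for j in range(k):
        if rng.random() < config.palindromic_frac:
            pair = PALINDROMIC_PAIRS[rng.integers(len(PALINDROMIC_PAIRS))]
        else:
            pair = NON_PALINDROMIC_PAIRS[rng.integers(len(NON_PALINDROMIC_PAIRS))]
        alleles.append(pair)

    b = -np.abs(rng.normal(0.05, 0.02, size=k))
    c2, c3 = 0.8, 0.6
    b2 = c2 * b + rng.normal(0.0, config.biomarker_noise_sd, size=k)
    b3 = c3 * b + rng.normal(0.0, config.biomarker_noise_sd, size=k)

    n_invalid = int(round(config.pleiotropy_frac * k))
    invalid = rng.choice(k, size=n_invalid, replace=False) if n_invalid else np.array([], dtype=int)
    alpha = np.zeros(k)
    alpha[invalid] = config.pleiotropy_mean
    by_true = config.theta_true * b + alpha

    se_x = _se_per_allele(config.n_exposure, maf)
    se_y = _se_per_allele(config.n_outcome, maf)

    obs_b1 = b + rng.normal(0.0, se_x)
    obs_b2 = b2 + rng.normal(0.0, se_x)
    obs_b3 = b3 + rng.normal(0.0, se_x)
    obs_by = by_true + rng.normal(0.0, se_y)

    t1 = _make_table("biomarker1", "continuous", rsids, alleles, maf, obs_b1, se_x, config.n_exposure)
    t2 = _make_table("biomarker2", "log_continuous", rsids, alleles, maf, obs_b2, se_x, config.n_exposure)
    t3 = _make_table("biomarker3", "continuous", rsids, alleles, maf, obs_b3, se_x, config.n_exposure)
    ty = _make_table("outcome", "absolute_risk", rsids, alleles, maf, obs_by, se_y, config.n_outcome)

    truth = {
        "theta_true": config.theta_true,
        "rsids": rsids,
        "b": b.tolist(),
        "alpha": alpha.tolist(),
        "invalid": sorted(rsids[j] for j in invalid),
        "maf": maf.tolist(),
        "se_exposure": se_x.tolist(),
        "se_outcome": se_y.tolist(),
    }
    return InstrumentPanel(exposures=(t1, t2, t3), outcome=ty, truth=truth)


@dataclass(frozen=True)
class ColocScenario:
    """One of the five regional colocalization ground truths."""

    hypothesis: str
    n_snps: int = 200
    causal_index_1: Optional[int] = None
    causal_index_2: Optional[int] = None
    causal_z: float = 8.0
    ld_rho: float = 0.9
    seed: int = 0
    n: float = 50_000.0
    maf: float = 0.3

    def __post_init__(self) -> None:
        if self.hypothesis not in {"H0", "H1", "H2", "H3", "H4"}:
            raise ValueError(f"hypothesis must be H0..H4, got {self.hypothesis!r}")
        if self.hypothesis == "H4" and self.causal_index_1 != self.causal_index_2:
            raise ValueError("H4 requires a shared causal index")
        if self.hypothesis == "H3" and (
            self.causal_index_1 is None
            or self.causal_index_2 is None
            or self.causal_index_1 == self.causal_index_2
        ):
            raise ValueError("H3 requires two distinct causal indices")
        needs_1 = self.hypothesis in {"H1", "H3", "H4"}
        needs_2 = self.hypothesis in {"H2", "H3", "H4"}
        if needs_1 and self.causal_index_1 is None:
            raise ValueError(f"{self.hypothesis} requires causal_index_1")
        if needs_2 and self.causal_index_2 is None:
            raise ValueError(f"{self.hypothesis} requires causal_index_2")


def simulate_coloc_region(scenario: ColocScenario) -> tuple[GwasTable, GwasTable]:
    """Two traits' marginal summary stats for one LD region.

    Marginal z-scores follow z = R·λ + MVN(0, R) with R the AR(1)
    correlation matrix and λ a spike of height ``causal_z`` at the trait's
    causal index (absent for traits that are null under the scenario).
    Betas are z·se at a constant SE from the nominal sample size.
    """
    rng = np.random.default_rng(scenario.seed)
    k = scenario.n_snps
    corr = _ar1_corr(k, scenario.ld_rho)
    chol = np.linalg.cholesky(corr)

    def draw(causal_index: Optional[int]) -> np.ndarray:
        lam = np.zeros(k)
        if causal_index is not None:
            lam[causal_index] = scenario.causal_z
        return corr @ lam + chol @ rng.standard_normal(k)

    h = scenario.hypothesis
    z1 = draw(scenario.causal_index_1 if h in {"H1", "H3", "H4"} else None)
    z2 = draw(scenario.causal_index_2 if h in {"H2", "H3", "H4"} else None)

    se = float(_se_per_allele(scenario.n, np.array([scenario.maf]))[0])
    rsids = [f"rs{scenario.seed}_{j:04d}" for j in range(k)]
    alleles = [("A", "G")] * k
    maf = np.full(k, scenario.maf)
    t1 = _make_table("trait1", "continuous", rsids, alleles, maf, z1 * se, np.full(k, se), scenario.n)
    t2 = _make_table("trait2", "continuous", rsids, alleles, maf, z2 * se, np.full(k, se), scenario.n)
    return t1, t2


# --------------------------------------------------------------------------
# Deterministic study fixture mirroring the source selection cascade
# --------------------------------------------------------------------------

GENE_REGION = {"chrom": "12", "start": 6_328_757, "end": 6_342_114, "flank": 15_000}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def write_study_fixture(out_dir: str | Path, seed: int = 0) -> Path:
    """Write a complete synthetic study (tables, LD, config) and return the config path.

    The candidate catalog holds 30 SNPs, 28 inside the flanked gene window.
    Of those 28, 15 appear in at least one biomarker GWAS; 7 of the 15
    violate the inclusion criteria (2 missing from a table, 3 discordant
    direction, 2 non-significant); 8 pass concordance and survive clumping;
    1 of the 8 is palindromic at eaf 0.5 and is dropped in harmonization
    against every outcome, leaving 7 SNPs in all combined estimates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_catalog = 30
    rsids = [f"rs99{j:04d}" for j in range(n_catalog)]
    start = GENE_REGION["start"] - GENE_REGION["flank"]
    pos = [start + 1200 * j for j in range(28)] + [6_200_000, 6_500_000]  # last two out of window
    maf = rng.uniform(0.15, 0.45, size=n_catalog)

    alleles = []
    for j in range(n_catalog):
        alleles.append(NON_PALINDROMIC_PAIRS[j % len(NON_PALINDROMIC_PAIRS)])
    alleles[7] = ("A", "T")  # the palindromic instrument
    maf[7] = 0.5

    # true per-allele CRP-lowering effects for the concordant eight
    beta_crp = -rng.uniform(0.08, 0.15, size=n_catalog)
    se_crp = np.full(n_catalog, 0.005)
    se_tnfr1 = np.full(n_catalog, 0.01)
    se_wbc = np.full(n_catalog, 0.004)
    beta_tnfr1 = 1.2 * beta_crp + rng.normal(0, 0.002, n_catalog)
    beta_wbc = 0.25 * beta_crp + rng.normal(0, 0.001, n_catalog)

    # arrange the cascade violations among indices 8..14
    beta_tnfr1[10] = 0.09   # discordant in TNFR1
    beta_crp[11] = 0.08     # discordant in CRP
    beta_wbc[12] = 0.05     # discordant in WBC
    weak = np.array([13, 14])
    beta_wbc[weak] = -0.1 * se_wbc[weak]  # right direction but p ~ 0.92 in WBC

    def subset_table(name, scale, idx, beta, se, n, swap=(), strand_flip=()):
        recs = []
        for j in idx:
            ea, nea = alleles[j]
            b, f = float(beta[j]), float(maf[j])
            if j in swap:
                ea, nea, b, f = nea, ea, -b, 1.0 - f
            if j in strand_flip:
                ea, nea = _COMPLEMENT[ea], _COMPLEMENT[nea]
            p = float(_pvals(np.array([b]), np.array([se[j]]))[0])
            recs.append(
                SnpRecord(rsid=rsids[j], chrom="12", pos=pos[j], ea=ea, nea=nea,
                          eaf=f, beta=b, se=float(se[j]), pval=p, n=n)
            )
        return GwasTable(trait_name=name, trait_scale=scale, records=tuple(recs))

    catalog_idx = list(range(n_catalog))
    biomarker_idx = list(range(15))          # 15 with any association
    crp_idx = [j for j in biomarker_idx if j != 8]   # rs..0008 missing from CRP
    wbc_idx = [j for j in biomarker_idx if j != 9]   # rs..0009 missing from WBC

    candidates = subset_table("TNFR1_catalog", "continuous", catalog_idx, beta_tnfr1, se_tnfr1, 21_758.0)
    tnfr1 = subset_table("TNFR1", "continuous", biomarker_idx, beta_tnfr1, se_tnfr1, 21_758.0)
    crp = subset_table("CRP", "log_continuous", crp_idx, beta_crp, se_crp, 204_402.0)
    wbc = subset_table("WBC", "continuous", wbc_idx, beta_wbc, se_wbc, 172_435.0,
                       swap={3})  # one row reported on the other allele

    # outcomes: betas proportional to the CRP effect, small seeded jitter
    sel = list(range(15))
    se_uc = np.full(n_catalog, 0.010)
    se_cd = np.full(n_catalog, 0.011)
    se_ms = np.full(n_catalog, 0.009)
    se_crc = np.full(n_catalog, 0.0020)
    beta_uc = 0.40 * beta_crp + rng.normal(0, 0.004, n_catalog)
    beta_cd = 0.45 * beta_crp + rng.normal(0, 0.004, n_catalog)
    beta_ms = -0.80 * beta_crp + rng.normal(0, 0.004, n_catalog)
    beta_crc = 0.021 * beta_crp + rng.normal(0, 0.0008, n_catalog)

    uc = subset_table("UC", "log_odds", sel, beta_uc, se_uc, 45_975.0)
    cd = subset_table("CD", "log_odds", sel, beta_cd, se_cd, 40_266.0)
    ms = subset_table("MS", "log_odds", sel, beta_ms, se_ms, 115_803.0)
    crc = subset_table("CRC", "absolute_risk", sel, beta_crc, se_crc, 377_673.0,
                       swap={2}, strand_flip={4})

    ld = simulate_ld_matrix(n_catalog, rho=0.03, rsids=rsids)

    files = {
        "candidates.tsv": candidates, "tnfr1.tsv": tnfr1, "crp.tsv": crp, "wbc.tsv": wbc,
        "uc.tsv": uc, "cd.tsv": cd, "ms.tsv": ms, "crc.tsv": crc,
    }
    for fname, table in files.items():
        write_gwas_table(table, out_dir / fname)
    write_ld_matrix(ld, out_dir / "ld.tsv")

    config = {
        "seed": int(seed),
        "out_dir": "results",
        "region": dict(GENE_REGION),
        "selection": {"p_threshold": 0.05, "r2_threshold": 0.001,
                      "required_direction": "negative", "mode": "all"},
        "harmonization": {"af_band": [0.42, 0.58]},
        "estimators": {"n_boot": 1000, "wald_se_order": "first"},
        "coloc": {"p1": 1.0e-4, "p2": 1.0e-4, "p12": 1.0e-5},
        "arr": {"deltas": [16.0, 13.9]},
        "ld_matrix": "ld.tsv",
        "tables": {
            "candidates": {"path": "candidates.tsv", "trait_name": "TNFR1_catalog", "trait_scale": "continuous"},
            "biomarkers": [
                {"path": "tnfr1.tsv", "trait_name": "TNFR1", "trait_scale": "continuous"},
                {"path": "crp.tsv", "trait_name": "CRP", "trait_scale": "log_continuous"},
                {"path": "wbc.tsv", "trait_name": "WBC", "trait_scale": "continuous"},
            ],
            "exposure": {"path": "crp.tsv", "trait_name": "CRP", "trait_scale": "log_continuous"},
            "controls": [
                {"path": "uc.tsv", "trait_name": "UC", "trait_scale": "log_odds", "expected_direction": "protective"},
                {"path": "cd.tsv", "trait_name": "CD", "trait_scale": "log_odds", "expected_direction": "protective"},
                {"path": "ms.tsv", "trait_name": "MS", "trait_scale": "log_odds", "expected_direction": "detrimental"},
            ],
            "outcome": {"path": "crc.tsv", "trait_name": "CRC", "trait_scale": "absolute_risk"},
        },
    }
    config_path = out_dir / "study.yaml"
    import yaml

    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    truth = {
        "n_catalog": n_catalog,
        "n_in_window": 28,
        "n_with_any_association": 15,
        "n_concordant": 8,
        "n_combined": 7,
        "palindromic_rsid": rsids[7],
        "theta_crc_per_unit_crp": 0.021,
    }
    with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return config_path
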