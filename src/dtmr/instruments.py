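"""Cis-instrument selection: gene-window extraction, concordance filtering, LD clumping."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gwas_io import ConfigurationError, GwasTable, SnpRecord

__all__ = [
    "GeneRegion",
    "LdMatrix",
    "SelectionReport",
    "extract_cis_window",
    "concordance_filter",
    "ld_clump",
    "read_ld_matrix",
    "write_ld_matrix",
]

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class GeneRegion:
    """A gene body plus a symmetric flanking window, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    flank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")

    @property
    def window_start(self) -> int:
        return self.start - self.flank

    @property
    def window_end(self) -> int:
        return self.end + self.flank

    def contains(self, chrom: Optional[str], pos: Optional[int]) -> bool:
        if chrom is None or pos is None:
            return False
        return str(chrom) == str(self.chrom) and self.window_start <= pos <= self.window_end


@dataclass(frozen=True)
class LdMatrix:
    """Squared-correlation (r²) matrix over an ordered set of SNPs."""

    rsids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rsids", tuple(self.rsids))
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        k = len(self.rsids)
        if r2.shape != (k, k):
            raise ValueError(f"r2 shape {r2.shape} does not match {k} rsids")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")

    def index_of(self, rsid: str) -> int:
        idx = self._index.get(rsid)
        if idx is None:
            raise KeyError(f"rsid {rsid} not present in LD matrix")
        return idx

    @property
    def _index(self) -> dict[str, int]:
        cache = self.__dict__.get("_index_cache")
        if cache is None:
            cache = {r: i for i, r in enumerate(self.rsids)}
            self.__dict__["_index_cache"] = cache
        return cache

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self.index_of(a), self.index_of(b)])


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read an LD matrix TSV: first column rsid, remaining columns the square matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix(rsids=tuple(str(r) for r in df.index), r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ld.r2, index=list(ld.rsids), columns=list(ld.rsids))
    df.to_csv(path, sep="\t", index_label="rsid")


@dataclass
class SelectionReport:
    """Stage-by-stage accounting of the instrument-selection cascade."""

    n_candidates: int
    n_with_any_association: int
    n_concordant: int
    n_after_clump: int
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = (
            self.n_candidates,
            self.n_with_any_association,
            self.n_concordant,
            self.n_after_clump,
        )
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"selection counts must be non-increasing, got {counts}")

    def to_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_with_any_association": self.n_with_any_association,
            "n_concordant": self.n_concordant,
            "n_after_clump": self.n_after_clump,
            "excluded": dict(sorted(self.excluded.items())),
        }


def extract_cis_window(table: GwasTable, region: GeneRegion) -> GwasTable:
    """Keep records on the region's chromosome with position inside the flanked window."""
    kept = tuple(r for r in table.records if region.contains(r.chrom, r.pos))
    return replace(table, records=kept)


def _orientation_sign(candidate: SnpRecord, other: SnpRecord) -> Optional[int]:
    """Sign aligning ``other``'s beta to the candidate's effect allele.

    +1 when alleles match directly or by strand complement, -1 when they are
    swapped (directly or by complement), None when irreconcilable. Palindromic
    pairs are compared at face value only, since their complement is their swap.
    """
    ca, cn = candidate.ea, candidate.nea
    oa, on = other.ea, other.nea
    if (oa, on) == (ca, cn):
        return 1
    if (oa, on) == (cn, ca):
        return -1
    if COMPLEMENT[ca] != cn:  # non-palindromic: try the other strand
        fa, fn = COMPLEMENT[oa], COMPLEMENT[on]
        if (fa, fn) == (ca, cn):
            return 1
        if (fa, fn) == (cn, ca):
            return -1
    return None


def concordance_filter(
    candidates: GwasTable,
    biomarkers: Sequence[GwasTable],
    p_threshold: float = 0.05,
    required_direction: int | str = "negative",
    mode: str = "all",
) -> tuple[GwasTable, SelectionReport]:
    """Keep candidates with a concordant, significant effect in the biomarker GWAS.

    A candidate is retained when it (a) appears in every biomarker table,
    (b) after orienting each biomarker's beta to the candidate's effect
    allele has the required sign in all of them, and (c) is associated at
    ``pval < p_threshold``. With ``mode="all"`` (default) the p-value
    criterion must hold in every biomarker table, with ``mode="any"`` in at
    least one; the direction criterion always applies to all tables.

    Exclusion reasons, one per dropped candidate, use a fixed priority
    (no_association > missing > allele_mismatch > direction > pvalue) so the
    result does not depend on the order of the biomarker tables.
    """
    if not biomarkers:
        raise ConfigurationError("at least one biomarker table is required")
    if not candidates.records:
        raise ConfigurationError("candidate table is empty")
    if not (0.0 < p_threshold < 1.0):
        raise ConfigurationError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    if mode not in ("all", "any"):
        raise ConfigurationError(f"mode must be 'all' or 'any', got {mode!r}")
    if required_direction in ("negative", -1):
        want_sign = -1
    elif required_direction in ("positive", 1):
        want_sign = 1
    else:
        raise ConfigurationError(f"required_direction must be 'negative' or 'positive', got {required_direction!r}")

    kept: list[SnpRecord] = []
    excluded: dict[str, str] = {}
    n_with_any = 0
    for cand in candidates.records:
        found = [bm.get(cand.rsid) for bm in biomarkers]
        present = [r for r in found if r is not None]
        if present:
            n_with_any += 1
        if not present:
            excluded[cand.rsid] = "no_association"
            continue
        if len(present) < len(biomarkers):
            excluded[cand.rsid] = "missing"
            continue
        signs = [_orientation_sign(cand, r) for r in found]
        if any(s is None for s in signs):
            excluded[cand.rsid] = "allele_mismatch"
            continue
        oriented = [s * r.beta for s, r in zip(signs, found)]
        if any(np.sign(b) != want_sign for b in oriented):
            excluded[cand.rsid] = "direction"
            continue
        sig = [r.pval < p_threshold for r in found]
        ok_p = all(sig) if mode == "all" else any(sig)
        if not ok_p:
            excluded[cand.rsid] = "pvalue"
            continue
        kept.append(cand)

    table = replace(candidates, records=tuple(kept))
    report = SelectionReport(
        n_candidates=len(candidates),
        n_with_any_association=n_with_any,
        n_concordant=len(kept),
        n_after_clump=len(kept),  # updated by ld_clump downstream
        excluded=excluded,
    )
    logger.info(
        "concordance_filter: %d candidates -> %d with any association -> %d concordant",
        report.n_candidates, report.n_with_any_association, report.n_concordant,
    )
    return table, report


def ld_clump(
    table: GwasTable,
    ld: LdMatrix,
    r2_threshold: float = 0.001,
    report: Optional[SelectionReport] = None,
) -> GwasTable:
    """Greedy LD clumping: keep the most significant SNP, discard its LD partners.

    SNPs are ranked by ascending p-value (ties broken by position, then
    rsid); each kept SNP removes every remaining SNP with r² strictly above
    ``r2_threshold`` against it. When a ``report`` is passed, its
    ``n_after_clump`` and exclusion log are updated in place.
    """
    if not (0.0 <= r2_threshold <= 1.0):
        raise ValueError(f"r2_threshold must lie in [0, 1], got {r2_threshold}")
    for r in table.records:
        ld.index_of(r.rsid)  # raises KeyError on absence

    def rank_key(rec: SnpRecord):
        return (rec.pval, rec.pos if rec.pos is not None else 0, rec.rsid)

    remaining = sorted(table.records, key=rank_key)
    kept_ids: list[str] = []
    clumped: dict[str, str] = {}
    while remaining:
        best = remaining.pop(0)
        kept_ids.append(best.rsid)
        still = []
        for rec in remaining:
            if ld.r2_between(best.rsid, rec.rsid) > r2_threshold:
                clumped[rec.rsid] = f"ld_with:{best.rsid}"
            else:
                still.append(rec)
        remaining = still

    kept_set = set(kept_ids)
    result = replace(table, records=tuple(r for r in table.records if r.rsid in kept_set))

    # post-condition: output mutually independent at the threshold
    for i, a in enumerate(result.records):
        for b in result.records[i + 1:]:
            r2 = ld.r2_between(a.rsid, b.rsid)
            if r2 > r2_threshold:
                raise AssertionError(f"clump postcondition violated: r2({a.rsid},{b.rsid})={r2}")

    if report is not None:
        report.n_after_clump = len(result)
        report.excluded.update(clumped)
    logger.info("ld_clump: %d -> %d SNPs at r2 <= %g", len(table), len(result), r2_threshold)
    return result
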