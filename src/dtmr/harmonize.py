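"""Allele harmonization of exposure/outcome summary statistics.

Aligns both traits to one effect-allele orientation, flipping outcome
effects where the reported alleles are swapped, strand-complementing
non-palindromic SNPs reported on opposite strands, and excluding
palindromic SNPs whose allele frequency is too close to 0.5 (or missing)
to resolve the strand.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

from .gwas_io import GwasTable

__all__ = [
    "HarmonizedPair",
    "HarmonizedSet",
    "EmptyOverlapError",
    "DEFAULT_AF_BAND",
    "is_palindromic",
    "is_intermediate_af",
    "harmonize_dataset",
    "orient_to_inhibition",
]

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Conventional two-sample MR ambiguity band for palindromic SNPs.
DEFAULT_AF_BAND = (0.42, 0.58)


class EmptyOverlapError(ValueError):
    """Exposure and outcome tables share no SNPs."""


def is_palindromic(ea: str, nea: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    pair = {ea.upper(), nea.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def is_intermediate_af(eaf: Optional[float], band: tuple[float, float] = DEFAULT_AF_BAND) -> bool:
    """True iff ``eaf`` falls inside the ambiguity band; missing counts as intermediate."""
    low, high = band
    if not (0.0 <= low < high <= 1.0):
        raise ValueError(f"band must satisfy 0 <= low < high <= 1, got {band}")
    if eaf is None:
        return True
    return low <= eaf <= high


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a shared allele orientation."""

    rsid: str
    ea: str
    nea: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: Optional[float] = None
    eaf_y: Optional[float] = None
    status: str = "aligned"

    def __post_init__(self) -> None:
        if self.status in ("aligned", "flipped") and not (self.se_x > 0 and self.se_y > 0):
            raise ValueError(f"{self.rsid}: harmonized pair requires positive SEs")


@dataclass(frozen=True)
class HarmonizedSet:
    """Usable harmonized pairs plus the per-SNP exclusion log."""

    pairs: tuple[HarmonizedPair, ...]
    exclusions: dict[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        seen: set[str] = set()
        for p in self.pairs:
            if p.status not in ("aligned", "flipped"):
                raise ValueError(f"{p.rsid}: pair with status {p.status!r} kept in set")
            if p.rsid in seen:
                raise ValueError(f"duplicate rsid {p.rsid} in harmonized set")
            seen.add(p.rsid)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def write_exclusion_log(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["rsid", "reason"])
            for rsid in sorted(self.exclusions):
                w.writerow([rsid, self.exclusions[rsid]])


def harmonize_dataset(
    exposure: GwasTable,
    outcome: GwasTable,
    band: tuple[float, float] = DEFAULT_AF_BAND,
) -> HarmonizedSet:
    """Harmonize shared SNPs onto the exposure's effect-allele orientation.

    Outcome records with swapped alleles have their beta negated and eaf
    reflected; non-palindromic records reported on the opposite strand are
    complemented first. Palindromic SNPs are excluded whenever either
    trait's eaf is inside ``band`` or missing; outside the band they are
    kept at face value without frequency-based strand inference.
    """
    shared = [r.rsid for r in exposure.records if outcome.get(r.rsid) is not None]
    if not shared:
        raise EmptyOverlapError(
            f"no shared rsids between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )

    pairs: list[HarmonizedPair] = []
    exclusions: dict[str, str] = {}
    for rsid in shared:
        x = exposure.get(rsid)
        y = outcome.get(rsid)
        assert x is not None and y is not None

        ya, yn, ybeta, yeaf = y.ea, y.nea, y.beta, y.eaf
        palindromic = is_palindromic(x.ea, x.nea)

        if palindromic:
            if is_intermediate_af(x.eaf, band) or is_intermediate_af(yeaf, band):
                exclusions[rsid] = "palindromic"
                continue
        elif (ya, yn) not in ((x.ea, x.nea), (x.nea, x.ea)):
            # try the opposite strand
            ya, yn = COMPLEMENT[ya], COMPLEMENT[yn]

        if (ya, yn) == (x.ea, x.nea):
            status = "aligned"
        elif (ya, yn) == (x.nea, x.ea):
            status = "flipped"
            ybeta = -ybeta
            yeaf = None if yeaf is None else 1.0 - yeaf
        else:
            exclusions[rsid] = "mismatch"
            continue

        pairs.append(
            HarmonizedPair(
                rsid=rsid,
                ea=x.ea,
                nea=x.nea,
                beta_x=x.beta,
                se_x=x.se,
                beta_y=ybeta,
                se_y=y.se,
                eaf_x=x.eaf,
                eaf_y=yeaf,
                status=status,
            )
        )

    if exclusions:
        logger.info(
            "harmonize %s vs %s: %d shared, %d excluded (%s)",
            exposure.trait_name, outcome.trait_name, len(shared), len(exclusions),
            ", ".join(f"{k}={v}" for k, v in sorted(exclusions.items())),
        )
    return HarmonizedSet(pairs=tuple(pairs), exclusions=exclusions)


def orient_to_inhibition(hset: HarmonizedSet) -> HarmonizedSet:
    """Re-orient every pair so the effect allele lowers the exposure (beta_x < 0).

    Pairs with a positive exposure effect have alleles swapped, both betas
    negated and both frequencies reflected; exact-zero exposure effects are
    excluded (no defined inhibition allele).
    """
    if not hset.pairs:
        raise ValueError("cannot orient an empty harmonized set")
    pairs: list[HarmonizedPair] = []
    exclusions = dict(hset.exclusions)
    for p in hset.pairs:
        if p.beta_x == 0:
            exclusions[p.rsid] = "null-exposure"
            continue
        if p.beta_x < 0:
            pairs.append(p)
            continue
        pairs.append(
            replace(
                p,
                ea=p.nea,
                nea=p.ea,
                beta_x=-p.beta_x,
                beta_y=-p.beta_y,
                eaf_x=None if p.eaf_x is None else 1.0 - p.eaf_x,
                eaf_y=None if p.eaf_y is None else 1.0 - p.eaf_y,
            )
        )
    return HarmonizedSet(pairs=tuple(pairs), exclusions=exclusions)
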