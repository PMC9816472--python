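"""Reading, validating and writing GWAS summary-statistics tables.

The canonical on-disk dialect is tab-separated UTF-8 with one header row.
Missing values are encoded as ``NA`` or an empty field. Column names in
source files are arbitrary and mapped onto the canonical schema through a
:class:`ColumnMap`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "SnpRecord",
    "GwasTable",
    "ColumnMap",
    "ConfigurationError",
    "EmptyInputError",
    "read_gwas_table",
    "write_gwas_table",
    "CANONICAL_COLUMNS",
    "TRAIT_SCALES",
]

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Canonical output column order.
CANONICAL_COLUMNS = ("rsid", "chrom", "pos", "ea", "nea", "eaf", "beta", "se", "pval", "n")

#: Fields that a ColumnMap must always provide.
MANDATORY_FIELDS = ("rsid", "ea", "nea", "beta", "se", "pval")

#: Recognised measurement scales for a trait.
TRAIT_SCALES = frozenset({"continuous", "log_continuous", "log_odds", "absolute_risk"})

#: Strings treated as missing on input.
NA_STRINGS = frozenset({"", "NA", "NaN", "nan", "na", "."})


class ConfigurationError(ValueError):
    """A column map, config file or argument set is unusable."""


class EmptyInputError(ValueError):
    """An input yielded zero usable records."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP's summary association with a single trait.

    ``beta`` is the effect per copy of the effect allele ``ea`` on the
    trait's native scale. ``eaf``, ``chrom``, ``pos`` and ``n`` may be
    missing (``None``).
    """

    rsid: str
    ea: str
    nea: str
    beta: float
    se: float
    pval: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ea", self.ea.upper())
        object.__setattr__(self, "nea", self.nea.upper())
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.ea not in VALID_ALLELES or self.nea not in VALID_ALLELES:
            raise ValueError(f"{self.rsid}: alleles must be single nucleotides, got {self.ea}/{self.nea}")
        if self.ea == self.nea:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.rsid}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf must lie in [0, 1], got {self.eaf}")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be 1-based positive")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class GwasTable:
    """Ordered collection of :class:`SnpRecord` for one trait."""

    trait_name: str
    trait_scale: str
    records: tuple[SnpRecord, ...]

    def __post_init__(self) -> None:
        if self.trait_scale not in TRAIT_SCALES:
            raise ValueError(
                f"unknown trait_scale {self.trait_scale!r}; expected one of {sorted(TRAIT_SCALES)}"
            )
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise ValueError(f"duplicate rsid {rec.rsid} in table {self.trait_name!r}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(r.rsid for r in self.records)

    def get(self, rsid: str) -> Optional[SnpRecord]:
        return self._index.get(rsid)

    @property
    def _index(self) -> dict[str, SnpRecord]:
        # cached lazily on the instance; frozen dataclass so go via __dict__
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {r.rsid: r for r in self.records}
            self.__dict__["_index_cache"] = idx
        return idx

    def subset(self, rsids: Sequence[str]) -> "GwasTable":
        """Records for ``rsids``, in the order given. Missing ids are skipped."""
        recs = tuple(self._index[r] for r in rsids if r in self._index)
        return replace(self, records=recs)


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical SnpRecord field names to source-file column headers."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.mapping) - set(CANONICAL_COLUMNS)
        if unknown:
            raise ConfigurationError(f"unknown fields in column map: {sorted(unknown)}")
        missing = [f for f in MANDATORY_FIELDS if f not in self.mapping]
        if missing:
            raise ConfigurationError(f"column map lacks mandatory fields: {missing}")
        object.__setattr__(self, "mapping", dict(self.mapping))

    @classmethod
    def identity(cls) -> "ColumnMap":
        """Column map for files already using the canonical header."""
        return cls({c: c for c in CANONICAL_COLUMNS})


def _parse_optional_float(raw: object) -> Optional[float]:
    s = str(raw).strip()
    if s in NA_STRINGS:
        return None
    return float(s)


def _parse_optional_int(raw: object) -> Optional[int]:
    v = _parse_optional_float(raw)
    return None if v is None else int(v)


def read_gwas_table(
    path: str | Path,
    column_map: ColumnMap,
    trait_name: str,
    trait_scale: str,
) -> GwasTable:
    """Read a summary-statistics TSV into a validated :class:`GwasTable`.

    Rows violating the :class:`SnpRecord` invariants are dropped; the drop
    count is reported through the module logger.

    Raises
    ------
    ConfigurationError
        If a mapped column is absent from the file header.
    EmptyInputError
        If no row survives validation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in column_map.mapping.values() if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(f"{path}: mapped columns absent from header: {missing_cols}")

    m = column_map.mapping
    records: list[SnpRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            rec = SnpRecord(
                rsid=str(row[m["rsid"]]).strip(),
                ea=str(row[m["ea"]]).strip(),
                nea=str(row[m["nea"]]).strip(),
                beta=float(row[m["beta"]]),
                se=float(row[m["se"]]),
                pval=float(row[m["pval"]]),
                chrom=str(row[m["chrom"]]).strip() if "chrom" in m and str(row[m["chrom"]]).strip() not in NA_STRINGS else None,
                pos=_parse_optional_int(row[m["pos"]]) if "pos" in m else None,
                eaf=_parse_optional_float(row[m["eaf"]]) if "eaf" in m else None,
                n=_parse_optional_float(row[m["n"]]) if "n" in m else None,
            )
        except (ValueError, KeyError):
            n_dropped += 1
            continue
        records.append(rec)

    if n_dropped:
        logger.info("read %s: dropped %d invalid row(s), kept %d", path, n_dropped, len(records))
    if not records:
        raise EmptyInputError(f"{path}: no valid records after validation")

    # duplicate rsids: keep first occurrence, drop the rest
    seen: set[str] = set()
    unique: list[SnpRecord] = []
    for rec in records:
        if rec.rsid in seen:
            n_dropped += 1
            logger.info("read %s: dropping duplicate rsid %s", path, rec.rsid)
            continue
        seen.add(rec.rsid)
        unique.append(rec)

    return GwasTable(trait_name=trait_name, trait_scale=trait_scale, records=tuple(unique))


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if float(value).is_integer() and abs(value) < 1e15:
            # keep integral sample sizes readable
            return repr(value)
        return repr(value)
    return str(value)


def write_gwas_table(table: GwasTable, path: str | Path) -> None:
    """Write ``table`` as canonical TSV; round-trips through :func:`read_gwas_table`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for rec in table.records:
            fields = [
                rec.rsid,
                rec.chrom if rec.chrom is not None else "NA",
                str(rec.pos) if rec.pos is not None else "NA",
                rec.ea,
                rec.nea,
                _fmt(rec.eaf),
                _fmt(rec.beta),
                _fmt(rec.se),
                _fmt(rec.pval),
                _fmt(rec.n),
            ]
            fh.write("\t".join(fields) + "\n")
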