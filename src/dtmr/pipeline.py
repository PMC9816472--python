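"""End-to-end study orchestration from one YAML config.

Stages: read and validate all tables → extract the cis gene window →
tri-biomarker concordance filter → LD clump → per-outcome harmonization and
inhibition orientation → per-SNP Wald ratios → IVW / Cochran's Q / weighted
median / Egger → positive-control direction verdicts → regional
colocalization of exposure vs primary outcome → absolute-risk
extrapolation. Every stage logs its input/output counts; the assembled
report is written as deterministic JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import yaml

from . import coloc as coloc_mod
from . import harmonize as hz
from . import instruments as ins
from . import mr
from .gwas_io import ColumnMap, ConfigurationError, GwasTable, read_gwas_table

__all__ = [
    "StudyConfig",
    "TableSpec",
    "load_config",
    "run_drug_target_mr",
    "run_positive_controls",
    "extrapolate_arr",
]

logger = logging.getLogger(__name__)


def extrapolate_arr(arr_per_unit: float, delta_biomarker: float) -> float:
    """Extrapolated risk change: per-unit risk change times the biomarker shift."""
    import math

    if not (math.isfinite(arr_per_unit) and math.isfinite(delta_biomarker)):
        raise ValueError("extrapolate_arr requires finite inputs")
    return arr_per_unit * delta_biomarker


@dataclass(frozen=True)
class TableSpec:
    """Location and metadata of one summary-statistics table."""

    path: Path
    trait_name: str
    trait_scale: str
    columns: ColumnMap = field(default_factory=ColumnMap.identity)
    expected_direction: Optional[str] = None  # positive controls only

    def read(self) -> GwasTable:
        return read_gwas_table(self.path, self.columns, self.trait_name, self.trait_scale)


@dataclass(frozen=True)
class StudyConfig:
    seed: int
    out_dir: Path
    region: ins.GeneRegion
    candidates: TableSpec
    biomarkers: tuple[TableSpec, ...]
    exposure: TableSpec
    controls: tuple[TableSpec, ...]
    outcome: TableSpec
    ld_matrix_path: Path
    p_threshold: float = 0.05
    r2_threshold: float = 0.001
    required_direction: str = "negative"
    concordance_mode: str = "all"
    af_band: tuple[float, float] = hz.DEFAULT_AF_BAND
    n_boot: int = 1000
    wald_se_order: str = "first"
    coloc_priors: coloc_mod.ColocPriors = field(default_factory=coloc_mod.ColocPriors)
    arr_deltas: tuple[float, ...] = (16.0,)
    arr_per_unit: Optional[float] = None


def _require(cfg: dict, key: str, context: str) -> Any:
    if key not in cfg:
        raise ConfigurationError(f"config field {context}.{key} is required")
    return cfg[key]


def _table_spec(entry: dict, base: Path, context: str, allow_direction: bool = False) -> TableSpec:
    path = base / _require(entry, "path", context)
    if not path.exists():
        raise ConfigurationError(f"{context}.path: file not found: {path}")
    columns = ColumnMap(entry["columns"]) if entry.get("columns") else ColumnMap.identity()
    direction = entry.get("expected_direction")
    if allow_direction:
        if direction not in ("protective", "detrimental"):
            raise ConfigurationError(
                f"{context}.expected_direction must be 'protective' or 'detrimental', got {direction!r}"
            )
    elif direction is not None:
        raise ConfigurationError(f"{context}: expected_direction only applies to controls")
    return TableSpec(
        path=path,
        trait_name=_require(entry, "trait_name", context),
        trait_scale=_require(entry, "trait_scale", context),
        columns=columns,
        expected_direction=direction,
    )


def load_config(path: str | Path, seed: Optional[int] = None, out_dir: Optional[str | Path] = None) -> StudyConfig:
    """Parse and validate a study YAML; ``seed``/``out_dir`` override the file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    base = path.parent

    if seed is None:
        seed = _require(raw, "seed", "<root>")
    region_cfg = _require(raw, "region", "<root>")
    region = ins.GeneRegion(
        chrom=str(_require(region_cfg, "chrom", "region")),
        start=int(_require(region_cfg, "start", "region")),
        end=int(_require(region_cfg, "end", "region")),
        flank=int(region_cfg.get("flank", 0)),
    )
    tables = _require(raw, "tables", "<root>")
    biomarkers = tuple(
        _table_spec(e, base, f"tables.biomarkers[{i}]")
        for i, e in enumerate(_require(tables, "biomarkers", "tables"))
    )
    if not biomarkers:
        raise ConfigurationError("tables.biomarkers must list at least one table")
    controls = tuple(
        _table_spec(e, base, f"tables.controls[{i}]", allow_direction=True)
        for i, e in enumerate(tables.get("controls", []))
    )
    sel = raw.get("selection", {})
    harm = raw.get("harmonization", {})
    est = raw.get("estimators", {})
    col = raw.get("coloc", {})
    arr = raw.get("arr", {})
    ld_path = base / _require(raw, "ld_matrix", "<root>")
    if not ld_path.exists():
        raise ConfigurationError(f"ld_matrix: file not found: {ld_path}")

    return StudyConfig(
        seed=int(seed),
        out_dir=Path(out_dir) if out_dir is not None else base / raw.get("out_dir", "results"),
        region=region,
        candidates=_table_spec(_require(tables, "candidates", "tables"), base, "tables.candidates"),
        biomarkers=biomarkers,
        exposure=_table_spec(_require(tables, "exposure", "tables"), base, "tables.exposure"),
        controls=controls,
        outcome=_table_spec(_require(tables, "outcome", "tables"), base, "tables.outcome"),
        ld_matrix_path=ld_path,
        p_threshold=float(sel.get("p_threshold", 0.05)),
        r2_threshold=float(sel.get("r2_threshold", 0.001)),
        required_direction=sel.get("required_direction", "negative"),
        concordance_mode=sel.get("mode", "all"),
        af_band=tuple(harm.get("af_band", hz.DEFAULT_AF_BAND)),
        n_boot=int(est.get("n_boot", 1000)),
        wald_se_order=est.get("wald_se_order", "first"),
        coloc_priors=coloc_mod.ColocPriors(
            p1=float(col.get("p1", 1e-4)),
            p2=float(col.get("p2", 1e-4)),
            p12=float(col.get("p12", 1e-5)),
        ),
        arr_deltas=tuple(float(d) for d in arr.get("deltas", [16.0])),
        arr_per_unit=float(arr["arr_per_unit"]) if arr.get("arr_per_unit") is not None else None,
    )


class StageError(RuntimeError):
    """A pipeline stage produced empty output."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _log_stage(stage: str, n_in: int, n_out: int, t0: float) -> None:
    logger.info("stage=%s n_in=%d n_out=%d wall=%.3fs", stage, n_in, n_out, time.perf_counter() - t0)


def _analyze_outcome(
    exposure: GwasTable,
    outcome: GwasTable,
    config: StudyConfig,
) -> dict:
    """Harmonize, orient to inhibition, and run every estimator on one outcome."""
    t0 = time.perf_counter()
    hset = hz.harmonize_dataset(exposure, outcome, band=config.af_band)
    hset = hz.orient_to_inhibition(hset)
    _log_stage(f"harmonize:{outcome.trait_name}", len(exposure), len(hset), t0)
    if not hset.pairs:
        raise StageError(f"harmonize:{outcome.trait_name}", "no usable harmonized pairs")

    walds = mr.wald_ratios(hset, se_order=config.wald_se_order)
    ivw = mr.ivw_fixed(walds)
    result: dict[str, Any] = {
        "trait_name": outcome.trait_name,
        "trait_scale": outcome.trait_scale,
        "harmonized_n": len(hset),
        "exclusions": dict(sorted(hset.exclusions.items())),
        "snps": [p.rsid for p in hset.pairs],
        "wald_per_snp": [
            dict(rsid=p.rsid, **w.to_dict()) for p, w in zip(hset.pairs, walds)
        ],
        "estimates": {"ivw_fe": ivw.to_dict()},
        # inhibition framing: effect per 1-unit *decrease* in the exposure
        "per_unit_decrease": {"ivw_fe": -ivw.theta},
    }
    if len(walds) >= 2:
        q = mr.cochran_q(walds)
        result["heterogeneity"] = q.to_dict()
        if q.pval < 0.05:
            logger.warning(
                "heterogeneity detected for %s (Q=%.3f, p=%.3g); continuing",
                outcome.trait_name, q.q, q.pval,
            )
    if len(hset) >= 3:
        wm = mr.weighted_median(hset, n_boot=config.n_boot, seed=config.seed, se_order=config.wald_se_order)
        slope, intercept = mr.mr_egger(hset)
        result["estimates"]["weighted_median"] = wm.to_dict()
        result["estimates"]["egger_slope"] = slope.to_dict()
        result["estimates"]["egger_intercept"] = intercept.to_dict()
        result["per_unit_decrease"]["weighted_median"] = -wm.theta
        result["per_unit_decrease"]["egger_slope"] = -slope.theta
    return result


def run_positive_controls(
    exposure: GwasTable,
    controls: Sequence[tuple[GwasTable, str]],
    config: StudyConfig,
) -> dict:
    """IVW estimate and direction verdict for each control outcome.

    Each control carries an expected direction for the effect of exposure
    *inhibition*: ``protective`` expects a negative per-unit-decrease
    estimate, ``detrimental`` a positive one.
    """
    if not controls:
        raise ConfigurationError("at least one positive-control outcome is required")
    section: dict[str, dict] = {}
    for table, expected in controls:
        if expected not in ("protective", "detrimental"):
            raise ConfigurationError(
                f"control {table.trait_name!r} needs expected_direction protective/detrimental"
            )
        res = _analyze_outcome(exposure, table, config)
        per_decrease = res["per_unit_decrease"]["ivw_fe"]
        observed = "protective" if per_decrease < 0 else "detrimental"
        res["expected_direction"] = expected
        res["observed_direction"] = observed
        res["verdict"] = "pass" if observed == expected else "fail"
        section[table.trait_name] = res
    return dict(sorted(section.items()))


def run_drug_target_mr(config: StudyConfig) -> dict:
    """Execute the full study and write report files under ``config.out_dir``.

    Returns the report dictionary (also serialized to ``report.json``).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    candidates_full = config.candidates.read()
    biomarkers = [spec.read() for spec in config.biomarkers]
    exposure = config.exposure.read()
    controls = [(spec.read(), spec.expected_direction) for spec in config.controls]
    outcome = config.outcome.read()
    ld = ins.read_ld_matrix(config.ld_matrix_path)
    _log_stage("read", 0, len(candidates_full), t0)

    t0 = time.perf_counter()
    candidates = ins.extract_cis_window(candidates_full, config.region)
    _log_stage("cis_window", len(candidates_full), len(candidates), t0)
    if not candidates.records:
        raise StageError("cis_window", "no candidates inside the gene window")

    t0 = time.perf_counter()
    concordant, report = ins.concordance_filter(
        candidates,
        biomarkers,
        p_threshold=config.p_threshold,
        required_direction=config.required_direction,
        mode=config.concordance_mode,
    )
    _log_stage("concordance", len(candidates), len(concordant), t0)
    if not concordant.records:
        raise StageError("concordance", "no concordant candidates")

    t0 = time.perf_counter()
    clumped = ins.ld_clump(concordant, ld, r2_threshold=config.r2_threshold, report=report)
    _log_stage("clump", len(concordant), len(clumped), t0)
    if not clumped.records:
        raise StageError("clump", "no independent instruments after clumping")

    instrument_rsids = list(clumped.rsids)
    exposure_sel = exposure.subset(instrument_rsids)
    if not exposure_sel.records:
        raise StageError("exposure_subset", "no instrument present in the exposure table")

    primary = _analyze_outcome(exposure_sel, outcome, config)
    control_section = run_positive_controls(exposure_sel, controls, config) if controls else {}

    # regional colocalization of exposure vs primary outcome
    t0 = time.perf_counter()
    region_x = ins.extract_cis_window(exposure, config.region)
    region_y = ins.extract_cis_window(outcome, config.region)
    coloc_res = coloc_mod.coloc_posteriors(
        region_x,
        region_y,
        priors=config.coloc_priors,
        prior_sd1=coloc_mod.prior_sd_for_scale(exposure.trait_scale),
        prior_sd2=coloc_mod.prior_sd_for_scale(outcome.trait_scale),
    )
    _log_stage("coloc", len(region_x), coloc_res.n_snps, t0)

    # absolute-risk extrapolation from the primary per-unit-decrease estimate
    if config.arr_per_unit is not None:
        arr_per_unit = config.arr_per_unit
    else:
        arr_per_unit = 100.0 * primary["per_unit_decrease"]["ivw_fe"]  # percent
    extrapolations = [
        {
            "arr_per_unit_pct": arr_per_unit,
            "delta_biomarker": d,
            "extrapolated_pct": extrapolate_arr(arr_per_unit, d),
        }
        for d in config.arr_deltas
    ]

    report_dict = {
        "seed": config.seed,
        "region": {
            "chrom": config.region.chrom,
            "start": config.region.start,
            "end": config.region.end,
            "flank": config.region.flank,
        },
        "selection": report.to_dict(),
        "instruments": instrument_rsids,
        "primary_outcome": primary,
        "positive_controls": control_section,
        "coloc": coloc_res.to_dict(),
        "arr_extrapolations": extrapolations,
    }

    _write_outputs(report_dict, report, primary, control_section, coloc_res, out)
    return report_dict


def _write_outputs(report_dict, selection, primary, controls, coloc_res, out: Path) -> None:
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(out / "selection_report.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("stage\tcount\n")
        fh.write(f"candidates\t{selection.n_candidates}\n")
        fh.write(f"with_any_association\t{selection.n_with_any_association}\n")
        fh.write(f"concordant\t{selection.n_concordant}\n")
        fh.write(f"after_clump\t{selection.n_after_clump}\n")

    with open(out / "exclusions.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("stage\trsid\treason\n")
        for rsid, reason in sorted(selection.excluded.items()):
            fh.write(f"selection\t{rsid}\t{reason}\n")
        for rsid, reason in sorted(primary["exclusions"].items()):
            fh.write(f"harmonize:{primary['trait_name']}\t{rsid}\t{reason}\n")
        for name, section in controls.items():
            for rsid, reason in sorted(section["exclusions"].items()):
                fh.write(f"harmonize:{name}\t{rsid}\t{reason}\n")

    estimates = []
    for key in ("ivw_fe", "weighted_median", "egger_slope", "egger_intercept"):
        if key in primary["estimates"]:
            e = primary["estimates"][key]
            estimates.append(mr.MrEstimate(**e))
    mr.write_estimates_tsv(estimates, out / "estimates.tsv")
    coloc_res.write_json(out / "coloc.json")
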