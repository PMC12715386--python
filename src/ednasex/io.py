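"""CSV/JSON/YAML interfaces and the end-to-end pipeline.

Tabular inputs and outputs are plain CSV with documented headers; the
machine-readable record of a run is a JSON report.  ``run_pipeline``
composes the stages in analysis order: per-sample well merging (with
saturation and control handling), optional LoD filtering, allele ratios
(optionally mass-corrected for eDNA samples), male-proportion estimates,
calibration regressions and group statistics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import quantification as q
from . import sexratio as sx
from .limits import LimitResult, apply_limits
from .quantification import (
    ConcentrationEstimate,
    RatioEstimate,
    ThresholdConfig,
    WellCount,
    allele_ratio,
    merge_wells,
    per_well_ratios,
    rsd,
)
from .sexratio import (
    ExpectedRatioModel,
    SampleComposition,
    SexRatioEstimate,
    accuracy_vs_expected,
    calibrate,
    compare_groups,
    estimate_male_proportion,
    mass_correct,
)

log = logging.getLogger(__name__)

DROPLET_CSV_COLUMNS = [
    "plate", "well", "sample_id", "target", "positives", "accepted",
    "template_volume_ul", "dilution_factor",
]
METADATA_CSV_COLUMNS = [
    "sample_id", "group", "n_males", "n_females",
    "male_mass_g", "total_mass_g", "series", "sample_type",
]
CONCENTRATION_CSV_COLUMNS = [
    "sample_id", "target", "wells_merged", "k_total", "n_total",
    "lambda", "conc_reaction", "conc_start", "ci_low", "ci_high", "saturated",
]


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass
class RunConfig:
    """Run-level configuration; every default is the assay's validated value."""

    droplet_volume_ul: float = q.DEFAULT_DROPLET_VOLUME_UL
    mix_volume_ul: float = q.DEFAULT_MIX_VOLUME_UL
    hex_min: float = 2400.0
    fam_min: float = 3000.0
    alpha: float = 0.05
    rsd_max_pct: float = 30.0
    rho: float = 7.0
    channel_map: dict = field(default_factory=lambda: dict(q.DEFAULT_CHANNEL_MAP))
    mass_correct: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @property
    def thresholds(self) -> ThresholdConfig:
        return ThresholdConfig(hex_min=self.hex_min, fam_min=self.fam_min)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_droplet_csv(path: str | Path, config: RunConfig | None = None) -> list[WellCount]:
    """Read the per-well droplet-count table into typed records.

    Required columns: ``plate, well, sample_id, target, positives, accepted,
    template_volume_ul, dilution_factor``.  Unknown columns are preserved as
    string annotations on each record.  Malformed rows (e.g. positives >
    accepted) are collected and reported together with their row numbers.
    """
    config = config or RunConfig()
    df = pd.read_csv(path)
    missing = [c for c in DROPLET_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"droplet CSV missing required column(s): {missing}")
    extra_cols = [c for c in df.columns if c not in DROPLET_CSV_COLUMNS]

    wells: list[WellCount] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            wells.append(WellCount(
                well_id=str(row["well"]),
                sample_id=str(row["sample_id"]),
                target=str(row["target"]),
                positives=int(row["positives"]),
                accepted=int(row["accepted"]),
                droplet_volume_ul=config.droplet_volume_ul,
                template_volume_ul=float(row["template_volume_ul"]),
                mix_volume_ul=config.mix_volume_ul,
                dilution_factor=float(row["dilution_factor"]),
                extra={c: str(row[c]) for c in (["plate"] + extra_cols)},
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise ValueError("droplet CSV validation failed:\n" + "\n".join(errors))
    return wells


def write_droplet_csv(wells: Sequence[WellCount], path: str | Path) -> None:
    pd.DataFrame([
        {
            "plate": w.extra.get("plate", ""), "well": w.well_id,
            "sample_id": w.sample_id, "target": w.target,
            "positives": w.positives, "accepted": w.accepted,
            "template_volume_ul": w.template_volume_ul,
            "dilution_factor": w.dilution_factor,
        }
        for w in wells
    ]).to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> tuple[dict[str, SampleComposition], list[str]]:
    """Read sample metadata; returns (compositions by sample_id, control ids).

    Rows whose ``sample_type`` is ``ntc``/``blank``/``control`` are returned
    as control ids rather than compositions.
    """
    df = pd.read_csv(path)
    missing = [c for c in METADATA_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata CSV missing required column(s): {missing}")
    comps: dict[str, SampleComposition] = {}
    controls: list[str] = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        stype = str(row["sample_type"]).lower()
        if stype in ("ntc", "blank", "control"):
            controls.append(sid)
            continue
        comps[sid] = SampleComposition(
            sample_id=sid,
            n_males=int(row["n_males"]),
            n_females=int(row["n_females"]),
            male_mass_g=float(row["male_mass_g"]),
            total_mass_g=float(row["total_mass_g"]),
            series_label=str(row["series"]),
            sample_type=stype,
        )
    # group labels recovered from the table for grouping downstream
    return comps, controls


def read_groups_csv(path: str | Path) -> dict[str, str]:
    """sample_id -> group label mapping from the metadata CSV."""
    df = pd.read_csv(path)
    return {str(r["sample_id"]): str(r["group"]) for _, r in df.iterrows()}


def write_concentration_csv(
    estimates: Sequence[ConcentrationEstimate], path: str | Path
) -> None:
    pd.DataFrame([
        {
            "sample_id": e.sample_id, "target": e.target,
            "wells_merged": e.wells_merged, "k_total": e.k_total,
            "n_total": e.n_total, "lambda": e.lam,
            "conc_reaction": e.conc_reaction, "conc_start": e.conc_start,
            "ci_low": e.ci_low, "ci_high": e.ci_high,
            "saturated": e.saturated_flag,
        }
        for e in estimates
    ]).to_csv(path, index=False)


def quantify_samples(
    wells: Sequence[WellCount],
) -> tuple[list[ConcentrationEstimate], dict[str, list[float]]]:
    """Merge wells per (sample, target) and quantify on pooled counts.

    Also returns per-sample per-well common-to-male ratios (for RSD
    reporting) keyed by sample_id.
    """
    grouped: dict[tuple[str, str], list[WellCount]] = {}
    for w in wells:
        grouped.setdefault((w.sample_id, w.target), []).append(w)

    estimates = [merge_wells(ws) for ws in grouped.values()]
    ratios: dict[str, list[float]] = {}
    samples = {sid for sid, _ in grouped}
    for sid in samples:
        cw = grouped.get((sid, "common"))
        mw = grouped.get((sid, "male"))
        if cw and mw and len(cw) == len(mw):
            ratios[sid] = per_well_ratios(cw, mw)
    return estimates, ratios


@dataclass
class PipelineResult:
    concentrations: list[ConcentrationEstimate]
    ratios: dict[str, RatioEstimate]
    estimates: dict[str, SexRatioEstimate]
    calibration: sx.CalibrationFit | None
    calibration_expected: sx.CalibrationFit | None
    group_comparison: dict | None
    accuracy: dict | None
    report: dict

    def estimates_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "sample_id": e.sample_id,
                "r_obs_male_to_common": e.r_obs,
                "p_male_raw": e.p_male_raw, "p_male": e.p_male,
                "ci_low": e.ci_low, "ci_high": e.ci_high,
                "mass_corrected": e.mass_corrected_flag,
            }
            for e in self.estimates.values()
        ])


def run_pipeline(
    config: RunConfig,
    wells: Sequence[WellCount],
    metadata: Mapping[str, SampleComposition],
    groups: Mapping[str, str] | None = None,
    controls: Sequence[str] = (),
    limits: LimitResult | None = None,
) -> PipelineResult:
    """Run droplet counts + metadata through the full analysis.

    Deterministic given inputs and config.  Controls (NTC, blanks) with
    positives raise a contamination warning and are excluded from
    estimation.  With ``limits`` provided, samples whose merged male-allele
    concentration falls below the LoD are excluded and logged.  Raises when
    no sample survives filtering.
    """
    report: dict = {"exclusions": [], "warnings": [], "stages": []}

    # --- controls ---
    control_set = set(controls)
    control_wells = [w for w in wells if w.sample_id in control_set]
    for w in control_wells:
        if w.positives > 0:
            msg = (f"control {w.sample_id} well {w.well_id} has "
                   f"{w.positives} positive droplet(s): possible contamination")
            log.warning(msg)
            report["warnings"].append(msg)
    analysis_wells = [w for w in wells if w.sample_id not in control_set]
    for sid in sorted(control_set):
        report["exclusions"].append({"sample_id": sid, "reason": "control well"})

    # --- quantification ---
    saturated = [w for w in analysis_wells if w.saturated]
    for w in saturated:
        report["exclusions"].append(
            {"sample_id": w.sample_id, "reason": f"saturated well {w.well_id}"}
        )
    estimates, perwell = quantify_samples(analysis_wells)
    by_sample: dict[str, dict[str, ConcentrationEstimate]] = {}
    for e in estimates:
        by_sample.setdefault(e.sample_id, {})[e.target] = e
    report["stages"].append({
        "stage": "quantify",
        "samples": len(by_sample),
        "wells": len(analysis_wells),
    })

    # --- LoD filtering ---
    pairs = [
        (t["common"], t["male"])
        for sid, t in sorted(by_sample.items())
        if "common" in t and "male" in t and sid in metadata
    ]
    if limits is not None and limits.lod_defined:
        pairs, excluded = apply_limits(pairs, limits)
        report["exclusions"] += excluded
        report["stages"].append({
            "stage": "lod_filter", "excluded": len(excluded), "retained": len(pairs),
        })
    if not pairs:
        raise ValueError("insufficient data: no samples retained after filtering")

    # --- ratios, mass correction, sex-ratio estimates ---
    model = ExpectedRatioModel(rho=config.rho)
    ratios: dict[str, RatioEstimate] = {}
    sex_estimates: dict[str, SexRatioEstimate] = {}
    for common, male in pairs:
        sid = common.sample_id
        pw = perwell.get(sid, [])
        r = allele_ratio(common, male,
                         rsd_pct=rsd(pw) if len(pw) >= 2 else math.nan)
        comp = metadata[sid]
        corrected = False
        if config.mass_correct and comp.sample_type == "edna":
            r = mass_correct(r, comp)
            corrected = True
        ratios[sid] = r
        ci = None
        if math.isfinite(r.ci_low) and r.common_to_male > 0 and math.isfinite(r.common_to_male):
            ci = (1.0 / r.ci_high, 1.0 / r.ci_low)
        sex_estimates[sid] = estimate_male_proportion(
            r.male_to_common if math.isfinite(r.male_to_common) else 0.0,
            model, sample_id=sid, ci=ci, mass_corrected=corrected,
        )
    report["stages"].append({"stage": "estimate", "samples": len(sex_estimates)})

    # --- calibration and group statistics ---
    cal_samples = [
        (metadata[sid], r) for sid, r in ratios.items()
        if math.isfinite(r.male_to_common)
    ]
    calibration = calibration_expected = None
    distinct_p = {c.p_male for c, _ in cal_samples}
    if len(cal_samples) >= 3 and len(distinct_p) >= 2:
        calibration = calibrate(cal_samples, variant="ratio")
        finite = [
            (c, r) for c, r in cal_samples
            if math.isfinite(r.common_to_male) and r.common_to_male > 0 and c.n_males > 0
        ]
        if len(finite) >= 3:
            try:
                calibration_expected = calibrate(finite, variant="expected", model=model)
            except ValueError:
                pass

    group_of = groups or {}
    ratio_groups: dict[str, list[float]] = {}
    comp_of_group: dict[str, SampleComposition] = {}
    for sid, r in ratios.items():
        g = group_of.get(sid)
        if g is None or not math.isfinite(r.common_to_male) or r.common_to_male <= 0:
            continue
        if metadata[sid].n_males == 0:
            # all-female groups have an unbounded expected ratio; any finite
            # observed ratio there is cross-reactivity, not signal
            continue
        ratio_groups.setdefault(g, []).append(r.common_to_male)
        comp_of_group.setdefault(g, metadata[sid])

    comparison = accuracy = None
    comparable = {g: v for g, v in ratio_groups.items() if len(v) >= 2}
    if len(comparable) >= 2:
        comparison = compare_groups(comparable, mode="auto")
    if ratio_groups:
        accuracy = accuracy_vs_expected(ratio_groups, comp_of_group, model=model)

    report["stages"].append({
        "stage": "statistics",
        "groups": sorted(ratio_groups),
        "calibration": calibration is not None,
    })

    return PipelineResult(
        concentrations=estimates,
        ratios=ratios,
        estimates=sex_estimates,
        calibration=calibration,
        calibration_expected=calibration_expected,
        group_comparison=comparison,
        accuracy=accuracy,
        report=report,
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return None if math.isnan(obj) else (obj if math.isfinite(obj) else "inf")
    return obj


def write_report_json(result: PipelineResult, path: str | Path) -> None:
    payload = {
        "report": _jsonable(result.report),
        "calibration": _jsonable(result.calibration),
        "calibration_expected": _jsonable(result.calibration_expected),
        "group_comparison": _jsonable(result.group_comparison),
        "accuracy_vs_expected": _jsonable(result.accuracy),
        "ratios": {k: _jsonable(v) for k, v in result.ratios.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def validate_assay(
    estimates: Sequence[ConcentrationEstimate],
    sexes: Mapping[str, str],
) -> dict:
    """Per-individual specificity check of the sex-linked assay.

    Every male must show the male allele; every female must not.  Also
    reports per-male common-to-male ratios and their mean/RSD, which is how
    the per-male copy-ratio parameter rho is calibrated for a population.
    """
    by_sample: dict[str, dict[str, ConcentrationEstimate]] = {}
    for e in estimates:
        by_sample.setdefault(e.sample_id, {})[e.target] = e

    failures: list[str] = []
    male_ratios: list[float] = []
    for sid, sex in sexes.items():
        t = by_sample.get(sid, {})
        male_conc = t["male"].conc_start if "male" in t else math.nan
        if sex == "M":
            if not male_conc > 0:
                failures.append(f"male {sid}: male allele not detected")
            elif "common" in t and t["common"].conc_start > 0:
                male_ratios.append(t["common"].conc_start / male_conc)
        elif sex == "F" and male_conc > 0:
            failures.append(f"female {sid}: male allele detected "
                            f"({male_conc:.3g} copies/uL)")

    out: dict = {
        "n_individuals": len(sexes),
        "specific": not failures,
        "failures": failures,
        "male_ratios": male_ratios,
    }
    if len(male_ratios) >= 2:
        out["rho_mean"] = float(sum(male_ratios) / len(male_ratios))
        out["rho_rsd_pct"] = rsd(male_ratios)
    return out
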