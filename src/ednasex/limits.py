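"""Limit of detection and limit of quantification from a dilution series.

The LoD is the lowest (most dilute) male-allele concentration whose
per-replicate starting-material concentrations differ significantly from a
negative (female) series; the LoQ is the lowest concentration at which
common-to-male ratios are measurable within a stated precision (default
30% RSD).  Both are evaluated on merged replicate wells, so the limits
reported reflect what pooled replicates achieve, not single wells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .quantification import (
    ConcentrationEstimate,
    WellCount,
    allele_ratio,
    concentration,
    merge_wells,
    per_well_ratios,
    rsd,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DilutionLevel:
    """One level of the series: replicate wells for each allele."""

    dilution_factor: float
    common_wells: tuple[WellCount, ...]
    male_wells: tuple[WellCount, ...]

    def __post_init__(self) -> None:
        if len(self.male_wells) < 2:
            raise ValueError("need >= 2 replicate wells per level")


@dataclass(frozen=True)
class DilutionSeries:
    """A k-fold dilution series of one extract, replicated per level."""

    levels: tuple[DilutionLevel, ...]
    starting_conc_ng_per_ul: float = math.nan

    def __post_init__(self) -> None:
        factors = [lv.dilution_factor for lv in self.levels]
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise ValueError("dilution factors must be strictly increasing")


@dataclass(frozen=True)
class LimitResult:
    """LoD and/or LoQ determination with the supporting statistics."""

    lod_copies_per_ul: float = math.nan
    lod_level: float = math.nan
    test_statistic: float = math.nan
    degrees_freedom: int = 0
    p_value: float = math.nan
    min_replicates: int = 0
    lod_defined: bool = False

    loq_copies_per_ul: float = math.nan
    loq_level: float = math.nan  # per-well mode
    loq_merged_level: float = math.nan
    loq_merged_copies_per_ul: float = math.nan
    merged_rsd_pct: float = math.nan
    per_level_rsd_pct: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    rsd_threshold_pct: float = 30.0
    loq_defined: bool = False

    warnings: tuple[str, ...] = field(default_factory=tuple)


def _replicate_concentrations(wells: Sequence[WellCount]) -> np.ndarray:
    return np.array([concentration(w).conc_start for w in wells if not w.saturated])


def detect_lod(
    series: DilutionSeries,
    negatives: Sequence[WellCount],
    alpha: float = 0.05,
) -> LimitResult:
    """Walk the series from most dilute to least dilute and find the LoD.

    At each level the per-replicate male-allele concentrations are tested
    against the negative series: a one-sample t-test against zero when every
    negative replicate is zero (the usual case for a clean female extract),
    a Welch two-sample t-test otherwise.  Zero-concentration replicates stay
    in the test sample — dropping them would bias the mean upward and the
    degrees of freedom downward.  Normality of the positive replicates is
    checked by Shapiro-Wilk and reported as a warning, not a gate.

    The LoD is the most dilute significant level; its reported concentration
    is the merged-well estimate there.  A non-monotone significance pattern
    (a less dilute level that fails while a more dilute one passes) is
    flagged in the warnings.
    """
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")

    neg = _replicate_concentrations(negatives) if negatives else np.array([])
    all_neg_zero = neg.size == 0 or bool(np.all(neg == 0))

    warns: list[str] = []
    results = []  # (level, significant, t, df, p)
    for level in series.levels:
        x = _replicate_concentrations(level.male_wells)
        if x.size < 2 or np.all(x == 0):
            results.append((level, False, math.nan, x.size - 1, math.nan))
            continue
        if x.size >= 3 and np.ptp(x) > 0:
            sw = stats.shapiro(x)
            if sw.pvalue < 0.05:
                warns.append(
                    f"level 1:{level.dilution_factor:g}: Shapiro-Wilk "
                    f"p={sw.pvalue:.3f} < 0.05; t-test normality questionable"
                )
        if all_neg_zero:
            t, p = stats.ttest_1samp(x, 0.0)
            df = x.size - 1
        else:
            t, p = stats.ttest_ind(x, neg, equal_var=False)
            df = stats.ttest_ind(x, neg, equal_var=False).df
        results.append((level, p < alpha, float(t), int(round(df)), float(p)))

    significant = [r for r in results if r[1]]
    if not significant:
        return LimitResult(lod_defined=False, warnings=tuple(warns))

    # most dilute = largest dilution factor = last in the ordered series
    level, _, t, df, p = significant[-1]
    idx = [r[0] for r in results].index(level)
    if any(not r[1] for r in results[:idx] if not math.isnan(r[4])):
        warns.append(
            "non-monotone significance pattern across levels; reporting the "
            "most dilute significant level"
        )

    merged = merge_wells(list(level.male_wells))
    return LimitResult(
        lod_copies_per_ul=merged.conc_start,
        lod_level=level.dilution_factor,
        test_statistic=t,
        degrees_freedom=df,
        p_value=p,
        min_replicates=len(level.male_wells),
        lod_defined=True,
        warnings=tuple(warns),
    )


def detect_loq(series: DilutionSeries, rsd_max: float = 30.0) -> LimitResult:
    """LoQ from ratio dispersion, in per-well and merged-well modes.

    Per-well mode: walking from the most concentrated level downward, the
    LoQ sits at the last level whose per-replicate common-to-male ratio RSD
    stays below ``rsd_max`` before the first exceedance — subsampling error
    inflates the per-well RSD as concentration falls.

    Merged mode: each level's ratio is recomputed on pooled counts and the
    RSD is taken across levels; when that cross-level RSD is below
    ``rsd_max``, pooled replicates quantify reliably all the way down, and
    the LoQ is placed at the most dilute level.
    """
    if rsd_max <= 0:
        raise ValueError("rsd_max must be positive")

    per_level: list[tuple[float, float]] = []
    merged_ratios: list[float] = []
    warns: list[str] = []
    for level in series.levels:
        ratios = per_well_ratios(level.common_wells, level.male_wells)
        if len(ratios) >= 2:
            per_level.append((level.dilution_factor, rsd(ratios)))
        else:
            per_level.append((level.dilution_factor, math.nan))
            warns.append(
                f"level 1:{level.dilution_factor:g}: fewer than 2 wells with "
                "male positives; per-well RSD undefined"
            )
        mc = merge_wells(list(level.common_wells))
        mm = merge_wells(list(level.male_wells))
        if mm.conc_start > 0:
            merged_ratios.append(allele_ratio(mc, mm).common_to_male)

    # per-well mode: last qualifying level before the first exceedance
    loq_level = math.nan
    for factor, level_rsd in per_level:
        if math.isnan(level_rsd) or level_rsd >= rsd_max:
            break
        loq_level = factor

    loq_copies = math.nan
    if not math.isnan(loq_level):
        lv = next(l for l in series.levels if l.dilution_factor == loq_level)
        loq_copies = merge_wells(list(lv.male_wells)).conc_start

    merged_rsd = rsd(merged_ratios) if len(merged_ratios) >= 2 else math.nan
    loq_merged_level = math.nan
    loq_merged_copies = math.nan
    if not math.isnan(merged_rsd) and merged_rsd < rsd_max:
        last = series.levels[-1]
        loq_merged_level = last.dilution_factor
        loq_merged_copies = merge_wells(list(last.male_wells)).conc_start

    defined = not math.isnan(loq_level) or not math.isnan(loq_merged_level)
    return LimitResult(
        loq_copies_per_ul=loq_copies,
        loq_level=loq_level,
        loq_merged_level=loq_merged_level,
        loq_merged_copies_per_ul=loq_merged_copies,
        merged_rsd_pct=merged_rsd,
        per_level_rsd_pct=tuple(per_level),
        rsd_threshold_pct=rsd_max,
        loq_defined=defined,
        warnings=tuple(warns),
    )


def apply_limits(
    samples: Sequence[tuple[ConcentrationEstimate, ConcentrationEstimate]],
    limits: LimitResult,
) -> tuple[list[tuple[ConcentrationEstimate, ConcentrationEstimate]], list[dict]]:
    """Drop samples whose merged male-allele concentration falls below the LoD.

    ``samples`` is a list of (common, male) merged estimates per sample.
    Returns the retained pairs and an exclusion log, one entry per dropped
    sample with the reason.
    """
    if not limits.lod_defined:
        raise ValueError("LoD is undefined; cannot filter")

    kept: list[tuple[ConcentrationEstimate, ConcentrationEstimate]] = []
    excluded: list[dict] = []
    for common, male in samples:
        if male.conc_start < limits.lod_copies_per_ul:
            excluded.append({
                "sample_id": male.sample_id,
                "reason": "male allele below LoD",
                "male_conc": male.conc_start,
                "lod": limits.lod_copies_per_ul,
            })
            log.info("excluding %s: male %.3g < LoD %.3g copies/uL",
                     male.sample_id, male.conc_start, limits.lod_copies_per_ul)
        else:
            kept.append((common, male))
    return kept, excluded
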