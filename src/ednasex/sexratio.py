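"""From allele ratios to sex-ratio estimates.

The model: at an X/Y-linked locus every individual carries the common
allele, while only males carry the male-specific allele, at an average
common-to-male per-male copy ratio ``rho`` (default 7, with substantial
inter-individual spread).  In a pooled DNA sample of M males and F females
contributing equally, the expected common-to-male concentration ratio is

    E[common/male] = rho * (M + F) / M

so the male proportion p = M/(M+F) is recovered from an observed
male-to-common ratio r as ``p_hat = rho * r``.  For eDNA samples, where
each individual's contribution scales with body mass, the mass-proportional
variant replaces head counts with masses, and observed ratios can be
mass-corrected before inversion.

The module also carries the validation statistics used on samples of known
composition: group comparisons (ANOVA/Tukey or Kruskal-Wallis/Dunn-BH),
one-sample Wilcoxon tests of observed vs. expected ratios, and calibration
regressions on the log10(x+1) scale.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .quantification import RatioEstimate

log = logging.getLogger(__name__)

_GROUP_RE = re.compile(r"^\s*(?:(\d+)\s*M)?\s*:?\s*(?:(\d+)\s*F)?\s*$", re.IGNORECASE)


def parse_group_label(label: str) -> tuple[int, int]:
    """Parse an "xM:yF" composition label; "1M" means one male, no females."""
    m = _GROUP_RE.match(label)
    if not m or (m.group(1) is None and m.group(2) is None):
        raise ValueError(f"cannot parse group label {label!r}")
    return int(m.group(1) or 0), int(m.group(2) or 0)


@dataclass(frozen=True)
class SampleComposition:
    """Known sex composition and biomass of one sample."""

    sample_id: str
    n_males: int
    n_females: int
    male_mass_g: float = math.nan
    total_mass_g: float = math.nan
    series_label: str = ""
    sample_type: str = "mock"  # "mock" or "edna"

    def __post_init__(self) -> None:
        if self.n_males + self.n_females < 1:
            raise ValueError("a sample needs at least one individual")
        if not math.isnan(self.male_mass_g):
            if self.male_mass_g < 0 or self.male_mass_g > self.total_mass_g:
                raise ValueError("need 0 <= male_mass <= total_mass")
        if self.sample_type == "edna" and not self.total_mass_g > 0:
            raise ValueError("eDNA samples need a positive total mass")

    @property
    def p_male(self) -> float:
        return self.n_males / (self.n_males + self.n_females)


@dataclass(frozen=True)
class ExpectedRatioModel:
    """Per-male copy-ratio model mapping compositions to expected allele ratios."""

    rho: float = 7.0
    contribution: str = "equal"  # "equal" (head count) or "mass"

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.contribution not in ("equal", "mass"):
            raise ValueError("contribution must be 'equal' or 'mass'")


@dataclass(frozen=True)
class SexRatioEstimate:
    """Estimated male proportion; raw (unclamped) and clamped to [0, 1]."""

    sample_id: str
    p_male_raw: float
    p_male: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    mass_corrected_flag: bool = False
    r_obs: float = math.nan  # male-to-common ratio the estimate is based on


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration of observed ratios against known composition."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_value: float
    slope_ci_low: float
    slope_ci_high: float
    slope_eq_one_p: float = math.nan  # test of H0: slope = 1 (expected-variant)
    variant: str = "ratio"
    n: int = 0


def expected_ratio(comp: SampleComposition, model: ExpectedRatioModel) -> float:
    """Expected common-to-male concentration ratio for a known composition.

    Equal-contribution mode: every individual contributes one unit of the
    common allele and every male 1/rho units of the male allele, giving
    ``rho * (M + F) / M``.  Mass-proportional mode scales contributions by
    body mass, giving ``rho * total_mass / male_mass``.  No males means an
    infinite expected ratio (sentinel).
    """
    if model.contribution == "mass":
        if math.isnan(comp.male_mass_g) or math.isnan(comp.total_mass_g):
            raise ValueError(f"sample {comp.sample_id}: masses required in mass mode")
        if comp.male_mass_g == 0:
            return math.inf
        return model.rho * comp.total_mass_g / comp.male_mass_g
    if comp.n_males == 0:
        return math.inf
    return model.rho * (comp.n_males + comp.n_females) / comp.n_males


def expected_ratio_from_individuals(
    male_rhos: Sequence[float], n_females: int
) -> float:
    """Expected common-to-male ratio from measured per-male copy ratios.

    When the per-individual ratios rho_i of the males in a sample are known
    (e.g. from single-individual validation runs), the expected pooled ratio
    under equal contribution is ``(M + F) / sum(1/rho_i)``; with all rho_i
    equal to rho this reduces to ``rho * (M + F) / M``.
    """
    male_rhos = list(male_rhos)
    if not male_rhos:
        return math.inf
    if any(r <= 0 for r in male_rhos):
        raise ValueError("per-male ratios must be positive")
    return (len(male_rhos) + n_females) / sum(1.0 / r for r in male_rhos)


def estimate_male_proportion(
    r_obs: float,
    model: ExpectedRatioModel,
    sample_id: str = "",
    ci: tuple[float, float] | None = None,
    mass_corrected: bool = False,
) -> SexRatioEstimate:
    """Invert the equal-contribution model: p_hat = rho * r_obs.

    ``r_obs`` is the male-to-common ratio (mass-corrected beforehand for
    eDNA samples, in which case p_hat estimates the male mass fraction
    translated back to the head-count scale).  The raw estimate can exceed
    one when a sample's males carry unusually many male-allele copies; the
    clamped value lives in [0, 1].  A CI on r_obs propagates through the
    same linear map.
    """
    if r_obs < 0:
        raise ValueError("r_obs must be nonnegative")
    raw = model.rho * r_obs
    ci_low = ci_high = math.nan
    if ci is not None:
        ci_low = min(1.0, max(0.0, model.rho * ci[0]))
        ci_high = min(1.0, max(0.0, model.rho * ci[1]))
    return SexRatioEstimate(
        sample_id=sample_id,
        p_male_raw=raw,
        p_male=min(1.0, max(0.0, raw)),
        ci_low=ci_low,
        ci_high=ci_high,
        mass_corrected_flag=mass_corrected,
        r_obs=r_obs,
    )


def mass_correct(r: RatioEstimate, comp: SampleComposition) -> RatioEstimate:
    """Rescale observed allele ratios by the male biomass fraction.

    Male-to-common ratios are multiplied by male/total mass; common-to-male
    ratios by total/male mass.  With a single shared shedding rate per gram
    this removes the biomass dependence, putting mixed-mass samples on the
    equal-contribution scale.  All-equal masses make this the identity.
    """
    if math.isnan(comp.male_mass_g) or math.isnan(comp.total_mass_g):
        raise ValueError(f"sample {comp.sample_id}: masses required for correction")
    if comp.male_mass_g == 0:
        if r.male_to_common > 0:
            raise ValueError(
                f"sample {comp.sample_id}: male allele observed but male mass is 0"
            )
        return replace(r, mass_corrected=True)
    f = comp.male_mass_g / comp.total_mass_g
    return RatioEstimate(
        sample_id=r.sample_id,
        common_to_male=r.common_to_male / f,
        male_to_common=r.male_to_common * f,
        ci_low=r.ci_low / f,
        ci_high=r.ci_high / f,
        rsd_pct=r.rsd_pct,
        mass_corrected=True,
    )


def calibrate(
    samples: Sequence[tuple[SampleComposition, RatioEstimate]],
    variant: str = "ratio",
    model: ExpectedRatioModel | None = None,
    expected: Sequence[float] | None = None,
) -> CalibrationFit:
    """Calibration regression of observed ratios against known composition.

    variant="ratio": OLS of log10(male-to-common ratio + 1) on
    log10(male proportion + 1); a positive slope demonstrates quantitative
    tracking of the sex ratio.

    variant="expected": OLS of log10(observed common-to-male ratio) on
    log10(expected common-to-male ratio); a slope not significantly
    different from one indicates accurate quantification, reported via
    ``slope_eq_one_p``.  Expected ratios come from ``model`` (the average
    per-male copy ratio applied to every composition) or, when ``expected``
    is given, from per-sample hypothesised values — e.g. computed from the
    measured copy ratios of the specific males in each sample via
    :func:`expected_ratio_from_individuals`.
    """
    if variant not in ("ratio", "expected"):
        raise ValueError("variant must be 'ratio' or 'expected'")
    if len(samples) < 3:
        raise ValueError("need >= 3 samples to calibrate")

    if variant == "ratio":
        x = np.log10(np.array([c.p_male for c, _ in samples]) + 1.0)
        y = np.log10(np.array([r.male_to_common for _, r in samples]) + 1.0)
    else:
        if expected is not None:
            if len(expected) != len(samples):
                raise ValueError("need one expected value per sample")
            pairs = [(e, r.common_to_male) for e, (_, r) in zip(expected, samples)]
        else:
            model = model or ExpectedRatioModel()
            pairs = [
                (expected_ratio(c, model), r.common_to_male)
                for c, r in samples
            ]
        pairs = [(e, o) for e, o in pairs if math.isfinite(e) and math.isfinite(o) and o > 0]
        if len(pairs) < 3:
            raise ValueError("need >= 3 finite observed/expected pairs")
        x = np.log10(np.array([e for e, _ in pairs]))
        y = np.log10(np.array([o for _, o in pairs]))

    if np.ptp(x) == 0:
        raise ValueError("degenerate design: a single distinct x value")

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    slope = float(fit.params[1])
    slope_se = float(fit.bse[1])
    eq_one_p = math.nan
    if variant == "expected":
        t = (slope - 1.0) / slope_se
        eq_one_p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
    return CalibrationFit(
        slope=slope,
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        slope_ci_low=float(ci[1][0]),
        slope_ci_high=float(ci[1][1]),
        slope_eq_one_p=eq_one_p,
        variant=variant,
        n=len(x),
    )


def _dunn_bh(groups: Mapping[str, Sequence[float]]) -> list[dict]:
    """Dunn's post hoc z-tests on rank sums, Benjamini-Hochberg adjusted.

    Pairwise statistic: z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)) over tied groups.
    """
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # mean rank per group
    mean_ranks, sizes = [], []
    start = 0
    for v in values:
        mean_ranks.append(ranks[start:start + v.size].mean())
        sizes.append(v.size)
        start += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr

    rows, pvals = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p_raw": p})
            pvals.append(p)
    adj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    for row, p_adj in zip(rows, adj):
        row["p_adj"] = float(p_adj)
        row["significant"] = bool(p_adj < 0.05)
    return rows


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    mode: str = "auto",
    log_transform: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Omnibus + post hoc comparison of allele ratios across sex-ratio groups.

    ``auto`` runs one-way ANOVA with Tukey HSD when the (optionally
    log10-transformed) ratios satisfy residual normality (Shapiro-Wilk) and
    homoscedasticity (Levene), and falls back to Kruskal-Wallis with Dunn's
    test (Benjamini-Hochberg) otherwise.  Returns a JSON-serialisable
    report: method, omnibus statistic, df, p, and pairwise results.
    """
    if mode not in ("auto", "parametric", "nonparametric"):
        raise ValueError("mode must be auto, parametric or nonparametric")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")

    data = {
        g: np.log10(np.asarray(v, dtype=float)) if log_transform
        else np.asarray(v, dtype=float)
        for g, v in groups.items()
    }
    arrays = list(data.values())

    assumption_report = {}
    if mode != "nonparametric":
        residuals = np.concatenate([v - v.mean() for v in arrays])
        normal_ok = levene_ok = True
        if np.ptp(residuals) > 0 and residuals.size >= 3:
            sw_p = float(stats.shapiro(residuals).pvalue)
            normal_ok = sw_p >= 0.05
            assumption_report["shapiro_p"] = sw_p
        if all(v.size >= 2 for v in arrays) and any(np.ptp(v) > 0 for v in arrays):
            lev_p = float(stats.levene(*arrays).pvalue)
            levene_ok = lev_p >= 0.05
            assumption_report["levene_p"] = lev_p
        parametric = normal_ok and levene_ok if mode == "auto" else True
    else:
        parametric = False

    if parametric and any(v.size < 2 for v in arrays):
        if mode == "parametric":
            raise ValueError("parametric mode needs >= 2 samples per group")
        parametric = False

    if parametric:
        if all(np.ptp(v) == 0 for v in arrays) and len({v[0] for v in arrays}) == 1:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.f_oneway(*arrays)
        values = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(v) for g, v in data.items()])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pair_idx = list(combinations(range(len(tk.groupsunique)), 2))
        pairwise = [
            {
                "group_a": str(tk.groupsunique[i]), "group_b": str(tk.groupsunique[j]),
                "mean_diff": float(d), "p_adj": float(pv),
                "significant": bool(rej),
            }
            for (i, j), d, pv, rej in zip(
                pair_idx, tk.meandiffs, tk.pvalues, tk.reject
            )
        ]
        return {
            "method": "anova_tukey",
            "statistic": float(stat),
            "df_between": len(groups) - 1,
            "df_within": int(sum(v.size for v in arrays)) - len(groups),
            "p_value": float(p),
            "log10_transformed": log_transform,
            "assumptions": assumption_report,
            "pairwise": pairwise,
        }

    stat, p = stats.kruskal(*arrays)
    return {
        "method": "kruskal_dunn_bh",
        "statistic": float(stat),
        "df_between": len(groups) - 1,
        "p_value": float(p),
        "log10_transformed": log_transform,
        "assumptions": assumption_report,
        "pairwise": _dunn_bh(data),
    }


def accuracy_vs_expected(
    groups: Mapping[str, Sequence[float]],
    compositions: Mapping[str, SampleComposition],
    model: ExpectedRatioModel | None = None,
    bh_adjust: bool = False,
) -> dict:
    """Per-group one-sample Wilcoxon signed-rank test of observed vs. expected.

    For each sex-ratio group, the observed common-to-male ratios are tested
    against the group's expected ratio under ``model``.  Groups with fewer
    than 3 samples are skipped with a warning.  The exact null distribution
    is used for n <= 25 (when free of zeros and ties), the normal
    approximation with continuity correction above.  BH adjustment across
    groups is optional and off by default.
    """
    model = model or ExpectedRatioModel()
    per_group: dict[str, dict] = {}
    pvals: list[tuple[str, float]] = []
    for label, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size < 3:
            log.warning("group %s: only %d samples; Wilcoxon skipped", label, x.size)
            per_group[label] = {"skipped": True, "n": int(x.size)}
            continue
        exp = expected_ratio(compositions[label], model)
        d = x - exp
        if np.all(d == 0):
            per_group[label] = {
                "skipped": False, "n": int(x.size), "expected": exp,
                "statistic": float(x.size * (x.size + 1) / 4), "p_value": 1.0,
            }
            pvals.append((label, 1.0))
            continue
        method = "exact" if x.size <= 25 and not np.any(d == 0) else "approx"
        res = stats.wilcoxon(d, method=method, correction=(method == "approx"))
        per_group[label] = {
            "skipped": False, "n": int(x.size), "expected": exp,
            "statistic": float(res.statistic), "p_value": float(res.pvalue),
            "method": method,
        }
        pvals.append((label, float(res.pvalue)))

    if bh_adjust and pvals:
        adj = multipletests([p for _, p in pvals], method="fdr_bh")[1]
        for (label, _), p_adj in zip(pvals, adj):
            per_group[label]["p_adj"] = float(p_adj)

    any_sig = any(
        g.get("p_value", 1.0) < 0.05 for g in per_group.values() if not g.get("skipped")
    )
    return {"groups": per_group, "any_significant": any_sig, "rho": model.rho}
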