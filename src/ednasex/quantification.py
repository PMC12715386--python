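"""Poisson quantification of ddPCR droplet counts.

A droplet digital PCR reaction is partitioned into ~10^4-10^5 nanolitre
droplets; copies distribute across droplets approximately Poisson, so the
mean copy number per droplet is recovered from the fraction of positive
droplets as ``lambda = -ln(1 - k/n)``.  Concentrations are expressed on two
scales: copies/uL in the PCR reaction (``lambda / V_d``) and copies/uL in
the starting material, obtained by multiplying with the total reaction
volume and dividing by the template volume loaded.

Replicate wells of the same sample may be merged by pooling droplet counts
into one "meta-well" before the Poisson correction; this is what enables
rare-allele detection at concentrations no single well could resolve.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: QX200 droplet volume in microlitres (0.85 nL).  Instrument-specific and
#: configurable on every WellCount.
DEFAULT_DROPLET_VOLUME_UL = 8.5e-4
DEFAULT_MIX_VOLUME_UL = 22.0

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SaturationError(ValueError):
    """All droplets positive: lambda is unbounded."""


class UndefinedRatioError(ZeroDivisionError):
    """Both allele concentrations are zero; the ratio carries no information."""


@dataclass(frozen=True)
class DropletRead:
    """A single droplet's fluorescence amplitude on one channel."""

    well_id: str
    channel: str  # "FAM" or "HEX"
    amplitude: float

    def __post_init__(self) -> None:
        if self.channel not in ("FAM", "HEX"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-channel fluorescence thresholds separating positive droplets.

    Defaults are conservative thresholds chosen so that low-amplitude
    cross-reactive signal on the male-allele (HEX) channel, which stays
    below ~2000 units, is never counted while true positives (3000-4000
    units) always are.  Comparison is inclusive: amplitude >= threshold
    is positive.
    """

    hex_min: float = 2400.0
    fam_min: float = 3000.0

    def __post_init__(self) -> None:
        if self.hex_min <= 0 or self.fam_min <= 0:
            raise ValueError("thresholds must be positive")

    def threshold_for(self, channel: str) -> float:
        return self.hex_min if channel == "HEX" else self.fam_min


#: Default duplex channel -> target-allele mapping.  The common-allele probe
#: reads on FAM and the male-specific probe on HEX; assays wired differently
#: can pass their own mapping.
DEFAULT_CHANNEL_MAP: Mapping[str, str] = {"FAM": "common", "HEX": "male"}


@dataclass(frozen=True)
class WellCount:
    """Droplet counts for one well and one target allele.

    The atom of quantification: ``positives`` of ``accepted`` droplets
    crossed the fluorescence threshold for this target.  Volumes travel
    with the count so concentration scales are always recoverable.
    """

    well_id: str
    sample_id: str
    target: str  # "common", "male" or "other"
    positives: int
    accepted: int
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    template_volume_ul: float = 4.0
    mix_volume_ul: float = DEFAULT_MIX_VOLUME_UL
    dilution_factor: float = 1.0
    extra: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.accepted <= 0:
            raise ValueError(f"well {self.well_id}: accepted droplets must be > 0")
        if not 0 <= self.positives <= self.accepted:
            raise ValueError(
                f"well {self.well_id}: need 0 <= positives <= accepted, "
                f"got {self.positives}/{self.accepted}"
            )
        if self.droplet_volume_ul <= 0 or self.template_volume_ul <= 0 or self.mix_volume_ul <= 0:
            raise ValueError(f"well {self.well_id}: volumes must be positive")
        if self.dilution_factor <= 0:
            raise ValueError(f"well {self.well_id}: dilution_factor must be positive")

    @property
    def saturated(self) -> bool:
        return self.positives == self.accepted

    @property
    def start_scale(self) -> float:
        """Reaction-to-starting-material conversion factor V_mix / V_t."""
        return self.mix_volume_ul / self.template_volume_ul


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Poisson-corrected concentration with a 95% CI on the starting-material scale."""

    sample_id: str
    target: str
    lam: float  # mean copies per droplet
    conc_reaction: float  # copies/uL in the PCR reaction
    conc_start: float  # copies/uL in the starting material
    ci_low: float
    ci_high: float
    wells_merged: int
    k_total: int
    n_total: int
    droplet_volume_ul: float
    template_volume_ul: float
    mix_volume_ul: float
    dilution_factor: float
    saturated_flag: bool = False

    @property
    def se_lambda(self) -> float:
        """Delta-method standard error of lambda-hat from pooled counts."""
        if self.saturated_flag or self.n_total == 0:
            return math.inf
        p = self.k_total / self.n_total
        if p >= 1.0:
            return math.inf
        return math.sqrt(p / (self.n_total * (1.0 - p)))


@dataclass(frozen=True)
class RatioEstimate:
    """Common-to-male allele ratio (and its inverse) for one sample."""

    sample_id: str
    common_to_male: float  # math.inf when the male allele is absent
    male_to_common: float
    ci_low: float = math.nan  # 95% CI on common_to_male
    ci_high: float = math.nan
    rsd_pct: float = math.nan  # across replicate wells, when computed per-well
    mass_corrected: bool = False

    def __post_init__(self) -> None:
        if self.common_to_male < 0 or self.male_to_common < 0:
            raise ValueError("ratios must be nonnegative")


def poisson_lambda(k: int, n: int) -> float:
    """Mean copies per droplet implied by ``k`` positive of ``n`` droplets.

    Raises :class:`SaturationError` when every droplet is positive.
    """
    if n <= 0:
        raise ValueError("need at least one accepted droplet")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == n:
        raise SaturationError(f"all {n} droplets positive; lambda unbounded")
    return -math.log1p(-k / n)


def _rule_of_three_upper(n: int) -> float:
    # 95% upper bound on lambda when zero positives are observed.
    return -math.log1p(-3.0 / n)


def concentration(wc: WellCount) -> ConcentrationEstimate:
    """Poisson-corrected concentration of a single well (or pooled meta-well).

    The 95% CI uses the delta-method SE of lambda-hat,
    ``sqrt(p / (n (1 - p)))`` with ``p = k/n``, a normal interval clamped at
    zero.  For k = 0 the point estimate is 0 and the upper bound is the
    rule-of-three bound ``-ln(1 - 3/n)`` mapped to concentration.  Saturated
    wells (k = n) yield a flagged estimate with an infinite point value.
    """
    scale = wc.start_scale / wc.droplet_volume_ul  # lambda -> conc_start

    if wc.saturated:
        return ConcentrationEstimate(
            sample_id=wc.sample_id, target=wc.target,
            lam=math.inf, conc_reaction=math.inf, conc_start=math.inf,
            ci_low=math.inf, ci_high=math.inf,
            wells_merged=1, k_total=wc.positives, n_total=wc.accepted,
            droplet_volume_ul=wc.droplet_volume_ul,
            template_volume_ul=wc.template_volume_ul,
            mix_volume_ul=wc.mix_volume_ul,
            dilution_factor=wc.dilution_factor,
            saturated_flag=True,
        )

    lam = poisson_lambda(wc.positives, wc.accepted)
    if wc.positives == 0:
        ci_low, ci_high = 0.0, _rule_of_three_upper(wc.accepted) * scale
    else:
        p = wc.positives / wc.accepted
        se = math.sqrt(p / (wc.accepted * (1.0 - p)))
        ci_low = max(0.0, (lam - Z95 * se) * scale)
        ci_high = (lam + Z95 * se) * scale

    return ConcentrationEstimate(
        sample_id=wc.sample_id, target=wc.target,
        lam=lam, conc_reaction=lam / wc.droplet_volume_ul,
        conc_start=lam * scale,
        ci_low=ci_low, ci_high=ci_high,
        wells_merged=1, k_total=wc.positives, n_total=wc.accepted,
        droplet_volume_ul=wc.droplet_volume_ul,
        template_volume_ul=wc.template_volume_ul,
        mix_volume_ul=wc.mix_volume_ul,
        dilution_factor=wc.dilution_factor,
        saturated_flag=False,
    )


def merge_wells(wells: Sequence[WellCount]) -> ConcentrationEstimate:
    """Pool replicate wells into one meta-well and quantify the pooled counts.

    Pooling the droplet counts (not averaging per-well concentrations) applies
    the Poisson correction to the total droplet population, which is what
    permits quantification below single-well limits.  All wells must share
    sample, target, volumes and dilution.  Saturated wells are excluded with
    a warning; if every well is saturated the pooled estimate is flagged.
    """
    if not wells:
        raise ValueError("no wells to merge")

    ref = wells[0]
    for w in wells[1:]:
        same = (
            w.sample_id == ref.sample_id and w.target == ref.target
            and w.droplet_volume_ul == ref.droplet_volume_ul
            and w.template_volume_ul == ref.template_volume_ul
            and w.mix_volume_ul == ref.mix_volume_ul
            and w.dilution_factor == ref.dilution_factor
        )
        if not same:
            raise ValueError(
                f"cannot merge wells with inconsistent sample/target/volumes/"
                f"dilution: {ref.well_id} vs {w.well_id}"
            )

    usable = [w for w in wells if not w.saturated]
    n_sat = len(wells) - len(usable)
    if n_sat:
        log.warning(
            "sample %s target %s: excluding %d saturated well(s) from merge",
            ref.sample_id, ref.target, n_sat,
        )
    if not usable:
        pooled = replace(ref, positives=ref.accepted)  # fully saturated meta-well
        est = concentration(pooled)
        return replace(est, wells_merged=len(wells))

    k_total = sum(w.positives for w in usable)
    n_total = sum(w.accepted for w in usable)
    pooled = replace(
        usable[0],
        well_id=f"{ref.sample_id}:{ref.target}:merged",
        positives=k_total,
        accepted=n_total,
    )
    est = concentration(pooled)
    return replace(est, wells_merged=len(usable))


def allele_ratio(
    common: ConcentrationEstimate,
    male: ConcentrationEstimate,
    rsd_pct: float = math.nan,
) -> RatioEstimate:
    """Common-to-male allele ratio from two concentration estimates.

    The 95% CI comes from the delta method on log(ratio), treating the two
    Poisson estimates as independent:
    ``Var(log r) = Var(lam_c)/lam_c^2 + Var(lam_m)/lam_m^2``.
    A male concentration of zero gives the infinity sentinel (all-female
    sample); both zero is an error because the ratio carries no information.
    """
    if common.sample_id != male.sample_id:
        raise ValueError("ratio requires estimates from the same sample")
    if common.dilution_factor != male.dilution_factor:
        raise ValueError("ratio requires estimates at the same dilution")

    c, m = common.conc_start, male.conc_start
    if c == 0 and m == 0:
        raise UndefinedRatioError(f"sample {common.sample_id}: both alleles at zero")
    if m == 0:
        return RatioEstimate(
            sample_id=common.sample_id,
            common_to_male=math.inf, male_to_common=0.0,
            ci_low=math.nan, ci_high=math.nan, rsd_pct=rsd_pct,
        )
    if c == 0:
        return RatioEstimate(
            sample_id=common.sample_id,
            common_to_male=0.0, male_to_common=math.inf,
            ci_low=math.nan, ci_high=math.nan, rsd_pct=rsd_pct,
        )

    r = c / m
    se_log = math.sqrt(
        (common.se_lambda / common.lam) ** 2 + (male.se_lambda / male.lam) ** 2
    )
    return RatioEstimate(
        sample_id=common.sample_id,
        common_to_male=r,
        male_to_common=1.0 / r,
        ci_low=r * math.exp(-Z95 * se_log),
        ci_high=r * math.exp(Z95 * se_log),
        rsd_pct=rsd_pct,
    )


def rsd(values: Iterable[float]) -> float:
    """Relative standard deviation, 100 * sample SD / mean, in percent."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("rsd needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("rsd undefined for zero mean")
    return 100.0 * x.std(ddof=1) / mean


def classify_droplets(
    reads: Sequence[DropletRead],
    cfg: ThresholdConfig | None = None,
    channel_map: Mapping[str, str] = DEFAULT_CHANNEL_MAP,
    sample_ids: Mapping[str, str] | None = None,
    template_volume_ul: float = 4.0,
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    mix_volume_ul: float = DEFAULT_MIX_VOLUME_UL,
    dilution_factor: float = 1.0,
) -> list[WellCount]:
    """Threshold per-droplet amplitudes into per-well, per-channel counts.

    A droplet is positive when its amplitude meets or exceeds the channel
    threshold (inclusive).  ``sample_ids`` maps well_id -> sample_id; wells
    absent from the mapping keep their well_id as sample_id.
    """
    if not reads:
        raise ValueError("no droplets: empty read list")
    cfg = cfg or ThresholdConfig()

    by_key: dict[tuple[str, str], list[float]] = {}
    for r in reads:
        by_key.setdefault((r.well_id, r.channel), []).append(r.amplitude)

    out: list[WellCount] = []
    for (well_id, channel), amps in sorted(by_key.items()):
        thr = cfg.threshold_for(channel)
        k = sum(1 for a in amps if a >= thr)
        out.append(WellCount(
            well_id=well_id,
            sample_id=(sample_ids or {}).get(well_id, well_id),
            target=channel_map.get(channel, "other"),
            positives=k,
            accepted=len(amps),
            droplet_volume_ul=droplet_volume_ul,
            template_volume_ul=template_volume_ul,
            mix_volume_ul=mix_volume_ul,
            dilution_factor=dilution_factor,
        ))
    return out


def per_well_ratios(
    common_wells: Sequence[WellCount], male_wells: Sequence[WellCount]
) -> list[float]:
    """Common-to-male ratios computed well by well (paired by order).

    Used only to express replicate dispersion (RSD); quantitative ratios
    should come from pooled counts via :func:`merge_wells` +
    :func:`allele_ratio`.  Wells where the male count is zero are skipped
    (their single-well ratio is unbounded).
    """
    if len(common_wells) != len(male_wells):
        raise ValueError("need one common well per male well")
    out = []
    for cw, mw in zip(common_wells, male_wells):
        if mw.positives == 0 or cw.saturated or mw.saturated:
            continue
        out.append(concentration(cw).conc_start / concentration(mw).conc_start)
    return out
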