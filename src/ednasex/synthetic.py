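"""Synthetic individuals, samples, dilution series and droplet plates.

Emulates the statistical structure the analysis assumes so the whole
pipeline runs with no laboratory data:

* individuals of known sex and mass, each male with his own
  common-to-male copy ratio ``rho_i`` drawn lognormal (mean 7, RSD 38%,
  clipped to the observed 3-14 range) — ratios are positive and
  right-skewed, and this inter-individual spread is the dominant noise
  source for single-male samples;
* mock samples (equal DNA input per individual) and eDNA tank samples
  (contribution proportional to body mass^b with lognormal shedding
  noise);
* droplet partitioning: positives per well are Binomial(n, 1 - e^-lambda)
  with the accepted-droplet count per well drawn uniformly in a typical
  instrument yield range, plus rare cross-reactive false positives on the
  male channel that scale with the amount of non-target DNA;
* optional per-droplet amplitudes: true male-channel positives near 3500
  fluorescence units, cross-reactive droplets below 2000, so the default
  2400 threshold separates them.

All randomness flows through one ``numpy.random.Generator``; identical
seed and configuration give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .limits import DilutionLevel, DilutionSeries
from .quantification import (
    DEFAULT_DROPLET_VOLUME_UL,
    DEFAULT_MIX_VOLUME_UL,
    DropletRead,
    WellCount,
)
from .sexratio import parse_group_label


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # "M" or "F"
    mass_g: float
    rho_i: float  # common-to-male copy ratio; females carry no male allele

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.mass_g <= 0:
            raise ValueError("mass must be positive")
        if self.sex == "M" and not self.rho_i > 0:
            raise ValueError("males need a positive rho_i")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the validated assay: per-male copy ratio averaging 7
    with 38% relative spread over a 3-14 range; females slightly heavier
    than males; triplicate wells for mock samples (2 uL template) and six
    replicates for eDNA samples (4 uL template); cross-reactive false
    positives at a level of a few droplets per six high-DNA wells.
    """

    rho_mean: float = 7.0
    rho_rsd_pct: float = 38.0
    rho_clip: tuple[float, float] | None = (3.0, 14.0)
    mass_mean_g: dict = field(default_factory=lambda: {"M": 6.0, "F": 7.0})
    mass_cv: float = 0.15
    droplets_range: tuple[int, int] = (14000, 20000)
    false_pos_rate_per_droplet: float = 4e-5
    false_pos_ref_conc: float = 770.0  # common-allele conc where the rate applies fully
    n_wells_mock: int = 3
    n_wells_edna: int = 6
    template_volume_mock_ul: float = 2.0
    template_volume_edna_ul: float = 4.0
    mock_common_per_individual: float = 50.0  # copies/uL contributed per individual
    shed_rate_per_g: float = 0.5  # copies/uL per gram (eDNA)
    shed_cv: float = 0.5  # lognormal noise on per-individual shedding
    allometry_b: float = 1.0  # contribution ~ mass^b
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    mix_volume_ul: float = DEFAULT_MIX_VOLUME_UL


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def simulate_individuals(
    n_m: int,
    n_f: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    prefix: str = "",
) -> list[Individual]:
    """Draw males and females with per-individual copy ratios and masses."""
    if n_m + n_f < 1:
        raise ValueError("need at least one individual")
    mu, sigma = _lognormal_params(cfg.rho_mean, cfg.rho_rsd_pct / 100.0)
    out: list[Individual] = []
    for i in range(n_m):
        rho = float(rng.lognormal(mu, sigma))
        if cfg.rho_clip is not None:
            rho = float(np.clip(rho, *cfg.rho_clip))
        mass = _draw_mass("M", cfg, rng)
        out.append(Individual(id=f"{prefix}M{i + 1}", sex="M", mass_g=mass, rho_i=rho))
    for i in range(n_f):
        mass = _draw_mass("F", cfg, rng)
        out.append(Individual(id=f"{prefix}F{i + 1}", sex="F", mass_g=mass, rho_i=math.inf))
    return out


def _draw_mass(sex: str, cfg: SimulationConfig, rng: np.random.Generator) -> float:
    mu, sigma = _lognormal_params(cfg.mass_mean_g[sex], cfg.mass_cv)
    return float(rng.lognormal(mu, sigma))


def simulate_sample(
    inds: Sequence[Individual],
    mode: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    noise: bool = True,
) -> tuple[float, float]:
    """True (common, male) allele concentrations of a pooled sample, copies/uL.

    Mock mode: every individual contributes an equal common-allele
    concentration; eDNA mode: contribution proportional to mass^b with
    lognormal shedding noise.  Each male's male-allele contribution is his
    common contribution divided by his rho_i.
    """
    if not inds:
        raise ValueError("sample needs at least one individual")
    if mode not in ("mock", "edna"):
        raise ValueError("mode must be 'mock' or 'edna'")

    common = male = 0.0
    for ind in inds:
        if mode == "mock":
            c = cfg.mock_common_per_individual
        else:
            c = cfg.shed_rate_per_g * ind.mass_g ** cfg.allometry_b
            if noise and cfg.shed_cv > 0:
                mu, sigma = _lognormal_params(1.0, cfg.shed_cv)
                c *= float(rng.lognormal(mu, sigma))
        common += c
        if ind.sex == "M":
            male += c / ind.rho_i
    return common, male


def simulate_droplets(
    true_conc: tuple[float, float],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    n_wells: int = 6,
    template_volume_ul: float = 4.0,
    dilution_factor: float = 1.0,
    well_prefix: str = "",
) -> list[WellCount]:
    """Partition a sample's true concentrations into replicate wells.

    ``true_conc`` is (common, male) on the starting-material scale of the
    loaded material (already divided by ``dilution_factor`` upstream when a
    dilution series is simulated; the factor here is metadata only).
    """
    common_conc, male_conc = true_conc
    if common_conc < 0 or male_conc < 0:
        raise ValueError("concentrations must be nonnegative")

    wells: list[WellCount] = []
    reaction_scale = template_volume_ul / cfg.mix_volume_ul
    lam_common = common_conc * reaction_scale * cfg.droplet_volume_ul
    lam_male = male_conc * reaction_scale * cfg.droplet_volume_ul
    # cross-reactivity scales with how much non-target (common) DNA is present
    fp_scale = min(1.0, common_conc / cfg.false_pos_ref_conc) if cfg.false_pos_ref_conc > 0 else 1.0
    fp_prob = cfg.false_pos_rate_per_droplet * fp_scale

    for w in range(n_wells):
        n = int(rng.integers(cfg.droplets_range[0], cfg.droplets_range[1] + 1))
        k_common = int(rng.binomial(n, 1.0 - math.exp(-lam_common)))
        k_male = int(rng.binomial(n, 1.0 - math.exp(-lam_male)))
        if fp_prob > 0:
            k_male = min(n, k_male + int(rng.binomial(n, fp_prob)))
        common_kw = dict(
            well_id=f"{well_prefix}{sample_id}-w{w + 1}",
            sample_id=sample_id,
            droplet_volume_ul=cfg.droplet_volume_ul,
            template_volume_ul=template_volume_ul,
            mix_volume_ul=cfg.mix_volume_ul,
            dilution_factor=dilution_factor,
        )
        wells.append(WellCount(target="common", positives=k_common, accepted=n, **common_kw))
        wells.append(WellCount(target="male", positives=k_male, accepted=n, **common_kw))
    return wells


def simulate_amplitudes(
    well: WellCount,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    cross_reactive: int = 0,
) -> list[DropletRead]:
    """Per-droplet fluorescence amplitudes consistent with a WellCount.

    True positives sit around 3500 units, negatives around 1000, and
    (male channel only) cross-reactive droplets around 1800, capped below
    2000 — below the 2400 threshold, so thresholding never counts them.
    """
    channel = "HEX" if well.target == "male" else "FAM"
    n_neg = well.accepted - well.positives - cross_reactive
    if n_neg < 0:
        raise ValueError("cross_reactive exceeds negative droplet count")
    amps = np.concatenate([
        rng.normal(3500.0, 200.0, size=well.positives),
        np.minimum(rng.normal(1800.0, 150.0, size=cross_reactive), 1999.0),
        rng.normal(1000.0, 150.0, size=n_neg),
    ])
    amps = np.clip(amps, 0.0, None)
    return [DropletRead(well_id=well.well_id, channel=channel, amplitude=float(a))
            for a in amps]


def simulate_dilution_series(
    extract_conc: tuple[float, float],
    factors: Sequence[float],
    replicates: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "series",
    template_volume_ul: float = 4.0,
) -> DilutionSeries:
    """A k-fold dilution series: each level's truth is extract / factor."""
    if any(f < 1 for f in factors):
        raise ValueError("dilution factors must be >= 1")
    if any(b <= a for a, b in zip(factors, list(factors)[1:])):
        raise ValueError("dilution factors must be strictly increasing")

    common0, male0 = extract_conc
    levels = []
    for f in factors:
        wells = simulate_droplets(
            (common0 / f, male0 / f), cfg, rng,
            sample_id=f"{sample_id}-d{f:g}",
            n_wells=replicates,
            template_volume_ul=template_volume_ul,
            dilution_factor=f,
        )
        levels.append(DilutionLevel(
            dilution_factor=float(f),
            common_wells=tuple(w for w in wells if w.target == "common"),
            male_wells=tuple(w for w in wells if w.target == "male"),
        ))
    return DilutionSeries(levels=tuple(levels))


#: Mock-design group labels: seven sex-ratio treatments from all-female-biassed
#: to male-biassed.
DEFAULT_GROUPS = ("1M", "1M:3F", "1M:2F", "1M:1F", "2M:2F", "2M:1F", "3M:1F")
#: Groups in which the shared male / shared female individual is reused.
SHARED_MALE_GROUPS = ("1M:1F", "2M:2F", "1M:2F", "1M:3F")
SHARED_FEMALE_GROUPS = ("1M:1F", "2M:2F", "2M:1F", "3M:1F")


def simulate_experiment(
    design: Sequence[tuple[str, int, int]] | None = None,
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "mock",
    shared_individuals: bool = True,
    shared_male_rho: float | None = None,
    include_controls: bool = True,
    contamination_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full multi-group experiment and emit pipeline-ready tables.

    ``design`` lists (group label, number of series, technical replicates);
    the default is the seven-group design, three series each, in triplicate
    (mock) or six replicates (eDNA).  One male and one female individual can
    be shared across the designated groups within every series, which makes
    single-male groups inherit that male's idiosyncratic copy ratio —
    ``shared_male_rho`` pins it (e.g., to a low value) instead of drawing it.

    Returns (wells, metadata, truth) DataFrames matching the droplet-count
    CSV, sample-metadata CSV and truth-table schemas.
    """
    cfg = cfg or SimulationConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    if design is None:
        reps = cfg.n_wells_mock if mode == "mock" else cfg.n_wells_edna
        design = [(g, 3, reps) for g in DEFAULT_GROUPS]
    template_ul = (
        cfg.template_volume_mock_ul if mode == "mock" else cfg.template_volume_edna_ul
    )

    shared_male = shared_female = None
    if shared_individuals:
        shared_male = simulate_individuals(1, 0, cfg, rng, prefix="shared-")[0]
        if shared_male_rho is not None:
            shared_male = Individual(
                id=shared_male.id, sex="M", mass_g=shared_male.mass_g,
                rho_i=shared_male_rho,
            )
        shared_female = simulate_individuals(0, 1, cfg, rng, prefix="shared-")[0]

    well_rows: list[WellCount] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []

    for label, n_series, n_reps in design:
        n_m, n_f = parse_group_label(label)
        for s in range(n_series):
            series = chr(ord("A") + s)
            sample_id = f"{label}-{series}"
            extra_m, extra_f = n_m, n_f
            inds: list[Individual] = []
            if shared_individuals and label in SHARED_MALE_GROUPS and n_m >= 1:
                inds.append(shared_male)
                extra_m -= 1
            if shared_individuals and label in SHARED_FEMALE_GROUPS and n_f >= 1:
                inds.append(shared_female)
                extra_f -= 1
            if extra_m + extra_f > 0:
                inds += simulate_individuals(
                    extra_m, extra_f, cfg, rng, prefix=f"{sample_id}-"
                )
            common, male = simulate_sample(inds, mode, cfg, rng)
            well_rows += simulate_droplets(
                (common, male), cfg, rng, sample_id=sample_id,
                n_wells=n_reps, template_volume_ul=template_ul,
            )
            male_mass = sum(i.mass_g for i in inds if i.sex == "M")
            total_mass = sum(i.mass_g for i in inds)
            meta_rows.append({
                "sample_id": sample_id, "group": label,
                "n_males": n_m, "n_females": n_f,
                "male_mass_g": male_mass, "total_mass_g": total_mass,
                "series": series, "sample_type": mode,
            })
            truth_rows.append({
                "sample_id": sample_id, "group": label, "series": series,
                "true_common_conc": common, "true_male_conc": male,
                "true_p_male": n_m / (n_m + n_f),
                "male_rho_values": ";".join(
                    f"{i.rho_i:.4f}" for i in inds if i.sex == "M"
                ),
            })

    if include_controls:
        for s in range(max((n for _, n, _ in design), default=0)):
            series = chr(ord("A") + s)
            reps = design[0][2] if design else 3
            # all-female control tank/mixture
            fem = simulate_individuals(0, 2, cfg, rng, prefix=f"ctrl-{series}-")
            common, male = simulate_sample(fem, mode, cfg, rng)
            sample_id = f"0M:2F-{series}"
            well_rows += simulate_droplets(
                (common, male), cfg, rng, sample_id=sample_id,
                n_wells=reps, template_volume_ul=template_ul,
            )
            meta_rows.append({
                "sample_id": sample_id, "group": "0M:2F",
                "n_males": 0, "n_females": 2,
                "male_mass_g": 0.0,
                "total_mass_g": sum(i.mass_g for i in fem),
                "series": series, "sample_type": mode,
            })
            truth_rows.append({
                "sample_id": sample_id, "group": "0M:2F", "series": series,
                "true_common_conc": common, "true_male_conc": male,
                "true_p_male": 0.0, "male_rho_values": "",
            })
            # no-template control
            ntc_id = f"NTC-{series}"
            ntc_conc = (0.0, 0.0)
            ntc_cfg = cfg
            if contamination_rate > 0:
                ntc_conc = (
                    float(rng.exponential(contamination_rate)),
                    float(rng.exponential(contamination_rate)),
                )
            well_rows += simulate_droplets(
                ntc_conc, ntc_cfg, rng, sample_id=ntc_id,
                n_wells=1, template_volume_ul=template_ul,
            )
            meta_rows.append({
                "sample_id": ntc_id, "group": "NTC",
                "n_males": 0, "n_females": 0,
                "male_mass_g": 0.0, "total_mass_g": 0.0,
                "series": series, "sample_type": "ntc",
            })

    wells_df = pd.DataFrame([
        {
            "plate": "sim-1", "well": w.well_id, "sample_id": w.sample_id,
            "target": w.target, "positives": w.positives, "accepted": w.accepted,
            "template_volume_ul": w.template_volume_ul,
            "dilution_factor": w.dilution_factor,
        }
        for w in well_rows
    ])
    return wells_df, pd.DataFrame(meta_rows), pd.DataFrame(truth_rows)
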