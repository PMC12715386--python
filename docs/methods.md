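# Methods

## Quantification model

Droplet digital PCR partitions a reaction of volume V_mix (default 22 µL,
of which V_t = 2 or 4 µL is template) into droplets of volume V_d (default
0.85 nL, the QX200 standard; configurable, since instruments differ).
Copies land in droplets approximately independently, so the count of
positive droplets k among n accepted is Binomial(n, 1 − e^(−λ)) and the
maximum-likelihood occupancy is λ̂ = −ln(1 − k/n). Concentrations are
reported on two scales: copies/µL of reaction (λ̂/V_d) and copies/µL of
starting material (× V_mix/V_t). Dilution factors are carried as metadata
and never folded into concentrations, matching how dilution-series tables
are reported.

**Confidence intervals.** The delta-method standard error of λ̂ is
SE = sqrt(p̂/(n(1−p̂))) with p̂ = k/n; the 95% interval is normal on the λ
scale, clamped at zero. For k = 0 the point estimate is zero and the upper
bound is the rule-of-three bound −ln(1 − 3/n). This reproduces published
single-well ddPCR statistics closely and is fully specified, which the
vendor software's internal formula is not. Simulated coverage is 93–97% at
occupancies from 0.001 to 1 (the package's calibration test measures it).

**Merging.** Replicate wells of one sample are merged by pooling raw
counts (Σk, Σn) into a meta-well and applying the Poisson correction to
the pool — *not* by averaging per-well concentrations. Pooling is exactly
invariant to how droplets are partitioned into wells and is what lowers
attainable detection limits as replicates are added. Wells with every
droplet positive (saturated) carry no finite information and are excluded
from merges with a logged warning; a fully saturated merge yields a
flagged infinite estimate.

**Ratios.** The common-to-male ratio of a sample uses the merged
concentrations of both targets; its CI comes from the delta method on
log(ratio) with independent numerator and denominator errors. Per-well
ratios are computed only to express replicate dispersion (RSD%,
100·SD/mean with the n−1 denominator). A male concentration of zero maps
to an infinity sentinel (male-to-common 0); both targets at zero is an
error rather than a silent NaN.

**Thresholding.** When per-droplet amplitudes are supplied, a droplet is
positive when its amplitude meets or exceeds the channel threshold
(inclusive reading of "minimum"). Defaults — 2400 on the male/HEX channel,
3000 on the common/FAM channel — sit above the ~2000-unit ceiling of
cross-reactive signal from non-target DNA while true positives cluster at
3000–4000 units. The channel→target mapping is configuration, not
hard-coded.

## Limits of detection and quantification

The LoD walks a dilution series from most dilute to least dilute and
reports the most dilute level whose per-replicate starting-material
concentrations differ significantly (default α = 0.05) from the negative
(female) series: a one-sample t-test against zero when every negative is
zero, a Welch two-sample test otherwise. Zero-concentration replicates
stay in the test sample; dropping them would bias the mean and the degrees
of freedom. Shapiro–Wilk non-normality is a warning, not a gate, as is a
non-monotone significance pattern across levels. The reported LoD
concentration is the merged-well estimate at the qualifying level.

The LoQ fixes a maximum acceptable ratio RSD (default 30%, chosen because
eDNA samples sit near subsampling-noise limits) and is assessed two ways:
per-well (the last level, walking downward in concentration, before
per-replicate ratio RSD first exceeds the bound) and merged (if the RSD of
pooled-count ratios across levels stays under the bound, pooled replicates
quantify reliably down to the most dilute level, which then defines the
LoQ). Samples whose merged male concentration falls below the LoD are
excluded from downstream estimation, each exclusion logged once with its
reason.

## Sex-ratio model

Equal contribution gives E[common/male] = ρ(M+F)/M and the inverse
estimator p̂ = ρ·r for observed male-to-common ratio r. ρ defaults to 7
(the package exposes it for per-population calibration via the
`validate_assay` summary of per-male ratios). p̂ is stored raw and clamped
to [0,1]; regressions see the raw value so censoring cannot bias slopes.
When the per-individual ratios of a sample's males are known, the
hypothesised ratio (M+F)/Σ(1/ρᵢ) is available instead
(`expected_ratio_from_individuals`); with all ρᵢ equal the two coincide.
Because 1/ρᵢ is convex in ρᵢ, inter-individual spread inflates p̂ slightly
on average (Jensen), which is visible in, and bounded by, the parameter-
recovery test.

Mass correction multiplies male-to-common ratios by the male-to-total mass
fraction (equivalently common-to-male by its inverse). This is a
standardisation that puts samples of different biomass composition on a
common scale before group comparison and regression — with all-equal
masses it is the identity — not a sharpened point estimate of the
head-count proportion. Whether eDNA contributions are better modelled
per-capita or per-mass is genuinely open; both contribution modes are
implemented and the simulator's mass-proportional mode (exponent b,
default 1, configurable for allometric shedding) lets either be stress-
tested.

**Statistics.** Group comparisons log₁₀-transform common-to-male ratios,
then run one-way ANOVA with Tukey HSD when Shapiro–Wilk residual normality
and Levene homoscedasticity hold, else Kruskal–Wallis with Dunn's rank
post hoc (Benjamini–Hochberg adjusted). Dunn's z statistics are computed
directly from rank sums with the tie correction Σ(t³−t)/(12(N−1)).
Accuracy against hypothesised ratios uses per-group one-sample Wilcoxon
signed-rank tests (exact null for n ≤ 25 without zeros/ties, normal
approximation with continuity correction otherwise; groups under 3 samples
are skipped with a warning; BH across groups is available but off by
default). Calibration regressions are OLS: log₁₀(male-to-common + 1) on
log₁₀(male proportion + 1), and log₁₀(observed) on log₁₀(expected)
common-to-male ratios with a t-test of slope = 1. All-female groups never
enter ratio statistics: their expected ratio is unbounded and any finite
observed ratio there is cross-reactivity, which the pipeline treats as a
specificity observation instead.

## Synthetic data

The generator emulates the assay's validated statistical structure:

- Per-male copy ratios ρᵢ ~ lognormal with mean 7 and RSD 38%, clipped to
  the observed 3–14 range (ratios are positive and right-skewed; clipping
  is configurable off). This inter-individual variation is the dominant
  noise source for single-male samples, and its averaging-out as males are
  added is a tested property.
- Masses lognormal, females 7 g and males 6 g on average (females run
  larger in the target system), CV 15%.
- Mock samples: equal common-allele input per individual, 50 copies/µL by
  default (a realistic post-mixing, post-dilution extract scale);
  triplicate wells at 2 µL template. eDNA samples: contribution
  ∝ mass^b × lognormal noise (CV 0.5 — a tuning default, chosen once to
  place simulated eDNA calibration fits in a realistic R² band, not a
  measured value); six wells at 4 µL template, shed rate 0.5 copies/µL
  per gram.
- Droplets: accepted counts uniform 14,000–20,000 per well (typical
  instrument yield); positives Binomial(n, 1 − e^(−λ)). Male-channel false
  positives at 4×10⁻⁵ per droplet scaled by the common-allele occupancy
  relative to a 770 copies/µL reference — about four droplets per six
  high-DNA wells, vanishing in dilute samples. Amplitude mode draws true
  positives ~N(3500, 200), cross-reactives ~N(1800, 150) capped below
  2000, negatives ~N(1000, 150), so the default thresholds separate them
  deterministically.
- Experiment designs: seven groups (1M … 3M:1F) × 3 series × replicate
  wells, with an optional shared male and female reused across designated
  groups in every series (`shared_male_rho` pins the shared male's ratio,
  e.g. low, to reproduce the disproportionate influence of one individual
  on single-male groups); all-female samples and NTCs included as
  controls. All randomness flows through one `numpy.random.Generator`;
  identical seed and config give byte-identical CSV output.

What the simulator does *not* model: spatial eDNA transport or
degradation, time dynamics of shedding, inhibition, or between-plate
effects. Passing tests therefore demonstrate the pipeline's statistical
behaviour under the assay's assumed noise structure, not field robustness.

## Problem sizes and numerical choices

The calibration check uses 2,000 simulated wells per occupancy and 2,000
six-well merges; dilution-series behaviour is summarised by medians over
20 simulated series (single-series RSD estimates on 6 replicates have
~30% sampling noise of their own); mock-experiment recovery uses 100
simulated experiments. These sizes make the summaries stable to the third
digit while keeping the whole suite fast.

Ties in Dunn's test use average ranks; the Wilcoxon exact method is
switched off in the presence of zeros or ties. Ratio CIs are undefined
(NaN) when either concentration is zero. Thresholds compare inclusively.
CSV serialisation keeps full precision; display rounding is cosmetic.

## Known limitations

- The estimator assumes the calibrated average ρ applies to the sampled
  males; a population whose ρ distribution drifts from its calibration
  will bias p̂ multiplicatively.
- p̂'s CI propagates only the ratio's Poisson uncertainty, not
  inter-individual ρ variation, so it understates total uncertainty for
  samples with few males.
- Mass correction presumes linear mass-proportional shedding; the
  simulator can generate allometric (b ≠ 1) data, but the estimator
  deliberately has no allometric parameter.
- Single-locus only: no combination of multiple sex-linked markers.
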