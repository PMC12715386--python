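"""Biomass correction of eDNA allele ratios.

In water samples each individual's DNA contribution scales with its body
mass, so sexes of different size skew allele ratios away from head-count
expectations.  Rescaling the observed male-to-common ratio by the male
mass fraction puts samples back on the equal-contribution scale before the
male proportion is estimated.
"""

import math

import numpy as np

from ednasex import (
    ExpectedRatioModel,
    SampleComposition,
    SimulationConfig,
    allele_ratio,
    estimate_male_proportion,
    mass_correct,
    merge_wells,
    simulate_droplets,
    simulate_individuals,
    simulate_sample,
)

cfg = SimulationConfig()  # females average 7 g, males 6 g
rng = np.random.default_rng(12)
model = ExpectedRatioModel()

inds = simulate_individuals(2, 2, cfg, rng)
male_mass = sum(i.mass_g for i in inds if i.sex == "M")
total_mass = sum(i.mass_g for i in inds)
comp = SampleComposition("tank-2M:2F", 2, 2, male_mass, total_mass,
                         "A", "edna")

conc = simulate_sample(inds, "edna", cfg, rng)
wells = simulate_droplets(conc, cfg, rng, comp.sample_id, n_wells=6)
ratio = allele_ratio(
    merge_wells([w for w in wells if w.target == "common"]),
    merge_wells([w for w in wells if w.target == "male"]))

raw = estimate_male_proportion(ratio.male_to_common, model,
                               sample_id=comp.sample_id)
corrected_ratio = mass_correct(ratio, comp)
corrected = estimate_male_proportion(corrected_ratio.male_to_common, model,
                                     sample_id=comp.sample_id,
                                     mass_corrected=True)

print(f"tank: 2 males ({male_mass:.1f} g) + 2 females "
      f"({total_mass - male_mass:.1f} g), true male proportion 0.50")
print(f"observed male-to-common ratio: {ratio.male_to_common:.4f}")
print(f"head-count estimate:       p_male = {raw.p_male:.2f}")
print(f"after biomass rescaling:   p_male = {corrected.p_male:.2f} "
      f"(male mass fraction {male_mass / total_mass:.2f})")
print(f"mass-corrected ratio (common-to-male): "
      f"{corrected_ratio.common_to_male:.1f}")
# The correction multiplies the male-to-common ratio by the male mass
# fraction, putting samples with different biomass compositions on a common
# scale before groups are compared or regressed against composition; it is
# a standardisation of the ratios, not a sharper point estimate of the
# head-count proportion.
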