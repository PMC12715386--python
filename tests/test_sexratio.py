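"""Expected-ratio model, its inversion, mass correction and group statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from ednasex import (
    CalibrationFit,
    ExpectedRatioModel,
    RatioEstimate,
    SampleComposition,
    accuracy_vs_expected,
    calibrate,
    compare_groups,
    estimate_male_proportion,
    expected_ratio,
    expected_ratio_from_individuals,
    mass_correct,
    parse_group_label,
)
from ednasex.sexratio import _dunn_bh


def comp(m, f, sid="s", male_mass=math.nan, total_mass=math.nan, stype="mock"):
    return SampleComposition(sid, m, f, male_mass, total_mass, "A", stype)


class TestExpectedRatio:
    @pytest.mark.parametrize("m,f,expected", [
        (1, 0, 7.0),       # single male: the per-male ratio itself
        (1, 1, 14.0),      # two common units per 1/7 male unit
        (3, 1, 28 / 3),
        (2, 2, 14.0),
    ])
    def test_equal_contribution(self, m, f, expected):
        assert expected_ratio(comp(m, f), ExpectedRatioModel()) == pytest.approx(expected)

    def test_no_males_sentinel(self):
        assert math.isinf(expected_ratio(comp(0, 3), ExpectedRatioModel()))

    def test_mass_proportional_mode(self):
        model = ExpectedRatioModel(contribution="mass")
        c = comp(1, 1, male_mass=10.0, total_mass=30.0)
        assert expected_ratio(c, model) == pytest.approx(21.0)

    def test_decreasing_in_males(self):
        vals = [expected_ratio(comp(m, 2), ExpectedRatioModel()) for m in (1, 2, 3, 4)]
        assert vals == sorted(vals, reverse=True) and len(set(vals)) == 4

    def test_measured_individual_ratios(self):
        # all males at rho collapses to the average-model formula
        assert expected_ratio_from_individuals([7.0, 7.0], 2) == pytest.approx(14.0)
        # a low-ratio male drags the pooled expectation down
        assert expected_ratio_from_individuals([3.0], 1) == pytest.approx(6.0)
        assert math.isinf(expected_ratio_from_individuals([], 3))


class TestEstimateMaleProportion:
    @pytest.mark.parametrize("r_obs,expected", [
        (1 / 7, 1.0),
        (0.0, 0.0),
        (1 / 14, 0.5),
    ])
    def test_inversion(self, r_obs, expected):
        est = estimate_male_proportion(r_obs, ExpectedRatioModel())
        assert est.p_male == pytest.approx(expected)

    def test_round_trip_identity(self):
        """estimate(1 / expected(M, F)) recovers M / (M + F) exactly."""
        model = ExpectedRatioModel()
        for m in range(1, 6):
            for f in range(0, 6):
                r = 1.0 / expected_ratio(comp(m, f), model)
                est = estimate_male_proportion(r, model)
                assert est.p_male_raw == pytest.approx(m / (m + f), rel=1e-12)

    def test_raw_can_exceed_one_clamped_does_not(self):
        est = estimate_male_proportion(0.2, ExpectedRatioModel())
        assert est.p_male_raw == pytest.approx(1.4)
        assert est.p_male == 1.0

    def test_strictly_increasing_in_r_obs(self):
        vals = [estimate_male_proportion(r, ExpectedRatioModel()).p_male_raw
                for r in (0.01, 0.05, 0.1, 0.14)]
        assert vals == sorted(vals) and len(set(vals)) == 4

    def test_ci_propagates_linearly(self):
        est = estimate_male_proportion(0.07, ExpectedRatioModel(),
                                       ci=(0.05, 0.09))
        assert est.ci_low == pytest.approx(0.35)
        assert est.ci_high == pytest.approx(0.63)


class TestMassCorrect:
    def test_male_to_common_scaled_by_mass_fraction(self):
        r = RatioEstimate("s", common_to_male=5.0, male_to_common=0.2,
                          ci_low=4.0, ci_high=6.0)
        out = mass_correct(r, comp(1, 2, male_mass=10.0, total_mass=30.0))
        assert out.male_to_common == pytest.approx(0.2 / 3)
        assert out.common_to_male == pytest.approx(15.0)
        assert out.mass_corrected

    def test_common_to_male_doubles_at_half_male_mass(self):
        r = RatioEstimate("s", common_to_male=14.0, male_to_common=1 / 14)
        out = mass_correct(r, comp(1, 1, male_mass=5.0, total_mass=10.0))
        assert out.common_to_male == pytest.approx(28.0)

    def test_all_male_mass_is_identity(self):
        r = RatioEstimate("s", common_to_male=7.0, male_to_common=1 / 7,
                          ci_low=6.0, ci_high=8.0)
        out = mass_correct(r, comp(2, 0, male_mass=12.0, total_mass=12.0))
        assert out.common_to_male == pytest.approx(7.0)
        assert out.ci_low == pytest.approx(6.0)

    def test_inconsistent_metadata_rejected(self):
        r = RatioEstimate("s", common_to_male=7.0, male_to_common=1 / 7)
        with pytest.raises(ValueError, match="male mass is 0"):
            mass_correct(r, comp(0, 2, male_mass=0.0, total_mass=10.0))


class TestCalibrate:
    def _noiseless_samples(self, model):
        out = []
        for i, (m, f) in enumerate([(1, 0), (1, 1), (1, 2), (2, 1), (3, 1), (2, 2)]):
            c = comp(m, f, sid=f"s{i}")
            e = expected_ratio(c, model)
            out.append((c, RatioEstimate(f"s{i}", e, 1 / e)))
        return out

    def test_exactly_linear_data_r2_one(self):
        # observed ratio constructed so log10(r+1) is exactly log10(p+1)
        samples = []
        for i, (m, f) in enumerate([(1, 0), (1, 1), (1, 2), (2, 1), (3, 1), (2, 2)]):
            c = comp(m, f, sid=f"s{i}")
            samples.append((c, RatioEstimate(f"s{i}", 1 / c.p_male, c.p_male)))
        fit = calibrate(samples, variant="ratio")
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)

    def test_expected_variant_slope_one_on_exact_data(self):
        fit = calibrate(self._noiseless_samples(ExpectedRatioModel()),
                        variant="expected")
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.slope_ci_low <= 1.0 <= fit.slope_ci_high
        assert fit.slope_eq_one_p > 0.05  # no evidence against slope = 1

    def test_expected_variant_with_per_sample_values(self):
        model = ExpectedRatioModel()
        samples = self._noiseless_samples(model)
        expected = [expected_ratio(c, model) for c, _ in samples]
        fit = calibrate(samples, variant="expected", expected=expected)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_design_rejected(self):
        model = ExpectedRatioModel()
        c = comp(1, 1)
        samples = [(c, RatioEstimate("s", 14.0, 1 / 14))] * 4
        with pytest.raises(ValueError, match="degenerate|distinct"):
            calibrate(samples, variant="ratio")

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            calibrate([], variant="ratio")


class TestCompareGroups:
    def test_identical_groups_statistic_zero(self):
        report = compare_groups(
            {"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]}, mode="parametric")
        assert report["statistic"] == 0.0
        assert report["p_value"] >= 0.999

    def test_auto_falls_back_to_kruskal_on_skewed_groups(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": list(rng.lognormal(0, 1.5, 12)),
            "b": list(np.concatenate([rng.lognormal(0.1, 0.05, 11), [900.0]])),
            "c": list(rng.lognormal(0.2, 2.0, 12)),
        }
        report = compare_groups(groups, mode="auto", log_transform=False)
        assert report["method"] == "kruskal_dunn_bh"
        direct = stats.kruskal(*groups.values())
        assert report["statistic"] == pytest.approx(direct.statistic)

    def test_anova_matches_scipy_on_log_scale(self):
        rng = np.random.default_rng(6)
        groups = {g: list(rng.lognormal(mu, 0.1, 6))
                  for g, mu in [("a", 2.0), ("b", 2.3), ("c", 2.6)]}
        report = compare_groups(groups, mode="parametric")
        logged = [np.log10(v) for v in groups.values()]
        f, p = stats.f_oneway(*logged)
        assert report["statistic"] == pytest.approx(f)
        assert report["df_between"] == 2
        assert len(report["pairwise"]) == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": []})


class TestDunnBH:
    def test_hand_computed_rank_example(self):
        """Three separated triples: mean ranks 2, 5, 8; z_AB = -3/sqrt(5)."""
        groups = {"A": [1.0, 2.0, 3.0], "B": [4.0, 5.0, 6.0], "C": [7.0, 8.0, 9.0]}
        rows = {(r["group_a"], r["group_b"]): r for r in _dunn_bh(groups)}
        z_ab = rows[("A", "B")]["z"]
        assert z_ab == pytest.approx(-3 / math.sqrt(5), rel=1e-9)
        assert rows[("A", "C")]["z"] == pytest.approx(-6 / math.sqrt(5), rel=1e-9)
        # BH-adjusted p-values frozen from the closed-form normal tails
        assert rows[("A", "C")]["p_adj"] == pytest.approx(0.02187, abs=2e-4)
        assert rows[("A", "B")]["p_adj"] == pytest.approx(0.17971, abs=2e-4)

    def test_tie_correction_reduces_variance(self):
        no_ties = _dunn_bh({"A": [1.0, 2.0], "B": [3.0, 4.0]})[0]["z"]
        with_ties = _dunn_bh({"A": [1.0, 1.0], "B": [3.0, 3.0]})[0]["z"]
        assert abs(with_ties) > abs(no_ties)


class TestAccuracyVsExpected:
    def test_exact_agreement_gives_p_one(self):
        model = ExpectedRatioModel()
        groups = {"1M:1F": [14.0] * 5}
        comps = {"1M:1F": comp(1, 1)}
        out = accuracy_vs_expected(groups, comps, model)
        assert out["groups"]["1M:1F"]["p_value"] == 1.0
        assert not out["any_significant"]

    def test_threefold_shift_significant_at_n9(self):
        # all nine signed ranks on one side: exact p = 2 / 2^9
        model = ExpectedRatioModel()
        obs = [14.0 * 3 * (1 + 0.01 * i) for i in range(9)]
        out = accuracy_vs_expected({"1M:1F": obs}, {"1M:1F": comp(1, 1)}, model)
        g = out["groups"]["1M:1F"]
        assert g["method"] == "exact"
        assert g["p_value"] == pytest.approx(2 / 512)
        assert out["any_significant"]

    def test_small_group_skipped(self):
        out = accuracy_vs_expected({"1M": [7.0, 7.1]}, {"1M": comp(1, 0)})
        assert out["groups"]["1M"]["skipped"]


class TestParseGroupLabel:
    @pytest.mark.parametrize("label,expected", [
        ("3M:1F", (3, 1)),
        ("1M", (1, 0)),
        ("4F", (0, 4)),
        ("2m:2f", (2, 2)),
    ])
    def test_convention(self, label, expected):
        assert parse_group_label(label) == expected

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_group_label("NTC")


class TestParameterRecovery:
    def test_mean_estimate_near_truth_and_spread_shrinks_with_males(self, sim_cfg):
        """Synthetic eDNA samples at p in {0.25, 0.5, 0.75}: the mean male
        proportion over 200 simulations lands within 0.08 of truth, and the
        estimator spread shrinks as males are added."""
        from ednasex import (
            allele_ratio, merge_wells, simulate_droplets,
            simulate_individuals, simulate_sample,
        )
        rng = np.random.default_rng(23)
        model = ExpectedRatioModel()
        spreads = {}
        for m, f in [(1, 3), (2, 2), (3, 1)]:
            truth = m / (m + f)
            est = []
            for _ in range(200):
                inds = simulate_individuals(m, f, sim_cfg, rng)
                conc = simulate_sample(inds, "edna", sim_cfg, rng)
                wells = simulate_droplets(conc, sim_cfg, rng, "s", n_wells=3)
                common = merge_wells([w for w in wells if w.target == "common"])
                male = merge_wells([w for w in wells if w.target == "male"])
                r = allele_ratio(common, male)
                est.append(estimate_male_proportion(
                    r.male_to_common, model).p_male)
            assert abs(np.mean(est) - truth) <= 0.08, f"bias too large at {m}M:{f}F"
            spreads[m] = np.std(est) / np.mean(est)
        assert spreads[3] < spreads[1]
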