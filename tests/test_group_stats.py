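"""Fisher averaging, Rüger areas, gated tests, and the hypothesis battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nremspec import (
    ElectrodeAdjacency, compare_independent_correlations, fisher_average,
    gated_association, rueger_test, run_hypotheses, synth_cohort,
)
from nremspec.synthetic import CohortSpec, PlantedEffects


class TestFisherAverage:
    def test_idempotent_on_equal_correlations(self):
        assert fisher_average([0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_antisymmetric_pair_averages_to_zero(self):
        assert fisher_average([0.5, -0.5]) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_example(self):
        want = math.tanh((math.atanh(0.9) + math.atanh(0.3)) / 2)
        got = fisher_average([0.9, 0.3])
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.712, abs=5e-4)

    def test_magnitude_bounded_by_largest_input(self, rng):
        for _ in range(20):
            r = rng.uniform(-0.95, 0.95, 8)
            assert abs(fisher_average(r)) <= np.abs(r).max() + 1e-12

    def test_sd_on_transformed_scale(self):
        mean, sd = fisher_average([0.2, 0.4, 0.6], return_sd=True)
        z = np.arctanh([0.2, 0.4, 0.6])
        assert sd == pytest.approx(np.tanh(np.std(z, ddof=1)))

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError, match=r"\|r\| < 1"):
            fisher_average([0.5, 1.0])


def brute_force_rueger(pvals, edges):
    """Independent oracle: components via union-find, criteria via counting."""
    sig = [ch for ch, p in pvals.items() if p < 0.05]
    parent = {ch: ch for ch in sig}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in edges:
        if a in parent and b in parent:
            parent[find(a)] = find(b)
    comps = {}
    for ch in sig:
        comps.setdefault(find(ch), set()).add(ch)
    out = {}
    for comp in comps.values():
        k = len(comp)
        n3 = sum(pvals[c] <= 0.05 / 3 for c in comp)
        n2 = sum(pvals[c] <= 0.05 / 2 for c in comp)
        out[frozenset(comp)] = (n3 >= math.ceil(k / 3)) and (n2 >= math.ceil(k / 2))
    return out


class TestRuegerTest:
    def test_uniformly_tiny_pvalues_give_one_significant_area(self):
        from nremspec.montage import CHANNELS_18
        res = rueger_test({ch: 0.001 for ch in CHANNELS_18})
        assert len(res) == 1
        assert set(res[0].area_channels) == set(CHANNELS_18)
        assert res[0].significant

    def test_five_member_area_passes_both_fraction_criteria(self):
        pvals = {"F3": 0.01, "Fz": 0.016, "F4": 0.02, "C3": 0.03, "C4": 0.04,
                 "Cz": 0.2}
        res = rueger_test(pvals)
        areas = {frozenset(r.area_channels): r for r in res}
        area = areas[frozenset({"F3", "Fz", "F4", "C3", "C4"})]
        assert area.n_p017 == 2 and area.n_p025 == 3
        assert area.significant

    def test_descriptive_only_area_is_not_significant(self):
        res = rueger_test({"F3": 0.04, "F4": 0.04, "Fz": 0.04})
        assert len(res) == 1
        assert res[0].n_p017 == 0 and res[0].n_p025 == 0
        assert not res[0].significant

    def test_matches_exhaustive_oracle_on_small_montages(self, rng):
        nodes = ("A", "B", "C", "D", "E", "F")
        for trial in range(50):
            all_edges = list(itertools.combinations(nodes, 2))
            chosen = [e for e in all_edges if rng.random() < 0.3]
            adj = ElectrodeAdjacency(nodes=nodes, edges=tuple(chosen))
            pvals = {ch: float(rng.choice(
                [0.001, 0.01, 0.016, 0.02, 0.025, 0.04, 0.2, 0.8]))
                for ch in nodes}
            got = {frozenset(r.area_channels): r.significant
                   for r in rueger_test(pvals, adj)}
            want = brute_force_rueger(pvals, chosen)
            assert got == want

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="absent from the adjacency"):
            rueger_test({"XX": 0.01})

    def test_disjunction_mode_is_weaker(self):
        # 1/3 criterion met, 1/2 criterion missed
        pvals = {"F3": 0.01, "F4": 0.03, "Fz": 0.04}
        strict = rueger_test(pvals)[0]
        loose = rueger_test(pvals, conjunction=False)[0]
        assert not strict.significant and loose.significant


class TestGatedAssociation:
    def test_gaussian_pair_uses_pearson(self, rng):
        x = rng.normal(size=80)
        y = 0.5 * x + rng.normal(size=80)
        rep = gated_association(x, y)
        assert rep.test == "pearson" and rep.gaussian

    def test_lognormal_variable_switches_to_spearman(self, rng):
        x = rng.normal(size=80)
        y = np.exp(2.5 * x + rng.normal(size=80))
        rep = gated_association(x, y)
        assert rep.test == "spearman" and not rep.gaussian

    def test_gaussian_groups_use_t_test(self, rng):
        x = np.r_[rng.normal(0, 1, 60), rng.normal(1, 1, 60)]
        g = np.r_[["a"] * 60, ["b"] * 60]
        rep = gated_association(x, g, kind="two-group")
        assert rep.test == "t-test"
        assert rep.p < 0.05
        assert 0 <= rep.effect_size <= 1

    def test_skewed_groups_use_mann_whitney_with_power(self, rng):
        # planted one-SD location shift on a lognormal scale, n=100 per group
        a = np.exp(rng.normal(0, 1, 100))
        b = np.exp(rng.normal(1, 1, 100))
        rep = gated_association(np.r_[a, b], np.r_[["a"] * 100, ["b"] * 100],
                                kind="two-group")
        assert rep.test == "mann-whitney"
        assert rep.p < 0.05
        assert rep.effect_size > 0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gated_association(np.ones(20), np.arange(20.0))


class TestCompareCorrelations:
    def test_equal_correlations_give_p_one(self):
        assert compare_independent_correlations(0.4, 50, 0.4, 80) == pytest.approx(1.0)

    def test_symmetric_in_the_two_samples(self):
        p1 = compare_independent_correlations(0.44, 79, 0.40, 60)
        p2 = compare_independent_correlations(0.40, 60, 0.44, 79)
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_closed_form_oracle(self):
        from scipy.stats import norm
        z = (np.arctanh(0.44) - np.arctanh(0.40)) / np.sqrt(1 / 76 + 1 / 57)
        want = 2 * norm.sf(abs(z))
        assert compare_independent_correlations(0.44, 79, 0.40, 60) == \
            pytest.approx(want, abs=1e-15)

    def test_undersized_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            compare_independent_correlations(0.4, 3, 0.4, 50)


class TestHypothesisBattery:
    def test_planted_age_alpha_effect_yields_significant_area(self):
        params, covars, _ = synth_cohort(CohortSpec(n_subjects=170, seed=14))
        res = run_hypotheses(params, covars)
        assert res["H1"].any_significant_area
        area = max(res["H1"].rueger, key=lambda r: len(r.area_channels))
        assert len(area.area_channels) == 18
        # flatter slopes (alpha closer to 0) in the aged: positive statistic
        assert (res["H1"].per_channel["statistic"] > 0).all()

    def test_null_sex_effect_on_peak_amplitude_stays_null(self):
        params, covars, _ = synth_cohort(CohortSpec(n_subjects=170, seed=14))
        res = run_hypotheses(params, covars)
        assert not res["H4_peak_amplitude"].any_significant_area

    def test_sex_effects_present_where_planted(self):
        params, covars, _ = synth_cohort(CohortSpec(n_subjects=170, seed=14))
        res = run_hypotheses(params, covars)
        assert res["H4"].any_significant_area
        assert res["H5"].any_significant_area

    def test_h7_reports_no_difference_when_none_planted(self):
        params, covars, _ = synth_cohort(CohortSpec(n_subjects=170, seed=14))
        res = run_hypotheses(params, covars)
        assert not res["H7"].any_significant_area
        assert (res["H7"].per_channel["p_difference"] > 0.001).all()

    def test_missing_covariate_rejected(self):
        params, covars, _ = synth_cohort(CohortSpec(n_subjects=30, seed=0))
        with pytest.raises(ValueError, match="age_years"):
            run_hypotheses(params, covars.drop(columns=["age_years"]))

    def test_empty_covariate_rejected(self):
        params, covars, _ = synth_cohort(CohortSpec(n_subjects=30, seed=0))
        covars["sex"] = pd.NA
        with pytest.raises(ValueError, match="sex"):
            run_hypotheses(params, covars)
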