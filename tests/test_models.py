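"""The seven predictive models: definitions, reductions, and selection rules."""

import numpy as np
import pytest

from prefnet.abundance import EffectiveAbundances, fit_effective_abundances
from prefnet.models import (
    abundant_pairs_rule,
    aggregate_counts_model,
    alternative_preferences_model,
    complete_characterisation_model,
    correlated_preferences_model,
    influential_interactions,
    null_model,
    predicted_counts,
    random_encounter_model,
    specified_preferences_model,
    switch_preference,
)
from prefnet.network_core import SupportMask, ValidationError, support_mask
from prefnet.preference import PreferenceMatrix, derive_preferences

from conftest import make_group


def abund(hosts, pars):
    return EffectiveAbundances(
        host_abundance=dict(hosts),
        parasitoid_abundance=dict(pars),
        alpha_hat=1.0,
        beta_hat=1.0,
        loglik=0.0,
        residual_norm=0.0,
        connected=True,
    )


def pm_from(entries, cal_hosts=None, cal_pars=None):
    return PreferenceMatrix(
        entries=dict(entries),
        normalisation_kappa=1.0,
        source_group="cal",
        abundances_used=abund(
            cal_hosts or {h: 1.0 for (h, _p) in entries},
            cal_pars or {p: 1.0 for (_h, p) in entries},
        ),
    )


def mask(*cells):
    return SupportMask(frozenset(cells))


class TestNullModel:
    def test_uniform_over_four_cells(self):
        s = mask(("h1", "p1", "s1"), ("h2", "p1", "s1"),
                 ("h1", "p1", "s2"), ("h2", "p1", "s2"))
        pred = null_model(s)
        assert all(p == pytest.approx(0.25) for p in pred.probs.values())

    def test_single_cell_gets_probability_one(self):
        pred = null_model(mask(("h1", "p1", "s1")))
        assert pred.probs[("h1", "p1", "s1")] == pytest.approx(1.0)

    def test_uniform_across_sites(self):
        s = mask(*[("h%d" % i, "p1", "s1") for i in range(3)],
                 *[("h%d" % i, "p1", "s2") for i in range(2)])
        pred = null_model(s)
        assert all(p == pytest.approx(0.2) for p in pred.probs.values())


class TestAggregateCountsModel:
    def test_probabilities_proportional_to_calibration_sums(self):
        cal = make_group({"s1": {("hA", "p1"): 6, ("hB", "p1"): 2, ("hC", "p1"): 2}})
        s = mask(("hA", "p1", "t1"), ("hB", "p1", "t1"), ("hC", "p1", "t1"))
        pred = aggregate_counts_model(cal, s)
        assert pred.probs[("hA", "p1", "t1")] == pytest.approx(0.6)
        assert pred.probs[("hB", "p1", "t1")] == pytest.approx(0.2)

    def test_link_mass_reused_at_each_test_site(self):
        cal = make_group({"s1": {("hA", "p1"): 3, ("hB", "p1"): 1}})
        s = mask(("hA", "p1", "t1"), ("hA", "p1", "t2"),
                 ("hB", "p1", "t1"), ("hB", "p1", "t2"))
        pred = aggregate_counts_model(cal, s)
        assert pred.probs[("hA", "p1", "t1")] == pytest.approx(3 / 8)
        assert pred.probs[("hA", "p1", "t2")] == pytest.approx(3 / 8)

    def test_single_calibration_link_gives_certainty(self):
        cal = make_group({"s1": {("hA", "p1"): 4}})
        pred = aggregate_counts_model(cal, mask(("hA", "p1", "t1")))
        assert pred.probs[("hA", "p1", "t1")] == pytest.approx(1.0)

    def test_unseen_links_get_small_pseudo_mass(self):
        cal = make_group({"s1": {("hA", "p1"): 10}})
        s = mask(("hA", "p1", "t1"), ("hB", "p1", "t1"))
        pred = aggregate_counts_model(cal, s)
        assert 0 < pred.probs[("hB", "p1", "t1")] < 1e-2

    def test_no_shared_links_is_an_error(self):
        cal = make_group({"s1": {("hA", "p1"): 10}})
        with pytest.raises(ValidationError):
            aggregate_counts_model(cal, mask(("hZ", "p9", "t1")))


class TestRandomEncounterModel:
    def test_proportional_to_abundance_products(self):
        ab = abund({"h1": 2.0, "h2": 1.0}, {"p1": 1.0})
        pred = random_encounter_model(ab, mask(("h1", "p1", "s1"), ("h2", "p1", "s1")))
        assert pred.probs[("h1", "p1", "s1")] == pytest.approx(2 / 3)

    def test_equal_abundances_reduce_to_null(self):
        ab = abund({"h1": 1.0, "h2": 1.0}, {"p1": 1.0, "p2": 1.0})
        s = mask(("h1", "p1", "s1"), ("h2", "p1", "s1"), ("h1", "p2", "s1"))
        re = random_encounter_model(ab, s)
        nu = null_model(s)
        for c in s.cells:
            assert re.probs[c] == pytest.approx(nu.probs[c])

    def test_weights_have_no_site_index(self):
        ab = abund({"h1": 2.0, "h2": 1.0}, {"p1": 1.0})
        s = mask(("h1", "p1", "s1"), ("h1", "p1", "s2"),
                 ("h2", "p1", "s1"), ("h2", "p1", "s2"))
        pred = random_encounter_model(ab, s)
        assert pred.probs[("h1", "p1", "s1")] == pytest.approx(1 / 3)
        assert pred.probs[("h2", "p1", "s2")] == pytest.approx(1 / 6)

    def test_missing_abundance_is_an_error(self):
        ab = abund({"h1": 1.0}, {"p1": 1.0})
        with pytest.raises(ValidationError):
            random_encounter_model(ab, mask(("h2", "p1", "s1")))


class TestSwitchPreference:
    def test_less_preferred_closed_form(self):
        assert switch_preference(1.0, 1.0, "less_preferred") == pytest.approx(0.5)

    def test_large_product_drives_preference_to_zero(self):
        assert switch_preference(100.0, 100.0, "less_preferred") < 1e-4

    def test_mass_action_is_always_one(self):
        assert switch_preference(3.7, 0.2, "mass_action") == 1.0

    def test_species_missing_from_calibration_falls_back_to_mass_action(self):
        assert switch_preference(None, 2.0, "less_preferred") == 1.0

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValidationError):
            switch_preference(0.0, 1.0, "less_preferred")


class TestAlternativePreferencesModel:
    def test_direct_weights(self):
        pm = pm_from({("h1", "p1"): 2.0, ("h2", "p1"): 1.0})
        ab = abund({"h1": 2.0, "h2": 1.0}, {"p1": 1.0})
        pred = alternative_preferences_model(
            pm, ab, "mass_action", mask(("h1", "p1", "s1"), ("h2", "p1", "s1"))
        )
        assert pred.probs[("h1", "p1", "s1")] == pytest.approx(0.8)

    def test_unit_preferences_reduce_to_random_encounter(self):
        pm = pm_from({("h1", "p1"): 1.0, ("h2", "p1"): 1.0})
        ab = abund({"h1": 1.7, "h2": 0.4}, {"p1": 1.0})
        s = mask(("h1", "p1", "s1"), ("h2", "p1", "s1"))
        alt = alternative_preferences_model(pm, ab, "mass_action", s)
        re = random_encounter_model(ab, s)
        for c in s.cells:
            assert alt.probs[c] == pytest.approx(re.probs[c])

    def test_less_preferred_switch_halves_the_unit_product_link(self):
        # switch with calibration product 1 gets γ = 0.5 under less_preferred
        pm = pm_from({("h1", "p1"): 1.0}, cal_hosts={"h1": 1.0, "h2": 1.0},
                     cal_pars={"p1": 1.0})
        ab = abund({"h1": 1.0, "h2": 1.0}, {"p1": 1.0})
        s = mask(("h1", "p1", "s1"), ("h2", "p1", "s1"))
        pred = alternative_preferences_model(pm, ab, "less_preferred", s)
        assert pred.probs[("h2", "p1", "s1")] == pytest.approx(0.5 / 1.5)


class TestCorrelatedPreferencesModel:
    def test_column_values_reassigned_by_rank_source_order(self):
        pm_cal = pm_from({("hA", "p1"): 2.0, ("hB", "p1"): 0.5, ("hC", "p1"): 1.0})
        rank = pm_from({("hA", "p1"): 0.1, ("hB", "p1"): 5.0, ("hC", "p1"): 1.0})
        ab = abund({"hA": 1.0, "hB": 1.0, "hC": 1.0}, {"p1": 1.0})
        s = mask(("hA", "p1", "s1"), ("hB", "p1", "s1"), ("hC", "p1", "s1"))
        pred = correlated_preferences_model(pm_cal, rank, ab, 1.0, s)
        gamma = pred.params["gamma_corr"]
        assert gamma[("hB", "p1")] == 2.0
        assert gamma[("hC", "p1")] == 1.0
        assert gamma[("hA", "p1")] == 0.5

    def test_self_rank_source_with_unit_delta_equals_alternative(self):
        pm_cal = pm_from({("hA", "p1"): 2.0, ("hB", "p1"): 0.5})
        ab = abund({"hA": 1.0, "hB": 3.0}, {"p1": 1.0})
        s = mask(("hA", "p1", "s1"), ("hB", "p1", "s1"))
        corr = correlated_preferences_model(pm_cal, pm_cal, ab, 1.0, s)
        alt = alternative_preferences_model(pm_cal, ab, "mass_action", s)
        for c in s.cells:
            assert corr.probs[c] == pytest.approx(alt.probs[c])

    def test_zero_delta_reduces_to_random_encounter(self):
        pm_cal = pm_from({("hA", "p1"): 2.0, ("hB", "p1"): 0.5})
        ab = abund({"hA": 1.0, "hB": 3.0}, {"p1": 1.0})
        s = mask(("hA", "p1", "s1"), ("hB", "p1", "s1"))
        corr = correlated_preferences_model(pm_cal, pm_cal, ab, 0.0, s)
        re = random_encounter_model(ab, s)
        for c in s.cells:
            assert corr.probs[c] == pytest.approx(re.probs[c])

    def test_column_multiset_is_conserved(self):
        pm_cal = pm_from(
            {("hA", "p1"): 2.0, ("hB", "p1"): 0.5, ("hC", "p1"): 1.0,
             ("hA", "p2"): 3.0, ("hB", "p2"): 1.0}
        )
        rank = pm_from(
            {("hA", "p1"): 1.0, ("hB", "p1"): 2.0, ("hC", "p1"): 3.0,
             ("hA", "p2"): 1.0, ("hB", "p2"): 2.0}
        )
        ab = abund({"hA": 1.0, "hB": 1.0, "hC": 1.0}, {"p1": 1.0, "p2": 1.0})
        s = mask(("hA", "p1", "s1"), ("hB", "p1", "s1"), ("hC", "p1", "s1"),
                 ("hA", "p2", "s1"), ("hB", "p2", "s1"))
        pred = correlated_preferences_model(pm_cal, rank, ab, 1.0, s)
        gamma = pred.params["gamma_corr"]
        assert sorted(gamma[(h, "p1")] for h in ("hA", "hB", "hC")) == [0.5, 1.0, 2.0]
        assert sorted(gamma[(h, "p2")] for h in ("hA", "hB")) == [1.0, 3.0]

    def test_missing_rank_source_column_is_an_error(self):
        pm_cal = pm_from({("hA", "p1"): 2.0, ("hB", "p1"): 0.5})
        rank = pm_from({("hA", "p1"): 1.0})
        ab = abund({"hA": 1.0, "hB": 1.0}, {"p1": 1.0})
        s = mask(("hA", "p1", "s1"), ("hB", "p1", "s1"))
        with pytest.raises(ValidationError, match="rank source"):
            correlated_preferences_model(pm_cal, rank, ab, 1.0, s)

    def test_delta_fit_requires_eval_counts(self):
        pm_cal = pm_from({("hA", "p1"): 2.0, ("hB", "p1"): 0.5})
        ab = abund({"hA": 1.0, "hB": 1.0}, {"p1": 1.0})
        s = mask(("hA", "p1", "s1"), ("hB", "p1", "s1"))
        with pytest.raises(ValueError):
            correlated_preferences_model(pm_cal, pm_cal, ab, "fit", s)


class TestInfluentialInteractions:
    def test_planted_strong_preference_is_ranked_first(self):
        # one link with γ = 10 among mass-action links, large counts: its
        # solo contribution to the likelihood dominates the ranking
        import numpy as np
        from prefnet.synthetic import GroundTruth, ScenarioSpec, sample_group

        hosts = {f"h{i:02d}": 1.0 for i in range(1, 7)}
        pars = {f"p{j:02d}": 1.0 for j in range(1, 6)}
        gamma = {(h, p): 1.0 for h in hosts for p in pars}
        gamma[("h01", "p01")] = 10.0
        truth = GroundTruth(hosts, pars, gamma, set())
        spec = ScenarioSpec(n_hosts=6, n_parasitoids=5, n_sites=3,
                            counts_per_site=2000, forbidden_fraction=0.0)
        g = sample_group(truth, spec, np.random.default_rng(9))
        ab = fit_effective_abundances(g)
        pm = derive_preferences(g, ab)
        sel = influential_interactions(g, pm, ab)
        assert sel.ranked[0][0] == ("h01", "p01")
        assert ("h01", "p01") in sel.selected
        assert len(sel.selected) <= 15  # 50% cap on 30 links

    def test_unit_preferences_select_nothing(self):
        g = make_group({"s1": {("h1", "p1"): 10, ("h2", "p1"): 10}})
        ab = abund({"h1": 1.0, "h2": 1.0}, {"p1": 1.0})
        pm = pm_from({("h1", "p1"): 1.0, ("h2", "p1"): 1.0})
        sel = influential_interactions(g, pm, ab)
        assert sel.selected == []

    def test_top_n_override(self):
        g = make_group({"s1": {("h1", "p1"): 30, ("h2", "p1"): 10, ("h3", "p1"): 5}})
        ab = fit_effective_abundances(g)
        pm = derive_preferences(g, ab)
        sel = influential_interactions(g, pm, ab, top_n=2)
        assert len(sel.selected) == 2


class TestAbundantPairsRule:
    def test_top_links_by_abundance_product(self):
        ab = abund({"h1": 3.0, "h2": 2.0, "h3": 1.0}, {"p1": 2.0, "p2": 1.0})
        s = mask(("h1", "p1", "s1"), ("h2", "p1", "s1"), ("h3", "p2", "s1"))
        assert abundant_pairs_rule(ab, s, 2) == [("h1", "p1"), ("h2", "p1")]

    def test_zero_n_rejected_and_overflow_warns(self):
        ab = abund({"h1": 1.0}, {"p1": 1.0})
        s = mask(("h1", "p1", "s1"))
        with pytest.raises(ValueError):
            abundant_pairs_rule(ab, s, 0)
        with pytest.warns(UserWarning):
            assert abundant_pairs_rule(ab, s, 5) == [("h1", "p1")]

    def test_ties_break_by_identifier_order(self):
        ab = abund({"h1": 1.0, "h2": 1.0}, {"p1": 1.0})
        s = mask(("h1", "p1", "s1"), ("h2", "p1", "s1"))
        assert abundant_pairs_rule(ab, s, 1) == [("h1", "p1")]


class TestSpecifiedAndCompleteModels:
    def setup_method(self):
        self.ab = abund({"h1": 1.0, "h2": 2.0}, {"p1": 1.0})
        self.s = mask(("h1", "p1", "s1"), ("h2", "p1", "s1"))
        self.pm_cal = pm_from({("h1", "p1"): 1.5, ("h2", "p1"): 0.7})
        self.pm_test = pm_from({("h1", "p1"): 0.4, ("h2", "p1"): 2.5})

    def test_full_hardcode_equals_complete_characterisation(self):
        spec = specified_preferences_model(
            self.pm_cal, self.pm_test, self.ab,
            [("h1", "p1"), ("h2", "p1")], "mass_action", self.s,
        )
        complete = complete_characterisation_model(self.pm_test, self.ab, self.s)
        for c in self.s.cells:
            assert spec.probs[c] == pytest.approx(complete.probs[c])

    def test_empty_hardcode_equals_alternative(self):
        spec = specified_preferences_model(
            self.pm_cal, self.pm_test, self.ab, [], "mass_action", self.s
        )
        alt = alternative_preferences_model(self.pm_cal, self.ab, "mass_action", self.s)
        for c in self.s.cells:
            assert spec.probs[c] == pytest.approx(alt.probs[c])

    def test_corr_base_with_no_hardcode_equals_correlated(self):
        spec = specified_preferences_model(
            self.pm_cal, self.pm_test, self.ab, [], "mass_action", self.s,
            base="corr", rank_source=self.pm_test, delta=1.0,
        )
        corr = correlated_preferences_model(
            self.pm_cal, self.pm_test, self.ab, 1.0, self.s
        )
        for c in self.s.cells:
            assert spec.probs[c] == pytest.approx(corr.probs[c])

    def test_hardcoded_link_missing_from_test_matrix_is_an_error(self):
        with pytest.raises(ValidationError):
            specified_preferences_model(
                self.pm_cal, pm_from({("h1", "p1"): 1.0}), self.ab,
                [("h2", "p1")], "mass_action", self.s,
            )

    def test_complete_with_unit_preferences_equals_random_encounter(self):
        pm = pm_from({("h1", "p1"): 1.0, ("h2", "p1"): 1.0})
        complete = complete_characterisation_model(pm, self.ab, self.s)
        re = random_encounter_model(self.ab, self.s)
        for c in self.s.cells:
            assert complete.probs[c] == pytest.approx(re.probs[c])

    def test_single_cell_support_gives_certainty(self):
        pm = pm_from({("h1", "p1"): 0.3})
        pred = complete_characterisation_model(pm, self.ab, mask(("h1", "p1", "s1")))
        assert pred.probs[("h1", "p1", "s1")] == pytest.approx(1.0)


class TestProbabilityInvariants:
    def test_all_models_sum_to_one_with_positive_entries(self, dense_group):
        ab = fit_effective_abundances(dense_group)
        pm = derive_preferences(dense_group, ab)
        s = support_mask(dense_group)
        counts = dense_group.counts_on(s.sorted_cells())
        preds = [
            null_model(s),
            aggregate_counts_model(dense_group, s),
            random_encounter_model(ab, s),
            alternative_preferences_model(pm, ab, "mass_action", s),
            correlated_preferences_model(pm, pm, ab, "fit", s, counts),
            complete_characterisation_model(pm, ab, s),
        ]
        for pred in preds:
            assert sum(pred.probs.values()) == pytest.approx(1.0, abs=1e-12)
            assert min(pred.probs.values()) > 0

    def test_predicted_counts_scale_to_total(self):
        pred = null_model(mask(("h1", "p1", "s1"), ("h2", "p1", "s1")))
        b_star = predicted_counts(pred, 50)
        assert sum(b_star.values()) == pytest.approx(50)
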