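import numpy as np
import pytest
from hypothesis import given, strategies as st

import morphoident as mi
from morphoident.identifier import Prediction, chain_probabilities, filter_probabilities


def prob_vectors(n):
    return (
        st.lists(st.floats(0.0, 1.0), min_size=n, max_size=n)
        .filter(lambda xs: sum(xs) > 1e-6)
        .map(lambda xs: np.array(xs) / sum(xs))
    )


def pred(classes, probs):
    return Prediction(tuple(classes), np.asarray(probs, dtype=float))


class TestPrediction:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            pred("ab", [0.5, 0.6])
        with pytest.raises(ValueError):
            pred("ab", [1.5, -0.5])

    def test_ranking_is_a_permutation_with_stable_ties(self):
        p = pred(["a", "b", "c"], [0.2, 0.4, 0.4])
        assert p.ranking == ["b", "c", "a"]
        assert sorted(p.ranking) == ["a", "b", "c"]


class TestPredict:
    def test_probabilities_sum_to_one(self, fitted_small_identifier):
        fit = fitted_small_identifier
        p = mi.predict(fit.identifier, fit.test_records[0])
        assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_training_record_recovers_own_class(self, fitted_small_identifier, small_genus):
        _, _, _, records = small_genus
        fit = fitted_small_identifier
        train = [r for r in records if r.collection_id in fit.split.train_ids
                 and mi.eligible(r, fit.identifier.group)]
        rec = train[0]
        assert mi.predict(fit.identifier, rec).ranking[0] == rec.species

    def test_identical_records_get_identical_predictions(self, fitted_small_identifier):
        fit = fitted_small_identifier
        rec = fit.test_records[0]
        a = mi.predict(fit.identifier, rec).probabilities
        b = mi.predict(fit.identifier, rec.copy()).probabilities
        assert a.tobytes() == b.tobytes()

    def test_missing_character_is_an_error_not_imputed(self, fitted_small_identifier):
        fit = fitted_small_identifier
        rec = fit.test_records[0].copy()
        del rec.values["spore_length"]
        with pytest.raises(ValueError, match="spore_length"):
            mi.predict(fit.identifier, rec)


class TestChain:
    def test_hand_worked_weighting(self):
        first = pred(["a", "b", "c"], [0.5, 0.3, 0.2])
        second = pred(["b", "c"], [0.6, 0.4])
        out = chain_probabilities(first, second, frozenset({"b", "c"}))
        assert out.probabilities == pytest.approx([0.5, 0.30, 0.20])
        assert out.probabilities.sum() == pytest.approx(1.0)

    def test_full_subset_reproduces_specialist(self):
        first = pred(["a", "b", "c"], [0.2, 0.3, 0.5])
        second = pred(["a", "b", "c"], [0.1, 0.1, 0.8])
        out = chain_probabilities(first, second, frozenset("abc"))
        assert out.probabilities == pytest.approx(second.probabilities)

    def test_zero_mass_on_subset_keeps_first_pass(self):
        first = pred(["a", "b", "c"], [1.0, 0.0, 0.0])
        second = pred(["b", "c"], [0.6, 0.4])
        out = chain_probabilities(first, second, frozenset({"b", "c"}))
        assert out.probabilities == pytest.approx([1.0, 0.0, 0.0])

    @given(prob_vectors(5), prob_vectors(2))
    def test_conserves_probability(self, p_first, p_second):
        first = pred(["a", "b", "c", "d", "e"], p_first)
        second = pred(["b", "d"], p_second)
        out = chain_probabilities(first, second, frozenset({"b", "d"}))
        assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert (out.probabilities >= -1e-12).all()

    def test_spec_validates_subset_coverage(self, fitted_small_identifier):
        ident = fitted_small_identifier.identifier
        with pytest.raises(ValueError, match="subset|classes"):
            mi.ChainSpec(ident, ident, subset=frozenset({"not-a-class"}))


class TestTrigger:
    def make_chain(self, small_genus, groups, threshold):
        spec, tax, _, records = small_genus
        cfg = mi.TrainingConfig(optimizer="adamw", amsgrad=True,
                                learning_rates=(0.005,), seed=spec.seed)
        first = mi.fit_identifier(records, groups["CG7"], "species", tax, cfg)
        target_section = tax.section_labels[0]
        section_species = [s for s in tax.class_list("species")
                          if tax.section_of(s) == target_section]
        sub_records = [r for r in records if r.species in section_species]
        second = mi.fit_identifier(sub_records, groups["CGA"], "species", None, cfg)
        subset = frozenset(second.identifier.classes)
        return (
            mi.ChainSpec(first.identifier, second.identifier, subset, threshold),
            first,
        )

    def test_trigger_fires_only_above_threshold(self, small_genus, groups):
        chain_spec, first_fit = self.make_chain(small_genus, groups, 0.90)
        fired = passed = 0
        for rec in first_fit.test_records:
            if not mi.eligible(rec, chain_spec.second_pass.group):
                continue
            base = mi.predict(chain_spec.first_pass, rec)
            mass = sum(p for c, p in zip(base.classes, base.probabilities)
                       if c in chain_spec.subset)
            out = mi.apply_trigger(chain_spec, rec)
            if mass >= 0.90:
                expected = mi.chain(chain_spec, rec)
                fired += 1
            else:
                expected = base
                passed += 1
            assert out.probabilities == pytest.approx(expected.probabilities)
            assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert fired > 0 and passed > 0

    def test_zero_threshold_always_chains(self, small_genus, groups):
        chain_spec, first_fit = self.make_chain(small_genus, groups, 0.0)
        rec = next(r for r in first_fit.test_records
                   if mi.eligible(r, chain_spec.second_pass.group))
        out = mi.apply_trigger(chain_spec, rec)
        assert out.probabilities == pytest.approx(
            mi.chain(chain_spec, rec).probabilities
        )


class TestFilter:
    def test_renormalization_after_exclusion(self):
        p = pred(["a", "b", "c"], [0.5, 0.3, 0.2])
        with pytest.warns(UserWarning, match="filter zeroes"):
            out = filter_probabilities(p, frozenset({"a"}))
        assert out.probabilities == pytest.approx([0.0, 0.6, 0.4])

    def test_empty_exclusion_is_identity(self):
        p = pred(["a", "b"], [0.7, 0.3])
        assert filter_probabilities(p, frozenset()) is p

    def test_everything_excluded_is_an_error(self):
        p = pred(["a", "b"], [0.7, 0.3])
        with pytest.raises(ValueError, match="admissible|every class"):
            filter_probabilities(p, frozenset({"a", "b"}))

    @given(prob_vectors(6))
    def test_conserves_probability(self, probs):
        p = pred(list("abcdef"), probs)
        survivors = probs[2:].sum()
        if survivors <= 0:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = filter_probabilities(p, frozenset({"a", "b"}))
        assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.probabilities[0] == 0.0 and out.probabilities[1] == 0.0

    def test_excluded_class_never_outranks_a_survivor(self):
        p = pred(list("abcd"), [0.4, 0.3, 0.2, 0.1])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = filter_probabilities(p, frozenset({"a"}))
        n_survivors = int((out.probabilities > 0).sum())
        for n in range(1, n_survivors + 1):
            assert "a" not in out.ranking[:n]

    def test_unknown_continent_disables_filtering(self, record_factory):
        p = pred(["a", "b"], [0.6, 0.4])
        fspec = mi.FilterSpec(exclusion={"Europe": frozenset({"a"})})
        rec = record_factory({}, continent=None)
        assert mi.continent_filter(p, rec, fspec) is p


class TestImpliedFilter:
    def make_train(self):
        return [
            mi.CollectionRecord("c1", species="sp_eu", continent="Europe"),
            mi.CollectionRecord("c2", species="sp_both", continent="Europe"),
            mi.CollectionRecord("c3", species="sp_both", continent="North America"),
            mi.CollectionRecord("c4", species="sp_na", continent="North America"),
        ]

    def test_exclusion_zones_follow_training_presence(self):
        fspec = mi.imply_filter_from_training(
            self.make_train(), ["sp_eu", "sp_both", "sp_na"]
        )
        assert fspec.excluded_for("North America") == frozenset({"sp_eu"})
        assert fspec.excluded_for("Europe") == frozenset({"sp_na"})
        assert "sp_both" not in fspec.excluded_for("Europe")

    def test_training_blind_spot_zeroes_a_true_species(self, record_factory):
        """A species trained only from one continent gets probability exactly
        zero for a query from the other continent."""
        fspec = mi.imply_filter_from_training(
            self.make_train(), ["sp_eu", "sp_both", "sp_na"]
        )
        p = pred(["sp_eu", "sp_both", "sp_na"], [0.2, 0.3, 0.5])
        rec = record_factory({}, continent="Europe")
        with pytest.warns(UserWarning):
            out = mi.continent_filter(p, rec, fspec)
        assert out.probability_of("sp_na") == 0.0
        assert out.probabilities.sum() == pytest.approx(1.0)

    def test_feature_missing_everywhere_is_an_error(self):
        records = [mi.CollectionRecord("c1", species="sp")]
        with pytest.raises(ValueError, match="continent"):
            mi.imply_filter_from_training(records, ["sp"])
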