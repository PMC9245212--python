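import itertools

import numpy as np
import pytest
from sklearn.metrics import f1_score

import morphoident as mi
from morphoident.identifier import Prediction
from morphoident.metrics import score


def make_record(true_class, classes, probs):
    return mi.PredictionRecord(true_class, Prediction(tuple(classes), np.asarray(probs)))


def brute_rank(probs, classes, true_class):
    """Worst rank of the true class over all orderings consistent with the
    probabilities (enumeration oracle for the pessimistic tie rule)."""
    idx = {c: p for c, p in zip(classes, probs)}
    worst = 0
    for perm in itertools.permutations(classes):
        sorted_ok = all(idx[a] >= idx[b] for a, b in zip(perm, perm[1:]))
        if sorted_ok:
            worst = max(worst, perm.index(true_class) + 1)
    return worst


class TestRank:
    def test_unique_max_is_rank_one(self):
        assert mi.rank_of(make_record("a", "abc", [0.5, 0.3, 0.2])) == 1

    def test_direct_ordering(self):
        assert mi.rank_of(make_record("c", "abc", [0.5, 0.3, 0.2])) == 3

    def test_pessimistic_tie(self):
        rec = make_record("a", "abc", [0.4, 0.4, 0.2])
        assert mi.rank_of(rec) == 2
        assert mi.rank_of(rec) == brute_rank([0.4, 0.4, 0.2], "abc", "a")

    def test_matches_enumeration_oracle_on_small_vectors(self, rng):
        for _ in range(200):
            probs = rng.integers(0, 4, size=4).astype(float)
            if probs.sum() == 0:
                continue
            probs = probs / probs.sum()
            true_class = "abcd"[rng.integers(4)]
            rec = make_record(true_class, "abcd", probs)
            assert mi.rank_of(rec) == brute_rank(list(probs), "abcd", true_class)


def ranked_records(ranks, n_classes=5):
    """Prediction records engineered to have exactly the given ranks."""
    classes = [f"k{i}" for i in range(n_classes)]
    out = []
    for r in ranks:
        probs = np.linspace(0.5, 0.1, n_classes)
        probs = probs / probs.sum()
        true_class = classes[r - 1]  # distinct descending probs: rank = position
        out.append(make_record(true_class, classes, probs))
    return out


class TestTopNAndMrr:
    def test_hand_worked_top_n(self):
        recs = ranked_records([1, 2, 1, 3])
        assert mi.top_n(recs, 1) == pytest.approx(0.5)
        assert mi.top_n(recs, 3) == pytest.approx(1.0)

    def test_hand_worked_mrr(self):
        recs = ranked_records([1, 2, 1, 3])
        assert mi.mrr(recs) == pytest.approx((1 + 0.5 + 1 + 1 / 3) / 4)
        assert mi.mrr(recs) == pytest.approx(0.7083, abs=1e-4)

    def test_perfect_and_single_record_cases(self):
        assert mi.mrr(ranked_records([1, 1, 1])) == 1.0
        assert mi.mrr(ranked_records([4])) == 0.25
        for n in (1, 2, 5):
            assert mi.top_n(ranked_records([1, 1]), n) == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mi.top_n([], 1)
        with pytest.raises(ValueError):
            mi.mrr([])


class TestMacroF1:
    def confusion_example(self):
        """True/predicted: (x->x), (x->y), (y->y), (y->z)."""
        classes = ["x", "y", "z"]
        mk = lambda t, p: make_record(
            t, classes, [0.8 if c == p else 0.1 for c in classes]
        )
        return [mk("x", "x"), mk("x", "y"), mk("y", "y"), mk("y", "z")]

    def test_hand_worked_confusion_example(self):
        """z is predicted once but never true, so it is tabulated (F1=0)
        without entering the average: (2/3 + 1/2)/2."""
        f1, per_class = mi.macro_f1(self.confusion_example())
        by_class = {row["class"]: row for row in per_class}
        assert by_class["x"]["f1"] == pytest.approx(2 / 3, abs=1e-4)
        assert by_class["y"]["f1"] == pytest.approx(0.5)
        assert by_class["z"]["f1"] == 0.0
        assert f1 == pytest.approx(0.5833, abs=1e-4)

    def test_matches_sklearn_on_classes_with_truth(self, rng):
        classes = [f"k{i}" for i in range(6)]
        for _ in range(50):
            n = int(rng.integers(5, 40))
            truths, preds, recs = [], [], []
            for _ in range(n):
                t = classes[rng.integers(6)]
                probs = rng.dirichlet(np.ones(6))
                p = classes[int(np.argmax(probs))]
                truths.append(t)
                preds.append(p)
                recs.append(make_record(t, classes, probs))
            ours, _ = mi.macro_f1(recs)
            theirs = f1_score(truths, preds, labels=sorted(set(truths)),
                              average="macro", zero_division=0)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_perfect_predictions(self):
        recs = ranked_records([1, 1, 1])
        f1, _ = mi.macro_f1(recs)
        assert f1 == 1.0

    def test_unmeasured_classes_excluded_from_average(self):
        classes = ["x", "y", "zz_never_seen"]
        recs = [make_record("x", classes, [0.9, 0.05, 0.05])]
        f1, per_class = mi.macro_f1(recs)
        assert {row["class"] for row in per_class} == {"x"}
        assert f1 == 1.0


class TestOracleEquivalence:
    def brute_force_report(self, recs):
        ranks = []
        for r in recs:
            idx = r.prediction.classes.index(r.true_class)
            p = r.prediction.probabilities
            ranks.append(brute_rank(list(p), r.prediction.classes, r.true_class)
                         if len(p) <= 6 else
                         1 + int((p > p[idx]).sum()) + int((p == p[idx]).sum()) - 1)
        ranks = np.array(ranks)
        return {
            "top1": (ranks <= 1).mean(),
            "top3": (ranks <= 3).mean(),
            "top5": (ranks <= 5).mean(),
            "mrr": (1 / ranks).mean(),
        }

    def test_random_prediction_sets_match_brute_force(self, rng):
        classes = list("abcdef")
        for _ in range(200):
            n = int(rng.integers(1, 30))
            recs = [
                make_record(classes[rng.integers(6)], classes, rng.dirichlet(np.ones(6)))
                for _ in range(n)
            ]
            expected = self.brute_force_report(recs)
            assert mi.top_n(recs, 1) == pytest.approx(expected["top1"], abs=1e-12)
            assert mi.top_n(recs, 3) == pytest.approx(expected["top3"], abs=1e-12)
            assert mi.top_n(recs, 5) == pytest.approx(expected["top5"], abs=1e-12)
            assert mi.mrr(recs) == pytest.approx(expected["mrr"], abs=1e-12)

    def test_metrics_are_permutation_invariant(self, rng):
        classes = list("abcd")
        recs = [
            make_record(classes[rng.integers(4)], classes, rng.dirichlet(np.ones(4)))
            for _ in range(20)
        ]
        shuffled = [recs[i] for i in rng.permutation(20)]
        assert mi.mrr(recs) == mi.mrr(shuffled)
        assert mi.top_n(recs, 2) == mi.top_n(shuffled, 2)
        assert mi.macro_f1(recs)[0] == mi.macro_f1(shuffled)[0]


class TestReport:
    def test_monotone_top_n_and_mrr_bounds(self, rng):
        classes = list("abcdefg")
        recs = [
            make_record(classes[rng.integers(7)], classes, rng.dirichlet(np.ones(7)))
            for _ in range(50)
        ]
        report = score(recs)
        assert 0 <= report.top1 <= report.top3 <= report.top5 <= 1
        assert report.top1 <= report.mrr <= 1

    def test_uniform_identifier_has_top5_one_top1_zero(self):
        """With 5 equiprobable classes every true class ranks 5 under the
        pessimistic tie rule."""
        classes = list("abcde")
        recs = [make_record(c, classes, [0.2] * 5) for c in classes]
        report = score(recs)
        assert report.top5 == 1.0
        assert report.top1 == 0.0
        assert report.mrr == pytest.approx(0.2)

    def test_scaled_presentation_is_out_of_100(self):
        recs = ranked_records([1, 2, 1, 3])
        report = score(recs)
        assert report.scaled()["top1"] == 50.0
        assert report.scaled()["mrr"] == 70.8

    def test_tsv_report_round_trip(self, tmp_path):
        recs = ranked_records([1, 2, 1, 3])
        report = score(recs)
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        text = out.read_text()
        assert "top1\t0.5" in text and "confused_as" in text

    def test_evaluate_on_fitted_identifier(self, fitted_small_identifier, small_genus):
        _, tax, _, _ = small_genus
        fit = fitted_small_identifier
        report = mi.evaluate(fit.identifier, fit.test_records, taxonomy=tax)
        assert report.n == len(fit.test_records)
        assert 0 <= report.top1 <= report.top5 <= 1

    def test_evaluate_empty_test_set_rejected(self, fitted_small_identifier):
        with pytest.raises(ValueError):
            mi.evaluate(fitted_small_identifier.identifier, [])
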