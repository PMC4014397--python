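import numpy as np
import pytest

from superpose.activity import ActivityCurve
from superpose.plate import ConditionSet
from superpose.prediction import (
    predict_dynamics,
    predict_weights,
    predict_weights_iterative,
)


def _restrictions(master: dict[str, float], size: int) -> dict:
    """Exact lower-order weights implied by a master simplex point."""
    full = ConditionSet(*master.keys())
    out = {}
    for sub in full.subsets(size):
        total = sum(master[l] for l in sub.labels)
        out[sub] = {l: master[l] / total for l in sub.labels}
    return out


class TestPredictWeights:
    def test_symmetric_pairs_give_uniform_triplet(self):
        pairs = {
            ConditionSet("A", "B"): {"A": 0.5, "B": 0.5},
            ConditionSet("A", "C"): {"A": 0.5, "C": 0.5},
            ConditionSet("B", "C"): {"B": 0.5, "C": 0.5},
        }
        w = predict_weights(pairs)
        for v in w.values():
            assert v == pytest.approx(1 / 3, abs=1e-12)

    def test_exact_consistency_round_trip_n3(self):
        master = {"A": 0.5, "B": 0.3, "C": 0.2}
        pairs = _restrictions(master, 2)
        # spot-check a restriction against the hand-derived value
        assert pairs[ConditionSet("A", "B")]["A"] == pytest.approx(0.625)
        assert pairs[ConditionSet("A", "C")]["A"] == pytest.approx(0.5 / 0.7)
        w = predict_weights(pairs)
        for label, truth in master.items():
            assert w[label] == pytest.approx(truth, abs=1e-12)

    def test_uniform_quadruplet_closed_form(self):
        # all triplet weights 1/3 -> each raw weight (N-2)/(3·3-1) = 1/4
        master = {l: 0.25 for l in "ABCD"}
        triplets = _restrictions(master, 3)
        for t in triplets.values():
            for v in t.values():
                assert v == pytest.approx(1 / 3)
        w = predict_weights(triplets)
        for v in w.values():
            assert v == pytest.approx(0.25, abs=1e-12)

    def test_exactness_over_random_simplex_points(self, rng):
        for n in (3, 4):
            labels = list("ABCD")[:n]
            for _ in range(200):
                point = rng.dirichlet(np.ones(n))
                point = 0.9 * point + 0.1 / n  # interior of the simplex
                master = dict(zip(labels, point))
                w = predict_weights(_restrictions(master, n - 1))
                err = max(abs(w[l] - master[l]) for l in labels)
                assert err < 1e-9

    def test_zero_weight_propagates(self):
        master = {"A": 0.6, "B": 0.4, "C": 0.0}
        lower = _restrictions(master, 2)
        w = predict_weights(lower)
        assert w["C"] == 0.0
        assert w["A"] + w["B"] == pytest.approx(1.0)

    def test_missing_subset_listed(self):
        pairs = {ConditionSet("A", "B"): {"A": 0.5, "B": 0.5}}
        with pytest.raises(ValueError, match="A\\+C"):
            predict_weights(pairs, target=ConditionSet("A", "B", "C"))

    def test_pairs_alone_cannot_predict_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            predict_weights({ConditionSet("A"): {"A": 1.0}},
                            target=ConditionSet("A", "B"))

    def test_permutation_equivariance(self, rng):
        point = rng.dirichlet(np.ones(3))
        point = 0.9 * point + 0.1 / 3
        master = dict(zip("ABC", point))
        w1 = predict_weights(_restrictions(master, 2))
        relabel = {"A": "X", "B": "Y", "C": "Z"}
        master2 = {relabel[k]: v for k, v in master.items()}
        w2 = predict_weights(_restrictions(master2, 2))
        for old, new in relabel.items():
            assert w1[old] == pytest.approx(w2[new], abs=1e-12)


class TestIterativePrediction:
    def test_exact_round_trip_from_pairs_to_quadruplet(self, rng):
        point = rng.dirichlet(np.ones(4))
        point = 0.9 * point + 0.1 / 4
        master = dict(zip("ABCD", point))
        pairs = _restrictions(master, 2)
        w = predict_weights_iterative(pairs, ConditionSet("A", "B", "C", "D"))
        for label, truth in master.items():
            assert w[label] == pytest.approx(truth, abs=1e-10)

    def test_uniform_pairs_give_uniform_quadruplet(self):
        master = {l: 0.25 for l in "ABCD"}
        w = predict_weights_iterative(
            _restrictions(master, 2), ConditionSet("A", "B", "C", "D")
        )
        for v in w.values():
            assert v == pytest.approx(0.25, abs=1e-12)

    def test_missing_pair_reported(self):
        master = {l: 0.25 for l in "ABCD"}
        pairs = _restrictions(master, 2)
        del pairs[ConditionSet("C", "D")]
        with pytest.raises(ValueError, match="C\\+D"):
            predict_weights_iterative(pairs, ConditionSet("A", "B", "C", "D"))

    def test_noisy_pairs_give_bounded_quadruplet_error(self, rng):
        errs = []
        for _ in range(200):
            point = rng.dirichlet(np.ones(4))
            point = 0.9 * point + 0.1 / 4
            master = dict(zip("ABCD", point))
            pairs = {}
            for sub, w in _restrictions(master, 2).items():
                a = np.clip(w[sub.labels[0]] + rng.uniform(-0.05, 0.05), 1e-6, None)
                b = np.clip(w[sub.labels[1]] + rng.uniform(-0.05, 0.05), 1e-6, None)
                pairs[sub] = {sub.labels[0]: a / (a + b), sub.labels[1]: b / (a + b)}
            w = predict_weights_iterative(pairs, ConditionSet("A", "B", "C", "D"))
            errs.append(max(abs(w[l] - master[l]) for l in "ABCD"))
        assert np.median(errs) < 0.15

    def test_error_grows_continuously_with_noise(self, rng):
        medians = []
        for scale in (0.0, 0.02, 0.05, 0.1):
            errs = []
            for _ in range(100):
                point = 0.9 * rng.dirichlet(np.ones(4)) + 0.1 / 4
                master = dict(zip("ABCD", point))
                pairs = {}
                for sub, w in _restrictions(master, 2).items():
                    a = np.clip(w[sub.labels[0]] + rng.uniform(-scale, scale), 1e-6, None)
                    b = np.clip(w[sub.labels[1]] + rng.uniform(-scale, scale), 1e-6, None)
                    pairs[sub] = {sub.labels[0]: a / (a + b),
                                  sub.labels[1]: b / (a + b)}
                w = predict_weights_iterative(pairs, ConditionSet("A", "B", "C", "D"))
                errs.append(max(abs(w[l] - master[l]) for l in "ABCD"))
            medians.append(np.median(errs))
        assert medians[0] < 1e-9
        assert all(m1 <= m2 + 1e-3 for m1, m2 in zip(medians, medians[1:]))


def _curve(label, values, promoter="p"):
    values = np.asarray(values, float)
    g = np.linspace(0, 6, values.size)
    cond = ConditionSet(label) if isinstance(label, str) else label
    return ActivityCurve(
        promoter=promoter, condition_set=cond, replicate_day=0,
        activity=values, time_min=g * 60.0, generations=g,
    )


class TestPredictDynamics:
    def test_unit_weight_returns_that_single(self, rng):
        singles = [_curve(l, rng.uniform(1, 5, 30)) for l in "ABC"]
        pred = predict_dynamics({"A": 1.0, "B": 0.0, "C": 0.0}, singles)
        np.testing.assert_array_equal(pred.predicted_curve, singles[0].values)

    def test_uniform_weights_on_identical_singles(self):
        v = np.linspace(1, 4, 20)
        singles = [_curve(l, v) for l in "ABC"]
        pred = predict_dynamics({l: 1 / 3 for l in "ABC"}, singles)
        np.testing.assert_allclose(pred.predicted_curve, v, atol=1e-12)

    def test_error_vs_measured_recorded(self, rng):
        singles = [_curve(l, rng.uniform(1, 5, 30)) for l in "AB"]
        w = {"A": 0.4, "B": 0.6}
        truthful = 0.4 * singles[0].values + 0.6 * singles[1].values
        measured = _curve(ConditionSet("A", "B"), truthful)
        pred = predict_dynamics(w, singles, measured=measured)
        assert pred.relative_error_vs_measured == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_truth_mixture_recovered_exactly(self, noiseless_run):
        truth = noiseless_run.truth
        g = np.linspace(0.5, 5.5, 50)
        prom = truth.promoters[0]
        target = ConditionSet(*truth.config.labels[:3])
        singles = [_curve(l, truth.single_curve(prom, l, g), promoter=prom)
                   for l in target.labels]
        w = truth.weights_for(prom, target)
        pred = predict_dynamics(w, singles, target=target)
        np.testing.assert_allclose(
            pred.predicted_curve, truth.activity(prom, target, g), atol=1e-9
        )

    def test_missing_single_rejected(self, rng):
        singles = [_curve("A", rng.uniform(1, 5, 30))]
        with pytest.raises(ValueError, match="B"):
            predict_dynamics({"A": 0.5, "B": 0.5}, singles)
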