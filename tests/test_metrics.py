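"""Metrics engine: confusion counting, conventions, curves, bootstrap, tests."""

import numpy as np
import pytest
from scipy import stats

from conftest import predictions_from_scores, reference_from_strings
from idrbench.metrics import (
    ConfusionMatrix,
    bootstrap_metric,
    compare_methods,
    confusion,
    curves,
    evaluate_at_threshold,
    point_metrics,
)
from idrbench.predictions import round_half_up
from idrbench.references import build_reference


def labels_from(s):
    return np.array([{"P": 1, "N": 0, "M": -1, "1": 1, "0": 0, "-": -1}[c] for c in s])


class TestConfusion:
    def test_perfect_prediction(self):
        cm = confusion(labels_from("PPPPNNNNNN"), np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0]))
        assert (cm.tp, cm.tn, cm.fp, cm.fn, cm.masked) == (4, 6, 0, 0, 0)

    def test_masked_residues_counted_separately(self):
        cm = confusion(labels_from("PPMN"), np.array([1, 0, 1, 1]))
        assert (cm.tp, cm.fn, cm.fp, cm.tn, cm.masked) == (1, 1, 1, 0, 1)

    def test_agrees_with_naive_counter_on_random_fixture(self):
        rng = np.random.default_rng(5)
        labels = rng.choice([-1, 0, 1], size=10_000, p=[0.2, 0.5, 0.3])
        states = rng.integers(0, 2, size=10_000)
        cm = confusion(labels, states)
        tp = fp = fn = tn = masked = 0  # position-by-position recount
        for l, s in zip(labels, states):
            if l == -1:
                masked += 1
            elif l == 1 and s == 1:
                tp += 1
            elif l == 1:
                fn += 1
            elif s == 1:
                fp += 1
            else:
                tn += 1
        assert (cm.tp, cm.fp, cm.fn, cm.tn, cm.masked) == (tp, fp, fn, tn, masked)

    def test_length_mismatch_names_target(self):
        with pytest.raises(ValueError, match="t1"):
            confusion({"t1": labels_from("PN")}, {"t1": np.array([1])})


class TestPointMetricConventions:
    def test_all_negative_prediction_conventions(self):
        m = point_metrics(ConfusionMatrix(tp=0, fp=0, fn=45, tn=601))
        assert (m.mcc, m.f1, m.ppv, m.tnr, m.bac) == (0.0, 0.0, 0.0, 1.0, 0.5)
        assert "mcc" in m.convention_fired and "ppv" in m.convention_fired

    def test_single_class_reference_zeroes_mcc(self):
        # a fully disordered target: no reference negatives -> MCC convention
        m = point_metrics(ConfusionMatrix(tp=10, fp=0, fn=5, tn=0))
        assert m.mcc == 0.0 and "mcc" in m.convention_fired
        assert m.f1 > 0

    def test_negative_mcc_preserved(self):
        m = point_metrics(ConfusionMatrix(tp=7, fp=160, fn=38, tn=441))
        assert m.mcc == pytest.approx(-0.064, abs=5e-4)


class TestCurves:
    def test_perfect_predictor_saturates(self):
        ref = reference_from_strings({"t": "11110000"})
        pset = predictions_from_scores({"t": [1, 1, 1, 1, 0, 0, 0, 0]})
        cs = curves(ref, pset, "dataset")
        assert cs.f_max == 1.0 and cs.auc == 1.0
        assert cs.f_max_threshold <= 1.0

    def test_fmax_ties_break_to_lowest_threshold(self):
        ref = reference_from_strings({"t": "1100"})
        pset = predictions_from_scores({"t": [0.8, 0.6, 0.2, 0.1]})
        cs = curves(ref, pset, "dataset")
        # F1 is maximal on every threshold in (0.2, 0.6]; the grid reports
        # the lowest such threshold
        assert cs.f_max == 1.0
        assert cs.f_max_threshold == pytest.approx(0.201)

    def test_uniform_scores_give_chance_auc(self):
        rng = np.random.default_rng(2)
        n = 20_000
        ref = reference_from_strings(
            {"t": "".join(rng.choice(["0", "1"], size=n, p=[0.7, 0.3]))}
        )
        pset = predictions_from_scores({"t": rng.uniform(size=n).tolist()})
        cs = curves(ref, pset, "dataset")
        assert cs.auc == pytest.approx(0.5, abs=0.02)

    def test_fmax_dominates_default_threshold_f1(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(20, 300))
            ref = reference_from_strings(
                {"t": "".join(rng.choice(["0", "1"], size=n))}
            )
            pset = predictions_from_scores({"t": rng.uniform(size=n).tolist()})
            cs = curves(ref, pset, "dataset")
            _, mset = evaluate_at_threshold(ref, pset, "dataset")
            assert cs.f_max >= mset.f1 - 1e-12

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        n = 3000
        labels = rng.integers(0, 2, size=n)
        # coarse scores so the transform cannot merge distinct values
        scores = round_half_up(rng.integers(0, 101, size=n) / 100.0)
        ref = reference_from_strings({"t": "".join(map(str, labels))})
        cs1 = curves(ref, predictions_from_scores({"t": scores.tolist()}), "dataset")
        transformed = round_half_up(np.sqrt(scores))
        cs2 = curves(ref, predictions_from_scores({"t": transformed.tolist()}), "dataset")
        assert cs2.auc == pytest.approx(cs1.auc, abs=1e-12)

    def test_target_strategy_averages_per_target_metrics(self):
        ref = reference_from_strings({"a": "1100", "b": "1000"})
        pset = predictions_from_scores(
            {"a": [0.9, 0.8, 0.1, 0.2], "b": [0.3, 0.9, 0.1, 0.2]}
        )
        cs = curves(ref, pset, "target")
        # naive per-target recomputation at threshold 0.5
        k = 500
        f1s = []
        for tid, lab in (("a", [1, 1, 0, 0]), ("b", [1, 0, 0, 0])):
            sc = pset.entries[tid].scores
            pred = sc >= 0.5
            tp = int(np.sum(pred & np.array(lab, bool)))
            fp = int(np.sum(pred & ~np.array(lab, bool)))
            fn = int(np.sum(~pred & np.array(lab, bool)))
            f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
        assert cs.f1[k] == pytest.approx(np.mean(f1s))


class TestStrategyEquivalence:
    def test_dataset_confusion_is_sum_of_targets(self, small_dataset):
        from idrbench.synthetic import generate_predictions

        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot_pdb")
        pset = generate_predictions(small_dataset)
        total, _ = evaluate_at_threshold(ref, pset, "dataset", threshold=0.5)
        summed = ConfusionMatrix(0, 0, 0, 0)
        for tid in ref.entries:
            summed = summed + confusion(
                ref.entries[tid].labels,
                (pset.entries[tid].scores >= 0.5).astype(int),
            )
        assert total == summed


class TestBootstrap:
    def test_constant_perfect_predictor_zero_width(self):
        ref = reference_from_strings({"t": "1111100000"})
        pset = predictions_from_scores({"t": [1] * 5 + [0] * 5})
        res = bootstrap_metric(ref, pset, "f1", n_boot=200, seed=1)
        assert res.point_estimate == 1.0
        assert res.ci_width == 0.0
        assert np.all(res.replicate_values == 1.0)

    def test_same_seed_bit_reproducible(self):
        rng = np.random.default_rng(8)
        n = 500
        ref = reference_from_strings({"t": "".join(rng.choice(["0", "1"], size=n))})
        pset = predictions_from_scores({"t": rng.uniform(size=n).tolist()})
        r1 = bootstrap_metric(ref, pset, "mcc", n_boot=300, seed=42)
        r2 = bootstrap_metric(ref, pset, "mcc", n_boot=300, seed=42)
        assert np.array_equal(r1.replicate_values, r2.replicate_values)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_ci_uses_student_t_on_replicates(self):
        rng = np.random.default_rng(3)
        n = 400
        ref = reference_from_strings({"t": "".join(rng.choice(["0", "1"], size=n))})
        pset = predictions_from_scores({"t": rng.uniform(size=n).tolist()})
        res = bootstrap_metric(ref, pset, "f1", n_boot=250, seed=0)
        tcrit = stats.t.ppf(0.975, 249)
        mean = res.replicate_values.mean()
        sd = res.replicate_values.std(ddof=1)
        assert res.ci_low == pytest.approx(mean - tcrit * sd)
        assert res.ci_high == pytest.approx(mean + tcrit * sd)

    def test_fmax_bootstrap_runs(self):
        rng = np.random.default_rng(6)
        n = 300
        ref = reference_from_strings({"t": "".join(rng.choice(["0", "1"], size=n))})
        pset = predictions_from_scores({"t": rng.uniform(size=n).tolist()})
        res = bootstrap_metric(ref, pset, "f_max", n_boot=100, seed=0)
        assert 0.0 <= res.point_estimate <= 1.0
        assert res.ci_low <= res.replicate_values.mean() <= res.ci_high


class TestCompareMethods:
    def test_identical_vectors_give_p_one(self):
        v = [0.5, 0.6, 0.7, 0.8]
        assert compare_methods(v, v) == 1.0

    def test_separated_methods_give_tiny_p(self):
        rng = np.random.default_rng(1)
        a = 0.5 + 0.01 * rng.standard_normal(100)
        b = 0.9 + 0.01 * rng.standard_normal(100)
        p = compare_methods(a, b)
        assert p < 0.001
        # independent recomputation from the t statistic of the differences
        d = a - b
        tstat = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p_manual = 2 * stats.t.sf(abs(tstat), d.size - 1)
        assert p == pytest.approx(p_manual, rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=50)
        b = rng.uniform(size=50)
        assert compare_methods(a, b) == pytest.approx(compare_methods(b, a))

    def test_degenerate_zero_variance_unequal_means(self):
        assert compare_methods([0.5, 0.5], [0.7, 0.7]) == 0.0
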