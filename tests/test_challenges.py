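"""Challenge orchestration: IDP calls, ranking, subsets, report bundles."""

import filecmp

import numpy as np
import pytest

from conftest import predictions_from_scores, reference_from_strings
from idrbench.challenges import (
    idp_challenge,
    load_published_idp_table,
    rank_idp_results,
    run_challenge,
    subset_evaluation,
    write_report,
)
from idrbench.metrics import evaluate_at_threshold
from idrbench.predictions import PredictionEntry, PredictionSet, resolve_threshold
from idrbench.references import build_reference
from idrbench.synthetic import (
    NoisyPredictorSpec,
    ScoreDistribution,
    generate_predictions,
)


def perfect_predictor(dataset):
    return generate_predictions(
        dataset,
        NoisyPredictorSpec(
            pos_dist=ScoreDistribution("point", 1.0),
            neg_dist=ScoreDistribution("point", 0.0),
        ),
        method_name="perfect",
    )


class TestIdpChallenge:
    def test_perfect_predictor_recovers_idp_composition(self, benchmark_dataset):
        """40 of the 646 targets are fully disordered; a perfect predictor
        calls exactly those at the 95% criterion."""
        ref = build_reference(
            benchmark_dataset.targets, benchmark_dataset.annotations, "disprot"
        )
        results = idp_challenge(ref, [perfect_predictor(benchmark_dataset)])
        cm = results["perfect"]["confusion"]
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (40, 606, 0, 0)
        assert results["perfect"]["metrics"].f1 == 1.0

    def test_saturating_predictor(self, small_dataset):
        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot")
        pset = PredictionSet("all-one")
        for t in small_dataset.targets:
            ones = np.ones(t.length)
            pset.entries[t.target_id] = PredictionEntry(
                t.target_id, ones, ones.astype(np.int8)
            )
        resolve_threshold(pset)
        m = idp_challenge(ref, [pset])["all-one"]["metrics"]
        assert m.tpr == 1.0 and m.tnr == 0.0

    def test_threshold_extremes(self, small_dataset):
        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot")
        pset = perfect_predictor(small_dataset)
        every = idp_challenge(ref, [pset], idp_threshold=0.0)["perfect"]
        assert all(c.annotated_idp for c in every["calls"])
        none = idp_challenge(ref, [pset], idp_threshold=1.0001)["perfect"]
        assert not any(c.annotated_idp for c in none["calls"])

    def test_ranking_ties_break_on_method_name(self):
        results = {
            "zeta": {"metrics": type("M", (), {"f1": 0.5})()},
            "alpha": {"metrics": type("M", (), {"f1": 0.5})()},
            "best": {"metrics": type("M", (), {"f1": 0.9})()},
        }
        assert rank_idp_results(results) == ["best", "alpha", "zeta"]

    def test_published_table_well_formed(self):
        rows = load_published_idp_table()
        assert len(rows) == 34
        assert all(r["tn"] + r["fp"] + r["fn"] + r["tp"] == 646 for r in rows)


class TestRunChallenge:
    def test_binding_challenge_with_mostly_negative_targets(self, benchmark_dataset):
        """The binding reference keeps its 414 annotation-free targets and the
        challenge still runs to completion with dataset-strategy metrics."""
        ref = build_reference(
            benchmark_dataset.targets, benchmark_dataset.annotations, "binding"
        )
        n_all_negative = sum(
            1 for e in ref.entries.values() if not (e.labels == 1).any()
        )
        assert n_all_negative == 646 - 232
        pset = generate_predictions(benchmark_dataset, method_name="noisy")
        report = run_challenge(ref, [pset], n_boot=50, seed=0)
        assert "noisy" in report.results
        assert 0.0 <= report.results["noisy"].metrics_dataset.f1 <= 1.0

    def test_report_rerun_is_byte_identical(self, small_dataset, tmp_path):
        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot")
        psets = [
            generate_predictions(small_dataset, NoisyPredictorSpec(seed=s), f"m{s}")
            for s in (1, 2)
        ]
        r1 = run_challenge(ref, psets, n_boot=50, seed=5)
        r2 = run_challenge(ref, psets, n_boot=50, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_report(r1, d1)
        write_report(r2, d2)
        for f in d1.iterdir():
            assert filecmp.cmp(f, d2 / f.name, shallow=False), f.name

    def test_ranking_orders_by_key_descending(self, small_dataset):
        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot")
        good = generate_predictions(small_dataset, NoisyPredictorSpec(seed=1), "good")
        bad = generate_predictions(
            small_dataset,
            NoisyPredictorSpec(
                pos_dist=ScoreDistribution("beta", 2.0, 2.0),
                neg_dist=ScoreDistribution("beta", 2.0, 2.0),
                seed=2,
            ),
            "bad",
        )
        report = run_challenge(ref, [bad, good], n_boot=50, seed=0)
        ranking = report.ranking()
        fmax = {m: report.results[m].curves_dataset.f_max for m in ranking}
        assert sorted(fmax.values(), reverse=True) == [fmax[m] for m in ranking]

    def test_unreadable_method_listed_in_exclusions(self, small_dataset):
        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot")
        incomplete = PredictionSet("broken")
        incomplete.entries["nonexistent"] = PredictionEntry(
            "nonexistent", np.array([0.5])
        )
        resolve_threshold(incomplete)
        ok = generate_predictions(small_dataset, method_name="ok")
        report = run_challenge(ref, [incomplete, ok], n_boot=20, seed=0)
        assert report.excluded == ["broken"]
        assert list(report.results) == ["ok"]


class TestSubsets:
    def test_full_subset_matches_run_challenge(self, small_dataset):
        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot")
        pset = generate_predictions(small_dataset, method_name="m")
        full = run_challenge(ref, [pset], n_boot=30, seed=2)
        sub = subset_evaluation(
            ref, [pset], list(ref.entries), n_boot=30, seed=2
        )
        a, b = full.results["m"], sub.results["m"]
        assert a.confusion == b.confusion
        assert a.curves_dataset.f_max == b.curves_dataset.f_max
        assert np.array_equal(
            a.bootstrap.replicate_values, b.bootstrap.replicate_values
        )

    def test_disjoint_subsets_sum_to_full_confusion(self, small_dataset):
        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot")
        pset = generate_predictions(small_dataset, method_name="m")
        ids = sorted(ref.entries)
        half = len(ids) // 2
        r1 = subset_evaluation(ref, [pset], ids[:half], n_boot=2, seed=0)
        r2 = subset_evaluation(ref, [pset], ids[half:], n_boot=2, seed=0)
        full = run_challenge(ref, [pset], n_boot=2, seed=0)
        assert (
            r1.results["m"].confusion + r2.results["m"].confusion
            == full.results["m"].confusion
        )

    def test_target_strategy_mean_restricts_correctly(self, small_dataset):
        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot")
        pset = generate_predictions(small_dataset, method_name="m")
        ids = sorted(ref.entries)[:7]
        sub = subset_evaluation(ref, [pset], ids, n_boot=2, seed=0)
        # naive loop over just those targets
        per_target = []
        for tid in ids:
            single_ref = reference_from_strings(
                {tid: "".join("10-"[{1: 0, 0: 1, -1: 2}[int(v)]] for v in ref.entries[tid].labels)}
            )
            single_pred = predictions_from_scores(
                {tid: pset.entries[tid].scores.tolist()}
            )
            _, m = evaluate_at_threshold(single_ref, single_pred, "dataset", threshold=0.5)
            per_target.append(m.f1)
        assert sub.results["m"].metrics_target.f1 == pytest.approx(
            np.mean(per_target)
        )

    def test_empty_intersection_rejected(self, small_dataset):
        ref = build_reference(small_dataset.targets, small_dataset.annotations, "disprot")
        pset = generate_predictions(small_dataset, method_name="m")
        with pytest.raises(ValueError, match="empty intersection"):
            subset_evaluation(ref, [pset], ["nope"], n_boot=2)
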