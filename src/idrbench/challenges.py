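"""Challenge orchestration: disorder, binding and fully disordered proteins.

``run_challenge`` evaluates a set of methods against one reference and
produces a self-describing report bundle: per-method threshold curves,
point metrics at the resolved default threshold, bootstrap confidence
intervals, a pairwise significance matrix and a ranking table, with
deterministic ordering (rank key descending, method name as tie-break).

``idp_challenge`` is the protein-level classification task: a target
counts as a fully disordered protein (IDP) when at least 95% of its
residues are annotated — or predicted — disordered; methods are ranked by
protein-level F1.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from idrbench.metrics import (
    BootstrapResult,
    ConfusionMatrix,
    CurveSet,
    MetricSet,
    POINT_METRIC_NAMES,
    bootstrap_metric,
    compare_methods,
    curves,
    evaluate_at_threshold,
    point_metrics,
)
from idrbench.predictions import PredictionSet, resolve_threshold
from idrbench.references import POSITIVE, ReferenceSet

logger = logging.getLogger(__name__)


@dataclass
class IdpCall:
    """Protein-level disorder call for one target under one method."""

    target_id: str
    annotated_fraction: float
    predicted_fraction: float
    annotated_idp: bool
    predicted_idp: bool


@dataclass
class MethodResult:
    """Everything computed for one method against one reference."""

    method_name: str
    reference_mode: str
    threshold: float
    confusion: ConfusionMatrix
    metrics_dataset: MetricSet
    metrics_target: MetricSet
    curves_dataset: CurveSet
    curves_target: CurveSet
    bootstrap: Optional[BootstrapResult] = None


@dataclass
class ChallengeReport:
    reference_mode: str
    rank_by: str
    seed: int
    results: dict[str, MethodResult] = field(default_factory=dict)
    pairwise_pvalues: dict[tuple[str, str], float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def ranking(self) -> list[str]:
        """Method names sorted by the rank key (3-decimal), descending.

        Keys equal to three decimals tie-break deterministically on the
        method name.
        """

        def key(name: str) -> tuple[float, str]:
            r = self.results[name]
            if self.rank_by == "f_max":
                v = r.curves_dataset.f_max
            elif self.rank_by == "auc":
                v = r.curves_dataset.auc
            else:
                v = getattr(r.metrics_dataset, self.rank_by)
            return (-round(v, 3), name)

        return sorted(self.results, key=key)


def evaluate_method(
    reference: ReferenceSet,
    predictions: PredictionSet,
    n_boot: int = 1000,
    seed: int = 0,
    bootstrap_of: Optional[str] = "f1",
) -> MethodResult:
    """Full single-method evaluation: curves, point metrics, bootstrap."""
    if predictions.effective_threshold is None:
        resolve_threshold(predictions)
    thr = predictions.effective_threshold
    cm, mset = evaluate_at_threshold(reference, predictions, "dataset")
    _, mset_t = evaluate_at_threshold(reference, predictions, "target")
    result = MethodResult(
        method_name=predictions.method_name,
        reference_mode=reference.mode.value,
        threshold=float(thr),
        confusion=cm,
        metrics_dataset=mset,
        metrics_target=mset_t,
        curves_dataset=curves(reference, predictions, "dataset"),
        curves_target=curves(reference, predictions, "target"),
    )
    if bootstrap_of is not None:
        result.bootstrap = bootstrap_metric(
            reference, predictions, metric=bootstrap_of,
            n_boot=n_boot, seed=seed,
        )
    return result


def run_challenge(
    reference: ReferenceSet,
    predictions: Sequence[PredictionSet],
    rank_by: str = "f_max",
    n_boot: int = 1000,
    seed: int = 0,
    bootstrap_of: str = "f1",
    threads: int = 1,
) -> ChallengeReport:
    """Evaluate every method and assemble the challenge report.

    Methods whose evaluation fails (malformed or incomplete predictions)
    are skipped, logged, and listed in the report's exclusions.  Pairwise
    two-sided p-values pair the methods' bootstrap replicate vectors by
    replicate index (each method is resampled with the same seed).
    """
    report = ChallengeReport(
        reference_mode=reference.mode.value, rank_by=rank_by, seed=seed
    )

    def one(pset: PredictionSet) -> Optional[MethodResult]:
        try:
            return evaluate_method(
                reference, pset, n_boot=n_boot, seed=seed, bootstrap_of=bootstrap_of
            )
        except (ValueError, KeyError) as exc:
            logger.error("skipping method %s: %s", pset.method_name, exc)
            return None

    if threads > 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=threads)(delayed(one)(p) for p in predictions)
    else:
        outcomes = [one(p) for p in predictions]
    for pset, res in zip(predictions, outcomes):
        if res is None:
            report.excluded.append(pset.method_name)
        else:
            report.results[pset.method_name] = res

    names = sorted(report.results)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, rb = report.results[a], report.results[b]
            if ra.bootstrap is None or rb.bootstrap is None:
                continue
            p = compare_methods(
                ra.bootstrap.replicate_values, rb.bootstrap.replicate_values
            )
            report.pairwise_pvalues[(a, b)] = p
    return report


def subset_evaluation(
    reference: ReferenceSet,
    predictions: Sequence[PredictionSet],
    target_ids: Sequence[str],
    **kwargs,
) -> ChallengeReport:
    """Run the challenge machinery on a restriction of the reference."""
    subset = set(target_ids)
    known = subset & set(reference.entries)
    if not known:
        raise ValueError("subset has empty intersection with the reference")
    if known != subset:
        raise ValueError(
            f"subset ids not in reference: {sorted(subset - known)}"
        )
    restricted = ReferenceSet(
        reference.mode,
        {t: reference.entries[t] for t in known},
        provenance=f"{reference.provenance}; subset of {len(known)} targets",
    )
    restricted_preds = []
    for pset in predictions:
        clone = PredictionSet(
            pset.method_name,
            {t: e for t, e in pset.entries.items() if t in known},
            declared_threshold=pset.declared_threshold,
            effective_threshold=pset.effective_threshold,
        )
        restricted_preds.append(clone)
    return run_challenge(restricted, restricted_preds, **kwargs)


# ---------------------------------------------------------------------------
# fully disordered proteins


def idp_challenge(
    reference: ReferenceSet,
    predictions: Sequence[PredictionSet],
    idp_threshold: float = 0.95,
) -> dict[str, dict]:
    """Protein-level separation of fully disordered proteins.

    A target is an annotated IDP when its fraction of disorder-positive
    residues (over the full sequence length) is at least ``idp_threshold``;
    it is a predicted IDP when the fraction of state-positive residues
    reaches the same threshold.  Returns, per method, the protein-level
    confusion matrix, the metric set and the individual calls; iterate
    sorted by descending F1 for the ranking.
    """
    annotated: dict[str, float] = {
        tid: float(np.mean(entry.labels == POSITIVE))
        for tid, entry in reference.entries.items()
    }
    out: dict[str, dict] = {}
    for pset in predictions:
        if pset.effective_threshold is None:
            resolve_threshold(pset)
        calls: list[IdpCall] = []
        tp = fp = fn = tn = 0
        for tid in sorted(reference.entries):
            if tid not in pset.entries:
                raise ValueError(
                    f"method {pset.method_name!r}: no prediction for {tid!r}"
                )
            entry = pset.entries[tid]
            pred_frac = float(np.mean(entry.states))
            ann_idp = annotated[tid] >= idp_threshold
            pred_idp = pred_frac >= idp_threshold
            calls.append(
                IdpCall(tid, annotated[tid], pred_frac, ann_idp, pred_idp)
            )
            tp += ann_idp and pred_idp
            fn += ann_idp and not pred_idp
            fp += pred_idp and not ann_idp
            tn += not ann_idp and not pred_idp
        cm = ConfusionMatrix(int(tp), int(fp), int(fn), int(tn))
        out[pset.method_name] = {
            "confusion": cm,
            "metrics": point_metrics(cm),
            "calls": calls,
        }
    return out


def rank_idp_results(results: dict[str, dict]) -> list[str]:
    """Method names of an IDP challenge, by F1 descending then name."""
    return sorted(
        results, key=lambda m: (-round(results[m]["metrics"].f1, 3), m)
    )


def load_published_idp_table() -> list[dict]:
    """The published protein-level confusion table shipped with the package.

    Each row carries a method name, its (tn, fp, fn, tp) counts over the
    646-target benchmark and the six printed metric columns; used as exact
    test vectors for the metric conventions.
    """
    text = (
        resources.files("idrbench.data")
        .joinpath("fully_disordered_benchmark.tsv")
        .read_text()
    )
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    rows = []
    for rec in reader:
        row: dict = {"method": rec["method"], "baseline": rec["baseline"] == "1"}
        for k in ("tn", "fp", "fn", "tp"):
            row[k] = int(rec[k])
        for k in ("mcc", "f1", "tnr", "tpr", "ppv", "bac"):
            row[k] = float(rec[k])
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# report serialization


def _curve_rows(cs: CurveSet) -> list[dict]:
    return [
        {
            "threshold": float(cs.thresholds[i]),
            "precision": float(cs.precision[i]),
            "recall": float(cs.recall[i]),
            "tpr": float(cs.tpr[i]),
            "fpr": float(cs.fpr[i]),
            "f1": float(cs.f1[i]),
        }
        for i in range(cs.thresholds.size)
    ]


def write_report(report: ChallengeReport, outdir: Union[str, Path]) -> None:
    """Write the ranking TSV/JSON, curve tables and p-value matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    header = (
        ["method", "reference_mode", "strategy", "threshold"]
        + list(POINT_METRIC_NAMES)
        + ["f_max", "f_max_threshold", "auc", "ci_low", "ci_high"]
    )
    rows = []
    json_rows = []
    for name in report.ranking():
        r = report.results[name]
        for strategy in ("dataset", "target"):
            mset = r.metrics_dataset if strategy == "dataset" else r.metrics_target
            cs = r.curves_dataset if strategy == "dataset" else r.curves_target
            row: dict = {
                "method": name,
                "reference_mode": r.reference_mode,
                "strategy": strategy,
                "threshold": r.threshold,
            }
            row.update({k: round(v, 3) for k, v in mset.as_dict().items()})
            row.update(
                {
                    "f_max": round(cs.f_max, 3),
                    "f_max_threshold": cs.f_max_threshold,
                    "auc": round(cs.auc, 3),
                    "ci_low": (
                        round(r.bootstrap.ci_low, 3) if r.bootstrap else ""
                    ),
                    "ci_high": (
                        round(r.bootstrap.ci_high, 3) if r.bootstrap else ""
                    ),
                }
            )
            rows.append(row)
            json_rows.append(row)
        (outdir / f"curves_{name}.tsv").write_text(
            "threshold\tprecision\trecall\ttpr\tfpr\tf1\n"
            + "\n".join(
                "\t".join(f"{cr[c]:.6g}" for c in (
                    "threshold", "precision", "recall", "tpr", "fpr", "f1"
                ))
                for cr in _curve_rows(r.curves_dataset)
            )
            + "\n"
        )

    with (outdir / "ranking.tsv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=header, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)

    payload = {
        "reference_mode": report.reference_mode,
        "rank_by": report.rank_by,
        "seed": report.seed,
        "ranking": report.ranking(),
        "excluded": report.excluded,
        "rows": json_rows,
        "pairwise_pvalues": [
            {"method_a": a, "method_b": b, "pvalue": p}
            for (a, b), p in sorted(report.pairwise_pvalues.items())
        ],
    }
    (outdir / "ranking.json").write_text(json.dumps(payload, indent=2) + "\n")
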