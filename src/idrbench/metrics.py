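"""Confusion matrices, point metrics, threshold curves, bootstrap and tests.

Conventions, applied uniformly:

* masked reference residues are excluded from every count;
* prediction is positive when ``score >= threshold`` (non-strict);
* the threshold grid is ``{0.000, 0.001, ..., 1.000}`` (step 0.001), which
  covers every representable rounded score;
* F-beta (0.5, 1, 2), precision, recall, specificity and FPR are set to 0
  when their denominator is 0;
* MCC is set to 0 whenever any confusion-matrix marginal (predicted
  positives, predicted negatives, reference positives, reference negatives)
  is 0 — in particular for fully disordered targets and for methods
  predicting everything one class;
* ROC points are augmented with (0,0) and (1,1) before trapezoidal
  integration, so the AUC is defined even for degenerate score
  distributions;
* ties in F_max are broken toward the lowest threshold (maximal recall at
  equal F1).

Two evaluation strategies are supported.  The *dataset* strategy
concatenates the residues of all targets and computes one confusion matrix
per threshold; it is exactly equivalent to summing per-target confusion
matrices.  The *target* strategy computes the metrics per target and takes
their unweighted mean.

The bootstrap resamples residues (label, score pairs) with replacement
1000 times; confidence intervals use the Student t-distribution at
alpha = 0.05: ``replicate mean +/- t(0.975, n_boot - 1) * replicate
standard deviation``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from idrbench.predictions import SCORE_SCALE, PredictionSet
from idrbench.references import MASKED, POSITIVE, ReferenceSet

logger = logging.getLogger(__name__)

N_BINS = SCORE_SCALE + 1  # score grid 0.000 .. 1.000
THRESHOLDS = np.arange(N_BINS) / SCORE_SCALE

POINT_METRIC_NAMES = ("f1", "f05", "f2", "mcc", "tnr", "tpr", "ppv", "fpr", "bac")
CURVE_METRIC_NAMES = ("f_max", "auc")


@dataclass
class ConfusionMatrix:
    """TP/FP/FN/TN counts plus the number of masked (excluded) residues."""

    tp: int
    fp: int
    fn: int
    tn: int
    masked: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "masked"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.masked + other.masked,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict[str, int]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "masked": self.masked,
        }


@dataclass
class MetricSet:
    """Point metrics of one confusion matrix, conventions applied.

    ``convention_fired`` lists the metrics whose denominator was zero and
    were therefore set to the convention value 0.
    """

    f1: float
    f05: float
    f2: float
    mcc: float
    tnr: float
    tpr: float
    ppv: float
    fpr: float
    bac: float
    convention_fired: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in POINT_METRIC_NAMES}


@dataclass
class CurveSet:
    """Per-threshold metric columns plus the derived summary statistics."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    f1: np.ndarray
    f_max: float
    f_max_threshold: float
    auc: float


@dataclass
class BootstrapResult:
    point_estimate: float
    replicate_values: np.ndarray
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    n_convention_replicates: int = 0

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


# ---------------------------------------------------------------------------
# confusion counting


def _pair_arrays(
    reference_labels: Union[np.ndarray, Mapping[str, np.ndarray]],
    predicted: Union[np.ndarray, Mapping[str, np.ndarray]],
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    if isinstance(reference_labels, Mapping):
        if not isinstance(predicted, Mapping):
            raise TypeError("predicted must be a mapping when reference is")
        missing = set(reference_labels) - set(predicted)
        if missing:
            raise ValueError(f"missing predictions for targets: {sorted(missing)}")
        return [
            (tid, np.asarray(reference_labels[tid]), np.asarray(predicted[tid]))
            for tid in sorted(reference_labels)
        ]
    return [("", np.asarray(reference_labels), np.asarray(predicted))]


def confusion(
    reference_labels: Union[np.ndarray, Mapping[str, np.ndarray]],
    predicted_states: Union[np.ndarray, Mapping[str, np.ndarray]],
) -> ConfusionMatrix:
    """Count TP/FP/FN/TN over one target or a mapping of targets.

    Reference labels are ternary (1 positive, 0 negative, -1 masked);
    masked residues contribute only to the masked count.
    """
    tp = fp = fn = tn = masked = 0
    for tid, labels, states in _pair_arrays(reference_labels, predicted_states):
        if labels.size != states.size:
            raise ValueError(
                f"length mismatch for target {tid!r}: "
                f"{labels.size} labels vs {states.size} states"
            )
        m = labels == MASKED
        masked += int(m.sum())
        lab = labels[~m]
        st = states[~m].astype(bool)
        pos = lab == POSITIVE
        tp += int(np.sum(pos & st))
        fn += int(np.sum(pos & ~st))
        fp += int(np.sum(~pos & st))
        tn += int(np.sum(~pos & ~st))
    return ConfusionMatrix(tp, fp, fn, tn, masked)


# ---------------------------------------------------------------------------
# point metrics (vectorized kernels shared by curves and bootstrap)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    np.divide(num, den, out=out, where=den > 0)
    return out


def _fbeta(tp, fp, fn, beta: float) -> np.ndarray:
    b2 = beta * beta
    return _safe_div((1 + b2) * np.asarray(tp, dtype=float), (1 + b2) * tp + b2 * fn + fp)


def _mcc(tp, fp, fn, tn) -> np.ndarray:
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    fn = np.asarray(fn, dtype=float)
    tn = np.asarray(tn, dtype=float)
    den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    num = tp * tn - fp * fn
    out = np.zeros(np.broadcast_shapes(num.shape, den2.shape))
    np.divide(num, np.sqrt(den2, where=den2 > 0, out=np.ones_like(den2)),
              out=out, where=den2 > 0)
    return out


def _metric_columns(tp, fp, fn, tn) -> dict[str, np.ndarray]:
    """All point metrics for (possibly vectorized) confusion counts."""
    ppv = _safe_div(tp, np.add(tp, fp))
    tpr = _safe_div(tp, np.add(tp, fn))
    tnr = _safe_div(tn, np.add(tn, fp))
    fpr = _safe_div(fp, np.add(fp, tn))
    return {
        "f1": _fbeta(tp, fp, fn, 1.0),
        "f05": _fbeta(tp, fp, fn, 0.5),
        "f2": _fbeta(tp, fp, fn, 2.0),
        "mcc": _mcc(tp, fp, fn, tn),
        "tnr": tnr,
        "tpr": tpr,
        "ppv": ppv,
        "fpr": fpr,
        "bac": (tpr + tnr) / 2.0,
    }


def point_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Compute the full metric set of a confusion matrix.

    Zero denominators yield the convention value 0 and are recorded in
    ``convention_fired``.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    cols = _metric_columns(
        np.array(tp), np.array(fp), np.array(fn), np.array(tn)
    )
    fired: list[str] = []
    if tp + fp == 0:
        fired.append("ppv")
    if tp + fn == 0:
        fired.extend(["tpr"])
    if tn + fp == 0:
        fired.extend(["tnr", "fpr"])
    if 2 * tp + fp + fn == 0:
        fired.extend(["f1", "f05", "f2"])
    if min(tp + fp, tp + fn, tn + fp, tn + fn) == 0:
        fired.append("mcc")
    return MetricSet(
        **{k: float(v) for k, v in cols.items()}, convention_fired=fired
    )


# ---------------------------------------------------------------------------
# score binning (the backbone of curves and bootstrap)


def _score_bins(scores: np.ndarray) -> np.ndarray:
    idx = np.rint(np.asarray(scores, dtype=float) * SCORE_SCALE).astype(np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= N_BINS):
        raise ValueError("scores outside [0, 1] after rounding")
    return idx


def binned_counts(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram rounded scores of unmasked residues by reference label.

    Returns ``(pos_counts, neg_counts)``, each of length 1001; bin *k*
    counts residues with rounded score ``k / 1000``.
    """
    labels = np.asarray(labels)
    keep = labels != MASKED
    idx = _score_bins(np.asarray(scores)[keep])
    lab = labels[keep]
    pos = np.bincount(idx[lab == POSITIVE], minlength=N_BINS)
    neg = np.bincount(idx[lab != POSITIVE], minlength=N_BINS)
    return pos, neg


def threshold_index(threshold: float) -> int:
    """Grid index of the lowest representable score >= threshold."""
    return int(np.ceil(threshold * SCORE_SCALE - 1e-9))


def confusion_from_counts(
    pos: np.ndarray, neg: np.ndarray, threshold: float, masked: int = 0
) -> ConfusionMatrix:
    k = threshold_index(threshold)
    tp = int(pos[k:].sum())
    fp = int(neg[k:].sum())
    return ConfusionMatrix(tp, fp, int(pos.sum()) - tp, int(neg.sum()) - fp, masked)


def _cumulative_cells(pos: np.ndarray, neg: np.ndarray):
    """Per-threshold tp/fp/fn/tn along the last axis of stacked histograms."""
    tp = np.flip(np.cumsum(np.flip(pos, axis=-1), axis=-1), axis=-1)
    fp = np.flip(np.cumsum(np.flip(neg, axis=-1), axis=-1), axis=-1)
    p = pos.sum(axis=-1, keepdims=True)
    n = neg.sum(axis=-1, keepdims=True)
    return tp, fp, p - tp, n - fp


def _roc_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area over ROC points augmented with (0,0) and (1,1)."""
    x = np.concatenate([fpr, [0.0, 1.0]])
    y = np.concatenate([tpr, [0.0, 1.0]])
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))


def _collect_pairs(
    reference: ReferenceSet, predictions: PredictionSet
) -> list[tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for tid in reference.target_ids:
        entry = reference.entries[tid]
        if tid not in predictions.entries:
            raise ValueError(
                f"method {predictions.method_name!r}: no prediction for "
                f"target {tid!r}"
            )
        pred = predictions.entries[tid]
        if pred.length != entry.length:
            raise ValueError(
                f"target {tid!r}: prediction length {pred.length} != "
                f"reference length {entry.length}"
            )
        pairs.append((entry.labels, pred.scores))
    return pairs


def curves(
    reference: ReferenceSet,
    predictions: PredictionSet,
    strategy: str = "dataset",
) -> CurveSet:
    """Precision/recall/ROC columns over the full threshold grid.

    ``strategy='dataset'`` evaluates one confusion matrix per threshold on
    the concatenated residues; ``strategy='target'`` averages per-target
    metric values (unweighted) per threshold.  F_max is the maximum of the
    F1 column, reported at the lowest threshold attaining it; AUC is the
    trapezoidal area under the (possibly averaged) ROC points augmented
    with the (0,0) and (1,1) endpoints.
    """
    if strategy not in ("dataset", "target"):
        raise ValueError(f"unknown strategy {strategy!r}")
    pairs = _collect_pairs(reference, predictions)
    hists = [binned_counts(lab, sc) for lab, sc in pairs]
    pos = np.stack([h[0] for h in hists])
    neg = np.stack([h[1] for h in hists])

    if strategy == "dataset":
        tp, fp, fn, tn = _cumulative_cells(pos.sum(0), neg.sum(0))
        cols = _metric_columns(tp, fp, fn, tn)
    else:
        tp, fp, fn, tn = _cumulative_cells(pos, neg)  # (targets, 1001)
        per_target = _metric_columns(tp, fp, fn, tn)
        cols = {k: v.mean(axis=0) for k, v in per_target.items()}

    f1 = cols["f1"]
    best = int(np.argmax(f1))  # argmax returns the first (lowest) threshold
    return CurveSet(
        thresholds=THRESHOLDS.copy(),
        precision=cols["ppv"],
        recall=cols["tpr"],
        tpr=cols["tpr"],
        fpr=cols["fpr"],
        f1=f1,
        f_max=float(f1[best]),
        f_max_threshold=float(THRESHOLDS[best]),
        auc=_roc_auc(cols["fpr"], cols["tpr"]),
    )


def evaluate_at_threshold(
    reference: ReferenceSet,
    predictions: PredictionSet,
    strategy: str = "dataset",
    threshold: Optional[float] = None,
) -> tuple[ConfusionMatrix, MetricSet]:
    """Confusion matrix and point metrics at one decision threshold.

    With the target strategy the returned confusion matrix is still the
    dataset-level sum (counts do not average meaningfully) while the
    metric set holds the unweighted per-target means.
    """
    if threshold is None:
        if predictions.effective_threshold is None:
            raise ValueError("threshold not resolved; call resolve_threshold first")
        threshold = predictions.effective_threshold
    pairs = _collect_pairs(reference, predictions)
    masked = sum(int(np.sum(lab == MASKED)) for lab, _ in pairs)
    hists = [binned_counts(lab, sc) for lab, sc in pairs]
    k = threshold_index(threshold)
    tp = np.array([int(h[0][k:].sum()) for h in hists])
    fp = np.array([int(h[1][k:].sum()) for h in hists])
    fn = np.array([int(h[0].sum()) - t for h, t in zip(hists, tp)])
    tn = np.array([int(h[1].sum()) - f for h, f in zip(hists, fp)])
    total = ConfusionMatrix(
        int(tp.sum()), int(fp.sum()), int(fn.sum()), int(tn.sum()), masked
    )
    if strategy == "dataset":
        return total, point_metrics(total)
    if strategy != "target":
        raise ValueError(f"unknown strategy {strategy!r}")
    cols = _metric_columns(tp, fp, fn, tn)
    means = {kk: float(v.mean()) for kk, v in cols.items()}
    return total, MetricSet(**means, convention_fired=[])


# ---------------------------------------------------------------------------
# bootstrap


def _metric_from_counts(
    name: str, pos: np.ndarray, neg: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Metric value(s) and convention-fired flags from stacked histograms.

    ``pos``/``neg`` may be 1-D (one sample) or 2-D (replicates, bins).
    """
    if name in POINT_METRIC_NAMES:
        k = threshold_index(threshold)
        tp = pos[..., k:].sum(axis=-1)
        fp = neg[..., k:].sum(axis=-1)
        fn = pos.sum(axis=-1) - tp
        tn = neg.sum(axis=-1) - fp
        value = _metric_columns(tp, fp, fn, tn)[name]
        if name in ("f1", "f05", "f2"):
            fired = 2 * tp + fp + fn == 0
        elif name == "mcc":
            fired = (
                np.minimum.reduce([tp + fp, tp + fn, tn + fp, tn + fn]) == 0
            )
        elif name == "ppv":
            fired = tp + fp == 0
        elif name == "tpr":
            fired = tp + fn == 0
        elif name in ("tnr", "fpr"):
            fired = tn + fp == 0
        else:  # bac
            fired = (tp + fn == 0) | (tn + fp == 0)
        return np.atleast_1d(value), np.atleast_1d(fired)
    if name in CURVE_METRIC_NAMES:
        pos2 = np.atleast_2d(pos)
        neg2 = np.atleast_2d(neg)
        tp, fp, fn, tn = _cumulative_cells(pos2, neg2)
        if name == "f_max":
            value = _metric_columns(tp, fp, fn, tn)["f1"].max(axis=-1)
        else:
            fpr = _safe_div(fp, fp + tn)
            tpr = _safe_div(tp, tp + fn)
            value = np.array(
                [_roc_auc(fpr[i], tpr[i]) for i in range(fpr.shape[0])]
            )
        fired = (pos2.sum(axis=-1) == 0) | (neg2.sum(axis=-1) == 0)
        return value, fired
    raise ValueError(f"unknown metric {name!r}")


def bootstrap_metric(
    reference: ReferenceSet,
    predictions: PredictionSet,
    metric: str = "f1",
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    threshold: Optional[float] = None,
) -> BootstrapResult:
    """Residue-level bootstrap of one evaluation metric.

    The concatenated unmasked (label, rounded score) pairs are resampled
    with replacement ``n_boot`` times; because residues are exchangeable
    the resample is drawn as a multinomial over the joint
    label x score-bin histogram, which is exact and fast.  Replicates on
    which the metric is undefined use the convention value 0 and are
    counted in ``n_convention_replicates``.
    """
    if threshold is None:
        threshold = (
            predictions.effective_threshold
            if predictions.effective_threshold is not None
            else 0.5
        )
    pairs = _collect_pairs(reference, predictions)
    pos = np.zeros(N_BINS, dtype=np.int64)
    neg = np.zeros(N_BINS, dtype=np.int64)
    for lab, sc in pairs:
        p, n = binned_counts(lab, sc)
        pos += p
        neg += n
    n_res = int(pos.sum() + neg.sum())
    if n_res < 2:
        raise ValueError("bootstrap requires at least 2 unmasked residues")

    point, _ = _metric_from_counts(metric, pos, neg, threshold)
    cells = np.concatenate([pos, neg]).astype(float)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_res, cells / n_res, size=n_boot)
    rep_pos = draws[:, :N_BINS]
    rep_neg = draws[:, N_BINS:]
    values, fired = _metric_from_counts(metric, rep_pos, rep_neg, threshold)

    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    tcrit = float(stats.t.ppf(1 - alpha / 2, n_boot - 1))
    return BootstrapResult(
        point_estimate=float(point[0]),
        replicate_values=values,
        ci_low=mean - tcrit * sd,
        ci_high=mean + tcrit * sd,
        alpha=alpha,
        n_convention_replicates=int(np.sum(fired)),
    )


def compare_methods(
    values_a: Sequence[float], values_b: Sequence[float]
) -> float:
    """Two-sided paired t-test p-value between two methods' metric vectors.

    The vectors pair per bootstrap replicate (or per target) and must have
    equal length >= 2.  Zero variance of the differences is degenerate:
    p = 1 when the means agree, else the 0-limit (flagged via a log
    warning).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.isclose(diffs.mean(), 0.0):
            return 1.0
        logger.warning("zero-variance differences with unequal means: p -> 0")
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)
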