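"""Synthetic assessment fixtures: sequences, annotations, profiles, predictors.

The generator emits complete, ground-truthed inputs in exactly the formats
the rest of the package consumes, so every pipeline stage is testable
without external data.  Defaults mirror the composition of the curated
disorder benchmark this toolkit assesses against: 646 targets, of which 40
are fully disordered proteins (>= 95% disordered residues) and 232 carry a
binding annotation inside a disordered region; disorder regions are at
least 10 residues long, the curation minimum.

Lengths follow a log-normal distribution (median 250 residues); this
imitates the scale of real protein length distributions without claiming
to match any database exactly.  Noisy predictors draw scores from
two class-conditional distributions on [0, 1] (Beta shapes or point
masses), for which the expected AUC — ``P(S+ > S-) + P(S+ = S-) / 2`` on
the rounded score grid — is computable by direct numerical integration and
serves as an oracle for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import stats

from idrbench.baselines import AMINO_ACIDS, FrequencyProfile, background_vector
from idrbench.predictions import (
    PredictionEntry,
    PredictionSet,
    SCORE_SCALE,
    round_half_up,
    resolve_threshold,
)
from idrbench.references import (
    AnnotationClass,
    IntervalAnnotation,
    TargetSequence,
    intervals_to_mask,
)

_MAX_PLACEMENT_ATTEMPTS = 500


@dataclass
class FixtureSpec:
    """Knobs of the synthetic dataset generator.

    ``disorder_density`` is the expected fraction of residues inside
    disorder regions on targets that are not fully disordered;
    ``structure_coverage`` is the probability that a maximal ordered run
    is covered by an observed-structure interval, and
    ``structure_overlap`` the probability that such an interval bleeds a
    few residues into adjacent disorder (exercising the precedence rule).
    """

    n_targets: int = 646
    length_median: float = 250.0
    length_sigma: float = 0.6
    min_length: int = 30
    max_length: int = 2500
    disorder_density: float = 0.25
    min_interval_length: int = 10
    structure_coverage: float = 0.8
    structure_overlap: float = 0.3
    binding_target_fraction: float = 232 / 646
    binding_within_disorder_fraction: float = 0.5
    idp_fraction: float = 40 / 646
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "disorder_density",
            "structure_coverage",
            "structure_overlap",
            "binding_target_fraction",
            "binding_within_disorder_fraction",
            "idp_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_interval_length < 1:
            raise ValueError("min_interval_length must be >= 1")
        if self.min_length < self.min_interval_length:
            raise ValueError("min_length must fit at least one interval")


@dataclass
class ScoreDistribution:
    """A distribution on [0, 1]: Beta(a, b) or a point mass.

    ``ScoreDistribution("beta", 4, 1.5)`` or ``ScoreDistribution("point", 1.0)``.
    """

    kind: str
    a: float
    b: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "point":
            return np.full(size, self.a)
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size=size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def grid_pmf(self) -> np.ndarray:
        """Probability mass of the half-up-rounded score on the 1001 grid."""
        if self.kind == "point":
            pmf = np.zeros(SCORE_SCALE + 1)
            pmf[int(np.floor(round(self.a * SCORE_SCALE, 6) + 0.5))] = 1.0
            return pmf
        edges = (np.arange(SCORE_SCALE + 2) - 0.5) / SCORE_SCALE
        cdf = stats.beta.cdf(np.clip(edges, 0.0, 1.0), self.a, self.b)
        return np.diff(cdf)


@dataclass
class NoisyPredictorSpec:
    """Class-conditional score distributions of a synthetic predictor."""

    pos_dist: ScoreDistribution = field(
        default_factory=lambda: ScoreDistribution("beta", 4.0, 1.5)
    )
    neg_dist: ScoreDistribution = field(
        default_factory=lambda: ScoreDistribution("beta", 1.5, 4.0)
    )
    seed: int = 0


@dataclass
class SyntheticDataset:
    spec: FixtureSpec
    targets: list[TargetSequence]
    annotations: list[IntervalAnnotation]
    truth: dict

    def disorder_mask(self, target_id: str) -> np.ndarray:
        length = next(
            t.length for t in self.targets if t.target_id == target_id
        )
        for ann in self.annotations:
            if (
                ann.target_id == target_id
                and ann.annotation_class is AnnotationClass.DISORDER
            ):
                return intervals_to_mask(ann.intervals, length)
        return np.zeros(length, dtype=bool)


def _place_intervals(
    rng: np.random.Generator,
    length: int,
    target_residues: int,
    min_len: int,
    cap_fraction: float,
) -> list[tuple[int, int]]:
    """Place non-overlapping intervals totalling about ``target_residues``.

    Rejection sampling with a hard attempt cap; exceeding the cap before
    reaching half the requested coverage is an error (silent under-filling
    would break the ground-truth bookkeeping).  A one-residue gap is kept
    between intervals so canonical merging preserves them.
    """
    if target_residues <= 0:
        return []
    cap = int(cap_fraction * length)
    if min_len > cap:
        raise ValueError(
            f"minimum interval length {min_len} exceeds the placeable "
            f"budget of a length-{length} target (density infeasible)"
        )
    target_residues = min(max(target_residues, min_len), cap)
    occupied = np.zeros(length, dtype=bool)
    intervals: list[tuple[int, int]] = []
    covered = 0
    attempts = 0
    while covered < target_residues:
        attempts += 1
        if attempts > _MAX_PLACEMENT_ATTEMPTS:
            if covered >= target_residues // 2 and intervals:
                break
            raise ValueError(
                f"cannot place {target_residues} interval residues in a "
                f"length-{length} target (density infeasible)"
            )
        want = min_len + int(rng.geometric(1.0 / (min_len + 1))) - 1
        want = min(want, target_residues - covered + min_len, length)
        if want < min_len:
            want = min_len
        start = int(rng.integers(1, length - want + 2))
        lo, hi = max(0, start - 2), min(length, start + want)
        if occupied[lo:hi].any():
            continue
        if covered + want > cap:
            continue
        occupied[start - 1 : start - 1 + want] = True
        intervals.append((start, start + want - 1))
        covered += want
    return sorted(intervals)


def _ordered_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of False in a boolean mask, as 1-based intervals."""
    runs = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if not v and not in_run:
            in_run, start = True, i
        elif v and in_run:
            runs.append((start + 1, i))
            in_run = False
    if in_run:
        runs.append((start + 1, len(mask)))
    return runs


def generate_dataset(spec: FixtureSpec) -> SyntheticDataset:
    """Generate targets, annotations and exact ground-truth bookkeeping.

    Reproducible from ``spec.seed``.  The number of fully disordered
    targets is exactly ``round(idp_fraction * n_targets)``; binding
    intervals always lie inside disorder intervals; per-class residue
    counts are recorded in ``truth`` after an explicit recount of the
    emitted intervals.
    """
    rng = np.random.default_rng(spec.seed)
    n_idp = int(round(spec.idp_fraction * spec.n_targets))
    n_binding = int(round(spec.binding_target_fraction * spec.n_targets))
    idp_flags = np.zeros(spec.n_targets, dtype=bool)
    idp_flags[rng.choice(spec.n_targets, size=n_idp, replace=False)] = True

    aa = np.array(list(AMINO_ACIDS))
    width = len(str(spec.n_targets))
    targets: list[TargetSequence] = []
    annotations: list[IntervalAnnotation] = []
    per_target: dict[str, dict] = {}

    for i in range(spec.n_targets):
        tid = f"T{i + 1:0{width}d}"
        length = int(
            np.clip(
                rng.lognormal(np.log(spec.length_median), spec.length_sigma),
                spec.min_length,
                spec.max_length,
            )
        )
        seq = "".join(aa[rng.integers(0, 20, size=length)])
        targets.append(TargetSequence(tid, seq))

        if idp_flags[i]:
            ndis = max(
                int(np.ceil(0.95 * length)),
                int(round(rng.uniform(0.95, 1.0) * length)),
            )
            ndis = min(ndis, length)
            start = int(rng.integers(1, length - ndis + 2))
            disorder = [(start, start + ndis - 1)]
        else:
            want = int(round(spec.disorder_density * length))
            disorder = _place_intervals(
                rng, length, want, spec.min_interval_length, cap_fraction=0.9
            )
        dis_mask = intervals_to_mask(disorder, length)
        if disorder:
            annotations.append(
                IntervalAnnotation(tid, AnnotationClass.DISORDER, disorder)
            )

        structure: list[tuple[int, int]] = []
        for s, e in _ordered_runs(dis_mask):
            if rng.uniform() >= spec.structure_coverage:
                continue
            run_len = e - s + 1
            keep = max(1, int(round(rng.uniform(0.6, 1.0) * run_len)))
            off = int(rng.integers(0, run_len - keep + 1))
            cs, ce = s + off, s + off + keep - 1
            if rng.uniform() < spec.structure_overlap:
                bleed = int(rng.integers(1, 6))
                cs = max(1, cs - bleed) if cs > 1 else cs
                ce = min(length, ce + bleed) if ce < length else ce
            structure.append((cs, ce))
        if structure:
            annotations.append(
                IntervalAnnotation(
                    tid, AnnotationClass.STRUCTURE_OBSERVED, structure
                )
            )

        per_target[tid] = {
            "length": length,
            "disorder_intervals": disorder,
            "structure_intervals": structure,
            "binding_intervals": [],
        }

    # binding: choose exactly n_binding among targets with a disorder interval
    candidates = [
        t.target_id
        for t in targets
        if per_target[t.target_id]["disorder_intervals"]
    ]
    if n_binding > len(candidates):
        raise ValueError(
            f"binding_target_fraction requires {n_binding} targets with "
            f"disorder but only {len(candidates)} have any"
        )
    chosen = rng.choice(len(candidates), size=n_binding, replace=False)
    for j in sorted(chosen):
        tid = candidates[j]
        ivs = per_target[tid]["disorder_intervals"]
        s, e = ivs[int(rng.integers(0, len(ivs)))]
        span = e - s + 1
        blen = max(1, int(round(spec.binding_within_disorder_fraction * span)))
        boff = int(rng.integers(0, span - blen + 1))
        binding = [(s + boff, s + boff + blen - 1)]
        per_target[tid]["binding_intervals"] = binding
        annotations.append(
            IntervalAnnotation(tid, AnnotationClass.BINDING, binding)
        )

    # ground truth by explicit recount of the emitted intervals
    truth_targets: dict[str, dict] = {}
    totals = {"disorder": 0, "structure_observed": 0, "binding": 0, "residues": 0}
    idp_ids = []
    for t in targets:
        rec = per_target[t.target_id]
        dmask = intervals_to_mask(rec["disorder_intervals"], t.length)
        smask = intervals_to_mask(rec["structure_intervals"], t.length)
        bmask = intervals_to_mask(rec["binding_intervals"], t.length)
        if bmask.any() and not (dmask | ~bmask).all():
            raise AssertionError("binding interval escaped its disorder region")
        frac = float(dmask.mean())
        is_idp = frac >= 0.95
        if is_idp:
            idp_ids.append(t.target_id)
        truth_targets[t.target_id] = {
            "length": t.length,
            "n_disorder": int(dmask.sum()),
            "n_structure": int(smask.sum()),
            "n_binding": int(bmask.sum()),
            "n_disorder_and_structure": int((dmask & smask).sum()),
            "disorder_fraction": frac,
            "is_idp": is_idp,
        }
        totals["disorder"] += int(dmask.sum())
        totals["structure_observed"] += int(smask.sum())
        totals["binding"] += int(bmask.sum())
        totals["residues"] += t.length

    if len(idp_ids) != n_idp:
        raise AssertionError(
            f"constructed {len(idp_ids)} fully disordered targets, wanted {n_idp}"
        )

    truth = {
        "seed": spec.seed,
        "n_targets": spec.n_targets,
        "n_idp": n_idp,
        "idp_targets": idp_ids,
        "n_binding_targets": n_binding,
        "totals": totals,
        "targets": truth_targets,
    }
    return SyntheticDataset(spec, targets, annotations, truth)


def generate_predictions(
    dataset: SyntheticDataset,
    noisy: Optional[NoisyPredictorSpec] = None,
    method_name: str = "synthetic-predictor",
) -> PredictionSet:
    """Draw per-residue scores from the class-conditional distributions.

    True-disorder residues draw from ``pos_dist``, everything else from
    ``neg_dist``; scores are rounded to the standard 3-decimal grid and
    binary states derived at threshold 0.5.
    """
    noisy = noisy or NoisyPredictorSpec()
    rng = np.random.default_rng(noisy.seed)
    pset = PredictionSet(method_name, declared_threshold=0.5)
    for t in sorted(dataset.targets, key=lambda t: t.target_id):
        dmask = dataset.disorder_mask(t.target_id)
        scores = np.empty(t.length)
        scores[dmask] = noisy.pos_dist.sample(rng, int(dmask.sum()))
        scores[~dmask] = noisy.neg_dist.sample(rng, int((~dmask).sum()))
        pset.entries[t.target_id] = PredictionEntry(
            t.target_id, round_half_up(scores)
        )
    resolve_threshold(pset)
    return pset


def expected_auc(noisy: NoisyPredictorSpec) -> float:
    """Oracle AUC of a noisy predictor: ``P(S+ > S-) + P(S+ = S-) / 2``.

    Computed exactly on the rounded score grid from the two distributions'
    discrete probability masses, independent of any sampling.
    """
    p = noisy.pos_dist.grid_pmf()
    q = noisy.neg_dist.grid_pmf()
    # P(S+ > S-): for each negative bin j, mass of positive bins above j
    tail_above = np.concatenate([np.cumsum(p[::-1])[::-1][1:], [0.0]])
    return float(np.sum(q * tail_above) + 0.5 * np.sum(q * p))


def generate_profiles(
    dataset: SyntheticDataset,
    contrast: float,
    seed: int = 0,
    background: Optional[np.ndarray] = None,
) -> dict[str, FrequencyProfile]:
    """Frequency profiles with tunable divergence from the background.

    Ordered positions carry the background distribution exactly (zero
    Jensen-Shannon divergence); disordered positions mix the background
    with a point mass on a random amino acid with weight ``contrast`` in
    [0, 1], so the conservation baseline's separation grows monotonically
    with the contrast and vanishes at 0.
    """
    if contrast < 0:
        raise ValueError("contrast must be >= 0")
    w = min(float(contrast), 1.0)
    bg = background_vector() if background is None else background
    rng = np.random.default_rng(seed)
    profiles: dict[str, FrequencyProfile] = {}
    for t in sorted(dataset.targets, key=lambda t: t.target_id):
        dmask = dataset.disorder_mask(t.target_id)
        freqs = np.tile(bg, (t.length, 1))
        n_dis = int(dmask.sum())
        if n_dis and w > 0:
            point = np.zeros((n_dis, 20))
            point[np.arange(n_dis), rng.integers(0, 20, size=n_dis)] = 1.0
            freqs[dmask] = (1.0 - w) * bg + w * point
        profiles[t.target_id] = FrequencyProfile(t.target_id, freqs)
    return profiles


# ---------------------------------------------------------------------------
# file emission


def write_dataset(dataset: SyntheticDataset, outdir: Union[str, Path]) -> dict:
    """Write FASTA, interval table and ground-truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "targets.fasta"
    with fasta.open("w") as fh:
        for t in dataset.targets:
            fh.write(f">{t.target_id}\n")
            for i in range(0, t.length, 60):
                fh.write(t.sequence[i : i + 60] + "\n")
    table = outdir / "annotations.tsv"
    with table.open("w") as fh:
        fh.write("target_id\tclass\tstart\tend\n")
        for ann in dataset.annotations:
            for s, e in ann.intervals:
                fh.write(
                    f"{ann.target_id}\t{ann.annotation_class.value}\t{s}\t{e}\n"
                )
    truth = outdir / "ground_truth.json"
    truth.write_text(json.dumps(dataset.truth, indent=2) + "\n")
    return {"fasta": fasta, "annotations": table, "truth": truth}
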