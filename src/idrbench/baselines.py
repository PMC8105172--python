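"""Naive baseline predictors for disorder assessment.

Four families:

* ``random_baseline`` — i.i.d. uniform scores in [0, 1], threshold 0.5;
* ``shuffled_baseline`` — global permutation of the reference labels, which
  preserves the dataset-level positive fraction but not per-target
  fractions;
* ``conservation_baseline`` — per-position Jensen-Shannon divergence
  (base 2, bounded in [0, 1]) between the target's homolog-derived residue
  frequency profile and the background amino-acid frequencies of the
  BLOSUM62 alignments; a position with score > 0.4 (strict) is called
  disordered.  Because intrinsically disordered regions are on average
  *less* conserved than globular ones, an ``invert`` flag is provided that
  emits ``1 - JSD`` instead;
* ``structure_complement_baseline`` — everything not covered by an
  observed-structure interval is disordered (score 1), the rest is not
  (score 0).  Variants (structures of the target itself, of close or
  remote homologs, or predicted domains) differ only in the provenance of
  the coverage intervals they consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, TextIO, Union

import numpy as np

from idrbench.predictions import (
    PredictionEntry,
    PredictionSet,
    round_half_up,
    resolve_threshold,
)
from idrbench.references import (
    MASKED,
    POSITIVE,
    IntervalAnnotation,
    ReferenceSet,
    TargetSequence,
    intervals_to_mask,
    merge_intervals,
)

#: fixed alphabetical amino-acid order used in profile tables
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: marginal amino-acid frequencies of the BLOSUM62 alignment blocks
BLOSUM62_BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}


@dataclass
class FrequencyProfile:
    """Per-position amino-acid frequency vectors for one target."""

    target_id: str
    frequencies: np.ndarray  # (length, 20), rows sum to 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.ndim != 2 or self.frequencies.shape[1] != 20:
            raise ValueError(
                f"target {self.target_id!r}: profile must be (length, 20)"
            )
        sums = self.frequencies.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"target {self.target_id!r}: profile row {bad + 1} sums to "
                f"{sums[bad]:.8f}, not 1"
            )

    @property
    def length(self) -> int:
        return int(self.frequencies.shape[0])


@dataclass
class StructureCoverage:
    """Observed-structure intervals for one target, with provenance."""

    target_id: str
    intervals: list[tuple[int, int]]
    provenance: str = "observed"  # observed | close_homolog | remote_homolog | domain_prediction

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)


def background_vector(
    frequencies: Optional[Mapping[str, float]] = None,
) -> np.ndarray:
    """Background frequencies as a vector in the fixed amino-acid order."""
    freqs = dict(BLOSUM62_BACKGROUND if frequencies is None else frequencies)
    vec = np.array([freqs[a] for a in AMINO_ACIDS], dtype=float)
    if np.any(vec <= 0):
        raise ValueError("background frequencies must be strictly positive")
    return vec / vec.sum()


def _entropy2(p: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits along the last axis, with 0*log0 = 0."""
    p = np.asarray(p, dtype=float)
    logs = np.log2(p, where=p > 0, out=np.zeros_like(p))
    return -(p * logs).sum(axis=-1)


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Base-2 Jensen-Shannon divergence, bounded in [0, 1].

    ``JSD(p, q) = H((p + q) / 2) - (H(p) + H(q)) / 2`` with Shannon
    entropies in bits.  Accepts arrays of distributions along the last
    axis.  Results are clamped to [0, 1] to absorb rounding at the bounds.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = (p + q) / 2.0
    jsd = _entropy2(m) - (_entropy2(p) + _entropy2(q)) / 2.0
    return np.clip(jsd, 0.0, 1.0)


# ---------------------------------------------------------------------------
# baseline constructors


def random_baseline(
    targets: Sequence[TargetSequence], seed: int
) -> PredictionSet:
    """Uniform random scores per residue with decision threshold 0.5."""
    rng = np.random.default_rng(seed)
    pset = PredictionSet("Random", declared_threshold=0.5)
    for t in sorted(targets, key=lambda t: t.target_id):
        scores = round_half_up(rng.uniform(0.0, 1.0, size=t.length))
        pset.entries[t.target_id] = PredictionEntry(t.target_id, scores)
    resolve_threshold(pset)
    return pset


def shuffled_baseline(reference: ReferenceSet, seed: int) -> PredictionSet:
    """Global permutation of the reference labels as a predictor.

    The unmasked positive/negative labels of the whole dataset are permuted
    across targets and emitted as binary scores, preserving the dataset-level
    positive count exactly while scrambling per-target composition.  Masked
    positions are outside the permutation pool and receive score 0 (inert:
    they are excluded from evaluation anyway).
    """
    rng = np.random.default_rng(seed)
    tids = reference.target_ids
    unmasked = [reference.entries[t].labels != MASKED for t in tids]
    pool = np.concatenate(
        [
            (reference.entries[t].labels[m] == POSITIVE).astype(float)
            for t, m in zip(tids, unmasked)
        ]
    )
    permuted = rng.permutation(pool)
    pset = PredictionSet("Shuffled dataset", declared_threshold=0.5)
    offset = 0
    for t, m in zip(tids, unmasked):
        n = int(m.sum())
        scores = np.zeros(reference.entries[t].length)
        scores[m] = permuted[offset : offset + n]
        offset += n
        pset.entries[t] = PredictionEntry(
            t, scores, states=scores.astype(np.int8)
        )
    resolve_threshold(pset)
    return pset


def conservation_baseline(
    profiles: Union[Mapping[str, FrequencyProfile], Sequence[FrequencyProfile]],
    background: Optional[Union[Mapping[str, float], np.ndarray]] = None,
    invert: bool = False,
) -> PredictionSet:
    """Jensen-Shannon divergence of per-position profiles vs background.

    Scores are the base-2 JSD values in [0, 1]; a position is called
    disordered when its score is strictly above 0.4.  With ``invert`` the
    emitted score is ``1 - JSD`` (low conservation signal treated as
    disorder) and the strict-rule states are derived from the inverted
    scores at the same threshold.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.target_id: p for p in profiles}
    if isinstance(background, np.ndarray):
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
    else:
        bg = background_vector(background)
    pset = PredictionSet("Conservation", declared_threshold=0.4)
    for tid in sorted(profiles):
        prof = profiles[tid]
        jsd = jensen_shannon_divergence(prof.frequencies, bg)
        scores = round_half_up(1.0 - jsd if invert else jsd)
        states = (scores > 0.4).astype(np.int8)  # strict rule
        pset.entries[tid] = PredictionEntry(tid, scores, states)
    pset.effective_threshold = 0.4
    return pset


def structure_complement_baseline(
    coverage: Union[Mapping[str, StructureCoverage], Sequence[StructureCoverage]],
    targets: Sequence[TargetSequence],
    method_name: str = "PDB Observed",
) -> PredictionSet:
    """Everything not observed in a structure is predicted disordered.

    Residues outside all coverage intervals score 1.0, inside 0.0; a target
    with no coverage record at all is scored all-1.0, i.e. classified
    entirely disordered.
    """
    if not isinstance(coverage, Mapping):
        coverage = {c.target_id: c for c in coverage}
    pset = PredictionSet(method_name, declared_threshold=0.5)
    for t in sorted(targets, key=lambda t: t.target_id):
        scores = np.ones(t.length)
        cov = coverage.get(t.target_id)
        if cov is not None:
            for s, e in cov.intervals:
                if e > t.length:
                    raise ValueError(
                        f"target {t.target_id!r}: coverage interval ({s}, {e}) "
                        f"exceeds length {t.length}"
                    )
            scores[intervals_to_mask(cov.intervals, t.length)] = 0.0
        pset.entries[t.target_id] = PredictionEntry(
            t.target_id, scores, states=scores.astype(np.int8)
        )
    resolve_threshold(pset)
    return pset


def coverage_from_annotations(
    annotations: Sequence[IntervalAnnotation], provenance: str = "observed"
) -> dict[str, StructureCoverage]:
    """Adapt ``structure_observed`` interval annotations to coverage records."""
    return {
        a.target_id: StructureCoverage(a.target_id, list(a.intervals), provenance)
        for a in annotations
        if a.annotation_class.value == "structure_observed"
    }


# ---------------------------------------------------------------------------
# profile table I/O


def write_profiles(
    profiles: Union[Mapping[str, FrequencyProfile], Sequence[FrequencyProfile]],
    path: Union[str, Path],
) -> None:
    """Write frequency profiles as a tab-separated table.

    Entries start with ``>`` + target id; a header row names the fixed
    amino-acid order; each data row is the position followed by 20
    frequencies.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.target_id: p for p in profiles}
    with Path(path).open("w") as fh:
        for tid in sorted(profiles):
            prof = profiles[tid]
            fh.write(f">{tid}\n")
            fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, row in enumerate(prof.frequencies, start=1):
                fh.write(
                    str(i) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n"
                )


def read_profiles(source: Union[str, Path, TextIO]) -> dict[str, FrequencyProfile]:
    """Read frequency profiles written by :func:`write_profiles`."""
    handle = Path(source).open() if isinstance(source, (str, Path)) else source
    profiles: dict[str, FrequencyProfile] = {}
    tid: Optional[str] = None
    rows: list[list[float]] = []
    order: Optional[list[int]] = None

    def flush() -> None:
        nonlocal rows
        if tid is not None:
            arr = np.array(rows, dtype=float)
            # renormalize away the 6-decimal write rounding
            arr = arr / arr.sum(axis=1, keepdims=True)
            profiles[tid] = FrequencyProfile(tid, arr)
        rows = []

    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                tid = line[1:].strip()
                order = None
                continue
            fields = line.split("\t")
            if fields[0] == "pos":
                header = fields[1:]
                if sorted(header) != sorted(AMINO_ACIDS):
                    raise ValueError("profile header must name the 20 amino acids")
                order = [header.index(a) for a in AMINO_ACIDS]
                continue
            if order is None:
                raise ValueError("profile entry missing its header row")
            values = [float(v) for v in fields[1:]]
            if len(values) != 20:
                raise ValueError(
                    f"target {tid!r}: profile row with {len(values)} values"
                )
            rows.append([values[j] for j in order])
        flush()
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    return profiles
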