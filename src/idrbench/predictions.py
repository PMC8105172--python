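"""Per-residue predictor output: parsing, rounding and threshold resolution.

Predictors emit a score and/or a binary state per residue.  The evaluation
conventions are:

* scores are rounded half-up to the third decimal, so the score grid has
  1001 representable values (0.000-1.000);
* if scores are missing, states are copied into scores verbatim;
* if states are missing, they are generated by applying a threshold to the
  scores with the non-strict rule ``score >= threshold -> positive``;
* the effective threshold is inferred from states when available (the
  minimum score among state-positive residues across the whole set),
  otherwise the method's declared threshold is used, otherwise 0.5.

File format (one file per method): an entry starts with ``>`` followed by
the target id; each subsequent line holds ``position TAB residue TAB score
TAB state`` where the score and state fields are individually optional
(an absent trailing state column may simply be omitted; an absent score
with a present state is written as an empty field).  Scores are written
with exactly three decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np

logger = logging.getLogger(__name__)

#: number of score grid steps per unit; grid values are k / SCORE_SCALE
SCORE_SCALE = 1000


def round_half_up(scores: np.ndarray, decimals: int = 3) -> np.ndarray:
    """Round half-up on the decimal representation.

    ``np.round`` rounds half to even; assessment reports use half-up
    (0.0005 -> 0.001).  Values are first snapped to 6 decimals in the scaled
    domain to absorb binary representation error.
    """
    scale = 10.0**decimals
    scaled = np.round(np.asarray(scores, dtype=float) * scale, 6)
    return np.floor(scaled + 0.5) / scale


@dataclass
class PredictionEntry:
    """Scores (and optional binary states) for every residue of one target."""

    target_id: str
    scores: np.ndarray
    states: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any((self.scores < 0) | (self.scores > 1)):
            bad = int(np.argmax((self.scores < 0) | (self.scores > 1)))
            raise ValueError(
                f"target {self.target_id!r}: score {self.scores[bad]} at "
                f"position {bad + 1} outside [0, 1]"
            )
        if self.states is not None:
            self.states = np.asarray(self.states, dtype=np.int8)
            if self.states.size != self.scores.size:
                raise ValueError(
                    f"target {self.target_id!r}: states/scores length mismatch"
                )
            if not np.isin(self.states, (0, 1)).all():
                raise ValueError(f"target {self.target_id!r}: states must be 0/1")

    @property
    def length(self) -> int:
        return int(self.scores.size)


@dataclass
class PredictionSet:
    """All entries of one method plus its resolved decision threshold."""

    method_name: str
    entries: dict[str, PredictionEntry] = field(default_factory=dict)
    declared_threshold: Optional[float] = None
    effective_threshold: Optional[float] = None

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def has_states(self) -> bool:
        return any(e.states is not None for e in self.entries.values())


def round_scores(entry: PredictionEntry) -> PredictionEntry:
    """Return the entry with scores rounded half-up to 3 decimals (idempotent)."""
    return replace(entry, scores=round_half_up(entry.scores))


def parse_prediction_file(
    source: Union[str, Path, TextIO],
    method_name: Optional[str] = None,
) -> PredictionSet:
    """Parse a per-residue prediction file.

    Positions must be consecutive from 1 within each entry.  Scores are
    validated to [0, 1] and rounded half-up to 3 decimals.  Entries with
    states but no scores get the states copied into the scores.  The
    returned set has no resolved threshold yet (see
    :func:`resolve_threshold`).
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        handle: TextIO = path.open()
        close = True
        if method_name is None:
            method_name = path.stem
    else:
        handle = source
        close = False
        if method_name is None:
            method_name = "unnamed"

    pset = PredictionSet(method_name)
    tid: Optional[str] = None
    rows: list[tuple[int, Optional[float], Optional[int]]] = []

    def flush() -> None:
        if tid is None:
            return
        if not rows:
            raise ValueError(f"target {tid!r}: entry has no residue lines")
        positions = [r[0] for r in rows]
        if positions != list(range(1, len(rows) + 1)):
            raise ValueError(
                f"target {tid!r}: positions are not consecutive from 1"
            )
        raw_scores = [r[1] for r in rows]
        raw_states = [r[2] for r in rows]
        have_scores = [s is not None for s in raw_scores]
        have_states = [s is not None for s in raw_states]
        if not all(have_scores) and any(have_scores):
            raise ValueError(f"target {tid!r}: score column partially present")
        if not all(have_states) and any(have_states):
            raise ValueError(f"target {tid!r}: state column partially present")
        states = np.array(raw_states, dtype=np.int8) if all(have_states) else None
        if all(have_scores):
            scores = np.array(raw_scores, dtype=float)
        elif states is not None:
            scores = states.astype(float)  # states used as scores
        else:
            raise ValueError(
                f"target {tid!r}: both score and state columns absent"
            )
        if tid in pset.entries:
            raise ValueError(f"duplicate prediction entry for target {tid!r}")
        entry = PredictionEntry(tid, scores, states)
        pset.entries[tid] = round_scores(entry)

    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                tid = line[1:].strip()
                rows = []
                continue
            if tid is None:
                raise ValueError(f"line {lineno}: residue line before '>' header")
            fields = line.split("\t")
            if len(fields) < 2 or len(fields) > 4:
                raise ValueError(
                    f"line {lineno}: expected 2-4 tab-separated fields"
                )
            pos = int(fields[0])
            score_s = fields[2] if len(fields) > 2 else ""
            state_s = fields[3] if len(fields) > 3 else ""
            score = float(score_s) if score_s != "" else None
            state = int(state_s) if state_s != "" else None
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(
                    f"target {tid!r} position {pos}: score {score} outside [0, 1]"
                )
            if state is not None and state not in (0, 1):
                raise ValueError(
                    f"target {tid!r} position {pos}: state {state} not binary"
                )
            rows.append((pos, score, state))
        flush()
    finally:
        if close:
            handle.close()

    if not pset.entries:
        logger.warning("prediction file for %s is empty", method_name)
    return pset


def write_prediction_file(
    pset: PredictionSet,
    path: Union[str, Path],
    sequences: Optional[dict[str, str]] = None,
) -> None:
    """Write a prediction set in the per-residue text format.

    ``sequences`` optionally maps target id to amino-acid string for the
    residue column; ``X`` is written when unknown.
    """
    with Path(path).open("w") as fh:
        for tid in pset.target_ids:
            entry = pset.entries[tid]
            seq = (sequences or {}).get(tid, "X" * entry.length)
            fh.write(f">{tid}\n")
            for i in range(entry.length):
                fields = [str(i + 1), seq[i], f"{entry.scores[i]:.3f}"]
                if entry.states is not None:
                    fields.append(str(int(entry.states[i])))
                fh.write("\t".join(fields) + "\n")


def resolve_threshold(pset: PredictionSet) -> float:
    """Resolve the effective decision threshold for a prediction set.

    States, when present, take priority: the threshold is the minimum
    rounded score among state-positive residues across the whole set, and
    consistency of ``score >= threshold`` with the provided states is
    checked (inconsistencies are counted and logged, never silently
    dropped).  Without states the declared threshold applies, and 0.5 is
    the final fallback.  The resolved value is stored on the set and
    returned; entries lacking states receive states derived at the
    resolved threshold.
    """
    threshold: Optional[float] = None
    if pset.has_states():
        pos_scores = [
            e.scores[e.states == 1]
            for e in pset.entries.values()
            if e.states is not None
        ]
        pos_scores = [s for s in pos_scores if s.size]
        if pos_scores:
            threshold = float(min(s.min() for s in pos_scores))
            mismatches = 0
            for e in pset.entries.values():
                if e.states is not None:
                    derived = (e.scores >= threshold).astype(np.int8)
                    mismatches += int(np.sum(derived != e.states))
            if mismatches:
                logger.warning(
                    "%s: %d residue states inconsistent with inferred "
                    "threshold %.3f",
                    pset.method_name,
                    mismatches,
                    threshold,
                )
        else:
            logger.warning(
                "%s: states present but no positive state; falling back to "
                "declared threshold / 0.5",
                pset.method_name,
            )
    if threshold is None:
        threshold = (
            pset.declared_threshold if pset.declared_threshold is not None else 0.5
        )
    pset.effective_threshold = float(threshold)
    for tid, e in pset.entries.items():
        if e.states is None:
            pset.entries[tid] = replace(
                e, states=(e.scores >= threshold).astype(np.int8)
            )
    return pset.effective_threshold
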