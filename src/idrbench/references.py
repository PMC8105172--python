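"""Reference-set construction from interval annotations.

Annotations arrive as 1-based inclusive residue intervals per target, one of
three classes: experimentally verified disorder, binding regions (which in
curated data lie inside disordered regions), and residues observed in
experimental structures.  Three reference modes are supported:

``disprot``
    Disorder-annotated residues are positive, everything else negative.
``disprot_pdb``
    Disorder-annotated residues are positive (disorder always overwrites
    structure), structure-observed residues that are not disorder-annotated
    are negative, and residues covered by neither annotation are masked and
    excluded from every downstream metric.
``binding``
    Binding-annotated residues are positive, everything else negative.
    Targets without any binding annotation are retained as all-negative
    entries.

Per-residue labels are stored as ``int8`` arrays with ``1`` = positive,
``0`` = negative and ``-1`` = masked.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

POSITIVE: int = 1
NEGATIVE: int = 0
MASKED: int = -1

_LABEL_CHARS = {POSITIVE: "1", NEGATIVE: "0", MASKED: "-"}
_CHAR_LABELS = {v: k for k, v in _LABEL_CHARS.items()}


class AnnotationClass(str, Enum):
    """The three interval annotation classes understood by the builder."""

    DISORDER = "disorder"
    BINDING = "binding"
    STRUCTURE_OBSERVED = "structure_observed"


class ReferenceMode(str, Enum):
    DISPROT = "disprot"
    DISPROT_PDB = "disprot_pdb"
    BINDING = "binding"


@dataclass(frozen=True)
class TargetSequence:
    """One assessment target: an identifier and its amino-acid sequence."""

    target_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"target {self.target_id!r} has an empty sequence")
        if not self.sequence.isupper() or not self.sequence.isalpha():
            raise ValueError(
                f"target {self.target_id!r}: sequence must be uppercase letters"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class IntervalAnnotation:
    """Canonical (sorted, merged) 1-based inclusive intervals for one class."""

    target_id: str
    annotation_class: AnnotationClass
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.annotation_class = AnnotationClass(self.annotation_class)
        self.intervals = merge_intervals(self.intervals)

    def n_residues(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


@dataclass
class ReferenceEntry:
    """Ternary per-residue labels for one target."""

    target_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        bad = ~np.isin(self.labels, (POSITIVE, NEGATIVE, MASKED))
        if bad.any():
            raise ValueError(f"target {self.target_id!r}: invalid label values")

    @property
    def length(self) -> int:
        return int(self.labels.size)

    def counts(self) -> dict[str, int]:
        return {
            "positive": int(np.sum(self.labels == POSITIVE)),
            "negative": int(np.sum(self.labels == NEGATIVE)),
            "masked": int(np.sum(self.labels == MASKED)),
        }


@dataclass
class ReferenceSet:
    """A complete reference: one labelled entry per target."""

    mode: ReferenceMode
    entries: dict[str, ReferenceEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mode = ReferenceMode(self.mode)

    @property
    def target_ids(self) -> list[str]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def total_residues(self) -> int:
        return sum(e.length for e in self.entries.values())


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort 1-based inclusive intervals and merge overlapping/adjacent ones.

    Merging is membership-preserving: the merged list covers exactly the
    residues covered by the input.  Intervals that touch, e.g. ``(2, 5)`` and
    ``(6, 9)``, are merged because their residue sets are contiguous.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"invalid interval ({s}, {e}): start > end")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intervals_to_mask(intervals: Sequence[tuple[int, int]], length: int) -> np.ndarray:
    """Boolean residue mask (0-based array) for 1-based inclusive intervals."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s - 1 : e] = True
    return mask


def read_fasta(source: Union[str, Path, TextIO]) -> list[TargetSequence]:
    """Read target sequences from FASTA; duplicate identifiers are an error."""
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        targets: list[TargetSequence] = []
        seen: set[str] = set()
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"duplicate FASTA id {record.id!r}")
            seen.add(record.id)
            targets.append(TargetSequence(record.id, str(record.seq).upper()))
        return targets
    finally:
        if isinstance(source, (str, Path)):
            handle.close()


def parse_annotations(
    annotation_table: Union[str, Path, TextIO],
    sequences: Union[str, Path, TextIO, Sequence[TargetSequence]],
) -> tuple[list[TargetSequence], list[IntervalAnnotation]]:
    """Parse an interval table plus a FASTA collection.

    The table is tab-separated with columns ``target_id  class  start  end``,
    one interval per line.  A header line is optional and ``#`` comment lines
    are ignored.  Coordinates are 1-based inclusive and validated against
    sequence bounds.  Intervals are returned canonicalized (sorted and merged
    per target and class).
    """
    if isinstance(sequences, (str, Path)) or hasattr(sequences, "read"):
        targets = read_fasta(sequences)  # type: ignore[arg-type]
    else:
        targets = list(sequences)
    lengths = {t.target_id: t.length for t in targets}
    if len(lengths) != len(targets):
        raise ValueError("duplicate target ids in sequence collection")

    if isinstance(annotation_table, (str, Path)):
        handle: TextIO = open(annotation_table)
        close = True
    else:
        handle = annotation_table
        close = False

    raw: dict[tuple[str, AnnotationClass], list[tuple[int, int]]] = {}
    valid_classes = {c.value for c in AnnotationClass}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            tid, cls, start_s, end_s = fields
            if cls not in valid_classes:
                if lineno == 1 and not (start_s.isdigit() and end_s.isdigit()):
                    continue  # header line
                raise ValueError(f"line {lineno}: unknown annotation class {cls!r}")
            start, end = int(start_s), int(end_s)
            if tid not in lengths:
                raise ValueError(f"line {lineno}: unknown target {tid!r}")
            if start < 1 or start > end:
                raise ValueError(
                    f"target {tid!r}: invalid interval ({start}, {end})"
                )
            if end > lengths[tid]:
                raise ValueError(
                    f"target {tid!r}: interval end {end} > length {lengths[tid]}"
                )
            raw.setdefault((tid, AnnotationClass(cls)), []).append((start, end))
    finally:
        if close:
            handle.close()

    annotations = [
        IntervalAnnotation(tid, cls, ivs) for (tid, cls), ivs in sorted(raw.items())
    ]
    return targets, annotations


def build_reference(
    targets: Sequence[TargetSequence],
    annotations: Sequence[IntervalAnnotation],
    mode: Union[str, ReferenceMode],
) -> ReferenceSet:
    """Build a reference set by applying the labelling rules of ``mode``.

    In ``disprot_pdb`` mode the precedence rule is: disorder always
    overwrites structure, so a residue both disorder-annotated and
    structure-observed is positive.  Targets with no annotations of any
    class are retained: all-negative in ``disprot``/``binding`` mode,
    all-masked in ``disprot_pdb`` mode.
    """
    mode = ReferenceMode(mode)
    lengths = {t.target_id: t.length for t in targets}
    by_target: dict[str, dict[AnnotationClass, IntervalAnnotation]] = {}
    for ann in annotations:
        if ann.target_id not in lengths:
            raise ValueError(
                f"annotation references unknown target {ann.target_id!r}"
            )
        by_target.setdefault(ann.target_id, {})[ann.annotation_class] = ann

    entries: dict[str, ReferenceEntry] = {}
    for t in targets:
        anns = by_target.get(t.target_id, {})

        def mask_for(cls: AnnotationClass) -> np.ndarray:
            ann = anns.get(cls)
            if ann is None:
                return np.zeros(t.length, dtype=bool)
            return intervals_to_mask(ann.intervals, t.length)

        if mode is ReferenceMode.DISPROT:
            labels = np.full(t.length, NEGATIVE, dtype=np.int8)
            labels[mask_for(AnnotationClass.DISORDER)] = POSITIVE
        elif mode is ReferenceMode.BINDING:
            labels = np.full(t.length, NEGATIVE, dtype=np.int8)
            labels[mask_for(AnnotationClass.BINDING)] = POSITIVE
        else:  # disprot_pdb
            labels = np.full(t.length, MASKED, dtype=np.int8)
            labels[mask_for(AnnotationClass.STRUCTURE_OBSERVED)] = NEGATIVE
            # disorder takes precedence over observed structure
            labels[mask_for(AnnotationClass.DISORDER)] = POSITIVE
        entry = ReferenceEntry(t.target_id, labels)
        c = entry.counts()
        assert c["positive"] + c["negative"] + c["masked"] == t.length
        entries[t.target_id] = entry

    provenance = (
        f"mode={mode.value}; targets={len(targets)}; "
        f"annotated_targets={len(by_target)}"
    )
    return ReferenceSet(mode, entries, provenance)


def reference_composition(ref: ReferenceSet) -> dict:
    """Aggregate residue counts per label class plus per-target presence.

    Returns a dict with ``positive``/``negative``/``masked``/``total``
    residue counts over the whole set and ``targets_with_positives``, the
    number of targets carrying at least one positive residue.
    """
    if not ref.entries:
        raise ValueError("empty reference set")
    totals = {"positive": 0, "negative": 0, "masked": 0}
    with_pos = 0
    for entry in ref.entries.values():
        c = entry.counts()
        for k in totals:
            totals[k] += c[k]
        if c["positive"] > 0:
            with_pos += 1
    out = dict(totals)
    out["total"] = sum(totals.values())
    out["n_targets"] = len(ref.entries)
    out["targets_with_positives"] = with_pos
    return out


def write_reference(ref: ReferenceSet, path: Union[str, Path]) -> None:
    """Write a reference as line-oriented text plus a JSON composition twin.

    Format: ``>`` + target id, then one line of characters from ``{1,0,-}``
    (positive/negative/masked), one per residue.  The JSON summary is written
    next to ``path`` with suffix ``.json``.
    """
    path = Path(path)
    with path.open("w") as fh:
        for tid in ref.target_ids:
            entry = ref.entries[tid]
            chars = "".join(_LABEL_CHARS[int(v)] for v in entry.labels)
            fh.write(f">{tid}\n{chars}\n")
    summary = {"mode": ref.mode.value, "provenance": ref.provenance}
    summary.update(reference_composition(ref))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )


def read_reference(path: Union[str, Path], mode: Union[str, ReferenceMode]) -> ReferenceSet:
    """Read a reference written by :func:`write_reference`."""
    entries: dict[str, ReferenceEntry] = {}
    tid: str | None = None
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        if line.startswith(">"):
            tid = line[1:].strip()
        else:
            if tid is None:
                raise ValueError("label line before any '>' header")
            labels = np.array([_CHAR_LABELS[c] for c in line], dtype=np.int8)
            entries[tid] = ReferenceEntry(tid, labels)
            tid = None
    return ReferenceSet(ReferenceMode(mode), entries, provenance=f"read from {path}")
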