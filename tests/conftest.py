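import numpy as np
import pytest

from idrbench.predictions import PredictionEntry, PredictionSet, resolve_threshold
from idrbench.references import ReferenceEntry, ReferenceSet
from idrbench.synthetic import FixtureSpec, generate_dataset

_CHAR = {"1": 1, "P": 1, "0": 0, "N": 0, "-": -1, "M": -1}


def reference_from_strings(labelled: dict[str, str], mode: str = "disprot") -> ReferenceSet:
    """Build a reference directly from label strings like '1110--00'."""
    entries = {
        tid: ReferenceEntry(tid, np.array([_CHAR[c] for c in s], dtype=np.int8))
        for tid, s in labelled.items()
    }
    return ReferenceSet(mode, entries, provenance="test fixture")


def predictions_from_scores(
    scores: dict[str, list[float]],
    method: str = "toy",
    declared_threshold: float | None = None,
    resolve: bool = True,
) -> PredictionSet:
    pset = PredictionSet(method, declared_threshold=declared_threshold)
    for tid, sc in scores.items():
        pset.entries[tid] = PredictionEntry(tid, np.asarray(sc, dtype=float))
    if resolve:
        resolve_threshold(pset)
    return pset


@pytest.fixture(scope="session")
def small_dataset():
    """30 synthetic targets with disorder, structure and binding annotations."""
    return generate_dataset(
        FixtureSpec(n_targets=30, length_median=120.0, seed=7)
    )


@pytest.fixture(scope="session")
def benchmark_dataset():
    """Full-size synthetic benchmark: 646 targets, 40 fully disordered."""
    return generate_dataset(FixtureSpec(seed=20))
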