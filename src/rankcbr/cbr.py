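"""The case-base and the retrieve-reuse-revise-retain cycle.

Classification is k-nearest-neighbour on the weighted rank-order similarity:
the k stored cases most similar to the target vote, and the class
conditional probability is the fraction of retrieved neighbours carrying
each label.  The original CBR classifier uses k = 1 (adopt the single most
similar case's label); k is exposed for the k-NN-style variants.

Ties are resolved deterministically: equal similarities break by case
insertion order (oldest first), and a 50/50 class vote predicts control —
the conservative call for a diagnostic screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import distance_table
from .errors import RetrievalError
from .labels import CANCER, CONTROL, encode_labels
from .profiles import FEATURES, FeatureVector
from .similarity import global_similarity, rank_distances


@dataclass
class CaseBase:
    """Labelled collection of feature vectors — the CBR knowledge store."""

    cases: list
    labels: np.ndarray  # int-coded, control=0 / cancer=1
    ids: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = encode_labels(self.labels)
        if len(self.cases) != self.labels.shape[0]:
            raise ValueError("cases and labels must be parallel")
        if not self.ids:
            self.ids = [f"C{i:03d}" for i in range(len(self.cases))]
        elif len(self.ids) != len(self.cases):
            raise ValueError("ids and cases must be parallel")

    def __len__(self) -> int:
        return len(self.cases)


@dataclass(frozen=True)
class Retrieval:
    """Result of one retrieval: neighbours sorted by similarity descending."""

    neighbor_indices: np.ndarray
    neighbor_ids: list
    similarities: np.ndarray
    k: int
    predicted_label: str
    probability: float  # class-conditional probability of the predicted label
    p_cancer: float


def similarity_vector(cb: CaseBase, target, weights, frechet_scale=None) -> np.ndarray:
    """Weighted rank-order similarity of every stored case to the target."""
    if len(cb) == 0:
        raise RetrievalError("case-base is empty")
    dt = distance_table(cb.cases, target, frechet_scale=frechet_scale)
    rt = {f: rank_distances(dt[f]) for f in FEATURES}
    return global_similarity(rt, weights)


def predict_from_distances(dt: dict, labels01: np.ndarray, weights, k: int):
    """Vote of the k most similar cases given a precomputed distance table.

    Returns ``(label01, p_cancer)``.  Shared by the CBR variants and the
    experiment harness so per-target local distances are computed once.
    """
    rt = {f: rank_distances(dt[f]) for f in FEATURES}
    s = global_similarity(rt, weights)
    order = np.argsort(-s, kind="stable")[:k]
    p_cancer = float(np.mean(labels01[order] == 1))
    return (1 if p_cancer > 0.5 else 0), p_cancer


def retrieve(cb: CaseBase, target, weights, k: int = 1, frechet_scale=None) -> Retrieval:
    """Retrieve the k most similar cases and the resulting class vote."""
    if k < 1:
        raise RetrievalError(f"k must be >= 1, got {k}")
    if k > len(cb):
        raise RetrievalError(f"k={k} exceeds case-base size {len(cb)}")
    s = similarity_vector(cb, target, weights, frechet_scale=frechet_scale)
    order = np.argsort(-s, kind="stable")[:k]
    p_cancer = float(np.mean(cb.labels[order] == 1))
    label01 = 1 if p_cancer > 0.5 else 0
    return Retrieval(
        neighbor_indices=order,
        neighbor_ids=[cb.ids[i] for i in order],
        similarities=s[order],
        k=k,
        predicted_label=CANCER if label01 == 1 else CONTROL,
        probability=p_cancer if label01 == 1 else 1.0 - p_cancer,
        p_cancer=p_cancer,
    )


def predict(cb: CaseBase, target, weights, k: int = 1, frechet_scale=None):
    """Predict the target's class label; returns ``(label, probability)``."""
    r = retrieve(cb, target, weights, k=k, frechet_scale=frechet_scale)
    return r.predicted_label, r.probability


def retain(cb: CaseBase, case: FeatureVector, confirmed_label, case_id=None) -> CaseBase:
    """Append a solved case to the case-base (returns a new CaseBase)."""
    if confirmed_label not in (CONTROL, CANCER, 0, 1):
        raise ValueError(f"unknown label {confirmed_label!r}")
    label01 = 1 if confirmed_label in (CANCER, 1) else 0
    return CaseBase(
        cases=list(cb.cases) + [case],
        labels=np.append(cb.labels, label01),
        ids=list(cb.ids) + [case_id if case_id is not None else f"C{len(cb):03d}"],
    )
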