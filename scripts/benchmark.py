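#!/usr/bin/env python
"""Extended benchmark: the six core models plus an SVM comparator.

The SVM (radial-basis kernel, library implementation) is not part of the
core engine; it classifies the extracted scalar features plus the curve
integral, standardised, under the same stratified folds as the core
models.

Usage::

    python scripts/benchmark.py --seed 1 [--n-subjects 70]
"""

from __future__ import annotations

import argparse

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from rankcbr.evaluation import (
    confusion_counts,
    information_indices,
    run_experiment,
    stratified_kfold,
    summarize,
)
from rankcbr.labels import encode_labels
from rankcbr.profiles import extract_features
from rankcbr.simulate import CohortSpec, generate_cohort


def svm_fold_reports(curves, labels, seed: int, k_folds: int = 5) -> pd.DataFrame:
    cases = [extract_features(c) for c in curves]
    X = np.array(
        [[c.ir, c.t1, c.t2, c.peak1, c.peak2,
          np.trapezoid(c.ind.dcp, c.ind.temps)] for c in cases]
    )
    y = encode_labels(labels)
    rows = []
    for fold_no, (tr, te) in enumerate(
            stratified_kfold(y, k_folds=k_folds, seed=seed), start=1):
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf"))
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        idx = information_indices(confusion_counts(y[te], pred))
        rows.append({"fold": fold_no, "model": "SVM", **idx})
    return pd.DataFrame(rows)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-subjects", type=int, default=70)
    args = ap.parse_args()

    spec = CohortSpec(n_subjects=args.n_subjects, seed=args.seed)
    curves, labels = generate_cohort(spec)
    core = run_experiment({"cohort": spec, "seed": args.seed})
    svm = svm_fold_reports(curves, labels, seed=args.seed)
    folds = pd.concat([core.folds, svm], ignore_index=True)
    summary = summarize(folds)
    pd.set_option("display.width", 140)
    print(summary.pivot(index="model", columns="index", values="AVG")
          .round(4).to_string())


if __name__ == "__main__":
    main()
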