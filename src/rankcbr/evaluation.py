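"""Evaluation harness: information indices, stratified CV, baselines.

The experiment mirrors a diagnostic benchmark: a balanced two-class cohort
is split by stratified 5-fold cross-validation; on each fold the weighted
CBR variants estimate their feature weights on the training cases only and
classify every test case; per-fold Precision, Recall, F-1 score and
G-measure (cancer = positive class) are then summarised as
MIN/AVG/STD/MAX over folds (sample standard deviation, n-1 denominator).

Baselines: a k-NN vote on min-max-scaled summed local distances, and SCUCC
— a statistical classifier whose composite coefficient is the weighted
product of the mean Pearson correlation with the control reference curves
and the mean point-wise probability of lying within the reference band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr
from sklearn.model_selection import StratifiedKFold

from .cbr import predict_from_distances
from .distances import distance_table
from .errors import ConfigError, StratificationError
from .labels import CANCER, CONTROL, encode_labels
from .profiles import FEATURES, extract_features
from .simulate import CohortSpec, generate_cohort, read_cohort
from .weights import entropy_weights, equal_weights, rank_weights, wald_weights

INDEX_NAMES = ("precision", "recall", "f1", "g")
MODEL_NAMES = ("KNN", "SCUCC", "CLCBR", "ETCBR", "LWCBR", "RWCBR")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with cancer as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    t = encode_labels(y_true)
    p = encode_labels(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; reporting 0", RuntimeWarning)
        return 0.0
    return num / den


def information_indices(cc: ConfusionCounts) -> dict:
    """Precision, Recall, F-1 score and G-measure from confusion counts.

    F-1 is the harmonic and G the geometric mean of precision and recall;
    zero denominators yield 0 with a warning so summaries stay total.
    """
    if cc.tp + cc.fp + cc.fn + cc.tn < 1:
        raise ValueError("need at least one test case")
    precision = _safe_ratio(cc.tp, cc.tp + cc.fp, "precision")
    recall = _safe_ratio(cc.tp, cc.tp + cc.fn, "recall")
    f1 = _safe_ratio(2.0 * precision * recall, precision + recall, "F-1")
    g = float(np.sqrt(precision * recall))
    return {"precision": precision, "recall": recall, "f1": f1, "g": g}


def summarize(fold_reports: pd.DataFrame) -> pd.DataFrame:
    """MIN/AVG/STD/MAX per model and index over folds.

    ``fold_reports`` needs columns ``model`` plus the four index names; STD
    uses the sample (n-1) convention.
    """
    if fold_reports.empty:
        raise ValueError("no fold reports to summarise")
    rows = []
    for model, grp in fold_reports.groupby("model", sort=False):
        for index in INDEX_NAMES:
            col = grp[index].to_numpy(dtype=float)
            rows.append(
                {
                    "model": model,
                    "index": index,
                    "MIN": col.min(),
                    "AVG": col.mean(),
                    "STD": col.std(ddof=1) if col.size > 1 else 0.0,
                    "MAX": col.max(),
                }
            )
    return pd.DataFrame(rows)


def stratified_kfold(labels, k_folds: int = 5, seed: int = 0):
    """Seeded stratified partition; returns ``[(train_idx, test_idx), ...]``."""
    y = encode_labels(labels)
    if k_folds < 2:
        raise StratificationError(f"k_folds must be >= 2, got {k_folds}")
    counts = np.bincount(y, minlength=2)
    if k_folds > counts.min():
        raise StratificationError(
            f"k_folds={k_folds} exceeds the smaller class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.shape[0]), y))


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


def knn_baseline(train_cases, train_labels, test_cases, k: int = 5):
    """Majority vote of the k nearest training cases under summed, per-feature
    min-max-scaled local distances (raw local distances mix units, so each
    feature's distance column is rescaled to [0, 1] across the training set
    before summing).  Returns ``(labels01, p_cancer)`` arrays.
    """
    y = encode_labels(train_labels)
    if k > len(train_cases):
        raise ValueError(f"k={k} exceeds training size {len(train_cases)}")
    preds, probs = [], []
    for target in test_cases:
        dt = distance_table(train_cases, target)
        total = np.zeros(len(train_cases))
        for f in FEATURES:
            col = dt[f]
            rng = col.max() - col.min()
            total += (col - col.min()) / rng if rng > 0 else np.zeros_like(col)
        order = np.argsort(total, kind="stable")[:k]
        p_cancer = float(np.mean(y[order] == 1))
        preds.append(1 if p_cancer > 0.5 else 0)
        probs.append(p_cancer)
    return np.array(preds), np.array(probs)


def scucc_composite(reference: np.ndarray, target: np.ndarray,
                    weight_factor: float = 1.0) -> float:
    """Composite coefficient of a target curve against control references.

    ``reference`` is an (r, g) array of control-class dCp curves on the
    target's grid.  The coefficient is ``rho_bar ** P * p_bar`` where
    ``rho_bar`` is the mean Pearson correlation between target and each
    reference curve and ``p_bar`` the mean over grid points of the
    two-sided normal tail probability of the target value under the
    reference point-wise mean and standard deviation.  Grid points with
    degenerate (zero) reference spread are skipped with a warning; if every
    point is degenerate, ``p_bar`` is 1 when the target matches the
    reference mean everywhere and 0 otherwise.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if reference.ndim != 2 or reference.shape[0] < 2:
        raise ValueError("need at least 2 reference curves")
    if reference.shape[1] != target.shape[0]:
        raise ValueError("target grid length does not match the reference")
    rhos = []
    for row in reference:
        if np.std(row) == 0 or np.std(target) == 0:
            rhos.append(1.0 if np.allclose(row, target) else 0.0)
        else:
            rhos.append(pearsonr(row, target)[0])
    rho_bar = float(np.mean(rhos))
    mu = reference.mean(axis=0)
    sd = reference.std(axis=0, ddof=1)
    ok = sd > 0
    if not ok.any():
        warnings.warn("all reference grid points degenerate", RuntimeWarning)
        p_bar = 1.0 if np.allclose(target, mu) else 0.0
    else:
        if not ok.all():
            warnings.warn(
                f"skipping {int((~ok).sum())} grid points with zero reference sd",
                RuntimeWarning,
            )
        z = np.abs(target[ok] - mu[ok]) / sd[ok]
        p_bar = float(np.mean(2.0 * norm.sf(z)))
    return float(np.sign(rho_bar) * np.abs(rho_bar) ** weight_factor * p_bar)


def calibrate_scucc_threshold(train_curves, train_labels,
                              weight_factor: float = 1.0) -> float:
    """Training-set threshold on the composite maximising F-1 (cancer+).

    A case is called control when its composite is >= the threshold, cancer
    otherwise; candidate thresholds are midpoints between consecutive sorted
    training composites (plus the extremes).
    """
    y = encode_labels(train_labels)
    ref = np.vstack([c for c, l in zip(train_curves, y) if l == 0])
    comps = np.array(
        [scucc_composite(ref, c, weight_factor) for c in train_curves]
    )
    order = np.sort(np.unique(comps))
    cands = [order[0] - 1.0]
    cands += list((order[:-1] + order[1:]) / 2.0)
    cands += [order[-1] + 1.0]
    best_thr, best_f1 = cands[0], -1.0
    for thr in cands:
        pred = (comps < thr).astype(int)  # below threshold -> cancer
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = information_indices(confusion_counts(y, pred))["f1"]
        if f1 > best_f1:
            best_thr, best_f1 = thr, f1
    return float(best_thr)


def scucc_classify(reference, target, threshold: float,
                   weight_factor: float = 1.0):
    """Classify one curve; returns ``(composite, label)``."""
    c = scucc_composite(np.asarray(reference), np.asarray(target), weight_factor)
    return c, (CONTROL if c >= threshold else CANCER)


# ---------------------------------------------------------------------------
# The full experiment
# ---------------------------------------------------------------------------

_WEIGHT_SCHEMES = {
    "CLCBR": lambda cases, labels: equal_weights(FEATURES),
    "ETCBR": lambda cases, labels: entropy_weights(cases),
    "LWCBR": lambda cases, labels: wald_weights(cases, labels),
    "RWCBR": lambda cases, labels: rank_weights(cases, labels),
}


@dataclass(frozen=True)
class ExperimentResult:
    weights: pd.DataFrame  # fold x model x feature
    folds: pd.DataFrame  # fold x model x index
    summary: pd.DataFrame  # model x index x statistic


def run_experiment(config: dict) -> ExperimentResult:
    """Run the full stratified-CV benchmark described by ``config``.

    Config keys: ``cohort`` (a CohortSpec, its dict form, or a path to a
    cohort CSV), ``models`` (subset of KNN/SCUCC/CLCBR/ETCBR/LWCBR/RWCBR),
    ``seed``, ``k_folds`` (default 5), ``bandwidth`` (default 1.0),
    ``knn_k`` (default 5), ``cbr_k`` (default 1), ``scucc_weight_factor``
    (default 1.0).  Weight estimation and SCUCC calibration touch training
    folds only.  Same config + seed reruns are byte-identical.
    """
    cfg = dict(config)
    if cfg.pop("retain", False):
        # retaining test cases mid-CV would leak them into the case-base
        warnings.warn(
            "retain is disabled during cross-validation to avoid test-set "
            "leakage; ignoring retain=True",
            RuntimeWarning,
        )
    models = list(cfg.get("models", MODEL_NAMES))
    unknown = set(models) - set(MODEL_NAMES)
    if unknown:
        raise ConfigError(f"unknown model name(s): {sorted(unknown)}")
    seed = int(cfg.get("seed", 0))
    k_folds = int(cfg.get("k_folds", 5))
    bandwidth = float(cfg.get("bandwidth", 1.0))
    knn_k = int(cfg.get("knn_k", 5))
    cbr_k = int(cfg.get("cbr_k", 1))
    wf = float(cfg.get("scucc_weight_factor", 1.0))

    cohort = cfg.get("cohort", None)
    if isinstance(cohort, str):
        curves, labels, _ = read_cohort(cohort)
    else:
        if cohort is None:
            spec = CohortSpec(seed=seed)
        elif isinstance(cohort, CohortSpec):
            spec = cohort
        else:
            spec = CohortSpec.from_dict(cohort)
        curves, labels = generate_cohort(spec)

    labels01 = encode_labels(labels)
    cases = [extract_features(c, bandwidth=bandwidth) for c in curves]
    dcp = np.vstack([c.dcp for c in curves])

    weight_rows, fold_rows = [], []
    folds = stratified_kfold(labels01, k_folds=k_folds, seed=seed)
    for fold_no, (train_idx, test_idx) in enumerate(folds, start=1):
        train_cases = [cases[i] for i in train_idx]
        test_cases = [cases[i] for i in test_idx]
        y_train, y_test = labels01[train_idx], labels01[test_idx]

        scheme_weights = {}
        for model in models:
            if model in _WEIGHT_SCHEMES:
                w = _WEIGHT_SCHEMES[model](train_cases, y_train)
                scheme_weights[model] = w
                weight_rows.append({"fold": fold_no, "model": model, **w})

        preds = {m: [] for m in models}
        if scheme_weights:
            for target in test_cases:
                dt = distance_table(train_cases, target)
                for model, w in scheme_weights.items():
                    label01, _ = predict_from_distances(dt, y_train, w, cbr_k)
                    preds[model].append(label01)
        if "KNN" in models:
            preds["KNN"] = list(
                knn_baseline(train_cases, y_train, test_cases, k=knn_k)[0]
            )
        if "SCUCC" in models:
            train_curves = dcp[train_idx]
            thr = calibrate_scucc_threshold(train_curves, y_train, wf)
            ref = train_curves[y_train == 0]
            scucc_pred = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for i in test_idx:
                    _, lab = scucc_classify(ref, dcp[i], thr, wf)
                    scucc_pred.append(1 if lab == CANCER else 0)
            preds["SCUCC"] = scucc_pred

        for model in models:
            idx = information_indices(confusion_counts(y_test, preds[model]))
            fold_rows.append({"fold": fold_no, "model": model, **idx})

    # drop the weight columns for IND-less schemes gracefully
    weights_df = pd.DataFrame(weight_rows) if weight_rows else pd.DataFrame(
        columns=["fold", "model", *FEATURES]
    )
    folds_df = pd.DataFrame(fold_rows)
    return ExperimentResult(
        weights=weights_df, folds=folds_df, summary=summarize(folds_df)
    )
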