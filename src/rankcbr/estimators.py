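"""scikit-learn-style estimators over the CBR core.

All estimators consume raw thermogram matrices ``X`` of shape
``(n_subjects, grid_length)`` — one dCp curve per row on a shared
temperature grid — and a two-level label vector ``y``.  They follow the
sklearn contract (``get_params``/``set_params``, fitted attributes with a
trailing underscore, ``classes_``) and compose with sklearn model
selection, e.g. ``cross_val_score(CBRClassifier(), X, y, cv=...)``.

:class:`CBRClassifier` is the package's centrepiece: feature extraction,
per-scheme weight estimation on the training cases, and k-NN retrieval by
weighted rank-order similarity.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cbr import CaseBase, predict_from_distances
from .distances import distance_table
from .errors import RetrievalError
from .evaluation import (
    calibrate_scucc_threshold,
    knn_baseline,
    scucc_composite,
)
from .labels import CANCER, encode_labels
from .profiles import FEATURES, SCALAR_FEATURES, Thermogram, extract_features
from .weights import entropy_weights, equal_weights, rank_weights, wald_weights

_WEIGHTING = {
    "equal": lambda cases, y: equal_weights(FEATURES),
    "entropy": lambda cases, y: entropy_weights(cases),
    "wald": lambda cases, y: wald_weights(cases, y),
    "rank": lambda cases, y: rank_weights(cases, y),
}


def _default_temps(n_points: int) -> np.ndarray:
    return np.linspace(45.0, 90.0, n_points)


def _as_curves(X, temps):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D (n_subjects, grid_length), got {X.ndim}-D")
    t = np.asarray(temps, dtype=float)
    if t.shape[0] != X.shape[1]:
        raise ValueError(
            f"temperature grid (len {t.shape[0]}) does not match X ({X.shape[1]} columns)"
        )
    return [Thermogram(temps=t, dcp=row) for row in X]


class _ThermoClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared label plumbing for the curve-input classifiers."""

    def _fit_labels(self, y):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.shape[0] != 2:
            raise ValueError(
                f"exactly two classes required, got {self.classes_.tolist()}"
            )
        self._y01 = encode_labels(y)
        # map internal 0/1 coding back to the original label objects
        self._decode = {}
        for lab, code in zip(y, self._y01):
            self._decode[int(code)] = lab
        return self._y01

    def _labels_from01(self, pred01):
        return np.asarray([self._decode[int(p)] for p in pred01])

    def predict_proba(self, X):
        """Class-conditional probabilities, columns ordered as ``classes_``."""
        p_cancer = self._p_cancer(X)
        out = np.empty((p_cancer.shape[0], 2))
        for j, lab in enumerate(self.classes_):
            is_cancer = encode_labels(np.asarray([lab]))[0] == 1
            out[:, j] = p_cancer if is_cancer else 1.0 - p_cancer
        return out


class ThermogramFeatureExtractor(TransformerMixin, BaseEstimator):
    """Extract the five scalar thermogram features (IR, T1, T2, PEAK1, PEAK2).

    ``transform`` returns an ``(n, 5)`` array in that column order;
    ``extract`` returns the full per-case feature vectors including the raw
    IND curve.  ``temps=None`` assumes the default 45-90 degC grid with as
    many points as X has columns.
    """

    def __init__(self, temps=None, bandwidth: float = 1.0,
                 initial_window: float = 2.0):
        self.temps = temps
        self.bandwidth = bandwidth
        self.initial_window = initial_window

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.temps_ = (
            _default_temps(X.shape[1]) if self.temps is None
            else np.asarray(self.temps, dtype=float)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def extract(self, X):
        check_is_fitted(self, "temps_")
        return [
            extract_features(c, bandwidth=self.bandwidth,
                             initial_window=self.initial_window)
            for c in _as_curves(X, self.temps_)
        ]

    def transform(self, X):
        cases = self.extract(X)
        return np.array([[fv[f] for f in SCALAR_FEATURES] for fv in cases],
                        dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(SCALAR_FEATURES, dtype=object)


class CBRClassifier(_ThermoClassifierBase):
    """Weighted rank-order CBR classifier on thermogram curves.

    Parameters
    ----------
    weighting : {"rank", "equal", "entropy", "wald"}
        Feature-weight scheme estimated on the training set ("rank" is the
        Wilcoxon rank-sum scheme; "equal" is the classical CBR baseline).
    k : int
        Number of retrieved neighbours (classical CBR uses 1).
    temps : array-like or None
        Temperature grid; None means 45-90 degC, ``X.shape[1]`` points.
    bandwidth : float
        Gaussian kernel-regression bandwidth (degC) for feature extraction.
    score_mode : {"reference", "mean-pairwise"}
        Scalar scoring used inside the rank scheme (see
        :func:`rankcbr.weights.rank_weights`).
    frechet_zscale : bool
        When True, z-scale the (temperature, dCp) axes of the Frechet
        ground space by training-set spreads instead of using raw units.

    Attributes
    ----------
    weights_ : dict
        Estimated feature weights (sum to 1).
    case_base_ : CaseBase
        The stored training cases.
    classes_ : ndarray
        The two class labels.
    """

    def __init__(self, weighting: str = "rank", k: int = 1, temps=None,
                 bandwidth: float = 1.0, initial_window: float = 2.0,
                 score_mode: str = "reference", frechet_zscale: bool = False):
        self.weighting = weighting
        self.k = k
        self.temps = temps
        self.bandwidth = bandwidth
        self.initial_window = initial_window
        self.score_mode = score_mode
        self.frechet_zscale = frechet_zscale

    def fit(self, X, y):
        if self.weighting not in _WEIGHTING:
            raise ValueError(
                f"unknown weighting {self.weighting!r}; "
                f"expected one of {sorted(_WEIGHTING)}"
            )
        X = np.asarray(X, dtype=float)
        y01 = self._fit_labels(y)
        self.temps_ = (
            _default_temps(X.shape[1]) if self.temps is None
            else np.asarray(self.temps, dtype=float)
        )
        self.n_features_in_ = X.shape[1]
        curves = _as_curves(X, self.temps_)
        cases = [
            extract_features(c, bandwidth=self.bandwidth,
                             initial_window=self.initial_window)
            for c in curves
        ]
        self.frechet_scale_ = None
        if self.frechet_zscale:
            t_sd = float(np.std(self.temps_))
            y_sd = float(np.std(X))
            self.frechet_scale_ = (
                1.0 / t_sd if t_sd > 0 else 1.0,
                1.0 / y_sd if y_sd > 0 else 1.0,
            )
        if self.weighting == "rank":
            self.weights_ = rank_weights(cases, y01, score_mode=self.score_mode)
        else:
            self.weights_ = _WEIGHTING[self.weighting](cases, y01)
        self.case_base_ = CaseBase(cases=cases, labels=y01)
        return self

    def _p_cancer(self, X):
        check_is_fitted(self, "case_base_")
        if self.k > len(self.case_base_):
            raise RetrievalError(
                f"k={self.k} exceeds case-base size {len(self.case_base_)}"
            )
        targets = _as_curves(np.asarray(X, dtype=float), self.temps_)
        probs = []
        for curve in targets:
            fv = extract_features(curve, bandwidth=self.bandwidth,
                                  initial_window=self.initial_window)
            dt = distance_table(self.case_base_.cases, fv,
                                frechet_scale=self.frechet_scale_)
            _, p_cancer = predict_from_distances(
                dt, self.case_base_.labels, self.weights_, self.k
            )
            probs.append(p_cancer)
        return np.asarray(probs)

    def predict(self, X):
        p = self._p_cancer(X)
        return self._labels_from01((p > 0.5).astype(int))


class LocalDistanceKNN(_ThermoClassifierBase):
    """k-NN baseline on summed, min-max-scaled per-feature local distances."""

    def __init__(self, k: int = 5, temps=None, bandwidth: float = 1.0,
                 initial_window: float = 2.0):
        self.k = k
        self.temps = temps
        self.bandwidth = bandwidth
        self.initial_window = initial_window

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y01 = self._fit_labels(y)
        self.temps_ = (
            _default_temps(X.shape[1]) if self.temps is None
            else np.asarray(self.temps, dtype=float)
        )
        self.n_features_in_ = X.shape[1]
        self.cases_ = [
            extract_features(c, bandwidth=self.bandwidth,
                             initial_window=self.initial_window)
            for c in _as_curves(X, self.temps_)
        ]
        self._y = y01
        return self

    def _p_cancer(self, X):
        check_is_fitted(self, "cases_")
        targets = [
            extract_features(c, bandwidth=self.bandwidth,
                             initial_window=self.initial_window)
            for c in _as_curves(np.asarray(X, dtype=float), self.temps_)
        ]
        _, probs = knn_baseline(self.cases_, self._y, targets, k=self.k)
        return probs

    def predict(self, X):
        p = self._p_cancer(X)
        return self._labels_from01((p > 0.5).astype(int))


class SCUCCClassifier(_ThermoClassifierBase):
    """Composite-coefficient statistical baseline.

    Fits a control-class reference band (point-wise mean and sd) plus a
    decision threshold on the training composites (maximising training
    F-1); classifies a curve as control when its composite coefficient is
    at or above the threshold.
    """

    def __init__(self, weight_factor: float = 1.0, temps=None):
        self.weight_factor = weight_factor
        self.temps = temps

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y01 = self._fit_labels(y)
        self.n_features_in_ = X.shape[1]
        self.reference_ = X[y01 == 0]
        if self.reference_.shape[0] < 2:
            raise ValueError("need at least 2 control-class training curves")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.threshold_ = calibrate_scucc_threshold(
                X, y01, weight_factor=self.weight_factor
            )
        return self

    def decision_function(self, X):
        """Composite coefficient per curve (higher = more control-like)."""
        check_is_fitted(self, "reference_")
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.array(
                [scucc_composite(self.reference_, row, self.weight_factor)
                 for row in X]
            )

    def predict(self, X):
        c = self.decision_function(X)
        pred01 = (c < self.threshold_).astype(int)  # below threshold -> cancer
        return self._labels_from01(pred01)

    def _p_cancer(self, X):
        # crude monotone map of the margin onto (0, 1) for predict_proba
        c = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(np.clip(c - self.threshold_, -30, 30) * 10.0))
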