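"""Feature-weight estimation for the weighted CBR classifier.

Four schemes, each mapping a labelled training set of
:class:`~rankcbr.profiles.FeatureVector` to a weight vector
``{feature: w_f}`` with ``0 <= w_f <= 1`` and ``sum_f w_f = 1``:

``equal_weights``
    the classical CBR baseline, w_f = 1/m.
``rank_weights``
    the rank-based scheme.  Per feature, each training case is scored by
    its local distance to a fixed control-class reference case; a Wilcoxon
    rank-sum test compares the cancer-class scores with the control-class
    scores, and features are weighted in proportion to the evidence of
    separation, w_f ∝ (1 - p_f).
``entropy_weights``
    label-free dispersion weighting: Shannon entropy of the empirical
    Bernoulli rate for IR, Gaussian differential entropy (floored at 0) for
    the scalar features, and the sum of per-grid-point Gaussian entropies
    for the IND curve; weights are the entropies normalised to sum 1.
``wald_weights``
    parametric comparator: ridge-stabilised binary logistic regression of
    the label on the six predictors (IND reduced to its curve integral),
    with weights proportional to the squared Wald statistics
    (beta_f / se_f)^2 of the standardised coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from .distances import local_distance
from .errors import ConvergenceError, EstimationError
from .labels import encode_labels
from .profiles import FEATURES, SCALAR_FEATURES, Thermogram

#: pooled-sample size at or below which the exact Wilcoxon null is used
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class RankSumResult:
    """Wilcoxon rank-sum test summary.

    ``w`` is the group-1 rank sum on the pooled sample (average ranks for
    ties); ``r`` is the Mann-Whitney form ``w - n1*(n1+1)/2``, which lies in
    ``[0, n1*n0]``; ``p`` is the two-sided p-value.
    """

    r: float
    w: float
    p: float
    n1: int
    n0: int


def wilcoxon_rank_sum(x, y, method: str | None = None) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of ``x`` vs ``y``.

    By default uses the exact null distribution when the pooled sample is
    small (<= 12) and tie-free, otherwise the normal approximation with
    tie-corrected variance and continuity correction; pass
    ``method="exact"`` or ``method="asymptotic"`` to force one.  Two
    identical constant samples carry no evidence and return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EstimationError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[: x.size].sum())
    r = w - x.size * (x.size + 1) / 2.0
    if np.all(pooled == pooled[0]):
        # every observation tied: zero rank variance, no evidence either way
        return RankSumResult(r=r, w=w, p=1.0, n1=x.size, n0=y.size)
    if method is None:
        has_ties = np.unique(pooled).size < pooled.size
        small = x.size + y.size <= EXACT_WILCOXON_MAX_N
        method = "exact" if (small and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return RankSumResult(r=r, w=w, p=p, n1=x.size, n0=y.size)


def _validate(wv: dict) -> dict:
    total = sum(wv.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise EstimationError(f"weights sum to {total}, expected 1")
    for f, v in wv.items():
        if not (-1e-12 <= v <= 1 + 1e-12):
            raise EstimationError(f"weight {f}={v} outside [0, 1]")
    return {f: float(min(max(v, 0.0), 1.0)) for f, v in wv.items()}


def equal_weights(features=FEATURES) -> dict:
    """Uniform weights, w_f = 1/m."""
    features = tuple(features)
    if not features:
        raise EstimationError("need at least one feature")
    return {f: 1.0 / len(features) for f in features}


def _reference_case(cases, labels01) -> dict:
    """Feature-wise median pseudo-case built from the control-class cases."""
    ref_cases = [c for c, l in zip(cases, labels01) if l == 0]
    ref = {
        f: float(np.median([c[f] for c in ref_cases])) for f in SCALAR_FEATURES
    }
    temps = ref_cases[0].ind.temps
    curve = np.median(np.vstack([c.ind.dcp for c in ref_cases]), axis=0)
    ref["IND"] = Thermogram(temps=temps, dcp=curve)
    return ref


def rank_weights(cases, labels, score_mode: str = "reference") -> dict:
    """Wilcoxon-rank-sum feature weights, w_f ∝ (1 - p_f).

    Parameters
    ----------
    cases : sequence of FeatureVector
        Training cases.
    labels : array-like
        Binary class labels (control/cancer or 0/1).
    score_mode : {"reference", "mean-pairwise"}
        How to reduce a feature to one scalar score per case before the
        rank-sum test.  ``"reference"`` (default) scores each case by its
        local distance to a fixed pseudo-case built from the control class
        (feature-wise median; point-wise median curve for IND).
        ``"mean-pairwise"`` scores each case by its mean local distance to
        every other training case.
    """
    labels01 = encode_labels(labels)
    if len(set(labels01.tolist())) < 2:
        raise EstimationError("training set must contain both classes")
    if score_mode not in ("reference", "mean-pairwise"):
        raise EstimationError(f"unknown score_mode {score_mode!r}")

    if score_mode == "reference":
        ref = _reference_case(cases, labels01)
        scores = {
            f: np.array([local_distance(f, c, ref) for c in cases]) for f in FEATURES
        }
    else:
        n = len(cases)
        scores = {}
        for f in FEATURES:
            pair = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    pair[i, j] = pair[j, i] = local_distance(f, cases[i], cases[j])
            scores[f] = pair.sum(axis=1) / max(n - 1, 1)

    one_minus_p = {}
    for f in FEATURES:
        res = wilcoxon_rank_sum(scores[f][labels01 == 1], scores[f][labels01 == 0])
        one_minus_p[f] = 1.0 - res.p
    total = sum(one_minus_p.values())
    if total <= 0:
        return equal_weights(FEATURES)
    return _validate({f: v / total for f, v in one_minus_p.items()})


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-(p * np.log2(p) + (1 - p) * np.log2(1 - p)))


def _normal_entropy(var: float) -> float:
    """Differential entropy of N(mu, var) in bits, floored at 0."""
    if var <= 0:
        return 0.0
    return max(0.5 * float(np.log2(2.0 * np.pi * np.e * var)), 0.0)


def entropy_weights(cases) -> dict:
    """Entropy-proportional weights (label-free)."""
    if len(cases) < 2:
        raise EstimationError("need at least 2 training cases")
    ent = {"IR": _binary_entropy(float(np.mean([c.ir for c in cases])))}
    for f in ("T1", "T2", "PEAK1", "PEAK2"):
        vals = np.array([c[f] for c in cases], dtype=float)
        ent[f] = _normal_entropy(float(np.var(vals, ddof=1)))
    curves = np.vstack([c.ind.dcp for c in cases])
    per_point = np.var(curves, axis=0, ddof=1)
    ent["IND"] = float(sum(_normal_entropy(v) for v in per_point))
    total = sum(ent.values())
    if total <= 0:
        return equal_weights(FEATURES)
    return _validate({f: v / total for f, v in ent.items()})


def _design_matrix(cases) -> np.ndarray:
    """Predictors for the logistic fit; IND enters as its curve integral."""
    rows = []
    for c in cases:
        area = float(np.trapezoid(c.ind.dcp, c.ind.temps))
        rows.append([c.ir, c.t1, c.t2, c.peak1, c.peak2, area])
    return np.asarray(rows, dtype=float)


def _logistic_irls(X, y, ridge: float, max_iter: int, tol: float) -> tuple:
    """Ridge-penalised logistic fit by damped Newton; returns (beta, cov)."""
    n, p = X.shape
    beta = np.zeros(p)

    def penalised_loglik(b):
        eta = np.clip(X @ b, -30, 30)
        return float(y @ eta - np.sum(np.log1p(np.exp(eta))) - 0.5 * ridge * (b @ b))

    ll = penalised_loglik(beta)
    H = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        wd = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - ridge * beta
        H = X.T @ (X * wd[:, None]) + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        # step-halving keeps the penalised log-likelihood monotone
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new = penalised_loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        ll = max(ll, ll_new)
        if np.max(np.abs(grad)) < tol * max(1.0, n):
            return beta, np.linalg.inv(H)
    grad = X.T @ (y - 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))) - ridge * beta
    if np.max(np.abs(grad)) < 1e-3 * max(1.0, n):
        # flat plateau near the optimum: accept
        return beta, np.linalg.inv(H)
    raise ConvergenceError(
        f"logistic fit did not converge (|grad|={np.max(np.abs(grad)):.3g})",
        last_iterate=beta,
    )


def wald_weights(
    cases, labels, ridge: float = 1e-4, max_iter: int = 100, tol: float = 1e-8
) -> dict:
    """Standardised-Wald feature weights from a binary logistic fit.

    Predictors are standardised before fitting (zero-variance columns are
    left centred with unit divisor, so their coefficients are exactly 0);
    a small ridge penalty keeps the fit defined under separation.  The
    intercept is excluded from the weights.  If every Wald statistic is
    numerically zero (no signal) the scheme falls back to equal weights.
    """
    labels01 = encode_labels(labels)
    if len(set(labels01.tolist())) < 2:
        raise EstimationError("training set must contain both classes")
    Xraw = _design_matrix(cases)
    mu = Xraw.mean(axis=0)
    sd = Xraw.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.column_stack([np.ones(len(cases)), (Xraw - mu) / sd])
    beta, cov = _logistic_irls(X, labels01.astype(float), ridge, max_iter, tol)
    se = np.sqrt(np.diag(cov))
    wald = (beta[1:] / se[1:]) ** 2
    total = float(wald.sum())
    if total <= 1e-12:
        return equal_weights(FEATURES)
    return _validate(dict(zip(FEATURES, wald / total)))
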