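"""Per-feature local distances.

Scalar features (IR, T1, T2, PEAK1, PEAK2) are compared by the *squared*
Euclidean distance; the square is kept because downstream only the
rank-order of distances matters, and ranks are invariant under any strictly
increasing transform.  The curve-valued IND feature is compared by the
discrete Frechet distance between the two polylines in the
(temperature, dCp) plane: the smallest leash length that lets two walkers
traverse both curves monotonically.  On sampled curves the discrete variant
(dynamic programming over the coupling lattice) upper-bounds the continuous
one and converges to it as the grid refines.
"""

from __future__ import annotations

import numpy as np

from .profiles import FEATURES, Thermogram

try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


def euclidean_sq(a, b) -> float:
    """Squared Euclidean distance between two equal-length real vectors."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return float(d @ d)


@njit(cache=False)
def _dfd_kernel(ax, ay, bx, by):  # pragma: no cover - compiled
    n = ax.shape[0]
    m = bx.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        dx = ax[0] - bx[j]
        dy = ay[0] - by[j]
        d = (dx * dx + dy * dy) ** 0.5
        prev[j] = d if j == 0 else max(prev[j - 1], d)
    for i in range(1, n):
        for j in range(m):
            dx = ax[i] - bx[j]
            dy = ay[i] - by[j]
            d = (dx * dx + dy * dy) ** 0.5
            if j == 0:
                best = prev[0]
            else:
                best = min(prev[j], prev[j - 1], cur[j - 1])
            cur[j] = d if d > best else best
        prev, cur = cur, prev
    return prev[m - 1]


def _dfd_python(ax, ay, bx, by):
    # rolling two-row DP, identical recurrence to the jitted kernel
    m = bx.shape[0]
    d0 = np.hypot(ax[0] - bx, ay[0] - by)
    prev = np.maximum.accumulate(d0)
    for i in range(1, ax.shape[0]):
        di = np.hypot(ax[i] - bx, ay[i] - by)
        cur = np.empty(m)
        cur[0] = max(prev[0], di[0])
        for j in range(1, m):
            cur[j] = max(di[j], min(prev[j], prev[j - 1], cur[j - 1]))
        prev = cur
    return float(prev[-1])


def _as_points(curve) -> np.ndarray:
    if isinstance(curve, Thermogram):
        return curve.as_points()
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("a curve must be a Thermogram or an (n, 2) point array")
    return pts


def discrete_frechet(a, b, x_scale: float = 1.0, y_scale: float = 1.0) -> float:
    """Discrete Frechet distance between two curves.

    Parameters
    ----------
    a, b : Thermogram or (n, 2) array
        Curves as sequences of (temperature, dCp) points.
    x_scale, y_scale : float
        Optional per-axis rescaling applied before the Euclidean ground
        metric (1.0 keeps raw units).
    """
    pa = _as_points(a)
    pb = _as_points(b)
    if pa.shape[0] == 0 or pb.shape[0] == 0:
        raise ValueError("curves must contain at least one point")
    ax = np.ascontiguousarray(pa[:, 0] * x_scale)
    ay = np.ascontiguousarray(pa[:, 1] * y_scale)
    bx = np.ascontiguousarray(pb[:, 0] * x_scale)
    by = np.ascontiguousarray(pb[:, 1] * y_scale)
    if _HAVE_NUMBA:
        return float(_dfd_kernel(ax, ay, bx, by))
    return _dfd_python(ax, ay, bx, by)


def _feature_value(case, feature: str):
    if hasattr(case, "__getitem__"):
        return case[feature]
    raise TypeError(f"cannot read feature {feature!r} from {type(case).__name__}")


def local_distance(feature: str, case, target, frechet_scale=None) -> float:
    """Dispatch the per-feature local distance.

    Scalars go through :func:`euclidean_sq`; ``IND`` through
    :func:`discrete_frechet`.  ``case`` and ``target`` may be
    :class:`~rankcbr.profiles.FeatureVector` instances or any mapping from
    feature name to value.
    """
    if feature not in FEATURES:
        raise KeyError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    a = _feature_value(case, feature)
    b = _feature_value(target, feature)
    if feature == "IND":
        xs, ys = frechet_scale if frechet_scale is not None else (1.0, 1.0)
        return discrete_frechet(a, b, x_scale=xs, y_scale=ys)
    return euclidean_sq(a, b)


def distance_table(cases, target, frechet_scale=None) -> dict[str, np.ndarray]:
    """Local distances of every case to one target, per feature.

    Returns a mapping ``feature -> (n_cases,)`` array of nonnegative
    distances, the raw material for rank-order similarity.
    """
    return {
        f: np.array(
            [local_distance(f, c, target, frechet_scale=frechet_scale) for c in cases]
        )
        for f in FEATURES
    }
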