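"""Thermogram profiles and per-case feature extraction.

A plasma thermogram is the excess heat capacity (dCp) of a plasma sample
recorded by differential scanning calorimetry on a fixed temperature grid,
conventionally 45-90 degC.  Its shape reflects the plasma proteome and
typically shows one or two melting peaks.  Each case is summarised by six
features:

``IR``
    binary initial-response flag: 1 if the curve initially increases.
``T1``, ``PEAK1``
    location (degC, in [45, 55]) and height of the low-temperature peak of
    the kernel-smoothed curve.
``T2``, ``PEAK2``
    location (degC, in (55, 90]) and height of the high-temperature peak.
``IND``
    the raw dCp vector itself, treated as one curve-valued feature.

Peak locations/heights are read off a Nadaraya-Watson (Gaussian kernel)
regression of the curve; ``IND`` stays unsmoothed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np

from .errors import CoverageError, ParseError
from .labels import check_label

#: Canonical feature order used throughout the package.
FEATURES = ("IR", "T1", "T2", "PEAK1", "PEAK2", "IND")

#: Column order used when serialising weight/feature tables.
SCALAR_FEATURES = ("IR", "T1", "T2", "PEAK1", "PEAK2")


@dataclass(frozen=True)
class Thermogram:
    """One subject's dCp curve on a strictly increasing temperature grid."""

    temps: np.ndarray
    dcp: np.ndarray

    def __post_init__(self):
        temps = np.asarray(self.temps, dtype=float)
        dcp = np.asarray(self.dcp, dtype=float)
        if temps.ndim != 1 or dcp.ndim != 1:
            raise ValueError("temps and dcp must be one-dimensional")
        if temps.shape[0] != dcp.shape[0]:
            raise ValueError(
                f"temps (len {temps.shape[0]}) and dcp (len {dcp.shape[0]}) differ"
            )
        if temps.shape[0] == 0:
            raise ValueError("a thermogram needs at least one point")
        if temps.shape[0] > 1 and not np.all(np.diff(temps) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temps", temps)
        object.__setattr__(self, "dcp", dcp)

    def __len__(self) -> int:
        return self.temps.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Thermogram):
            return NotImplemented
        return np.array_equal(self.temps, other.temps) and np.array_equal(
            self.dcp, other.dcp
        )

    def as_points(self) -> np.ndarray:
        """Return the curve as an (n, 2) array of (temperature, dCp) points."""
        return np.column_stack([self.temps, self.dcp])


@dataclass(frozen=True)
class FeatureVector:
    """The six per-case features; ``ind`` holds the full raw curve."""

    ir: int
    t1: float
    t2: float
    peak1: float
    peak2: float
    ind: Thermogram

    def __post_init__(self):
        if self.ir not in (0, 1):
            raise ValueError(f"IR must be 0 or 1, got {self.ir}")
        if self.peak1 < 0 or self.peak2 < 0:
            raise ValueError("peak heights must be nonnegative")

    def __getitem__(self, feature: str):
        try:
            return {
                "IR": self.ir,
                "T1": self.t1,
                "T2": self.t2,
                "PEAK1": self.peak1,
                "PEAK2": self.peak2,
                "IND": self.ind,
            }[feature]
        except KeyError:
            raise KeyError(f"unknown feature {feature!r}; expected one of {FEATURES}")


def smooth_curve(t: Thermogram, bandwidth: float) -> Thermogram:
    """Nadaraya-Watson Gaussian-kernel regression of a curve onto its own grid.

    Parameters
    ----------
    t : Thermogram
        Input curve.
    bandwidth : float
        Kernel standard deviation in degC; must be positive.

    Returns
    -------
    Thermogram
        Smoothed curve on the same grid (same length as the input).
    """
    if not bandwidth > 0:
        raise ValueError(f"bandwidth must be > 0, got {bandwidth}")
    # Gaussian weights between every pair of grid points; constants cancel.
    diff = (t.temps[:, None] - t.temps[None, :]) / bandwidth
    logw = -0.5 * diff * diff
    # Subtract the row max before exponentiating so a tiny bandwidth
    # degenerates gracefully to nearest-point interpolation.
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    smoothed = (w @ t.dcp) / w.sum(axis=1)
    return replace(t, dcp=smoothed)


def _initial_slope(t: Thermogram, window: float) -> float:
    """Least-squares slope of the curve over its first `window` degC."""
    mask = t.temps <= t.temps[0] + window
    if mask.sum() < 2:
        mask[: min(2, len(t))] = True
    x = t.temps[mask]
    y = t.dcp[mask]
    if np.ptp(x) == 0:
        return 0.0
    return float(np.polyfit(x, y, 1)[0])


def _window_argmax(t: Thermogram, lo: float, hi: float, include_lo: bool):
    mask = (t.temps >= lo if include_lo else t.temps > lo) & (t.temps <= hi)
    if not mask.any():
        raise CoverageError(
            f"grid [{t.temps[0]}, {t.temps[-1]}] has no points in "
            f"window ({lo}, {hi}]"
        )
    idx = np.flatnonzero(mask)
    # ties on a plateau resolve to the lowest temperature (argmax takes the
    # first maximum), which is deterministic and grid-stable
    best = idx[int(np.argmax(t.dcp[idx]))]
    return float(t.temps[best]), float(t.dcp[best])


def extract_features(
    t: Thermogram,
    bandwidth: float = 1.0,
    t1_window: tuple[float, float] = (45.0, 55.0),
    t2_window: tuple[float, float] = (55.0, 90.0),
    initial_window: float = 2.0,
) -> FeatureVector:
    """Extract the six-feature summary of a thermogram.

    The curve is smoothed by Gaussian kernel regression; ``T1``/``PEAK1`` are
    the location and height of the maximum of the smoothed curve on
    ``[t1_window[0], t1_window[1]]`` and ``T2``/``PEAK2`` on
    ``(t2_window[0], t2_window[1]]`` (half-open so every grid point belongs
    to exactly one window).  ``IR`` is 1 when the least-squares slope of the
    smoothed curve over the first ``initial_window`` degC is strictly
    positive (a flat start counts as non-increasing).  ``IND`` is the raw,
    unsmoothed input curve.
    """
    if t.temps[0] > t1_window[0] or t.temps[-1] < t2_window[1]:
        raise CoverageError(
            f"grid [{t.temps[0]}, {t.temps[-1]}] does not cover the feature "
            f"windows [{t1_window[0]}, {t2_window[1]}]"
        )
    s = smooth_curve(t, bandwidth)
    t1, peak1 = _window_argmax(s, t1_window[0], t1_window[1], include_lo=True)
    t2, peak2 = _window_argmax(s, t2_window[0], t2_window[1], include_lo=False)
    ir = 1 if _initial_slope(s, initial_window) > 0 else 0
    return FeatureVector(
        ir=ir,
        t1=t1,
        t2=t2,
        peak1=max(peak1, 0.0),
        peak2=max(peak2, 0.0),
        ind=t,
    )


# ---------------------------------------------------------------------------
# Feature-table I/O: a scalar-feature CSV plus a curve sidecar for IND.
# ---------------------------------------------------------------------------

FEATURE_HEADER = ["subject_id", "label", "IR", "T1", "T2", "PEAK1", "PEAK2"]


def write_features(cases, labels, path, ids=None) -> None:
    """Write the scalar features to ``path`` (CSV, one row per case)."""
    ids = ids if ids is not None else [f"S{i:03d}" for i in range(len(cases))]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FEATURE_HEADER)
        for sid, label, fv in zip(ids, labels, cases):
            writer.writerow(
                [sid, label, fv.ir]
                + [repr(float(v)) for v in (fv.t1, fv.t2, fv.peak1, fv.peak2)]
            )


def read_features(path, curves) -> tuple[list[FeatureVector], list[str], list[str]]:
    """Read a scalar-feature CSV and attach curves (the IND sidecar).

    ``curves`` is the parallel list of :class:`Thermogram` read from the
    cohort CSV (see :mod:`rankcbr.simulate`), in the same row order.
    """
    cases: list[FeatureVector] = []
    labels: list[str] = []
    ids: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != FEATURE_HEADER:
            raise ParseError(f"bad feature header: {header!r}")
        for row_no, row in enumerate(reader):
            if len(row) != len(FEATURE_HEADER):
                raise ParseError(f"row {row_no}: expected {len(FEATURE_HEADER)} cells")
            sid, label = row[0], check_label(row[1], row_no)
            try:
                ir = int(row[2])
                t1, t2, p1, p2 = (float(v) for v in row[3:7])
            except ValueError as exc:
                raise ParseError(f"row {row_no}: non-numeric cell ({exc})") from exc
            if row_no >= len(curves):
                raise ParseError(f"row {row_no}: no matching curve in sidecar")
            cases.append(
                FeatureVector(ir=ir, t1=t1, t2=t2, peak1=p1, peak2=p2,
                              ind=curves[row_no])
            )
            labels.append(label)
            ids.append(sid)
    return cases, labels, ids
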