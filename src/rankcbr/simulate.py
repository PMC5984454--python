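"""Seeded synthetic plasma-thermogram cohorts.

Real plasma thermograms show one or two melting peaks on 45-90 degC with
large between-subject variation even within a clinical class.  The
generator emulates exactly that structure: each subject's curve is a sum of
one or two Gaussian bumps whose centres, widths and amplitudes are
class-dependent, jittered per subject, scaled by a lognormal per-subject
factor, overlaid with i.i.d. measurement noise and clipped at zero from
below (excess heat capacity is reported nonnegative).

Reproducibility: each subject draws from an independent substream keyed by
``(seed, subject_index)``, so subject *i*'s curve does not depend on how
many other subjects are generated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InvalidSpecError, ParseError
from .labels import CANCER, CONTROL, check_label
from .profiles import Thermogram


@dataclass(frozen=True)
class PeakParams:
    """Class-level geometry of the one-or-two-peak curve family.

    ``mu1``/``mu2`` are the peak-centre temperatures (degC), constrained to
    the low-temperature window [45, 55] and the high-temperature window
    [56, 90] that the feature extractor searches.  ``p_single_peak`` is the
    probability that a subject's second peak is suppressed entirely;
    ``jitter_sd`` (degC) jitters both peak centres per subject.
    """

    mu1: float
    mu2: float
    sd1: float
    sd2: float
    amp1: float
    amp2: float
    p_single_peak: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self):
        if not (45.0 <= self.mu1 <= 55.0):
            raise InvalidSpecError(f"mu1 must lie in [45, 55], got {self.mu1}")
        if not (56.0 <= self.mu2 <= 90.0):
            raise InvalidSpecError(f"mu2 must lie in [56, 90], got {self.mu2}")
        for name in ("sd1", "sd2", "amp1", "amp2"):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"{name} must be > 0")
        if not (0.0 <= self.p_single_peak <= 1.0):
            raise InvalidSpecError("p_single_peak must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise InvalidSpecError("jitter_sd must be >= 0")


def default_class_params() -> dict[str, PeakParams]:
    """Default two-class peak geometry (see docs/methods.md for rationale)."""
    return {
        CONTROL: PeakParams(
            mu1=50.0, mu2=62.0, sd1=2.5, sd2=4.0, amp1=1.0, amp2=0.65,
            p_single_peak=0.15, jitter_sd=1.2,
        ),
        CANCER: PeakParams(
            mu1=51.5, mu2=65.0, sd1=3.0, sd2=5.5, amp1=0.8, amp2=0.85,
            p_single_peak=0.30, jitter_sd=1.8,
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_subjects: int = 70
    cancer_fraction: float = 0.5
    grid_start: float = 45.0
    grid_end: float = 90.0
    grid_length: int = 451
    class_params: dict[str, PeakParams] = field(default_factory=default_class_params)
    noise_sd: float = 0.05
    subject_sd: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.n_subjects, (int, np.integer)) and self.n_subjects > 0):
            raise InvalidSpecError(f"n_subjects must be a positive int, got {self.n_subjects}")
        if not (isinstance(self.grid_length, (int, np.integer)) and self.grid_length >= 2):
            raise InvalidSpecError(f"grid_length must be an int >= 2, got {self.grid_length}")
        if not self.grid_start < self.grid_end:
            raise InvalidSpecError("grid_start must be < grid_end")
        if not (0.0 <= self.cancer_fraction <= 1.0):
            raise InvalidSpecError("cancer_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise InvalidSpecError("noise_sd and subject_sd must be >= 0")
        missing = {CONTROL, CANCER} - set(self.class_params)
        if missing:
            raise InvalidSpecError(f"class_params missing classes: {sorted(missing)}")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_start, self.grid_end, self.grid_length)

    @property
    def n_cancer(self) -> int:
        # round-half-even is deliberate: matches the documented contract
        return int(round(self.n_subjects * self.cancer_fraction))

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "class_params" in d:
            d["class_params"] = {
                check_label(k): (v if isinstance(v, PeakParams) else PeakParams(**v))
                for k, v in d["class_params"].items()
            }
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_params"] = {k: asdict(v) for k, v in self.class_params.items()}
        return d


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    z = (t - mu) / sd
    return np.exp(-0.5 * z * z)


def generate_cohort(spec: CohortSpec) -> tuple[list[Thermogram], list[str]]:
    """Generate ``spec.n_subjects`` curves plus class labels.

    The first ``round(n_subjects * cancer_fraction)`` subjects are labelled
    cancer, the rest control.  Identical specs (including seed) produce
    bitwise-identical cohorts.
    """
    grid = spec.grid
    curves: list[Thermogram] = []
    labels: list[str] = []
    n_cancer = spec.n_cancer
    for i in range(spec.n_subjects):
        label = CANCER if i < n_cancer else CONTROL
        pp = spec.class_params[label]
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, i])
        jitter1 = rng.normal(0.0, pp.jitter_sd) if pp.jitter_sd > 0 else 0.0
        jitter2 = rng.normal(0.0, pp.jitter_sd) if pp.jitter_sd > 0 else 0.0
        keep_second = rng.random() >= pp.p_single_peak if pp.p_single_peak > 0 else True
        scale = float(np.exp(rng.normal(0.0, spec.subject_sd))) if spec.subject_sd > 0 else 1.0
        curve = pp.amp1 * _gauss(grid, pp.mu1 + jitter1, pp.sd1)
        if keep_second:
            curve = curve + pp.amp2 * _gauss(grid, pp.mu2 + jitter2, pp.sd2)
        curve = scale * curve
        if spec.noise_sd > 0:
            curve = curve + rng.normal(0.0, spec.noise_sd, size=grid.shape[0])
        curves.append(Thermogram(temps=grid, dcp=np.clip(curve, 0.0, None)))
        labels.append(label)
    return curves, labels


# ---------------------------------------------------------------------------
# Cohort CSV round trip: header "subject_id,label,T45.0,...,T90.0"
# ---------------------------------------------------------------------------


def _temp_columns(temps: np.ndarray) -> list[str]:
    # repr round-trips doubles exactly, so read(write(x)) preserves the grid
    return [f"T{float(t)!r}" for t in temps]


def write_cohort(curves, labels, path, ids=None) -> None:
    """Write a cohort to CSV with full float precision (round-trip exact)."""
    if not curves:
        raise InvalidSpecError("cannot write an empty cohort")
    ids = ids if ids is not None else [f"S{i:03d}" for i in range(len(curves))]
    temps = curves[0].temps
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label"] + _temp_columns(temps))
        for sid, label, tg in zip(ids, labels, curves):
            if tg.temps.shape != temps.shape or not np.array_equal(tg.temps, temps):
                raise InvalidSpecError("all curves in a cohort must share one grid")
            writer.writerow([sid, label] + [repr(float(v)) for v in tg.dcp])


def read_cohort(path, expected_grid_length: int | None = None):
    """Read a cohort CSV; returns ``(curves, labels, ids)``.

    Raises :class:`ParseError` naming the offending row/column on malformed
    headers, non-numeric cells or unknown labels, and when the file's grid
    length disagrees with ``expected_grid_length``.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[:2] != ["subject_id", "label"] or len(header) < 3:
            raise ParseError(f"malformed cohort header: {header!r}")
        try:
            temps = np.array([float(c[1:]) for c in header[2:]])
        except ValueError:
            raise ParseError("malformed temperature columns in header")
        if expected_grid_length is not None and temps.shape[0] != expected_grid_length:
            raise ParseError(
                f"file has {temps.shape[0]} temperature columns, "
                f"expected {expected_grid_length}"
            )
        curves, labels, ids = [], [], []
        for row_no, row in enumerate(reader):
            if len(row) != len(header):
                raise ParseError(
                    f"row {row_no}: {len(row)} cells, expected {len(header)}"
                )
            check_label(row[1], row_no)
            try:
                dcp = np.array([float(v) for v in row[2:]])
            except ValueError:
                bad = next(i for i, v in enumerate(row[2:]) if not _is_float(v))
                raise ParseError(
                    f"row {row_no}, column {header[2 + bad]}: non-numeric cell {row[2 + bad]!r}"
                )
            curves.append(Thermogram(temps=temps, dcp=dcp))
            labels.append(row[1])
            ids.append(row[0])
    return curves, labels, ids


def _is_float(v: str) -> bool:
    try:
        float(v)
        return True
    except ValueError:
        return False
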