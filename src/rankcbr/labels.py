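"""Two-class label handling: ``control`` (negative) vs ``cancer`` (positive)."""

from __future__ import annotations

import numpy as np

from .errors import ParseError

CONTROL = "control"
CANCER = "cancer"
CLASS_LABELS = (CONTROL, CANCER)


def encode_labels(y) -> np.ndarray:
    """Encode labels as integers with cancer = 1, control = 0.

    Accepts the canonical string labels, a 0/1 integer coding, or any other
    two-level coding (mapped by sorted order, smaller level -> 0).
    """
    arr = np.asarray(y)
    if arr.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    out = np.empty(arr.shape[0], dtype=int)
    levels = set(np.unique(arr).tolist())
    if levels <= {CONTROL, CANCER}:
        out[:] = [1 if v == CANCER else 0 for v in arr]
    elif levels <= {0, 1}:
        out[:] = arr.astype(int)
    elif len(levels) <= 2:
        order = sorted(levels, key=str)
        mapping = {lvl: i for i, lvl in enumerate(order)}
        out[:] = [mapping[v] for v in arr]
    else:
        raise ValueError(f"more than two label levels: {sorted(map(str, levels))}")
    return out


def check_label(value: str, row: int | None = None) -> str:
    """Validate a single stored label string, raising :class:`ParseError`."""
    if value not in CLASS_LABELS:
        where = f" at row {row}" if row is not None else ""
        raise ParseError(
            f"invalid class label {value!r}{where}; expected one of {CLASS_LABELS}"
        )
    return value
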