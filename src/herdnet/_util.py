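"""Small internal helpers shared across modules."""

from __future__ import annotations

import numpy as np

POSITION_COLUMNS = ["animal_id", "day_index", "timestamp", "x_m", "y_m"]


def runs_true(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal runs of True in a 1-D or 2-D boolean mask.

    For 2-D input runs never straddle rows.  Returns ``(row, start, length)``
    arrays; for 1-D input ``row`` is all zeros.
    """
    mask = np.asarray(mask, dtype=bool)
    squeeze = mask.ndim == 1
    if squeeze:
        mask = mask[None, :]
    nrow, ncol = mask.shape
    padded = np.zeros((nrow, ncol + 2), dtype=bool)
    padded[:, 1:-1] = mask
    flat = padded.ravel()
    prev = np.empty_like(flat)
    prev[0] = False
    prev[1:] = flat[:-1]
    nxt = np.empty_like(flat)
    nxt[-1] = False
    nxt[:-1] = flat[1:]
    starts = np.flatnonzero(flat & ~prev)
    ends = np.flatnonzero(flat & ~nxt)
    row = starts // (ncol + 2)
    col = starts % (ncol + 2) - 1
    length = ends - starts + 1
    return row, col, length


def subseed(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for a named stream derived from a master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, int(stream)])


def require_sorted_unique(timestamps: np.ndarray, label: str = "track") -> None:
    t = np.asarray(timestamps)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{label}: timestamps must be strictly increasing per animal")
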