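"""Numeric rules for multiplexed-IHC histo-cytometry.

Colour-deconvolved staining channels (floating point, roughly 0-3) are
converted to pseudo-immunofluorescence integers via a fixed 8-bit-style
mapping; background is removed with a large moving-average window; the red
marker channel additionally requires the red signal to exceed a fixed
fraction of the brown registration signal (the two chromogens have similar
colour profiles). Per-cell marker-coverage tables are then classified:
cells positive for epithelial/endothelial/mural lineage markers are
excluded, remaining cells positive for at least one fibroblast marker are
assigned to the subpopulation of their most highly covered marker (ACTA2
and POSTN both indicate myofibroblasts, AOC3 alveolar and CD34 adventitial
fibroblasts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "hsd_to_pif8",
    "subtract_background",
    "coverage_from_channel",
    "classify_histocytometry",
    "EXCLUSION_MARKERS",
    "FIBROBLAST_MARKERS",
]

EXCLUSION_MARKERS = ("PanCK", "CD31", "MCAM")
#: marker -> subpopulation; listed in tie-break priority order
FIBROBLAST_MARKERS = (
    ("CD34", "adventitial"),
    ("AOC3", "alveolar"),
    ("POSTN", "myofibroblast"),
    ("ACTA2", "myofibroblast"),
)
#: pixel-level staining threshold separating signal from blush/bleed
PIXEL_STAIN_THRESHOLD = 7


def hsd_to_pif8(value):
    """Map a non-negative stain-density float to the pseudo-IF integer range.

    ``min(256, ceil(value / 1.5 * 256))`` — the upstream imaging pipeline's
    fixed conversion. Accepts scalars or arrays.
    """
    arr = np.asarray(value, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("input must be finite")
    if (arr < 0).any():
        raise ValueError("input must be >= 0")
    out = np.minimum(256, np.ceil(arr / 1.5 * 256.0)).astype(np.int32)
    if np.isscalar(value) or arr.ndim == 0:
        return int(out)
    return out


def subtract_background(
    channel: np.ndarray,
    window: int = 151,
    min_signal: int = 5,
    brown: np.ndarray | None = None,
    red_brown_ratio: float = 0.43,
) -> np.ndarray:
    """Zero pixels not clearly above the local moving-average background.

    The background of each pixel is the mean over a ``window x window``
    neighbourhood (edge-replicated padding); pixels with
    ``original - background < min_signal`` are set to 0, all others keep
    their original value. When ``brown`` is given (red-channel mode),
    pixels where ``red < red_brown_ratio * brown`` are also zeroed.
    """
    ch = np.asarray(channel)
    if ch.ndim != 2:
        raise ValueError("channel must be 2-D")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > max(ch.shape):
        raise ValueError("window larger than both image dimensions")
    if brown is not None and np.asarray(brown).shape != ch.shape:
        raise ValueError("brown channel shape mismatch")

    # window sums via a summed-area table on the edge-replicated image;
    # for integer channels the threshold comparison is then exact
    # (original - background >= min_signal  <=>  original * w^2 - sum >= min_signal * w^2)
    r = window // 2
    is_int = np.issubdtype(ch.dtype, np.integer)
    pad = np.pad(ch, r, mode="edge").astype(np.int64 if is_int else float)
    sat = np.zeros((pad.shape[0] + 1, pad.shape[1] + 1), dtype=pad.dtype)
    sat[1:, 1:] = pad.cumsum(axis=0).cumsum(axis=1)
    h, w = ch.shape
    win_sum = (
        sat[window : window + h, window : window + w]
        - sat[:h, window : window + w]
        - sat[window : window + h, :w]
        + sat[:h, :w]
    )
    w2 = window * window
    if is_int:
        keep = ch.astype(np.int64) * w2 - win_sum >= min_signal * w2
    else:
        keep = ch - win_sum / w2 >= min_signal
    if brown is not None:
        keep &= ch >= red_brown_ratio * np.asarray(brown, dtype=float)
    return np.where(keep, ch, 0)


def coverage_from_channel(
    channel: np.ndarray, cell_mask: np.ndarray, threshold: int = PIXEL_STAIN_THRESHOLD
) -> float:
    """Fraction of a cell region's pixels with significant staining."""
    m = np.asarray(cell_mask, dtype=bool)
    if m.sum() == 0:
        raise ValueError("empty cell mask")
    return float((np.asarray(channel)[m] >= threshold).mean())


def classify_histocytometry(
    cells: pd.DataFrame, positive_min_coverage: float = 0.01
) -> pd.DataFrame:
    """Assign stromal subpopulation labels from per-cell marker coverages.

    A cell is ``excluded`` when any of PanCK/CD31/MCAM reaches the
    positivity floor; ``unclassified`` when no fibroblast marker does;
    otherwise labelled by the most highly covered fibroblast marker (ACTA2
    or POSTN -> myofibroblast, AOC3 -> alveolar, CD34 -> adventitial). Exact
    coverage ties are broken by the fixed priority
    CD34 > AOC3 > POSTN > ACTA2 and flagged in the ``tie`` column.
    """
    fib_markers = [m for m, _ in FIBROBLAST_MARKERS]
    missing = [m for m in (*EXCLUSION_MARKERS, *fib_markers) if m not in cells.columns]
    if missing:
        raise KeyError(f"missing marker columns: {missing}")

    excl = (cells[list(EXCLUSION_MARKERS)] >= positive_min_coverage).any(axis=1)
    fib_cov = cells[fib_markers].to_numpy(dtype=float)
    any_fib = (fib_cov >= positive_min_coverage).any(axis=1)

    # argmax in priority order: first index wins on exact ties
    best = fib_cov.argmax(axis=1)
    max_cov = fib_cov.max(axis=1)
    tie = (fib_cov == max_cov[:, None]).sum(axis=1) > 1

    marker_to_label = dict(FIBROBLAST_MARKERS)
    labels = np.where(
        excl,
        "excluded",
        np.where(
            ~any_fib,
            "unclassified",
            [marker_to_label[fib_markers[b]] for b in best],
        ),
    )
    out = cells.copy()
    out["label"] = labels
    out["tie"] = tie & ~excl & any_fib
    return out
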