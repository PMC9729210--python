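"""Overlap metrics for binary segmentation masks.

Jaccard ``J = |X∩Y| / |X∪Y|`` and Sørensen–Dice ``D = 2|X∩Y| / (|X|+|Y|)``,
related by ``D = 2J/(1+J)``.  Convention for degenerate inputs: two empty
masks agree perfectly (1.0, with a warning); exactly one empty mask scores 0.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["jaccard", "dice"]


def _as_masks(x, y) -> tuple[np.ndarray, np.ndarray]:
    mx, my = np.asarray(x), np.asarray(y)
    if mx.shape != my.shape:
        raise ValueError(f"mask shapes differ: {mx.shape} vs {my.shape}")
    for m in (mx, my):
        if m.dtype != bool and not np.isin(m, (0, 1)).all():
            raise ValueError("masks must be binary (bool or {0,1})")
    return mx.astype(bool), my.astype(bool)


def jaccard(x, y) -> float:
    """Jaccard overlap |X∩Y| / |X∪Y| of two same-shape binary masks."""
    mx, my = _as_masks(x, y)
    union = np.logical_or(mx, my).sum()
    if union == 0:
        warnings.warn("both masks empty: Jaccard defined as 1.0", RuntimeWarning,
                      stacklevel=2)
        return 1.0
    return float(np.logical_and(mx, my).sum() / union)


def dice(x, y) -> float:
    """Sørensen–Dice overlap 2|X∩Y| / (|X|+|Y|) of two binary masks."""
    mx, my = _as_masks(x, y)
    total = int(mx.sum()) + int(my.sum())
    if total == 0:
        warnings.warn("both masks empty: Dice defined as 1.0", RuntimeWarning,
                      stacklevel=2)
        return 1.0
    return float(2.0 * np.logical_and(mx, my).sum() / total)
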