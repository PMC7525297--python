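"""Segmentation agreement metrics: Dice similarity coefficient and maximum
Hausdorff distance.

Dice measures region overlap, 2|A∩B|/(|A|+|B|) ∈ [0, 1]. The maximum
Hausdorff distance HD(A,B) = max{h(A,B), h(B,A)} with
h(A,B) = max_{a∈A} min_{b∈B} ‖a−b‖ is the worst-case boundary disagreement;
it is computed here on boundary pixel sets in Euclidean pixel units (the only
length unit the rasters carry — note this makes reported HD values
resolution-dependent). A high Dice can coexist with a large HD when the
contour is mostly right but locally protrudes or recesses, which is exactly
why both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .snake import mask_boundary

__all__ = ["MetricsRecord", "dice", "directed_hausdorff", "max_hausdorff", "evaluate"]


@dataclass
class MetricsRecord:
    dice: float
    max_hd: float
    channel_label: str = ""
    phantom_id: str = ""
    n_pred_pixels: int = 0
    n_truth_pixels: int = 0
    valid: bool = True


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|) of two binary masks."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * int((A & B).sum()) / (na + nb)


def _as_points(pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("point set must be a nonempty (N, 2) array")
    return pts


def directed_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """h(A,B) = max over a∈A of the Euclidean distance to the nearest b∈B."""
    A, B = _as_points(A), _as_points(B)
    d, _ = cKDTree(B).query(A, k=1)
    return float(np.max(d))


def max_hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric maximum Hausdorff distance max{h(A,B), h(B,A)}."""
    return max(directed_hausdorff(A, B), directed_hausdorff(B, A))


def evaluate(
    pred: np.ndarray,
    truth: np.ndarray,
    channel_label: str = "",
    phantom_id: str = "",
) -> MetricsRecord:
    """Dice on the full masks and max Hausdorff on their boundary pixel sets.

    An empty prediction yields a flagged record (dice 0, max_hd NaN) rather
    than an exception, so cohort evaluations survive failed segmentations.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    if not truth.any():
        raise ValueError("ground-truth mask is empty")
    n_pred, n_truth = int(pred.sum()), int(truth.sum())
    if n_pred == 0:
        return MetricsRecord(0.0, float("nan"), channel_label, phantom_id,
                             0, n_truth, valid=False)
    hd = max_hausdorff(mask_boundary(pred), mask_boundary(truth))
    return MetricsRecord(dice(pred, truth), hd, channel_label, phantom_id,
                         n_pred, n_truth)
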