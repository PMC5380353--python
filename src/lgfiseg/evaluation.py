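"""Mask scaling, phase-to-region extraction and overlap metrics.

A converged level set is turned into hard regions by its sign pattern,
optionally after scaling by a binary region-of-interest mask (xi = phi * m),
which zeroes — and thereby excludes — everything outside the mask.  Overlap
against ground truth is measured by the Jaccard index J = |S∩G| / |S∪G|,
the Dice coefficient D = 2|S∩G| / (|S| + |G|) = 2J / (1 + J), and the
percentage accuracy 100 * J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionSet",
    "mask_scale",
    "extract_regions",
    "accuracy",
    "jaccard_dice",
    "match_regions",
    "evaluate_labels",
]


@dataclass(frozen=True)
class RegionSet:
    """Binary masks of the extracted regions, mutually disjoint.

    Two-phase: [phi > 0, phi < 0].  Four-phase: the four sign combinations
    R1 = (xi1>0)&(xi2>0), R2 = (xi1>0)&(xi2<0), R3 = (xi1<0)&(xi2>0),
    R4 = (xi1<0)&(xi2<0); R4 is retained but is typically empty in brain
    segmentations and can be discarded by the caller.
    """

    masks: tuple[np.ndarray, ...]

    def __len__(self):
        return len(self.masks)

    def __getitem__(self, i):
        return self.masks[i]


def mask_scale(phi: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """xi = phi * m: outside-mask pixels become exactly 0 and therefore
    belong to no region under the strict sign tests of extraction."""
    phi = np.asarray(phi, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if phi.shape != mask.shape:
        raise ValueError("phi and mask must share a shape")
    return phi * mask


def extract_regions(xi) -> RegionSet:
    """Hard regions from one scaled level set or a pair of them.

    Sign tests are strict, so exactly-zero pixels (contour points and
    anything zeroed by the mask) are assigned to no region.
    """
    if isinstance(xi, (tuple, list)):
        xi1, xi2 = (np.asarray(a, dtype=float) for a in xi)
        if xi1.shape != xi2.shape:
            raise ValueError("the two level sets must share a shape")
        return RegionSet((
            (xi1 > 0) & (xi2 > 0),
            (xi1 > 0) & (xi2 < 0),
            (xi1 < 0) & (xi2 > 0),
            (xi1 < 0) & (xi2 < 0),
        ))
    xi = np.asarray(xi, dtype=float)
    return RegionSet((xi > 0, xi < 0))


def accuracy(A: np.ndarray, B: np.ndarray) -> float:
    """Percentage overlap 100 * |A∩B| / |A∪B| (identically 100 * Jaccard)."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError("masks must share a shape")
    union = np.count_nonzero(A | B)
    if union == 0:
        warnings.warn("both masks empty; accuracy defined as 100")
        return 100.0
    return 100.0 * np.count_nonzero(A & B) / union


def jaccard_dice(S: np.ndarray, G: np.ndarray) -> tuple[float, float]:
    """(Jaccard, Dice) of a segmented region against its ground truth."""
    S = np.asarray(S, dtype=bool)
    G = np.asarray(G, dtype=bool)
    if S.shape != G.shape:
        raise ValueError("masks must share a shape")
    inter = np.count_nonzero(S & G)
    union = np.count_nonzero(S | G)
    size_sum = np.count_nonzero(S) + np.count_nonzero(G)
    if union == 0:
        warnings.warn("both masks empty; similarity defined as 1")
        return 1.0, 1.0
    return inter / union, 2.0 * inter / size_sum


def match_regions(predicted: RegionSet, truth_masks) -> list[int | None]:
    """Greedy one-to-one assignment of predicted regions to ground-truth
    regions by decreasing Jaccard, making evaluation invariant to which
    phase ended up carrying which region label."""
    truth_masks = [np.asarray(g, dtype=bool) for g in truth_masks]
    pairs = []
    for ti, g in enumerate(truth_masks):
        for pi in range(len(predicted)):
            pairs.append((jaccard_dice(predicted[pi], g)[0], ti, pi))
    pairs.sort(reverse=True)
    assignment: list[int | None] = [None] * len(truth_masks)
    used_pred: set[int] = set()
    for j, ti, pi in pairs:
        if assignment[ti] is None and pi not in used_pred:
            assignment[ti] = pi
            used_pred.add(pi)
    return assignment


def evaluate_labels(pred_labels: np.ndarray, true_labels: np.ndarray,
                    mask: np.ndarray | None = None,
                    include_background: bool = False) -> dict[int, dict[str, float]]:
    """Per-ground-truth-region overlap metrics with greedy label matching.

    Returns ``{true_label: {"jaccard", "dice", "accuracy"}}`` for every
    label present in ``true_labels`` (background label 0 excluded unless
    ``include_background``).  ``mask`` restricts both maps to a region of
    interest.
    """
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        pred_labels = np.where(mask, pred_labels, -1)
        true_labels = np.where(mask, true_labels, -1)
    true_ids = [int(v) for v in np.unique(true_labels) if v >= 0]
    if not include_background:
        true_ids = [v for v in true_ids if v != 0]
    pred_ids = [int(v) for v in np.unique(pred_labels) if v >= 0]
    pred_set = RegionSet(tuple(pred_labels == v for v in pred_ids))
    truth_masks = [true_labels == v for v in true_ids]
    assignment = match_regions(pred_set, truth_masks)
    out: dict[int, dict[str, float]] = {}
    for ti, tid in enumerate(true_ids):
        pi = assignment[ti]
        S = pred_set[pi] if pi is not None else np.zeros_like(true_labels, bool)
        j, d = jaccard_dice(S, truth_masks[ti])
        out[tid] = {"jaccard": j, "dice": d, "accuracy": 100.0 * j}
    return out
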