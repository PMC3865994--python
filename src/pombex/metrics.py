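"""Segmentation quality metrics against ground-truth instance masks.

A predicted contour *correctly segments* a ground-truth cell when its
Dice overlap with that cell is at least 0.7 under a greedy one-to-one
matching (a merged pair scores ~2/3 against either member and a half
cell ~2/3 against its whole, so 0.7 cleanly excludes both error types
while accepted contours on the membrane midline score well above it).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

CORRECT_DICE = 0.7


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def match_instances(truth: np.ndarray, pred: np.ndarray,
                    ) -> List[Tuple[int, int, float]]:
    """Greedy one-to-one matching of predicted to truth labels by Dice.

    Returns (truth_label, pred_label, dice) triples, best overlaps first.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    pairs = []
    for t in range(1, truth.max() + 1):
        tmask = truth == t
        if not tmask.any():
            continue
        overlapping = np.unique(pred[tmask])
        for p in overlapping:
            if p == 0:
                continue
            d = dice(tmask, pred == p)
            if d > 0:
                pairs.append((t, int(p), d))
    pairs.sort(key=lambda x: -x[2])
    used_t, used_p = set(), set()
    matches = []
    for t, p, d in pairs:
        if t in used_t or p in used_p:
            continue
        used_t.add(t)
        used_p.add(p)
        matches.append((t, p, d))
    return matches


def evaluate_segmentation(truth: np.ndarray, pred: np.ndarray) -> Dict:
    """Detection recall, precision and mean per-cell Dice of a predicted
    instance mask against the truth instance mask."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n_truth = len([t for t in range(1, truth.max() + 1)
                   if (truth == t).any()])
    n_pred = len([p for p in range(1, pred.max() + 1) if (pred == p).any()])
    matches = match_instances(truth, pred)
    correct = [m for m in matches if m[2] >= CORRECT_DICE]
    matched_dice = [m[2] for m in correct]
    recall = len(correct) / n_truth if n_truth else 1.0
    precision = len(correct) / n_pred if n_pred else 1.0
    return {
        "n_truth": n_truth,
        "n_pred": n_pred,
        "n_correct": len(correct),
        "recall": recall,
        "precision": precision,
        # over correctly segmented cells only
        "mean_dice": float(np.mean(matched_dice)) if matched_dice else 0.0,
        # over all truth cells (undetected cells contribute 0), the
        # fairer quantity when comparing runs with different recall
        "mean_dice_all": (float(np.sum(matched_dice)) / n_truth
                          if n_truth else 1.0),
    }


def contour_correctness(truth: np.ndarray, masks: Sequence[np.ndarray],
                        ) -> List[bool]:
    """Per-contour correctness flags.

    A contour is correct when it reaches the Dice bar against its
    greedily matched cell AND does not swallow a second cell (cover at
    least half of any other instance) -- a merged contour over a large
    and a small cell can still score high Dice against the large one.
    """
    truth = np.asarray(truth)
    pred = np.zeros_like(truth, dtype=np.int32)
    # Later (smaller) contours may overlap; paint sequentially.
    for i, m in enumerate(masks, start=1):
        pred[m & (pred == 0)] = i
    matches = match_instances(truth, pred)
    matched = {p: t for t, p, d in matches if d >= CORRECT_DICE}
    areas = {t: (truth == t).sum() for t in range(1, truth.max() + 1)}
    out = []
    for i, m in enumerate(masks, start=1):
        ok = i in matched
        if ok:
            for t, a in areas.items():
                if t != matched[i] and a > 0                         and (m & (truth == t)).sum() >= 0.5 * a:
                    ok = False
                    break
        out.append(ok)
    return out
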