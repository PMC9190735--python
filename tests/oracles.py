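"""Independent reference implementations used to validate the pipeline.

These are deliberately naive: geometric hard-margin classification for tiny
point sets and exhaustive sign-flip enumeration. They share no code with the
package internals they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def _closest_point_on_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = b - a
    denom = float(d @ d)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ d / denom, 0.0, 1.0))
    return a + t * d


def hard_margin_classify(
    train_neg: np.ndarray, train_pos: np.ndarray, test: np.ndarray
) -> np.ndarray:
    """Maximum-margin labels for 2-points-per-class training sets.

    The maximum-margin separator of two separable convex hulls is the
    perpendicular bisector of the closest pair of hull points. With two
    points per class the hulls are segments, so the closest pair is found by
    checking each vertex against the opposite segment.
    """
    candidates = []
    for p in train_neg:
        q = _closest_point_on_segment(p, train_pos[0], train_pos[1])
        candidates.append((p, q))
    for q in train_pos:
        p = _closest_point_on_segment(q, train_neg[0], train_neg[1])
        candidates.append((p, q))
    p, q = min(candidates, key=lambda pq: float(np.sum((pq[0] - pq[1]) ** 2)))
    w = q - p
    mid = (p + q) / 2.0
    scores = (test - mid) @ w
    return np.where(scores >= 0, 1.0, -1.0)


def pairwise_supertrial_accuracy_oracle(data: np.ndarray) -> np.ndarray:
    """Leave-one-super-trial-out pairwise accuracy by direct enumeration.

    ``data``: conditions x 3 super-trials x channels x timepoints. For every
    condition pair, fold and timepoint, classifies the two held-out
    super-trials with the geometric hard-margin rule and averages.
    """
    n_cond, S, C, T = data.shape
    assert S == 3
    accs = []
    for a in range(n_cond):
        for b in range(a + 1, n_cond):
            correct = np.zeros(T)
            for fold in range(S):
                others = [s for s in range(S) if s != fold]
                for t in range(T):
                    pred = hard_margin_classify(
                        data[a, others, :, t],
                        data[b, others, :, t],
                        np.stack([data[a, fold, :, t], data[b, fold, :, t]]),
                    )
                    correct[t] += float(pred[0] == -1.0) + float(pred[1] == 1.0)
            accs.append(correct / (2 * S))
    return 100.0 * np.mean(accs, axis=0)


def exhaustive_signflip_pointwise_p(effects: np.ndarray) -> np.ndarray:
    """Exact one-sided sign-flip p-values per timepoint by full enumeration.

    ``effects``: participants x timepoints, already centered on chance.
    Enumerates all 2**P sign assignments of the group-mean statistic.
    """
    P, T = effects.shape
    obs = effects.mean(axis=0)
    count = np.zeros(T)
    n = 0
    for signs in product((-1.0, 1.0), repeat=P):
        stat = (np.asarray(signs) @ effects) / P
        count += stat >= obs - 1e-12
        n += 1
    return count / n
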