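"""Independent test oracles, deliberately implemented apart from the package."""

from collections import Counter

import numpy as np

from cavitrack import svm_objective


def brute_force_predict(points, k, x):
    """kNN oracle re-deriving the stated rules from first principles:
    sort by (distance, arrival order), take k, majority vote; ties fall to
    the label with the closest member, then the smaller label."""
    ranked = sorted(
        ((abs(p.x - x), i, p.label) for i, p in enumerate(points)),
        key=lambda t: (t[0], t[1]),
    )[:k]
    votes = Counter(lab for _, _, lab in ranked)
    top = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == top]
    best_by_label = {lab: min(d for d, _, l in ranked if l == lab) for lab in tied}
    return min(tied, key=lambda lab: (best_by_label[lab], lab))


def grid_search_objective(x, y, C, span=10.0, levels=5, width=201):
    """SVM oracle: nested zooming grid search over (w, b)."""
    best = (0.0, 0.0, svm_objective(0.0, 0.0, x, y, C))
    w_lo, w_hi = -span, span
    b_lo, b_hi = -span * (np.abs(x).max() + 1), span * (np.abs(x).max() + 1)
    for _ in range(levels):
        ws = np.linspace(w_lo, w_hi, width)
        bs = np.linspace(b_lo, b_hi, width)
        W, B = np.meshgrid(ws, bs, indexing="ij")
        margins = 1.0 - y[None, None, :] * (W[..., None] * x[None, None, :] + B[..., None])
        F = 0.5 * W**2 + C * np.maximum(margins, 0.0).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(F), F.shape)
        if F[i, j] < best[2]:
            best = (ws[i], bs[j], float(F[i, j]))
        dw, db = (w_hi - w_lo) / (width - 1), (b_hi - b_lo) / (width - 1)
        w_lo, w_hi = best[0] - 2 * dw, best[0] + 2 * dw
        b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db
    return best[2]
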