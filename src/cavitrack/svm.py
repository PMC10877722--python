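"""Soft-margin linear SVM on a single scalar feature.

Fits (w, b) minimising the primal objective

    F(w, b) = 1/2 w^2 + C * sum_i max(0, 1 - y_i (w x_i + b)),

i.e. hinge loss with cost C on margin violations.  Because the feature is
one-dimensional the inner minimisation over the bias b is an exact
piecewise-linear problem, and the outer profile F*(w) = min_b F(w, b) is a
convex scalar function minimised deterministically by bounded Brent search.
No randomness is involved, so refits are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["LinearSvm1D", "svm_fit_binary", "svm_objective"]


@dataclass(frozen=True)
class LinearSvm1D:
    """Fitted 1-D linear SVM; decision score s(x) = w*x + b."""

    w: float
    b: float
    C: float = 1.0

    def score(self, x: float) -> float:
        return self.w * x + self.b

    def predict(self, x: float) -> int:
        """Return the sign class (+1 or -1); ties go to +1."""
        return 1 if self.score(x) >= 0 else -1


def svm_objective(
    w: float, b: float, x: np.ndarray, y: np.ndarray, C: float
) -> float:
    """Primal soft-margin objective 1/2 w^2 + C * sum hinge."""
    margins = 1.0 - y * (w * x + b)
    return 0.5 * w * w + C * float(np.sum(np.maximum(margins, 0.0)))


def _best_bias(w: float, x: np.ndarray, y: np.ndarray, C: float) -> tuple[float, float]:
    """Exact minimiser of F(w, .): convex piecewise-linear in b.

    Each point contributes max(0, t_i - y_i b) with t_i = 1 - y_i w x_i, a
    hinge with breakpoint b = y_i t_i and slope -C y_i on its active side.
    The subgradient in b is a step function over sorted breakpoints; the
    minimum sits where it changes sign (midpoint of a flat segment, for
    symmetry under label flips).
    """
    t = 1.0 - y * w * x
    bp = y * t  # breakpoint of each hinge in b
    bp_sorted = np.sort(bp)
    n_pos = int(np.sum(y == 1))
    # The subgradient on the segment below breakpoint i is C*(i - n_pos):
    # for b below all breakpoints every +1 hinge is active (slope -C each)
    # and every -1 hinge inactive; crossing any breakpoint adds +C (a +1
    # hinge deactivates or a -1 hinge activates).  Track the slope in
    # integer units of C so the zero-slope (flat) segment is found exactly.
    n = len(bp_sorted)
    if n_pos == 0:  # cannot happen via svm_fit_binary, kept for safety
        b_star = float(bp_sorted[0])
    elif n_pos == n:
        b_star = float(bp_sorted[-1])
    elif n_pos < n:
        lo, hi = float(bp_sorted[n_pos - 1]), float(bp_sorted[n_pos])
        b_star = 0.5 * (lo + hi)  # midpoint of the zero-slope segment
    return b_star, svm_objective(w, b_star, x, y, C)


def svm_fit_binary(
    points: Sequence[tuple[float, int]], C: float = 1.0
) -> LinearSvm1D:
    """Fit the 1-D soft-margin SVM on (x, y) pairs with y in {-1, +1}.

    Deterministic exact-profile solver; the objective is within ~1e-9 of the
    global optimum.  Raises on single-class input or non-positive C.
    """
    if C <= 0:
        raise ValueError("C must be > 0")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if not (np.any(y == 1) and np.any(y == -1)):
        raise ValueError("both classes (+1 and -1) must be present")
    if np.any(np.abs(y) != 1):
        raise ValueError("labels must be +1 or -1")

    # canonicalise under label flip so flipped inputs give exactly (-w, -b)
    sign = 1.0 if y[0] > 0 else -1.0
    ys = sign * y

    def profile(w: float) -> float:
        return _best_bias(w, x, ys, C)[1]

    # |w*| <= sqrt(2 F(0,b0)) since 1/2 w*^2 <= F(w*,b*) <= F(0, b0)
    bound = math.sqrt(2.0 * _best_bias(0.0, x, ys, C)[1]) + 1.0
    res = minimize_scalar(
        profile, bounds=(-bound, bound), method="bounded",
        options={"xatol": 1e-12, "maxiter": 500},
    )
    # polish: the profile is piecewise quadratic; a local quadratic fit around
    # the Brent minimiser nails the vertex
    w_star = float(res.x)
    h = 1e-6 * max(abs(w_star), 1.0)
    f0, fm, fp = profile(w_star), profile(w_star - h), profile(w_star + h)
    denom = fp + fm - 2.0 * f0
    if denom > 0:
        w_candidate = w_star + 0.5 * h * (fm - fp) / denom
        if profile(w_candidate) <= f0:
            w_star = float(w_candidate)
    b_star, _ = _best_bias(w_star, x, ys, C)
    return LinearSvm1D(w=sign * w_star, b=sign * b_star, C=C)
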