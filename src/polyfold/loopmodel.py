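"""Stochastic anchored-loop model for PRE clustering.

Two loop anchors (PRC1-bound PREs) sit on a line at positions l0 and may
form loops whose lengths are Gaussian around the anchor.  Whether a loop in
a given direction is long-lived depends on whether the flanking chromatin is
"sticky" (methylated) or not; anchors flanked by non-sticky chromatin on one
side draw from a half-Gaussian restricted to the sticky side.  The observable
is the mean absolute distance between the two anchors,

    mean |l1 - l2|,

which shrinks as anchors become more inward-restricted -- the one-line
explanation of why PREs near the edges of a methylated domain cluster.

In the far-separated limit (anchor separation L >> sigma_l) the mean has the
closed form  L - k * sigma_l * sqrt(2/pi)  where k counts inward-restricted
anchors; this serves as the analytic oracle for the sampler.

Note on sigma_l: the printed means 2.00 / 1.76 / 1.52 for the three standard
configurations correspond to sigma_l = 0.3 (the default here), although 0.2
also circulates for the symmetric configuration; both are selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

BOTH = "both"
RIGHT_ONLY = "right-only"
LEFT_ONLY = "left-only"
_DIRECTIONS = (BOTH, RIGHT_ONLY, LEFT_ONLY)


@dataclass(frozen=True)
class LoopModelSpec:
    """Anchor positions, loop-length spread and per-anchor directionality."""

    anchor_positions: tuple[float, ...] = (0.0, 2.0)
    sigma_l: float = 0.3
    directionality: tuple[str, ...] = (BOTH, BOTH)
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_l <= 0:
            raise ValueError("sigma_l must be positive")
        if len(set(self.anchor_positions)) != len(self.anchor_positions):
            raise ValueError("anchor positions must be distinct")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if len(self.directionality) != len(self.anchor_positions):
            raise ValueError("one directionality entry per anchor required")
        for d in self.directionality:
            if d not in _DIRECTIONS:
                raise ValueError(f"unknown directionality {d!r}")


def standard_configuration(which: int, sigma_l: float = 0.3, n_draws: int = 10_000,
                           seed: int = 0) -> LoopModelSpec:
    """The three canonical anchor arrangements (1: both free, 2: one restricted,
    3: both inward-restricted), anchors at 0 and 2."""
    dirs = {
        1: (BOTH, BOTH),
        2: (RIGHT_ONLY, BOTH),
        3: (RIGHT_ONLY, LEFT_ONLY),
    }
    if which not in dirs:
        raise ValueError("configuration must be 1, 2 or 3")
    return LoopModelSpec((0.0, 2.0), sigma_l, dirs[which], n_draws, seed)


def sample_loop_lengths(spec: LoopModelSpec, rng=None) -> np.ndarray:
    """Draw loop-end positions, one column per anchor, shape (n_draws, n_anchors).

    ``both`` anchors draw from the full Gaussian N(l0, sigma_l); restricted
    anchors from the half-Gaussian on the allowed side (implemented as the
    absolute-value transform of a centered normal, which is
    distribution-identical to rejection sampling).
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    cols = []
    for l0, d in zip(spec.anchor_positions, spec.directionality):
        z = rng.normal(0.0, spec.sigma_l, size=spec.n_draws)
        if d == BOTH:
            cols.append(l0 + z)
        elif d == RIGHT_ONLY:
            cols.append(l0 + np.abs(z))
        else:
            cols.append(l0 - np.abs(z))
    return np.column_stack(cols)


def mean_anchor_distance(spec: LoopModelSpec, rng=None, with_error: bool = False):
    """Monte Carlo mean of |l1 - l2| over ``n_draws`` loop-formation events."""
    if len(spec.anchor_positions) != 2:
        raise ValueError("mean_anchor_distance requires exactly two anchors")
    samples = sample_loop_lengths(spec, rng)
    delta = np.abs(samples[:, 0] - samples[:, 1])
    if with_error:
        return float(delta.mean()), float(delta.std(ddof=1) / math.sqrt(delta.size))
    return float(delta.mean())


def closed_form_mean(spec: LoopModelSpec) -> float:
    """Analytic oracle: L - k * sigma_l * sqrt(2/pi) in the no-sign-flip limit.

    Exact when the anchors are far apart relative to sigma_l (separation
    >= ~4 sigma_l); k counts anchors restricted toward the other anchor.
    A ``both`` anchor contributes 0 (its Gaussian mean is the anchor itself,
    and E[l2 - l1] is unaffected by symmetric spread when signs never flip).
    """
    if len(spec.anchor_positions) != 2:
        raise ValueError("closed_form_mean requires exactly two anchors")
    (a, da), (b, db) = sorted(zip(spec.anchor_positions, spec.directionality))
    L = b - a
    if L < 4 * spec.sigma_l:
        import warnings
        warnings.warn("anchors closer than 4 sigma_l: closed form degrades", stacklevel=2)
    k = 0
    if da == RIGHT_ONLY:   # left anchor pulled right, toward the other
        k += 1
    elif da == LEFT_ONLY:  # pulled away: widens the mean distance
        k -= 1
    if db == LEFT_ONLY:    # right anchor pulled left, toward the other
        k += 1
    elif db == RIGHT_ONLY:
        k -= 1
    return L - k * spec.sigma_l * math.sqrt(2.0 / math.pi)
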