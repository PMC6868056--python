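"""Cone-based dynamic-DHS classification for a two-sample comparison.

Each union DHS is plotted at (x, y) = (log10 cuts in sample A, log10 cuts in
sample B).  DHSs falling outside the cone bounded by the lines

    y = (1 - m) x + b      and      y = (1 + m) x - b

with default margin m = 0.21 and intercept b = 0.9 (log10 units), and with
more than ``min_cleavage`` (default 50) raw cuts in at least one sample, are
called dynamic: "activated" above the cone (more accessible in B),
"deactivated" below it.  Points on a boundary line are static (closed cone).

The two lines cross at x = 2b / (2m) = b/m; past the crossing the upper and
lower envelopes of the two lines keep "inside the cone" meaning the band
between them.  The cone is intentionally not symmetric under swapping the
two samples: the printed line equations are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .intervals import GenomicInterval
from .quantify import DhsMatrix

__all__ = ["ConeParams", "DynamicCall", "classify_pair", "call_dynamic"]

ACTIVATED = "activated"
DEACTIVATED = "deactivated"
STATIC = "static"


@dataclass(frozen=True)
class ConeParams:
    """Cone geometry and the minimum-cleavage gate.

    slope_margin : unitless slope offset m of the two lines (0 < m < 1)
    intercept    : log10-unit intercept offset b (> 0)
    min_cleavage : raw-cut gate; a DHS can only be dynamic if at least one
                   sample exceeds this many cuts
    """

    slope_margin: float = 0.21
    intercept: float = 0.9
    min_cleavage: float = 50

    def __post_init__(self) -> None:
        if not 0 < self.slope_margin < 1:
            raise ValueError("slope_margin must be in (0, 1)")
        if self.intercept <= 0:
            raise ValueError("intercept must be positive")
        if self.min_cleavage <= 0:
            raise ValueError("min_cleavage must be positive")

    def bounds(self, x: np.ndarray):
        """Lower and upper cone envelopes at log10-count ``x``."""
        l1 = (1 - self.slope_margin) * x + self.intercept
        l2 = (1 + self.slope_margin) * x - self.intercept
        return np.minimum(l1, l2), np.maximum(l1, l2)


class DynamicCall(NamedTuple):
    """Classification of one union DHS in an A-vs-B comparison."""

    dhs: GenomicInterval
    x: float  # log10 cuts in sample A (NaN when count is 0)
    y: float  # log10 cuts in sample B
    label: str


def classify_pair(count_a: float, count_b: float,
                  params: ConeParams = ConeParams()) -> str:
    """Classify one DHS from its raw cut counts in samples A and B."""
    if count_a < 0 or count_b < 0:
        raise ValueError("cut counts must be non-negative")
    if max(count_a, count_b) <= params.min_cleavage:
        return STATIC
    # the gate guarantees at least one positive count; a zero count on the
    # other axis is treated as maximally dynamic (log10(0) -> -inf)
    x = np.log10(count_a) if count_a > 0 else -np.inf
    y = np.log10(count_b) if count_b > 0 else -np.inf
    lower, upper = params.bounds(np.asarray(x, dtype=float))
    if y > upper:
        return ACTIVATED
    if y < lower:
        return DEACTIVATED
    return STATIC


def call_dynamic(matrix: DhsMatrix, sample_a: str, sample_b: str,
                 params: ConeParams = ConeParams()):
    """Classify every union DHS in ``matrix`` for the A-vs-B comparison.

    Returns (calls, summary) where summary has the counts of DHSs above
    (activated) and below (deactivated) the cone.
    """
    ca = matrix.column(sample_a)
    cb = matrix.column(sample_b)
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("cut counts must be non-negative")

    with np.errstate(divide="ignore"):
        x = np.where(ca > 0, np.log10(np.maximum(ca, 1e-300)), -np.inf)
        y = np.where(cb > 0, np.log10(np.maximum(cb, 1e-300)), -np.inf)
    lower, upper = params.bounds(x)
    gate = np.maximum(ca, cb) > params.min_cleavage
    activated = gate & (y > upper)
    deactivated = gate & (y < lower)

    labels = np.where(activated, ACTIVATED, np.where(deactivated, DEACTIVATED, STATIC))
    calls = [
        DynamicCall(iv, float(xi), float(yi), str(lab))
        for iv, xi, yi, lab in zip(matrix.dhss, x, y, labels)
    ]
    summary = {"n_above": int(activated.sum()), "n_below": int(deactivated.sum())}
    return calls, summary
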