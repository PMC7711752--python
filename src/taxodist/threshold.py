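"""Equal-error thresholds between adjacent taxonomic rank strata.

Given the distance (or similarity) values of two strata — a *lower* (more
specific, e.g. within-species) and a *higher* (less specific, e.g.
between-species-within-genus) one — a single cut value is sought such that
both strata leave a nearly identical share of values on the wrong side.  The
search bisects the interval between the two stratum medians, at each midpoint
comparing the wrong-side shares and moving toward the stratum whose wrongly
classified values lie beyond the current cut, until the shares differ by less
than a tolerance (default 1e-4) or 100 halvings have been performed.

Orientation decides which side is "correct": for a distance the lower stratum
belongs below the threshold; for a similarity it belongs above.  A value
exactly at the threshold counts as correctly classified for the lower
stratum (floating-point ties must land somewhere; this choice is fixed and
documented rather than left to chance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdResult",
    "RankSummary",
    "find_threshold",
    "misclassification_rate",
    "rank_summaries",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Equal-error cut between two strata with per-side wrong shares."""

    threshold: float
    orientation: str  # "distance" or "similarity"
    share_lower_wrong: float
    share_higher_wrong: float
    pooled_misclassified: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class RankSummary:
    level: str
    n_pairs: int
    median: float
    mean: float


def _wrong_shares(
    sorted_lower: np.ndarray,
    sorted_higher: np.ndarray,
    threshold: float,
    orientation: str,
) -> tuple[float, float]:
    """Fractions of each stratum on the wrong side of ``threshold``.

    distance: lower stratum wrong if value > t, higher wrong if value <= t.
    similarity: lower wrong if value < t, higher wrong if value >= t.
    (Ties at t are correct for the lower stratum in both orientations.)
    """
    n_lo, n_hi = sorted_lower.size, sorted_higher.size
    if orientation == "distance":
        wrong_lo = n_lo - np.searchsorted(sorted_lower, threshold, side="right")
        wrong_hi = np.searchsorted(sorted_higher, threshold, side="right")
    elif orientation == "similarity":
        wrong_lo = np.searchsorted(sorted_lower, threshold, side="left")
        wrong_hi = n_hi - np.searchsorted(sorted_higher, threshold, side="left")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return wrong_lo / n_lo, wrong_hi / n_hi


def find_threshold(
    lower_values: Sequence[float],
    higher_values: Sequence[float],
    orientation: str = "distance",
    tolerance: float = 1e-4,
    max_iter: int = 100,
) -> ThresholdResult:
    """Bisect between the stratum medians for the equal-error threshold.

    The candidate interval is the closed span of the two medians; each
    midpoint evaluation moves the boundary so as to shrink the larger
    wrong-side share.  Stops when the shares differ by less than
    ``tolerance`` or after ``max_iter`` halvings (then ``converged`` is
    False).  Identical medians return that value directly, with convergence
    judged by the same share test.
    """
    lower = np.sort(np.asarray(lower_values, dtype=float))
    higher = np.sort(np.asarray(higher_values, dtype=float))
    if lower.size == 0 or higher.size == 0:
        raise ValueError("both strata must be non-empty")
    if orientation not in ("distance", "similarity"):
        raise ValueError(f"unknown orientation {orientation!r}")

    med_lo = float(np.median(lower))
    med_hi = float(np.median(higher))
    a, b = min(med_lo, med_hi), max(med_lo, med_hi)

    t = (a + b) / 2.0
    share_lo, share_hi = _wrong_shares(lower, higher, t, orientation)
    iterations = 0
    converged = abs(share_lo - share_hi) < tolerance
    while not converged and iterations < max_iter:
        iterations += 1
        t = (a + b) / 2.0
        share_lo, share_hi = _wrong_shares(lower, higher, t, orientation)
        if abs(share_lo - share_hi) < tolerance:
            converged = True
            break
        # move the cut toward the wrongly classified values of the stratum
        # with the larger wrong-side share
        if orientation == "distance":
            if share_lo > share_hi:
                a = t  # lower's wrong values are above t: raise the cut
            else:
                b = t
        else:
            if share_lo > share_hi:
                b = t  # lower's wrong values are below t: lower the cut
            else:
                a = t

    pooled = misclassification_rate(lower, higher, t, orientation)
    return ThresholdResult(
        threshold=float(t),
        orientation=orientation,
        share_lower_wrong=float(share_lo),
        share_higher_wrong=float(share_hi),
        pooled_misclassified=float(pooled),
        iterations=iterations,
        converged=bool(converged),
    )


def misclassification_rate(
    lower_values: Sequence[float],
    higher_values: Sequence[float],
    threshold: float,
    orientation: str = "distance",
) -> float:
    """Pooled fraction of values on the wrong side of ``threshold``.

    (wrong lower-stratum count + wrong higher-stratum count) / total pairs.
    Classification accuracy is 1 minus this value.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    lower = np.sort(np.asarray(lower_values, dtype=float))
    higher = np.sort(np.asarray(higher_values, dtype=float))
    share_lo, share_hi = _wrong_shares(lower, higher, threshold, orientation)
    n_lo, n_hi = lower.size, higher.size
    return (share_lo * n_lo + share_hi * n_hi) / (n_lo + n_hi)


def rank_summaries(distances: pd.DataFrame) -> list[RankSummary]:
    """Per-level pair count, median and mean of computed distances.

    ``distances`` needs columns ``level`` and ``value``; levels are reported
    in the order of first appearance and empty levels are omitted.
    """
    out: list[RankSummary] = []
    for level in pd.unique(distances["level"]):
        vals = distances.loc[distances["level"] == level, "value"].to_numpy()
        if vals.size == 0:
            continue
        out.append(
            RankSummary(
                level=str(level),
                n_pairs=int(vals.size),
                median=float(np.median(vals)),
                mean=float(np.mean(vals)),
            )
        )
    return out
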