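"""Ranking of fitted contigs and the unique-expression screen.

Fits are ordered by ascending p-value, ties broken by descending ALFCA
and then lexicographic contig id, so the "top k" set is deterministic.
The unique-expression screen scales each sample's counts to the mean
library size and calls a condition expressed only when both of its
replicates exceed the high threshold, and not expressed only when both
fall below the low threshold (strict inequalities); everything in
between is indeterminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InvalidInputError
from .model import CountQuartet, GlmFit, LibrarySizes

__all__ = [
    "RankedResult",
    "ExpressionCall",
    "rank_results",
    "select_top_k",
    "count_significant",
    "screen_unique",
]


@dataclass(frozen=True)
class RankedResult:
    rank: int
    fit: GlmFit
    direction: str  # "up" | "down" | "flat"


@dataclass(frozen=True)
class ExpressionCall:
    contig_id: str
    call_resistant: str  # "expressed" | "not_expressed" | "indeterminate"
    call_susceptible: str
    unique_in: str  # "resistant" | "susceptible" | "none"


def _direction(fit: GlmFit) -> str:
    if not fit.estimable or fit.gamma == 0 or math.isnan(fit.gamma):
        return "flat"
    return "up" if fit.gamma > 0 else "down"


def _sort_key(fit: GlmFit) -> tuple[float, float, str]:
    # Non-estimable fits carry alfca = NaN; rank them last among p ties.
    alfca = fit.alfca if math.isfinite(fit.alfca) else -math.inf
    return (fit.p, -alfca, fit.contig_id)


def rank_results(fits: Iterable[GlmFit]) -> list[RankedResult]:
    """Total order: ascending p, then descending ALFCA, then contig id."""
    fits = list(fits)
    if not fits:
        raise InvalidInputError("cannot rank an empty collection of fits")
    ordered = sorted(fits, key=_sort_key)
    return [
        RankedResult(rank=i + 1, fit=f, direction=_direction(f))
        for i, f in enumerate(ordered)
    ]


def select_top_k(ranked: Sequence[RankedResult], k: int) -> list[RankedResult]:
    """First min(k, n) entries of an already-ranked list."""
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")
    return list(ranked[:k])


def count_significant(fits: Iterable[GlmFit], alpha: float = 0.005) -> int:
    """Number of fits with p strictly below alpha."""
    if not (0 < alpha < 1):
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha!r}")
    return sum(1 for f in fits if f.p < alpha)


def _call_condition(scaled: tuple[float, float], low: float, high: float) -> str:
    a, b = scaled
    if a < low and b < low:
        return "not_expressed"
    if a > high and b > high:
        return "expressed"
    return "indeterminate"


def screen_unique(
    counts_by_replicate: Iterable[CountQuartet],
    libs: LibrarySizes,
    low: float = 10,
    high: float = 100,
) -> list[ExpressionCall]:
    """Call uniquely expressed contigs from per-replicate counts.

    ``counts_by_replicate`` reuses the quartet container with the two
    batches read as the two biological replicates of each condition.
    Counts are scaled per sample by (mean library size / library size)
    before thresholding, so equal-depth libraries leave raw counts
    unchanged and rescaling every library by a constant changes no call.
    """
    if not (0 < low < high):
        raise InvalidInputError(
            f"thresholds must satisfy 0 < low < high, got low={low}, high={high}"
        )
    nbar = libs.mean()
    s_r1 = nbar / libs.n_r1
    s_s1 = nbar / libs.n_s1
    s_r2 = nbar / libs.n_r2
    s_s2 = nbar / libs.n_s2
    calls = []
    for q in counts_by_replicate:
        res = _call_condition((q.y_r1 * s_r1, q.y_r2 * s_r2), low, high)
        sus = _call_condition((q.y_s1 * s_s1, q.y_s2 * s_s2), low, high)
        if res == "expressed" and sus == "not_expressed":
            unique = "resistant"
        elif sus == "expressed" and res == "not_expressed":
            unique = "susceptible"
        else:
            unique = "none"
        calls.append(
            ExpressionCall(
                contig_id=q.contig_id,
                call_resistant=res,
                call_susceptible=sus,
                unique_in=unique,
            )
        )
    return calls
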