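"""Assembly-completeness statistics: N50 and the ortholog hit ratio.

N50 is the contig length at which the cumulative length of all contigs
that long or longer first reaches half the assembly's total length.

The ortholog hit ratio (OHR) of a contig is the fraction of its best
putative ortholog's length covered by the alignment: 1 means a fully
assembled transcript, values near 0 a fragmentary one.  Only the best
hit per query contributes (highest bitscore, ties by lowest e-value
then subject id); overlapping HSPs are not merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "OrthologHit",
    "n50",
    "ortholog_hit_ratio",
    "best_hits",
    "ohr_distribution",
    "OhrDistribution",
]


def n50(lengths: Sequence[int]) -> int:
    """N50 of a set of contig lengths (nt)."""
    arr = np.asarray(list(lengths))
    if arr.size == 0:
        raise InvalidInputError("N50 of an empty length set is undefined")
    if np.any(arr <= 0):
        raise InvalidInputError("contig lengths must be positive")
    desc = np.sort(arr)[::-1]
    half = desc.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(desc), half))
    return int(desc[idx])


@dataclass(frozen=True)
class OrthologHit:
    """One alignment between a contig (query) and a putative ortholog."""

    query_id: str
    subject_id: str
    subject_length: int
    aligned_subject_span: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.subject_length <= 0:
            raise InvalidInputError(
                f"{self.query_id}: subject_length must be > 0, "
                f"got {self.subject_length}"
            )
        if self.aligned_subject_span <= 0:
            raise InvalidInputError(
                f"{self.query_id}: aligned_subject_span must be > 0, "
                f"got {self.aligned_subject_span}"
            )


def ortholog_hit_ratio(hit: OrthologHit) -> float:
    """OHR = aligned subject span / subject length, clamped to [0, 1]."""
    ratio = hit.aligned_subject_span / hit.subject_length
    if ratio > 1.0:
        warnings.warn(
            f"{hit.query_id}: aligned span {hit.aligned_subject_span} exceeds "
            f"subject length {hit.subject_length}; OHR clamped to 1",
            stacklevel=2,
        )
        ratio = 1.0
    return ratio


def best_hits(hits: Iterable[OrthologHit]) -> dict[str, OrthologHit]:
    """Best hit per query: highest bitscore, ties by lowest e-value then
    lexicographic subject id."""
    best: dict[str, OrthologHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return best


@dataclass(frozen=True)
class OhrDistribution:
    """Decile-binned OHR fractions plus the >0.8 and >0.5 tail fractions."""

    bin_edges: tuple[float, ...]
    fractions: tuple[float, ...]
    frac_above_0_8: float
    frac_above_0_5: float
    n_queries: int


def ohr_distribution(hits: Iterable[OrthologHit]) -> OhrDistribution:
    """Per-query best-hit OHRs binned into deciles [0,0.1), ..., [0.9,1.0].

    Fractions sum to 1; also reports the strict-tail fractions above
    0.8 and 0.5.
    """
    per_query = best_hits(hits)
    if not per_query:
        raise InvalidInputError("no hits provided")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ohrs = np.array(
            [ortholog_hit_ratio(h) for h in per_query.values()]
        )
    edges = np.linspace(0.0, 1.0, 11)
    counts, _ = np.histogram(ohrs, bins=edges)
    fractions = counts / ohrs.size
    return OhrDistribution(
        bin_edges=tuple(edges),
        fractions=tuple(float(f) for f in fractions),
        frac_above_0_8=float(np.mean(ohrs > 0.8)),
        frac_above_0_5=float(np.mean(ohrs > 0.5)),
        n_queries=int(ohrs.size),
    )
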