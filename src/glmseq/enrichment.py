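"""GO-term enrichment: two-tailed Fisher's exact test with BH FDR.

A test set of contigs (e.g. the top-k differentially expressed) is
compared against a reference set (all annotated contigs outside the
test group).  For every GO term annotated to at least one contig in
either set a 2x2 table is built and tested with the two-tailed
(minimum-likelihood) Fisher's exact test; Benjamini-Hochberg adjusted
values are computed across all tested terms and terms with q below the
FDR cutoff are reported.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

__all__ = [
    "GoMapping",
    "ContingencyTable",
    "EnrichmentResult",
    "build_tables",
    "fisher_two_tailed",
    "bh_fdr",
    "enrich",
]

_GO_PATTERN = re.compile(r"^GO:\d{7}$")


class GoMapping:
    """Set of (contig_id, go_term_id) associations.

    Term ids must match the ``GO:NNNNNNN`` pattern; duplicate pairs
    collapse to one association.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        by_term: dict[str, set[str]] = {}
        by_gene: dict[str, set[str]] = {}
        n = 0
        for contig_id, term in pairs:
            if not _GO_PATTERN.match(term):
                raise InvalidInputError(
                    f"malformed GO term id {term!r} (expected GO:NNNNNNN)"
                )
            if not contig_id:
                raise InvalidInputError("empty contig_id in GO mapping")
            if contig_id not in by_term.setdefault(term, set()):
                by_term[term].add(contig_id)
                by_gene.setdefault(contig_id, set()).add(term)
                n += 1
        self._by_term = by_term
        self._by_gene = by_gene
        self._n = n

    def __len__(self) -> int:
        return self._n

    def terms(self) -> list[str]:
        return sorted(self._by_term)

    def genes_for(self, term: str) -> frozenset[str]:
        return frozenset(self._by_term.get(term, set()))

    def terms_for(self, contig_id: str) -> frozenset[str]:
        return frozenset(self._by_gene.get(contig_id, set()))

    def annotated_genes(self) -> frozenset[str]:
        return frozenset(self._by_gene)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(
            (g, t) for t, gs in self._by_term.items() for g in gs
        )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for one GO term.

    ``a``/``b``: test-set contigs with/without the term;
    ``c``/``d``: reference-set contigs with/without the term.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidInputError(f"negative cell in 2x2 table {self}")


@dataclass(frozen=True)
class EnrichmentResult:
    go_term_id: str
    table: ContingencyTable
    p: float
    q: float
    enriched_direction: str  # "over" | "under"


def build_tables(
    test: Iterable[str],
    reference: Iterable[str],
    mapping: GoMapping,
) -> dict[str, ContingencyTable]:
    """One 2x2 table per GO term occurring in test or reference.

    Contigs present in both sets are removed from the reference (with a
    warning) so the two margins stay disjoint.
    """
    test = set(test)
    reference = set(reference)
    if not test:
        raise InvalidInputError("test set is empty")
    overlap = test & reference
    if overlap:
        warnings.warn(
            f"{len(overlap)} contigs present in both test and reference; "
            "removed from reference",
            stacklevel=2,
        )
        reference = reference - test
    n_test = len(test)
    n_ref = len(reference)
    tables: dict[str, ContingencyTable] = {}
    for term in mapping.terms():
        genes = mapping.genes_for(term)
        a = len(genes & test)
        c = len(genes & reference)
        if a + c == 0:
            continue  # term absent from the universe under test
        tables[term] = ContingencyTable(a=a, b=n_test - a, c=c, d=n_ref - c)
    return tables


def _hypergeom_logpmf_support(
    n1: int, n2: int, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Log point probabilities over the support of a for fixed margins.

    Margins: row sums n1 (test) and n2 (reference), first-column sum k.
    """
    lo = max(0, k - n2)
    hi = min(k, n1)
    a = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(n1 + 1)
        - gammaln(a + 1)
        - gammaln(n1 - a + 1)
        + gammaln(n2 + 1)
        - gammaln(k - a + 1)
        - gammaln(n2 - k + a + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(k + 1) - gammaln(n1 + n2 - k + 1))
    )
    return a, logpmf


def fisher_two_tailed(t: ContingencyTable) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table.

    Minimum-likelihood rule: the p-value is the total hypergeometric
    probability of every table with the same margins whose point
    probability does not exceed the observed one (tie comparison with a
    1e-7 log-scale tolerance to absorb floating-point round-off).
    Degenerate margins admit a single table and return 1.
    """
    n1 = t.a + t.b
    n2 = t.c + t.d
    k = t.a + t.c
    if n1 == 0 or n2 == 0 or k == 0 or k == n1 + n2:
        return 1.0
    support, logpmf = _hypergeom_logpmf_support(n1, n2, k)
    obs = logpmf[np.searchsorted(support, t.a)]
    p = float(np.exp(logpmf[logpmf <= obs + 1e-7]).sum())
    return min(p, 1.0)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(t: ContingencyTable) -> str:
    test_frac = t.a / (t.a + t.b) if (t.a + t.b) else 0.0
    ref_frac = t.c / (t.c + t.d) if (t.c + t.d) else 0.0
    return "over" if test_frac > ref_frac else "under"


def enrich(
    test: Iterable[str],
    reference: Iterable[str],
    mapping: GoMapping,
    fdr_cutoff: float = 0.05,
) -> list[EnrichmentResult]:
    """Full enrichment: tables -> Fisher p -> BH q -> filter q < cutoff.

    The universe is restricted to annotated contigs (those with at
    least one GO term), so contigs absent from the mapping carry no
    weight in the margins.  Results are sorted by ascending q then p
    then term id.
    """
    if not (0 < fdr_cutoff <= 1):
        raise InvalidInputError(
            f"fdr_cutoff must be in (0, 1], got {fdr_cutoff!r}"
        )
    annotated = mapping.annotated_genes()
    test = set(test) & annotated
    reference = set(reference) & annotated
    if not test:
        return []
    tables = build_tables(test, reference, mapping)
    if not tables:
        return []
    terms = sorted(tables)
    pvals = [fisher_two_tailed(tables[t]) for t in terms]
    qvals = bh_fdr(pvals)
    results = [
        EnrichmentResult(
            go_term_id=term,
            table=tables[term],
            p=p,
            q=float(q),
            enriched_direction=_direction(tables[term]),
        )
        for term, p, q in zip(terms, pvals, qvals)
        if q < fdr_cutoff
    ]
    results.sort(key=lambda r: (r.q, r.p, r.go_term_id))
    return results
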