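"""Synthetic count quartets and GO universes with known ground truth.

The generator mirrors the model's own assumptions: every cell count is
an independent Poisson variate whose mean is the sample's library size
times a per-contig rate,

    mu_cell = N_cell * exp(b + beta*[batch2] + gamma*[resistant]
                           + delta*[batch2, resistant]) / mean(N),

so ``b`` reads as the expected count in an average-depth library.  A
configurable fraction of contigs is differentially expressed (nonzero
``gamma``, and then also a drawn interaction ``delta``); the rest are
strict nulls.  Ground truth is returned alongside the counts for
parameter-recovery and calibration experiments.  An optional
negative-binomial mode adds overdispersion for robustness experiments
beyond the Poisson model.

Defaults reflect a deep paired-batch insect RNA-Seq study: the four
library sizes default to 6.3e7/7.2e7/6.2e7/7.2e7 reads, 30% of contigs
differentially expressed, log-normal baselines with median ~150 counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .model import CountQuartet, LibrarySizes

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_quartets",
    "generate_go_universe",
]

#: Library sizes of the four samples (r1, s1, r2, s2), reads after
#: quality trimming, used as the default simulation depths.
DEFAULT_LIBRARY_SIZES = LibrarySizes(6.3e7, 7.2e7, 6.2e7, 7.2e7)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the quartet generator.

    ``baseline_log_mean_distribution``, ``gamma_distribution`` and
    ``delta_distribution`` are (location, scale) pairs of normal
    distributions on the natural-log scale; ``batch_effect`` is a fixed
    log-scale shift applied to both batch-2 samples beyond their
    library-size offsets.
    """

    n_contigs: int = 1000
    library_sizes: LibrarySizes = DEFAULT_LIBRARY_SIZES
    baseline_log_mean_distribution: tuple[float, float] = (5.0, 1.5)
    de_fraction: float = 0.3
    gamma_distribution: tuple[float, float] = (0.0, 1.0)
    delta_distribution: tuple[float, float] = (0.0, 0.5)
    batch_effect: float = 0.2
    seed: int = 0
    dispersion: Optional[float] = None  # NB size parameter; None = Poisson

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise InvalidInputError(
                f"n_contigs must be >= 1, got {self.n_contigs}"
            )
        if not (0.0 <= self.de_fraction <= 1.0):
            raise InvalidInputError(
                f"de_fraction must be in [0, 1], got {self.de_fraction}"
            )
        for name in (
            "baseline_log_mean_distribution",
            "gamma_distribution",
            "delta_distribution",
        ):
            loc, scale = getattr(self, name)
            if scale < 0:
                raise InvalidInputError(f"{name} scale must be >= 0")
        if self.dispersion is not None and self.dispersion <= 0:
            raise InvalidInputError("dispersion must be > 0 when set")


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-contig generating parameters; ``is_de`` iff gamma != 0."""

    table: pd.DataFrame  # columns: contig_id, baseline, gamma, delta, is_de

    def __post_init__(self) -> None:
        expected = ["contig_id", "baseline", "gamma", "delta", "is_de"]
        if list(self.table.columns) != expected:
            raise InvalidInputError(
                f"truth table must have columns {expected}"
            )


def cell_means(
    baseline: np.ndarray,
    gamma: np.ndarray,
    delta: np.ndarray,
    batch_effect: float,
    libs: LibrarySizes,
) -> np.ndarray:
    """Expected counts, columns in sample order (r1, s1, r2, s2)."""
    nbar = libs.mean()
    n = np.array(libs.totals()) / nbar
    log_mu = np.column_stack(
        [
            baseline + gamma,
            baseline,
            baseline + batch_effect + gamma + delta,
            baseline + batch_effect,
        ]
    )
    return n * np.exp(log_mu)


def generate_quartets(
    config: SimulationConfig,
) -> tuple[list[CountQuartet], SyntheticTruth]:
    """Draw count quartets and their generating truth.

    Reproducible: the same config (including seed) yields identical
    counts on any platform using numpy's PCG64 integer streams.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_contigs
    loc_b, scale_b = config.baseline_log_mean_distribution
    baseline = rng.normal(loc_b, scale_b, size=n)
    is_de = rng.random(n) < config.de_fraction
    gamma = np.zeros(n)
    delta = np.zeros(n)
    loc_g, scale_g = config.gamma_distribution
    loc_d, scale_d = config.delta_distribution
    n_de = int(is_de.sum())
    if n_de:
        gamma[is_de] = rng.normal(loc_g, scale_g, size=n_de)
        delta[is_de] = rng.normal(loc_d, scale_d, size=n_de)

    mu = cell_means(baseline, gamma, delta, config.batch_effect,
                    config.library_sizes)
    if config.dispersion is None:
        counts = rng.poisson(mu)
    else:
        # Gamma-Poisson mixture: mean mu, variance mu + mu^2 / size.
        size = config.dispersion
        counts = rng.poisson(rng.gamma(size, mu / size))

    width = len(str(n - 1)) if n > 1 else 1
    ids = [f"sim_{i:0{width}d}" for i in range(n)]
    quartets = [
        CountQuartet(
            contig_id=ids[i],
            y_r1=int(counts[i, 0]),
            y_s1=int(counts[i, 1]),
            y_r2=int(counts[i, 2]),
            y_s2=int(counts[i, 3]),
        )
        for i in range(n)
    ]
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "contig_id": ids,
                "baseline": baseline,
                "gamma": gamma,
                "delta": delta,
                "is_de": gamma != 0.0,
            }
        )
    )
    return quartets, truth


def generate_go_universe(
    n_genes: int,
    n_terms: int,
    planted: Optional[list[tuple[str, float]]] = None,
    seed: int = 0,
    background_prob_range: tuple[float, float] = (0.01, 0.05),
    planted_subset_size: int = 100,
):
    """Random GO universe with optional planted enrichments.

    Genes are ``gene_0000``..; terms ``GO:0000001``..  Each term is
    assigned to every gene independently with a term-specific
    background probability drawn uniformly from
    ``background_prob_range``.  For every (term, odds) pair in
    ``planted``, membership probability within the designated subset
    (the first ``planted_subset_size`` genes) is multiplied by
    ``odds`` (capped at 1).

    Returns ``(mapping, truth)`` where ``truth`` records, per planted
    term, the subset gene ids and the odds used.
    """
    from .enrichment import GoMapping

    if n_terms < 1:
        raise InvalidInputError(f"n_terms must be >= 1, got {n_terms}")
    if n_genes < 1:
        raise InvalidInputError(f"n_genes must be >= 1, got {n_genes}")
    if planted_subset_size > n_genes:
        raise InvalidInputError("planted subset larger than the universe")
    planted = planted or []
    rng = np.random.default_rng(seed)
    gw = max(4, len(str(n_genes - 1)))
    genes = [f"gene_{i:0{gw}d}" for i in range(n_genes)]
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    term_set = set(terms)
    for term, odds in planted:
        if term not in term_set:
            raise InvalidInputError(f"planted term {term} not in universe")
        if odds <= 0:
            raise InvalidInputError("planted odds must be > 0")
    odds_by_term = dict(planted)
    subset = genes[:planted_subset_size]
    subset_mask = np.zeros(n_genes, dtype=bool)
    subset_mask[:planted_subset_size] = True

    lo, hi = background_prob_range
    pairs: list[tuple[str, str]] = []
    for term in terms:
        p_bg = rng.uniform(lo, hi)
        prob = np.full(n_genes, p_bg)
        if term in odds_by_term:
            prob[subset_mask] = min(1.0, p_bg * odds_by_term[term])
        member = rng.random(n_genes) < prob
        pairs.extend((genes[i], term) for i in np.flatnonzero(member))

    truth = {
        term: {"subset": list(subset), "odds": odds}
        for term, odds in odds_by_term.items()
    }
    return GoMapping(pairs), truth
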