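"""Two-way Poisson GLM for paired-batch count quartets.

Each contig contributes four un-normalized read counts laid out as
2 conditions (resistant / susceptible) x 2 batches.  A saturated
log-linear Poisson model with library-size offsets,

    log E[y_ij] = log N_ij + alpha + beta*[batch 2] + gamma*[resistant]
                  + delta*[batch 2, resistant],

is fit independently to every quartet.  ``gamma`` is the main
condition (resistance) effect on the log scale; ``delta`` is a
contig-specific batch x condition interaction that absorbs any
batch-2 disparity, so the main-effect test is driven by the batch-1
cells alone.  The reference cell is (batch 1, susceptible).

Because the model is saturated, the maximum-likelihood coefficients
have closed forms (offset-adjusted log count ratios) and the Wald
standard error of ``gamma`` follows from the Poisson information:
``SE = sqrt(1/y_r1 + 1/y_s1)``.  ``fit_quartet_irls`` fits the same
model by iteratively reweighted least squares and serves as an
in-package oracle for the closed form.

Zero cells are handled by a configurable policy; the default adds the
Haldane-Anscombe 0.5 continuity correction to all four cells and flags
the fit as ``corrected``.  A quartet whose batch-1 row is entirely
zero carries no information about the main effect and is reported with
``estimable=False`` and p = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import norm

from .errors import ConvergenceError, InvalidInputError

__all__ = [
    "CountQuartet",
    "LibrarySizes",
    "GlmFit",
    "fit_quartet_closed_form",
    "fit_quartet_irls",
    "wald_p",
    "fit_table",
    "ZERO_POLICIES",
]

LN2 = math.log(2.0)

#: Supported zero-count policies: ``"haldane"`` adds 0.5 to every cell of a
#: quartet containing a zero; ``"strict"`` raises on any zero cell.
ZERO_POLICIES = ("haldane", "strict")


@dataclass(frozen=True)
class CountQuartet:
    """The four per-contig counts: (resistant, susceptible) x (batch 1, 2)."""

    contig_id: str
    y_r1: int
    y_s1: int
    y_r2: int
    y_s2: int

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise InvalidInputError("contig_id must be non-empty")
        for name in ("y_r1", "y_s1", "y_r2", "y_s2"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
                raise InvalidInputError(
                    f"{self.contig_id}: count {name}={v!r} is not an integer"
                )
            if v < 0:
                raise InvalidInputError(
                    f"{self.contig_id}: count {name}={v} is negative"
                )

    def counts(self) -> tuple[int, int, int, int]:
        return (self.y_r1, self.y_s1, self.y_r2, self.y_s2)

    def swap_conditions(self) -> "CountQuartet":
        """Relabel resistant <-> susceptible in both batches."""
        return CountQuartet(
            self.contig_id, self.y_s1, self.y_r1, self.y_s2, self.y_r2
        )


@dataclass(frozen=True)
class LibrarySizes:
    """Per-sample sequencing totals N_ij defining the offsets log N_ij."""

    n_r1: float
    n_s1: float
    n_r2: float
    n_s2: float

    def __post_init__(self) -> None:
        for name in ("n_r1", "n_s1", "n_r2", "n_s2"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise InvalidInputError(
                    f"library size {name}={v!r} must be finite and > 0"
                )

    def totals(self) -> tuple[float, float, float, float]:
        return (self.n_r1, self.n_s1, self.n_r2, self.n_s2)

    def mean(self) -> float:
        return sum(self.totals()) / 4.0

    def scaled(self, c: float) -> "LibrarySizes":
        return LibrarySizes(*(c * n for n in self.totals()))


@dataclass(frozen=True)
class GlmFit:
    """Fitted quartet model: coefficients, Wald test and fold change.

    ``fc_main = exp(gamma)`` is the offset-adjusted resistant/susceptible
    fold change; ``alfca = |log2 fc_main|`` is its absolute log2
    magnitude, the ranking companion statistic.
    """

    contig_id: str
    alpha: float
    beta_batch: float
    gamma: float
    delta: float
    se_gamma: float
    z: float
    p: float
    fc_main: float
    log2fc: float
    alfca: float
    estimable: bool
    corrected: bool


def wald_p(gamma: float, se: float) -> float:
    """Two-sided standard-normal Wald p-value for gamma/se.

    Parameters
    ----------
    gamma : log-scale effect estimate.
    se : its standard error; must be > 0.
    """
    if not (se > 0):
        raise InvalidInputError(f"standard error must be > 0, got {se!r}")
    return float(2.0 * norm.sf(abs(gamma / se)))


def _apply_zero_policy(
    q: CountQuartet, zero_policy: str
) -> tuple[tuple[float, float, float, float], bool]:
    """Return (working cell values, corrected flag) per the zero policy."""
    if zero_policy not in ZERO_POLICIES:
        raise InvalidInputError(
            f"unknown zero policy {zero_policy!r}; choose from {ZERO_POLICIES}"
        )
    y = q.counts()
    if min(y) > 0:
        return tuple(float(v) for v in y), False
    if zero_policy == "strict":
        raise InvalidInputError(
            f"{q.contig_id}: zero cell under zero_policy='strict'"
        )
    return tuple(float(v) + 0.5 for v in y), True


def _batch1_row_zero(q: CountQuartet) -> bool:
    return q.y_r1 == 0 and q.y_s1 == 0


def _inestimable_fit(
    q: CountQuartet, libs: LibrarySizes, corrected: bool
) -> GlmFit:
    # No batch-1 information: the main effect cannot be estimated.
    nan = float("nan")
    return GlmFit(
        contig_id=q.contig_id,
        alpha=nan,
        beta_batch=nan,
        gamma=nan,
        delta=nan,
        se_gamma=nan,
        z=nan,
        p=1.0,
        fc_main=nan,
        log2fc=nan,
        alfca=nan,
        estimable=False,
        corrected=corrected,
    )


def fit_quartet_closed_form(
    q: CountQuartet, libs: LibrarySizes, zero_policy: str = "haldane"
) -> GlmFit:
    """Fit the saturated two-way Poisson GLM by its closed-form MLE.

    With treatment coding and reference cell (batch 1, susceptible):

    - ``alpha = log(y_s1 / n_s1)``
    - ``gamma = log((y_r1 / n_r1) / (y_s1 / n_s1))``
    - ``beta  = log((y_s2 / n_s2) / (y_s1 / n_s1))``
    - ``delta = log((y_r2 / n_r2) / (y_r1 / n_r1)) - beta``

    ``SE(gamma) = sqrt(1/y_r1 + 1/y_s1)`` from the observed Poisson
    information; the two-sided p-value is standard normal.
    """
    if _batch1_row_zero(q):
        return _inestimable_fit(q, libs, corrected=False)
    y, corrected = _apply_zero_policy(q, zero_policy)
    y_r1, y_s1, y_r2, y_s2 = y
    n_r1, n_s1, n_r2, n_s2 = libs.totals()

    alpha = math.log(y_s1 / n_s1)
    gamma = math.log((y_r1 / n_r1) / (y_s1 / n_s1))
    beta = math.log((y_s2 / n_s2) / (y_s1 / n_s1))
    delta = math.log((y_r2 / n_r2) / (y_r1 / n_r1)) - beta
    se = math.sqrt(1.0 / y_r1 + 1.0 / y_s1)
    z = gamma / se
    p = wald_p(gamma, se)
    log2fc = gamma / LN2
    return GlmFit(
        contig_id=q.contig_id,
        alpha=alpha,
        beta_batch=beta,
        gamma=gamma,
        delta=delta,
        se_gamma=se,
        z=z,
        p=p,
        fc_main=math.exp(gamma),
        log2fc=log2fc,
        alfca=abs(log2fc),
        estimable=True,
        corrected=corrected,
    )


# Design matrix rows in sample order (r1, s1, r2, s2); columns
# (intercept, batch, resistance, interaction); reference cell (batch 1,
# susceptible).
_DESIGN = np.array(
    [
        [1.0, 0.0, 1.0, 0.0],  # resistant, batch 1
        [1.0, 0.0, 0.0, 0.0],  # susceptible, batch 1
        [1.0, 1.0, 1.0, 1.0],  # resistant, batch 2
        [1.0, 1.0, 0.0, 0.0],  # susceptible, batch 2
    ]
)


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_quartet_irls(
    q: CountQuartet,
    libs: LibrarySizes,
    tol: float = 1e-8,
    max_iter: int = 50,
    zero_policy: str = "haldane",
) -> GlmFit:
    """Fit the same model by iteratively reweighted least squares.

    Uses the standard Poisson log-link IRLS with offsets, starting from
    mu = y + 0.5, converging on the change in deviance.  Independent of
    the closed form; used as its oracle.
    """
    if not (tol > 0):
        raise InvalidInputError(f"tol must be > 0, got {tol!r}")
    if max_iter < 1:
        raise InvalidInputError(f"max_iter must be >= 1, got {max_iter!r}")
    if _batch1_row_zero(q):
        return _inestimable_fit(q, libs, corrected=False)
    yv, corrected = _apply_zero_policy(q, zero_policy)
    y = np.array(yv, dtype=float)
    offset = np.log(np.array(libs.totals(), dtype=float))
    X = _DESIGN

    mu = y + 0.5
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    change = math.inf
    for _ in range(max_iter):
        w = mu
        zwork = (eta - offset) + (y - mu) / mu
        wx = X * w[:, None]
        coef = np.linalg.solve(X.T @ wx, X.T @ (w * zwork))
        eta = X @ coef + offset
        mu = np.exp(eta)
        dev_new = _poisson_deviance(y, mu)
        change = abs(dev - dev_new)
        dev = dev_new
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"{q.contig_id}: IRLS did not converge in {max_iter} iterations "
            f"(last deviance change {change:.3e})",
            n_iter=max_iter,
            last_change=change,
        )

    cov = np.linalg.inv(X.T @ (X * mu[:, None]))
    alpha, beta, gamma, delta = (float(c) for c in coef)
    se = float(math.sqrt(cov[2, 2]))
    z = gamma / se
    log2fc = gamma / LN2
    return GlmFit(
        contig_id=q.contig_id,
        alpha=alpha,
        beta_batch=beta,
        gamma=gamma,
        delta=delta,
        se_gamma=se,
        z=z,
        p=wald_p(gamma, se),
        fc_main=math.exp(gamma),
        log2fc=log2fc,
        alfca=abs(log2fc),
        estimable=True,
        corrected=corrected,
    )


def fit_table(
    quartets: Iterable[CountQuartet],
    libs: LibrarySizes,
    zero_policy: str = "haldane",
) -> list[GlmFit]:
    """Fit every quartet independently, preserving input order.

    No pooling or shrinkage across contigs: each row's fit is exactly
    ``fit_quartet_closed_form`` on that row.
    """
    quartets = list(quartets)
    seen: set[str] = set()
    for q in quartets:
        if q.contig_id in seen:
            raise InvalidInputError(f"duplicate contig_id: {q.contig_id}")
        seen.add(q.contig_id)
    return [fit_quartet_closed_form(q, libs, zero_policy) for q in quartets]
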