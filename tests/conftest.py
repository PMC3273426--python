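import math

import pytest
from hypothesis import HealthCheck, settings

from glmseq import CountQuartet, GlmFit, LibrarySizes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=50,
)
settings.load_profile("ci")


@pytest.fixture
def table1_libs() -> LibrarySizes:
    """Post-trimming read totals of the four libraries (r1, s1, r2, s2)."""
    return LibrarySizes(6.3e7, 7.2e7, 6.2e7, 7.2e7)


@pytest.fixture
def example_a() -> CountQuartet:
    """Worked example A: a huge batch-2 disparity but no batch-1 signal."""
    return CountQuartet("Contig_18664", 4, 4, 75359, 22)


@pytest.fixture
def example_b() -> CountQuartet:
    """Worked example B: a consistent positive resistance effect."""
    return CountQuartet("Contig_27586", 18, 4, 15041, 527)


def make_fit(
    contig_id: str,
    p: float = 0.5,
    alfca: float = 1.0,
    gamma: float = 0.5,
    estimable: bool = True,
) -> GlmFit:
    """Minimal consistent GlmFit for ranking/selection tests."""
    se = 1.0
    return GlmFit(
        contig_id=contig_id,
        alpha=0.0,
        beta_batch=0.0,
        gamma=gamma,
        delta=0.0,
        se_gamma=se,
        z=gamma / se,
        p=p,
        fc_main=math.exp(gamma),
        log2fc=gamma / math.log(2),
        alfca=alfca,
        estimable=estimable,
        corrected=False,
    )
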