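"""Unit and property tests for the two-way Poisson GLM fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glmseq import (
    ConvergenceError,
    CountQuartet,
    InvalidInputError,
    LibrarySizes,
    fit_quartet_closed_form,
    fit_quartet_irls,
    fit_table,
    wald_p,
)

COEF_FIELDS = ("alpha", "beta_batch", "gamma", "delta", "se_gamma", "z", "p")

positive_counts = st.integers(min_value=1, max_value=100_000)
lib_totals = st.floats(min_value=1e6, max_value=1e9, allow_nan=False)


@st.composite
def positive_quartets(draw):
    return CountQuartet(
        "c",
        draw(positive_counts),
        draw(positive_counts),
        draw(positive_counts),
        draw(positive_counts),
    )


@st.composite
def libraries(draw):
    return LibrarySizes(
        draw(lib_totals), draw(lib_totals), draw(lib_totals), draw(lib_totals)
    )


class TestClosedForm:
    def test_reproduces_printed_worked_examples(
        self, table1_libs, example_a, example_b
    ):
        fit_a = fit_quartet_closed_form(example_a, table1_libs)
        assert round(fit_a.fc_main, 2) == 1.14
        assert round(fit_a.p, 2) == 0.85
        fit_b = fit_quartet_closed_form(example_b, table1_libs)
        assert fit_b.fc_main == pytest.approx(5.15, rel=2e-3)
        assert round(fit_b.p, 3) == 0.003

    def test_coefficients_match_hand_computed_log_ratios(
        self, table1_libs, example_b
    ):
        fit = fit_quartet_closed_form(example_b, table1_libs)
        assert fit.gamma == pytest.approx(
            math.log((18 / 6.3e7) / (4 / 7.2e7)), rel=1e-12
        )
        assert fit.se_gamma == pytest.approx(
            math.sqrt(1 / 18 + 1 / 4), rel=1e-12
        )
        assert fit.beta_batch == pytest.approx(
            math.log((527 / 7.2e7) / (4 / 7.2e7)), rel=1e-12
        )
        assert fit.delta == pytest.approx(
            math.log((15041 / 6.2e7) / (18 / 6.3e7)) - fit.beta_batch,
            rel=1e-12,
        )

    def test_all_equal_quartet_is_null(self):
        libs = LibrarySizes(1e7, 1e7, 1e7, 1e7)
        fit = fit_quartet_closed_form(CountQuartet("c", 10, 10, 10, 10), libs)
        assert fit.gamma == 0.0
        assert fit.fc_main == 1.0
        assert fit.z == 0.0
        assert fit.p == 1.0
        assert fit.delta == 0.0

    def test_derived_fields_are_exact_functions_of_gamma(
        self, table1_libs, example_b
    ):
        fit = fit_quartet_closed_form(example_b, table1_libs)
        assert fit.fc_main == math.exp(fit.gamma)
        assert fit.log2fc == fit.gamma / math.log(2)
        assert fit.alfca == abs(fit.log2fc)

    @given(q=positive_quartets(), libs=libraries())
    def test_saturation_fitted_means_reproduce_counts(self, q, libs):
        """In the saturated model the fitted cell means equal the data."""
        fit = fit_quartet_closed_form(q, libs)
        n = libs.totals()
        log_mu = np.array(
            [
                math.log(n[0]) + fit.alpha + fit.gamma,
                math.log(n[1]) + fit.alpha,
                math.log(n[2]) + fit.alpha + fit.beta_batch + fit.gamma
                + fit.delta,
                math.log(n[3]) + fit.alpha + fit.beta_batch,
            ]
        )
        mu = np.exp(log_mu)
        y = np.array(q.counts(), dtype=float)
        assert mu == pytest.approx(y, rel=1e-9)
        dev = 2.0 * np.sum(y * np.log(y / mu) - (y - mu))
        assert abs(dev) < 1e-8

    @given(q=positive_quartets(), libs=libraries())
    def test_condition_label_antisymmetry(self, q, libs):
        fit = fit_quartet_closed_form(q, libs)
        swapped_libs = LibrarySizes(
            libs.n_s1, libs.n_r1, libs.n_s2, libs.n_r2
        )
        rfit = fit_quartet_closed_form(q.swap_conditions(), swapped_libs)
        assert rfit.gamma == pytest.approx(-fit.gamma, rel=1e-12, abs=1e-12)
        assert rfit.fc_main == pytest.approx(1 / fit.fc_main, rel=1e-9)
        assert rfit.p == pytest.approx(fit.p, rel=1e-9, abs=1e-15)
        assert rfit.alfca == pytest.approx(fit.alfca, rel=1e-9, abs=1e-12)

    @given(
        q=positive_quartets(),
        libs=libraries(),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_offset_scale_invariance(self, q, libs, c):
        """A common rescaling of all library sizes changes nothing."""
        fit = fit_quartet_closed_form(q, libs)
        scaled = fit_quartet_closed_form(q, libs.scaled(c))
        for field in ("gamma", "delta", "se_gamma", "z", "p"):
            assert getattr(scaled, field) == pytest.approx(
                getattr(fit, field), rel=1e-9, abs=1e-12
            )

    def test_main_effect_depends_only_on_batch1_cells(self, table1_libs):
        """The interaction absorbs batch-2 disparity: changing batch-2
        counts leaves gamma, its SE and p untouched."""
        base = fit_quartet_closed_form(
            CountQuartet("c", 4, 4, 75359, 22), table1_libs
        )
        other = fit_quartet_closed_form(
            CountQuartet("c", 4, 4, 17, 9000), table1_libs
        )
        assert other.gamma == base.gamma
        assert other.se_gamma == base.se_gamma
        assert other.p == base.p
        assert other.delta != base.delta

    def test_zero_cell_triggers_continuity_correction(self, table1_libs):
        fit = fit_quartet_closed_form(
            CountQuartet("c", 5, 0, 30, 20), table1_libs
        )
        assert fit.corrected
        assert fit.estimable
        assert fit.gamma == pytest.approx(
            math.log((5.5 / 6.3e7) / (0.5 / 7.2e7)), rel=1e-12
        )
        assert fit.se_gamma == pytest.approx(
            math.sqrt(1 / 5.5 + 1 / 0.5), rel=1e-12
        )

    def test_zero_batch1_row_is_inestimable(self, table1_libs):
        fit = fit_quartet_closed_form(
            CountQuartet("c", 0, 0, 30, 20), table1_libs
        )
        assert not fit.estimable
        assert fit.p == 1.0
        assert math.isnan(fit.gamma)

    def test_strict_zero_policy_raises(self, table1_libs):
        with pytest.raises(InvalidInputError):
            fit_quartet_closed_form(
                CountQuartet("c", 5, 0, 30, 20), table1_libs,
                zero_policy="strict",
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            CountQuartet("c", -1, 2, 3, 4)
        with pytest.raises(InvalidInputError):
            CountQuartet("c", 1.5, 2, 3, 4)
        with pytest.raises(InvalidInputError):
            CountQuartet("", 1, 2, 3, 4)
        with pytest.raises(InvalidInputError):
            LibrarySizes(0.0, 1e7, 1e7, 1e7)
        with pytest.raises(InvalidInputError):
            LibrarySizes(-1e7, 1e7, 1e7, 1e7)


class TestIrls:
    def test_matches_closed_form_on_worked_example(
        self, table1_libs, example_b
    ):
        cf = fit_quartet_closed_form(example_b, table1_libs)
        ir = fit_quartet_irls(example_b, table1_libs)
        for field in COEF_FIELDS:
            assert getattr(ir, field) == pytest.approx(
                getattr(cf, field), rel=1e-8, abs=1e-10
            )

    def test_all_equal_quartet_is_null(self):
        libs = LibrarySizes(1e7, 1e7, 1e7, 1e7)
        fit = fit_quartet_irls(CountQuartet("c", 10, 10, 10, 10), libs)
        assert fit.gamma == pytest.approx(0.0, abs=1e-10)
        assert fit.p == pytest.approx(1.0, abs=1e-9)

    def test_random_sweep_agrees_with_closed_form(self, table1_libs):
        rng = np.random.default_rng(20_240_001)
        worst = 0.0
        for _ in range(300):
            y = rng.integers(1, 100_000, size=4)
            q = CountQuartet("c", *(int(v) for v in y))
            cf = fit_quartet_closed_form(q, table1_libs)
            ir = fit_quartet_irls(q, table1_libs)
            for field in ("alpha", "beta_batch", "gamma", "delta"):
                a, b = getattr(cf, field), getattr(ir, field)
                worst = max(worst, abs(a - b) / max(abs(a), 1e-8))
        assert worst < 1e-6

    # statsmodels flags saturated fits (zero residual df) — expected here
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_agrees_with_statsmodels_glm(self, table1_libs):
        """Third-route check against an established GLM implementation."""
        import statsmodels.api as sm

        X = np.array(
            [
                [1, 0, 1, 0],
                [1, 0, 0, 0],
                [1, 1, 1, 1],
                [1, 1, 0, 0],
            ],
            dtype=float,
        )
        rng = np.random.default_rng(7)
        for _ in range(10):
            counts = [int(v) for v in rng.integers(1, 50_000, size=4)]
            q = CountQuartet("c", *counts)
            res = sm.GLM(
                np.array(counts, dtype=float),
                X,
                family=sm.families.Poisson(),
                offset=np.log(np.array(table1_libs.totals())),
            ).fit()
            ours = fit_quartet_irls(q, table1_libs)
            assert ours.gamma == pytest.approx(res.params[2], rel=1e-6)
            assert ours.se_gamma == pytest.approx(res.bse[2], rel=1e-6)

    def test_zero_cell_handled_like_closed_form(self, table1_libs):
        q = CountQuartet("c", 5, 0, 30, 20)
        cf = fit_quartet_closed_form(q, table1_libs)
        ir = fit_quartet_irls(q, table1_libs)
        assert ir.corrected
        assert ir.gamma == pytest.approx(cf.gamma, rel=1e-8)

    def test_bad_controls_rejected(self, table1_libs, example_b):
        with pytest.raises(InvalidInputError):
            fit_quartet_irls(example_b, table1_libs, tol=0.0)
        with pytest.raises(InvalidInputError):
            fit_quartet_irls(example_b, table1_libs, max_iter=0)

    def test_nonconvergence_raises_with_diagnostics(
        self, table1_libs, example_b
    ):
        with pytest.raises(ConvergenceError) as err:
            fit_quartet_irls(example_b, table1_libs, tol=1e-300, max_iter=2)
        assert err.value.n_iter == 2


class TestWaldP:
    def test_known_values(self):
        assert wald_p(0.0, 1.0) == 1.0
        assert wald_p(
            math.log(5.1429), math.sqrt(1 / 18 + 1 / 4)
        ) == pytest.approx(0.003, abs=5e-4)

    @pytest.mark.parametrize("s", [0.1, 1.0, 17.3])
    def test_normal_quantile_oracle(self, s):
        assert wald_p(1.959963984540054 * s, s) == pytest.approx(
            0.05, rel=1e-9
        )

    def test_rejects_nonpositive_se(self):
        with pytest.raises(InvalidInputError):
            wald_p(1.0, 0.0)
        with pytest.raises(InvalidInputError):
            wald_p(1.0, -2.0)


class TestFitTable:
    def test_empty_collection(self, table1_libs):
        assert fit_table([], table1_libs) == []

    def test_paper_quartets_round_to_printed_pairs(
        self, table1_libs, example_a, example_b
    ):
        fits = fit_table([example_a, example_b], table1_libs)
        assert [f.contig_id for f in fits] == [
            example_a.contig_id,
            example_b.contig_id,
        ]
        assert (round(fits[0].fc_main, 2), round(fits[0].p, 2)) == (1.14, 0.85)
        assert round(fits[1].p, 3) == 0.003

    def test_duplicate_contig_id_named_in_error(self, table1_libs):
        q = CountQuartet("dup", 1, 2, 3, 4)
        with pytest.raises(InvalidInputError, match="dup"):
            fit_table([q, q], table1_libs)

    def test_equivalent_to_per_quartet_fits(self, table1_libs):
        rng = np.random.default_rng(42)
        quartets = [
            CountQuartet(f"c{i}", *(int(v) for v in rng.integers(1, 1000, 4)))
            for i in range(100)
        ]
        table = fit_table(quartets, table1_libs)
        for q, f in zip(quartets, table):
            assert f == fit_quartet_closed_form(q, table1_libs)
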