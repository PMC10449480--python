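import itertools

import numpy as np
import pandas as pd
import pytest

import meltcycle as mc
from meltcycle.factorial_design import (
    ALL_VARIANTS,
    DesignError,
    N_TERMS,
    TERMS,
    replicate_design,
)


def term_index(name):
    return mc.TERM_NAMES.index(name)


class TestDesignMatrix:
    def test_wild_type_row(self):
        row = mc.design_row(mc.VariantBarcode((0, 0, 0, 0)))
        assert row[0] == 1.0
        assert np.all(row[1:] == 0.0)

    def test_quadruple_mutant_row(self):
        row = mc.design_row(mc.VariantBarcode((1, 1, 1, 1)))
        assert np.all(row == 1.0)

    def test_full_design_invertible(self):
        X = mc.build_design_matrix().X
        assert X.shape == (16, 16)
        assert np.linalg.matrix_rank(X) == 16
        assert abs(np.linalg.det(X)) > 1e-9

    def test_interaction_columns_are_products(self):
        for coding in ("ZERO_ONE", "CENTERED"):
            X = mc.build_design_matrix(coding=coding).X
            mains = {(i,): X[:, 1 + i] for i in range(4)}
            for j, term in enumerate(TERMS):
                if len(term) < 2:
                    continue
                prod = np.prod([mains[(i,)] for i in term], axis=0)
                np.testing.assert_allclose(X[:, j], prod)

    def test_duplicate_variant_fatal(self):
        variants = [mc.VariantBarcode.from_index(0)] * 2
        with pytest.raises(DesignError, match="duplicate"):
            mc.build_design_matrix(variants)

    def test_index_barcode_bijection(self):
        seen = set()
        for i in range(16):
            b = mc.VariantBarcode.from_index(i)
            assert b.variant_index == i
            seen.add(b.indicators)
        assert len(seen) == 16
        assert mc.VariantBarcode.from_index(1).indicators == (1, 0, 0, 0)


class TestFitFactorial:
    @staticmethod
    def _tm_from_beta(beta, coding="ZERO_ONE"):
        X = mc.build_design_matrix(coding=coding)
        return X, X.X @ beta

    def test_exact_recovery_noise_free(self):
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 1, N_TERMS)
        beta[0] = 64.0
        X, tm = self._tm_from_beta(beta)
        fit = mc.fit_factorial(X, tm)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-9)
        assert fit.df_resid == 0
        assert np.all(np.isnan(fit.se))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = replicate_design(mc.build_design_matrix(), 3)
        y = rng.normal(64.0, 1.0, X.n_obs)
        fit = mc.fit_factorial(X, y)
        brute = np.linalg.solve(X.X.T @ X.X, X.X.T @ y)
        np.testing.assert_allclose(fit.beta, brute, atol=1e-9)

    def test_perturbation_residual_matches_projection_oracle(self):
        # reduced model: the terms of the phi regression plus constant
        names = ["Constant", "I4", "F26", "Y33", "F37",
                 "I4*F26", "I4*Y33", "F26*Y33", "I4*F26*Y33"]
        retained = np.zeros(N_TERMS, bool)
        for n in names:
            retained[term_index(n)] = True
        beta = np.zeros(N_TERMS)
        beta[0] = 64.0
        beta[term_index("F37")] = 2.5
        X, tm = self._tm_from_beta(beta)
        tm = tm.copy()
        tm[5] += 1.0  # one perturbed variant
        fit = mc.fit_factorial(X, tm, retained=retained)
        Xr = X.X[:, retained]
        H = Xr @ np.linalg.solve(Xr.T @ Xr, Xr.T)
        eps = (np.eye(16) - H) @ tm
        np.testing.assert_allclose(fit.residuals, eps, atol=1e-9)

    def test_r2_equals_brute_force(self):
        rng = np.random.default_rng(2)
        X = replicate_design(mc.build_design_matrix(), 6)
        beta = np.zeros(N_TERMS)
        beta[0], beta[4] = 64.0, 2.5
        y = X.X @ beta + rng.normal(0, 0.3, X.n_obs)
        fit = mc.fit_factorial(X, y)
        ssres = np.sum(fit.residuals**2)
        sstot = np.sum((y - y.mean()) ** 2)
        assert fit.R2 == pytest.approx(1 - ssres / sstot, rel=1e-12)

    def test_centered_coding_contrast_is_context_average(self):
        # under centered coding each main effect equals the mutation's
        # Tm change averaged over its 8 background contexts
        rng = np.random.default_rng(3)
        beta = rng.normal(0, 1, N_TERMS)
        X, tm = self._tm_from_beta(beta, coding="ZERO_ONE")
        fitc = mc.fit_factorial(mc.build_design_matrix(coding="CENTERED"), tm)
        tm_by_idx = dict(zip([v.variant_index for v in ALL_VARIANTS], tm))
        for site in range(4):
            deltas = [
                tm_by_idx[idx | (1 << site)] - tm_by_idx[idx]
                for idx in range(16) if not idx & (1 << site)
            ]
            assert fitc.beta[1 + site] == pytest.approx(
                np.mean(deltas), abs=1e-9
            )

    def test_zero_one_coefficients_equal_mutant_cycle_differences(self):
        # Moebius inversion over mutation subsets: each coefficient is the
        # alternating sum of the Tm values of its sub-variants, the
        # combinatorial multi-mutant thermodynamic-cycle construction
        rng = np.random.default_rng(4)
        beta = rng.normal(0, 1, N_TERMS)
        X, tm = self._tm_from_beta(beta)
        fit = mc.fit_factorial(X, tm)
        tm_by_idx = dict(zip([v.variant_index for v in ALL_VARIANTS], tm))
        for j, term in enumerate(TERMS):
            total = 0.0
            for r in range(len(term) + 1):
                for sub in itertools.combinations(term, r):
                    idx = sum(1 << s for s in sub)
                    total += (-1) ** (len(term) - r) * tm_by_idx[idx]
            assert fit.beta[j] == pytest.approx(total, abs=1e-9)

    def test_rank_deficiency_fatal(self):
        X = mc.build_design_matrix()
        bad = mc.DesignMatrix(X=np.hstack([X.X[:, :15], X.X[:, :1]]),
                              variants=X.variants, coding=X.coding)
        with pytest.raises(DesignError, match="rank"):
            mc.fit_factorial(bad, np.zeros(16))


class TestReduceModel:
    @staticmethod
    def _noisy_fit(beta, sd, seed, n_rep=6):
        rng = np.random.default_rng(seed)
        X = replicate_design(mc.build_design_matrix(), n_rep)
        y = X.X @ beta + rng.normal(0, sd, X.n_obs)
        return X, y, mc.fit_factorial(X, y)

    def test_strong_effects_nothing_dropped(self):
        beta = np.full(N_TERMS, 5.0)
        beta[0] = 64.0
        X, y, fit = self._noisy_fit(beta, sd=0.05, seed=0)
        red = mc.reduce_model(fit, X, y)
        assert red.retained.all()

    def test_null_fourway_term_eliminated_or_nonsignificant(self):
        # a truly null four-way term has a uniform P value, so the
        # P > 0.5 removal rule fires about half the time; what backward
        # elimination guarantees is that the term is either dropped or
        # left clearly non-significant
        beta = np.zeros(N_TERMS)
        beta[0] = 64.0
        beta[1:5] = [0.5, -0.8, 0.6, 2.5]
        four_way = term_index("I4*F26*Y33*F37")
        dropped_or_ns = 0
        X = replicate_design(mc.build_design_matrix(coding="CENTERED"), 6)
        X01 = replicate_design(mc.build_design_matrix(), 6)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = X01.X @ beta + rng.normal(0, 0.3, X.n_obs)
            red = mc.reduce_model(mc.fit_factorial(X, y), X, y)
            if not red.retained[four_way] or red.P[four_way] > 0.05:
                dropped_or_ns += 1
        assert dropped_or_ns >= 40  # >= 80% of runs

    def test_weak_heredity_protects_parent_of_significant_triple(self):
        beta = np.zeros(N_TERMS)
        beta[0] = 64.0
        beta[term_index("I4*F26*Y33")] = 3.0  # strong three-way, null mains
        for seed in range(5):
            X, y, fit = self._noisy_fit(beta, sd=0.2, seed=seed)
            red = mc.reduce_model(fit, X, y)
            assert red.retained[term_index("I4*F26*Y33")]
            assert red.P[term_index("I4*F26*Y33")] < 0.05
            for parent in ("I4", "F26", "Y33", "I4*F26", "I4*Y33",
                           "F26*Y33"):
                assert red.retained[term_index(parent)]


class TestBatchAlign:
    def test_identical_batches_zero_offset(self):
        a = pd.Series(np.linspace(60, 66, 16))
        offset, aligned = mc.batch_align(a, a)
        assert offset == 0.0
        pd.testing.assert_series_equal(aligned, a)

    def test_exact_constant_offset_recovered(self):
        a = pd.Series(np.linspace(60, 66, 16))
        offset, aligned = mc.batch_align(a, a - 0.62)
        assert offset == pytest.approx(0.62, abs=1e-12)
        np.testing.assert_allclose(aligned, a)

    def test_noisy_offset_recovered(self):
        rng = np.random.default_rng(5)
        a = pd.Series(np.linspace(60, 66, 16))
        b = a - 0.62 + rng.normal(0, 0.1, 16)
        offset, _ = mc.batch_align(a, b)
        assert offset == pytest.approx(0.62, abs=0.1)

    def test_disjoint_batches_fatal(self):
        a = pd.Series([60.0] * 8, index=range(8))
        b = pd.Series([60.0] * 8, index=range(8, 16))
        with pytest.raises(DesignError):
            mc.batch_align(a, b)


class TestPredictTm:
    def test_wild_type_predicts_constant(self):
        beta = np.zeros(N_TERMS)
        beta[0] = 64.0
        X = mc.build_design_matrix()
        fit = mc.fit_factorial(X, X.X @ beta)
        assert mc.predict_tm(fit, mc.VariantBarcode((0, 0, 0, 0))) == (
            pytest.approx(64.0)
        )

    def test_predictions_minus_observations_equal_residuals(self):
        rng = np.random.default_rng(6)
        X = mc.build_design_matrix()
        y = rng.normal(64, 1, 16)
        fit = mc.fit_factorial(X, y)
        preds = np.array([mc.predict_tm(fit, v) for v in ALL_VARIANTS])
        np.testing.assert_allclose(y - preds, fit.residuals, atol=1e-9)
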