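import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from translatomix import (
    ExpressionMatrix,
    NormalizedData,
    ValidationError,
    bh_adjust,
    fit_contrast_lm,
    moderate_ebayes,
    nb_dispersion,
    nb_glm_test,
    run_differential,
)
from translatomix.engines import LinearFit, estimate_prior, _apl
from translatomix.simulate import SimulationSpec, simulate_study
from tests.conftest import NULL_PROPORTIONS, binomial_interval


def _norm(values: pd.DataFrame, weights: pd.DataFrame | None = None) -> NormalizedData:
    return NormalizedData(
        logexpr=values,
        weights=weights,
        lib_sizes=pd.Series(1.0, index=values.columns),
        factors=pd.Series(1.0, index=values.columns),
    )


def _two_class_design(samples) -> tuple[pd.DataFrame, pd.DataFrame]:
    half = len(samples) // 2
    design = pd.DataFrame(0, index=samples, columns=["ctl", "exp"])
    design.iloc[:half, 0] = 1
    design.iloc[half:, 1] = 1
    contrasts = pd.DataFrame({"exp-ctl": pd.Series([-1, 1], index=["ctl", "exp"])})
    return design, contrasts


class TestLinearFit:
    def test_logfc_is_class_mean_difference(self):
        y = pd.DataFrame(
            [[1.0, 3.0, 10.0, 14.0], [5.0, 5.0, 5.0, 5.0]],
            index=["g1", "g2"], columns=list("abcd"),
        )
        design, contrasts = _two_class_design(y.columns)
        fit = fit_contrast_lm(_norm(y), design, contrasts)
        assert fit.coefficients.loc["g1", "exp-ctl"] == pytest.approx(12.0 - 2.0)
        assert fit.coefficients.loc["g2", "exp-ctl"] == pytest.approx(0.0)
        assert fit.sigma2.loc["g2"] == pytest.approx(0.0)
        assert fit.df_resid == 2

    def test_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(17)
        y = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        w = pd.DataFrame(rng.uniform(0.2, 5.0, size=(30, 6)), columns=list("abcdef"))
        design, contrasts = _two_class_design(y.columns)
        fit = fit_contrast_lm(_norm(y, w), design, contrasts)
        X = design.to_numpy(dtype=float)
        c = contrasts.to_numpy(dtype=float)[:, 0]
        for g in range(30):
            W = np.diag(w.iloc[g].to_numpy())
            xtwx = X.T @ W @ X
            beta = np.linalg.solve(xtwx, X.T @ W @ y.iloc[g].to_numpy())
            resid = y.iloc[g].to_numpy() - X @ beta
            s2 = resid @ W @ resid / (6 - 2)
            assert fit.coefficients.iloc[g, 0] == pytest.approx(c @ beta)
            assert fit.sigma2.iloc[g] == pytest.approx(s2)
            se_unscaled = np.sqrt(c @ np.linalg.inv(xtwx) @ c)
            assert fit.stdev_unscaled.iloc[g, 0] == pytest.approx(se_unscaled)

    def test_rank_deficient_design_rejected(self):
        y = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        design = pd.DataFrame(
            {"a": [1, 1, 1, 1], "b": [1, 1, 1, 1]}, index=y.columns
        )
        contrasts = pd.DataFrame({"c": pd.Series([1, -1], index=["a", "b"])})
        with pytest.raises(ValidationError, match="rank"):
            fit_contrast_lm(_norm(y), design, contrasts)


class TestEmpiricalBayes:
    def _fit_from_sigma2(self, sigma2: np.ndarray, df: float) -> LinearFit:
        G = sigma2.size
        genes = pd.Index([f"g{i}" for i in range(G)])
        ones = pd.DataFrame({"c": np.ones(G)}, index=genes)
        return LinearFit(
            coefficients=ones,
            stdev_unscaled=ones,
            sigma2=pd.Series(sigma2, index=genes),
            df_resid=df,
            amean=pd.Series(np.zeros(G), index=genes),
        )

    def test_identical_variances_are_fixed_point(self):
        fit = self._fit_from_sigma2(np.full(50, 2.5), df=4.0)
        mod = moderate_ebayes(fit)
        np.testing.assert_allclose(mod.s2_post, 2.5, rtol=1e-9)

    def test_prior_recovery_from_scaled_inv_chi2(self):
        rng = np.random.default_rng(123)
        G, d0, s02, d = 5000, 4.0, 2.0, 6.0
        true_var = s02 * d0 / rng.chisquare(d0, size=G)
        s2 = true_var * rng.chisquare(d, size=G) / d
        df0_hat, s02_hat = estimate_prior(s2, d)
        assert df0_hat == pytest.approx(d0, rel=0.15)
        assert s02_hat == pytest.approx(s02, rel=0.15)

    def test_posterior_between_prior_and_observed(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(4, size=300) / 4
        fit = self._fit_from_sigma2(s2, df=4.0)
        mod = moderate_ebayes(fit)
        lo = np.minimum(s2, mod.s2_prior)
        hi = np.maximum(s2, mod.s2_prior)
        assert ((mod.s2_post >= lo - 1e-12) & (mod.s2_post <= hi + 1e-12)).all()

    def test_limits_recover_ordinary_and_pooled_t(self):
        rng = np.random.default_rng(31)
        y = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        design, contrasts = _two_class_design(y.columns)
        fit = fit_contrast_lm(_norm(y), design, contrasts)
        ordinary_t = fit.coefficients.to_numpy() / (
            fit.stdev_unscaled.to_numpy() * np.sqrt(fit.sigma2.to_numpy())[:, None]
        )
        mod0 = moderate_ebayes(fit, prior=(1e-12, 1.0))
        np.testing.assert_allclose(mod0.t.to_numpy(), ordinary_t, rtol=1e-6)
        mod_inf = moderate_ebayes(fit, prior=(np.inf, 0.7))
        pooled = fit.coefficients.to_numpy() / (
            fit.stdev_unscaled.to_numpy() * np.sqrt(0.7)
        )
        np.testing.assert_allclose(mod_inf.t.to_numpy(), pooled, rtol=1e-9)

    def test_all_zero_variances_rejected(self):
        fit = self._fit_from_sigma2(np.zeros(10), df=4.0)
        with pytest.raises(ValidationError, match="zero"):
            moderate_ebayes(fit)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    m = len(p)
    adj = np.empty(m)
    for i in range(m):
        candidates = [
            p[j] * m / (np.sum(p <= p[j]))
            for j in range(m)
            if p[j] >= p[i]
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


class TestBH:
    def test_hand_computed(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.42])), [0.42])
        np.testing.assert_allclose(bh_adjust(np.ones(5)), np.ones(5))
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=30,
        )
    )
    def test_matches_brute_force(self, pvals):
        p = np.asarray(pvals)
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)


class TestNBDispersion:
    def test_poisson_counts_give_floor_dispersion(self):
        rng = np.random.default_rng(6)
        x = rng.poisson(300, size=(400, 6)).astype(float)
        m = ExpressionMatrix(
            values=pd.DataFrame(x, index=[f"g{i}" for i in range(400)],
                                columns=list("abcdef")),
            platform="rnaseq",
        )
        design, _ = _two_class_design(m.sample_ids)
        phi = nb_dispersion(m, design)
        assert phi.median() < 0.01

    def test_recovers_planted_dispersion(self):
        # two classes, n=4 each, gamma-Poisson counts at dispersion 0.1
        rng = np.random.default_rng(5)
        G, n = 2000, 8
        means = 2.0 ** rng.uniform(4, 10, size=G)
        lam = rng.gamma(10.0, means[:, None] / 10.0, size=(G, n))
        x = rng.poisson(lam).astype(float)
        m = ExpressionMatrix(
            values=pd.DataFrame(x, index=[f"g{i}" for i in range(G)],
                                columns=[f"s{j}" for j in range(n)]),
            platform="rnaseq",
        )
        design, _ = _two_class_design(m.sample_ids)
        phi = nb_dispersion(m, design)
        # tagwise values shrink toward the common value near the truth 0.1
        assert np.median(phi) == pytest.approx(0.1, rel=0.2)

    def test_tagwise_between_genewise_and_common(self):
        rng = np.random.default_rng(14)
        G, n = 200, 6
        means = 2.0 ** rng.uniform(5, 9, size=G)
        lam = rng.gamma(5.0, means[:, None] / 5.0, size=(G, n))  # phi = 0.2
        x = rng.poisson(lam).astype(float)
        m = ExpressionMatrix(
            values=pd.DataFrame(x, index=[f"g{i}" for i in range(G)],
                                columns=list("abcdef")),
            platform="rnaseq",
        )
        design, _ = _two_class_design(m.sample_ids)
        phi = nb_dispersion(m, design).to_numpy()
        common = np.exp(np.average(np.log(phi)))  # near the pooled optimum
        X = design.to_numpy(dtype=float)
        offset = np.log(x.sum(axis=0))
        grid = np.clip(np.median(phi) * 2.0 ** np.linspace(-5, 5, 11), 1e-6, 10.0)
        apl = np.column_stack([_apl(x, X, offset, g) for g in grid])
        genewise = grid[np.argmax(apl, axis=1)]
        # shrunk dispersion lies between the gene-wise and common estimates,
        # up to one grid step of resolution
        step = np.log(2.0)
        lo = np.minimum(np.log(genewise), np.log(common)) - step
        hi = np.maximum(np.log(genewise), np.log(common)) + step
        frac_between = np.mean((np.log(phi) >= lo) & (np.log(phi) <= hi))
        assert frac_between > 0.95


class TestNBGLM:
    def _matrix(self, x: np.ndarray) -> ExpressionMatrix:
        return ExpressionMatrix(
            values=pd.DataFrame(
                x, index=[f"g{i}" for i in range(x.shape[0])],
                columns=[f"s{j}" for j in range(x.shape[1])],
            ),
            platform="rnaseq",
        )

    def test_identical_classes_give_null_stats(self):
        x = np.tile(np.array([[100.0], [50.0], [400.0]]), (1, 6))
        m = self._matrix(x)
        design, contrasts = _two_class_design(m.sample_ids)
        phi = pd.Series(0.05, index=m.values.index)
        res = nb_glm_test(m, design, contrasts, phi)["exp-ctl"]
        np.testing.assert_allclose(res["logFC"], 0.0, atol=1e-6)
        np.testing.assert_allclose(res["stat"], 0.0, atol=1e-6)

    def test_planted_fourfold_change_recovered(self):
        rng = np.random.default_rng(77)
        G, n = 200, 8
        base = rng.poisson(5000, size=(G, n)).astype(float)
        base[:20, n // 2:] *= 4.0
        m = self._matrix(base)
        design, contrasts = _two_class_design(m.sample_ids)
        phi = pd.Series(1e-4, index=m.values.index)
        from translatomix import tmm_factors

        res = nb_glm_test(m, design, contrasts, phi, factors=tmm_factors(m))["exp-ctl"]
        assert res["logFC"].iloc[:20].mean() == pytest.approx(2.0, abs=0.05)
        assert (res["adj_pvalue"].iloc[:20] < 1e-6).all()

    def test_allzero_gene_gets_na(self):
        x = np.vstack([np.zeros(6), np.full(6, 100.0)])
        m = self._matrix(x)
        design, contrasts = _two_class_design(m.sample_ids)
        phi = pd.Series(0.1, index=m.values.index)
        res = nb_glm_test(m, design, contrasts, phi)["exp-ctl"]
        assert np.isnan(res["stat"].iloc[0])
        assert np.isfinite(res["stat"].iloc[1])


class TestRunDifferential:
    def test_geter_shaped_study_gives_three_tables(self, planted_study):
        de = run_differential(planted_study.matrix, planted_study.design)
        assert len(de) == 3
        names = list(de)
        assert names[0].endswith("transcription-ctl.transcription")
        for table in de.values():
            assert list(table.columns) == [
                "logFC", "ave_expr", "stat", "pvalue", "adj_pvalue"
            ]
            assert (table["adj_pvalue"].dropna() >= table["pvalue"].dropna() - 1e-15).all()

    def test_microarray_with_nb_glm_rejected(self, planted_study):
        import dataclasses

        bad = dataclasses.replace(
            planted_study.design, platform="microarray", engine="nb_glm"
        )
        with pytest.raises(ValidationError):
            run_differential(planted_study.matrix, bad)

    def test_engines_rank_planted_genes_concordantly(self):
        spec = SimulationSpec(
            n_genes=800, n_fractions=1, n_replicates=3, dispersion=0.01,
            baseline_mean=6.0, seed=9,
        )
        study = simulate_study(spec)
        lm = run_differential(study.matrix, study.design)
        import dataclasses

        nb_design = dataclasses.replace(study.design, engine="nb_glm")
        nb = run_differential(study.matrix, nb_design)
        name = list(lm)[0]
        with np.errstate(divide="ignore"):
            a = -np.log10(lm[name]["pvalue"].to_numpy())
            b = -np.log10(nb[name]["pvalue"].to_numpy())
        ok = np.isfinite(a) & np.isfinite(b)
        assert spearmanr(a[ok], b[ok]).statistic > 0.9


class TestTypeIError:
    def test_moderated_lm_controls_alpha(self, null_study):
        de = run_differential(null_study.matrix, null_study.design)
        p = np.concatenate([t["pvalue"].to_numpy() for t in de.values()])
        lo, hi = binomial_interval(0.05, p.size)
        assert lo < (p < 0.05).mean() < hi
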