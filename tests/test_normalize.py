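import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from translatomix import (
    ExpressionMatrix,
    ValidationError,
    filter_min_reads,
    log_cpm,
    mds_coordinates,
    precision_weights,
    tmm_factors,
)
from translatomix.normalize import leading_logfc_distances


def _counts(values, samples=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                            columns=samples),
        platform="rnaseq",
    )


class TestFilterMinReads:
    def test_threshold_zero_keeps_all_positive(self):
        m = _counts(np.arange(1, 13).reshape(4, 3))
        out = filter_min_reads(m, threshold=0)
        assert out.gene_ids == m.gene_ids

    def test_strict_inequality_at_256(self):
        rows = [[257, 300], [256, 300], [255, 300], [1000, 1000]]
        m = _counts(rows)
        out = filter_min_reads(m, threshold=256)
        # exactly 256 in one subset sample fails the strict > rule
        assert out.gene_ids == ["g0", "g3"]

    def test_manual_enumeration_on_subset(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 600, size=(10, 4)).astype(float)
        m = _counts(vals)
        subset = ["s0", "s2"]
        expected = [
            f"g{i}" for i in range(10) if vals[i, 0] > 256 and vals[i, 2] > 256
        ]
        out = filter_min_reads(m, threshold=256, subset=subset)
        assert out.gene_ids == expected

    def test_idempotent_and_subset_errors(self):
        m = _counts([[300, 300], [10, 10]])
        once = filter_min_reads(m, threshold=256)
        twice = filter_min_reads(once, threshold=256)
        assert once.gene_ids == twice.gene_ids
        with pytest.raises(ValidationError, match="not in matrix"):
            filter_min_reads(m, threshold=0, subset=["nope"])


def brute_force_tmm(x: np.ndarray, j: int, ref: int) -> float:
    """Plain-loop trimmed weighted mean of log ratios (independent of the
    package implementation)."""
    n_obs, n_ref = x[:, j].sum(), x[:, ref].sum()
    rows = []
    for g in range(x.shape[0]):
        o, r = x[g, j], x[g, ref]
        if o > 0 and r > 0:
            m = np.log2((o / n_obs) / (r / n_ref))
            a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
            w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
            rows.append((m, a, w))
    ms = np.array([t[0] for t in rows])
    as_ = np.array([t[1] for t in rows])
    ws = np.array([t[2] for t in rows])
    n = len(rows)
    lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
    rm, ra = rankdata(ms), rankdata(as_)
    keep = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
    return float(np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep]))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 21, dtype=float)
        m = _counts(np.column_stack([col, col, col]))
        np.testing.assert_allclose(tmm_factors(m), 1.0, atol=1e-12)

    def test_depth_absorbed_by_library_size(self):
        col = np.arange(1, 51, dtype=float)
        m = _counts(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(tmm_factors(m), 1.0, atol=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        x = rng.poisson(100, size=(200, 2)).astype(float)
        x[:10, 1] *= 40  # a block of highly expressed genes in sample B
        m = _counts(x)
        factors = tmm_factors(m)
        lib = x.sum(axis=0)
        f75 = np.quantile(x / lib, 0.75, axis=0)
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        logf = np.array([brute_force_tmm(x, j, ref) for j in range(2)])
        expected = 2.0 ** (logf - logf.mean())
        np.testing.assert_allclose(factors.to_numpy(), expected, rtol=1e-10)

    def test_invariant_under_global_scaling(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(50, size=(100, 4)).astype(float)
        f1 = tmm_factors(_counts(x))
        f2 = tmm_factors(_counts(x * 7))
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-12)

    def test_zero_library_rejected(self):
        m = _counts([[0, 5], [0, 5]])
        with pytest.raises(ValidationError, match="zero library"):
            tmm_factors(m)


class TestLogCpm:
    def test_closed_form_zero_count(self):
        m = _counts([[0.0], [1_000_000.0]])
        out = log_cpm(m)
        expected = np.log2(0.5 / (1e6 + 1.0) * 1e6)
        assert out.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert out.iloc[0, 0] == pytest.approx(-1.0, abs=1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.poisson(200, size=(50, 3)).astype(float)
        a = log_cpm(_counts(x))
        b = log_cpm(_counts(2 * x))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=0.01)

    def test_strictly_increasing_in_counts(self):
        m = _counts(np.column_stack([np.arange(0, 50, dtype=float)]))
        out = log_cpm(m).to_numpy().ravel()
        assert (np.diff(out) > 0).all()


@pytest.fixture(scope="module")
def nb_fixture():
    rng = np.random.default_rng(21)
    G, n = 600, 6
    means = 2.0 ** rng.uniform(2, 12, size=G)
    lam = rng.gamma(10.0, means[:, None] / 10.0, size=(G, n))
    x = rng.poisson(lam).astype(float)
    m = _counts(x)
    design = pd.DataFrame(
        {"a": [1, 1, 1, 0, 0, 0], "b": [0, 0, 0, 1, 1, 1]},
        index=m.sample_ids,
    )
    return m, design


class TestPrecisionWeights:
    def test_weights_increase_with_count(self, nb_fixture):
        m, design = nb_fixture
        norm = precision_weights(m, design)
        rho = spearmanr(
            m.values.to_numpy().ravel(), norm.weights.to_numpy().ravel()
        ).statistic
        assert rho > 0.7

    def test_identical_genes_identical_weights(self, nb_fixture):
        m, design = nb_fixture
        vals = m.values.copy()
        vals.iloc[1] = vals.iloc[0]
        twin = ExpressionMatrix(values=vals, platform="rnaseq")
        norm = precision_weights(twin, design)
        np.testing.assert_allclose(
            norm.weights.iloc[0].to_numpy(), norm.weights.iloc[1].to_numpy()
        )

    def test_weights_finite_positive(self, nb_fixture):
        m, design = nb_fixture
        w = precision_weights(m, design).weights.to_numpy()
        assert np.isfinite(w).all() and (w > 0).all()

    def test_underdetermined_design_rejected(self):
        m = _counts([[1, 2], [3, 4]])
        design = pd.DataFrame(np.eye(2), index=m.sample_ids, columns=["a", "b"])
        with pytest.raises(ValidationError):
            precision_weights(m, design)


class TestMDS:
    def test_identical_samples_zero_distance(self):
        y = pd.DataFrame(
            np.column_stack([np.arange(10.0)] * 3 + [np.arange(10.0) + 5]),
            columns=["a", "b", "c", "d"],
        )
        d = leading_logfc_distances(y, top=5)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "d"] > 0
        np.testing.assert_allclose(d.to_numpy(), d.to_numpy().T)
        assert (np.diag(d.to_numpy()) == 0).all()

    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(4)
        y = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        top = 7
        d = leading_logfc_distances(y, top=top)
        for i, si in enumerate(y.columns):
            for j, sj in enumerate(y.columns):
                diffs = sorted(np.abs(y[si] - y[sj]), reverse=True)[:top]
                expected = np.sqrt(np.mean(np.square(diffs)))
                assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_dimension_one_separates_fraction_types(self):
        # fraction effect much larger than condition effect
        rng = np.random.default_rng(8)
        G = 400
        base = rng.normal(8, 2, size=G)
        shift = np.where(rng.random(G) < 0.5, 3.0, -3.0)
        cols = {}
        for r in range(3):
            cols[f"total_{r}"] = base + rng.normal(0, 0.2, G)
            cols[f"poly_{r}"] = base + shift + rng.normal(0, 0.2, G)
        y = pd.DataFrame(cols)
        coords = mds_coordinates(y, top=100)
        totals = coords.loc[[c for c in y if c.startswith("total")], "dim1"]
        polys = coords.loc[[c for c in y if c.startswith("poly")], "dim1"]
        assert totals.max() < polys.min() or polys.max() < totals.min()

    def test_top_validation(self):
        y = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValidationError):
            mds_coordinates(y, top=0)
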