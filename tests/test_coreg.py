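import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coregbuf.core import ConfigError, DataError, ExpressionMatrix
from coregbuf.coreg import (
    bh_adjust,
    build_map,
    call_coregulation,
    distance_curve,
    pair_pcc,
    pairwise_pcc,
)


def _mat(values, layer="mrna"):
    vals = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(len(values))],
        columns=[f"s{j}" for j in range(len(values[0]))],
    )
    return ExpressionMatrix(vals, layer)


def pcc_oracle(x, y):
    """From-definition PCC over complete pairs, explicit sums."""
    pairs = [(a, b) for a, b in zip(x, y) if np.isfinite(a) and np.isfinite(b)]
    n = len(pairs)
    sx = sum(a for a, _ in pairs)
    sy = sum(b for _, b in pairs)
    sxx = sum(a * a for a, _ in pairs)
    syy = sum(b * b for _, b in pairs)
    sxy = sum(a * b for a, b in pairs)
    num = n * sxy - sx * sy
    den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den, n


class TestPairPcc:
    def test_self_correlation_is_one(self):
        m = _mat([np.arange(40.0)])
        r, n, p = pair_pcc(m, "g0", "g0", min_overlap=2)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-30)

    def test_anticorrelation(self):
        m = _mat([[1, 2, 3], [3, 2, 1]])
        r, n, p = pair_pcc(m, "g0", "g1", min_overlap=2)
        assert r == pytest.approx(-1.0)
        assert n == 3

    def test_matches_definition_oracle_with_missing(self, rng):
        for _ in range(50):
            x = rng.normal(size=60)
            y = 0.4 * x + rng.normal(size=60)
            x[rng.random(60) < 0.1] = np.nan
            y[rng.random(60) < 0.1] = np.nan
            m = _mat([x, y])
            r, n, _ = pair_pcc(m, "g0", "g1", min_overlap=5)
            r_exp, n_exp = pcc_oracle(x, y)
            assert n == n_exp
            assert r == pytest.approx(r_exp, rel=1e-12)

    def test_below_min_overlap_flagged(self):
        x = [1.0, 2.0, np.nan, np.nan]
        y = [1.0, 2.0, 3.0, 4.0]
        r, n, p = pair_pcc(_mat([x, y]), "g0", "g1", min_overlap=3)
        assert np.isnan(r) and n == 2

    def test_zero_variance_flagged(self):
        r, n, p = pair_pcc(_mat([[1, 1, 1], [1, 2, 3]]), "g0", "g1", min_overlap=2)
        assert np.isnan(r)

    def test_absent_gene_errors(self):
        with pytest.raises(DataError):
            pair_pcc(_mat([[1, 2]]), "g0", "missing")

    def test_vectorized_agrees_with_scalar(self, rng):
        vals = rng.normal(size=(20, 30))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        m = _mat(vals)
        ia = rng.integers(0, 20, 40)
        ib = rng.integers(0, 20, 40)
        r, n, p = pairwise_pcc(m.values.to_numpy(), ia, ib, min_overlap=5)
        for k in range(40):
            rs, ns, ps = pair_pcc(m, f"g{ia[k]}", f"g{ib[k]}", min_overlap=5)
            if np.isnan(rs):
                assert np.isnan(r[k])
            else:
                assert r[k] == pytest.approx(rs, rel=1e-12)
                assert p[k] == pytest.approx(ps, rel=1e-9)


class TestBHAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == 0.42

    def test_out_of_range_errors(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_dominates_input_and_capped(self, ps):
        out = bh_adjust(ps)
        assert np.all(out >= np.asarray(ps) - 1e-15)
        assert np.all(out <= 1.0 + 1e-15)


class TestCallCoregulation:
    def _pairs(self, n):
        return pd.DataFrame(
            {"gene_a": [f"g{2*i}" for i in range(n)],
             "gene_b": [f"g{2*i+1}" for i in range(n)]}
        )

    def test_thresholds(self, rng):
        # one strongly correlated pair among many null pairs
        n_samples = 60
        base = rng.normal(size=n_samples)
        rows = [base + rng.normal(0, 0.3, n_samples),
                base + rng.normal(0, 0.3, n_samples)]
        for _ in range(38):
            rows.append(rng.normal(size=n_samples))
        m = _mat(rows)
        res = call_coregulation(m, self._pairs(20), min_overlap=10)
        assert bool(res.loc[0, "co_regulated"])
        assert res.loc[0, "adj_p"] >= res.loc[0, "p_value"]
        assert not res.loc[1:, "co_regulated"].any()

    def test_anticorrelated_not_coregulated(self, rng):
        base = rng.normal(size=60)
        m = _mat([base, -base + rng.normal(0, 0.1, 60)])
        res = call_coregulation(m, self._pairs(1), min_overlap=10)
        assert not res.loc[0, "co_regulated"]
        assert res.loc[0, "anti_regulated"]

    def test_empty_pairs_error(self, rng):
        m = _mat(rng.normal(size=(4, 10)))
        with pytest.raises(ConfigError):
            call_coregulation(m, pd.DataFrame(columns=["gene_a", "gene_b"]))


class TestDistanceCurve:
    def test_flat_input_flat_curve(self):
        df = pd.DataFrame({"tss_distance": np.linspace(0, 1e6, 50), "pcc": 0.3})
        curve = distance_curve(df)
        assert np.allclose(curve["mean_pcc"], 0.3)

    def test_planted_step_decreases_and_crosses_midpoint(self, rng):
        d = rng.uniform(0, 2e6, 400)
        pcc = np.where(d < 1e6, 0.8, 0.0)
        curve = distance_curve(pd.DataFrame({"tss_distance": d, "pcc": pcc}),
                               smoother_span=0.2)
        y = curve["mean_pcc"].to_numpy()
        assert y[0] > 0.6 and y[-1] < 0.2
        # curve crosses 0.4 near the step
        cross = curve["tss_distance"][np.argmin(np.abs(y - 0.4))]
        assert 0.7e6 < cross < 1.3e6

    def test_bounded_by_data(self, rng):
        d = rng.uniform(0, 1e6, 200)
        pcc = rng.uniform(-1, 1, 200)
        curve = distance_curve(pd.DataFrame({"tss_distance": d, "pcc": pcc}))
        assert curve["mean_pcc"].between(pcc.min(), pcc.max()).all()

    def test_too_few_points_errors(self):
        df = pd.DataFrame({"tss_distance": [1, 2, 3], "pcc": [0.1, 0.2, 0.3]})
        with pytest.raises(DataError):
            distance_curve(df)


class TestBuildMap:
    def test_perfectly_correlated_pair(self):
        m = _mat([np.arange(10.0), np.arange(10.0) * 2 + 1])
        cmap = build_map(m, ["g0", "g1"])
        assert cmap.matrix.loc["g0", "g1"] == pytest.approx(1.0)
        assert cmap.matrix.loc["g0", "g0"] == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        m = _mat(rng.normal(size=(8, 20)))
        genes = [f"g{i}" for i in range(8)]
        base = build_map(m, genes).matrix
        perm = list(rng.permutation(genes))
        permuted = build_map(m, perm).matrix
        pd.testing.assert_frame_equal(permuted.loc[genes, genes], base)

    def test_block_design_matches_pairwise_loop(self, rng):
        shared = rng.normal(size=30)
        rows = [shared + rng.normal(0, 0.2, 30) for _ in range(10)] + [
            rng.normal(size=30) for _ in range(10)
        ]
        m = _mat(rows)
        genes = list(m.genes)
        cmap = build_map(m, genes)
        for i in range(0, 20, 5):
            for j in range(0, 20, 7):
                r, _, _ = pair_pcc(m, genes[i], genes[j], min_overlap=2)
                got = cmap.matrix.iloc[i, j]
                if np.isnan(r):
                    assert i == j or np.isnan(got)
                else:
                    assert got == pytest.approx(r, rel=1e-10)

    def test_symmetry(self, rng):
        m = _mat(rng.normal(size=(6, 15)))
        M = build_map(m, list(m.genes)).matrix.to_numpy()
        assert np.allclose(M, M.T, equal_nan=True)

    def test_rectangular_map(self, rng):
        m = _mat(rng.normal(size=(7, 12)))
        cmap = build_map(m, ["g0", "g1", "g2"], ["g3", "g4", "g5", "g6"])
        assert cmap.matrix.shape == (3, 4)
        assert not cmap.is_square


class TestPermutationP:
    def test_agrees_with_t_based_p_in_order_of_magnitude(self, rng):
        x = rng.normal(size=25)
        y = 0.8 * x + rng.normal(0, 0.6, 25)
        m = _mat([x, y])
        from coregbuf.coreg import pair_pcc_permutation_p

        r_t, n, p_t = pair_pcc(m, "g0", "g1", min_overlap=5)
        r_p, _, p_perm = pair_pcc_permutation_p(m, "g0", "g1", 4000, seed=1,
                                                min_overlap=5)
        assert r_p == pytest.approx(r_t)
        # both should call this clearly significant
        assert p_t < 0.01 and p_perm < 0.01

    def test_null_p_not_significant(self, rng):
        m = _mat([rng.normal(size=20), rng.normal(size=20)])
        from coregbuf.coreg import pair_pcc_permutation_p

        _, _, p = pair_pcc_permutation_p(m, "g0", "g1", 2000, seed=2, min_overlap=5)
        assert p > 0.01
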