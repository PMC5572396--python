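import numpy as np
import pandas as pd
import pytest

from coregbuf.core import DataError, IntervalTrack
from coregbuf.hic import (
    assign_subcompartment,
    contact_map_from_triplets,
    gene_contact_matrix,
    map_correlation,
    pair_contact,
    read_contact_map,
    subcompartment_enrichment,
    write_contact_map,
)


def _gene(chrom, tss):
    return pd.Series({"chromosome": chrom, "tss": tss, "strand": "+"})


def _toy_map(rng, n_bins=30, bin_size=10_000, density=0.4, chrom="chr1"):
    iu = np.triu_indices(n_bins)
    keep = rng.random(len(iu[0])) < density
    trip = pd.DataFrame(
        {
            "bin_i": iu[0][keep],
            "bin_j": iu[1][keep],
            "count": rng.gamma(2.0, 1.0, keep.sum()),
        }
    )
    return contact_map_from_triplets(
        trip, bin_size=bin_size, chrom_a=chrom, chrom_b=chrom,
        chrom_a_length=n_bins * bin_size,
    )


class TestPairContact:
    def test_9x9_block_median_matches_enumeration(self, rng):
        cmap = _toy_map(rng)
        a, b = _gene("chr1", 123_456), _gene("chr1", 201_000)
        got, covered = pair_contact(cmap, a, b, window_bp=40_000)
        # enumerate the 81 pixels by hand from the dense matrix
        dense = np.asarray(cmap.matrix.todense())
        r0, r1 = (123_456 - 40_000) // 10_000, (123_456 + 40_000) // 10_000
        c0, c1 = (201_000 - 40_000) // 10_000, (201_000 + 40_000) // 10_000
        block = dense[r0 : r1 + 1, c0 : c1 + 1]
        assert block.size == 81
        assert got == pytest.approx(np.median(block), rel=1e-12)
        assert covered

    def test_constant_matrix_returns_constant(self):
        n = 10
        iu = np.triu_indices(n)
        trip = pd.DataFrame({"bin_i": iu[0], "bin_j": iu[1], "count": 3.5})
        cmap = contact_map_from_triplets(trip, 10_000, "chr1", "chr1", n * 10_000)
        got, _ = pair_contact(cmap, _gene("chr1", 50_000), _gene("chr1", 50_000))
        assert got == 3.5

    def test_absent_block_zero_with_flag(self):
        trip = pd.DataFrame({"bin_i": [0], "bin_j": [0], "count": [1.0]})
        cmap = contact_map_from_triplets(trip, 10_000, "chr1", "chr1", 1_000_000)
        got, covered = pair_contact(cmap, _gene("chr1", 500_000), _gene("chr1", 800_000))
        assert got == 0.0 and not covered

    def test_symmetric_in_gene_order(self, rng):
        cmap = _toy_map(rng)
        a, b = _gene("chr1", 60_000), _gene("chr1", 240_000)
        assert pair_contact(cmap, a, b) == pair_contact(cmap, b, a)

    def test_tss_outside_bounds_errors(self, rng):
        cmap = _toy_map(rng)
        with pytest.raises(DataError):
            pair_contact(cmap, _gene("chr1", 10**9), _gene("chr1", 1000))

    def test_nan_pixels_excluded_from_median(self):
        trip = pd.DataFrame(
            {"bin_i": [5, 5, 6], "bin_j": [5, 6, 6], "count": [np.nan, 2.0, np.nan]}
        )
        cmap = contact_map_from_triplets(trip, 10_000, "chr1", "chr1", 200_000)
        got, covered = pair_contact(cmap, _gene("chr1", 55_000), _gene("chr1", 55_000), 5_000)
        # block = bins 5..6 x 5..6: values {nan, 2, 2, nan} plus implicit 0s none
        assert covered
        assert got == pytest.approx(2.0)

    def test_gene_contact_matrix_matches_pair_contact(self, rng):
        cmap = _toy_map(rng)
        genes = pd.DataFrame(
            {"chromosome": "chr1", "tss": rng.integers(45_000, 250_000, 8),
             "strand": "+"},
            index=[f"g{i}" for i in range(8)],
        )
        M = gene_contact_matrix(cmap, genes, genes, 40_000)
        for gi in genes.index[:4]:
            for gj in genes.index[4:]:
                expected, _ = pair_contact(cmap, genes.loc[gi], genes.loc[gj], 40_000)
                assert M.loc[gi, gj] == pytest.approx(expected, rel=1e-12)


class TestContactMapIO:
    def test_roundtrip(self, rng, tmp_path):
        cmap = _toy_map(rng)
        path = tmp_path / "map.tsv"
        write_contact_map(cmap, path)
        back = read_contact_map(path)
        assert back.bin_size == cmap.bin_size
        assert np.allclose(back.matrix.toarray(), cmap.matrix.toarray(), equal_nan=True)

    def test_symmetry_implied_from_upper_triangle(self, rng):
        cmap = _toy_map(rng)
        dense = cmap.matrix.toarray()
        assert np.allclose(dense, dense.T, equal_nan=True)

    def test_negative_counts_rejected(self):
        trip = pd.DataFrame({"bin_i": [0], "bin_j": [1], "count": [-1.0]})
        with pytest.raises(DataError):
            contact_map_from_triplets(trip, 10_000, "chr1", "chr1", 100_000)


class TestMapCorrelation:
    def test_self_correlation_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 10)))
        m = (m + m.T) / 2
        r, p = map_correlation(m, m)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 10)))
        m = (m + m.T) / 2
        r, _ = map_correlation(m, 3.0 * m + 7.0)
        assert r == pytest.approx(1.0)

    def test_matches_upper_triangle_oracle(self, rng):
        a = pd.DataFrame(rng.normal(size=(30, 30)))
        b = pd.DataFrame(rng.normal(size=(30, 30)))
        r, p = map_correlation(a, b)
        iu = np.triu_indices(30, k=1)
        from scipy import stats

        r_exp, p_exp = stats.pearsonr(a.to_numpy()[iu], b.to_numpy()[iu])
        assert len(iu[0]) == 435
        assert r == pytest.approx(r_exp, rel=1e-12)
        assert p == pytest.approx(p_exp, rel=1e-9)

    def test_common_permutation_invariance(self, rng):
        genes = [f"g{i}" for i in range(12)]
        a = pd.DataFrame(rng.normal(size=(12, 12)), index=genes, columns=genes)
        b = pd.DataFrame(rng.normal(size=(12, 12)), index=genes, columns=genes)
        a, b = (a + a.T) / 2, (b + b.T) / 2
        r1, _ = map_correlation(a, b)
        perm = list(rng.permutation(genes))
        r2, _ = map_correlation(a.loc[perm, perm], b.loc[perm, perm])
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_ordering_mismatch_errors(self, rng):
        genes = [f"g{i}" for i in range(5)]
        a = pd.DataFrame(np.eye(5), index=genes, columns=genes)
        b = a.iloc[::-1]
        with pytest.raises(DataError):
            map_correlation(a, b)


class TestSubcompartments:
    def _track(self):
        return IntervalTrack(
            pd.DataFrame(
                {
                    "chromosome": ["chr1", "chr1", "chr1"],
                    "start": [0, 100, 300],
                    "end": [100, 200, 400],
                    "label": ["A1", "B2", "A2"],
                }
            )
        )

    def test_tss_inside_interval(self):
        ann = pd.DataFrame({"chromosome": ["chr1"], "tss": [50]}, index=["g"])
        assert assign_subcompartment(ann, self._track())["g"] == "A1"

    def test_boundary_belongs_downstream(self):
        ann = pd.DataFrame(
            {"chromosome": ["chr1", "chr1"], "tss": [100, 200]}, index=["g1", "g2"]
        )
        lab = assign_subcompartment(ann, self._track())
        assert lab["g1"] == "B2"       # half-open: 100 starts the next interval
        assert lab["g2"] == "unassigned"  # gap

    def test_matches_bruteforce_scan(self, rng):
        starts = np.sort(rng.choice(np.arange(0, 10_000, 10), 30, replace=False))
        ends = starts + rng.integers(5, 10, 30)
        labels = rng.choice(["A1", "A2", "B1"], 30)
        track = IntervalTrack(
            pd.DataFrame(
                {"chromosome": "chr1", "start": starts, "end": ends, "label": labels}
            )
        )
        tss = rng.integers(0, 10_000, 100)
        ann = pd.DataFrame(
            {"chromosome": "chr1", "tss": tss}, index=[f"g{i}" for i in range(100)]
        )
        got = assign_subcompartment(ann, track)
        for g, t in zip(ann.index, tss):
            expected = "unassigned"
            for s, e, l in zip(starts, ends, labels):
                if s <= t < e:
                    expected = l
            assert got[g] == expected

    def test_enrichment_counting(self):
        labels = pd.Series(
            ["A1"] * 6 + ["B1"] * 4, index=[f"g{i}" for i in range(10)]
        )
        tab = subcompartment_enrichment({"c1": [f"g{i}" for i in range(4)]}, labels)
        row = tab[(tab["cluster"] == "c1") & (tab["label"] == "A1")].iloc[0]
        assert row["observed_pct"] == 100.0
        assert row["expected_pct"] == 60.0
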