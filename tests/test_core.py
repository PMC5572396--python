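import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coregbuf.core import (
    DataError,
    ExpressionMatrix,
    center_samples,
    filter_by_detection,
    load_expression,
    match_layers,
    read_annotation_bed,
    read_annotation_gff3,
    write_annotation_bed,
    write_expression,
)


def _write_tsv(tmp_path, text, name="expr.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadExpression:
    def test_reference_subtraction(self, tmp_path):
        p = _write_tsv(tmp_path, "gene_id\tref\ts1\ng\t1.0\t3.0\n")
        m = load_expression(p, "mrna", reference_column="ref")
        assert m.values.loc["g", "s1"] == pytest.approx(2.0)
        assert "ref" not in m.samples

    def test_missing_token_sets_flag(self, tmp_path):
        p = _write_tsv(tmp_path, "gene_id\ts1\ts2\ng\tNA\t1.5\n")
        m = load_expression(p, "mrna")
        assert m.missing_mask().loc["g", "s1"]
        assert not m.missing_mask().loc["g", "s2"]

    def test_reference_subtraction_matches_row_arithmetic(self, tmp_path, rng):
        # independent spreadsheet-style oracle on a random 3x3 table
        vals = rng.normal(size=(3, 3)).round(4)
        lines = ["gene_id\tref\ts1\ts2"] + [
            f"g{i}\t" + "\t".join(map(str, vals[i])) for i in range(3)
        ]
        p = _write_tsv(tmp_path, "\n".join(lines) + "\n")
        m = load_expression(p, "mrna", reference_column="ref")
        expected = {
            (f"g{i}", s): vals[i, j + 1] - vals[i, 0]
            for i in range(3)
            for j, s in enumerate(["s1", "s2"])
        }
        for (g, s), v in expected.items():
            assert m.values.loc[g, s] == pytest.approx(v, abs=1e-12)

    def test_duplicate_gene_ids_error(self, tmp_path):
        p = _write_tsv(tmp_path, "gene_id\ts1\ts2\ng\t1\t2\ng\t3\t4\n")
        with pytest.raises(DataError, match="duplicate"):
            load_expression(p, "mrna")

    def test_non_numeric_cell_reported_with_position(self, tmp_path):
        p = _write_tsv(tmp_path, "gene_id\ts1\ts2\ng\toops\t2\n")
        with pytest.raises(DataError, match="non-numeric"):
            load_expression(p, "mrna")

    def test_linear_input_log2(self, tmp_path):
        p = _write_tsv(tmp_path, "gene_id\ts1\ts2\ng\t4.0\t8.0\n")
        m = load_expression(p, "mrna", linear=True)
        assert m.values.loc["g"].tolist() == [2.0, 3.0]

    def test_roundtrip_preserves_values_and_mask(self, tmp_path, rng):
        vals = pd.DataFrame(
            rng.normal(size=(10, 6)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(6)],
        )
        vals.iloc[rng.random(vals.shape) < 0.2] = np.nan
        mask = rng.random(vals.shape) < 0.2
        vals = vals.mask(mask)
        m = ExpressionMatrix(vals, "protein")
        path = tmp_path / "out.tsv"
        write_expression(m, path)
        back = load_expression(path, "protein")
        pd.testing.assert_frame_equal(back.values, m.values, check_names=False)
        pd.testing.assert_frame_equal(back.missing_mask(), m.missing_mask(),
                                      check_names=False)


class TestDetectionFilter:
    @pytest.mark.parametrize(
        "n_detected,strict,kept",
        [(29, False, False), (30, False, True), (30, True, False), (31, True, True)],
    )
    def test_threshold_conventions(self, n_detected, strict, kept):
        row = [0.0] * n_detected + [np.nan] * (60 - n_detected)
        vals = pd.DataFrame([row, [1.0] * 60], index=["g_test", "g_full"],
                            columns=[f"s{j}" for j in range(60)])
        out = filter_by_detection(ExpressionMatrix(vals, "mrna"), 30, strict=strict)
        assert ("g_test" in out.genes) == kept

    def test_identity_when_all_detected(self, rng):
        vals = pd.DataFrame(rng.normal(size=(5, 40)),
                            index=[f"g{i}" for i in range(5)],
                            columns=[f"s{j}" for j in range(40)])
        out = filter_by_detection(ExpressionMatrix(vals, "mrna"), 30)
        assert list(out.genes) == list(vals.index)

    def test_empty_result_errors(self):
        vals = pd.DataFrame([[1.0, np.nan]], index=["g"], columns=["a", "b"])
        with pytest.raises(DataError, match="threshold"):
            filter_by_detection(ExpressionMatrix(vals, "mrna"), 2)


class TestMatchLayers:
    def _mat(self, genes, samples, layer):
        vals = pd.DataFrame(0.0, index=genes, columns=samples)
        return ExpressionMatrix(vals, layer)

    def test_ambiguous_mapping_dropped(self):
        m = self._mat(["g1", "g2"], ["a", "b"], "mrna")
        p = self._mat(["p1", "p2", "p3"], ["a", "b"], "protein")
        id_map = pd.DataFrame(
            {"mrna_id": ["g1", "g1", "g2"], "protein_id": ["p1", "p2", "p3"]}
        )
        mo, po = match_layers(m, p, id_map)
        assert list(mo.genes) == ["g2"]
        assert list(po.genes) == ["g2"]

    def test_identical_id_spaces_intersect(self):
        m = self._mat(["g1", "g2", "g3"], ["a", "b"], "mrna")
        p = self._mat(["g2", "g3", "g4"], ["b", "c"], "protein")
        mo, po = match_layers(m, p)
        assert list(mo.genes) == ["g2", "g3"] == list(po.genes)
        assert list(mo.samples) == ["b"] == list(po.samples)

    def test_random_map_matches_set_logic_oracle(self, rng):
        genes_m = [f"m{i}" for i in range(30)]
        genes_p = [f"p{i}" for i in range(30)]
        m = self._mat(genes_m, ["a", "b"], "mrna")
        p = self._mat(genes_p, ["a", "b"], "protein")
        id_map = pd.DataFrame(
            {
                "mrna_id": rng.choice(genes_m + ["mX"], 18),
                "protein_id": rng.choice(genes_p + ["pX"], 18),
            }
        ).drop_duplicates()
        mo, _ = match_layers(m, p, id_map)
        # brute-force oracle: unique 1:1 links present in both matrices
        links = [tuple(r) for r in id_map.to_numpy()]
        expected = set()
        for a, b in links:
            if (
                sum(1 for x, _ in links if x == a) == 1
                and sum(1 for _, y in links if y == b) == 1
                and a in genes_m
                and b in genes_p
            ):
                expected.add(a)
        assert set(mo.genes) == expected

    def test_zero_overlap_errors(self):
        m = self._mat(["g1"], ["a"], "mrna")
        p = self._mat(["h1"], ["a"], "protein")
        with pytest.raises(DataError, match="overlap"):
            match_layers(m, p)

    def test_filter_then_match_commutes_with_match_then_filter(self, rng):
        genes = [f"g{i}" for i in range(20)]
        vm = pd.DataFrame(rng.normal(size=(20, 10)), index=genes,
                          columns=[f"s{j}" for j in range(10)])
        vp = vm.copy()
        vm[vm.abs() > 1.2] = np.nan
        vp[vp.abs() > 0.9] = np.nan
        m = ExpressionMatrix(vm, "mrna")
        p = ExpressionMatrix(vp, "protein")
        a1, b1 = match_layers(filter_by_detection(m, 5), filter_by_detection(p, 5))
        a2, b2 = match_layers(m, p)
        a2, b2 = filter_by_detection(a2, 5), filter_by_detection(b2, 5)
        shared = sorted(set(a2.genes) & set(b2.genes))
        assert sorted(set(a1.genes)) == shared


class TestCenterSamples:
    def test_simple_and_missing_columns(self):
        vals = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [1.0, np.nan, 5.0]},
            index=["g1", "g2", "g3"],
        )
        out = center_samples(ExpressionMatrix(vals, "mrna"))
        assert out.values["s1"].tolist() == [-1.0, 0.0, 1.0]
        assert out.values.loc["g1", "s2"] == -2.0
        assert np.isnan(out.values.loc["g2", "s2"])

    def test_random_matrix_medians_vanish(self, rng):
        vals = pd.DataFrame(rng.normal(2, 3, size=(50, 10)))
        vals.index = [f"g{i}" for i in range(50)]
        out = center_samples(ExpressionMatrix(vals, "mrna"))
        assert np.abs(out.values.median(axis=0)).max() < 1e-12

    def test_idempotent(self, rng):
        vals = pd.DataFrame(rng.normal(size=(30, 8)), index=[f"g{i}" for i in range(30)])
        vals = vals.mask(rng.random(vals.shape) < 0.1)
        once = center_samples(ExpressionMatrix(vals, "mrna"))
        twice = center_samples(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_missing_column_names_sample(self):
        vals = pd.DataFrame({"ok": [1.0, 2.0], "bad": [np.nan, np.nan]},
                            index=["g1", "g2"])
        with pytest.raises(DataError, match="bad"):
            center_samples(ExpressionMatrix(vals, "mrna"))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-20, 20), min_size=2, max_size=30))
def test_center_samples_median_property(values):
    vals = pd.DataFrame({"s": values}, index=[f"g{i}" for i in range(len(values))])
    out = center_samples(ExpressionMatrix(vals, "mrna"))
    assert abs(out.values["s"].median()) < 1e-9


class TestAnnotationIO:
    def test_bed_roundtrip_and_tss_convention(self, tmp_path, toy_annotation):
        path = tmp_path / "genes.bed"
        write_annotation_bed(toy_annotation, path)
        back = read_annotation_bed(path)
        # + strand TSS = body_start; − strand TSS = body_end
        assert back.loc["gB", "tss"] == 10_800
        assert back.loc["gA", "tss"] == 10_000
        pd.testing.assert_frame_equal(
            back[["chromosome", "tss", "strand"]],
            toy_annotation[["chromosome", "tss", "strand"]],
        )

    def test_gff3_coordinates_converted(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=gene:gX\n"
            "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=tX\n"
            "chr1\tsrc\tgene\t501\t900\t.\t-\t.\tID=gY\n"
        )
        p = tmp_path / "genes.gff3"
        p.write_text(gff)
        ann = read_annotation_gff3(p)
        assert ann.loc["gX", "body_start"] == 100 and ann.loc["gX", "body_end"] == 200
        assert ann.loc["gX", "tss"] == 100
        assert ann.loc["gY", "tss"] == 900


class TestGeneBodySignal:
    def test_mean_over_body_with_partial_overlap(self, toy_annotation):
        from coregbuf.core import gene_body_signal

        bedgraph = pd.DataFrame(
            {
                "chromosome": ["chr1", "chr1"],
                "start": [9_000, 9_600],
                "end": [9_600, 10_400],
                "value": [2.0, 4.0],
            }
        )
        sig = gene_body_signal(toy_annotation, bedgraph, "H3K4me3")
        # gA body 9,200..10,000: 400 bp at 2.0 + 400 bp at 4.0 over 800 bp
        assert sig["gA"] == pytest.approx((400 * 2.0 + 400 * 4.0) / 800)
        assert sig["gE"] == 0.0  # other chromosome, no signal
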