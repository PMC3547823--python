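import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pathologit as pl
from pathologit import tables_io


ROW = "1\t{pos}\tA\tG\t{sift}\t0.5\t0.5\t0.5\t0.5"


class TestReadScoreTable:
    def test_parses_rows_and_preserves_missing(self, toy_table):
        path = toy_table(
            [
                ROW.format(pos=1, sift="0.1"),
                ROW.format(pos=2, sift="."),
                ROW.format(pos=3, sift="0.9"),
            ]
        )
        frame = pl.read_score_table(path)
        assert len(frame) == 3
        assert frame["SIFT"].isna().sum() == 1
        assert frame["SIFT"].iloc[0] == pytest.approx(0.1)

    def test_missing_column_is_named_in_error(self, toy_table):
        path = toy_table(["1\t1\tA\tG\t0.1"], header="chrom\tpos\tref\talt\tSIFT")
        with pytest.raises(pl.FormatError, match="PolyPhen2"):
            pl.read_score_table(path)

    def test_empty_labeled_table_rejected(self, toy_table):
        path = toy_table([], header="chrom\tpos\tref\talt\tSIFT\tPolyPhen2\tLRT\tMutationTaster\tPhyloP\tlabel")
        with pytest.raises(pl.ValidationError):
            pl.read_score_table(path, has_labels=True)
        # unlabeled empty table is fine
        path2 = toy_table([], name="empty.tsv")
        assert len(pl.read_score_table(path2)) == 0

    def test_score_out_of_range_reports_line(self, toy_table):
        path = toy_table([ROW.format(pos=1, sift="0.2"), ROW.format(pos=2, sift="1.7")])
        with pytest.raises(pl.ValidationError, match="line 3"):
            pl.read_score_table(path)

    def test_exovar_like_composition(self):
        dataset = pl.generate_benchmark(
            pl.GeneratorConfig(n_positive=5340, n_negative=4752, seed=1)
        )
        assert len(dataset) == 10092
        assert dataset.p_disease_sample == pytest.approx(5340 / 10092)

    def test_label_round_trip_through_tsv(self, tmp_path, signal_benchmark):
        path = tmp_path / "bench.tsv"
        frame = signal_benchmark.frame.copy()
        frame["label"] = np.where(frame["label"] == 1, "positive", "negative")
        pl.write_predictions(frame, path)
        back = pl.read_score_table(path, has_labels=True)
        assert back.p_disease_sample == pytest.approx(signal_benchmark.p_disease_sample)
        assert np.array_equal(back.labels, signal_benchmark.labels)


class TestStandardize:
    def test_sift_orientation_flip(self):
        assert pl.standardize_score(0.0, "SIFT") == 1.0
        assert pl.standardize_score(1.0, "SIFT") == 0.0

    def test_phylop_endpoints_and_midpoint(self):
        scale = tables_io.DEFAULT_SCALES["PhyloP"]
        assert pl.standardize_score(scale.native_max, "PhyloP") == 1.0
        mid = (scale.native_min + scale.native_max) / 2
        assert pl.standardize_score(mid, "PhyloP") == pytest.approx(0.5)

    def test_unknown_tool_rejected(self):
        with pytest.raises(tables_io.ConfigurationError):
            pl.standardize_score(0.5, "CADD")

    def test_table_fit_rescales_phylop_minmax(self):
        frame = pd.DataFrame({"PhyloP": [-3.0, 0.0, 5.0, np.nan]})
        out, scales = pl.standardize_table(frame)
        assert out["PhyloP"].min() == 0.0 and out["PhyloP"].max() == 1.0
        assert np.isnan(out["PhyloP"].iloc[3])
        assert scales["PhyloP"].native_min == -3.0

    @given(
        raw=st.tuples(
            st.floats(-10, 10, allow_nan=False), st.floats(-10, 10, allow_nan=False)
        ),
        tool=st.sampled_from(pl.TOOLS),
    )
    def test_standardization_monotone_after_orientation(self, raw, tool):
        lo, hi = min(raw), max(raw)
        a, b = pl.standardize_score(lo, tool), pl.standardize_score(hi, tool)
        if tables_io.DEFAULT_SCALES[tool].flip:
            assert a >= b
        else:
            assert a <= b


def _records(n=4, false_at=()):
    frame = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n + 1),
            "ref": "A",
            "alt": "G",
            "derived_is_alt": [i not in false_at for i in range(n)],
        }
    )
    return frame


class TestFilters:
    def test_derived_orientation_counts(self):
        kept, report = pl.filter_derived_orientation(_records(4, false_at=(2,)))
        assert len(kept) == 3
        assert report.n_removed == 1 and report.n_in == 4

    def test_derived_orientation_identity_and_degenerate(self):
        kept, _ = pl.filter_derived_orientation(_records(3))
        assert len(kept) == 3
        with pytest.warns(UserWarning, match="removed every record"):
            kept, report = pl.filter_derived_orientation(_records(3, false_at=(0, 1, 2)))
        assert len(kept) == 0 and report.n_kept + report.n_removed == report.n_in

    def test_maf_filter_counting_and_absent_kept(self):
        frame = _records(10)
        maf = np.array([0.05] * 7 + [np.nan] * 3)
        kept, report = pl.maf_filter(frame, maf)
        assert len(kept) == 3 and report.n_removed == 7

    def test_maf_boundary_is_strict(self):
        frame = _records(2)
        kept, _ = pl.maf_filter(frame, np.array([0.01, 0.0100001]))
        assert len(kept) == 1  # exactly 1% is kept, strictly above is removed

    def test_maf_threshold_validated(self):
        with pytest.raises(pl.ValidationError):
            pl.maf_filter(_records(1), np.array([0.1]), threshold=1.5)

    def test_filters_commute(self):
        frame = _records(8, false_at=(1, 5))
        maf = np.array([0.2, 0.0, np.nan, 0.2, 0.0, np.nan, 0.0, 0.2])
        a, _ = pl.maf_filter(*[x for x in [frame]], maf)
        a, _ = pl.filter_derived_orientation(a)
        b, _ = pl.filter_derived_orientation(frame)
        keep_mask = frame["derived_is_alt"].to_numpy()
        b, _ = pl.maf_filter(b, maf[keep_mask])
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True)[["pos"]], b.reset_index(drop=True)[["pos"]]
        )

    def test_summary_reports_funnel(self):
        kept, r1 = pl.filter_derived_orientation(_records(6, false_at=(0,)))
        kept, r2 = pl.maf_filter(kept, np.array([0.5, 0.0, 0.0, 0.0, 0.0]))
        summary = pl.filter_summary([r1, r2])
        assert summary["n_in"] == 6 and summary["n_out"] == 4
        assert [s["n_kept"] for s in summary["stages"]] == [5, 4]


VCF_TEMPLATE = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
{body}"""


def _vcf(tmp_path, rows):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_TEMPLATE.format(body="\n".join(rows) + "\n"))
    return path


class TestVcfQualityFilter:
    def test_boundaries_excluded(self, tmp_path):
        rows = [
            "1\t100\t.\tA\tG\t99\t.\t.\tGT:DP:GQ\t0/1:4:60",   # DP at boundary: out
            "1\t200\t.\tA\tG\t99\t.\t.\tGT:DP:GQ\t0/1:30:60",  # passes
            "1\t300\t.\tA\tG\t50\t.\t.\tGT:DP:GQ\t0/1:30:60",  # QUAL at boundary: out
            "1\t400\t.\tA\tG\t99\t.\t.\tGT:DP:GQ\t0/1:30:20",  # GQ at boundary: out
            "1\t500\t.\tA\tG\t99\t.\t.\tGT:DP:GQ\t0/1:5:21",   # just inside: passes
        ]
        kept, report = pl.vcf_quality_filter(_vcf(tmp_path, rows))
        assert list(kept["pos"]) == [200, 500]
        assert report.n_in == 5 and report.n_kept == 2

    def test_missing_fields_excluded_with_warning(self, tmp_path):
        rows = [
            "1\t100\t.\tA\tG\t99\t.\t.\tGT\t0/1",
            "1\t200\t.\tA\tG\t99\t.\t.\tGT:DP:GQ\t0/1:30:60",
        ]
        with pytest.warns(UserWarning, match="lacked DP/GQ/QUAL"):
            kept, report = pl.vcf_quality_filter(_vcf(tmp_path, rows))
        assert list(kept["pos"]) == [200]
        assert report.detail["n_missing_fields"] == 1

    def test_non_snv_records_skipped(self, tmp_path):
        rows = [
            "1\t100\t.\tAT\tG\t99\t.\t.\tGT:DP:GQ\t0/1:30:60",
            "1\t200\t.\tA\tG,T\t99\t.\t.\tGT:DP:GQ\t0/1:30:60",
            "1\t300\t.\tA\tG\t99\t.\t.\tGT:DP:GQ\t0/1:30:60",
        ]
        kept, report = pl.vcf_quality_filter(_vcf(tmp_path, rows))
        assert report.detail["n_non_snv_skipped"] == 2 and len(kept) == 1


class TestWritePredictions:
    def test_round_trip_keys_and_scores(self, tmp_path, signal_benchmark):
        frame = signal_benchmark.frame.head(50).drop(columns="label")
        frame["posterior"] = np.linspace(0.001234567890123, 0.99, 50)
        path = tmp_path / "pred.tsv"
        pl.write_predictions(frame, path)
        back = pl.read_score_table(path)
        for col in ("chrom", "pos", "ref", "alt"):
            assert (back[col].astype(str) == frame[col].astype(str)).all()
        for col in pl.TOOLS:
            np.testing.assert_allclose(back[col], frame[col], rtol=1e-11)
        np.testing.assert_allclose(back["posterior"], frame["posterior"], rtol=1e-11)

    def test_empty_input_writes_header_only(self, tmp_path):
        frame = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", *pl.TOOLS])
        path = tmp_path / "empty.tsv"
        pl.write_predictions(frame, path)
        assert len(path.read_text().strip().splitlines()) == 1
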