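import numpy as np
import pandas as pd
import pytest

from warmclip import geochip_preprocess as gp
from warmclip import synthetic_data as sd


def make_records(rows):
    """Build a probe-record frame from (slide, sample, subgrid, probe, gene,
    signal, background, background_sd, flag) tuples."""
    frame = pd.DataFrame(
        rows,
        columns=["slide_id", "sample_id", "subgrid", "probe_id", "gene_id",
                 "signal", "background", "background_sd", "flag"],
    )
    frame.insert(5, "category", "cat")
    return frame[list(gp.PROBE_COLUMNS)]


class TestQcFilter:
    def test_flagged_spots_removed(self):
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 100.0, 10.0, 1.0, 1),
            ("s1", "a", 1, "p2", "g1", 100.0, 10.0, 1.0, 3),
            ("s1", "a", 1, "p3", "g1", 100.0, 10.0, 1.0, 0),
            ("s1", "a", 1, "p4", "g1", 100.0, 10.0, 1.0, 2),
        ])
        out = gp.qc_filter_probes(records)
        assert sorted(out["probe_id"]) == ["p3", "p4"]

    def test_snr_boundary(self):
        # SNR = (signal - background) / background_sd; 1.99 removed, 2.00 kept
        records = make_records([
            ("s1", "a", 1, "lo", "g1", 11.99, 10.0, 1.0, 0),
            ("s1", "a", 1, "hi", "g1", 12.00, 10.0, 1.0, 0),
        ])
        out = gp.qc_filter_probes(records)
        assert list(out["probe_id"]) == ["hi"]

    def test_ratio_mode(self):
        records = make_records([
            ("s1", "a", 1, "lo", "g1", 19.0, 10.0, 100.0, 0),
            ("s1", "a", 1, "hi", "g1", 20.0, 10.0, 100.0, 0),
        ])
        out = gp.qc_filter_probes(records, snr_mode="ratio")
        assert list(out["probe_id"]) == ["hi"]

    def test_all_clean_is_identity(self):
        records = make_records(
            [("s1", "a", 1, f"p{i}", "g1", 100.0, 10.0, 1.0, 0) for i in range(5)]
        )
        pd.testing.assert_frame_equal(gp.qc_filter_probes(records), records)

    def test_nonpositive_background_sd_names_probe(self):
        records = make_records([
            ("s1", "a", 1, "bad_probe", "g1", 100.0, 10.0, 0.0, 0),
        ])
        with pytest.raises(ValueError, match="bad_probe"):
            gp.qc_filter_probes(records)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="no probe records"):
            gp.qc_filter_probes(make_records([]))

    def test_idempotent(self, messy_fixture):
        _, records = messy_fixture
        once = gp.qc_filter_probes(records)
        twice = gp.qc_filter_probes(once)
        pd.testing.assert_frame_equal(once, twice)


class TestNormalize:
    def test_single_slide_single_subgrid_stage1_identity(self):
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 100.0, 10.0, 1.0, 0),
            ("s1", "a", 1, "p2", "g1", 300.0, 10.0, 1.0, 0),
        ])
        out = gp.normalize(records)
        # one sample: stage 3 is also the identity
        np.testing.assert_allclose(sorted(out["signal"]), [100.0, 300.0])

    def test_subgrid_means_equalized_within_slide(self):
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 100.0, 10.0, 1.0, 0),
            ("s1", "a", 1, "p2", "g1", 200.0, 10.0, 1.0, 0),
            ("s1", "a", 2, "p3", "g1", 300.0, 10.0, 1.0, 0),
            ("s1", "a", 2, "p4", "g1", 500.0, 10.0, 1.0, 0),
        ])
        out = gp.normalize(records)
        by_grid = out.merge(
            records[["probe_id", "subgrid"]], on="probe_id", suffixes=("", "_r")
        ).groupby("subgrid")["signal"].mean()
        assert by_grid[1] == pytest.approx(by_grid[2])

    def test_technical_replicates_averaged(self):
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 4.0, 1.0, 1.0, 0),
            ("s2", "a", 1, "p1", "g1", 6.0, 1.0, 1.0, 0),
        ])
        out = gp.normalize(records)
        assert len(out) == 1
        assert out["signal"].iloc[0] == pytest.approx(5.0)

    def test_sample_totals_equal_after_stage3(self, messy_fixture):
        _, records = messy_fixture
        out = gp.normalize(gp.qc_filter_probes(records))
        totals = out.groupby("sample_id")["signal"].sum()
        np.testing.assert_allclose(totals, totals.mean())

    def test_relative_order_within_subgrid_preserved(self, clean_fixture):
        _, records = clean_fixture
        out = gp.normalize(records)
        merged = records.merge(
            out, on=["sample_id", "probe_id"], suffixes=("_raw", "_norm")
        )
        for _, grp in merged.groupby(["sample_id", "subgrid_raw"]):
            raw_order = grp.sort_values("signal_raw")["probe_id"].tolist()
            norm_order = grp.sort_values("signal_norm")["probe_id"].tolist()
            assert raw_order == norm_order

    def test_all_zero_subgrid_left_unscaled_with_warning(self, caplog):
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 0.0, 1.0, 1.0, 0),
            ("s1", "a", 2, "p2", "g1", 100.0, 1.0, 1.0, 0),
        ])
        with caplog.at_level("WARNING", logger="warmclip.geochip_preprocess"):
            out = gp.normalize(records)
        assert "all-zero" in caplog.text
        assert (out.loc[out["probe_id"] == "p1", "signal"] == 0).all()


class TestDetectionFilters:
    def test_gene_with_one_probe_removed(self):
        # 1 of 10 designed probes: fails both the 33.3% and the >= 2 rule
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 50.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p1", "g1", 60.0, 1.0, 1.0, 0),
        ])
        out = gp.filter_genes_and_probes(records, {"g1": 10})
        assert out.empty

    def test_gene_with_two_of_three_probes_retained(self):
        rows = []
        for sample in ("a", "b"):
            for probe in ("p1", "p2"):
                rows.append(("s1", sample, 1, probe, "g1", 50.0, 1.0, 1.0, 0))
        out = gp.filter_genes_and_probes(make_records(rows), {"g1": 3})
        assert set(out["probe_id"]) == {"p1", "p2"}

    def test_one_third_passes_the_fraction_rule(self):
        rows = [
            ("s1", s, 1, "p1", "g1", 50.0, 1.0, 1.0, 0) for s in ("a", "b")
        ] + [
            ("s1", s, 1, "p2", "g1", 50.0, 1.0, 1.0, 0) for s in ("a", "b")
        ]
        out = gp.filter_genes_and_probes(make_records(rows), {"g1": 6})
        assert not out.empty  # 2/6 = 1/3 >= 33.3%

    def test_probe_in_single_sample_removed(self):
        rows = [
            ("s1", "a", 1, "p1", "g1", 50.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p1", "g1", 50.0, 1.0, 1.0, 0),
            ("s1", "a", 1, "p2", "g1", 50.0, 1.0, 1.0, 0),  # only sample a
            ("s1", "a", 1, "p3", "g1", 50.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p3", "g1", 50.0, 1.0, 1.0, 0),
        ]
        out = gp.filter_genes_and_probes(make_records(rows), {"g1": 3})
        assert set(out["probe_id"]) == {"p1", "p3"}

    def test_unknown_gene_rejected(self):
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 50.0, 1.0, 1.0, 0),
        ])
        with pytest.raises(ValueError, match="designed_probe_counts"):
            gp.filter_genes_and_probes(records, {"g2": 3})

    def test_matches_brute_force_enumeration(self, messy_fixture):
        spec, records = messy_fixture
        counts = sd.designed_counts_for(spec)
        norm = gp.normalize(gp.qc_filter_probes(records))
        out = gp.filter_genes_and_probes(norm, counts)

        # independent rule-by-rule enumeration
        keep_probe = {
            p: norm.loc[norm["probe_id"] == p, "sample_id"].nunique() >= 2
            for p in norm["probe_id"].unique()
        }
        survivors = norm[norm["probe_id"].map(keep_probe)]
        expected_genes = set()
        for gene in survivors["gene_id"].unique():
            n_det = survivors.loc[survivors["gene_id"] == gene, "probe_id"].nunique()
            if n_det >= 2 and n_det / counts[gene] >= 0.333 - 1e-9:
                expected_genes.add(gene)
        assert set(out["gene_id"].unique()) == expected_genes
        expected_probes = set(
            survivors.loc[survivors["gene_id"].isin(expected_genes), "probe_id"]
        )
        assert set(out["probe_id"].unique()) == expected_probes

    def test_idempotent(self, messy_fixture):
        spec, records = messy_fixture
        counts = sd.designed_counts_for(spec)
        norm = gp.normalize(gp.qc_filter_probes(records))
        once = gp.filter_genes_and_probes(norm, counts)
        twice = gp.filter_genes_and_probes(once, counts)
        pd.testing.assert_frame_equal(once, twice)


class TestRescaleLogTransform:
    def test_hand_arithmetic_example(self):
        # sample a sums to 100, sample b to 300; probe p1 is half of a's
        # signal -> rescaled 0.5 * 200 = 100 -> stored ln(101)
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 50.0, 1.0, 1.0, 0),
            ("s1", "a", 1, "p2", "g2", 50.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p1", "g1", 150.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p2", "g2", 150.0, 1.0, 1.0, 0),
        ])
        matrix = gp.rescale_log_transform(records)
        assert matrix.probe_values.loc["p1", "a"] == pytest.approx(np.log(101.0))

    def test_undetected_probe_stored_as_zero(self):
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 50.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p1", "g1", 60.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p2", "g2", 30.0, 1.0, 1.0, 0),
        ])
        matrix = gp.rescale_log_transform(records)
        assert matrix.probe_values.loc["p2", "a"] == 0.0

    def test_linear_sample_sums_equal_mean_of_sums(self, clean_fixture):
        _, records = clean_fixture
        matrix = gp.rescale_log_transform(gp.normalize(records))
        sums = matrix.probe_values_linear.sum(axis=0)
        np.testing.assert_allclose(sums, sums.mean())

    def test_zero_total_sample_rejected(self):
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 0.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p1", "g1", 60.0, 1.0, 1.0, 0),
        ])
        with pytest.raises(ValueError, match="zero total"):
            gp.rescale_log_transform(records)

    def test_gene_value_is_mean_over_probes(self):
        records = make_records([
            ("s1", "a", 1, "p1", "g1", 30.0, 1.0, 1.0, 0),
            ("s1", "a", 1, "p2", "g1", 70.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p1", "g1", 30.0, 1.0, 1.0, 0),
            ("s1", "b", 1, "p2", "g1", 70.0, 1.0, 1.0, 0),
        ])
        matrix = gp.rescale_log_transform(records)
        expected = matrix.probe_values.loc[["p1", "p2"], "a"].mean()
        assert matrix.values.loc["g1", "a"] == pytest.approx(expected)


class TestPipeline:
    def test_trivial_fixture_reduces_to_log_of_rescaled_signal(self, design6):
        # no flags, one subgrid, one replicate -> normalization only
        # equalizes sample totals, then ln(rescaled + 1)
        spec = sd.ArrayFixtureSpec(
            n_genes=6, probes_per_gene=3, n_subgrids=1, seed=3,
            flag_rate=0.0, low_snr_rate=0.0,
        )
        records = sd.generate_geochip_fixture(spec, design6)
        matrix = gp.preprocess_pipeline(records, sd.designed_counts_for(spec))
        raw = records.pivot_table(
            index="probe_id", columns="sample_id", values="signal"
        )
        sums = raw.sum(axis=0)
        expected = np.log1p(raw / sums * sums.mean())
        np.testing.assert_allclose(
            matrix.probe_values.to_numpy(), expected.to_numpy(), rtol=1e-12
        )

    def test_bit_reproducible(self, messy_fixture):
        spec, records = messy_fixture
        counts = sd.designed_counts_for(spec)
        m1 = gp.preprocess_pipeline(records, counts)
        m2 = gp.preprocess_pipeline(records.copy(), counts)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(m1.probe_values, m2.probe_values)


class TestProbeTableIO:
    def test_round_trip(self, tmp_path, clean_fixture):
        _, records = clean_fixture
        path = tmp_path / "probes.tsv"
        gp.write_probe_table(records, path)
        loaded = gp.load_probe_table(path)
        pd.testing.assert_frame_equal(loaded, records.reset_index(drop=True))

    def test_empty_body(self, tmp_path):
        path = tmp_path / "probes.tsv"
        path.write_text("\t".join(gp.PROBE_COLUMNS) + "\n")
        assert gp.load_probe_table(path).empty

    def test_three_rows(self, tmp_path):
        header = "\t".join(gp.PROBE_COLUMNS)
        row = "s1\ta\t1\tp{i}\tg1\tcat\t10.0\t1.0\t0.5\t0"
        path = tmp_path / "probes.tsv"
        path.write_text(
            header + "\n" + "\n".join(row.format(i=i) for i in range(3)) + "\n"
        )
        assert len(gp.load_probe_table(path)) == 3

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "probes.tsv"
        path.write_text("slide_id\tsample_id\n" "s1\ta\n")
        with pytest.raises(ValueError, match="missing column"):
            gp.load_probe_table(path)

    def test_non_numeric_signal_reports_line(self, tmp_path):
        header = "\t".join(gp.PROBE_COLUMNS)
        good = "s1\ta\t1\tp1\tg1\tcat\t10.0\t1.0\t0.5\t0"
        bad = "s1\ta\t1\tp2\tg1\tcat\toops\t1.0\t0.5\t0"
        path = tmp_path / "probes.tsv"
        path.write_text(header + "\n" + good + "\n" + bad + "\n")
        with pytest.raises(ValueError, match="line 3"):
            gp.load_probe_table(path)

    def test_matrix_tsv_round_trip(self, tmp_path, clean_fixture):
        spec, records = clean_fixture
        matrix = gp.preprocess_pipeline(records, sd.designed_counts_for(spec))
        path = tmp_path / "matrix.tsv"
        matrix.to_tsv(path)
        loaded = gp.GeneSignalMatrix.read_values_tsv(path)
        np.testing.assert_allclose(loaded.to_numpy(), matrix.values.to_numpy())
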