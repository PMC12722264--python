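"""ROH detection, classification, summaries, coverage, and islands."""

import numpy as np
import pandas as pd
import pytest

from bovpop.genotype_io import GenotypeDataset
from bovpop.roh import (
    ROHParams,
    call_roh,
    chromosome_coverage,
    classify_roh,
    roh_islands,
    roh_summary,
    window_homozygosity_calls,
)
from bovpop.simdata import SimConfig, simulate_dataset
from tests.conftest import make_dataset


def _uniform_map_dataset(calls, spacing=20_000):
    calls = np.asarray(calls, dtype=np.uint8)
    pos = [(j + 1) * spacing for j in range(calls.shape[1])]
    return make_dataset(calls, positions=pos)


class TestWindowEligibility:
    def test_all_homozygous_chromosome_fully_eligible(self):
        ds = _uniform_map_dataset(np.zeros((1, 120), dtype=np.uint8))
        frac = window_homozygosity_calls(ds.calls[0], ds.markers)
        np.testing.assert_allclose(frac, 1.0)

    def test_all_heterozygous_chromosome_ineligible(self):
        ds = _uniform_map_dataset(np.ones((1, 120), dtype=np.uint8))
        frac = window_homozygosity_calls(ds.calls[0], ds.markers)
        np.testing.assert_allclose(frac, 0.0)

    def test_single_het_in_long_homozygous_stretch_stays_eligible(self):
        calls = np.zeros((1, 200), dtype=np.uint8)
        calls[0, 100] = 1
        ds = _uniform_map_dataset(calls)
        frac = window_homozygosity_calls(ds.calls[0], ds.markers)
        assert (frac >= 0.05).all()  # one het allowed per window

    def test_short_chromosome_uses_truncated_window(self):
        ds = _uniform_map_dataset(np.zeros((1, 20), dtype=np.uint8))
        frac = window_homozygosity_calls(ds.calls[0], ds.markers)
        np.testing.assert_allclose(frac, 1.0)


class TestCallROH:
    def test_long_homozygous_run_called_with_exact_bounds(self):
        calls = np.ones((1, 300), dtype=np.uint8)
        calls[0, 100:200] = 0  # 100 hom markers spanning ~2 Mb at 20 kb
        ds = _uniform_map_dataset(calls)
        seg = call_roh(ds)
        assert len(seg) == 1
        row = seg.iloc[0]
        # the window threshold trims exactly one marker at each end of the
        # block when the background is purely heterozygous
        assert row.start_bp == 102 * 20_000 and row.end_bp == 199 * 20_000
        assert row.n_snps == 98

    def test_stretch_below_min_length_not_reported(self):
        # 40 hom markers at 10 kb spacing = 390 kb < 500 kb
        calls = np.ones((1, 300), dtype=np.uint8)
        calls[0, 100:140] = 0
        ds = make_dataset(calls, positions=[(j + 1) * 10_000 for j in range(300)])
        seg = call_roh(ds)
        assert len(seg) == 0

    def test_all_heterozygous_dataset_yields_nothing(self):
        ds = _uniform_map_dataset(np.ones((3, 400), dtype=np.uint8))
        assert len(call_roh(ds)) == 0

    def test_gap_splits_runs(self):
        calls = np.zeros((1, 120), dtype=np.uint8)
        pos = [(j + 1) * 20_000 for j in range(60)]
        pos += [2_500_000 + (j + 1) * 20_000 for j in range(60)]  # 1.3 Mb gap
        ds = make_dataset(calls, positions=pos)
        seg = call_roh(ds)
        assert len(seg) == 2
        assert seg["end_bp"].iloc[0] <= 1_200_000 < seg["start_bp"].iloc[1]

    def test_reported_segments_satisfy_final_filters(self):
        cfg = SimConfig(
            seed=77, n_populations=1, n_per_population=20, n_markers=4000,
            chromosome_lengths_bp=(50_000_000,) * 2,
            roh_plan=((0.2, 4_000_000), (0.1, 2_000_000)),
        )
        ds, _ = simulate_dataset(cfg)
        params = ROHParams()
        seg = call_roh(ds, params)
        assert len(seg) > 0
        assert (seg["n_snps"] >= params.min_snps).all()
        assert (seg["length_kb"] >= params.min_length_kb).all()
        assert (seg["length_kb"] / seg["n_snps"] <= params.max_density_kb_per_snp).all()

    def test_planted_long_segments_recovered(self):
        cfg = SimConfig(
            seed=31, n_populations=1, n_per_population=30, n_markers=5000,
            chromosome_lengths_bp=(50_000_000,) * 3,
            roh_plan=((1 / 30, 5_000_000), (1 / 30, 8_000_000)),
        )
        ds, truth = simulate_dataset(cfg)
        seg = call_roh(ds)
        for sid, c, s, e in truth.planted_roh:
            hit = seg[
                (seg.sample_id == sid) & (seg.chromosome == c)
                & (seg.end_bp >= s) & (seg.start_bp <= e)
            ]
            assert len(hit) >= 1, (sid, c, s, e)


class TestClassification:
    @pytest.mark.parametrize(
        "kb,label",
        [
            (1_900, "<2 Mb"),
            (2_000, "<2 Mb"),
            (3_000, "2-4 Mb"),
            (16_000, "8-16 Mb"),
            (16_100, ">16 Mb"),
        ],
    )
    def test_bounds(self, kb, label):
        seg = pd.DataFrame({"length_kb": [kb]})
        assert classify_roh(seg)["length_class"].iloc[0] == label


class TestSummaryAndCoverage:
    def test_empty_segment_table(self):
        samples = pd.DataFrame({"sample_id": ["a", "b"], "population": "P"})
        seg = pd.DataFrame(columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_kb"])
        summ = roh_summary(seg, samples)
        row = summ.iloc[0]
        assert row["min_per_individual"] == row["max_per_individual"] == 0
        assert row["total"] == 0

    def test_counts_include_zero_individuals(self):
        samples = pd.DataFrame({"sample_id": ["a", "b"], "population": "P"})
        seg = pd.DataFrame(
            {
                "sample_id": ["a", "a"],
                "chromosome": "1",
                "start_bp": [1, 100],
                "end_bp": [50, 200],
                "n_snps": 30,
                "length_kb": 600.0,
            }
        )
        row = roh_summary(seg, samples).iloc[0]
        assert row["mean_per_individual"] == 1.0
        assert row["min_per_individual"] == 0 and row["max_per_individual"] == 2

    def test_coverage_single_segment_mean_over_individuals(self):
        markers = pd.DataFrame(
            {"marker_id": ["m1", "m2"], "chromosome": "1", "position_bp": [1, 10_000_000]}
        )
        seg = pd.DataFrame(
            {"sample_id": ["s1"], "chromosome": "1", "start_bp": [1_000_000], "end_bp": [1_999_999]}
        )
        cov = chromosome_coverage(seg, markers, n_individuals=10)
        assert cov["percent_covered"].iloc[0] == pytest.approx(1.0)

    def test_overlapping_segments_union_not_sum(self):
        markers = pd.DataFrame(
            {"marker_id": ["m1", "m2"], "chromosome": "1", "position_bp": [1, 10_000_000]}
        )
        seg = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "chromosome": "1",
                "start_bp": [1_000_000, 1_500_000],
                "end_bp": [2_000_000, 2_500_000],
            }
        )
        cov = chromosome_coverage(seg, markers, n_individuals=1)
        assert cov["percent_covered"].iloc[0] == pytest.approx(15.0, rel=1e-3)


class TestIslands:
    def _planted(self, fraction, seed=5):
        cfg = SimConfig(
            seed=seed, n_populations=1, n_per_population=30, n_markers=3000,
            chromosome_lengths_bp=(50_000_000,) * 2,
            roh_plan=((fraction, 5_000_000),),
        )
        ds, truth = simulate_dataset(cfg)
        return ds, truth

    def test_majority_interval_becomes_island(self):
        ds, truth = self._planted(0.6)
        seg = call_roh(ds)
        islands = roh_islands(seg, ds, 0.5)
        assert len(islands) >= 1
        c, s, e = truth.planted_roh[0][1], truth.planted_roh[0][2], truth.planted_roh[0][3]
        hit = islands[(islands.chromosome == c) & (islands.end_bp >= s) & (islands.start_bp <= e)]
        assert len(hit) == 1
        assert hit["peak_frequency"].iloc[0] >= 0.5

    def test_minority_interval_is_not_island(self):
        ds, truth = self._planted(0.3)
        seg = call_roh(ds)
        islands = roh_islands(seg, ds, 0.5)
        c, s, e = truth.planted_roh[0][1], truth.planted_roh[0][2], truth.planted_roh[0][3]
        hit = islands[(islands.chromosome == c) & (islands.end_bp >= s) & (islands.start_bp <= e)]
        assert len(hit) == 0

    def test_zero_threshold_covers_every_marker_run(self):
        ds, _ = self._planted(0.6)
        seg = call_roh(ds)
        islands = roh_islands(seg, ds, 0.0)
        # threshold 0: every marker qualifies, one island per chromosome
        assert len(islands) == len(ds.markers["chromosome"].unique())

    def test_island_calls_idempotent_under_recomputation(self):
        ds, _ = self._planted(0.6)
        seg = call_roh(ds)
        i1 = roh_islands(seg, ds, 0.5)
        i2 = roh_islands(seg, ds, 0.5)
        pd.testing.assert_frame_equal(i1, i2)
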