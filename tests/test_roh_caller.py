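"""Sliding-window ROH detection against exhaustive-interval brute force."""

import math

import numpy as np
import pandas as pd
import pytest

from rohscan import roh
from rohscan.panel import HET, HOM_A, HOM_B, MISSING
from conftest import make_panel, random_panel
from _oracles import bruteforce_roh


class TestLenczMinSnps:
    def test_hand_arithmetic_example(self):
        # ln(0.05 / 1e5) / ln(0.7) = ln(5e-7)/ln(0.7) = 40.67... -> 41
        assert roh.lencz_min_snps(0.05, 1000, 100, 0.3) == 41

    def test_high_heterozygosity_limit_is_one(self):
        assert roh.lencz_min_snps(0.05, 1000, 100, 1 - 1e-12) == 1

    def test_study_scale_panel(self):
        # at the published panel size the count is moderate for any
        # realistic array heterozygosity
        l = roh.lencz_min_snps(0.05, 50_933, 380, 0.35)
        assert 30 < l < 60

    @pytest.mark.parametrize("het", [0.0, 1.0, -0.2])
    def test_domain_errors(self, het):
        with pytest.raises(roh.RohError):
            roh.lencz_min_snps(0.05, 100, 10, het)


class TestMeanHeterozygosity:
    def test_all_het(self):
        assert roh.mean_heterozygosity(make_panel(np.full((3, 4), HET))) == 1.0

    def test_missing_excluded_from_denominator(self):
        panel = make_panel([[HOM_A, HET], [MISSING, HOM_B]])
        assert roh.mean_heterozygosity(panel) == pytest.approx(1 / 3)

    def test_matches_cell_tally_on_random_panels(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            panel = random_panel(rng, 5, 50)
            n_het = sum(
                1
                for i in range(5)
                for j in range(50)
                if panel.calls[i, j] == HET
            )
            n_obs = sum(
                1
                for i in range(5)
                for j in range(50)
                if panel.calls[i, j] != MISSING
            )
            assert roh.mean_heterozygosity(panel) == pytest.approx(n_het / n_obs)

    def test_all_missing_rejected(self):
        with pytest.raises(roh.RohError):
            roh.mean_heterozygosity(make_panel(np.full((2, 2), MISSING)))


def _params(**kw):
    defaults = dict(
        window_snps=5,
        max_het_per_window=1,
        max_missing_per_window=1,
        max_gap_bp=200_000,
        min_density_bp_per_snp=100_000,
        min_length_bp=100_000,
        window_hit_threshold=0.05,
    )
    defaults.update(kw)
    return roh.RohParams(**defaults)


class TestDetectRoh:
    def test_fully_homozygous_chromosome_single_segment(self):
        n = 60
        positions = [1 + j * 50_000 for j in range(n)]  # ~3 Mb span
        panel = make_panel(np.full((1, n), HOM_A), positions=positions)
        params = _params(max_gap_bp=1_000_000, min_length_bp=1_000_000, window_snps=50)
        segments = roh.detect_roh(panel, params, min_snps=10)
        assert len(segments) == 1
        seg = segments.iloc[0]
        assert seg.start_bp == positions[0] and seg.end_bp == positions[-1]
        assert seg.n_snps == n and seg.length_bp == positions[-1] - positions[0] + 1

    def test_oversized_gap_splits_run(self):
        positions = [1 + j * 50_000 for j in range(30)]
        positions += [positions[-1] + 1_200_000 + j * 50_000 for j in range(30)]
        panel = make_panel(np.full((1, 60), HOM_B), positions=positions)
        params = _params(max_gap_bp=1_000_000, min_length_bp=1_000_000, window_snps=10)
        segments = roh.detect_roh(panel, params, min_snps=5)
        assert len(segments) == 2
        assert segments.iloc[0].end_bp == positions[29]
        assert segments.iloc[1].start_bp == positions[30]

    def test_ends_trimmed_to_homozygous_calls(self):
        n = 40
        calls = np.full((1, n), HOM_A, dtype=np.int8)
        calls[0, 0] = HET
        calls[0, -1] = MISSING
        positions = [1 + j * 40_000 for j in range(n)]
        panel = make_panel(calls, positions=positions)
        segments = roh.detect_roh(panel, _params(window_snps=10, min_length_bp=500_000), min_snps=5)
        assert len(segments) == 1
        assert segments.iloc[0].start_bp == positions[1]
        assert segments.iloc[0].end_bp == positions[-2]

    def test_short_chromosome_yields_nothing(self):
        # fewer SNPs than the window: no window exists, no SNP is in-run
        panel = make_panel(np.full((1, 4), HOM_A), spacing=50_000)
        assert len(roh.detect_roh(panel, _params(window_snps=5), min_snps=2)) == 0

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_interval_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_ind = int(rng.integers(1, 6))
        n_snps = int(rng.integers(30, 201))
        n_chrom = int(rng.integers(1, 3))
        panel = random_panel(rng, n_ind, n_snps, n_chrom=n_chrom,
                             hom_bias=float(rng.uniform(0.6, 0.9)))
        params = _params(
            window_snps=int(rng.integers(3, 9)),
            max_het_per_window=int(rng.integers(0, 2)),
            max_missing_per_window=int(rng.integers(0, 2)),
            max_gap_bp=int(rng.integers(40_000, 120_000)),
            min_length_bp=int(rng.integers(30_000, 150_000)),
            min_density_bp_per_snp=int(rng.integers(20_000, 60_000)),
        )
        min_snps = int(rng.integers(2, 8))
        got = roh.detect_roh(panel, params, min_snps=min_snps)
        got_set = {
            (r.individual_id, r.chromosome, r.start_bp, r.end_bp, r.n_snps, r.length_bp)
            for r in got.itertuples()
        }
        expected = set()
        for chrom, sl in panel.chromosome_slices().items():
            pos = panel.positions[sl]
            for i, iid in enumerate(panel.individual_ids):
                for s in bruteforce_roh(
                    panel.calls[i, sl],
                    pos,
                    params.window_snps,
                    params.max_het_per_window,
                    params.max_missing_per_window,
                    params.window_hit_threshold,
                    params.max_gap_bp,
                    params.min_length_bp,
                    min_snps,
                    params.min_density_bp_per_snp,
                ):
                    expected.add((iid, chrom, *s))
        assert got_set == expected

    @pytest.mark.parametrize("stricter", ["min_length_bp", "min_snps"])
    def test_tightening_thresholds_shrinks_output(self, stricter):
        rng = np.random.default_rng(99)
        panel = random_panel(rng, 4, 150, hom_bias=0.85)
        base = _params(window_snps=5)
        loose = roh.detect_roh(panel, base, min_snps=3)
        if stricter == "min_length_bp":
            tight = roh.detect_roh(panel, _params(window_snps=5, min_length_bp=300_000), min_snps=3)
        else:
            tight = roh.detect_roh(panel, base, min_snps=8)
        loose_set = {tuple(r) for r in loose.itertuples(index=False)}
        tight_set = {tuple(r) for r in tight.itertuples(index=False)}
        assert tight_set <= loose_set

    def test_determinism(self):
        rng = np.random.default_rng(3)
        panel = random_panel(rng, 3, 120, hom_bias=0.8)
        a = roh.detect_roh(panel, _params(), min_snps=4)
        b = roh.detect_roh(panel, _params(), min_snps=4)
        pd.testing.assert_frame_equal(a, b)

    def test_emitted_segments_pass_validator(self):
        rng = np.random.default_rng(17)
        panel = random_panel(rng, 5, 180, hom_bias=0.85)
        params = _params(window_snps=6)
        segments = roh.detect_roh(panel, params, min_snps=4)
        assert len(segments) > 0  # the validator must actually see segments
        roh.validate_segments(segments, params, min_snps=4, panel=panel)


class TestClassifyRoh:
    def _segments(self, lengths_mb):
        return pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(len(lengths_mb))],
                "chromosome": "1",
                "start_bp": 1,
                "end_bp": [int(l * 1e6) for l in lengths_mb],
                "n_snps": 50,
                "length_bp": [int(l * 1e6) for l in lengths_mb],
            }
        )

    def test_one_segment_per_class(self):
        table = roh.classify_roh(self._segments([3, 7, 12, 25]))
        assert table["n_segments"].tolist() == [1, 1, 1, 1, 4]
        assert table["pct_of_number"].tolist()[:4] == [25.0] * 4

    def test_boundary_five_mb_goes_to_upper_class(self):
        table = roh.classify_roh(self._segments([5.0]))
        assert table.set_index("class").loc["5-10 Mb", "n_segments"] == 1

    def test_empty_input_zero_table(self):
        table = roh.classify_roh(self._segments([]))
        assert table["n_segments"].sum() == 0
        assert table["total_length_mb"].sum() == 0.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        table = roh.classify_roh(self._segments(rng.uniform(1, 40, size=50)))
        body = table[table["class"] != "All"]
        assert body["pct_of_number"].sum() == pytest.approx(100.0)
        assert body["pct_of_length"].sum() == pytest.approx(100.0)
        assert body["n_segments"].sum() == table["n_segments"].iloc[-1]


class TestChromosomeSummary:
    def _seg(self, iid, chrom, length_mb):
        L = int(length_mb * 1e6)
        return {
            "individual_id": iid,
            "chromosome": chrom,
            "start_bp": 1,
            "end_bp": L,
            "n_snps": 10,
            "length_bp": L,
        }

    def test_single_individual_coverage(self):
        segments = pd.DataFrame([self._seg("a", "1", 10)])
        table = roh.chromosome_summary(segments, {"1": 100_000_000}, n_individuals=1)
        assert table["coverage_pct"].iloc[0] == pytest.approx(10.0)

    def test_population_average_coverage(self):
        segments = pd.DataFrame([self._seg("a", "1", 10), self._seg("b", "1", 30)])
        table = roh.chromosome_summary(segments, {"1": 100_000_000}, n_individuals=2)
        assert table["coverage_pct"].iloc[0] == pytest.approx(20.0)

    def test_cohort_total_variant(self):
        segments = pd.DataFrame([self._seg("a", "1", 10), self._seg("b", "1", 30)])
        table = roh.chromosome_summary(
            segments, {"1": 100_000_000}, n_individuals=2, per_individual=False
        )
        assert table["coverage_pct"].iloc[0] == pytest.approx(40.0)

    def test_empty_chromosome_row(self):
        segments = pd.DataFrame([self._seg("a", "1", 10)])
        table = roh.chromosome_summary(
            segments, {"1": 100_000_000, "2": 50_000_000}, n_individuals=1
        )
        row = table.set_index("chromosome").loc["2"]
        assert row["n_segments"] == 0 and row["coverage_pct"] == 0.0

    def test_unknown_chromosome_raises(self):
        segments = pd.DataFrame([self._seg("a", "7", 10)])
        with pytest.raises(KeyError, match="7"):
            roh.chromosome_summary(segments, {"1": 100_000_000}, n_individuals=1)
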