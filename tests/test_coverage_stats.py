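"""Coverage curves, gene quantile summaries, flags, and variability."""

import numpy as np
import pytest

from panelcov.annotations import build_db
from panelcov.coverage_stats import (
    capture_fraction,
    count_flags,
    coverage_curve,
    gene_summaries,
    intersample_variability,
)
from panelcov.depth import DepthTrack, SampleDepthMatrix
from panelcov.intervals import GenomicInterval as GI
from panelcov.intervals import merge_intervals
from oracle_utils import quantile_sorted


def _track(depths, chrom="chr1", start=0):
    n = len(depths)
    return DepthTrack(
        chroms=np.full(n, chrom, dtype=object),
        positions=np.arange(start, start + n, dtype=np.int64),
        mean_depth=np.asarray(depths, dtype=float),
    )


def _region(n, chrom="chr1", start=0):
    return merge_intervals([GI(chrom, start, start + n)])


class TestCoverageCurve:
    def test_constant_track_is_step_function(self):
        curve = coverage_curve(_track([10.0] * 20), _region(20), max_depth=15)
        assert all(curve.at(d) == 1.0 for d in range(1, 11))
        assert all(curve.at(d) == 0.0 for d in range(11, 16))

    def test_counting_oracle(self):
        # 92 of 100 target bases at depth >= 3
        depths = [5.0] * 92 + [2.0] * 8
        curve = coverage_curve(_track(depths), _region(100), max_depth=10)
        assert curve.at(3) == 0.92

    def test_all_zero_track(self):
        curve = coverage_curve(_track([0.0] * 10), _region(10), max_depth=5)
        assert (curve.fraction_covered == 0.0).all()

    def test_missing_target_bases_count_as_zero(self):
        curve = coverage_curve(_track([9.0] * 50), _region(100), max_depth=5)
        assert curve.at(1) == 0.5

    def test_monotone_non_increasing(self, rng):
        for _ in range(10):
            depths = rng.gamma(2.0, 20.0, size=200)
            curve = coverage_curve(_track(depths), _region(200), max_depth=100)
            assert (np.diff(curve.fraction_covered) <= 0).all()
            assert ((curve.fraction_covered >= 0) & (curve.fraction_covered <= 1)).all()

    def test_empty_targets_error(self):
        from panelcov.intervals import IntervalSet

        with pytest.raises(ValueError):
            coverage_curve(_track([1.0]), IntervalSet())


class TestCaptureFraction:
    def test_zero_threshold_is_one(self):
        assert capture_fraction(_track([0.0] * 5), _region(5), 0) == 1.0

    def test_counting(self):
        depths = [4.0] * 55 + [1.0] * 45
        assert capture_fraction(_track(depths), _region(100), 3) == 0.55

    def test_above_max_depth_is_zero(self):
        assert capture_fraction(_track([7.0] * 10), _region(10), 1000) == 0.0

    def test_matches_curve_point(self, rng):
        depths = rng.poisson(30, 300).astype(float)
        track, region = _track(depths), _region(300)
        curve = coverage_curve(track, region, max_depth=60)
        for d in (1, 3, 30, 60):
            assert capture_fraction(track, region, d) == curve.at(d)


class TestGeneSummaries:
    def _db_one_gene(self, n, start=0):
        return build_db([(GI("chr1", start, start + n), "G")], "db")

    def test_five_point_quantiles(self):
        track = _track([10, 20, 30, 40, 50])
        (s,) = gene_summaries(track, self._db_one_gene(5))
        assert (s.q1, s.median, s.q3) == (20, 30, 40)

    def test_constant_35_flags(self):
        (s,) = gene_summaries(_track([35.0] * 8), self._db_one_gene(8))
        assert (s.median_below_optimal, s.iqr_above_optimal) == (False, True)

    def test_constant_29_boundary_strict(self):
        (s,) = gene_summaries(_track([29.0] * 8), self._db_one_gene(8))
        assert (s.median_below_optimal, s.iqr_above_optimal) == (True, False)

    def test_exactly_30_is_not_below(self):
        (s,) = gene_summaries(_track([30.0] * 8), self._db_one_gene(8))
        assert not s.median_below_optimal and s.iqr_above_optimal

    def test_span_rule(self):
        track = _track([0.0] * 2 + [100.0] * 2)
        (s,) = gene_summaries(track, self._db_one_gene(4), iqr_rule="span")
        assert s.iqr_above_optimal  # q3 - q1 = 75 >= 30

    def test_matches_sort_oracle_random_genes(self, rng):
        """Quantiles agree with an explicit order-statistic interpolation."""
        for _ in range(100):
            n = int(rng.integers(1, 60))
            depths = np.round(rng.gamma(2.0, 25.0, n), 3)
            (s,) = gene_summaries(_track(depths), self._db_one_gene(n))
            assert s.q1 == pytest.approx(quantile_sorted(depths, 0.25), abs=1e-12)
            assert s.median == pytest.approx(quantile_sorted(depths, 0.50), abs=1e-12)
            assert s.q3 == pytest.approx(quantile_sorted(depths, 0.75), abs=1e-12)
            assert s.q1 <= s.median <= s.q3

    def test_gene_outside_track_universe_flagged(self):
        db = build_db([(GI("chr1", 0, 5), "IN"), (GI("chr9", 0, 5), "OUT")], "db")
        summaries = gene_summaries(_track([50.0] * 5), db)
        by = {s.gene: s for s in summaries}
        assert by["IN"].in_track and not by["OUT"].in_track
        assert by["OUT"].median == 0.0


class TestCountFlags:
    def test_all_high(self):
        summaries = gene_summaries(_track([100.0] * 10), build_db(
            [(GI("chr1", 0, 5), "A"), (GI("chr1", 5, 10), "B")], "db"))
        assert count_flags(summaries) == (0, 2)

    def test_empty(self):
        assert count_flags([]) == (0, 0)

    def test_well_separated_regimes(self, rng):
        """Flags match construction when depth regimes are far from 30X."""
        n_genes, low = 20, 7
        records, depths = [], []
        for g in range(n_genes):
            start = g * 50
            records.append((GI("chr1", start, start + 50), f"G{g:02d}"))
            mu = 5.0 if g < low else 80.0
            depths.extend(rng.normal(mu, 2.0, 50).clip(min=0))
        summaries = gene_summaries(_track(depths), build_db(records, "db"))
        assert count_flags(summaries) == (low, n_genes - low)


class TestIntersampleVariability:
    def _matrix(self, depths):
        depths = np.asarray(depths)
        n = depths.shape[0]
        return SampleDepthMatrix(
            chroms=np.full(n, "chr1", dtype=object),
            positions=np.arange(n, dtype=np.int64),
            sample_ids=tuple(f"s{j}" for j in range(depths.shape[1])),
            depths=depths.astype(np.int64),
        )

    def test_identical_samples_zero_halfwidth(self):
        m = self._matrix(np.tile(np.arange(10)[:, None], (1, 5)))
        prof = intersample_variability(m)
        assert (prof.half_widths == 0).all()
        assert prof.fraction_within(0.001) == 1.0

    def test_two_sample_closed_form(self):
        prof = intersample_variability(self._matrix([[10, 20]]))
        expected = 1.96 * (10 / np.sqrt(2)) / np.sqrt(2)
        assert prof.half_widths[0] == pytest.approx(expected, abs=1e-12)
        assert prof.half_widths[0] == pytest.approx(9.8, abs=0.005)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            intersample_variability(self._matrix([[5]]))

    def test_fraction_within_monotone_in_k(self, rng):
        m = self._matrix(rng.poisson(40, size=(100, 6)))
        prof = intersample_variability(m)
        fracs = [prof.fraction_within(k) for k in (0.5, 1, 2, 5, 10)]
        assert fracs == sorted(fracs)
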