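"""Similarity statistics: correlation, entropy/MI, box-counting, transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from propseq.exceptions import DegenerateInputError, DimensionError, PropseqError
from propseq.simstats import (
    BoxCountConfig,
    PairStatTable,
    autocorrelation,
    average_mutual_information,
    box_counting_dimension,
    box_counts,
    combine_over_properties,
    pairwise_stat,
    shannon_entropy,
    stat_to_distance,
)
from propseq.alignment import PropertyWave


class TestAutocorrelation:
    def test_printed_bounds(self):
        assert autocorrelation([1, 2, 3], [1, 2, 3]) == 1.0
        assert autocorrelation([1, 2, 3], [3, 2, 1]) == -1.0
        assert autocorrelation([1, -1, 1, -1], [1, 1, -1, -1]) == 0.0

    def test_zero_variance_is_an_error(self):
        with pytest.raises(DegenerateInputError):
            autocorrelation([1, 1, 1], [1, 2, 3])

    def test_symmetry(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        assert autocorrelation(x, y) == pytest.approx(autocorrelation(y, x))

    @settings(max_examples=40, deadline=None)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_affine_invariance_and_sign_flip(self, a, b):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(25), rng.standard_normal(25)
        r = autocorrelation(x, y)
        assert autocorrelation(x, a * y + b) == pytest.approx(r, abs=1e-9)
        assert autocorrelation(x, -a * y + b) == pytest.approx(-r, abs=1e-9)

    def test_lag_shifts_alignment(self):
        # one full period of lag realigns a period-4 wave with itself
        x = np.array([0.0, 1.0, 0.0, -1.0, 0.0, 1.0, 0.0, -1.0])
        assert autocorrelation(x, x, lag=4) == 1.0
        assert autocorrelation(x, x, lag=2) == -1.0

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            autocorrelation([1, 2], [1, 2, 3])


class TestEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [([2, 2], np.log(2)), ([4], 0.0), ([1, 1, 1, 1], np.log(4))],
    )
    def test_plug_in_values(self, counts, expected):
        assert shannon_entropy(counts) == pytest.approx(expected)

    def test_empty_distribution(self):
        with pytest.raises(DegenerateInputError):
            shannon_entropy([0, 0, 0])

    def test_bits_unit(self):
        assert shannon_entropy([1, 1], unit="bits") == pytest.approx(1.0)


class TestAMI:
    def test_identity_equals_marginal_entropy(self, rng):
        x = rng.integers(0, 21, 100).astype(float)
        counts = np.unique(x, return_counts=True)[1]
        assert average_mutual_information(x, x) == pytest.approx(
            shannon_entropy(counts), abs=1e-12
        )

    def test_constructed_independence(self):
        assert average_mutual_information([1, 1, 2, 2], [1, 2, 1, 2]) == 0.0

    def test_identity_simple(self):
        assert average_mutual_information([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(
            np.log(2)
        )

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            x = rng.integers(0, 6, 40).astype(float)
            y = rng.integers(0, 6, 40).astype(float)
            mi = average_mutual_information(x, y)
            assert mi == pytest.approx(average_mutual_information(y, x), abs=1e-12)
            hx = shannon_entropy(np.unique(x, return_counts=True)[1])
            hy = shannon_entropy(np.unique(y, return_counts=True)[1])
            assert -1e-12 <= mi <= min(hx, hy) + 1e-12

    def test_binned_mode(self, rng):
        x = rng.standard_normal(100)
        mi = average_mutual_information(x, x, mode="equal_width_bins", bins=8)
        assert mi > 0
        with pytest.raises(PropseqError):
            average_mutual_information(x, x, mode="equal_width_bins", bins=1)


class TestBoxCounting:
    def test_identical_waves_near_line_dimension(self, rng):
        x = rng.uniform(0, 1, 2000)
        assert box_counting_dimension(x, x) == pytest.approx(1.0, abs=0.15)

    def test_independent_waves_approach_plane(self, rng):
        x = rng.uniform(0, 1, 2000)
        y = rng.uniform(0, 1, 2000)
        d = box_counting_dimension(x, y)
        assert 1.0 < d <= 2.0

    def test_constant_waves_degenerate_zero(self):
        res = box_counts(np.ones(10), np.ones(10))
        assert res.degenerate
        assert box_counting_dimension(np.ones(10), np.ones(10)) == 0.0

    def test_too_short(self):
        with pytest.raises(DimensionError):
            box_counting_dimension(np.arange(5), np.arange(5))

    def test_output_bounded(self, rng):
        for _ in range(10):
            x, y = rng.standard_normal(64), rng.standard_normal(64)
            assert -0.2 <= box_counting_dimension(x, y) <= 2.2

    def test_more_offsets_never_increase_counts(self, rng):
        x, y = rng.uniform(0, 1, 500), rng.uniform(0, 1, 500)
        prev = None
        for offsets in (1, 2, 4, 8):
            counts = box_counts(x, y, BoxCountConfig(offsets=offsets)).counts
            if prev is not None:
                assert np.all(counts <= prev)
            prev = counts

    def test_fit_range_subsets_scales(self, rng):
        x = rng.uniform(0, 1, 300)
        d = box_counting_dimension(x, x, BoxCountConfig(n_scales=6, fit_range=(0, 4)))
        assert np.isfinite(d)

    def test_bad_config(self):
        with pytest.raises(PropseqError):
            BoxCountConfig(n_scales=2)
        with pytest.raises(PropseqError):
            BoxCountConfig(offsets=0)


class TestTables:
    def _table(self, fill):
        return PairStatTable(("a", "b"), "s", np.full((2, 2), float(fill)))

    def test_combine_identity(self):
        t = self._table(1.5)
        assert np.array_equal(combine_over_properties([t]).values, t.values)

    def test_combine_mean(self):
        mean = combine_over_properties([self._table(1), self._table(3)])
        assert np.array_equal(mean.values, np.full((2, 2), 2.0))

    def test_combine_seeded_oracle(self, rng):
        mats = [rng.standard_normal((3, 3)) for _ in range(3)]
        mats = [(m + m.T) / 2 for m in mats]
        tables = [PairStatTable(("a", "b", "c"), "s", m) for m in mats]
        assert np.allclose(
            combine_over_properties(tables).values, np.mean(mats, axis=0)
        )

    def test_combine_taxa_mismatch(self):
        with pytest.raises(PropseqError):
            combine_over_properties(
                [self._table(1), PairStatTable(("x", "y"), "s", np.zeros((2, 2)))]
            )

    def test_tsv_and_long_round_trip(self, tmp_path):
        t = PairStatTable(("a", "b"), "ami", np.array([[1.0, 0.5], [0.5, 1.0]]))
        t.to_tsv(tmp_path / "t.tsv")
        back = PairStatTable.from_tsv(tmp_path / "t.tsv", "ami")
        assert back.taxa == t.taxa and np.allclose(back.values, t.values)
        t.to_long_csv(tmp_path / "t_long.csv")
        import pandas as pd

        long = pd.read_csv(tmp_path / "t_long.csv")
        assert len(long) == 4 and set(long.columns) == {"taxon_i", "taxon_j", "stat", "value"}


class TestStatToDistance:
    def test_reciprocal(self):
        t = PairStatTable(("a", "b"), "s", np.array([[1.0, 0.5], [0.5, 1.0]]))
        dm = stat_to_distance(t)
        assert dm.value("a", "b") == 2.0
        assert np.all(np.diag(dm.d) == 0)

    def test_clamped_cells_flagged(self):
        t = PairStatTable(("a", "b"), "s", np.array([[1.0, -0.2], [-0.2, 1.0]]))
        dm = stat_to_distance(t)
        assert dm.value("a", "b") == pytest.approx(1e9)
        assert dm.meta["clamped"] == [("a", "b")]

    def test_identical_taxa_unit_distance(self):
        t = PairStatTable(("a", "b"), "s", np.ones((2, 2)))
        dm = stat_to_distance(t)
        assert dm.value("a", "b") == 1.0

    def test_monotone_decreasing(self, rng):
        vals = np.sort(rng.uniform(0.1, 5.0, 10))
        dists = [
            stat_to_distance(
                PairStatTable(("a", "b"), "s", np.array([[1.0, v], [v, 1.0]]))
            ).value("a", "b")
            for v in vals
        ]
        assert np.all(np.diff(dists) < 0)


class TestPairwiseStat:
    def test_table_assembly(self, rng):
        waves = [PropertyWave(f"t{i}", "p", rng.integers(0, 5, 30)) for i in range(3)]
        t = pairwise_stat(waves, "ami")
        assert t.taxa == ("t0", "t1", "t2")
        assert np.allclose(t.values, t.values.T)
        assert t.values[0, 0] == pytest.approx(
            average_mutual_information(waves[0], waves[0])
        )
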