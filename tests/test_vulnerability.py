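import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString

from mangresil.vulnerability import (
    VARIABLES,
    ShorePoint,
    exposure_index,
    rank_variable,
    risk_class,
    sample_shoreline,
    scenario_compare,
)


def point(**ranks):
    full = dict.fromkeys(VARIABLES, 3)
    full.update(ranks)
    return ShorePoint(id=0, x=0.0, y=0.0, ranks=full)


class TestSampleShoreline:
    def test_point_count_on_1km_line(self):
        line = LineString([(0, 0), (1000, 0)])
        assert len(sample_shoreline(line, 250.0)) == 5

    def test_spacing_longer_than_line_gives_one_point(self):
        assert len(sample_shoreline(LineString([(0, 0), (100, 0)]), 250.0)) == 1

    def test_148km_coast_gives_593_points(self):
        line = LineString([(0, 0), (148_000, 0)])
        assert len(sample_shoreline(line, 250.0)) == 593

    def test_points_are_equally_spaced(self):
        line = LineString([(0, 0), (500, 500), (1000, 0)])
        pts = sample_shoreline(line, 100.0)
        gaps = [np.hypot(b.x - a.x, b.y - a.y) for a, b in zip(pts, pts[1:])]
        assert all(g <= 100.0 + 1e-9 for g in gaps)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sample_shoreline(LineString([(0, 0), (0, 0)]), 250.0)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            sample_shoreline(LineString([(0, 0), (1, 0)]), 0.0)


class TestRankVariable:
    def test_quantile_bins_on_uniform_values(self):
        values = np.arange(1, 101)
        ranks = rank_variable(values, "higher_is_riskier")
        assert ranks[values == 10][0] == 1
        assert ranks[values == 50][0] == 3
        assert ranks[values == 95][0] == 5

    def test_constant_field_maps_to_neutral_rank(self):
        assert (rank_variable(np.full(10, 7.0)) == 3).all()

    def test_lower_is_riskier_reverses(self):
        values = np.arange(1, 101)
        ranks = rank_variable(values, "lower_is_riskier")
        assert ranks[0] == 5 and ranks[-1] == 1

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rank_variable([np.nan, np.nan])

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            rank_variable([1.0], "sideways")


class TestExposureIndex:
    def test_all_ones_and_all_fives(self):
        assert exposure_index(point(**dict.fromkeys(VARIABLES, 1))) == pytest.approx(1.0)
        assert exposure_index(point(**dict.fromkeys(VARIABLES, 5))) == pytest.approx(5.0)

    def test_mixed_ranks_closed_form(self):
        p = point(geomorphology=1, relief=2, habitats=3, wind=4, wave=5, surge=5)
        assert exposure_index(p) == pytest.approx(600 ** (1 / 6), abs=1e-12)

    def test_missing_rank_names_variable(self):
        p = point()
        del p.ranks["wave"]
        with pytest.raises(ValueError, match="wave"):
            exposure_index(p)

    @given(st.lists(st.integers(1, 5), min_size=6, max_size=6), st.randoms(use_true_random=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_permutation_symmetric(self, ranks, rnd):
        ei = exposure_index(point(**dict(zip(VARIABLES, ranks))))
        assert 1.0 <= ei <= 5.0
        shuffled = list(ranks)
        rnd.shuffle(shuffled)
        assert exposure_index(point(**dict(zip(VARIABLES, shuffled)))) == pytest.approx(ei)

    @given(st.lists(st.integers(1, 5), min_size=6, max_size=6), st.integers(0, 5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_increasing_in_each_rank(self, ranks, which):
        if ranks[which] == 5:
            ranks[which] = 4
        lower = exposure_index(point(**dict(zip(VARIABLES, ranks))))
        raised = list(ranks)
        raised[which] += 1
        upper = exposure_index(point(**dict(zip(VARIABLES, raised))))
        assert upper > lower


class TestRiskClass:
    @pytest.mark.parametrize(
        "ei,expected",
        [
            (1.0, "very low"),
            (1.79, "very low"),
            (1.8, "low"),
            (2.6, "moderate"),
            (600 ** (1 / 6), "moderate"),
            (3.4, "high"),
            (4.2, "very high"),
            (5.0, "very high"),
        ],
    )
    def test_equal_width_bins(self, ei, expected):
        assert risk_class(ei) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            risk_class(0.5)


class TestScenarioCompare:
    def random_points(self, n=50, seed=11):
        rng = np.random.default_rng(seed)
        points = []
        for i in range(n):
            ranks = {v: int(r) for v, r in zip(VARIABLES, rng.integers(1, 6, size=6))}
            points.append(ShorePoint(id=i, x=float(i), y=0.0, ranks=ranks))
        return points

    def test_equal_habitat_ranks_identical_scenarios(self):
        results, _ = scenario_compare(self.random_points(), 3, 3)
        assert all(r.ei_with_habitat == r.ei_without_habitat for r in results)

    def test_known_ei_shift(self):
        p = point()  # all other variables at rank 3
        results, _ = scenario_compare([p], 1, 5)
        assert results[0].ei_with_habitat == pytest.approx((3**5 * 1) ** (1 / 6), abs=1e-9)
        assert results[0].ei_without_habitat == pytest.approx((3**5 * 5) ** (1 / 6), abs=1e-9)

    def test_removing_habitat_never_lowers_exposure(self):
        results, _ = scenario_compare(self.random_points(200, seed=12), 1, 5)
        assert all(r.ei_without_habitat >= r.ei_with_habitat for r in results)

    def test_high_risk_share_non_decreasing(self):
        _, summary = scenario_compare(self.random_points(200, seed=13), 1, 5)
        high = summary.loc[["high", "very high"]].sum()
        assert high["without_habitat_pct"] >= high["with_habitat_pct"]

    def test_percentages_partition(self):
        _, summary = scenario_compare(self.random_points(), 1, 5)
        assert summary.sum().tolist() == pytest.approx([100.0, 100.0])

    def test_rank_ordering_enforced(self):
        with pytest.raises(ValueError, match=">="):
            scenario_compare(self.random_points(), 4, 2)
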