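"""Field selection, counting conventions, percentages and the control t test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rcaspot.detection import Spot
from rcaspot.quantification import (
    RegionLayout,
    compare_to_control,
    count_in_fields,
    mutant_percentage,
    quantify_regions,
    round_half_up,
    select_fields,
    star_label,
)


def make_spot(y, x, allele, region=None):
    return Spot(x=x, y=y, channel="", peak=1.0, background=1.0, sb_ratio=10.0,
                allele=allele, region=region)


def uniform_layout(shape=(128, 256), content=0.9):
    labels = np.zeros(shape, dtype=np.int16)
    labels[:, : shape[1] // 2] = 1
    labels[:, shape[1] // 2:] = 2
    return RegionLayout(labels=labels, tumor_content={1: content, 2: content},
                        control_region=2)


class TestSelectFields:
    def test_uniform_content_yields_requested_fields(self):
        layout = uniform_layout()
        fields = select_fields(layout, 1, field_size=(32, 32), n=8, seed=0)
        assert len(fields) == 8
        assert all(f.mean_tumor_content > 0.8 for f in fields)

    def test_low_content_region_errors(self):
        layout = uniform_layout(content=0.5)
        with pytest.raises(ValueError, match="eligible"):
            select_fields(layout, 1, field_size=(32, 32), n=4, seed=0)

    def test_fields_do_not_overlap_and_stay_inside_region(self):
        layout = uniform_layout()
        fields = select_fields(layout, 1, field_size=(32, 32), n=8, seed=3)
        boxes = [(f.row0, f.col0) for f in fields]
        assert len(set(boxes)) == len(boxes)
        for f in fields:
            region = layout.labels[f.row0: f.row0 + f.height,
                                   f.col0: f.col0 + f.width]
            assert (region == 1).all()

    def test_low_content_stripe_avoided(self):
        labels = np.ones((128, 128), dtype=np.int16)
        labels[:, 120:] = 2  # token second region for layout validity
        content = np.full((128, 128), 0.95)
        content[40:80, :] = 0.3  # stromal stripe
        layout = RegionLayout(labels=labels, tumor_content=content, control_region=2)
        fields = select_fields(layout, 1, field_size=(16, 16), n=6, seed=1)
        for f in fields:
            assert f.row0 + f.height <= 40 or f.row0 >= 80

    def test_seed_determinism(self):
        layout = uniform_layout()
        a = select_fields(layout, 1, field_size=(32, 32), n=6, seed=5)
        b = select_fields(layout, 1, field_size=(32, 32), n=6, seed=5)
        assert [(f.row0, f.col0) for f in a] == [(f.row0, f.col0) for f in b]


class TestCountInFields:
    def test_empty_field_counts_zero(self):
        layout = uniform_layout()
        fields = select_fields(layout, 1, field_size=(32, 32), n=2, seed=0)
        count_in_fields([], fields)
        assert all(f.counts["wildtype"] == f.counts["mutant"] == 0 for f in fields)

    def test_half_open_membership_on_toy_field(self):
        """A spot on the lower/left edge is in; upper/right edge is out."""
        from rcaspot.quantification import FieldOfView

        f = FieldOfView(region=1, row0=2, col0=2, height=2, width=2,
                        mean_tumor_content=1.0, field_id=0)
        inside, outside = [], []
        for y, x in itertools.product(range(1, 6), repeat=2):
            (inside if f.contains(y, x) else outside).append((y, x))
        assert sorted(inside) == [(2, 2), (2, 3), (3, 2), (3, 3)]
        assert (4, 4) in outside and (2, 4) in outside and (4, 2) in outside

    def test_partition_sum_over_fields(self):
        layout = uniform_layout()
        fields = select_fields(layout, 1, field_size=(32, 32), n=8, seed=2)
        rng = np.random.default_rng(0)
        spots = [make_spot(int(y), int(x), "mutant" if rng.random() < 0.3 else "wildtype")
                 for y, x in zip(rng.integers(0, 128, 300), rng.integers(0, 128, 300))]
        count_in_fields(spots, fields)
        in_union = sum(
            1 for s in spots if any(f.contains(s.y, s.x) for f in fields)
        )
        total = sum(f.counts["wildtype"] + f.counts["mutant"] for f in fields)
        assert total == in_union

    def test_control_and_unspecific_excluded_from_percentage(self):
        from rcaspot.quantification import FieldOfView

        f = FieldOfView(region=1, row0=0, col0=0, height=10, width=10,
                        mean_tumor_content=1.0, field_id=0)
        spots = [make_spot(1, 1, "wildtype"), make_spot(2, 2, "mutant"),
                 make_spot(3, 3, "control"), make_spot(4, 4, "unspecific")]
        count_in_fields(spots, [f])
        assert f.counts == {"wildtype": 1, "mutant": 1, "control": 1, "unspecific": 1}
        assert f.mutant_pct == pytest.approx(50.0)


class TestMutantPercentage:
    # every printed count/percentage pair from the two tumors, at its
    # printed precision (the two truncation-consistent values are checked
    # in the acceptance suite with +-0.1)
    @pytest.mark.parametrize("mutant,total,decimals,expected", [
        (3, 342, 1, 0.9),
        (2, 295, 1, 0.7),
        (17, 273, 1, 6.2),
        (4, 262, 1, 1.5),
        (25, 371, 1, 6.7),
        (57, 252, 1, 22.6),
        (50, 203, 1, 24.6),
        (1, 127, 2, 0.79),
    ])
    def test_printed_pairs(self, mutant, total, decimals, expected):
        assert mutant_percentage(mutant, total, decimals=decimals) == expected

    def test_exact_value_and_edge_cases(self):
        assert mutant_percentage(0, 100) == 0.0
        assert mutant_percentage(57, 252) == pytest.approx(100 * 57 / 252)
        assert math.isnan(mutant_percentage(0, 0))
        with pytest.raises(ValueError):
            mutant_percentage(5, 3)

    def test_round_half_up_ties(self):
        # built-in round() gives 0.2 / 13.4 for these (banker's + binary float)
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(0.35, 1) == 0.4
        assert round_half_up(13.45, 1) == 13.5
        assert round_half_up(0.785, 2) == 0.79


class TestCompareToControl:
    def test_identical_samples_null(self):
        t, p, stars = compare_to_control([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and stars == ""

    def test_pooled_t_closed_form(self):
        """(1,2,3) vs (4,5,6): |t| = 3.674, p ~ 0.0213, one star."""
        t, p, stars = compare_to_control([1, 2, 3], [4, 5, 6])
        # closed form: pooled var = 1, se = sqrt(2/3)
        assert abs(t) == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-3)
        assert p == pytest.approx(2 * stats.t.sf(3.6742, df=4), abs=1e-4)
        assert stars == "*"

    def test_matches_exhaustive_permutation_small_n(self):
        """Equal-variance t p-value tracks the exact permutation p on small
        samples (coarse agreement: the permutation null is discrete)."""
        a = [3.1, 4.5, 2.8, 5.0]
        b = [6.2, 7.1, 5.9]
        t_obs, p_t, _ = compare_to_control(a, b)
        pooled = np.array(a + b)
        n_a = len(a)
        count = 0
        combos = list(itertools.combinations(range(len(pooled)), n_a))
        for idx in combos:
            ga = pooled[list(idx)]
            gb = np.delete(pooled, list(idx))
            t = stats.ttest_ind(ga, gb, equal_var=True).statistic
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        p_perm = count / len(combos)
        assert abs(p_t - p_perm) < 0.05

    def test_welch_option(self):
        a, b = [1.0, 2.0, 3.0, 14.0], [4.0, 5.0, 6.0]
        t_w, p_w, _ = compare_to_control(a, b, equal_var=False)
        res = stats.ttest_ind(a, b, equal_var=False)
        assert t_w == pytest.approx(res.statistic)
        assert p_w == pytest.approx(res.pvalue)

    def test_sample_size_validation(self):
        with pytest.raises(ValueError):
            compare_to_control([1.0], [2.0, 3.0])

    @pytest.mark.parametrize("p,stars", [
        (0.2, ""), (0.05, ""), (0.049, "*"), (0.0011, "*"),
        (0.0004, "***"), (0.0001, "***"), (0.00009, "****"),
    ])
    def test_star_legend_three_levels(self, p, stars):
        """The legend has no two-star level: 0.001 <= p < 0.05 is one star."""
        assert star_label(p) == stars


class TestQuantifyRegions:
    def _layout_and_spots(self, frac_by_region, n=400, seed=0):
        labels = np.zeros((64, 192), dtype=np.int16)
        for i in range(3):
            labels[:, i * 64: (i + 1) * 64] = i + 1
        layout = RegionLayout(labels=labels,
                              tumor_content={1: 0.9, 2: 0.9, 3: 0.9},
                              control_region=3)
        rng = np.random.default_rng(seed)
        spots = []
        for rid, frac in frac_by_region.items():
            xs = rng.integers((rid - 1) * 64, rid * 64, n)
            ys = rng.integers(0, 64, n)
            for x, y in zip(xs, ys):
                allele = "mutant" if rng.random() < frac else "wildtype"
                spots.append(make_spot(int(y), int(x), allele, region=rid))
        return layout, spots

    def test_recovers_configured_fractions(self):
        layout, spots = self._layout_and_spots({1: 0.05, 2: 0.3, 3: 0.01})
        results = quantify_regions(spots, layout, field_size=(16, 16),
                                   n_fields=10, seed=1)
        for res, frac in zip(results, (0.05, 0.3, 0.01)):
            n = res.total
            se = 100 * np.sqrt(frac * (1 - frac) / n)
            assert abs(res.pooled_pct - 100 * frac) < 3 * se

    def test_output_order_and_control_flag(self):
        layout, spots = self._layout_and_spots({1: 0.1, 2: 0.1, 3: 0.0})
        results = quantify_regions(spots, layout, field_size=(16, 16),
                                   n_fields=8, seed=0)
        assert [r.region for r in results] == [1, 2, 3]
        assert [r.is_control for r in results] == [False, False, True]
        assert results[2].t_statistic is None
        assert results[0].t_statistic is not None

    def test_zero_mutants_give_zero_percent(self):
        layout, spots = self._layout_and_spots({1: 0.0, 2: 0.0, 3: 0.0})
        results = quantify_regions(spots, layout, field_size=(16, 16),
                                   n_fields=8, seed=0)
        assert all(r.pooled_pct == 0.0 for r in results)

    def test_pooled_pct_recomputable_from_counts(self):
        layout, spots = self._layout_and_spots({1: 0.2, 2: 0.4, 3: 0.01})
        results = quantify_regions(spots, layout, field_size=(16, 16),
                                   n_fields=10, seed=2)
        for r in results:
            assert r.pooled_pct == pytest.approx(100 * r.mutant / r.total)
            # pooled and per-field mean are different statistics in general
            assert 0.0 <= r.pooled_pct <= 100.0
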