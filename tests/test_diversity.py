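import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridscape import ValidationError
from gridscape.diversity import (
    COLLAPSED_CATEGORIES,
    GROUPS_6,
    N_COLLAPSED,
    N_INHABITED,
    ClassifierParams,
    classify_cell,
    classify_map,
    collapse_density,
    density_class,
    full_legend,
    label_components,
    legend_table,
    merge_groups,
    standardized_entropy,
)
from conftest import grid_set_from_stack


def entropy_direct(shares):
    """Direct evaluation of -sum p ln p / ln 6, the oracle for E."""
    return -sum(p * math.log(p) for p in shares if p > 0) / math.log(6)


class TestMergeGroups:
    def test_nhas_nhpi_summed(self):
        # 7-group order: NHW, NHB, NHAS, NHAM, NHPI, NHO, H
        out = merge_groups([0, 0, 2, 0, 1, 0, 0])
        np.testing.assert_allclose(out, [0, 0, 3, 0, 0, 0])

    def test_all_zero(self):
        np.testing.assert_array_equal(merge_groups([0] * 7), np.zeros(6))

    def test_total_preserved_on_random_vectors(self):
        rng = np.random.default_rng(2)
        v = rng.random((50, 7)) * 100
        np.testing.assert_allclose(merge_groups(v).sum(axis=1), v.sum(axis=1), rtol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            merge_groups([1, -1, 0, 0, 0, 0, 0])


class TestStandardizedEntropy:
    def test_uniform_is_one(self):
        assert standardized_entropy([1 / 6] * 6) == pytest.approx(1.0, abs=1e-12)

    def test_single_group_is_zero(self):
        assert standardized_entropy([5, 0, 0, 0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_skewed_composition_matches_direct_formula(self):
        shares = [0.9, 0.02, 0.02, 0.02, 0.02, 0.02]
        expected = entropy_direct(shares)  # ~0.2713
        assert expected == pytest.approx(0.2713, abs=5e-4)
        assert standardized_entropy(shares) == pytest.approx(expected, rel=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            standardized_entropy([0.0] * 6)

    @given(st.lists(st.floats(0.01, 1000), min_size=6, max_size=6),
           st.floats(0.001, 1000))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_in_unit_interval_and_scale_invariant(self, d, k):
        e = standardized_entropy(d)
        assert 0.0 <= e <= 1.0 + 1e-12
        assert standardized_entropy([k * x for x in d]) == pytest.approx(e, rel=1e-9)


class TestDensityClass:
    @pytest.mark.parametrize(
        "dens,expected",
        [(2.9, "low"), (3.0, "medium"), (30.0, "medium"), (30.1, "high"),
         (1e6 / 900, "high")],  # 1 person in a 30 m cell
    )
    def test_thresholds(self, dens, expected):
        assert density_class(dens) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            density_class(0.0)


class TestClassifyCell:
    CELL30_HIGH = 30.0  # any cell total >= ~0.03 people at 30 m is high density

    def dens_cell(self, shares, people_km2=100.0, cell=30.0):
        """People/cell composition with given shares and total density."""
        total_cell = people_km2 * cell**2 / 1e6
        return [s * total_cell for s in shares]

    def test_zero_cell_is_uninhabited(self):
        lab = classify_cell([0] * 6, 30.0)
        assert lab.code == 0 and lab.uninhabited

    def test_uniform_composition_is_high_diversity(self):
        lab = classify_cell(self.dens_cell([1 / 6] * 6), 30.0)
        assert lab.diversity == "high"
        assert lab.dominant is None
        assert lab.density == "high"

    def test_ninety_percent_white_is_low_diversity(self):
        lab = classify_cell(self.dens_cell([0.9, 0.02, 0.02, 0.02, 0.02, 0.02]), 30.0)
        assert (lab.dominant, lab.diversity, lab.density) == ("NHW", "low", "high")

    def test_sixty_forty_is_medium(self):
        # share 60% fails both the low (>80%) and high (<50%) tests
        lab = classify_cell(self.dens_cell([0.6, 0.4, 0, 0, 0, 0]), 30.0)
        assert (lab.dominant, lab.diversity) == ("NHW", "medium")

    def test_share_exactly_eighty_percent_is_medium(self):
        # E ~ 0.279 < 0.37 but the share inequality is strict
        lab = classify_cell(self.dens_cell([0.8, 0.2, 0, 0, 0, 0]), 30.0)
        assert lab.diversity == "medium"

    def test_share_exactly_fifty_percent_is_medium(self):
        # E = 0.86 > 0.73 but share == 50% is not < 50%
        lab = classify_cell(self.dens_cell([0.5, 0.125, 0.125, 0.125, 0.125, 0]), 30.0)
        assert entropy_direct([0.5, 0.125, 0.125, 0.125, 0.125]) > 0.73
        assert lab.diversity == "medium"

    def test_entropy_boundary_strict(self):
        # thresholds moved onto the observed E: equality must NOT make it low
        shares = [0.9, 0.02, 0.02, 0.02, 0.02, 0.02]
        e = entropy_direct(shares)
        params = ClassifierParams(entropy_low=e)  # E < threshold is now false
        lab = classify_cell(self.dens_cell(shares), 30.0, params)
        assert lab.diversity == "medium"

    def test_density_boundaries_fall_in_medium(self):
        lab3 = classify_cell(self.dens_cell([1, 0, 0, 0, 0, 0], people_km2=3.0), 30.0)
        lab30 = classify_cell(self.dens_cell([1, 0, 0, 0, 0, 0], people_km2=30.0), 30.0)
        assert lab3.density == "medium" and lab30.density == "medium"

    def test_dominance_tie_goes_to_first_group(self):
        lab = classify_cell(self.dens_cell([0.4, 0.4, 0.2, 0, 0, 0]), 30.0)
        assert lab.dominant == "NHW"


class TestTaxonomy:
    def test_inhabited_codes_count_is_39(self):
        legend = full_legend()
        assert len(legend) == 40
        assert sorted(legend) == list(range(40))
        assert N_INHABITED == 39 == (6 * 2 + 1) * 3

    def test_every_code_reachable_by_classification(self):
        """Each of the 39 labels is produced by some composition/density."""
        seen = set()
        dens_km2 = {"low": 1.0, "medium": 10.0, "high": 100.0}
        for gi in range(6):
            # low: share 0.9 (> 80%, E < 0.37); medium: share 0.6 (fails both tests)
            for div, dom_share, rest in (("low", 0.9, 0.02), ("medium", 0.6, 0.08)):
                s = [rest] * 6
                s[gi] = dom_share
                tot = sum(s)
                s = [x / tot for x in s]
                for dname, d in dens_km2.items():
                    lab = classify_cell([x * d * 900 / 1e6 for x in s], 30.0)
                    assert (lab.dominant, lab.diversity, lab.density) == (GROUPS_6[gi], div, dname)
                    seen.add(lab.code)
        for dname, d in dens_km2.items():
            lab = classify_cell([d * 150 / 1e6] * 6, 30.0)
            assert (lab.dominant, lab.diversity, lab.density) == (None, "high", dname)
            seen.add(lab.code)
        assert seen == set(range(1, 40))

    def test_collapsed_categories_count_is_13(self):
        assert N_COLLAPSED == 13 == len(COLLAPSED_CATEGORIES)

    def test_legend_table_shape_and_colors(self):
        t = legend_table()
        assert len(t) == 40
        assert t["color"].str.match(r"#[0-9a-f]{6}").all()
        assert t["code"].tolist() == list(range(40))


class TestClassifyMap:
    def test_single_group_cells(self):
        stack = np.zeros((7, 3, 3))
        stack[1] = 1.0  # one NHB person per cell -> low diversity, high density
        grids = grid_set_from_stack(stack)
        out = classify_map(grids)
        assert len(np.unique(out.values)) == 1
        lab = label_components(int(out.values[0, 0]))
        assert (lab.dominant, lab.diversity, lab.density) == ("NHB", "low", "high")

    def test_all_zero_grids_all_uninhabited(self):
        out = classify_map(grid_set_from_stack(np.zeros((7, 4, 4))))
        assert np.all(out.values == 0)

    def test_random_grids_labels_in_range(self):
        rng = np.random.default_rng(3)
        stack = rng.random((7, 12, 12)) * rng.integers(0, 2, (7, 12, 12))
        out = classify_map(grid_set_from_stack(stack))
        assert set(np.unique(out.values)) <= set(range(40))

    def test_matches_per_cell_classifier(self):
        """The vectorized map agrees with classify_cell everywhere."""
        rng = np.random.default_rng(4)
        stack = rng.random((7, 9, 9)) * 0.05 * rng.integers(0, 2, (7, 9, 9))
        grids = grid_set_from_stack(stack)
        out = classify_map(grids)
        merged = merge_groups(np.moveaxis(stack, 0, -1))
        for r in range(9):
            for c in range(9):
                assert out.values[r, c] == classify_cell(merged[r, c], 30.0).code

    def test_code_zero_iff_zero_total(self):
        rng = np.random.default_rng(5)
        stack = rng.random((7, 10, 10)) * (rng.random((7, 10, 10)) > 0.7)
        grids = grid_set_from_stack(stack)
        out = classify_map(grids)
        np.testing.assert_array_equal(out.values == 0, stack.sum(axis=0) == 0)


class TestCollapse:
    def test_all_39_codes_collapse_to_13(self):
        from conftest import cat
        vals = np.arange(40, dtype=np.int32).reshape(5, 8)
        collapsed = collapse_density(cat(vals, legend=full_legend()))
        inhabited = collapsed.values[vals > 0]
        assert set(inhabited) == set(range(1, 14))

    def test_density_variants_share_one_code(self):
        from conftest import cat
        for code in range(1, 40):
            lab = label_components(code)
            low_variant = (code - 1) % 13 + 1
            got = collapse_density(cat([[code]], legend=full_legend())).values[0, 0]
            assert got == low_variant
            got_lab = COLLAPSED_CATEGORIES[got - 1]
            assert got_lab == (lab.dominant, lab.diversity)

    def test_all_uninhabited_unchanged(self):
        from conftest import cat
        m = cat(np.zeros((3, 3), dtype=np.int32), legend={0: "uninhabited"})
        np.testing.assert_array_equal(collapse_density(m).values, 0)

    def test_idempotent(self):
        from conftest import cat
        vals = np.arange(40, dtype=np.int32).reshape(5, 8)
        once = collapse_density(cat(vals, legend=full_legend()))
        twice = collapse_density(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_unknown_code_rejected(self):
        from conftest import cat
        with pytest.raises(ValidationError):
            collapse_density(cat([[77]]))
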