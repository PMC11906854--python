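"""Weighted overlay, equal-interval classing, masking, area tabulation."""

import numpy as np
import pytest

from cropsuit import ahp, overlay, presets
from cropsuit.errors import SuitabilityError
from cropsuit.grids import CategoricalGrid, Grid

from conftest import small_grid


def theoretical_index_bounds(crop):
    """[Σ W_i·min_k w_ik, Σ W_i·max_k w_ik] from the printed tables."""
    scheme = presets.crop_scheme(crop)
    weights = presets.PRINTED_WEIGHTS[crop]
    lo = sum(weights[c] * min(s.weights) for c, s in scheme.items())
    hi = sum(weights[c] * max(s.weights) for c, s in scheme.items())
    return lo, hi


class TestWeightedOverlay:
    def test_single_criterion_passthrough(self):
        out = overlay.weighted_overlay(
            {"elevation": small_grid(np.full((3, 3), 0.58))}, {"elevation": 1.0}
        )
        assert np.allclose(out.values, 0.58)

    def test_top_subclass_everywhere_hits_upper_bound(self):
        """All nine rice criteria at their best bin → Σ W_i·max_k w_ik."""
        scheme = presets.rice_scheme()
        weights = ahp.analyze(presets.rice_matrix()).weights_by_label()
        layers = {
            c: small_grid(np.full((2, 2), max(s.weights))) for c, s in scheme.items()
        }
        out = overlay.weighted_overlay(layers, weights)
        expected = sum(weights[c] * max(s.weights) for c, s in scheme.items())
        assert np.allclose(out.values, expected)

    def test_printed_range_inside_theoretical_bounds(self):
        """The published rice index range [0.072, 0.466] fits the bounds
        implied by the printed criterion and subclass weights."""
        lo, hi = theoretical_index_bounds("rice")
        assert lo <= 0.072 and 0.466 <= hi

    def test_matches_per_cell_loop(self):
        rng = np.random.default_rng(31)
        names = ["a", "b", "c"]
        w = {"a": 0.5, "b": 0.3, "c": 0.2}
        layers = {n: small_grid(rng.uniform(0, 1, (4, 4))) for n in names}
        out = overlay.weighted_overlay(layers, w)
        for i in range(4):
            for j in range(4):
                expected = sum(w[n] * layers[n].values[i, j] for n in names)
                assert out.values[i, j] == pytest.approx(expected)

    def test_nodata_in_any_layer_propagates(self):
        a = small_grid([[0.5, 0.5]])
        b = small_grid([[0.5, -9999.0]])
        out = overlay.weighted_overlay({"a": a, "b": b}, {"a": 0.5, "b": 0.5})
        assert out.values[0, 1] == out.nodata

    def test_missing_layer_named(self):
        with pytest.raises(SuitabilityError, match="rainfall"):
            overlay.weighted_overlay({"slope": small_grid([[0.5]])},
                                     {"slope": 0.5, "rainfall": 0.5})

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(SuitabilityError, match="sum"):
            overlay.weighted_overlay({"a": small_grid([[1.0]])}, {"a": 0.9})

    def test_monotone_in_subclass_upgrade(self):
        """Raising one cell's subclass weight never lowers its index."""
        rng = np.random.default_rng(77)
        layers = {n: small_grid(rng.uniform(0, 1, (3, 3))) for n in "abc"}
        w = {"a": 0.6, "b": 0.3, "c": 0.1}
        before = overlay.weighted_overlay(layers, w).values[1, 1]
        layers["c"].values[1, 1] += 0.2
        after = overlay.weighted_overlay(layers, w).values[1, 1]
        assert after >= before


class TestEqualIntervalClassify:
    def test_unit_range_breaks(self):
        assert overlay.equal_interval_breaks(0.0, 1.0) == (0.25, 0.5, 0.75)

    def test_published_index_range_breaks(self):
        """(0.466 − 0.072)/4 = 0.0985 → breaks at 0.1705, 0.269, 0.3675."""
        breaks = overlay.equal_interval_breaks(0.072, 0.466)
        assert np.allclose(breaks, (0.1705, 0.269, 0.3675))
        assert (0.466 - 0.072) / 4 == pytest.approx(0.0985)

    def test_highest_interval_is_s1_and_max_included(self):
        g = small_grid([[0.0, 0.3], [0.6, 1.0]])
        classes = overlay.equal_interval_classify(g)
        labels = classes.labels()
        assert labels[1, 1] == "S1"
        assert labels[0, 0] == "N"

    def test_value_on_break_goes_to_upper_class(self):
        g = small_grid([[0.0, 0.25, 0.5, 1.0]])
        classes = overlay.equal_interval_classify(g)
        labels = classes.labels()
        assert labels[0, 1] == "S3"  # 0.25 is the N/S3 break
        assert labels[0, 2] == "S2"

    def test_constant_index_rejected_with_guidance(self):
        with pytest.raises(SuitabilityError, match="degenerate"):
            overlay.equal_interval_classify(small_grid(np.full((3, 3), 0.4)))

    def test_nodata_excluded_from_range_and_output(self):
        g = small_grid([[0.0, 1.0, -9999.0]])
        classes = overlay.equal_interval_classify(g)
        assert classes.codes[0, 2] == classes.nodata


def lulc_grid(labels_2d):
    inv = {v: k for k, v in presets.LULC_LEGEND.items()}
    codes = np.array([[inv[l] for l in row] for row in labels_2d])
    return CategoricalGrid(codes, dict(presets.LULC_LEGEND))


class TestApplyConstraint:
    def constraint(self, labels_2d):
        return overlay.ConstraintMap(
            lulc_grid(labels_2d), presets.CROPLAND_CLASSES, presets.NONCROPLAND_CLASSES
        )

    def classes(self, codes):
        return CategoricalGrid(np.asarray(codes), dict(overlay.CLASS_LEGEND))

    def test_trees_masked_crops_kept(self):
        out = overlay.apply_constraint(
            self.classes([[1, 2]]), self.constraint([["trees", "crops"]])
        )
        assert out.labels()[0, 0] == "non-cropland"
        assert out.labels()[0, 1] == "S2"

    def test_all_cropland_is_identity(self):
        out = overlay.apply_constraint(
            self.classes([[1, 4]]), self.constraint([["crops", "rangeland"]])
        )
        assert np.array_equal(out.codes, [[1, 4]])

    def test_cell_count_conserved(self):
        classes = self.classes([[1, 2], [3, 4]])
        out = overlay.apply_constraint(
            classes, self.constraint([["water", "crops"], ["built area", "bare ground"]])
        )
        assert out.mask.sum() == classes.mask.sum()

    def test_unpartitioned_lulc_code_rejected(self):
        from cropsuit.errors import DomainError

        with pytest.raises(DomainError, match="trees"):
            overlay.ConstraintMap(
                lulc_grid([["water", "crops"]]),
                frozenset({"crops"}),
                frozenset({"water"}),  # six legend classes left unassigned
            )


class TestTabulateAreas:
    def test_single_class_100_cells(self):
        codes = np.ones((10, 10), dtype=int)
        table = overlay.tabulate_areas(CategoricalGrid(codes, dict(overlay.CLASS_LEGEND)))
        s1 = table.set_index("class").loc["S1"]
        assert s1.area_ha == pytest.approx(625.0)  # 100 cells × 6.25 ha
        assert s1.area_pct == pytest.approx(100.0)

    def test_sixty_forty_split(self):
        codes = np.array([1] * 60 + [4] * 40).reshape(10, 10)
        table = overlay.tabulate_areas(CategoricalGrid(codes, dict(overlay.CLASS_LEGEND)))
        by = table.set_index("class")
        assert by.loc["S1", "area_pct"] == pytest.approx(60.0)
        assert by.loc["N", "area_pct"] == pytest.approx(40.0)
        assert by.loc["S2", "area_ha"] == 0.0  # zero classes still listed

    def test_matches_histogram_oracle_and_sums_to_100(self):
        rng = np.random.default_rng(13)
        codes = rng.integers(1, 5, size=(20, 20))
        grid = CategoricalGrid(codes, dict(overlay.CLASS_LEGEND))
        table = overlay.tabulate_areas(grid)
        assert table.area_pct.sum() == pytest.approx(100.0, abs=0.01)
        for cls_code, label in overlay.CLASS_LEGEND.items():
            expected = (codes == cls_code).sum() * 6.25
            assert table.set_index("class").loc[label, "area_ha"] == pytest.approx(expected)


class TestMaskingConservation:
    def test_per_class_areas_conserve_total(self):
        rng = np.random.default_rng(55)
        codes = rng.integers(1, 5, size=(16, 16))
        classes = CategoricalGrid(codes, dict(overlay.CLASS_LEGEND))
        lulc_codes = rng.integers(0, 8, size=(16, 16))
        lulc = CategoricalGrid(lulc_codes, dict(presets.LULC_LEGEND))
        constraint = overlay.ConstraintMap(
            lulc, presets.CROPLAND_CLASSES, presets.NONCROPLAND_CLASSES
        )
        masked = overlay.apply_constraint(classes, constraint)
        before = overlay.tabulate_areas(classes).set_index("class")
        after = overlay.tabulate_areas(masked).set_index("class")
        for label in overlay.CLASS_LEGEND.values():
            assert after.loc[label, "area_ha"] <= before.loc[label, "area_ha"] + 1e-9
        assert after.area_ha.sum() == pytest.approx(before.area_ha.sum())
        assert after.area_pct.sum() == pytest.approx(100.0, abs=0.01)
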