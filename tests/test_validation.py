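"""Absence sampling, score extraction, AUROC, and area correlation."""

import numpy as np
import pandas as pd
import pytest

from cropsuit import overlay, validation
from cropsuit.errors import SuitabilityError
from cropsuit.grids import CategoricalGrid, Grid

from conftest import small_grid


def pair_counting_auroc(scores, labels):
    """Independent oracle: fraction of presence/absence pairs correctly
    ordered, ties counted half (exhaustive double loop)."""
    pres = [s for s, l in zip(scores, labels) if l == "presence"]
    abse = [s for s, l in zip(scores, labels) if l == "absence"]
    wins = 0.0
    for p in pres:
        for a in abse:
            if p > a:
                wins += 1.0
            elif p == a:
                wins += 0.5
    return wins / (len(pres) * len(abse))


def scored_frame(scores, labels):
    return pd.DataFrame({
        "x": np.arange(len(scores), dtype=float),
        "y": np.zeros(len(scores)),
        "label": labels,
        "score": scores,
    })


class TestSampleAbsences:
    def classes_grid(self, codes):
        return CategoricalGrid(np.asarray(codes), dict(overlay.MASKED_LEGEND))

    def test_single_eligible_cell_forced(self):
        codes = np.ones((3, 3), dtype=int)  # all S1
        codes[2, 1] = 3
        pts = validation.sample_absences(self.classes_grid(codes), n=1, seed=0)
        g = self.classes_grid(codes)
        assert g.point_to_index(pts.x[0], pts.y[0]) == (2, 1)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(10)
        codes = rng.integers(1, 5, (20, 20))
        g = self.classes_grid(codes)
        a = validation.sample_absences(g, n=50, seed=123)
        b = validation.sample_absences(g, n=50, seed=123)
        pd.testing.assert_frame_equal(a, b)

    def test_never_lands_on_s1_or_noncropland(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 5, (40, 40))  # includes non-cropland code 0
        g = self.classes_grid(codes)
        pts = validation.sample_absences(g, n=500, seed=2)
        for x, y in zip(pts.x, pts.y):
            r, c = g.point_to_index(x, y)
            assert codes[r, c] not in (validation.S1_CODE, overlay.NONCROPLAND_CODE)

    def test_allow_noncropland_restores_literal_rule(self):
        codes = np.zeros((5, 5), dtype=int)  # all non-cropland
        codes[0, 0] = 1
        g = self.classes_grid(codes)
        with pytest.raises(SuitabilityError, match="eligible"):
            validation.sample_absences(g, n=1, seed=0)
        pts = validation.sample_absences(g, n=10, seed=0, allow_noncropland=True)
        assert len(pts) == 10

    def test_no_duplicate_coordinates(self):
        rng = np.random.default_rng(20)
        codes = rng.integers(2, 5, (10, 10))
        pts = validation.sample_absences(self.classes_grid(codes), n=60, seed=5)
        assert not pts.duplicated(subset=["x", "y"]).any()


class TestExtract:
    def test_cell_center_returns_cell_value(self):
        g = small_grid([[1.0, 2.0], [3.0, 4.0]])
        pts = pd.DataFrame({"x": [375.0], "y": [125.0], "label": ["presence"]})
        out = validation.extract(g, pts)
        assert out.score[0] == 4.0

    def test_boundary_point_follows_half_open_convention(self):
        g = small_grid([[1.0, 2.0], [3.0, 4.0]])
        # x = 250 is the left edge of column 1; y = 250 is the top of row 1
        pts = pd.DataFrame({"x": [250.0], "y": [250.0], "label": ["presence"]})
        out = validation.extract(g, pts)
        assert out.score[0] == 4.0

    def test_nodata_points_dropped_with_count(self, caplog):
        g = small_grid([[1.0, -9999.0]])
        pts = pd.DataFrame({"x": [125.0, 375.0], "y": [125.0, 125.0],
                            "label": ["presence", "absence"]})
        with caplog.at_level("INFO", logger="cropsuit.validation"):
            out = validation.extract(g, pts)
        assert len(out) == 1
        assert "dropped 1" in caplog.text

    def test_all_nodata_rejected(self):
        g = small_grid([[-9999.0]])
        pts = pd.DataFrame({"x": [125.0], "y": [125.0], "label": ["presence"]})
        with pytest.raises(SuitabilityError):
            validation.extract(g, pts)

    def test_matches_per_point_indexing_oracle(self):
        rng = np.random.default_rng(30)
        vals = rng.uniform(0, 1, (8, 8))
        g = small_grid(vals)
        xs = rng.uniform(0, 1999, 40)
        ys = rng.uniform(0.5, 2000, 40)
        pts = pd.DataFrame({"x": xs, "y": ys, "label": ["presence"] * 40})
        out = validation.extract(g, pts)
        for _, row in out.iterrows():
            r, c = g.point_to_index(row.x, row.y)
            assert row.score == vals[r, c]


class TestAuroc:
    def test_perfect_separation(self):
        out = validation.auroc(scored_frame([0.9, 0.8, 0.2, 0.1],
                                            ["presence", "presence", "absence", "absence"]))
        assert out.auroc == 1.0
        assert out.band == "very high"

    def test_all_tied_scores_give_half(self):
        out = validation.auroc(scored_frame([0.5] * 6,
                                            ["presence"] * 3 + ["absence"] * 3))
        assert out.auroc == 0.5
        assert out.band == "low"

    def test_interleaved_example_equals_pair_counting(self):
        scores = [0.9, 0.8, 0.7, 0.6]
        labels = ["presence", "absence", "presence", "absence"]
        out = validation.auroc(scored_frame(scores, labels))
        assert out.auroc == 0.75
        assert out.auroc == pair_counting_auroc(scores, labels)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            n = 30
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)
            labels = rng.choice(["presence", "absence"], size=n)
            if len(set(labels)) < 2:
                continue
            out = validation.auroc(scored_frame(scores, labels))
            assert out.auroc == pytest.approx(pair_counting_auroc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(42)
        scores = rng.uniform(0, 1, 50)
        labels = ["presence" if rng.random() < 0.5 else "absence" for _ in range(50)]
        if "presence" not in labels:
            labels[0] = "presence"
        if "absence" not in labels:
            labels[1] = "absence"
        base = validation.auroc(scored_frame(scores, labels)).auroc
        warped = validation.auroc(scored_frame(np.exp(5 * scores), labels)).auroc
        assert warped == pytest.approx(base)

    def test_label_swap_complements_auroc(self):
        rng = np.random.default_rng(43)
        scores = rng.uniform(0, 1, 40)
        labels = ["presence"] * 20 + ["absence"] * 20
        fwd = validation.auroc(scored_frame(scores, labels)).auroc
        swapped = ["absence" if l == "presence" else "presence" for l in labels]
        rev = validation.auroc(scored_frame(scores, swapped)).auroc
        assert fwd + rev == pytest.approx(1.0)

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(44)
        scores = rng.uniform(0, 1, 60)
        labels = ["presence"] * 30 + ["absence"] * 30
        out = validation.auroc(scored_frame(scores, labels))
        assert (np.diff(out.fpr) >= 0).all()
        assert (np.diff(out.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(SuitabilityError, match="both classes"):
            validation.auroc(scored_frame([0.1, 0.2], ["presence", "presence"]))


class TestAreaCorrelation:
    def test_identical_vectors(self):
        assert validation.area_correlation([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_exact_linear_reversal(self):
        assert validation.area_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(50)
        x = rng.uniform(0, 100, 12)
        y = 0.7 * x + rng.normal(0, 10, 12)
        r = validation.area_correlation(x, y)
        expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(SuitabilityError, match="variance"):
            validation.area_correlation([1, 1, 1], [1, 2, 3])

    def test_too_few_districts_rejected(self):
        with pytest.raises(SuitabilityError, match="3"):
            validation.area_correlation([1, 2], [1, 2])


class TestDedupe:
    def test_exact_coordinate_duplicates_removed_within_label(self):
        pts = pd.DataFrame({
            "x": [1.0, 1.0, 1.0], "y": [2.0, 2.0, 2.0],
            "label": ["presence", "presence", "absence"],
        })
        out = validation.dedupe_points(pts)
        assert len(out) == 2
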