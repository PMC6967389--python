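import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import rescan_thresholds_oracle
from speciesgap import delineation
from speciesgap.delineation import (ani_landscape, binned_median_curve,
                                    pair_labels_from_ani,
                                    pair_labels_from_taxonomy,
                                    precision_recall_f1, scan_thresholds)


class TestPairLabels:
    def test_from_taxonomy(self):
        labels = pair_labels_from_taxonomy({"g1": "x", "g2": "x", "g3": "y"})
        assert labels[("g1", "g2")] is True
        assert labels[("g1", "g3")] is False
        assert labels[("g3", "g2")] is False  # order-insensitive lookup
        assert len(labels.pairs()) == 3

    def test_all_same_and_all_distinct(self):
        same = pair_labels_from_taxonomy({"a": "x", "b": "x", "c": "x"})
        assert all(same[p] for p in same.pairs())
        diff = pair_labels_from_taxonomy({"a": "x", "b": "y", "c": "z"})
        assert not any(diff[p] for p in diff.pairs())

    def test_missing_label_is_an_error(self):
        with pytest.raises(ValueError):
            pair_labels_from_taxonomy({"g1": "x", "g2": ""})

    @pytest.mark.parametrize("ani, same", [
        (96.0, True), (94.9, False), (95.0, True),  # closed boundary at 95
    ])
    def test_from_ani_cutoff(self, ani, same):
        df = pd.DataFrame([{"genome1": "a", "genome2": "b", "ani": ani}])
        assert pair_labels_from_ani(df)[("a", "b")] is same

    def test_no_alignment_pairs_are_different_species(self):
        df = pd.DataFrame([{"genome1": "a", "genome2": "b", "ani": None}])
        assert pair_labels_from_ani(df)[("a", "b")] is False


class TestPrecisionRecallF1:
    def test_printed_formula_arithmetic(self):
        scores = precision_recall_f1(tp=8, fp=0, fn=2)
        assert scores.recall == pytest.approx(0.8)
        assert scores.precision == pytest.approx(1.0)
        assert scores.f1 == pytest.approx(2 * 0.8 / 1.8)

    def test_degenerate_zero_counts(self):
        scores = precision_recall_f1(0, 0, 0)
        assert (scores.recall, scores.precision, scores.f1) == (0, 0, 0)
        assert scores.degenerate

    def test_perfect_classification(self):
        assert precision_recall_f1(10, 0, 0).f1 == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 0)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 1000), st.integers(0, 1000), st.integers(0, 1000))
    def test_scores_bounded(self, tp, fp, fn):
        scores = precision_recall_f1(tp, fp, fn)
        assert 0 <= scores.recall <= 1
        assert 0 <= scores.precision <= 1
        assert min(scores.recall, scores.precision) - 1e-12 <= scores.f1 \
            <= max(scores.recall, scores.precision) + 1e-12


def _toy_scan(identities_list, labels_list, **kwargs):
    genomes = [f"g{i}" for i in range(len(labels_list))]
    labels = pair_labels_from_taxonomy(dict(zip(genomes, labels_list)))
    identities = dict(zip(itertools.combinations(genomes, 2),
                          identities_list))
    return scan_thresholds(identities, labels, **kwargs)


class TestScanThresholds:
    def test_grid_has_201_points(self):
        scan = _toy_scan([98.0, 85.0, 85.0], ["x", "x", "y"])
        assert len(scan.thresholds) == 201
        assert scan.thresholds[0] == 80.0 and scan.thresholds[-1] == 100.0

    def test_translation_equivariance(self):
        base = _toy_scan([93.0, 85.0, 84.0], ["x", "x", "y"],
                         lo=80, hi=99, step=0.1)
        shifted = _toy_scan([94.0, 86.0, 85.0], ["x", "x", "y"],
                            lo=80, hi=99, step=0.1)
        assert shifted.plateau_low == pytest.approx(base.plateau_low + 1.0)
        assert shifted.plateau_high == pytest.approx(base.plateau_high + 1.0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            _toy_scan([98.0, 97.0, 96.0], ["x", "x", "x"])

    def test_matches_brute_force_rescan(self):
        rng = np.random.default_rng(12)
        genomes = [f"g{i}" for i in range(12)]
        species = {g: f"s{rng.integers(0, 3)}" for g in genomes}
        labels = pair_labels_from_taxonomy(species)
        identities = {}
        for g1, g2 in itertools.combinations(genomes, 2):
            base = 97.0 if species[g1] == species[g2] else 88.0
            identities[tuple(sorted((g1, g2)))] = base + rng.normal(0, 2.0)
        scan = scan_thresholds(identities, labels)
        expected = rescan_thresholds_oracle(
            identities, {p: labels[p] for p in labels.pairs()},
            scan.thresholds)
        for idx, (recall, precision, f1) in enumerate(expected):
            assert scan.recall[idx] == pytest.approx(recall)
            assert scan.precision[idx] == pytest.approx(precision)
            assert scan.f1[idx] == pytest.approx(f1)

    def test_relabeling_species_names_does_not_change_f1(self):
        s1 = _toy_scan([97.0, 85.0, 86.0], ["x", "x", "y"])
        s2 = _toy_scan([97.0, 85.0, 86.0], ["blue", "blue", "red"])
        assert np.array_equal(s1.f1, s2.f1)

    def test_unknown_pairs_rejected(self):
        labels = pair_labels_from_taxonomy({"a": "x", "b": "x", "c": "y"})
        with pytest.raises(ValueError, match="lack an identity"):
            scan_thresholds({("a", "b"): 97.0}, labels)


class TestAniLandscape:
    def _df(self, points):
        return pd.DataFrame([{"genome1": f"a{i}", "genome2": f"b{i}",
                              "ani": x, "alignment_fraction": y}
                             for i, (x, y) in enumerate(points)])

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        points = list(zip(rng.normal(95, 1, 200), rng.normal(80, 5, 200)))
        grid = ani_landscape(self._df(points), grid_size=120, pad=6.0)
        assert grid.integral() == pytest.approx(1.0, abs=0.01)
        assert (grid.density >= 0).all()

    def test_two_clusters_show_two_peaks_with_a_saddle(self):
        rng = np.random.default_rng(1)
        cluster1 = zip(rng.normal(99, 0.3, 120), rng.normal(95, 1, 120))
        cluster2 = zip(rng.normal(85, 0.3, 120), rng.normal(40, 1, 120))
        grid = ani_landscape(self._df(list(cluster1) + list(cluster2)),
                             grid_size=200, pad=4.0)
        peak1 = grid.density[np.abs(grid.ani_grid - 99).argmin(),
                             np.abs(grid.af_grid - 95).argmin()]
        peak2 = grid.density[np.abs(grid.ani_grid - 85).argmin(),
                             np.abs(grid.af_grid - 40).argmin()]
        saddle = grid.density[np.abs(grid.ani_grid - 92).argmin(),
                              np.abs(grid.af_grid - 67).argmin()]
        assert saddle < peak1 and saddle < peak2

    def test_point_mass_peaks_at_its_cell(self):
        grid = ani_landscape(self._df([(95.0, 80.0)] * 5), grid_size=50)
        peak = np.unravel_index(grid.density.argmax(), grid.density.shape)
        assert abs(grid.ani_grid[peak[0]] - 95.0) < 1e-5
        assert abs(grid.af_grid[peak[1]] - 80.0) < 1e-5

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        points = list(zip(rng.normal(95, 1, 60), rng.normal(80, 4, 60)))
        df = self._df(points)
        g1 = ani_landscape(df, grid_size=50)
        g2 = ani_landscape(df.sample(frac=1.0, random_state=7), grid_size=50)
        assert np.allclose(g1.density, g2.density, atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ani_landscape(self._df([(95, 80)]))


class TestBinnedMedianCurve:
    def _df(self, anis, hrs, excluded=None):
        n = len(anis)
        return pd.DataFrame({
            "ani": anis, "hr": hrs,
            "dnds": hrs, "a": np.ones(n), "e": np.zeros(n), "i": np.ones(n),
            "excluded_flag": excluded if excluded is not None
            else [False] * n})

    def test_constant_bin_has_degenerate_ci(self):
        df = self._df([95.1] * 8, [0.25] * 8)
        curve = binned_median_curve(df, "hr", seed=1)
        b = np.nanargmax(curve.n)
        assert curve.median[b] == pytest.approx(0.25)
        assert curve.ci_low[b] == pytest.approx(0.25)
        assert curve.ci_high[b] == pytest.approx(0.25)

    def test_small_bins_masked(self):
        df = self._df([90.2, 95.2, 95.3, 95.4], [0.1, 0.2, 0.3, 0.4])
        curve = binned_median_curve(df, "hr", min_n=3, seed=1)
        frame = curve.to_frame()
        low_bin = frame[np.isclose(frame.bin_center, 90.25)]
        assert np.isnan(low_bin["median"]).all()

    def test_excluded_pairs_omitted_from_hr_bins(self):
        df = self._df([95.1] * 6, [0.2] * 3 + [9.9] * 3,
                      excluded=[False] * 3 + [True] * 3)
        curve = binned_median_curve(df, "hr", seed=1)
        b = np.nanargmax(curve.n)
        assert curve.n[b] == 3
        assert curve.median[b] == pytest.approx(0.2)

    def test_ci_brackets_median(self):
        rng = np.random.default_rng(3)
        df = self._df(rng.uniform(94, 96, 200), rng.normal(0.1, 0.05, 200))
        curve = binned_median_curve(df, "hr", seed=2)
        ok = curve.n >= 3
        assert (curve.ci_low[ok] <= curve.median[ok] + 1e-12).all()
        assert (curve.ci_high[ok] >= curve.median[ok] - 1e-12).all()

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            binned_median_curve(self._df([95.0, 95.1], [0, 0]), "banana")
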