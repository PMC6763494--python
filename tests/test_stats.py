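"""Correlation machinery: correlograms, salience maps, clusters, features."""

import math

import numpy as np
import pytest

from pixelpeck.grids import (
    ALL_LOCATIONS,
    SALIENT_H_LOCATIONS,
    SALIENT_Z_LOCATIONS,
    PixelGrid,
    parse_location,
)
from pixelpeck.indices import TestCase, index_breakdown
from pixelpeck.stats import (
    PixelCorrelationMap,
    feature_pair_analysis,
    index_choice_correlation,
    mean_scores,
    pearson_p,
    pearson_r,
    pixelwise_correlation,
    pooled_cluster_correlation,
    salient_clusters,
)


def naive_pearson(x, y):
    """Straight product-moment formula, independent of the implementation."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_binary_regressor_matches_hand_formula(self):
        x = [1, 0, 1, 0, 1]
        y = [90, 55, 80, 60, 85]
        assert pearson_r(x, y) == pytest.approx(naive_pearson(x, y), abs=1e-12)

    def test_constant_input_masked(self):
        assert math.isnan(pearson_r([1, 1, 1], [1, 2, 3]))

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r = pearson_r(x, y)
        assert pearson_r(2.5 * x + 7, y) == pytest.approx(r, abs=1e-12)
        assert pearson_r(-x, y) == pytest.approx(-r, abs=1e-12)

    @pytest.mark.parametrize(
        "r,n,bound",
        [(0.30, 84, 0.01), (0.40, 84, 0.0005), (0.68, 84, 0.0001)],
    )
    def test_significance_bounds_at_n84(self, r, n, bound):
        assert 0 < pearson_p(r, n) < bound

    def test_null_and_degenerate_p(self):
        assert pearson_p(0.0, 84) == pytest.approx(1.0)
        assert pearson_p(1.0, 84) == 0.0

    def test_p_monotone_in_r_and_n(self):
        rs = np.linspace(0.05, 0.9, 12)
        ps = [pearson_p(r, 30) for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        ns = range(5, 100, 7)
        ps = [pearson_p(0.3, n) for n in ns]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestIndexChoiceCorrelation:
    def test_affine_scores_give_unit_r(self, experiment, class_map):
        cases = experiment.cases
        vals = {
            c.test_id: 50 + 2.5 * index_breakdown(c, class_map).index_base
            for c in cases
        }
        r, p, n = index_choice_correlation(cases, vals, "base", class_map)
        assert r == pytest.approx(1.0)
        assert n == len(cases)

    def test_shuffled_scores_match_permutation_p(self, experiment, class_map):
        """The analytic two-sided p agrees with a permutation p to within
        Monte-Carlo error for seeded, shuffled scores."""
        rng = np.random.default_rng(7)
        cases = experiment.cases[:40]
        idx = np.array([
            index_breakdown(c, class_map).index_base for c in cases
        ], dtype=float)
        y = rng.permutation(np.linspace(50, 100, len(cases)))
        r_obs = pearson_r(idx, y)
        p_analytic = pearson_p(r_obs, len(cases))
        n_perm = 2000
        centred_x = idx - idx.mean()
        centred_x /= np.linalg.norm(centred_x)
        hits = 0
        for _ in range(n_perm):
            yy = rng.permutation(y)
            yc = yy - yy.mean()
            r_perm = float(centred_x @ (yc / np.linalg.norm(yc)))
            if abs(r_perm) >= abs(r_obs) - 1e-12:
                hits += 1
        p_mc = hits / n_perm
        assert abs(p_mc - p_analytic) < 4 * math.sqrt(p_analytic * (1 - p_analytic) / n_perm) + 0.02

    def test_default_suite_band(self, experiment, scores):
        r, p, n = index_choice_correlation(
            experiment.cases, scores, "base", experiment.class_map
        )
        assert 0.5 <= r <= 0.95 and p < 1e-5


class TestPixelwiseMap:
    def test_matches_naive_double_loop(self, experiment, scores):
        cmap = pixelwise_correlation(experiment.cases, scores, "Z")
        y = [scores[c.test_id] for c in experiment.cases]
        for loc in ALL_LOCATIONS:
            x = [1 if c.grid_Zlike.is_lit(loc) else 0 for c in experiment.cases]
            row, col = parse_location(loc)
            if len(set(x)) < 2:
                assert cmap.masked[row - 1, col - 1]
            else:
                assert cmap.value(loc) == pytest.approx(naive_pearson(x, y), abs=1e-10)

    def test_constant_location_masked(self, class_map):
        always = PixelGrid.from_locations(["iv3"])
        grids = [
            PixelGrid.from_locations(["iv3", loc]) for loc in ("ii1", "ii2", "vi2")
        ]
        cases = [
            TestCase(i + 1, g, PixelGrid.from_locations(["iv1"]))
            for i, g in enumerate(grids)
        ]
        cmap = pixelwise_correlation(cases, {1: 60.0, 2: 70.0, 3: 80.0}, "Z")
        assert cmap.masked[3, 2]  # iv3 lit in every test

    def test_perfectly_predictive_pixel(self, class_map):
        lit = PixelGrid.from_locations(["ii1", "iv3"])
        unlit = PixelGrid.from_locations(["iv3"])
        cases = [
            TestCase(i + 1, lit if s == 100 else unlit, PixelGrid.empty())
            for i, s in enumerate([100, 50, 100, 50])
        ]
        cmap = pixelwise_correlation(
            cases, {1: 100.0, 2: 50.0, 3: 100.0, 4: 50.0}, "Z"
        )
        assert cmap.value("ii1") == pytest.approx(1.0)


def synthetic_map(locations, side, r_value=0.5):
    """Synthetic stand-in salience map: supra-threshold r at the given
    locations, zero elsewhere (no figure-derived coefficients involved)."""
    r = np.zeros((7, 5))
    for loc in locations:
        row, col = parse_location(loc)
        r[row - 1, col - 1] = r_value
    return PixelCorrelationMap(
        r=r, p=np.full((7, 5), 0.5), n=84,
        masked=np.zeros((7, 5), dtype=bool), side=side,
    )


class TestClusters:
    def test_all_subthreshold_is_empty(self):
        cs = salient_clusters(synthetic_map([], "Z"))
        assert len(cs) == 0 and cs.locations == frozenset()

    def test_single_location_is_singleton(self):
        cs = salient_clusters(synthetic_map(["iv2"], "Z"))
        assert [set(c) for c in cs.clusters] == [{"iv2"}]

    def test_salient_z_geometry_four_clusters(self):
        """The 8 salient z locations split into 4 two-pixel clusters."""
        cs = salient_clusters(synthetic_map(SALIENT_Z_LOCATIONS, "Z"))
        assert len(cs) == 4
        assert cs.locations == frozenset(SALIENT_Z_LOCATIONS)
        assert sorted(map(len, cs.clusters)) == [2, 2, 2, 2]

    def test_salient_h_geometry_two_clusters(self):
        """The 6 salient h locations split into 2 three-pixel clusters."""
        cs = salient_clusters(synthetic_map(SALIENT_H_LOCATIONS, "H"))
        assert len(cs) == 2
        assert sorted(map(len, cs.clusters)) == [3, 3]

    def test_partition_and_maximality(self, experiment, scores):
        cmap = pixelwise_correlation(experiment.cases, scores, "Z")
        cs = salient_clusters(cmap)
        supra = {
            loc for loc in ALL_LOCATIONS
            if not np.isnan(cmap.value(loc)) and cmap.value(loc) >= 0.30
        }
        assert cs.locations == frozenset(supra)
        # disjoint, and no two clusters touch under 8-connectivity
        seen = set()
        for c in cs.clusters:
            assert not (c & seen)
            seen |= c
        for i, a in enumerate(cs.clusters):
            for b in cs.clusters[i + 1:]:
                dist = min(
                    max(abs(parse_location(p)[0] - parse_location(q)[0]),
                        abs(parse_location(p)[1] - parse_location(q)[1]))
                    for p in a for q in b
                )
                assert dist >= 2


class TestPooledClusters:
    def test_singleton_reduces_to_pixel_r(self, experiment, scores):
        cmap = pixelwise_correlation(experiment.cases, scores, "Z")
        r, p = pooled_cluster_correlation(experiment.cases, scores, ["ii2"], "Z")
        assert r == pytest.approx(cmap.value("ii2"), abs=1e-10)

    def test_colit_pair_scale_invariance(self):
        """Two always-co-lit pixels pool to twice an indicator: same r."""
        both = PixelGrid.from_locations(["ii1", "ii2"])
        cases = [
            TestCase(i + 1, both if s else PixelGrid.from_locations(["vi4"]),
                     PixelGrid.empty())
            for i, s in enumerate([1, 0, 1, 0, 1])
        ]
        sc = {1: 90.0, 2: 55.0, 3: 80.0, 4: 60.0, 5: 85.0}
        r_pool, _ = pooled_cluster_correlation(cases, sc, ["ii1", "ii2"], "Z")
        r_single, _ = pooled_cluster_correlation(cases, sc, ["ii1"], "Z")
        assert r_pool == pytest.approx(r_single, abs=1e-12)

    def test_planted_cluster_pooling_improves_r(self, experiment, scores):
        """Pooling two planted salient neighbours should not fall below the
        weaker member's individual r (averaging out indicator noise)."""
        cmap = pixelwise_correlation(experiment.cases, scores, "Z")
        r_pool, _ = pooled_cluster_correlation(
            experiment.cases, scores, ["ii1", "ii2"], "Z"
        )
        assert r_pool >= min(cmap.value("ii1"), cmap.value("ii2")) - 1e-9


class TestFeaturePairs:
    def test_always_colit_pair_equals_single_pixel_r(self, experiment, scores):
        res = feature_pair_analysis(
            experiment.cases, scores, SALIENT_Z_LOCATIONS, SALIENT_H_LOCATIONS,
            seed=3,
        )
        assert res["n_neighbouring"] > 0 and res["n_control"] > 0
        assert abs(res["mean_r_neighbouring"]) <= 1
        assert abs(res["mean_r_control"]) <= 1

    def test_no_configural_effect_means_similar(self, experiment, scores):
        """Without a planted two-pixel bonus the neighbouring and control
        mean correlations stay close."""
        res = feature_pair_analysis(
            experiment.cases, scores, SALIENT_Z_LOCATIONS, SALIENT_H_LOCATIONS,
            seed=11,
        )
        assert abs(res["mean_r_neighbouring"] - res["mean_r_control"]) < 0.25

    def test_planted_configural_bonus_detected(self, experiment):
        """A score bonus whenever ii1+ii2 are co-lit raises that feature's r
        above both members' individual correlations."""
        cases = experiment.cases
        rng = np.random.default_rng(5)
        sc = {}
        for c in cases:
            bonus = 30.0 if (c.grid_Zlike.is_lit("ii1") and c.grid_Zlike.is_lit("ii2")) else 0.0
            sc[c.test_id] = 50.0 + bonus + rng.normal(0, 5)
        y = [sc[c.test_id] for c in cases]
        pair_ind = [
            1.0 if (c.grid_Zlike.is_lit("ii1") and c.grid_Zlike.is_lit("ii2")) else 0.0
            for c in cases
        ]
        r_pair = pearson_r(pair_ind, y)
        for loc in ("ii1", "ii2"):
            x = [1.0 if c.grid_Zlike.is_lit(loc) else 0.0 for c in cases]
            assert r_pair > pearson_r(x, y)
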