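"""Replication, relativity, concordance and inter-individual analyses."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from pixelpeck.cohort import (
    binomial_test,
    interindividual_correlations,
    part_repeat_table,
    replication_table,
    team_concordance,
)
from pixelpeck.grids import PixelGrid
from pixelpeck.indices import TestCase
from pixelpeck.simulate import SimulationConfig, simulate_experiment
from pixelpeck.stats import ChoiceRecord, mean_scores


def exact_binomial_upper(k, n):
    """Exhaustive fair-coin tail probability in exact rational arithmetic."""
    return Fraction(sum(comb(n, j) for j in range(k, n + 1)), 2 ** n)


class TestBinomial:
    def test_headline_tallies(self):
        assert binomial_test(69, 84) < 0.0001
        assert binomial_test(0, 84) == pytest.approx(1.0)
        # exact: sum_{j>=21} C(30,j) / 2^30
        assert binomial_test(21, 30) == pytest.approx(
            float(exact_binomial_upper(21, 30)), rel=1e-12
        )
        assert binomial_test(21, 30) < 0.05

    def test_two_sided_doubles_smaller_tail(self):
        one = binomial_test(15, 20, sided="one")
        two = binomial_test(15, 20, sided="two")
        assert two == pytest.approx(min(1.0, 2 * one))

    def test_spot_checks_against_enumeration(self):
        for k, n in [(3, 5), (10, 17), (0, 8), (20, 20), (7, 13)]:
            assert binomial_test(k, n) == pytest.approx(
                float(exact_binomial_upper(k, n)), rel=1e-12
            )

    def test_invalid_tally_rejected(self):
        with pytest.raises(ValueError):
            binomial_test(5, 4)


def _two_cases(score1, score2, s1=5, s2=33):
    g1 = PixelGrid.from_locations(["ii1", "iv1"])
    g2 = PixelGrid.from_locations(["iv2", "v1"])
    first = TestCase(1, g1, g2, session=s1)
    second = TestCase(2, g1, g2, session=s2, repeat_of=1)
    return [first, second], {1: score1, 2: score2}


class TestReplication:
    def test_identical_scores_zero_difference(self):
        cases, sc = _two_cases(75.0, 75.0)
        table, summary = replication_table(cases, sc)
        assert len(table) == 1
        assert table.loc[0, "difference"] == 0.0

    def test_constructed_difference_and_gap(self):
        cases, sc = _two_cases(80.0, 62.0)
        table, _ = replication_table(cases, sc)
        assert table.loc[0, "difference"] == -18.0
        assert table.loc[0, "gap"] == 28

    def test_backwards_repeat_rejected(self):
        cases, sc = _two_cases(80.0, 62.0, s1=33, s2=5)
        with pytest.raises(ValueError):
            replication_table(cases, sc)

    def test_planted_drift_recovered(self, experiment):
        """Second presentations scored 5 points lower (plus noise) yield a
        mean difference near -5."""
        rng = np.random.default_rng(99)
        sc = {}
        for c in experiment.cases:
            if c.repeat_of is None:
                sc[c.test_id] = float(rng.uniform(55, 95))
            else:
                sc[c.test_id] = sc[c.repeat_of] - 5.0 + float(rng.normal(0, 2))
        table, summary = replication_table(experiment.cases, sc)
        assert summary["n_repetitions"] == 19
        assert summary["mean_difference"] == pytest.approx(-5.0, abs=2.0)

    def test_null_mean_difference_centred_on_zero(self, experiment):
        """Exchangeable scores give a mean difference of 0 in expectation
        (checked over 200 seeded replicates against a CLT band)."""
        rng = np.random.default_rng(2024)
        diffs = []
        for _ in range(200):
            sc = {c.test_id: float(rng.uniform(50, 100)) for c in experiment.cases}
            _, summary = replication_table(experiment.cases, sc)
            diffs.append(summary["mean_difference"])
        # each mean-diff averages 19 iid differences with sd ~ sqrt(2)*sd(U)
        sd_single = np.sqrt(2) * (50 / np.sqrt(12)) / np.sqrt(19)
        assert abs(np.mean(diffs)) < 4 * sd_single / np.sqrt(200)


class TestPartRepeats:
    def test_same_pattern_same_partner_no_flip(self):
        cases, sc = _two_cases(70.0, 70.0)
        table = part_repeat_table(cases, sc)
        same_partner = table[~table["partner_changed"]]
        assert (same_partner["change"] == 0.0).all()
        assert not same_partner["flip"].any()

    def test_relativity_triple_flags_two_flips(self):
        """A pattern judged barely H-like (54 %), then clearly Z-like (91 %),
        then barely H-like again (53 %) flips preference twice."""
        x = PixelGrid.from_locations(["iii3", "iv3", "v3"])
        z_partner = PixelGrid.from_locations(["ii1", "ii2"])
        h_partner = PixelGrid.from_locations(["iv1", "iv2"])
        cases = [
            TestCase(10, z_partner, x, session=10),  # x as H-like, 54 %
            TestCase(15, x, h_partner, session=15),  # x as Z-like, 91 %
            TestCase(18, z_partner, x, session=18),  # x as H-like, 53 %
        ]
        sc = {10: 54.0, 15: 91.0, 18: 53.0}
        table = part_repeat_table(cases, sc)
        x_rows = table[table["pattern_key"] == x.key()]
        assert len(x_rows) == 2
        assert x_rows["flip"].all()

    def test_flip_count_matches_naive_recount(self, experiment, scores):
        table = part_repeat_table(experiment.cases, scores)
        naive = 0
        for _, row in table.iterrows():
            naive += (row["first_pref"] - 50) * (row["second_pref"] - 50) < 0
        assert int(table["flip"].sum()) == naive


def _team_frame(z_scores, h_scores):
    return pd.DataFrame({
        "Z+H-": z_scores, "H+Z-": h_scores,
    }, index=range(1, len(z_scores) + 1))


class TestConcordance:
    def test_unanimous_tests(self):
        res = team_concordance(_team_frame([100.0] * 10, [100.0] * 10))
        assert res.k_concordant == 10
        assert res.p_value == pytest.approx(2.0 ** -10)

    def test_split_teams_not_concordant(self):
        res = team_concordance(_team_frame([60.0], [40.0]))
        assert res.k_concordant == 0

    def test_exact_fifty_breaks_concordance(self):
        res = team_concordance(_team_frame([50.0, 80.0], [80.0, 80.0]))
        assert res.k_concordant == 1

    def test_relabel_invariance(self, experiment):
        """Swapping which pattern counts as correct on a test (for both
        teams at once) leaves the concordance count unchanged."""
        team_scores = mean_scores(experiment.records, by="team")
        base = team_concordance(team_scores).k_concordant
        flipped = team_scores.copy()
        flipped.iloc[::3] = 100.0 - flipped.iloc[::3]
        assert team_concordance(flipped).k_concordant == base

    def test_shared_weights_agree_independent_weights_guess(self):
        shared = simulate_experiment(SimulationConfig(seed=21, n_tests=40))
        res = team_concordance(mean_scores(shared.records, by="team"))
        assert res.k_concordant / res.n_tests > 0.8
        noise = simulate_experiment(SimulationConfig(
            seed=21, n_tests=40, salient_weight=0.0, base_weight=0.0,
            ambiguous_weight=0.0, team_jitter_scale=1.0, jitter_scale=0.0,
        ))
        res0 = team_concordance(mean_scores(noise.records, by="team"))
        assert 0.2 <= res0.k_concordant / res0.n_tests <= 0.8

    def test_missing_team_rejected(self):
        with pytest.raises(ValueError):
            team_concordance(pd.DataFrame({"Z+H-": [60.0]}))


class TestInterindividual:
    def test_identical_birds_correlate_perfectly(self):
        records = []
        rng = np.random.default_rng(0)
        tallies = rng.integers(5, 20, size=12)
        for pid in ("p1", "p2"):
            for t, k in enumerate(tallies, start=1):
                records.append(ChoiceRecord(t, pid, "Z+H-", 20, int(k)))
        mat, summary = interindividual_correlations(records)
        assert mat.loc["p1", "p1"] == 1.0
        assert mat.loc["p1", "p2"] == pytest.approx(1.0)

    def test_default_cohort_team_structure(self, experiment):
        mat, summary = interindividual_correlations(experiment.records)
        assert summary["n_pairs"] == 15
        assert summary["mean_r_within_team"] > summary["mean_r_between_team"]

    def test_too_few_shared_tests_masked(self):
        records = [
            ChoiceRecord(1, "p1", "Z+H-", 20, 10),
            ChoiceRecord(2, "p1", "Z+H-", 20, 15),
            ChoiceRecord(1, "p2", "H+Z-", 20, 12),
            ChoiceRecord(2, "p2", "H+Z-", 20, 18),
        ]
        mat, _ = interindividual_correlations(records)
        assert np.isnan(mat.loc["p1", "p2"])
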