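"""Replication, relativity, team-concordance and inter-individual analyses.

These operate on per-test choice scores aggregated from the six-bird cohort
(two three-bird teams with opposite reward assignments). Concordance across
teams is assessed with an exact binomial test, replication consistency with
score differences across repeat presentations, and individual agreement
with pairwise Pearson correlations of the per-bird score vectors.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indices import TestCase
from .stats import TEAMS, ChoiceRecord, mean_scores, pearson_p, pearson_r


# ---------------------------------------------------------------------------
# Exact binomial test
# ---------------------------------------------------------------------------


def binomial_test(
    k: int, n: int, p0: float = 0.5, sided: str = "one"
) -> float:
    """Exact binomial tail probability.

    One-sided upper tail P(X >= k) by default; ``sided="two"`` doubles the
    smaller tail, capped at 1. Exact summation throughout (no normal
    approximation).
    """
    if not (0 <= k <= n):
        raise ValueError(f"invalid tally k={k}, n={n}")
    if sided == "one":
        return float(sps.binomtest(k, n, p=p0, alternative="greater").pvalue)
    if sided == "two":
        upper = sps.binom.sf(k - 1, n, p0)
        lower = sps.binom.cdf(k, n, p0)
        return float(min(1.0, 2.0 * min(upper, lower)))
    raise ValueError("sided must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# Replications
# ---------------------------------------------------------------------------


def replication_table(
    cases: Sequence[TestCase],
    scores: Mapping[int, float] | pd.Series,
) -> tuple[pd.DataFrame, dict]:
    """One row per repeat event (linked via ``TestCase.repeat_of``).

    The difference is later minus earlier score, in percent points; the
    summary reports the mean difference and the Pearson r (with p) between
    the differences and the session gaps.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    by_id = {c.test_id: c for c in cases}
    rows = []
    for case in cases:
        if case.repeat_of is None:
            continue
        earlier = by_id.get(case.repeat_of)
        if earlier is None:
            raise ValueError(
                f"test {case.test_id} repeats unknown test {case.repeat_of}"
            )
        gap = case.session - earlier.session
        if gap <= 0:
            raise ValueError(
                f"test {case.test_id} repeats test {earlier.test_id} "
                f"from a later or equal session"
            )
        rows.append({
            "pair_key": earlier.grid_Zlike.key() + "|" + earlier.grid_Hlike.key(),
            "first_test_id": earlier.test_id,
            "second_test_id": case.test_id,
            "first_score": float(scores[earlier.test_id]),
            "second_score": float(scores[case.test_id]),
            "difference": float(scores[case.test_id]) - float(scores[earlier.test_id]),
            "gap": gap,
        })
    table = pd.DataFrame(
        rows,
        columns=["pair_key", "first_test_id", "second_test_id",
                 "first_score", "second_score", "difference", "gap"],
    )
    summary: dict = {"n_repetitions": len(table)}
    if len(table):
        summary["mean_difference"] = float(table["difference"].mean())
    if len(table) >= 3 and table["difference"].nunique() > 1 and table["gap"].nunique() > 1:
        r = pearson_r(table["difference"].to_numpy(), table["gap"].to_numpy())
        summary["r_difference_vs_gap"] = r
        summary["p_difference_vs_gap"] = pearson_p(r, len(table))
    return table, summary


def part_repeat_table(
    cases: Sequence[TestCase],
    scores: Mapping[int, float] | pd.Series,
) -> pd.DataFrame:
    """Score changes for single patterns re-presented with changed partners.

    Pattern identity is bit-exact grid equality (content-addressed). For a
    recurring pattern, its per-test preference score is the pair score when
    it sits on its first-appearance side's class and ``100 - score`` when it
    reappears designated as the other class. A flip is a crossing of the
    50 % line between consecutive appearances (preference turning into
    avoidance or vice versa).
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    appearances: dict[str, list] = {}
    for case in sorted(cases, key=lambda c: c.session):
        appearances.setdefault(case.grid_Zlike.key(), []).append((case, "Z"))
        appearances.setdefault(case.grid_Hlike.key(), []).append((case, "H"))

    rows = []
    for key, occs in appearances.items():
        if len(occs) < 2:
            continue
        ref_class = occs[0][1]
        prefs = []
        for case, side in occs:
            s = float(scores[case.test_id])
            prefs.append((case, side, s if side == ref_class else 100.0 - s))
        for (c1, side1, p1), (c2, side2, p2) in zip(prefs, prefs[1:]):
            partner_changed = (
                (c1.grid_Hlike if side1 == "Z" else c1.grid_Zlike)
                != (c2.grid_Hlike if side2 == "Z" else c2.grid_Zlike)
            )
            rows.append({
                "pattern_key": key,
                "first_test_id": c1.test_id,
                "second_test_id": c2.test_id,
                "first_side": side1,
                "second_side": side2,
                "partner_changed": partner_changed,
                "first_pref": p1,
                "second_pref": p2,
                "change": p2 - p1,
                "flip": (p1 - 50.0) * (p2 - 50.0) < 0,
            })
    return pd.DataFrame(
        rows,
        columns=["pattern_key", "first_test_id", "second_test_id",
                 "first_side", "second_side", "partner_changed",
                 "first_pref", "second_pref", "change", "flip"],
    )


# ---------------------------------------------------------------------------
# Team concordance
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ConcordanceResult:
    n_tests: int
    k_concordant: int
    p_value: float
    team_means: pd.DataFrame  # test_id x team percent-correct means

    def __post_init__(self):
        if self.k_concordant > self.n_tests:
            raise ValueError("k cannot exceed n")


def team_concordance(
    team_scores: pd.DataFrame,
    sided: str = "one",
) -> ConcordanceResult:
    """Count tests where both teams' mean percent-correct lies strictly on
    the same side of 50 %.

    ``team_scores`` is a test x team DataFrame of mean percent-correct (as
    produced by :func:`pixelpeck.stats.mean_scores` with ``by="team"``). A
    team mean of exactly 50 counts as no preference, hence not concordant.
    An exact one-sided binomial test against chance agreement is attached.
    """
    missing = [t for t in TEAMS if t not in team_scores.columns]
    if missing:
        raise ValueError(f"missing team column(s): {missing}")
    if team_scores[list(TEAMS)].isna().any().any():
        raise ValueError("both teams must be scored on every included test")
    a = team_scores[TEAMS[0]].to_numpy() - 50.0
    b = team_scores[TEAMS[1]].to_numpy() - 50.0
    concordant = (a * b) > 0
    n = len(team_scores)
    k = int(concordant.sum())
    return ConcordanceResult(
        n_tests=n,
        k_concordant=k,
        p_value=binomial_test(k, n, 0.5, sided=sided),
        team_means=team_scores.copy(),
    )


def team_concordance_from_records(
    records: Iterable[ChoiceRecord], sided: str = "one"
) -> ConcordanceResult:
    return team_concordance(mean_scores(records, by="team"), sided=sided)


# ---------------------------------------------------------------------------
# Inter-individual correlations
# ---------------------------------------------------------------------------


def interindividual_correlations(
    records: Iterable[ChoiceRecord],
) -> tuple[pd.DataFrame, dict]:
    """Pairwise Pearson r of per-bird score vectors over shared tests.

    Returns the pigeon x pigeon correlation matrix and summary means over
    all pairs, within-team pairs, and between-team pairs. Pairs with fewer
    than 3 shared tests (or constant scores) are masked (NaN).
    """
    records = list(records)
    per_pigeon = mean_scores(records, by="pigeon_id")
    teams = {r.pigeon_id: r.team for r in records}
    pigeons = list(per_pigeon.columns)
    if len(pigeons) < 2:
        raise ValueError("need at least 2 pigeons")
    mat = pd.DataFrame(np.eye(len(pigeons)), index=pigeons, columns=pigeons)
    all_rs, within, between = [], [], []
    for a, b in itertools.combinations(pigeons, 2):
        sub = per_pigeon[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            r = float("nan")
        else:
            r = pearson_r(sub[a].to_numpy(), sub[b].to_numpy())
        mat.loc[a, b] = mat.loc[b, a] = r
        if not np.isnan(r):
            all_rs.append(r)
            (within if teams[a] == teams[b] else between).append(r)
    summary = {
        "mean_r_all": float(np.mean(all_rs)) if all_rs else float("nan"),
        "mean_r_within_team": float(np.mean(within)) if within else float("nan"),
        "mean_r_between_team": float(np.mean(between)) if between else float("nan"),
        "n_pairs": len(all_rs),
    }
    return mat, summary
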