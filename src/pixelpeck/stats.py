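"""Correlation machinery: index/choice correlograms, pixel-wise salience
maps (classification images), cluster extraction and pooling, and two-pixel
feature analysis.

All correlations are plain product-moment (Pearson) coefficients; with a
binary 0/1 regressor this is exactly the point-biserial case, so a single
routine serves both the index correlograms and the pixel-wise maps.
Two-sided p-values come from the t transform ``t = r * sqrt(n-2) /
sqrt(1-r^2)`` on ``n-2`` degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .grids import (
    N_COLS,
    N_ROWS,
    PixelClassMap,
    location_name,
    parse_location,
)
from .indices import INDEX_VARIANTS, TestCase, index_breakdown

TEAMS = ("Z+H-", "H+Z-")


@dataclasses.dataclass(frozen=True)
class ChoiceRecord:
    """One pigeon's choice tally on one test.

    ``n_correct`` counts choices of the designated unreinforced pattern
    matching the bird's rewarded class (Z-like for the Z+H- team, H-like
    for the H+Z- team).
    """

    test_id: int
    pigeon_id: str
    team: str
    n_trials: int
    n_correct: int

    def __post_init__(self):
        if self.team not in TEAMS:
            raise ValueError(f"unknown team label {self.team!r}")
        if not (0 <= self.n_correct <= self.n_trials):
            raise ValueError(
                f"n_correct {self.n_correct} outside [0, {self.n_trials}]"
            )

    @property
    def percent_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_trials


# ---------------------------------------------------------------------------
# Score aggregation
# ---------------------------------------------------------------------------


def records_frame(records: Iterable[ChoiceRecord]) -> pd.DataFrame:
    rows = [
        {
            "test_id": r.test_id, "pigeon_id": r.pigeon_id, "team": r.team,
            "n_trials": r.n_trials, "n_correct": r.n_correct,
            "percent_correct": r.percent_correct,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def mean_scores(
    records: Iterable[ChoiceRecord],
    by: Optional[str] = None,
    pooled: bool = False,
) -> pd.Series | pd.DataFrame:
    """Per-test percent-correct scores.

    By default the unweighted mean of the per-pigeon percentages (the
    conventional 6-bird average). ``pooled=True`` instead divides summed
    correct tallies by summed trials. ``by="team"`` or ``by="pigeon_id"``
    returns a test x group DataFrame.
    """
    df = records_frame(records)
    if df.empty:
        raise ValueError("no choice records")
    keys = ["test_id"] + ([by] if by else [])
    if pooled:
        g = df.groupby(keys)[["n_correct", "n_trials"]].sum()
        out = 100.0 * g["n_correct"] / g["n_trials"]
    else:
        out = df.groupby(keys)["percent_correct"].mean()
    if by:
        return out.unstack(by)
    return out


# ---------------------------------------------------------------------------
# Pearson machinery
# ---------------------------------------------------------------------------


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN for constant input (masked downstream)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def pearson_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n via the t transform."""
    if n < 3:
        raise ValueError("need n >= 3")
    if math.isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _aligned_scores(
    cases: Sequence[TestCase], scores: Mapping[int, float] | pd.Series
) -> np.ndarray:
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    try:
        return np.array([float(scores[c.test_id]) for c in cases])
    except KeyError as exc:
        raise KeyError(f"no score for test_id {exc.args[0]}") from None


def index_choice_correlation(
    cases: Sequence[TestCase],
    scores: Mapping[int, float] | pd.Series,
    variant: str = "base",
    class_map: Optional[PixelClassMap] = None,
    adjust_translocation: bool = False,
    **kwargs,
) -> tuple[float, float, int]:
    """Pearson r (with p and n) between an index variant and choice scores.

    ``variant`` is one of :data:`~pixelpeck.indices.INDEX_VARIANTS`;
    ``base_adjusted`` is shorthand for the base index with translocation
    adjustment on.
    """
    if variant == "base_adjusted":
        variant, adjust_translocation = "base", True
    if variant not in INDEX_VARIANTS:
        raise ValueError(f"unknown index variant {variant!r}")
    if class_map is None:
        raise ValueError("a class map is required")
    if len(cases) < 3:
        raise ValueError("need at least 3 tests")
    vals = np.array([
        index_breakdown(c, class_map, adjust_translocation, **kwargs).value(variant)
        for c in cases
    ], dtype=float)
    y = _aligned_scores(cases, scores)
    r = pearson_r(vals, y)
    if math.isnan(r):
        raise ValueError(f"index variant {variant!r} is constant over these tests")
    return r, pearson_p(r, len(cases)), len(cases)


# ---------------------------------------------------------------------------
# Pixel-wise salience maps
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PixelCorrelationMap:
    """Per-location point-biserial correlation map (classification image)."""

    r: np.ndarray  # (7, 5) float; NaN where masked
    p: np.ndarray  # (7, 5) float; NaN where masked
    n: int
    masked: np.ndarray  # (7, 5) bool; True where the pixel never varied
    side: str  # "Z" or "H"

    def value(self, name: str) -> float:
        row, col = parse_location(name)
        return float(self.r[row - 1, col - 1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rr in range(N_ROWS):
            for cc in range(N_COLS):
                name = location_name(rr + 1, cc + 1)
                rows.append({
                    "row_label": name[:-1], "col": cc + 1, "side": self.side,
                    "r": None if self.masked[rr, cc] else float(self.r[rr, cc]),
                    "p": None if self.masked[rr, cc] else float(self.p[rr, cc]),
                    "n": self.n, "masked": bool(self.masked[rr, cc]),
                })
        return pd.DataFrame(rows)


def pixelwise_correlation(
    cases: Sequence[TestCase],
    scores: Mapping[int, float] | pd.Series,
    side: str = "Z",
    registration: Optional[PixelClassMap] = None,
    max_shift: tuple[int, int] = (2, 2),
) -> PixelCorrelationMap:
    """Correlate each location's lit indicator (on one pair side) with scores.

    Locations that never vary (always or never lit across the suite) are
    masked rather than assigned r = 0. Passing a class map as
    ``registration`` first registers each member against its training
    reference (pattern-centred coordinates).
    """
    if len(cases) < 3:
        raise ValueError("need at least 3 tests")
    if side not in ("Z", "H"):
        raise ValueError("side must be 'Z' or 'H'")
    y = _aligned_scores(cases, scores)
    indicators = np.zeros((len(cases), N_ROWS, N_COLS))
    from .grids import register_to_reference  # local to avoid cycle at import

    for i, case in enumerate(cases):
        grid = case.grid_Zlike if side == "Z" else case.grid_Hlike
        if registration is not None:
            ref = registration.pair.grid_Z if side == "Z" else registration.pair.grid_H
            grid = register_to_reference(grid, ref, max_shift).aligned
        indicators[i] = grid.cells

    r = np.full((N_ROWS, N_COLS), np.nan)
    p = np.full((N_ROWS, N_COLS), np.nan)
    masked = np.zeros((N_ROWS, N_COLS), dtype=bool)
    for rr in range(N_ROWS):
        for cc in range(N_COLS):
            x = indicators[:, rr, cc]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                masked[rr, cc] = True
                continue
            r[rr, cc] = pearson_r(x, y)
            p[rr, cc] = pearson_p(r[rr, cc], len(cases))
    return PixelCorrelationMap(r=r, p=p, n=len(cases), masked=masked, side=side)


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ClusterSet:
    """Maximal 8-connected components of supra-threshold map locations."""

    clusters: tuple[frozenset, ...]
    r_threshold: float
    connectivity: int
    side: str

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def locations(self) -> frozenset:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def to_json(self) -> str:
        return json.dumps({
            "side": self.side,
            "r_threshold": self.r_threshold,
            "connectivity": self.connectivity,
            "clusters": [sorted(c) for c in self.clusters],
        }, indent=2)


_STRUCTURE = {8: np.ones((3, 3), dtype=int), 4: ndimage.generate_binary_structure(2, 1)}


def salient_clusters(
    corr_map: PixelCorrelationMap,
    r_threshold: float = 0.30,
    connectivity: int = 8,
) -> ClusterSet:
    """Group supra-threshold locations (r >= threshold) into connected clusters."""
    if connectivity not in _STRUCTURE:
        raise ValueError("connectivity must be 4 or 8")
    supra = np.where(np.isnan(corr_map.r), False, corr_map.r >= r_threshold)
    labels, n_clusters = ndimage.label(supra, structure=_STRUCTURE[connectivity])
    clusters = []
    for k in range(1, n_clusters + 1):
        rr, cc = np.nonzero(labels == k)
        clusters.append(frozenset(location_name(r + 1, c + 1) for r, c in zip(rr, cc)))
    return ClusterSet(
        clusters=tuple(clusters),
        r_threshold=r_threshold,
        connectivity=connectivity,
        side=corr_map.side,
    )


def pooled_cluster_correlation(
    cases: Sequence[TestCase],
    scores: Mapping[int, float] | pd.Series,
    cluster: Iterable[str],
    side: str = "Z",
) -> tuple[float, float]:
    """Correlate the per-test count of lit cluster members with scores."""
    cluster = list(cluster)
    if not cluster:
        raise ValueError("cluster must be non-empty")
    y = _aligned_scores(cases, scores)
    counts = []
    for case in cases:
        grid = case.grid_Zlike if side == "Z" else case.grid_Hlike
        counts.append(sum(1 for loc in cluster if grid.is_lit(loc)))
    r = pearson_r(np.array(counts, dtype=float), y)
    if math.isnan(r):
        raise ValueError("pooled cluster count is constant over these tests")
    return r, pearson_p(r, len(cases))


# ---------------------------------------------------------------------------
# Two-pixel feature analysis
# ---------------------------------------------------------------------------


def _chebyshev(a: str, b: str) -> int:
    ra, ca = parse_location(a)
    rb, cb = parse_location(b)
    return max(abs(ra - rb), abs(ca - cb))


def _pair_r(
    cases: Sequence[TestCase], y: np.ndarray, pair: tuple[str, str], side: str
) -> float:
    ind = []
    for case in cases:
        grid = case.grid_Zlike if side == "Z" else case.grid_Hlike
        ind.append(1.0 if (grid.is_lit(pair[0]) and grid.is_lit(pair[1])) else 0.0)
    return pearson_r(np.array(ind), y)


def feature_pair_analysis(
    cases: Sequence[TestCase],
    scores: Mapping[int, float] | pd.Series,
    select_Z: Sequence[str],
    select_H: Sequence[str],
    n_pairs: int = 14,
    seed: int = 0,
) -> dict:
    """Compare neighbouring vs non-neighbouring conjointly-lit pixel pairs.

    A "feature" is two same-class salient pixels that are vertical,
    horizontal or diagonal neighbours, scored 1 on a test iff both are lit
    in the relevant member. Control pairs are same-class pairs at Chebyshev
    distance >= 2, sampled with the given seed. Returns the mean feature r,
    the mean control r, and the pair lists used (pairs whose indicator never
    varies are skipped).
    """
    if not select_Z or not select_H:
        raise ValueError("select sets must be non-empty")
    y = _aligned_scores(cases, scores)
    rng = np.random.default_rng(seed)

    def same_class_pairs(locs, pred):
        locs = sorted(locs)
        return [
            (a, b)
            for i, a in enumerate(locs)
            for b in locs[i + 1:]
            if pred(_chebyshev(a, b))
        ]

    neighbouring = [(p, "Z") for p in same_class_pairs(select_Z, lambda d: d == 1)]
    neighbouring += [(p, "H") for p in same_class_pairs(select_H, lambda d: d == 1)]
    controls = [(p, "Z") for p in same_class_pairs(select_Z, lambda d: d >= 2)]
    controls += [(p, "H") for p in same_class_pairs(select_H, lambda d: d >= 2)]

    def evaluate(pool, k):
        pool = list(pool)
        if len(pool) > k:
            idx = rng.choice(len(pool), size=k, replace=False)
            pool = [pool[i] for i in sorted(idx)]
        rs, used = [], []
        for pair, side in pool:
            r = _pair_r(cases, y, pair, side)
            if not math.isnan(r):
                rs.append(r)
                used.append({"pair": list(pair), "side": side, "r": r})
        return rs, used

    feat_rs, feat_used = evaluate(neighbouring, n_pairs)
    ctrl_rs, ctrl_used = evaluate(controls, n_pairs)
    return {
        "mean_r_neighbouring": float(np.mean(feat_rs)) if feat_rs else float("nan"),
        "mean_r_control": float(np.mean(ctrl_rs)) if ctrl_rs else float("nan"),
        "n_neighbouring": len(feat_rs),
        "n_control": len(ctrl_rs),
        "neighbouring_pairs": feat_used,
        "control_pairs": ctrl_used,
    }
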