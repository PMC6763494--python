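"""Generative simulator for pattern suites and pigeon choice behaviour.

The analysis pipeline needs data with the statistical structure it assumes:
84 test sessions of pattern pairs with 4-26 lit pixels per pair, a repeat
schedule (17 pairs shown twice, two of them three times), six pigeons in two
three-bird teams with opposite reward assignments, and about 20 unreinforced
test trials per bird per test. This module fabricates such data from an
explicit generative choice model so that every pipeline stage is testable
without the original data set.

The choice rule is the minimal model consistent with evidence-count
reasoning: each bird carries a weight per pixel location (positive for its
rewarded class's pixels, negative for the punished class's, near zero for
ambiguous and neutral pixels); on a test, the evidence for the designated
"correct" member is the summed weight of its lit pixels minus that of the
other member's, and each trial chooses the correct member with probability
``1 / (1 + exp(-beta * E))``. ``beta`` is the choice sharpness; ``beta = 0``
yields pure guessing. By default a subset of salient locations (8 z + 6 h)
carries a 3x elevated weight, planting the cluster structure the salience
analysis is meant to recover.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .grids import (
    N_COLS,
    N_ROWS,
    SALIENT_H_LOCATIONS,
    SALIENT_Z_LOCATIONS,
    PixelClassMap,
    PixelGrid,
    TrainingPair,
    classify_pixels,
    parse_location,
    transcribe_training_pair,
)
from .indices import TestCase
from .stats import TEAMS, ChoiceRecord


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic experiment."""

    n_tests: int = 84
    richness_range: tuple[int, int] = (4, 26)  # lit pixels per pattern pair
    # repeat schedule; None scales the canonical 17-pairs-twice /
    # 2-pairs-thrice 84-test schedule proportionally to n_tests
    n_repeat_pairs: Optional[int] = None
    n_triple_pairs: Optional[int] = None
    min_gap: int = 5  # minimum sessions between repeat presentations
    n_pigeons: int = 6  # split into two equal teams
    trials_per_test: int = 20
    beta: float = 0.12  # logistic choice sharpness (~80 % mean accuracy)
    salient_weight: float = 1.5  # planted salient-location weight magnitude
    base_weight: float = 0.5  # remaining own-class weight magnitude
    ambiguous_weight: float = 0.0  # zh and n locations
    jitter_scale: float = 0.15  # per-pigeon idiosyncrasy (s.d. of weight noise)
    team_jitter_scale: float = 1.0  # team-shared weight deviation (s.d.)
    planted_z: tuple[str, ...] = SALIENT_Z_LOCATIONS
    planted_h: tuple[str, ...] = SALIENT_H_LOCATIONS
    seed: int = 0

    def __post_init__(self):
        if self.n_tests < 1 or self.trials_per_test < 1 or self.n_pigeons < 2:
            raise ValueError("all counts must be positive")
        if self.n_repeat_pairs is None:
            object.__setattr__(
                self, "n_repeat_pairs", round(17 * self.n_tests / 84)
            )
        if self.n_triple_pairs is None:
            object.__setattr__(
                self, "n_triple_pairs",
                min(round(2 * self.n_tests / 84), self.n_repeat_pairs),
            )
        if self.n_pigeons % 2:
            raise ValueError("n_pigeons must split into two equal teams")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        lo, hi = self.richness_range
        if not (2 <= lo <= hi <= 70):
            raise ValueError(f"invalid richness range {self.richness_range}")
        n_repeats = self.n_repeat_pairs + self.n_triple_pairs
        if self.n_triple_pairs > self.n_repeat_pairs:
            raise ValueError("n_triple_pairs cannot exceed n_repeat_pairs")
        if n_repeats >= self.n_tests:
            raise ValueError("repeat schedule exceeds the number of tests")


@dataclasses.dataclass(frozen=True)
class PigeonModel:
    """Per-bird pixel weight map driving the logistic choice rule."""

    pigeon_id: str
    team: str
    weights: np.ndarray  # (7, 5) float

    def __post_init__(self):
        if self.team not in TEAMS:
            raise ValueError(f"unknown team {self.team!r}")
        if self.weights.shape != (N_ROWS, N_COLS):
            raise ValueError("weights must be a 7x5 array")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        self.weights.setflags(write=False)

    def evidence(self, case: TestCase) -> float:
        """Summed-weight evidence for the bird's designated-correct member."""
        correct = case.grid_Zlike if self.team == "Z+H-" else case.grid_Hlike
        other = case.grid_Hlike if self.team == "Z+H-" else case.grid_Zlike
        return float(
            self.weights[correct.cells].sum() - self.weights[other.cells].sum()
        )


# ---------------------------------------------------------------------------
# Pattern sampling
# ---------------------------------------------------------------------------


def sample_test_pattern(
    class_map: PixelClassMap,
    n_z: int,
    n_h: int,
    n_zh: int,
    n_n: int,
    rng: np.random.Generator | int,
) -> PixelGrid:
    """Light a uniform random subset of each pixel class."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    cells = np.zeros((N_ROWS, N_COLS), dtype=bool)
    for label, want in (("z", n_z), ("h", n_h), ("zh", n_zh), ("n", n_n)):
        locs = class_map.locations(label)
        if want > len(locs):
            raise ValueError(
                f"requested {want} {label} pixels but only {len(locs)} exist"
            )
        if want:
            for loc in rng.choice(len(locs), size=want, replace=False):
                r, c = parse_location(locs[loc])
                cells[r - 1, c - 1] = True
    return PixelGrid(cells)


def _allocate_member(m: int, rng: np.random.Generator) -> dict[str, int]:
    """Split a member's lit count over classes: mostly own-class, a few
    ambiguous, occasional cross-class and neutral pixels."""
    caps = {"own": 10, "zh": 3, "cross": 10, "n": 12}
    own = min(caps["own"], int(round(m * rng.uniform(0.6, 0.95))))
    rest = m - own
    zh = min(caps["zh"], int(rng.binomial(rest, 0.5))) if rest else 0
    rest -= zh
    cross = min(caps["cross"], int(rng.binomial(rest, 0.5))) if rest else 0
    rest -= cross
    n = min(caps["n"], rest)
    rest -= n
    counts = {"own": own, "zh": zh, "cross": cross, "n": n}
    for key in ("own", "cross", "zh", "n"):  # spill any remainder
        take = min(rest, caps[key] - counts[key])
        counts[key] += take
        rest -= take
    if rest:
        raise ValueError(f"member lit count {m} exceeds the 35-pixel frame")
    return counts


def _sample_pair(
    class_map: PixelClassMap, richness: int, rng: np.random.Generator
) -> tuple[PixelGrid, PixelGrid]:
    m_z = richness // 2
    m_h = richness - m_z
    if rng.random() < 0.5:
        m_z, m_h = m_h, m_z
    az = _allocate_member(m_z, rng)
    ah = _allocate_member(m_h, rng)
    grid_z = sample_test_pattern(class_map, az["own"], az["cross"], az["zh"], az["n"], rng)
    grid_h = sample_test_pattern(class_map, ah["cross"], ah["own"], ah["zh"], ah["n"], rng)
    return grid_z, grid_h


def _phase_for(session: int, n_tests: int) -> str:
    if session <= round(n_tests * 61 / 84):
        return "I"
    if session <= round(n_tests * 74 / 84):
        return "II"
    return "III"


def sample_test_suite(
    config: SimulationConfig,
    class_map: Optional[PixelClassMap] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[TestCase]:
    """Draw a full test suite honouring the repeat schedule.

    Distinct pairs are content-addressed; repeated pairs reappear at later
    sessions with at least ``config.min_gap`` sessions between successive
    presentations. Session indices are 1-based and strictly increasing.
    """
    if class_map is None:
        class_map = classify_pixels(transcribe_training_pair("A"))
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_repeats = (config.n_repeat_pairs - config.n_triple_pairs) + 2 * config.n_triple_pairs
    n_distinct = config.n_tests - n_repeats
    if config.n_repeat_pairs > n_distinct:
        raise ValueError("infeasible repeat schedule: more repeated pairs than pairs")

    lo, hi = config.richness_range
    pairs, seen = [], set()
    while len(pairs) < n_distinct:
        richness = int(rng.integers(lo, hi + 1))
        gz, gh = _sample_pair(class_map, richness, rng)
        key = gz.key() + "|" + gh.key()
        if key in seen:
            continue
        seen.add(key)
        pairs.append((gz, gh))

    multiplicity = np.ones(n_distinct, dtype=int)
    repeated = rng.choice(n_distinct, size=config.n_repeat_pairs, replace=False)
    multiplicity[repeated] = 2
    if config.n_triple_pairs:
        multiplicity[repeated[: config.n_triple_pairs]] = 3

    occurrences = [i for i, m in enumerate(multiplicity) for _ in range(m)]
    for _ in range(500):
        order = rng.permutation(len(occurrences))
        sessions_of: dict[int, list[int]] = {}
        for slot, occ_idx in enumerate(order):
            sessions_of.setdefault(occurrences[occ_idx], []).append(slot + 1)
        ok = all(
            b - a >= config.min_gap
            for slots in sessions_of.values()
            for a, b in zip(sorted(slots), sorted(slots)[1:])
        )
        if ok:
            break
    else:
        raise ValueError("infeasible repeat schedule: could not honour min_gap")

    cases: list[TestCase] = []
    last_seen: dict[int, int] = {}
    by_slot = sorted(
        ((slot, pair_idx) for pair_idx, slots in sessions_of.items() for slot in slots)
    )
    for session, pair_idx in by_slot:
        gz, gh = pairs[pair_idx]
        cases.append(TestCase(
            test_id=session,
            grid_Zlike=gz,
            grid_Hlike=gh,
            phase=_phase_for(session, config.n_tests),
            session=session,
            repeat_of=last_seen.get(pair_idx),
        ))
        last_seen[pair_idx] = session
    return cases


# ---------------------------------------------------------------------------
# Cohort and choices
# ---------------------------------------------------------------------------


def make_pigeon_cohort(
    config: SimulationConfig,
    class_map: Optional[PixelClassMap] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[PigeonModel]:
    """Two teams sharing team-level base weights plus per-bird jitter.

    For a Z+H- bird the planted salient z locations carry
    ``+salient_weight``, the remaining z locations ``+base_weight``, h
    locations the mirrored negative weights, and zh/n locations
    ``ambiguous_weight``. H+Z- birds carry the sign-flipped map.
    """
    if class_map is None:
        class_map = classify_pixels(transcribe_training_pair("A"))
    if rng is None:
        rng = np.random.default_rng(config.seed)

    base = np.full((N_ROWS, N_COLS), config.ambiguous_weight)
    base[class_map.mask("z")] = config.base_weight
    base[class_map.mask("h")] = -config.base_weight
    for loc in config.planted_z:
        r, c = parse_location(loc)
        base[r - 1, c - 1] = config.salient_weight
    for loc in config.planted_h:
        r, c = parse_location(loc)
        base[r - 1, c - 1] = -config.salient_weight

    def noise(scale):
        if scale > 0:
            return rng.normal(0.0, scale, size=(N_ROWS, N_COLS))
        return np.zeros((N_ROWS, N_COLS))

    # team-shared deviations make within-team birds more alike than
    # between-team birds, emulating the teams' higher internal agreement
    team_jitter = {t: noise(config.team_jitter_scale) for t in TEAMS}

    cohort = []
    per_team = config.n_pigeons // 2
    for i in range(config.n_pigeons):
        team = TEAMS[0] if i < per_team else TEAMS[1]
        sign = 1.0 if team == TEAMS[0] else -1.0
        cohort.append(PigeonModel(
            pigeon_id=f"p{i + 1}",
            team=team,
            weights=sign * base + team_jitter[team] + noise(config.jitter_scale),
        ))
    return cohort


def simulate_choices(
    pigeon: PigeonModel,
    case: TestCase,
    trials: int,
    beta: float,
    rng: np.random.Generator | int,
) -> ChoiceRecord:
    """Binomial choice tally from the logistic evidence rule."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    e = pigeon.evidence(case)
    p_correct = 1.0 / (1.0 + np.exp(-beta * e))
    n_correct = int(rng.binomial(trials, p_correct))
    return ChoiceRecord(
        test_id=case.test_id,
        pigeon_id=pigeon.pigeon_id,
        team=pigeon.team,
        n_trials=trials,
        n_correct=n_correct,
    )


@dataclasses.dataclass(frozen=True)
class SimulatedExperiment:
    config: SimulationConfig
    pair: TrainingPair
    class_map: PixelClassMap
    cases: list[TestCase]
    pigeons: list[PigeonModel]
    records: list[ChoiceRecord]


def simulate_experiment(
    config: SimulationConfig, pair: Optional[TrainingPair] = None
) -> SimulatedExperiment:
    """Full deterministic synthetic experiment from a master seed."""
    if pair is None:
        pair = transcribe_training_pair("A")
    class_map = classify_pixels(pair)
    root = np.random.SeedSequence(config.seed)
    rng_suite, rng_cohort, rng_choices = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    cases = sample_test_suite(config, class_map, rng_suite)
    pigeons = make_pigeon_cohort(config, class_map, rng_cohort)
    records = [
        simulate_choices(pg, case, config.trials_per_test, config.beta, rng_choices)
        for case in cases
        for pg in pigeons
    ]
    return SimulatedExperiment(
        config=config, pair=pair, class_map=class_map,
        cases=cases, pigeons=pigeons, records=records,
    )
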