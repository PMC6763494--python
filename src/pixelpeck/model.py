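"""Model / Results facade over the full analysis pipeline.

``PatternDiscriminationModel`` bundles a test-pattern suite, the governing
training pair, and the cohort's choice records; ``fit()`` runs the whole
analysis (index correlogram, pixel-wise salience maps with clusters,
replication and relativity tables, team concordance, inter-individual
correlations) and returns a ``PatternDiscriminationResults`` object with a
``summary()`` table and structured accessors, in the spirit of statsmodels'
model/results split.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import cohort as cohort_mod
from . import io as io_mod
from .grids import (
    SALIENT_H_LOCATIONS,
    SALIENT_Z_LOCATIONS,
    PixelClassMap,
    TrainingPair,
    classify_pixels,
    transcribe_training_pair,
)
from .indices import TestCase, breakdown_table, pixel_presentation_frequencies
from .simulate import SimulationConfig, simulate_experiment
from .stats import (
    ChoiceRecord,
    ClusterSet,
    PixelCorrelationMap,
    feature_pair_analysis,
    index_choice_correlation,
    mean_scores,
    pixelwise_correlation,
    pooled_cluster_correlation,
    salient_clusters,
)

logger = logging.getLogger("pixelpeck")

_CORRELOGRAM_VARIANTS = (
    ("richness", False),
    ("base", False),
    ("base", True),
    ("minus_inhib", True),
    ("plus_zh", True),
    ("plus_n", True),
    ("select", True),
)


class PatternDiscriminationModel:
    """A test suite plus choice records, ready to be analysed.

    Parameters
    ----------
    cases
        The test pattern pairs (one per session).
    records
        Per-bird, per-test choice tallies.
    training_pair
        The governing training pair; defaults to the canonical variant A.
    """

    def __init__(
        self,
        cases: Sequence[TestCase],
        records: Iterable[ChoiceRecord],
        training_pair: Optional[TrainingPair] = None,
    ):
        self.cases = list(cases)
        self.records = list(records)
        if not self.cases:
            raise ValueError("at least one test case is required")
        if not self.records:
            raise ValueError("at least one choice record is required")
        self.training_pair = training_pair or transcribe_training_pair("A")
        self.class_map: PixelClassMap = classify_pixels(self.training_pair)
        case_ids = {c.test_id for c in self.cases}
        orphan = {r.test_id for r in self.records} - case_ids
        if orphan:
            raise ValueError(f"choice records reference unknown tests {sorted(orphan)}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        patterns_path: str | os.PathLike,
        choices_path: str | os.PathLike,
        training_variant: str = "A",
    ) -> "PatternDiscriminationModel":
        """Build from a ``.pat`` suite file and a choices CSV.

        Pattern record ids must follow ``<test_id>Z`` / ``<test_id>H``
        (e.g. ``12Z``, ``12H``), optionally with metadata.
        """
        grids = io_mod.read_patterns(patterns_path)
        by_test: dict[int, dict[str, object]] = {}
        for ident, grid in grids.items():
            side = ident[-1].upper()
            if side not in ("Z", "H") or not ident[:-1].isdigit():
                raise io_mod.FormatError(
                    f"pattern id {ident!r} does not follow '<test_id>Z|H'"
                )
            by_test.setdefault(int(ident[:-1]), {})[side] = grid
        cases = []
        for test_id in sorted(by_test):
            sides = by_test[test_id]
            if set(sides) != {"Z", "H"}:
                raise io_mod.FormatError(f"test {test_id} lacks a Z or H member")
            cases.append(TestCase(
                test_id=test_id, grid_Zlike=sides["Z"], grid_Hlike=sides["H"],
                session=test_id,
            ))
        records = io_mod.read_choices(choices_path)
        return cls(cases, records, transcribe_training_pair(training_variant))

    @classmethod
    def from_simulation(
        cls, config: Optional[SimulationConfig] = None, **kwargs
    ) -> "PatternDiscriminationModel":
        """Build from the generative simulator (see :mod:`pixelpeck.simulate`)."""
        exp = simulate_experiment(config or SimulationConfig(**kwargs))
        model = cls(exp.cases, exp.records, exp.pair)
        model.simulated = exp
        return model

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        adjust_translocation: bool = True,
        r_threshold: float = 0.30,
        max_shift: tuple[int, int] = (2, 2),
        select_Z: Sequence[str] = SALIENT_Z_LOCATIONS,
        select_H: Sequence[str] = SALIENT_H_LOCATIONS,
        pooled_scores: bool = False,
        seed: int = 0,
    ) -> "PatternDiscriminationResults":
        """Run every analysis stage and collect the results."""
        scores = mean_scores(self.records, pooled=pooled_scores)
        team_scores = mean_scores(self.records, by="team", pooled=pooled_scores)
        logger.info("scores: %d tests, %d records", len(scores), len(self.records))

        breakdowns = breakdown_table(
            self.cases, self.class_map, adjust_translocation,
            max_shift=max_shift, select_Z=select_Z, select_H=select_H,
        )
        corr = {}
        for variant, adjusted in _CORRELOGRAM_VARIANTS:
            key = variant + ("_adjusted" if adjusted and variant == "base" else "")
            try:
                r, p, n = index_choice_correlation(
                    self.cases, scores, variant, self.class_map,
                    adjust_translocation=adjusted, max_shift=max_shift,
                    select_Z=select_Z, select_H=select_H,
                )
                corr[key] = {"r": r, "p": p, "n": n}
            except ValueError as exc:
                logger.warning("index correlation %s skipped: %s", key, exc)
        logger.info("index correlogram: %d variants", len(corr))

        maps, clusters, pooled = {}, {}, {}
        for side in ("Z", "H"):
            m = pixelwise_correlation(self.cases, scores, side)
            maps[side] = m
            cs = salient_clusters(m, r_threshold=r_threshold)
            clusters[side] = cs
            pooled[side] = []
            for cl in cs.clusters:
                try:
                    r, p = pooled_cluster_correlation(self.cases, scores, cl, side)
                    pooled[side].append({"cluster": sorted(cl), "r": r, "p": p})
                except ValueError:
                    pass
            logger.info("side %s: %d clusters over %d locations",
                        side, len(cs), len(cs.locations))

        features = feature_pair_analysis(
            self.cases, scores, select_Z, select_H, seed=seed,
        )
        replication, replication_summary = cohort_mod.replication_table(
            self.cases, scores
        )
        part_repeats = cohort_mod.part_repeat_table(self.cases, scores)
        try:
            concordance = cohort_mod.team_concordance(team_scores)
        except ValueError as exc:
            logger.warning("concordance skipped: %s", exc)
            concordance = None
        inter_matrix, inter_summary = cohort_mod.interindividual_correlations(
            self.records
        )
        frequencies = pixel_presentation_frequencies(self.cases, self.class_map)

        return PatternDiscriminationResults(
            model=self,
            scores=scores,
            team_scores=team_scores,
            breakdowns=breakdowns,
            index_correlations=corr,
            maps=maps,
            clusters=clusters,
            pooled_cluster_correlations=pooled,
            feature_pairs=features,
            replication=replication,
            replication_summary=replication_summary,
            part_repeats=part_repeats,
            concordance=concordance,
            interindividual=inter_matrix,
            interindividual_summary=inter_summary,
            frequencies=frequencies,
        )


@dataclasses.dataclass
class PatternDiscriminationResults:
    """Container for all fitted quantities, with summary and export."""

    model: PatternDiscriminationModel
    scores: pd.Series
    team_scores: pd.DataFrame
    breakdowns: pd.DataFrame
    index_correlations: dict
    maps: dict[str, PixelCorrelationMap]
    clusters: dict[str, ClusterSet]
    pooled_cluster_correlations: dict
    feature_pairs: dict
    replication: pd.DataFrame
    replication_summary: dict
    part_repeats: pd.DataFrame
    concordance: Optional[cohort_mod.ConcordanceResult]
    interindividual: pd.DataFrame
    interindividual_summary: dict
    frequencies: pd.DataFrame

    def summary(self) -> str:
        """Human-readable overview of every analysis block."""
        lines = []
        lines.append("Pattern discrimination analysis")
        lines.append("=" * 47)
        lines.append(f"tests: {len(self.model.cases)}   "
                     f"records: {len(self.model.records)}   "
                     f"mean score: {self.scores.mean():.1f}%")
        lines.append("")
        lines.append("Index / choice correlations (Pearson)")
        lines.append(f"{'variant':<16}{'r':>8}{'p':>12}{'n':>6}")
        for key, v in self.index_correlations.items():
            lines.append(f"{key:<16}{v['r']:>8.3f}{v['p']:>12.2g}{v['n']:>6d}")
        lines.append("")
        for side in ("Z", "H"):
            cs = self.clusters[side]
            lines.append(
                f"{side}-side salience: {len(cs)} cluster(s) over "
                f"{len(cs.locations)} location(s) at r >= {cs.r_threshold:.2f}"
            )
            for entry in self.pooled_cluster_correlations[side]:
                lines.append(
                    f"  pooled {'+'.join(entry['cluster'])}: "
                    f"r = {entry['r']:.2f}, p = {entry['p']:.2g}"
                )
        lines.append("")
        fp = self.feature_pairs
        lines.append(
            f"two-pixel features: neighbouring mean r = "
            f"{fp['mean_r_neighbouring']:.2f} (n={fp['n_neighbouring']}), "
            f"control mean r = {fp['mean_r_control']:.2f} (n={fp['n_control']})"
        )
        rs = self.replication_summary
        if rs.get("n_repetitions"):
            line = (f"replications: n = {rs['n_repetitions']}, "
                    f"mean diff = {rs['mean_difference']:+.1f} pp")
            if "r_difference_vs_gap" in rs:
                line += (f", diff-vs-gap r = {rs['r_difference_vs_gap']:.2f} "
                         f"(p = {rs['p_difference_vs_gap']:.2g})")
            lines.append(line)
        if len(self.part_repeats):
            flips = int(self.part_repeats["flip"].sum())
            lines.append(f"part-repeats: n = {len(self.part_repeats)}, "
                         f"preference flips = {flips}")
        if self.concordance is not None:
            c = self.concordance
            lines.append(f"team concordance: {c.k_concordant}/{c.n_tests} tests "
                         f"(exact binomial p = {c.p_value:.2g})")
        ii = self.interindividual_summary
        lines.append(
            f"inter-individual r: all pairs {ii['mean_r_all']:.2f}, "
            f"within-team {ii['mean_r_within_team']:.2f}, "
            f"between-team {ii['mean_r_between_team']:.2f}"
        )
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        """Machine-readable summary (JSON-serializable)."""
        out = {
            "n_tests": len(self.model.cases),
            "n_records": len(self.model.records),
            "mean_score": float(self.scores.mean()),
            "index_correlations": self.index_correlations,
            "clusters": {
                side: json.loads(cs.to_json()) for side, cs in self.clusters.items()
            },
            "pooled_cluster_correlations": self.pooled_cluster_correlations,
            "feature_pairs": {
                k: v for k, v in self.feature_pairs.items()
                if not k.endswith("_pairs")
            },
            "replication_summary": self.replication_summary,
            "n_part_repeats": int(len(self.part_repeats)),
            "part_repeat_flips": int(self.part_repeats["flip"].sum())
            if len(self.part_repeats) else 0,
            "interindividual": self.interindividual_summary,
        }
        if self.concordance is not None:
            out["concordance"] = {
                "n": self.concordance.n_tests,
                "k": self.concordance.k_concordant,
                "p": self.concordance.p_value,
            }
        return out

    def save(self, outdir: str | os.PathLike) -> None:
        """Write every analysis block as TSV/JSON under ``outdir``."""
        os.makedirs(outdir, exist_ok=True)
        p = lambda name: os.path.join(outdir, name)  # noqa: E731
        self.breakdowns.to_csv(p("index_breakdowns.tsv"), sep="\t", index=False)
        pd.concat([m.to_frame() for m in self.maps.values()]).to_csv(
            p("pixel_maps.tsv"), sep="\t", index=False
        )
        for side, cs in self.clusters.items():
            with open(p(f"clusters_{side}.json"), "w") as fh:
                fh.write(cs.to_json())
        self.replication.to_csv(p("replications.tsv"), sep="\t", index=False)
        self.part_repeats.to_csv(p("part_repeats.tsv"), sep="\t", index=False)
        self.frequencies.to_csv(p("pixel_frequencies.tsv"), sep="\t", index=False)
        self.interindividual.to_csv(p("interindividual.tsv"), sep="\t")
        with open(p("summary.json"), "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)
        logger.info("results written to %s", os.fspath(outdir))
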