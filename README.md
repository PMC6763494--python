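# pixelpeck

Analysis pipeline for two-alternative forced-choice discrimination of
pixelated LED patterns by pigeons.

## The problem

Six pigeons, in two three-bird teams with opposite reward assignments,
learned to discriminate two 13-pixel figures — a Z-shaped pattern (`Z*`)
and an H-shaped "Viking cross" (`H*`) — displayed on 7×5 LED matrices.
They were then probed with 84 unreinforced *generalization* test pairs of
degraded, translocated, or recombined patterns (4–26 lit pixels per pair),
roughly 20 test trials per bird per test. The analytical question: which
pixels, and which combinations of pixels, drive the birds' choices?

`pixelpeck` implements the full analysis as a tested, reusable library:

- **Pixel classification.** Against a training pair, each of the 35
  locations is `z` (lit in Z\* only), `h` (lit in H\* only), `zh` (both) or
  `n` (neither); for the standard pair the counts are 10/10/3/12.
- **Discriminability indices.** The base index of a test pair is
  `z_Z + h_H` — z pixels lit in the Z-like member plus h pixels lit in the
  H-like member, ranging 0–20 — with variants subtracting the "inhibitory"
  cross-class count (`h_Z + z_H`) or adding the ambiguous/neutral counts,
  and a *select* index restricted to the 14 salient cluster pixels (0–14).
- **Translocation adjustment.** Pigeons show translational invariance, so
  shifted test patterns are registered against their training reference
  (best lit-pixel overlap within a ±2-row/±2-column window) before
  counting, moving from matrix-centred to pattern-centred coordinates.
- **Classification-image salience maps.** Per-location point-biserial
  correlations between a pixel's lit indicator and the per-test mean
  percent-correct score, with 8-connected supra-threshold clusters
  (r ≥ 0.30 at n = 84 ⟺ p < 0.01), pooled-cluster correlations, and a
  two-pixel feature analysis.
- **Cohort analyses.** Replication and part-repeat (relativity) tables,
  across-team concordance with an exact binomial test, and inter-individual
  correlation structure.
- **A generative choice simulator.** Each simulated bird carries a weight
  per pixel (positive for its rewarded class, negative for the punished
  class); each trial chooses the designated-correct member with probability
  `1/(1 + exp(-βE))`, where `E` is the lit-weight difference between the
  two members. The simulator plants a known salient-pixel structure, so
  every analysis stage can be validated by parameter recovery without the
  original data set.

## Worked example

```python
import pixelpeck as pp

model = pp.PatternDiscriminationModel.from_simulation(seed=7)
print(model.fit().summary())
```

```
Pattern discrimination analysis
===============================================
tests: 84   records: 504   mean score: 80.3%

Index / choice correlations (Pearson)
variant                r           p     n
richness           0.822       1e-21    84
base               0.836     4.7e-23    84
base_adjusted      0.831     1.3e-22    84
minus_inhib        0.848     2.6e-24    84
plus_zh            0.837     3.8e-23    84
plus_n             0.833     7.9e-23    84
select             0.827     3.4e-22    84

Z-side salience: 3 cluster(s) over 9 location(s) at r >= 0.30
  pooled ii1+ii2: r = 0.55, p = 4.6e-08
  pooled ii4+ii5+iii4: r = 0.66, p = 7.2e-12
  pooled vi2+vi3+vi4+vi5: r = 0.75, p = 1.1e-16
H-side salience: 1 cluster(s) over 9 location(s) at r >= 0.30
  pooled iii1+iii3+iii5+iv1+iv2+iv4+iv5+v3+v5: r = 0.83, p = 1.6e-22

two-pixel features: neighbouring mean r = 0.48 (n=10), control mean r = 0.49 (n=14)
replications: n = 19, mean diff = +0.2 pp, diff-vs-gap r = -0.35 (p = 0.14)
part-repeats: n = 38, preference flips = 0
team concordance: 82/84 tests (exact binomial p = 1.8e-22)
inter-individual r: all pairs 0.62, within-team 0.66, between-team 0.60
```

Reading the output: the simulated cohort averaged 80 % correct; the base
index `z_Z + h_H` correlates r = 0.84 with the per-test scores (the planted
evidence weights make the index a strong predictor); the salience maps
recover supra-threshold clusters covering the planted salient locations;
the 19 replications (17 pairs twice, 2 thrice) show no systematic drift,
the teams agreed on 82 of 84 tests, and birds within a team agree more
than birds across teams.

The same pipeline runs from files: `.pat` pattern suites (7 lines of
`#`/`.` per record) and a choices CSV
(`test_id,pigeon_id,team,n_trials,n_correct`), either through
`PatternDiscriminationModel.from_files(...)` or the CLI:

```sh
pixelpeck simulate --seed 7 --outdir sim/
pixelpeck report sim/suite.pat sim/choices.csv --outdir out/
pixelpeck index sim/suite.pat --adjust
pixelpeck clusters sim/suite.pat sim/choices.csv --side Z
```

## Layout

- `pixelpeck.grids` — patterns, classification, transforms, registration
- `pixelpeck.indices` — index breakdowns and presentation frequencies
- `pixelpeck.stats` — correlations, salience maps, clusters, features
- `pixelpeck.cohort` — replications, concordance, inter-individual analyses
- `pixelpeck.simulate` — synthetic suites, cohorts, choice simulation
- `pixelpeck.io` — `.pat` / CSV / config formats, deposited-sheet adapter
- `pixelpeck.model` — `PatternDiscriminationModel` / results facade
- `pixelpeck.cli` — command-line interface

See `docs/methods.md` for the model assumptions, parameter choices, and
limitations.
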