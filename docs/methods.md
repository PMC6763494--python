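# Methods

## Stimulus representation and the training-pair transcription

Patterns live on a 7×5 binary grid; rows are named i–vii top to bottom and
columns 1–5 left to right, so each location has a name such as `ii5`. All
I/O and all tests use these names directly.

The canonical training pair (variant A) consists of two 13-pixel figures
on the central 5×5 core: a Z (full top core row ii1–ii5, the descending
diagonal iii4–iv3–v2, full bottom core row vi1–vi5) and an H-shaped Viking
cross (full central column ii3–vi3, full crossbar row iv1–iv5, and short
flanking bars iii1/v1 and iii5/v5). Classifying every location against the
pair yields 10 `z`, 10 `h`, 3 `zh` (ii3, iv3, vi3) and 12 `n` locations,
ten of the latter on the outer rows i and vii and two inner ones at iii2
and v4.

This geometry is a **reconstruction**: the published figures were not
available in machine-readable form, so the patterns were derived from the
complete set of published per-location facts — the class counts, the
identity of the two inner neutral pixels, which named locations are z or h,
the shape of the salient clusters (four two-pixel z clusters excluding the
vertices ii5 and vi1; two point-symmetric three-pixel h clusters excluding
iii1 and v5; isolated meridian h pixels iii3/v3 with only diagonal h
neighbours), and the h-dominant classification of the rotated Z. The
reconstruction satisfies every one of these constraints simultaneously;
any remaining deviation from the original display could only concern
details the published record does not constrain.

Variant B removes four pixels from each A figure. Only two removals are
documented by name (the Z vertices ii5 and vi1); the default removal sets
({ii1, ii5, vi1, vi5} and {iii1, iii5, v1, v5}) are likewise a labelled
reconstruction. Variant C shifts Z\* one row south and H\* one row north.

The 8 salient z and 6 salient h locations exposed as
`SALIENT_Z_LOCATIONS` / `SALIENT_H_LOCATIONS` are the text-derived cluster
pixels above; the select index and the simulator's planted weights use
them as defaults.

## Indices

For a test pair (a designated Z-like and H-like member) the base
discriminability index is `z_Z + h_H`: z-class pixels lit in the Z-like
member plus h-class pixels lit in the H-like member (0–20). Variants:

- `minus_inhib`: base − (`h_Z + z_H`), subtracting wrong-class pixels
  inside each member;
- `plus_zh` / `plus_n`: base plus the ambiguous (0–6) or neutral lit
  count, each summed over *both* members — pair-level counts, matching the
  0–6 and 0–8 ceilings of the materials;
- `select`: the same count restricted to the salient sets (0–14);
- `richness`: total lit pixels of the pair (4–26 in the emulated design).

Rows i and vii participate fully in the neutral counts.

## Translocation adjustment (registration)

Pigeons recognise translated patterns, so a shifted member is re-registered
before counting: all integer shifts within ±2 rows and ±2 columns are
searched and the shift maximizing the count of lit pixels coinciding with
the member's own training reference (Z-like vs Z\*, H-like vs H\*) is
applied. Ties break toward the smaller |Δrow| + |Δcol|, then
north-before-south, west-before-east, making the procedure deterministic.
Translation semantics are curtailing: pixels pushed over the frame edge are
dropped, with no wrap-around. Shifts beyond the ±2 window are never
applied — a four-row translocation exceeds the birds' demonstrated
translational range and receives only the best in-range alignment. The
overlap-maximization objective is this package's formalization of an
adjustment the original analysis defined by worked examples; it reproduces
the intent of all illustrated cases. Richness always refers to the raw
display, not the re-registered grids. An empty test grid registers as
(0, 0) with a warning flag.

## Correlation machinery

All correlations are product-moment (Pearson) coefficients; a binary lit
indicator makes them point-biserial with no separate formula. Two-sided
p-values use the t transform on n − 2 degrees of freedom, consistent with
the conventional thresholds at n = 84 (r = 0.30 ⟺ p < 0.01). The per-test
score entering correlations is by default the unweighted mean of the
per-bird percent-correct values; a pooled-trials percentage is available
as an option.

Pixel-wise maps mask zero-variance locations (never or always lit) rather
than assigning r = 0; masked locations never enter clusters. Salient
clusters are maximal 8-connected components (horizontal, vertical and
diagonal contact) of locations with r ≥ 0.30; the threshold and the
connectivity are arguments.

The two-pixel feature analysis scores a pair of same-class salient pixels
as 1 on a test iff both are lit in the relevant member. Neighbouring pairs
(Chebyshev distance 1) are compared against control pairs of clearly
non-neighbouring same-class pixels (Chebyshev distance ≥ 2), sampled with a
documented seed; up to 14 pairs per set are used, fewer if fewer exist,
with the counts reported. Pairs whose indicator never varies are skipped.

## Cohort analyses

- **Replications** are linked explicitly (`repeat_of`); each repeat event
  contributes one row with the score difference (later − earlier) and the
  session gap, plus a summary mean and difference-vs-gap correlation.
- **Part repeats** identify recurring single patterns by bit-exact grid
  equality (content addressing). A pattern's preference score is the pair
  score when it occupies its first-appearance class and 100 − score when it
  reappears as the other class; a crossing of 50 % between consecutive
  appearances is flagged as a preference flip.
- **Concordance**: a test is concordant iff both teams' mean
  percent-correct falls strictly on the same side of 50 %; an exact 50 %
  mean counts as no preference and breaks concordance (a deliberately
  conservative tie rule). The attached binomial test is exact tail
  summation, one-sided (upper) by default since the hypothesis is
  directional; the two-sided option doubles the smaller tail, capped at 1.
- **Inter-individual correlations** are pairwise Pearson r over shared
  tests, with means over all pairs, within-team pairs and between-team
  pairs; pairs with fewer than 3 shared tests are masked.

## The generative simulator

The simulator is this package's own construction — the original study
posits no generative model — chosen as the minimal mechanism consistent
with evidence-count reasoning, which makes index and salience recovery a
meaningful validation.

Defaults emulate the study conditions: 84 tests, pair richness uniform on
4–26 split near-evenly between members, a repeat schedule of 17 pairs
presented twice with 2 of them three times (19 repeat events; for other
suite sizes the schedule scales proportionally), at least 5 sessions
between repeats, 6 birds in two teams, 20 trials per bird per test. Member
composition draws mostly own-class pixels (a uniform 60–95 % fraction)
with the remainder split between ambiguous, cross-class and neutral
locations, respecting class capacities.

Weights: for a Z-team bird, +1.5 on the 8 planted salient z locations,
+0.5 on the other z locations, the mirrored negative values on h
locations, 0 on zh/n; H-team birds carry the sign-flipped map. On top of
the base map each *team* receives a shared Gaussian weight deviation
(s.d. 1.0) and each bird an individual deviation (s.d. 0.15). The
team-shared component makes within-team agreement exceed between-team
agreement, the structure the cohort analyses are designed to detect (the
original teams likewise diverged markedly in their salience maps). The
choice sharpness default β = 0.12 was set once so that the default cohort
averages ≈ 80 % correct, the intended operating point; with these settings
the base-index/score correlation lies around 0.85–0.90 and the top-8
Z-side map locations recover at least 6 of the 8 planted z locations on
the large majority of seeds.

All randomness flows from one master seed through spawned generator
streams (suite, cohort, choices), so an identical configuration reproduces
byte-identical suites and choice tables.

### What the simulator does not emulate

Trial-by-trial learning, correction-trial logic, reaction times,
translocated or rotated test patterns, session-embedding effects, and any
configural (multi-pixel) evidence beyond the additive weight sum. Passing
recovery tests therefore shows the *pipeline* is sound on data satisfying
its assumptions — not that real choice behaviour is additive in pixel
evidence.

## Numerical and design choices

- Percent scores stay on the 0–100 scale everywhere; probabilities appear
  only inside the choice rule.
- Exact binomial tail summation is used for all concordance tests (no
  normal approximation at the relevant n).
- Pearson on constant input returns NaN and is masked or raised,
  depending on whether a map (maskable) or a scalar statistic (error) is
  being computed.
- Registration tie-breaks and the control-pair sampler are deterministic
  given their seeds; the report CLI surfaces a single `--seed`.
- Analysis problem sizes in the test suite (84-test suites, 10-seed
  recovery sweeps) match the emulated design; they run in seconds.

## Known limitations

- The training-pair and variant-B geometry is a constraint-based
  reconstruction (see above), not a facsimile of the original figures.
- The adapter for deposited spreadsheet tables is best-effort column-name
  matching; the deposited layout is described only in prose.
- The registration objective (lit-overlap maximization) is one
  formalization of a procedure defined by example; alternatives (e.g.
  index-maximization) could differ on pathological patterns.
- Headline correlations from the original data set (r = 0.74 etc.) depend
  on the deposited choice data and the exact 84 test pairs, and are not
  reproduced by the synthetic suites, which have their own (higher)
  signal-to-noise ratio.
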