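# Methods

This note documents the models, conventions and numerical choices behind
`efoscreen`, and what its synthetic benchmarks do and do not show.

## Score channels and orientation

A docking campaign is a long table of pose-level scores keyed by
(ligand, frame, monomer, score type, pose index). Pose stacks are
collapsed into two channels per key — BEST (the extremum over available
poses in the direction of the score's orientation) and MEAN (arithmetic
mean) — yielding, for a full campaign, frames × monomers × 3 score
types × 2 aggregations columns per preparation variant.

All three docking scores (PS, CS, CSopt) carry a `higher_is_better`
flag, defaulting to true. The consensus layer tries both signs for
every channel, so results do not depend on this convention; the flag
only fixes which pose is "best" within a stack and which direction a
missing value is pushed.

**Missing data.** A (ligand, frame, monomer, score type) group with no
poses is a docking failure. At ranking time — and only there — the
missing channel value is imputed with the worst observed value of that
channel, shifted by one scale epsilon (`1e-9 + 1e-6·range`), so failed
dockings can be ranked but can never top a single-channel ranking.
Imputation never feeds back into the stored matrix.

**Tie-breaking.** Rankings sort descending by score with ligand id as
the final key (stable sort over the id-sorted array). This makes every
ranking a pure function of (scores, ids). A corollary the synthetic
generator respects: ligand ids must not encode activity, otherwise
tied blocks (e.g. groups of imputed failures) would leak labels into
the ranking. Generated ids are neutral (`LIG0001…`) with the active
subset drawn at random.

## Quality function

The search objective is lexicographic: EF at the top fraction α
(default 0.01), then a rank-skewness tie-breaker; a scalar blend
`EF + λ·skew` is available via `QualityConfig.skew_weight`.

* `n_top = round(α·N)` with half-up rounding, minimum 1 (N = 1000 →
  10; a 300-ligand test split → 3).
* The skewness statistic is the third moment of `0.5 − r_i/N` over the
  actives' normalized ranks, standardized by the uniform-null
  dispersion `(1/12)^{3/2}`. Standardizing by the *null* rather than
  the sample dispersion keeps the statistic monotone toward
  top-concentration (an all-actives-on-top ranking scores highest),
  which is the property a tie-breaker needs; the sample-standardized
  version can prefer a lone straggler. It is ≈0 for uniformly spread
  actives and exactly negates under ranking reversal (up to the 1/N
  discretization).

Attainable EF values are coarse (with n_top = 10 and A = 20:
{0, 5, …, 50}), so EF ties are common and the skew term decides them;
with λ = 0 it can never override an EF difference.

## Incremental consensus search

Models are signed linear combinations of at most `max_vars = 3`
channels. The leading coefficient is pinned to ±1.00 — linear rankings
are scale-invariant, so one degree of freedom is removable, and the
convention matches how such equations are conventionally printed.

The search is greedy: (1) pick the best single (channel, sign); (2) for
each remaining channel, grid-search its coefficient over signed
log-spaced magnitudes (default 25 points per sign spanning 0.01–100)
with the current coefficients held fixed; (3) refine the winning
candidate by joint coordinate descent over the same grid (sweeps until
stable), followed by an off-grid multiplicative pattern search (factors
1.6/1.25/1.1), both within a shared budget of 200 evaluations; (4) stop
when the best candidate does not strictly improve the quality key, or
at `max_vars`. The quality is piecewise constant in the coefficients
(it depends on the ranking only), which is why the refinement is
derivative-free by design. `off_grid_refine=False` keeps every
coefficient on the grid, which makes the search space exactly
comparable to an exhaustive-subset oracle — the configuration the test
suite uses for the greedy-vs-exhaustive equivalence check.

Every distinct channel set evaluated during the search is retained as a
candidate (best coefficients seen), not just the greedy frontier; the
multi-frame "top 20 models" statistics draw from this candidate pool.

## Validation and y-scrambling

Candidates are re-ranked by the mean test EF over 5 stratified 70/30
splits (scikit-learn `StratifiedShuffleSplit`; stratification keeps the
2% active rate in both halves so the test EF always exists). The
variable set and leading sign chosen on the full data are frozen; free
coefficients are re-fit per training split. The same splits are shared
by all candidates. The per-frame EF1% a campaign reports is this
mean-over-splits value — whether a published per-frame EF is a split
mean, a best split, or a full-data value is generally ambiguous, so the
convention is fixed here and flagged.

y-scrambling permutes the activity labels (seeded), reruns search +
validation, and averages the best validated EF over K repetitions
(default 20). Note the scrambled baseline is the *optimum over the
variable pool* under the null, not 1.0: selection bias inflates it, and
the suite measures it empirically rather than assuming it.

## Campaign filters

A monomer of a frame is unsuitable when more than three actives have
zero poses on it across all score types — pose absence is the only
failure observable in a score table, and the count is joint over score
types. A frame is discarded when more than two of its four monomers are
unsuitable. Channels of discarded monomers leave the frame's variable
pool. The filters are idempotent.

## Trajectory-level analyses

Per-frame EF series use an acceptance mask; discarded frames are
excluded from every aggregate, never zero-filled. Segment means use
label-inclusive 250 ns windows (`25–250`, `275–500`, …; en dash in
labels, ASCII accepted on input). Reported table statistics round
half-up at the printed precision (2 decimals for EF and r, 1 for
volumes) — bankers' rounding would corrupt e.g. a 19.895 segment mean.
Pocket-volume summaries average per monomer over frames; the overall
mean is the unweighted mean of the four monomer means. Correlations are
sample Pearson r (scipy), with explicit errors for n < 3 or zero
variance.

The packaged reference tables (see `src/efoscreen/data/README.md`) are
verbatim transcriptions; typographic variants in the printed equations
are normalized at parse time, with exactly one equation (`CbestA`)
needing the bare-`C` → CS normalization. Re-derived statistics
reproduce the published derived numbers except for a handful of
internal inconsistencies of the published tables themselves (overall EF
means, three optimized-set segment means, the first/second-half
mean-score counts, and a CS count that excludes the `CbestA` typo);
`efoscreen.reference.diff_report` lists each recomputed-vs-published
pair and flags the mismatches rather than hard-coding printed values.

## Synthetic campaigns

The generator emulates the statistical structure the analysis assumes:

* **Equilibration quality** `q(t) = 1/(1+exp(−(t−400)/150))` (ns): a
  sigmoid reflecting a trajectory that starts constrained and relaxes,
  with the transition centred at 400 ns.
* **Scores**: decoy poses are Gaussian per score type (PS 60±8, CS
  40±10, CSopt 42±10, arbitrary units), correlated across score types
  via a shared latent (ρ = 0.6 — high enough that the three scores are
  redundant but not interchangeable). Active poses are shifted by
  `δ_s · q(t) · m_monomer` with δ = (3, 11, 13) units (≈0.4–1.3 decoy
  SD at full quality) and monomer multipliers A 0.9 / B 1.1 / C 1.0 /
  D 0.7.
* **Failures** delete whole pose groups with probability
  `0.08·(1−q)·m_fail`, concentrated on monomers D (×3.0) and A (×1.5),
  so early frames can trip the suitability filters.
* **Volumes**: `base_m·(1 + 0.35·q) + N(0, 25)` Å³, with the
  side-chain-optimized variant inflating volumes ×1.39, damping
  failures ×0.6 and boosting the active effect ×1.15.

Pose draws are independent within a pose group, so MEAN channels enjoy
a ≈√P noise reduction and dominate the selected models — a structural
bias that echoes the empirically observed prevalence of mean scores,
but means synthetic campaigns at default effect sizes often validate
near the EF ceiling. What passing tests show is therefore that the
pipeline recovers planted structure, orders frames by planted quality,
and collapses under label scrambling — not that generated scores
resemble any real docking program numerically, nor that real campaigns
reach these EF values. Real pose stacks are correlated, failures are
not independent of ligand chemistry, and decoy scores are not Gaussian.

Determinism: one seeded `numpy` Generator drives everything; identical
config + seed gives byte-identical CSV output.

## Problem sizes used by the shipped analyses

The acceptance script runs the synthetic end-to-end campaign at 500
ligands / 10 actives / 10 frames / both variants (search grid 13 points,
refinement budget 80, 5-fold validation, 10 scrambling repetitions),
and the parameter-recovery suite uses 20 campaigns of 1000 ligands / 20
actives on a single late frame — sizes chosen to exercise every stage
at the default library composition while keeping a full run in the
tens of seconds on one CPU.

## Known limitations

* The coefficient fitter is a heuristic over a piecewise-constant
  objective; it matches exhaustive subset search on small shared-grid
  instances ~80–90% of the time and is not guaranteed globally optimal.
* The skewness tie-breaker is a documented surrogate; other
  early-recognition tie-breakers (e.g. BEDROC-style weights) are out of
  scope.
* Validation freezes variable selection outside the split
  (`refit_selection` is not implemented as an inside-split search);
  reported validated EF therefore carries residual selection optimism,
  which the y-scrambling baseline quantifies empirically.
* Published per-frame EF values themselves are not reproducible from
  the shipped tables (they required the original docking scores, which
  are consumed upstream of this package); everything derived *from* the
  printed values is.
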