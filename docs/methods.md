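# Methods

## The assertion datacube

A single exometabolomic observation is the qualitative net action on one
metabolite by one organism in one environment. The datacube holds one
observation per (metabolite, organism, environment) key; the key is
unique, and every cube owns exactly one reserved control pseudo-organism,
`The Environment`, whose observations may only be `detected` /
`not detected`. Transformed (organism) observations may only be
`increase`, `decrease`, `no change` or `not investigated`. Directional
observations carry a log2 fold change whose sign must match the action
and a confidence in (0, 5]; all other actions carry confidence 0 exactly.
`validate()` enforces all of this and is the contract every generator and
parser in the package is tested against.

Assertions are *net* turnover: `no change` can mean no interaction or
balanced production and consumption, and an `increase` need not be de
novo synthesis (peptide hydrolysis can release free amino acids). The
scores below inherit these caveats.

## Assertion pipeline

Inputs are replicate relative abundances (arbitrary instrument units) for
a control pool and one spent pool, per metabolite. The pipeline is:

1. **Detection.** A pool is present when at least
   `min_detected_replicates` (default 1) replicates are strictly greater
   than `detection_threshold` (default 0, i.e. any positive signal; the
   strict inequality makes an all-zero pool undetected even at threshold
   0). Both pools undetected → `not investigated`, and nothing else is
   computed — this is also why an all-zero comparison can never reach the
   fold-change division.
2. **Testing.** Otherwise the two replicate sets are compared with a
   two-sided test: Welch's unequal-variance *t* by default, Mann–Whitney
   *U* as the nonparametric alternative. The choice is a parameter
   because the right test depends on the experimental design. p ≥ alpha
   (default 0.05) → `no change`.
3. **Direction and confidence.** Significant differences are called by
   the sign of log2(mean spent / mean control), using the ratio of
   replicate means; confidence is min(|log2 FC|, 5) and maps linearly to
   cell shading (shade = confidence / 5). When exactly one side is
   detected, the direction comes from the detected side, no fold change
   is reported, and confidence is pinned at the cap 5 — significance is
   still required first.

Degenerate replicate sets make the *t* statistic undefined (zero variance
on both sides, or single replicates). The tie-break: pools that are
identical constants compare as p = 1 (`no change`); constant but
different pools compare as p = 0 (significant, usual fold change). This
keeps toy fixtures and plate-reader-style data from raising instead of
asserting.

Multiple-testing correction is off by default, mirroring simple
per-metabolite testing; `benjamini_hochberg` applies the FDR step-up
across all tested metabolites of one experiment before the alpha
comparison. Batch results carry the full configuration snapshot as
provenance.

Useful properties, all tested: swapping control and spent mirrors the
call and negates the fold change; rescaling all abundances together with
the threshold changes nothing; confidence never exceeds 5 and is zero
exactly for non-directional calls.

## Compatibility scores

Within one environment, with `D_o`/`I_o` the decrease/increase sets of
organism *o* and `P` the control-present set:

* `EUS(scored) = |D_scored ∩ P| / |P|`
* `OCS-FMC(scored; ref) = |D_scored ∩ D_ref| / |D_scored|`
* `OCS-FME(scored; ref) = |D_scored ∩ I_ref| / |D_scored|`

Two readings deserve a note. First, the OCS denominator is the scored
organism's **total** decrease count, not the decreases exclusive to it:
the published two-isolate walkthrough (25 shared decreases being "50% of
the total it decreases", and 25/26 ≈ 0.96) only works under the total
reading, so that is what is implemented. Second, the EUS numerator is
intersected with `P`: a product that was absent from the starting pool
cannot be consumed from it. Metabolites asserted `not investigated`
never enter any set. A zero denominator yields an UNDEFINED score
(`value is None`), serialized as an empty cell — never 0, which is a
meaningful score. Cell marks (competition = both decrease, exchange =
scored decreases what the reference increases) count exactly to the FMC
and FME numerators by construction.

## Views

All three slice tables and the web share one encoding: color from the
action (tan/gray for the control column, red/blue/white for organisms,
checkered for `not investigated`), shade from confidence only. A
(metabolite, organism, environment) combination with no observation
renders as a checkered cell in **every** view; this uniform fill rule is
what makes the three slices agree cell-for-cell, a property tested over
random cubes. Row/column order is lexicographic with the control column
first (determinism for diffs); the One Metabolite slice is oriented
environments × organisms.

The web draws one edge per increase/decrease assertion (nothing for
`no change`); metabolite node size is the number of interacting
organisms, and nodes are filled when the metabolite was detected in the
control pool, hollow when it appeared only after transformation.
Control-pool metabolites with no edges keep degree 0 and stay in the
graph — the starting pool is part of the picture; non-control degree-0
nodes are dropped.

## Synthetic data

`generate_cube` draws a dense random cube: each control cell detected
with probability 0.8; transformed actions with probabilities 0.2 / 0.3 /
0.4 / 0.1 (increase / decrease / no change / not investigated), a 5%
chance that a directional call is a capped one-sided detection, and
exponential(1.2) fold-change magnitudes. These mixes exercise every
action state and both the present and absent control cases; they do not
model correlation between organisms or environments, chemical classes,
or realistic pool sizes — passing the round-trip, oracle and
view-consistency suites says the *mechanics* are right, not that any
biological pattern is reproduced.

`generate_experiment` models LCMS-style replicate abundances as
log-normal: per-metabolite baselines with natural-log mean 7 and sd 1
(median ≈ 1100 units, essentially always above the default detection
threshold of 10), multiplicative replicate noise with natural-log sd 0.1
(≈ 10% CV, a well-behaved instrument), 5 replicates per side, and spike
fractions of 10% up and 10% down at |log2 FC| = 2. Log-normal
multiplicative noise is the conventional model for relative peak areas;
batch effects, missingness beyond the threshold rule, and
heteroscedastic ion suppression are deliberately out of scope. Under
these conditions the suite checks calibration at n = 1000 metabolites:
the null false-assertion rate must sit within three binomial standard
errors of alpha = 0.05, and ≥ 95% of spiked metabolites must be called
in the right direction. Welch's *t* on log-normal data at n = 5 runs
slightly conservative (observed ≈ 0.04), comfortably inside the band.

The fixed two-isolate R2A fixture encodes the set sizes back-solved from
a published score walkthrough: 25 metabolites decreased by both
organisms, 50 decreased by GW123-8A04 in total, 26 by FW300-N2A2 (25/26
rounds to the published 0.96), 8 of GW123-8A04's decreases increased by
FW300-N2A2, none of FW300-N2A2's increased by GW123-8A04. The control
pool size was not published; it is set to 100 so that the uptake score
of GW123-8A04 is 50/100 = 0.5, matching its published value, while the
published 0.3 for FW300-N2A2 is not exactly representable from these
counts (26/100 = 0.26) — EUS is therefore treated as a consistency
check, not a target, and only the four OCS values are asserted exactly.

## Numerical and design choices

* Detection uses strict `>` with a replicate count, because "limit of
  detection" is otherwise unspecified; the boundary case (value equal to
  the threshold) is *not detected*.
* Fold change uses the ratio of replicate means — the natural summary
  when the underlying comparison is "measured value over control value".
* Upload floats are serialized with `repr`, making
  write → parse → write byte-stable and float-exact.
* Duplicate upload keys: strict mode (default) rejects the file; lenient
  mode keeps the first occurrence and logs — curation-first defaults.
* `not investigated` is accepted explicitly in uploads as the sixth
  action word alongside the five assertion words.
* The relational store is plain SQLite with five tables (environments,
  organisms, metabolites, observations, projects) and a uniqueness
  constraint on the observation key; loading runs a foreign-key check
  and refuses files with dangling references.

## Known limitations

The scores ignore growth, toxins, regulation and catabolite repression;
they rank candidate partners, nothing more. Co-eluting isomers share one
assertion. The assertion engine assumes exchangeable replicates and no
batch structure. Upload files carry only the eight canonical columns, so
metabolite annotations, MSI levels and free-text descriptions survive
the SQLite round trip but not the text round trip.
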