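# Methods

## Experimental model

The package analyses plate co-culture bioassays: each focal organism is
grown on an agar medium either alone (monoculture control) or paired
with one cross-kingdom partner, in triplicate, and its colony area is
measured at days 3, 5 and 7. The measurement table is long-format with
one row per `(focal, partner, medium, day, replicate)`; an empty
partner marks the control. Comparisons are always focal-vs-its-own
control on the same medium and day, so every directed pair (the effect
of A on B, and of B on A) is tested separately — the resulting networks
are directed, and an induction of one partner implies nothing about the
other.

## Growth comparison

Per cell, co-culture areas are compared to control areas with a
two-tailed Welch *t*-test on the raw area scale, implemented from the
closed-form statistic and Welch–Satterthwaite degrees of freedom (the
*t* tail probability comes from `scipy.stats.t`). The significance call
is strict: +1/−1 only when p < α (default α = 0.05) with the matching
sign of the mean difference. Degenerate zero-variance inputs — possible
with noiseless synthetic data — are handled explicitly: both samples
constant and equal gives t = 0, p = 1; constant and unequal gives
p = 0; both flagged. No multiple-testing correction is applied by
default, matching the per-comparison thresholding of the original
screens this pipeline reproduces; Benjamini–Hochberg can be enabled
(`compare_all(bh_correct=True)`) for sensitivity analyses.

At three replicates per group, Welch's approximation is conservative:
the empirical size at nominal α = 0.05 is ≈ 0.035 under the lognormal
null, and scipy's independent implementation shows the same (≈ 0.035)
under exact normality. The test suite therefore asserts validity
(size ≤ nominal, up to Monte-Carlo error) rather than exact nominal
attainment, and the null-chain calibration check derives its expected
nonzero-grade rate from the measured per-day call rate.

## Grading

The day-3/5/7 sign pattern is graded by an exact 14-row lookup
(+6 strong induction … +1 acceleration, mirrored for inhibition),
not a weighted sum — (0,0,1) and (1,0,1) both grade +4, which no
per-day weighting reproduces. (0,0,0) grades 0 ("none"). Patterns
mixing +1 and −1 across days lie outside the monotone taxonomy; they
are graded 0 with an explicit `mixed` flag rather than assigned a net
direction, keeping the gap auditable. The map is total over all 27
patterns and antisymmetric by construction.

## Networks

One network per medium per direction, stored as a rectangular
source × target integer matrix in fixed roster order (F1–F4, B1–B5):
within-kingdom links are structurally impossible in the bipartite
design, so the 4 × 5 roster has exactly 20 possible links per
direction, and connectivity is 100 × (nonzero links)/20. Networks are
serialized as edge-list CSV (nonzero links only, signed grade plus an
induction/repression label; re-import needs the node rosters because
isolated nodes leave no edges) and as GraphML via networkx
(self-describing; round-trips exactly).

## Dominance test

Whether a network is dominated by inductions or repressions is tested
with a one-sample sign-flip permutation test of its grades against
median 0 — the permutation analogue of the exact Wilcoxon signed-rank
test as implemented by `wilcox.exact`-style tools, which is the
appropriate form for small samples with heavy ties. Zeros are dropped
from the rank statistic (Wilcoxon convention); tied magnitudes receive
mid-ranks; the statistic is the sum of signed ranks; the null flips
each sign independently. For m ≤ 20 nonzero links the full null
distribution over the 2^m equally likely assignments is computed
exactly by integer shift-convolution over the doubled ranks (mid-ranks
of .5 become integers), so exhaustive p-values are rationals with
denominator 2^m; beyond that, Monte Carlo with the add-one correction
(1 + #extreme)/(1 + n_perm) is used, with a default of 500 draws
matching common practice for these screens (the exhaustive mode is
exact and preferred whenever feasible). The reported estimate is the
median of the full grade list, zeros included; the alternative reading
(median over observed links only) is equally consistent with how such
medians are usually tabulated, and the choice only affects the reported
location, never the p-value. The verdict requires p < α and takes the
median's sign; a significant test with a zero median (possible when
fewer than half the possible links are present) is reported as "no
dominance".

## QAP correlation

Similarity of two media's networks is measured by the Pearson
correlation of their weight matrices over all cells, with significance
from the Quadratic Assignment Procedure: the row labels and,
independently, the column labels of one matrix are permuted uniformly
and r recomputed. Rows and columns permute separately because the
bipartite matrices are rectangular — the exchangeability being
preserved is "strain labels within a kingdom". The permutation count
defaults to 1000; p-values are two-sided with the add-one correction,
hence never zero and conservative on discrete nulls. A constant matrix
(no variation in grades — e.g. a fully saturated planted scenario or an
empty network) leaves r undefined and is reported as an explicit error;
`qap_all_pairs` records the error for that pair and continues.

## Synthetic data generator

The generator emulates the measurement table's statistical structure:
per-strain monoculture baseline areas at each day (default linear in
day: 150·day mm² for fungi, 40·day mm² for bacteria — placeholder
magnitudes plausible for a 90 mm dish, not calibrated to any measured
growth curves), planted direction-specific effects as step functions of
day (a fractional change in expected area from an onset day onward, so
onsets 3/5/7 generate exactly the monotone patterns (1,1,1)/(0,1,1)/
(0,0,1) the grading taxonomy is built around), and mean-one
multiplicative lognormal replicate noise with configurable CV (areas
are positive and right-skewed; σ² = ln(1 + CV²)). Identical
configuration and seed give byte-identical output.

The canned `stress_gradient_config` plants +50% inductions on every
cross-kingdom link of the low-nutrient MM medium and −50% repressions
on rich PDA, both directions, CV 10%, triplicates — the maximal form of
the nutrient-dependent shift the pipeline is designed to detect.

What the generator does *not* emulate: growth-curve dynamics beyond the
three sampling days, spatial plate effects (inoculation distance,
colony collision), day-to-day correlation within a physical plate
(records are independent draws), or heteroscedasticity beyond the
constant-CV model. Passing tests therefore demonstrate the correctness
and calibration of the inference chain under these assumptions, not the
biological fidelity of any particular dataset.

## Numerical and design choices

* Significance boundary strict (p < α), the conventional reading of a
  0.05 threshold.
* Sign-flip p-values compare |T| with a 1e-9 slack so mid-rank ties at
  exactly |T_obs| count as extreme.
* Per-pair QAP seeds are spawned from one `SeedSequence`, keeping pairs
  independent but jointly reproducible from a single seed.
* `dominance_summary` and `qap_all_pairs` never mutate their inputs;
  stage outputs are pure functions of stage inputs, and the pipeline
  manifest (parameters + seeds, no timestamps) determines the bundle
  byte-for-byte.
* Taxonomy banding uses half-open intervals [94, 98) and [80, 94) so
  fractional identities between the printed integer bands map totally;
  coverage below 94% gates a hit to "unassigned" regardless of
  identity.

## Problem sizes in the test and calibration runs

The acceptance suite runs the full chain at the study design size
(1764 records, 480 comparisons, 160 grades, 8 networks per run): 100
seeds each for the null-calibration and stress-gradient-recovery
experiments, 500 replicates for the QAP null calibration (1000
permutations each), and 10,000 draws for the Monte-Carlo vs exhaustive
agreement checks. The analysis drivers use 50 seeds for the same
calibration summaries.

## Known limitations

* The dominance test's zero-handling drops absent links from the rank
  statistic, so sparsely connected networks have little power (with
  m ≤ 5 links the smallest achievable two-sided p is 1/16 > 0.05).
* A fully saturated, uniform network is constant, making QAP against it
  undefined — visible in the planted maximal scenario.
* Welch's test at n = 3 is conservative (see above); real screens with
  triplicates inherit that conservatism.
* The generator's baselines and noise level are design placeholders;
  conclusions about power on real data require plugging in measured
  baselines and replicate CVs.
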