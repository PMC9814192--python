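# Methods

This package quantifies three things: organelle contact sites in 2-D
electron-microscopy segmentations of neuronal somas, Drosophila sleep
architecture from activity-monitor counts, and differential expression
intersected with organelle gene lists. Every estimator is exercised
against seeded synthetic data with serialized ground truth; this note
records the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Contact-site detection

A contact site is a maximal stretch of a reference membrane lying
strictly closer than `d_max_nm` to a partner membrane. The reference
boundary is resampled at `sample_step_nm` arc spacing; each sample's
minimum Euclidean distance to the partner curve is computed exactly
(point-to-polyline); maximal apposed runs are formed; runs on the same
organelle pair separated by an arc gap under `merge_gap_nm` are merged;
runs shorter than `min_len_nm` are dropped. Kinds are fixed by the pair:
ER–mitochondrion (MAM, reference ER), ER–plasma membrane (PAM, reference
ER), mitochondrion–plasma membrane (reference mito), and
mitochondrion–mitochondrion (reference: lower-index member, one record
per unordered pair — a mitochondrion touching two neighbours contributes
two contacts).

Parameters, defaults, and why:

| parameter        | default | rationale |
|------------------|---------|-----------|
| `d_max_nm`       | 20 nm   | the canonical MAM apposition threshold, applied strictly (`<`); no lower bound is needed because overlapping membranes are rejected as invalid segmentations |
| `sample_step_nm` | 2 nm    | an order finer than the threshold; detected lengths carry ±2 samples of discretization error |
| `merge_gap_nm`   | 30 nm   | two apposed runs closer than this along the reference are one annotation; manual annotation never states this, so it is surfaced in config |
| `min_len_nm`     | 5 nm    | suppresses single-sample specks |

Pairs whose exact polygon distance is ≥ `d_max_nm` are pruned without
resampling; this cannot change the result because the sampled minimum
distance is never smaller than the true minimum. Intersecting curves
raise an error: distance zero is segmentation failure, not a contact.

The implementation is checked against a 1-nm brute-force sampling
reference with independently written run-grouping on > 100 random
synthetic cells: segment counts must agree exactly, lengths within two
sample steps.

## Morphometry

Per cell: cytoplasmic area (outer ring minus the nucleus hole, µm²); ER
count, density (count per cytoplasmic area), area fraction, and
compactness as the perimeter-to-area ratio in nm⁻¹. Compactness is
pooled per cell (Σ perimeter / Σ area) as the primary definition because
it is robust to many tiny cisternae; the per-cisterna mean is emitted as
a secondary column since either reading of "perimeter to area ratio" is
defensible. Mitochondria get count, density, mean profile area, and the
pair-contact count. Undefined quantities (mean contact length with zero
contacts, compactness with zero ER) propagate as NaN and are excluded
pairwise from group statistics — never imputed.

All metrics are invariant (to 1e-6 relative) under rescaling pixel
coordinates with a compensating change of the nm-per-pixel calibration.
Calibration is a required input for every geometry file: section pixel
sizes vary between datasets and a default would silently corrupt every
nm-scale quantity.

## Statistics

Group contrasts are reported as percent change of group B's mean over
group A's, with a seeded bootstrap SE (default 10 000 resamples of both
groups) — the plain-text "± x %" after a contrast is always this
bootstrap SE and labelled as such. Two-sample tests: unpaired Student's
t for the EM metrics, Welch for expression, exact Mann-Whitney for small
blot groups (combined n ≤ 20 without ties; tie-corrected normal
approximation otherwise). Multi-group: Kruskal-Wallis with tie
correction, Dunn's rank-mean z-tests with Bonferroni correction (written
in-house from the standard formula — no installed package provides
Dunn), and optional paired Wilcoxon follow-ups for within-fly
baseline-vs-after contrasts. Ties take mid-ranks; ranking ties break by
cell id so exports are deterministic.

`rank_top_density` and `flag_above_max` implement the density-ranked
top-k tables and the "cells above the comparison group's maximum" count
(strict inequality) used for the heavy-tail analysis.

Blot normalization follows the total-protein rule: lane factor = lane
Ponceau signal / highest Ponceau signal on the blot; normalized signal =
observed signal / factor. The lane with the largest total is unchanged.

## Sleep scoring

Sleep is ≥ 5 consecutive minutes of zero activity counts; a day runs
lights-on to lights-on with a 12:12 schedule. Bouts crossing a
light/dark (or day) boundary contribute minutes to each window but are
counted once, in the window of their onset — totals are conserved while
counts stay integral. Stability is max wake bout − max sleep bout
(positive = more wakeful); because the opposite order also circulates, a
`stability_convention="figure"` flag flips the sign rather than
asserting either as canonical. Latency is measured from lights-off to
the onset of the first sleep bout starting in the dark, where flies
sleep most. Monitor rows with a non-OK status are missing: they break
bout runs and should disqualify days with > 5 % missing bins. A fly is
dead when immobile for ≥ 12 h running to the end of the recording (the
recordings themselves give no rule; this one never misclassifies a
half-day siesta) and is removed with a logged death-onset estimate.
Baseline is the 4-day LD mean per fly; rebound is the post-deprivation
day's total sleep minus that baseline, per fly, also as percent.

## Differential expression

Welch's t per probe on log2 values, Benjamini-Hochberg across all tested
probes, *then* collapse to gene symbols by minimum raw p — adjusting
before collapsing keeps the adjusted values coherent with the family
actually tested. Fold change is linear, from the log2 group means:
`FC% = (2^mean_SD − 2^mean_S)/2^mean_S × 100`. A gene is up when
FC% > +30 and adjusted p < 0.01; down when FC% < −30 (a decrease
exceeding 30 %, the symmetric reading) with the same p rule. The filter
defaults to the BH-adjusted p, consistent with a 1 % FDR; `use_raw_p`
switches to raw p since both conventions exist in practice. Gene-set
intersection operates on uppercase-normalized symbols; the ER/Mito list
contents are user inputs — the original catalog versions are not
reconstructible, so lists ship with the synthetic study only.

## Synthetic data: what it emulates, and what it does not

**Cells.** An annular cytoplasm (outer radius 3.8–4.6 µm, nucleus
1.8–2.2 µm) holds 14–18 mitochondrion ellipses (semi-axes 250–420 ×
140–220 nm) and ~25 ER profiles (tubes 300–1000 nm long, 40–65 nm wide).
Contacts are planted *geometrically*: a MAM is an ER tube wrapped around
a mitochondrion at a sampled separation in (6, 16) nm over a sampled arc
(80–250 nm); mitochondrion pairs are translated until their membrane gap
hits a sampled sub-threshold value; PAMs hug the plasma membrane from
inside. Everything else keeps a ≥ 45 nm clearance, so detection is
genuinely exercised and no accidental contact corrupts the recorded
truth. Planted per-mitochondrion MAM counts are Poisson with rate 0.4
(sleep condition); pair contacts arise from per-slot Bernoulli draws
(p = 0.45 per disjoint mitochondrion pair slot); group effects multiply
these rates. A detected MAM run slightly exceeds its planted arc length
(by about 2·(20 − separation) nm of tube end-caps under the threshold) —
truth-based length checks account for this; the oracle checks do not
need to. Not emulated: ER sheet/tubule distinction, curved/branched
mitochondria, nucleus indentation, segmentation noise — so passing
recovery here shows estimator correctness on clean geometry, not
robustness to annotation error.

**Flies.** A two-state semi-Markov process per fly: dwell time = state
minimum (5 min sleep, 1 min wake) + (mean excess / shape) × Gamma(shape)
minutes, with separate light/dark excess means (sleep 9/42 min, wake
21/13 min — roughly 820 min sleep/day, mostly at night) and the regime
fixed at bout onset. Dwell shape 3 gives cohort-level contrast
uncertainties of a few tenths of a percent at n ≈ 140–180, the order of
the dispersions the study conditions prescribe; exponential dwells
(shape 1) are far noisier than real cohorts. Waking minutes always carry
≥ 1 count, so scored sleep equals the state path exactly — immobile
wakefulness is deliberately not modelled, which is precisely what makes
the ground truth exact. The enforced-wake protocol forces the wake state
(hence nonzero counts) through a chosen 12-h dark phase; a rebound
multiplier shortens wake excesses on the following day. Group effects:
`fragmentation` divides all excess means (more, shorter bouts at roughly
constant sleep fraction); `sleep_offset` multiplies sleep excesses only.
Because the planted quantities of interest are *pipeline-level*
contrasts (episode number, rebound percent), the multipliers realizing a
target contrast are found by seeded bisection on an independent
calibration cohort (600–700 flies, fixed internal seeds) — the
calibrated multiplier, not the target, is then the generator condition.

**Coupling.** All randomness derives from `SeedSequence(seed, unit
index, purpose)`. The same per-unit base draws are reused across groups,
with group effects entering only through rate multipliers via comonotone
inverse-CDF (or scale-family) sampling. Contrast estimates therefore use
common random numbers: the planted contrast is realized tightly at the
study group sizes instead of drowning in between-group sampling noise.
This is a paired-simulation design choice; the estimators themselves
never see the pairing.

**Expression and blots.** Log2 expression = gene baseline N(7, 1.5) +
group effect log2(1 + FC/100) + N(0, σ) noise per sample; blot lanes
multiply a true expression by a uniform (0.55–1.0) loading factor that
also drives the Ponceau signal, so normalization must undo it.

## Problem sizes and numerical choices

The recovery runs use the study group sizes throughout: 139 vs 132
cells, 181/118 flies at baseline, 139 flies through the deprivation
night, 6 vs 6 arrays, 5 vs 5 blot lanes. At these sizes the whole
recovery suite completes in a few minutes on one CPU. Boundary
resampling uses exact arc-length interpolation; ellipses are 128-gons
(sagitta error ≪ 1 nm); organelle placement is rejection sampling with
bounded retries, raising a generation error (rather than degrading
silently) when packing is infeasible; bisections (pair gaps, dwell
calibrations) run to fixed iteration counts for determinism.

## Known limitations

Detection operates on 2-D profiles; 3-D contact surfaces and
serial-section continuity are out of scope. The MITO_MITO length is
reference-dependent to ~10 % on smooth convex shapes (counts are not).
The sleep generator has no circadian structure beyond the light/dark
dwell split, no siesta ramp, and no inter-fly heterogeneity; recovery
results quantify estimator accuracy under the planted model only. The
DE stage assumes probe-level log2 input that is already normalized;
array preprocessing is not reproduced.
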