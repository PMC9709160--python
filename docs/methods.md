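# Methods

This note documents the models and procedures implemented in `stresspheno`,
the conventions chosen where the underlying methodology is genuinely open,
and what the synthetic-data generators do and do not emulate.

## 1. Composite physiological stress scoring (`stresspheno.phenoscore`)

### Model

Three physiological markers index chronic HPA-axis activation: body-weight
gain (g; lower under stress), adrenal weight normalized to body weight
(g/g; higher under stress), and normalized thymus weight (g/g; lower under
stress). Each marker is treated as a binary classifier of the experimental
group with *stress* as the positive class.

**ROC construction.** Candidate thresholds are the midpoints between
consecutive distinct sorted marker values, plus one sentinel below the
minimum and one above the maximum, so the curve always starts at (0, 0)
and ends at (1, 1) and every cutoff falls strictly between observations.
A mouse tests positive when its value is strictly beyond the threshold in
the stress direction (`> t` for stress-higher markers, `< t` for
stress-lower). AUC is computed by trapezoid integration of TPR over FPR;
with this threshold set the trapezoid AUC equals the tie-corrected
Mann–Whitney statistic U/(n₁n₂) exactly (ties contribute ½), which the
test suite verifies against a brute-force pairwise oracle.

**Youden cutoff.** The selected cutoff maximizes J = TPR − FPR. Ties are
broken deterministically: highest TPR first (favoring sensitivity), then
the smallest threshold value. The tie-break is a package convention; the
methodology itself does not prescribe one.

**Scoring.** A mouse receives one point per marker strictly beyond its
cutoff; equality at the cutoff never scores (cutoffs sit at midpoints
between observed values, so equality is measure-zero on real data and the
strict reading is the conservative resolution). The D-score is the sum
(0–3); 0–1 classifies as non-stressed, 2–3 as stressed. Corticosterone,
when present, is reported in the predictiveness table (AUC with an
uninformativeness flag at a configurable margin, default |AUC − 0.5| <
0.05) but is never part of the D-score.

**Cutoff provenance.** By default cutoffs are derived from the analyzed
cohort (`fit(cutoffs="auto")`). The published constants (3.565 g
body-weight gain, 1.225 × 10⁻⁴ adrenal, 1.551 × 10⁻³ thymus) ship in
`stresspheno.config.PAPER_CUTOFFS` and can be frozen into a fit; outputs
record which source was used.

### Statistical behaviour of the cutoff estimator

The empirical Youden cutoff is an argmax of an empirical process and
converges at the cube-root rate: at n = 10⁴ per group its sampling
standard deviation is ≈ 0.04–0.05 pooled-σ across group separations of
1.5–6 σ (measured by simulation). Recovery tests therefore check the
estimator's mean over replicate cohorts against the analytic equal-variance
Bayes boundary (the midpoint of the group means) rather than a single
draw, at a tolerance of 2% of the between-mean gap.

## 2. Spike-waveform unit typing (`stresspheno.ephys`)

### Feature extraction

Features are measured on each unit's mean waveform (µV, known sampling
rate; 30 kS/s typical):

* **Baseline** — the median of the first 25% of the window, subtracted
  before any measurement. The window start is the most reliably quiescent
  region when the spike occupies the window center; the median is robust
  to residual spike energy.
* **Trough** — the global minimum after baseline subtraction. Waveforms
  whose positive excursion dominates are inverted with a logged warning
  rather than rejected (electrode geometry occasionally flips polarity).
* **Half-width** — the time between the two linearly interpolated
  crossings of half the trough amplitude bracketing the trough (ms).
* **Trough-to-peak** — the time from the trough sample to the maximum
  occurring after it (ms). A trough at the window edge, or no post-trough
  maximum above the trough, is an error.

Both features are amplitude-scale invariant and time-shift equivariant up
to one sample period (a near-tie at the discrete peak can resolve to
either neighboring sample). Accuracy is validated against a 1 MS/s
dense-grid measurement of analytic templates: agreement within one 30 kS/s
sample period (0.033 ms).

### Classification

A two-component Gaussian mixture with full covariances is fitted to the
pooled (half-width, trough-to-peak) cloud — all units, both experimental
groups, one model — with 10 restarts and a fixed seed (default 0), so
refits are bit-identical. Features enter in raw milliseconds without
standardization: the two features live on comparable scales (tenths of a
millisecond) and raw units keep the component means interpretable; this
choice is recorded in the mixture summary. The component with the larger
mean trough-to-peak duration is labeled **MSN** regardless of the
component order returned by the optimizer, making the labeling rule
deterministic. Units are assigned by maximum posterior, and the posterior
of the assigned component is reported per unit. Degenerate input (all
features identical) is an error.

On synthetic ensembles with the default templates the mixture recovers
every ground-truth label; at configured overlap its accuracy stays within
2% of the analytic Bayes-optimal rule computed from the generating
densities (test-suite checks).

### Firing rates

Rate = spike count / recording duration (spontaneous-activity recordings,
30 min typical). The class report gives mean ± sd/sem per (group × class)
cell, class counts and percentages per group, rate histograms with
configurable bins, and a Welch two-sample comparison per class between
groups (descriptive; only when both groups have ≥ 2 units of the class).
Empty cells are reported as absent, not errors.

## 3. Behavioral motif communities (`stresspheno.motifs`)

### Usage and syntax

Motif usage is the fraction of frames per motif (sums to 1 per session).
Transition matrices are computed after **collapsing runs** of repeated
labels (configurable, `collapse=True` by default): motifs persist over
many frames, so a frame-level matrix is dominated by its diagonal, while
the behavioral syntax of interest is which motif follows which. Rows with
observed outgoing transitions are normalized to 1; unobserved rows stay
all-zero and are flagged. Counts may be pooled across sessions (never
across session boundaries).

### Community tree

Affinity A = (P + Pᵀ)/2; distance 1 − A. Average-linkage agglomeration
proceeds greedily to a single root; exact ties are broken by the
lexicographically smallest pair of cluster-minimum motif indices, making
the merge order deterministic and the construction equivariant to motif
relabeling (up to ties). Symmetrization and average linkage are package
conventions for "hierarchy from transition probabilities" — validated not
by appeal to a reference implementation but by structure-recovery
properties: on block-structured Markov chains (between-block weight ≤ 0.1×
within-block, ≥ 10⁴ frames per session) pruning to the true block count
recovers the exact partition in ≥ 95% of seeds. Motifs never observed
have affinity 0 to everything and attach last as singleton leaves.

**Pruning** replays the first K − c merges (average linkage is monotone,
so this equals cutting at a height) and renumbers communities by their
smallest member motif. Community *names* (walk, groom, ...) are applied
only through an explicit user-supplied label map; the shipped
`PAPER_COMMUNITY_LABELS` uses the same smallest-member numbering so an
exactly recovered partition lines up with its labels. Of the 38 motifs,
35 have published community memberships; the remaining three (8, 22, 25)
are assigned to "other", which is the natural reading of the published
grouping.

### Comparisons

Per community: Welch's unpaired t-test of control vs stress within each
condition, and a paired t-test of saline vs CNO within each group (mice
missing a condition are dropped from the paired test with a warning).
These are standard tests included for report completeness; identical
inputs yield a zero statistic rather than NaN.

## 4. Synthetic data (`stresspheno.synthetic`)

All generators take a frozen spec dataclass with a seed and are driven by
`numpy.random.default_rng`; identical spec + seed ⇒ bit-identical output.

**Physiological cohorts.** 88 control + 90 stressed mice by default. The
three markers are drawn independently per mouse (in real cohorts of this
kind the markers are not mutually correlated, which is what makes a
composite score informative). Default parameters: body-weight gain
control 5.0 ± 1.0 g vs stress 4.25 ± 1.12 g; adrenal 1.10 ± 0.15 vs
1.21 ± 0.17 (×10⁻⁴ g/g); thymus 1.75 ± 0.20 vs 1.60 ± 0.22 (×10⁻³ g/g);
corticosterone 70 ± 25 ng/mL in *both* groups (deliberately
uninformative). The stress-group spread is set slightly wider than
control and the mean shifts modest, chosen analytically (via the Youden
density-crossing condition and binomial flag-count algebra) so the default
pipeline retains roughly 70–80% of controls and 55–70% of stressed
animals; individual cohorts of this size scatter around those means by
±10 percentage points, as expected for n ≈ 90 with estimated cutoffs.
These defaults are configuration describing a plausible cohort, not
ground truth. Organ weights are floored at a tiny positive value against
the far Gaussian tail.

**Spike waveforms and trains.** Each unit is a raised-cosine (Hann)
trough of configured width and amplitude plus a smaller raised-cosine
post-trough peak — chosen because both shape features are then known
analytically (half-width = trough width / 2; trough-to-peak = the
configured lag) — with additive white Gaussian noise (default sd 2 µV).
Defaults: MSN 80 µV / 0.50 ms width / 0.75 ms lag; interneuron 60 µV /
0.22 ms / 0.30 ms; 30 kS/s, 3 ms window, 285 MSNs + 16 interneurons per
ensemble; 30 min recordings. Spike trains are homogeneous Poisson (the
analyses only consume mean rates); per-unit rates are lognormal around
the class mean (log-sd 0.4, disableable) to give realistic rate
histograms. Ground-truth class labels are carried on each record and
never mutated downstream.

**Motif sequences.** A between-distinct-motif Markov chain with weight 1
inside a community and 0.1 across (row-normalized, zero diagonal) over 38
motifs in the 8 shipped communities; a scalar self-persistence
probability (default 0.95, i.e. geometric runs of ~20 frames ≈ 0.33 s at
60 fps) makes motifs last multiple frames. Sessions default to 10 min at
60 fps (36 000 frames), 20 mice, with the same mouse ids across
saline/CNO so paired comparisons pair. An optional per-community inflow
bias scales a community's stationary usage, the mechanism used to
configure group or condition effects. A partition row with no exits
(e.g. a singleton community with zero between-weight) is a validation
error.

**What the generators do not emulate.** No raw voltage traces, spike
sorting, video, pose or embedding dynamics; no marker correlations,
litter/batch structure or outliers in the cohort; no bursting,
refractoriness or non-stationarity in spike trains; no heavy-tailed run
lengths or time-of-session effects in behavior. Passing recovery tests
therefore demonstrates correctness of the downstream procedures under
their stated assumptions, not robustness to every failure mode of real
recordings.

## 5. Orchestration (`stresspheno.pipeline`, CLI)

One YAML/JSON config (all keys defaulted, all validation errors reported
at once) selects stages, seeds, cutoff mode (auto/frozen), mixture
settings, motif K and community target. Sub-seeds for the generators are
derived deterministically from the master seed. Every run writes a
manifest with the config snapshot, package version, per-output SHA-256
checksums and timestamps; a failing stage aborts the run with the failed
stage recorded. Exit codes: 0 success, 2 config error, 1 runtime error.

## 6. Test problem sizes

Oracle-equivalence checks run 200 random instances at n ≤ 50; cutoff
recovery uses 10–25 replicate cohorts of 10⁴ per group; mixture checks use
the default 625-unit ensemble and 2–3 × 10³-point feature clouds;
transition recovery pools 10 sessions of 10⁴ frames; community recovery
runs 100 seeded chains of 10⁴ frames (12 motifs, 3 blocks). These sizes
make the statistical tolerances comfortable for the quantities under test
while keeping the default suite fast.

## 7. Known limitations

* The ROC machinery assumes complete marker data; there is no imputation.
* The mixture assumes exactly two unit classes; rarer striatal cell types
  (e.g. TANs) would be absorbed into whichever component fits better.
* The community tree is one reasonable hierarchy over transition
  affinity; alternative linkages or directed-affinity constructions can
  give different mid-level merges on weakly structured data.
* Paired behavioral comparisons assume the two conditions are sessions of
  the same animal identified by `mouse_id`.
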