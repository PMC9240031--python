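# Methods

## Overview

`ebmseq` implements an event-based view of disease progression: each brain
region contributes one "structural alteration" event, the disease is assumed
to accumulate events monotonically, and the population-level order of events
is estimated from a single cross-sectional cohort. The pipeline has five
stages: (1) normative modelling and alteration weights, (2) pairwise
conditional probabilities with McNemar precedence tests, (3) stochastic
trajectory simulation and modal-sequence extraction, (4) clinical staging,
and (5) per-patient disease-state prediction with a severity association.
A synthetic-cohort generator with planted ground truth supports all
validation.

## Normative model and alteration weights

For every region, the measure (cortical thickness for GM, FA for WM) is
regressed on age and sex **over controls only** (ordinary least squares,
three parameters; residual SD uses the n−3 degrees-of-freedom correction).
Patients are then residualized against this model: the deviation
d = (predicted − observed)/residual SD is positive when the measure is
reduced. The weight is a linear ramp w = clamp(d/c, 0, 1) with cutoff
c = 2.5 SD by default (2.0 and 3.0 as sensitivity settings). The ramp's two
endpoints (0 at the normative mean, 1 at c SD below) are the defining
contract; the *linear* interpolation between them is the minimal-assumption
choice and is pluggable (`WeightConfig.ramp`). Deviations in the healthy
direction are truncated at 0.

Sex may arrive in any two-level encoding; the lexicographically first level
is coded 0, the second 1, and the fitted contrast is stored with the model
so patients are encoded identically.

A structural consequence worth stating explicitly: because d is a z-score,
a healthy region has d ~ N(0, 1) regardless of how small the raw measurement
noise is, so the expected weight of an unaffected region is
E[clamp(Z/c, 0, 1)] = 0.159 for c = 2.5 (0.195 at c = 2.0, 0.133 at c = 3.0;
by numerical integration). This irreducible "fuzzy floor" drives the
identifiability behaviour discussed below.

## Fuzzy event semantics

Weights are treated as per-patient event probabilities, independent within a
patient, so joint probabilities are products:
P(X+ ∩ Y−) = mean_i w_iX(1 − w_iY). This uses all the information in the
continuous weights and reduces exactly to patient counting when weights are
binary (a property the test suite enforces against an enumeration oracle).
When the conditioning event is degenerate (P(Y−) = 0, i.e. Y altered in
every patient) the conditional is reported as 0.

## Pairwise precedence testing

McNemar's test of marginal homogeneity is applied to binarized events
(threshold w ≥ 0.5, the ramp midpoint, configurable): with discordant
counts b = #(X+, Y−) and c = #(X−, Y+), the exact two-sided binomial p is
used when b + c < 25, otherwise the continuity-corrected chi-square; b = c =
0 yields p = 1. Direction is sign(b − c). Benjamini–Hochberg FDR correction
is applied within the tested family (all 62×48 cross-tissue pairs, or all
unordered pairs for the all-region census), at level 0.05. The cross-tissue
census counts unordered GM–WM pairs (total 2976); the all-region census is
reported over ordered pairs (110×109 = 11990), each significant unordered
pair contributing both orderings.

Per-region precedence summaries average the conditional over the opposing
tissue: for a GM region g, P(GM+|WM−)_g = mean over WM tracts y of
P(g+|y−); the mapped "difference" score is the region's own precedence
minus the opposing tissue's average precedence over it.

## Trajectory simulation

A trajectory starts with no events and adds one per step. With remaining
set R, the score of candidate X is

    score(X) = Σ_i w_iX Π_{Y∈R, Y≠X}(1 − w_iY)  /  Σ_i Π_{Y∈R, Y≠X}(1 − w_iY),

i.e. P(X+ | all other remaining events absent) under the fuzzy semantics;
the next event is sampled from the scores normalized over R. If every score
is zero (no conditioning mass left), the step falls back to uniform over R
— this arises when no patient separates two events, and makes the
degeneracy explicit rather than producing NaNs.

Two implementations share these semantics. The reference path
(`step_probabilities`, `sample_trajectory`) evaluates every leave-one-out
product directly and is exact for any weights including exact 0/1. The
production path (`simulate`) advances all trajectories in lock-step:
per-patient running products over the remaining set are maintained, and the
leave-one-out numerators/denominators for all candidates at once are two
matrix products per step. Numerical policy: weights within ε of 1 (ε =
1e-9, configurable) are snapped to exactly 1 and handled by counting zero
factors per patient — so certain events occur first without dividing by a
vanishing (1 − w) — and the running products are rescaled per trajectory
each step to avoid underflow with many events. The two paths are
cross-checked distributionally in the test suite (chi-square on step
distributions). Cost is O(patients × events × trajectories) per step via
BLAS; 10,000 trajectories over 110 events and 130 patients take ≈ 8 s on
one CPU. The default `n_trajectories` is one million (the conventional
production depth); the bundled analyses run at 10,000, which at these
cohort sizes is already limited by weight noise, not Monte-Carlo error.

The **modal sequence** assigns, at each step in order, the not-yet-assigned
event with the largest count at that step; ties break toward the event with
more cumulative mass up to that step, then toward atlas order. This greedy
rule guarantees a valid permutation while honouring the "most frequent at
each step" definition; per-step modal frequencies are reported so users can
judge stability.

## Clinical staging

Milestone indicators are binary per-patient events: HYS ≥ 2 and HYS ≥ 3
(the modified scale may be fractional, thresholds use ≥), or cognitive
status ∈ {MCI, D} and = D. The later milestone is patient-wise a subset of
the earlier, which alone forces the natural milestone order in every
trajectory: P(later+ | earlier−) has an identically zero numerator.
Indicators enter the simulation as ordinary events (values exactly 0/1);
structural events between adjacent milestones in the resulting modal
sequence share a stage, and per-stage counts are reported.

## Disease states and severity

State k means the first k events of the sequence have occurred. A patient's
state maximizes the scalar product between the cumulative indicator
template and the patient's weights reordered by the sequence — equivalently
the argmax over k of the running sum of reordered weights, continuous
weights used as-is. Ties resolve to the earliest state, which absorbs the
all-zero patient into state 1 (no state 0 exists). The state–UPDRS
association is Kendall's τ-b (states are heavily tied at cohort sizes of
~130) with the asymptotic two-sided p, significance at p ≤ 0.05.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes. Controls:
measure = tissue baseline + age·slope + sex·offset + N(0, noise_sd), with
GM baseline 2.5 (thickness-like units, slope −0.005/yr) and FA-like WM
baseline 0.45, one shared generative law per the tissue-agnostic pipeline.
Patients additionally lose effect_size · sigmoid((t − onset_r)/width) in
region r, where t is the patient's latent disease time (uniform over the
onset span ± a margin, or explicitly supplied). Onsets increase strictly
along the planted order (WM tracts first by default). Clinical milestones
are threshold crossings of t; UPDRS = 4·t + N(0, 8), floored at 0, matching
the ~20–50 range of a moderate PD cohort. Defaults (130 patients, 75
controls, 62+48 regions, effect 0.3 ≈ 6 residual SD, onsets on [1, 9])
describe a single-site study-scale cohort.

Deliberately **not** modelled: within-patient correlation of regional noise
(residuals are independent across regions, which real cohorts violate),
scanner/site effects, missing data, symptom reversion, and clinical
subtypes. Passing tests therefore demonstrate correctness of the inference
machinery under the model's own assumptions, not robustness to those
real-data features.

Two canned regimes: `guttman_config` (zero noise, step onsets, latent times
stratified across every inter-onset gap so each prefix pattern occurs — the
noise-free limit in which recovery must be exact) and `recovery_config`
(20 events, 200 patients, steep onsets, 6-SD planted contrast — the
standard noisy recovery benchmark). For noise-free or low-noise cohorts,
`binary_alteration_matrix` binarizes patients' deficits against the known
generative law (threshold at half the planted effect), yielding the
ground-truth event matrix.

## Identifiability: what the method can and cannot recover

The analyses of the estimator carried out while building the package are
themselves results worth recording:

- **Pairwise census: robust.** On the study-scale synthetic cohort the
  McNemar census recovers the planted WM-before-GM structure essentially
  perfectly (≈ 96% of 2976 pairs significant toward WM precedence, none
  reversed). The census aggregates over all patients per pair and is the
  dependable cross-tissue readout.
- **Full-sequence simulation: weakly identified under fuzzy weights.** The
  step score conditions on *all* remaining events being absent; with the
  0.159 fuzzy floor on every healthy region, the per-patient products decay
  like 0.84^|R|, so the conditioning mass concentrates on a handful of
  patients and every step's distribution is nearly flat. Even with the
  true prefix given and thousands of patients, p(next) stays ≈ 0.1–0.2, so
  trajectories mix and the per-step marginal counts blur: planted-vs-
  inferred τ saturates near 0.5–0.65 for 20 events / 200 patients and near
  0 for 110 events / 130 patients, *independent of trajectory count and of
  the raw noise level* (the floor is a property of z-scoring, not of the
  measurement noise). Per-step modal frequencies are reported precisely so
  this flatness is visible to the user.
- **Binary events: sharply identified, but fragile to single flukes.** On
  ground-truth binarized cohorts the chains are near-deterministic and the
  planted order is recovered exactly in the noise-free limit. At a 6-SD
  planted contrast, the ~0.13% per-entry flip rate leaves a few false
  positives per cohort; because a step score can be dominated by a single
  patient, one false positive on a late event in an early patient
  occasionally promotes that event far up the sequence (observed in ≈ 10%
  of recovery cohorts, costing ~0.1–0.2 in τ). This single-patient
  sensitivity is intrinsic to the conditional-probability estimator.
- **Cutoff sensitivity.** Because the fuzzy floor itself depends on the
  cutoff (0.195 / 0.159 / 0.133 at 2.0 / 2.5 / 3.0), the mixing level and
  hence the inferred sequence shift with the cutoff; orders inferred at
  different cutoffs on the same cohort agree only partially (pairwise τ
  ≈ 0.5–0.95 across cohorts, unchanged at 10× trajectories — the
  disagreement is score-level, not Monte-Carlo).

## Numerical and design choices

| parameter | default | meaning / rationale |
|---|---|---|
| `cutoff_sd` | 2.5 | weight saturation, in control residual SD; 2.0/3.0 for sensitivity |
| binarize threshold | 0.5 | ramp midpoint (= cutoff/2 SD) for McNemar events |
| exact-test switch | b+c < 25 | standard exact-vs-asymptotic McNemar practice |
| FDR level | 0.05 | corrected significance level |
| `n_trajectories` | 1,000,000 | production depth; analyses use 10,000 (weight-noise-limited) |
| `epsilon` | 1e-9 | weights above 1−ε treated as certain events |
| tie-breaks | cumulative mass, then atlas order | deterministic modal extraction |
| state ties | earliest state | conservative staging; absorbs all-zero patients |

Degenerate inputs: fewer than four controls, or a region with zero control
residual variance (detected with a relative tolerance), abort the normative
fit with the offending region named; saturated conditioning events flag as
degenerate; empty-separation steps fall back to uniform as described.

## Limitations

Temporal precedence inferred cross-sectionally is hypothetical and would
need longitudinal validation. The monotone single-sequence assumption
ignores symptom reversion and clinical subtypes. The fuzzy-independence
coupling of weights is a modelling convention, not an estimated quantity.
And as quantified above, the full-sequence readout is only weakly
identified at realistic cohort sizes under continuous weights — users
should weight conclusions toward the pairwise census, the staging milestone
positions, and the state–severity association, and read the per-step modal
frequencies as the sequence's confidence statement.
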