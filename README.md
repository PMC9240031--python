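# ebmseq — event-based ordering of brain structural alterations

`ebmseq` infers the population-level sequence in which brain regions become
structurally altered in a neurodegenerative disease — cortical thinning in
gray-matter (GM) regions, fractional-anisotropy (FA) loss in white-matter
(WM) tracts — from a single **cross-sectional** cohort, and relates the
inferred sequence to clinical milestones and symptom severity. It is aimed
at neuroimaging groups who already have regional measures (from a
surface/tract pipeline) for a patient group and a normative control group,
and who want a data-driven ordering and staging of those regional deficits
without longitudinal follow-up.

## The model

Each region *X* contributes a binary "structural alteration" event. Because
only cross-sectional data are available, alterations are quantified softly:
for patient *i* and region *X*, the weight

```
w_iX = clamp( d_iX / c , 0, 1 ),    d_iX = (ŷ_iX − y_iX) / σ_X
```

where ŷ_iX is the age- and sex-adjusted normative prediction (fitted on
controls), σ_X the control residual SD, and c the saturation cutoff
(default 2.5 SD). w = 0 at the normative mean, w = 1 at or below c SD under
it; supra-normal values map to 0.

Treating weights as per-patient event probabilities (independent within
patient), the probability that *X* has occurred while *Y* has not is

```
P(X+ | Y−) = mean_i[ w_iX (1 − w_iY) ] / mean_i[ 1 − w_iY ] ,
```

which reduces to patient counting for binary weights. Pairwise precedence
between a GM region and a WM tract is tested with McNemar's test of
marginal homogeneity on the binarized events (Benjamini–Hochberg FDR across
pairs). The full ordering is inferred by simulating monotone stochastic
progressions: at each step the next event is drawn with probability
proportional to P(X+ | all remaining events absent), and the **modal
sequence** — the event most frequent at each step across trajectories —
is the population ordering. Clinical milestones (Hoehn–Yahr ≥ 2 / ≥ 3, or
MCI / dementia) can be added as events, staging the structural sequence;
each patient's **disease state** is the sequence prefix whose indicator
template maximizes the scalar product with the patient's weights, and
states are related to UPDRS totals by Kendall's τ-b.

Because no patient-level imaging data ship with the package, a first-class
synthetic-cohort generator (`ebmseq.synthetic`) plants a known event
ordering along a latent disease timeline, with normative age/sex structure
and milestone/severity fields coupled to the same timeline — providing
ground truth for every stage of the analysis.

## Worked example

The numbered scripts under `analysis/` run the full study-scale analysis on
a synthetic cohort (130 patients, 75 controls, 62 GM + 48 WM regions, WM
events planted first). Running them in order:

```
$ python analysis/01_simulate_cohort.py
wrote cohort: 130 patients, 75 controls, 110 regions -> results/data
$ python analysis/02_alteration_weights.py
fitted normative model on 75 controls
weight matrix 130 patients x 110 regions; mean weight 0.603
control self-weights average 0.157 (the ramp's expectation under the standard normal is 0.159)
$ python analysis/03_pairwise_ordering.py
cross-tissue census over 2976 pairs: 2854 (96%) significant toward WM-precedes-GM, 0 (0%) toward GM-precedes-WM
all-region census: 9508/11990 ordered pairs significant (79%)
48/48 WM regions have positive precedence difference
$ python analysis/06_state_severity.py
state-UPDRS association: Kendall tau = 0.26, p = 0.000175, n = 130
```

Reading these numbers: of the 62×48 = 2976 GM–WM pairs, 96% are
FDR-significant in the direction "the WM tract is altered while the GM
region is not", and none in the reverse direction — the pairwise census
recovers the planted WM-before-GM structure essentially perfectly. Every WM
tract has a positive precedence difference P(WM+|GM−) − P(GM+|WM−). Later
predicted disease states go with higher UPDRS scores (τ = 0.26), as planted.
The trajectory-simulation sequence itself (script 04) is reported with
per-step modal frequencies; at this cohort size those are low (≈ 0.06),
and `docs/methods.md` discusses why the census is the robust cross-tissue
readout while the full 110-step sequence is only weakly identified.

The same pipeline is available as a CLI (`ebmseq simulate-data | validate |
weights | pairwise | order | stage | predict | report`) for use on real
cohort tables; see `ebmseq --help`.

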