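# Methods

This note documents the model and the choices behind `dcgnet`'s
implementation: the clustering geometry, its tunable parameters, the
synthetic cohorts used for validation, and the places where the method's
original description is incomplete and a concrete rule had to be fixed.

## Input model and validation

The pipeline's raw input is a subject- and trial-tagged symmetric
correlation matrix over named ROIs: unit diagonal, entries in [−1, 1],
symmetric within 1e−8.  The raw correlations carry an unknown, possibly
subject-specific scale; nothing in the pipeline estimates it.  Instead the
power transform `s_ij = |r_ij|^(1/T)` is applied over a wide temperature
range, which makes the unknown scale irrelevant: every analysis is phrased
in terms of the temperature-indexed family of similarity matrices.

## Regulated random walks and cluster sharing

At a fixed temperature, cluster structure is read off an ensemble of
regulated random walks on the similarity graph.  Walk mechanics (the
original method's description defers the details):

* the walk starts at a uniformly random node; from the current node it
  moves to an *active* (not yet removed) node `j` with probability
  proportional to `s(current, j)`, never staying put;
* every arrival counts as a visit; a node is removed when its cumulative
  visit count reaches `removal_visits` (default m = 3);
* after a removal the walk transitions out of the removed node by the same
  similarity rule.  This detail matters: it keeps the walk inside a
  partially exhausted cluster until the cluster is finished, which is what
  makes removal bursts coincide with clusters.  When the current node's
  active-similarity row is all zero (a dead end) the walk restarts at a
  uniformly random active node;
* a walk therefore takes exactly `n × m` steps.

**Segment boundaries.**  Removal-time gaps within a cluster burst are
short; gaps between bursts (wandering, re-accumulating visits in a fresh
cluster) are long.  The boundary rule splits the walk's gap distribution at
the threshold maximising between-class variance (Otsu's criterion) and cuts
at large-class gaps — but only when the largest gap exceeds
`mean + gap_factor × sd` (default gap_factor 1.0) of all gaps, so a
homogeneous removal stream (a single cluster) is never sliced.  A fixed
`mean + c·sd` rule alone cannot serve both scales: at the finest scale the
burst/wander contrast (gaps of ~1 vs ~3 steps) is well inside one standard
deviation, while the coarse scale needs roughly c = 1.  The bimodal split
adapts to both; with it, planted left/right pair motifs are recovered
essentially perfectly at T = 0.001 *and* planted region blocks at the
10-cluster level, which no fixed c achieved in our calibration runs.

The ensemble (default `n_walks = 100`) is summarised in the
cluster-sharing probability matrix `P`: entry (i, j) is the fraction of
walks in which i and j were removed within the same segment.  Every walk
draws its RNG stream from `SeedSequence([seed', walk_index])` with `seed'`
derived from the user seed and the temperature bit pattern, so sharing
matrices are reproducible bit for bit and independent of evaluation order.

## Cluster count and membership

The cluster count is the number of eigenvalues of the symmetrically
normalised sharing matrix `D^(−1/2) P D^(−1/2)` lying above the largest
consecutive gap of the sorted spectrum ("significantly non-zero"
eigenvalues).  A flat spectrum — no gap above 1e−8, e.g. the identity —
falls back to counting eigenvalues above 1e−8, so n mutually unrelated
nodes yield n clusters.  Membership comes from cutting the
complete-linkage tree on dissimilarity `1 − P` (complete linkage at every
scale, for uniformity with the fine-scale construction).

## Temperature tuning

The cluster-count trajectory (default grid: 40 log-spaced temperatures in
[0.001, 5]) shows the characteristic shape: a high plateau (~50 for the
106-ROI pair structure), a steep drop at a critical temperature, and decay
to 1.  Critical temperatures are the interval midpoints where the absolute
count change is at least half the largest change (the fraction is
configurable).  Trajectories are reported raw, without smoothing or
monotonicity enforcement.

`tune_to_count(K)` must pick, per subject, the temperature whose geometry
has K clusters.  Two available signals are individually unreliable in the
transition window: the eigengap estimate is bistable there (it can read 1
where a forced K-cut of the same tree is perfect), and the count achieved
by a forced K-cut is trivially K on featureless trees at large
temperatures.  The rule therefore gates on *tree support* — the width of
the merge-height interval over which the tree has exactly K clusters,
which is wide only where the geometry genuinely contains K clusters —
keeping temperatures with at least half the maximal support, and among
them prefers agreement of estimate and achieved cut with K, then the lower
temperature.  The returned level is the K-cluster cut at the selected
temperature, reporting the achieved label count (ties in the tree can
yield fewer) and the raw eigengap estimate as a diagnostic.  A target
beyond the finest attainable count (e.g. K = n) clamps to the finest
supported level at its natural cut.  In validation on the default
synthetic cohort, 64 of 64 tuned subject-trials matched the planted
10-region partition with adjusted Rand ≥ 0.95.

## Coarse-scale features

At the tuned 10-cluster level, concordance with the 10-region anatomical
atlas is measured by the Rand index (implemented on
`sklearn.metrics.rand_score`; an exhaustive pair-enumeration oracle covers
it in the tests).  The 55 retention features are, for each region, the
fraction of within-region ROI pairs sharing a cluster, and for each of the
45 region pairs the fraction of cross-region pairs sharing a cluster — a
cross-region pair that remains co-clustered is read as retained long-range
connectivity.  Feature order is fixed (10 intra then 45 inter, regions in
the canonical table order) for reproducible indexing.  Group screening
uses Welch two-sample t-tests, sign = ASD minus TD, raw p-values with
p ≤ 0.105 retained and no multiplicity correction: the screen is feature
selection, not inference.

The bundled 106-ROI atlas reproduces the true region sizes (Subcortical
10, Parietal 10, Occipital 14, Cerebelum 20, Frontal 22, Temporal 8,
Limbic 8, Insular 2, Central 6, Cingulum 6); its coordinates are synthetic
placeholders (region-clustered, left/right mirrored pairs) standing in for
real stereotaxic coordinates, which are not bundled.

## Fine-scale features

Motifs are the branches (≥ 2 ROIs; singletons excluded) of the
complete-linkage tree on `1 − P` at T = 0.001, cut at dissimilarity 0.85.
A motif is identified by its exact ROI set.  A group-trial domain maps
each motif to its prevalence (number of member subjects carrying it);
restriction at threshold τ keeps motifs with prevalence ≥ τ.

Two components are not fully specified in the method's original
description and are replaced by documented stand-ins:

* **odds score** — the sum over the subject's motifs present in both
  restricted domains of the log prevalence ratio (ASD over TD).  When the
  domains record member counts the ratio compares per-subject
  *proportions*; with equal-sized domains this reduces exactly to the
  count ratio (log(10/21) ≈ −0.742 for the worked example).  The
  per-capita form matters under the jackknife (below).
* **predictor transformation** — per trial, the odds score and the
  miss-count difference `miss_TD − miss_asd`, giving four predictors from
  the six fine-scale components (odds, missing-from-ASD-domain count,
  missing-from-TD-domain count, per trial).

**Jackknife consistency.**  A subject's own group's domain excludes the
subject; the opposite group's domain uses all members.  Two artifacts of
this asymmetry are corrected, because both encode group membership itself
and inflate classification on cohorts with *no* group signal:

1. raw count ratios are systematically smaller on the (smaller) own-group
   side — hence the per-capita odds;
2. a motif whose full-group prevalence is exactly τ is below threshold in
   the 28-member own-group domain of each carrier but present for everyone
   else.  Since every feature involves only motifs the subject carries
   (for which the jackknifed count is exactly full − 1), restricting a
   domain that lacks n of its group's members at τ − n reproduces the
   full-domain membership and removes the artifact.  Measured on null
   cohorts, these two corrections plus the leakage-free cross-validation
   below bring accuracy from ~0.66/0.71 to chance (~0.49/0.47).

## Classification

Leave-one-out logistic regression on the four fine predictors (optionally
augmented with named coarse variable sets), label cut at probability 0.5,
sensitivity = correct ASD fraction, specificity = correct TD fraction,
with explicit numerators and denominators.  By default each fold
recomputes training subjects' features with the held-out subject removed
from every motif domain, so nothing about the held-out subject can touch
the fit; the faster precompute-once mode (a single self-jackknife per
subject) is available but leaves the held-out subject inside training
subjects' domains — a transductive leak worth ~6–10 accuracy points on
null cohorts.  Maximum-likelihood fits use statsmodels; on perfect
separation or a singular Hessian the fit falls back to a small ridge
penalty (1e−4 on standardized slopes, intercept unpenalised), which strong
synthetic signal routinely triggers.  The τ sweep re-runs the procedure
over τ = 2..22 and the three trial modes.

With features collapsed to constants (τ above every prevalence), LOOCV on
a balanced cohort degenerates to the base-rate intercept and classifies
*below* chance (the held-out subject's group is always the training
minority); tests assert "no better than chance" for this regime.

## Synthetic cohorts

Each subject's matrix is a three-level template — baseline 0.10,
within-region 0.45 over the 10 regions, within-motif 0.90 over planted
left/right pairs (ids (1,2), (3,4), …, (105,106)) — plus optional
group-level regional shifts, symmetric Gaussian noise (sd 0.05; red trials
1.5× noisier, emulating their smaller trial counts), clipping, and repair
to the nearest valid correlation matrix by eigenvalue clipping with
diagonal renormalisation.  Motifs are included independently per
subject-trial with group-specific probabilities; the defaults are the
strong-signal study condition: base inclusion 0.7, four ASD-enriched and
four TD-enriched motifs at (0.85, 0.10), i.e. an expected prevalence gap
of ~22 of 29 subjects, and two modest regional shifts (±0.08).  The null
design removes every group difference.  Inclusion probabilities around
0.7 put typical prevalences near 20 of 29, matching the magnitudes
reported for real cohorts of this size; 29 + 29 subjects × green/red
trials mirror the motivating study layout.

What the generator does *not* emulate: fMRI time series and the upstream
GLM beta-series estimation (noise is a single dispersion knob), spatial
autocorrelation, scanner/site effects, partial-overlap motifs, or
subject-specific correlation scales.  Passing tests therefore show the
pipeline recovers the planted generative structure and behaves correctly
at its endpoints — not that real cohorts of this size are classifiable at
the same rates.

## Numerical choices and conventions

* symmetry/diagonal tolerance 1e−8; similarity underflow at extreme
  temperatures is harmless (a zero active row triggers the uniform
  restart);
* membership labels are canonicalised to 1..k by order of first
  appearance; cluster-label permutations never change features;
* all randomness flows from one seed via `SeedSequence`, fanned out per
  (subject, trial, temperature, walk) so results are order-independent;
* matrices are dense throughout (n ≈ 106).

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use the full 29 + 29 cohort for
classification endpoints (a few seconds per cohort with the numba walk
kernel), the green trials of all 58 subjects for tuned-level region
recovery (~2 s per subject at 40 grid temperatures × 100 walks), replicate
null cohorts (3 seeds) for the chance-level check — a single 29-subject
rate has binomial sd ≈ 0.09, so the mean over replicates is the honest
estimator — and two noiseless subjects for trajectory endpoints.

## Known limitations

* The original walk mechanics, the odds display and the four-predictor
  transformation are reconstructions; they are monotone-equivalent to the
  described quantities but not guaranteed identical to the originals.
* The eigengap estimate is bistable in the phase-transition window;
  tuning compensates via the tree-support gate, but reported trajectories
  can jump (e.g. 46 → 1) across the transition instead of pausing at
  intermediate counts.
* No real clinical cohort is bundled, so real-data classification rates
  are out of reach here.  The package reproduces the method's arithmetic
  identities, its worked examples, and its qualitative behaviour on
  synthetic data with known truth.
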