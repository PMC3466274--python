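# dcgnet

Multiscale clustering geometry of functional brain connectivity, with
motif-based classification.

`dcgnet` turns a subject's symmetric ROI × ROI correlation matrix (for
example a beta-series functional-connectivity matrix over 106 anatomical
parcels) into a *connectivity clustering geometry*: a temperature-indexed
hierarchy of clustering levels, fine to coarse.  From that geometry it
extracts two kinds of pattern information —

* **fine scale**: the ~50 small core clusters ("motifs", typically
  left/right homologue ROI pairs) at the bottom level, their per-group
  prevalence, and odds / missing-motif features for each subject;
* **coarse scale**: at the 10-cluster level, the 55 regional-connectivity
  retention proportions (10 within-region + 45 between-region) and their
  concordance (Rand index) with the anatomical parcellation —

and feeds them to a leave-one-out cross-validated logistic regression that
classifies subjects into two groups (ASD vs TD in the motivating
application), reporting sensitivity and specificity.

It is written for researchers analysing correlation-matrix connectivity
data who need scale-matched comparisons across heterogeneous subjects, and
ships a synthetic-cohort generator with planted ground truth so the whole
pipeline is testable without access to clinical data.

## The method in brief

A correlation matrix `r` is mapped to similarities by the power transform

    s_ij(T) = |r_ij|^(1/T)

where the temperature `T` acts as a focal scale: at `T = 0.001` only
near-perfect correlations survive (many small clusters), at large `T`
everything fuses into one cluster.  At each temperature an ensemble of
*regulated random walks* explores the similarity graph — each walk moves to
an active node with probability proportional to similarity and removes a
node on its m-th visit, so a walk trapped in a tight cluster exhausts it in
a burst of removals.  Bursts (segments of the removal-time sequence)
delimit clusters per walk, and the ensemble is summarised in a
cluster-sharing probability matrix `P`: entry (i, j) is the fraction of
walks in which i and j fell in the same burst.  The cluster count is read
from the spectrum of `D^(-1/2) P D^(-1/2)` (eigengap rule), and the
membership from cutting a complete-linkage tree on `1 − P`.  Sweeping `T`
gives the cluster-count trajectory with its phase-transition temperatures;
"tuning" selects the level with a target cluster count (10 for the coarse
scale) per subject, making subjects with unknown, heterogeneous raw scales
comparable.

## Worked example

```python
import numpy as np
from dcgnet import (CohortDesign, ConnectivityClassifier, DataCloudGeometry,
                    WalkParams, simulate_cohort)

# a cohort of 29 + 29 subjects x 2 trials with planted pair-motifs,
# 10 region blocks, and group-differential motif prevalence
cohort = simulate_cohort(CohortDesign(seed=101))

# one subject's geometry, tuned to the 10-cluster level
model = DataCloudGeometry(cohort.matrices[("ASD01", "green")],
                          walk_params=WalkParams(seed=7))
res = model.tune(10)
print(res.summary())
print("Rand index vs anatomy:", round(res.rand_index_against(cohort.atlas), 3))

# fine-scale motif features -> leave-one-out logistic classification
clf = ConnectivityClassifier.from_cohort(cohort, base_seed=11)
print(clf.fit().summary())
```

Output:

```
Data cloud geometry level
========================================
subject:       ASD01 (ASD/green)
n ROIs:        106
temperature:   0.1519
clusters (k):  10  [eigengap estimate 9]
cluster sizes: [22, 20, 14, 10, 10, 8, 8, 6, 6, 2]
Rand index vs anatomy: 1.0
Leave-one-out logistic classification
=============================================
variables:    fine
tau:          14
trials:       green+red
sensitivity:  29/29 = 1.000
specificity:  29/29 = 1.000
```

The tuned level's ten clusters coincide exactly with the ten planted
anatomical regions (Rand index 1.0; the bracketed eigengap estimate is the
raw spectral count at that temperature, a diagnostic).  On this
strong-signal cohort — eight motifs planted with a prevalence gap of about
22 of 29 subjects between groups — the leave-one-out classifier separates
the groups perfectly, while on a null cohort with no group differences it
performs at chance.

A command-line interface mirrors the library:

```bash
dcgnet simulate --out cohort/ --seed 1
dcgnet tune --matrix cohort/matrices/ASD01_green.tsv --k 10 --out mem.tsv
dcgnet motifs --matrix cohort/matrices/ASD01_green.tsv --out motifs.tsv
dcgnet classify --cohort cohort/ --tau 14 --trials green,red --out cls.tsv
dcgnet sweep --cohort cohort/ --tau 2:22 --out sweep.tsv
```

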