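# muscnet

Multi-source brain functional connectivity networks with weighted-voting
fusion, for classifying mild cognitive impairment (MCI) against normal
controls (NC) from resting-state fMRI ROI time series.

## The problem and the model

A brain functional connectivity network (BFCN) represents each atlas region
of interest (ROI) as a node and weights the edge between ROI *i* and ROI *j*
by a pairwise association of their BOLD time series,

    W_ij = corr(V_i, V_j),

where `corr` is one of five metrics: Pearson (PCC), Spearman (SCC),
Kendall tau-b (KCC), cosine similarity (CS), or the maximal information
coefficient (MIC).  PCC equals cosine similarity of the mean-centred
vectors; MIC — the maximum over all r×c grids with `r·c ≤ floor(n^0.6)` of
the gridded mutual information over `log2 min(r, c)` — also captures
nonlinear couplings that correlation-style metrics miss, and is implemented
here from scratch with an exhaustive small-n oracle.

Networks are built either statically (whole series) or dynamically: the
series is cut into

    num_window = floor((num_volume − window_size) / window_step) + 1

sliding windows, one connectivity square per window, averaged element-wise.
Each subject's square is flattened to an edge-feature vector; a univariate
two-sample filter (Student t, Wilcoxon rank-sum, or two-sample
Kolmogorov–Smirnov) keeps features with p < threshold, computed inside each
cross-validation fold from training subjects only.  One linear-kernel SVM is
trained per metric of a duet and their decision scores are fused as

    score = α·score_A + (1−α)·score_B,   α ∈ {0.1, …, 0.9},

with MCI predicted when the fused score is positive.  Evaluation is
leave-one-out cross-validation (LOOCV) reporting accuracy, sensitivity and
specificity; a nested (two-level) LOOCV tunes (α, threshold) on inner folds
only.  Selection frequencies across folds rank edges and ROIs by stability,
and top-k rankings of two metrics can be compared edge by edge.

A bundled generator produces two-group synthetic BOLD cohorts with known
differential connectivity — linear correlation shifts or quadratic couplings
planted on a chosen edge set, with AR(1) temporal smoothness — so the whole
pipeline is testable without any scanner data.

## Worked example

```bash
muscnet simulate --out cohort --seed 42 --n-per-group 10 --num-roi 10 \
                 --num-volume 137 --effect-delta 0.5
muscnet evaluate --manifest cohort/manifest.tsv --duet PCC,SCC \
                 --window-size 50 --window-step 8 --threshold 0.05 --out eval
muscnet report   --evaluation eval/evaluation.json --num-roi 10 --top-k 5 --out rep
```

prints

```
wrote cohort manifest: cohort/manifest.tsv
PCC&SCC: Acc=1.0000 Sn=1.0000 Sp=1.0000
PCC&SCC: top-5 overlap = 4
```

and the first lines of `rep/frequency_PCC_SCC_PCC.tsv` are

```
feature	roi_i	roi_j	label_i	label_j	count
4	0	5	ROI0	ROI5	20
13	1	6	ROI1	ROI6	20
```

Reading: the simulated cohort plants a +0.5 correlation shift on edges such
as (0,5) and (1,6) in the patient group.  The PCC&SCC fusion separates the
groups perfectly under LOOCV (20 subjects, each predicted once), the two
metrics' top-5 stability rankings share 4 of 5 edges, and the planted edges
are selected by the t-test filter in all 20 folds (`count` = folds
selected).  The same stages are available as library calls
(`generate_cohort`, `feature_matrix`, `loocv`, `alpha_grid`,
`frequency_table`) and through `muscnet sweep` for window/duet grids and
`muscnet evaluate --nested` for the two-level protocol.

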