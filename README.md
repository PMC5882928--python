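# mcs — multidimensional cluster statistics

`mcs` decides whether labeled clusters of points in n-dimensional space are
significantly **disjoint**. It was built for sustained-activity
neurophysiology: multichannel recordings (LFP, MEG, EEG) under known
stimulus conditions are converted into n-dimensional *state vectors* (one
per sliding time window, n = number of channels), each carrying its
condition label, and the question is whether different conditions occupy
statistically distinguishable regions of state space — even when overall
activity levels do not differ between conditions. The statistic works on
any labeled point cloud, not only on electrophysiology.

## The statistic

For clusters A and B, let d(A,A) and d(B,B) be the mean pairwise Euclidean
distances within each cluster and d(A,B) the mean distance across them
(the *proximity matrix* holds these block means). The **discrimination
value**

    Δ(A, B) = d(A, A) + d(B, B) − 2 d(A, B)

is negative when the clusters are dense and far apart (geometrically:
disjoint), positive when they overlap; the factor 2 balances the intra- and
inter-cluster contributions. Significance comes from a label-permutation
test: the labels are randomly re-assigned N times (class sizes preserved;
default N = 10⁴), Δ is recomputed for each re-labeling, and the p-value is
the probability of finding a re-labeling that separates at least as well
as the observed one. By default the add-one estimator
p = (1 + #{Δᵢ ≤ Δ₀})/(N + 1) is used; when the number of distinct
labelings is small the null is enumerated exhaustively. For L > 2 clusters
the global discrimination value sums Δ over all unordered cluster pairs.
The same quantity assigns new points: x joins the cluster whose tentative
membership minimizes the global Δ.

Multidimensional scaling (classical/Torgerson) is included for
visualization only — trajectories through state space and "attractor
basin" summaries (cluster centroids with disks whose diameters equal the
mean intra-cluster distances). No statistic depends on the projection.

## Worked example

```bash
python examples/01_cluster_disjointness_test.py
```

```
mean intra-cluster distances: d(A,A) = 5.587, d(B,B) = 5.604
mean inter-cluster distance:  d(A,B) = 7.578
discrimination value delta  = -3.965
permutation p-value         = 1.00e-04 (N = 10000)
-> delta < 0 with a tiny p: the clusters are significantly disjoint.
```

Two 16-dimensional Gaussian clusters (100 points each, centroids 5σ apart)
are denser within than across (5.59/5.60 vs 7.58), giving Δ = −3.97; none
of 10⁴ random re-labelings separates as well, so p hits the estimator's
floor 1/(N+1) = 10⁻⁴. `examples/02_recording_to_state_vectors.py` runs the
full recording pipeline (a surrogate 16-channel session with four
conditions, power-matched so amplitude carries no information) and prints
the matrix of pairwise p-values, all at the 0.001 floor;
`03_trajectory_visualization.py` and `04_assign_new_points.py` demonstrate
the MDS plots and the assignment rule.

The same functionality is reachable from a shell:

```bash
mcs simulate recording --out rec.csv --schedule sched.csv --seed 3
mcs preprocess --input rec.csv --schedule sched.csv --rate 1000 --out pts.csv
mcs test --input pts.csv --pair silence 1kHz --n-perm 10000 --seed 1
mcs run --recording rec.csv --schedule sched.csv --rate 1000 --out results/
```

## Layout

- `src/mcs/core.py` — point sets, distance/proximity matrices, Δ
- `src/mcs/permutation.py` — permutation null, p-value estimators
- `src/mcs/preprocessing.py` — onset exclusion, sliding RMS, z-score
- `src/mcs/mds.py` — classical MDS, trajectory and basin plots
- `src/mcs/assignment.py` — Δ-based assignment of new points
- `src/mcs/synthetic.py` — cluster / trajectory / recording generators
- `src/mcs/io.py`, `pipeline.py`, `cli.py` — delimited-text IO, the
  composed run, and the `mcs` command

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations (in particular the exchangeability caveat for
overlapping windows).
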