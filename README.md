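# dtwshift

Time-shift estimation between biological time series, with
simulation-based significance.

## The problem

Development runs at different speeds in different species, individuals or
conditions.  Given two noisy expression time series for a gene — say human
and chimpanzee prefrontal cortex sampled across postnatal ages — the
question is not only *whether* the trajectories differ, but *when* one
lags the other, and by how much at each age.  `dtwshift` answers this with
a modified dynamic-time-warping alignment and attaches per-gene
significance, so that heterochrony calls (delayed vs accelerated
development, i.e. neoteny vs acceleration) come with a calibrated false
positive rate.

## The method

Each group's trajectory is smoothed with a natural cubic smoothing spline
(target effective df or GCV) and resampled at uniform time points —
M points for the reference series X, N ≤ M for the query series Y.  The
aligner then finds the minimum-cost monotone warping of Y onto X subject
to:

* **balance** — exactly N of the M reference columns are aligned (so
  exactly M − N are omitted);
* **multiple mapping** — a point of either series may align to several
  consecutive points of the other;
* **unanchored ends** — omissions are allowed before the first and after
  the last match.

Cost is the sum of squared expression differences over aligned pairs.  The
dynamic program fills the cube Mat[i][j][k] — the best alignment of the
first i query points to the first j reference columns with k omissions —
in O(M·N·(M−N)) with O(1) work per cell, and is verified exactly against
an exhaustive oracle.  Per query point,

    shift(Yᵢ) = mean(time(Xⱼ), …, time(Xⱼ₊q)) − time(Yᵢ),

and on the chronological reporting scale log₂(query age / aligned
reference age), positive values mean the query trajectory is delayed.

Significance is Monte-Carlo, per gene: a spline model fitted to one
observed series plus its residual error distribution generates B
zero-shift pairs; the pointwise p-value is the fraction of simulations
with at least the observed |shift|.  The count of significant points per
gene is thresholded at the smallest c whose false positive rate
FPR(c) = P_null(count ≥ c)/P_real(count ≥ c) — estimated from G extra
zero-shift replicates per gene — falls below a target (default 10%).

## Worked example

Recover a known injected shift from synthetic data: a sine-wave signal
(one full period), 15% of total variance as noise, and a constant time
shift of 5 units between the two series:

```bash
dtwshift simulate --model sine --shift const:5 --sd 0.3 \
    --n 20 --N 20 --M 40 --R 100 --seed 7 --out report.json
```

prints

```
interior mean estimate: 4.9560 (true interior mean 5.0000)
```

and `report.json` holds the per-time-point summary over the 100
replicates; its `mean_estimate` at the twelve central query points is

```
4.32 4.48 4.77 5.08 5.09 5.27 5.71 5.45 5.22 4.54 3.95 4.36
```

— the injected shift of 5 recovered within a fraction of the observed
grid step at interior ages (edge points are biased by design: estimated
shifts cannot leave the reference age range).

On real data the same machinery runs from TSV inputs (an expression
matrix, genes × samples, plus a `sample / group / age` metadata table):

```bash
dtwshift align --expr expr.tsv --meta meta.tsv \
    --query-group chimp --ref-group human --Kq 20 --Kr 40 --out shifts.tsv
dtwshift significance --expr expr.tsv --meta meta.tsv \
    --query-group chimp --ref-group human --B 1000 --G 50 \
    --target-fpr 0.10 --seed 17 --out sig.tsv
dtwshift classify --shifts shifts.tsv --sig sig.tsv \
    --min-consistency 0.7 --k 3 --runs 1000 --seed 3 --out calls.tsv
```

`shifts.tsv` has one row per gene and query time point (raw and reporting
shifts plus alignment cost); `sig.tsv` the per-gene significant-point
counts, calls and the FPR-calibrated threshold (with an `sig.tsv.json`
sidecar holding the full FPR(c) curve); `calls.tsv` the
delayed/accelerated/none direction calls and k-means cluster labels, with
per-cluster mean profiles and a clustering-stability report alongside.

See `docs/methods.md` for the model, conventions and numerical choices.

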