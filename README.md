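# smartclust

Clustering with automatic selection of the number of clusters, for
object-by-feature matrices such as gene-expression profiles (genes ×
samples) or planar signal constellations.  The package implements a
*splitting-while-merging* control loop: starting from one or two clusters
it alternately splits where structure is unexplained and merges where two
clusters describe the same structure, records every intermediate
clustering, and returns the one with the minimal **message length** — so
neither the number of clusters nor a range for it is ever supplied.

Two interchangeable engines drive the loop:

* **Competitive learning** (`run_smart1`): each prototype `P` carries an
  *asymptotic property vector* `A` defining a shrinking dynamic
  neighbourhood (input `X` is "inside" when `‖X − P‖ ≤ ‖A − P‖`) and a
  *distant property vector* `D` tracking far patterns.  The learning rate
  `α = (‖A−P‖ / (‖X−P‖ + ‖A−P‖))²` makes one prototype settle inside one
  natural cluster; the cluster with the largest within-cluster variance
  is split at its DPV, and clusters are merged when the largest pairwise
  *cohesion* (mean over the union of `2·min(p_i,p_j)/(p_i+p_j)` under the
  two fitted normal densities) exceeds γ times the median cohesion.
* **Finite Gaussian mixtures** (`run_smart2`): component-wise EM where a
  Dirichlet-type prior turns the weight update into
  `α_m ∝ max(0, Σ_i w_im − N/2)` (`N` = free parameters per component),
  so under-supported components are annihilated — learning and merging in
  one sweep.  Splitting injects a deterministic new component at the data
  row farthest from its closest component mean, with the average of the
  surviving covariances.

Both engines score every recorded candidate with the two-part code length

```
L(θ, Y) = (N/2) Σ_{m: α_m>0} ln(n α_m / 12) + (k/2) ln(n/12)
        + k (N + 1) / 2 − ln p(Y | θ)
```

and output the candidate minimizing `L`.  Covariances may be full,
diagonal or spherical; the default is full for `d ≤ 3` and diagonal for
gene-expression dimensionality.

The package also ships the four synthetic benchmark generators used to
validate the method (QPSK constellations, overlapping bivariate Gaussian
mixtures, state-based and periodic cell-cycle gene expression) and the
standard validation metrics (ARI, NMI, Jaccard, silhouette,
Calinski–Harabasz, correct selection rate).

## Worked example

```python
import numpy as np
from smartclust.simulate import QpskSpec, gen_qpsk
from smartclust.smart import SmartConfig, run_smart2
from smartclust.metrics import adjusted_rand_index

data, truth = gen_qpsk(QpskSpec(n=512, snr_db=15.0), np.random.default_rng(7))
result = run_smart2(data, SmartConfig(seed=0))
for cand in result.candidates:
    print(f"k={cand.k_nz}  L={cand.message_length:9.2f}")
print(result.k_selected, adjusted_rand_index(truth, result.labels))
```

prints

```
k=1  L=  1121.17
k=2  L=   856.92
k=3  L=   317.88
k=4  L=    31.62
k=4  L=    31.62
...
4 1.0
```

The code length drops steeply while genuine constellation components are
being added (1 → 2 → 3 → 4) and flattens once all four corners are
covered: later injected components are annihilated and the loop stops
after the merge budget.  The selected clustering has four clusters and
adjusted Rand index 1.0 — no sample is mis-assigned.  The
`examples/` directory contains one narrative script per capability
(QPSK, periodic and state-based expression, competitive learning, the
metrics).

## Command line

```bash
smartclust simulate s2 --seed 1 --out cycle          # data + truth labels
smartclust cluster --input cycle.tsv --seed 1 --out run
smartclust evaluate --pred run.labels.tsv --truth cycle.labels.tsv
smartclust replicate d1 --reps 20 --seed 1           # reduced-scale benchmark
```

`cluster` writes a two-column label TSV and a plain-text manifest (config,
seed, input digest, per-candidate code lengths) sufficient to replay the
run.

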