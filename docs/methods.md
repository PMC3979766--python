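# Methods

## The problem

Given `n` objects with `d` real-valued features (typically genes by
samples), find both a partition and its cardinality `K` without any
dataset-dependent parameter.  The package's splitting-while-merging (SWM)
loop interleaves cluster splitting and merging inside one process: after
each learn-and-merge phase the current clustering is recorded as a
candidate, the loop terminates once the cumulative number of merges
reaches a budget `M_max`, and a minimum-message-length (MML) criterion
selects the final clustering among the candidates.  Splitting supplies
candidates at increasing `K`; merging both corrects over-splitting and
provides the termination signal ("merges become frequent once the natural
clustering has been passed").

## Selection criterion

Every candidate is scored as a two-part code: parameters first, then the
data given the parameters.  For a Gaussian mixture with surviving weights
`α_m` and `N` free parameters per component,

    L(θ, Y) = (N/2) Σ_{α_m>0} ln(n α_m / 12)
            + (k/2) ln(n / 12) + k (N + 1)/2 − ln p(Y | θ),

in nats, with `N = d + d(d+1)/2`, `2d`, or `d+1` for full, diagonal and
spherical covariances.  Zero-weight components are excluded.  Hard
partitions (from the competitive-learning engine) are bridged into this
criterion by refitting a Gaussian to each cluster with weight equal to
the member fraction.  Ties in `L` break toward fewer clusters.

Absolute values of `L` depend on scaling conventions and are not
comparable across datasets; only the ordering of candidates on one
dataset matters.

## Mixture engine (component-wise EM with annihilation)

Components are visited one at a time.  At component `m`'s turn the
responsibilities are computed in log space, the weight M-step

    α_m ← max(0, Σ_i w_im − N/2) / n   (then all weights rescaled to 1)

is applied to that component only, and — if it survived — its mean and
covariance are re-estimated by weighted MLE and its cached densities
refreshed.  A component whose expected support falls below `N/2` is
annihilated: merging and learning happen in the same sweep.  Sweeps stop
when the relative change of `L` falls below `tol` (default `1e-5`, cap
500 sweeps).

Two numerical guards sit on top of the textbook update:

* **Coding-validity floor.**  A survivor must also carry the criterion's
  quantization mass, `n·α_m ≥ 12`, so that its parameter-cost term
  `ln(n α_m/12)` is non-negative.  Below that mass the asymptotic
  approximation behind the criterion is invalid and, left unchecked,
  rewards 2–4-point "parasite" components whose ridge-regularized
  covariances produce arbitrarily high densities.  The same floor (as
  `⌈N/2 + 12⌉` members) is applied before hard partitions are refitted.
* **Ridge regularization.**  Every estimated covariance receives
  `1e-6 · mean(diag) · I`.  A consequence is that the per-sweep decrease
  of `L` is exact only to ~`1e-5` relative (each M-step is an inexact
  argmax), which the tests assert at that tolerance.

### Growth: deterministic injection with an establishment hold

After convergence the candidate is recorded and a new component is
injected at the data row farthest (Euclidean) from its closest surviving
mean, with the element-wise average of the surviving covariances and
weight `1/(k+1)` (survivors rescaled).  Because that row is by
construction in a low-density tail, the newcomer initially has no basin
of support: judged immediately, its weight collapses before it can
migrate, and the loop stalls below the true `K`.  The run therefore
*holds* the newcomer's weight for up to 3 sweeps (released early once its
mean settles to within `1e-3` of the data radius per sweep) while its
mean and covariance adapt freely; only then does the support-based update
judge it.  Three sweeps is long enough for a newcomer to migrate onto a
cluster the incumbents do not explain and short enough that a newcomer
parked on covered territory still starves; longer holds measurably let
tail sub-clumps establish, shorter ones re-introduce the stall.

The `k=2` start uses two distinct random data rows with *small spherical*
covariances (one tenth of the mean per-feature variance).  Starting tight
and local lets each component grow onto coherent nearby structure; broad
initial covariances straddle several clusters and bias the two-component
fit into axis-split local optima that poison every later split.

The `k=1` candidate (single Gaussian, no learning) is always in the
candidate list.

## Competitive-learning engine

One-prototype-take-one-cluster (OPTOC) learning: each prototype `P` pairs
with an asymptotic property vector `A` (initialized at the farthest
object) and a distant property vector `D` (initialized at `P`).  For each
input `X` and winner prototype `i` (nearest by Euclidean distance):

* neighbourhood test: `X` is inside iff `‖X − P_i‖ ≤ ‖A_i − P_i‖`;
* inside: `n_A ← n_A + 1`, `A ← A + (X − A)/n_A`;
* always: `P ← P + α (X − P)` with
  `α = (‖A−P‖ / (‖X−P‖ + ‖A−P‖))²`, so outside patterns contribute less;
* outside and farther than the DPV: `n_D ← n_D + 1`,
  `D ← D + (X − D)/n_D`.

The input order is re-randomized every epoch.  Convergence is the
relative, data-independent test `‖A − P‖ / data_radius ≤ ε` (default
`ε = 0.005`, capped at 500 epochs with a logged warning).  Splitting
appends a prototype at the DPV of the cluster with the largest mean
squared member-to-prototype distance (fallback: its farthest member),
and all APVs/counters reset for re-learning.  Merging fits a Gaussian to
each nearest-prototype cluster and repeatedly merges the pair with the
largest cohesion

    Cohesion(C_i, C_j) = (1/(|C_i|+|C_j|)) Σ_{x ∈ C_i ∪ C_j}
                         2 min(p_i(x), p_j(x)) / (p_i(x) + p_j(x))

while it is at least `γ = 20` times the median of all pairwise cohesions,
with two guards: fewer than three pairs make the median meaningless (no
merge), and the maximum must exceed an absolute floor of `1e-6` —
when every pairwise cohesion has underflown, the ratio of two negligible
numbers says nothing about closeness (well-separated unit-variance
clusters a hundred standard deviations apart already score below the
floor).

A known limitation: when `K` is below the true cluster count,
nearest-prototype clusters straddle shared groups and their fitted
Gaussians genuinely overlap, so the cohesion rule can merge them and
consume the merge budget early.  On geometries like the four-corner
constellation the competitive-learning engine therefore underestimates
`K`; it is reliable on configurations where each prototype can own one
cluster at every stage (up to a handful of separated groups).  The
mixture engine is the recommended default.

## Parameters

| name | default | meaning |
|---|---|---|
| `eps` | 0.005 | OPTOC relative convergence threshold, dimensionless, range (0,1) |
| `gamma` | 20 | cohesion max-vs-median merge ratio, > 1 |
| `m_max` | 5 | cumulative merges before the SWM loop stops |
| `cov_structure` | full if `d ≤ 3` else diagonal | component covariance constraint |
| `tol` | 1e-5 | relative message-length change ending a CEM sweep phase |
| `hold_sweeps` | 3 | establishment hold for an injected component |
| `seed` | 0 | all randomness flows from one generator |

`m_max` and `gamma` are deliberately neutral: the selected `K̂` on the
benchmark generators is identical for `m_max ∈ {2, 5, 10, 20}` (asserted
in the test suite).  With diagonal covariance `N/2 = d`, so on 20–24
sample expression matrices a component needs ≥ `d` expected members —
full covariance there would demand more members than realistic clusters
have, which is why diagonal is the high-dimensional default.

## Synthetic data generators

* **QPSK** — four unit-energy constellation points `(±1/√2, ±1/√2)` with
  white Gaussian noise of per-dimension variance `10^(−SNR/10)/2` (the
  standard Es/N0 convention); default 512 samples at 15 dB.  A planar
  4-component mixture whose components are ~11 within-cluster standard
  deviations apart.
* **Overlapping bivariate mixture** — three equal-weight components at
  means `(0,−2), (0,0), (0,2)` with shared diagonal covariance
  `diag(4, 0.4)` (the classic demonstration's `diag(2, 0.2)`, doubled),
  900 points: adjacent means are ~3.2 standard deviations apart along the
  separation axis, so ~7% of points are on the wrong side of the optimal
  boundary and the best achievable ARI is ≈ 0.7.
* **State-based expression (11 clusters)** — per cluster: size
  `max(10, Poisson(60))`; the sample axis (default 20) is cut into four
  contiguous periods by a uniform random composition; a period template
  `~N(0, 1.5²)`, per-sample template `~N(template, 0.5²)` shared by the
  cluster's genes, per-gene values `~N(sample template, 0.5²)`, plus
  additive noise `N(0, noise_sd²)`.  The hierarchy scales are this
  package's calibration of a model whose printed constants are not
  recoverable; they produce near-perfect clustering at noise sd ≤ 0.1 and
  breakdown above ~0.4.  Because the 11 templates are random, two
  clusters occasionally nearly coincide and are then statistically one
  group — the dominant failure mode at low noise, and the reason correct
  selection saturates near 60% rather than 100%.
* **Periodic (cell-cycle) expression** — gene `g` in cluster `c` at
  sample `j`:
  `x = (λ + θ_mag·u) · sin(2π j/8 + 2π c/K + θ_phase·v)` with `u, v`
  independent standard normals, `λ = 3`, 24 samples (three 8-sample
  cycles), 5 clusters of 100 genes.  Phases are equally spaced.

What the generators do *not* emulate: real-array artefacts (dye bias,
missing values, heteroscedastic noise), gene-gene correlation within a
cluster beyond the shared template, and autocorrelated noise.  Passing
the benchmark tests therefore demonstrates correct model-order recovery
under the stated generative models, not performance on real arrays.

## Measured behaviour and honest limits

At the defaults, across seeded replicate datasets: the QPSK benchmark is
recovered perfectly in ~96% of replicates (mean ARI ≥ 0.99), the periodic
expression benchmark in 100% (ARI 1.0), the state-based benchmark in
~55–60% at noise sd 0.1 (failures merge template-collision pairs), and
the overlapping mixture's component count in ~82–90% with ARI ≈ 0.7.  The
overlapping-mixture failures are not search failures: on those data
realizations a fit with a small fourth component (13–90 points capturing
tail structure of the heavy-tailed doubled covariance) has a genuinely
lower code length than the truth-initialized three-component fit, by
0.4–9 nats.  Under the criterion "select the minimal message length"
those selections are correct by definition of the criterion; a selection
rule is not overridden case-by-case here.

## Numerical choices

* All densities and responsibilities in log space (`logsumexp`); cohesion
  evaluated as `2/(1 + exp(|log p_i − log p_j|))`, floored at `1e-300`.
* Nearest-prototype and maximum-posterior ties break toward the lower
  index; labels are always re-compacted to contiguous `1..K`.
* Row standardization (`standardize_rows`) uses the `n−1` denominator and
  refuses constant rows by name.  It is available behind a CLI flag and
  off by default for simulated data, which is clustered as generated.
* An injection target coinciding exactly with an existing mean is
  perturbed by `1e-6` of the data radius (logged).
* Degenerate guards: singleton clusters are absorbed into their
  nearest-centroid neighbour before any Gaussian refit; a mixture whose
  components all annihilate aborts the phase and selection falls back to
  the recorded candidates; if `K` returns to 1 twice in the
  competitive-learning loop the run terminates (oscillation guard).
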