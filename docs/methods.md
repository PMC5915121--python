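# Methods

## Problem and model

`netprio` implements guilt-by-association candidate nomination on a
protein–protein interaction (PPI) network: proteins that participate in a
functional system (the motivating case is angiogenesis) tend to be mutually
proximal in the interactome, so a random walker that repeatedly restarts at
the known members visits the undiscovered members more often than the
background. The stationary visit distribution

    p∞ = r (I − (1 − r) W)⁻¹ p0

is linear in the restart distribution `p0` (uniform over the seed set) and
defines both a per-node score and, column by column, an affinity kernel
`K = r (I − (1−r) W)⁻¹` between node pairs. The system is nonsingular for
every `r ∈ (0, 1]` because the spectral radius of `(1−r) W` is at most
`1 − r < 1` under either supported normalization.

Two transition normalizations are supported, because the literature uses
both and neither is canonical:

* **column-stochastic** (default): `W = A D⁻¹`. Classical RWR; probability
  mass is conserved (`Σ p∞ = 1`) whenever the restart mass sits on
  non-isolated nodes.
* **symmetric-degree**: `W = D^(−1/2) A D^(−1/2)`. `K` is then a symmetric
  positive-definite graph kernel; the score vector is no longer a
  probability distribution.

**Isolated nodes.** A degree-0 node has an all-zero transition column. It
can never receive propagated mass; if it *carries* restart mass it retains
exactly the `r·p0` share (so a single isolated restart node scores `r`, not
1). This convention is deliberate and documented rather than patched over
with self-loops: a protein with no interactions genuinely supports no
propagation, and silently renormalizing would hide that.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `r` (restart probability) | 0.3 | per-step probability of teleporting back to the seeds; larger values localize the walk. 0.3 is a community-standard choice for PPI prioritization and results are insensitive to moderate changes. |
| `normalization` | column-stochastic | see above |
| `tol` | 1e-10 | L1 convergence threshold of the power iteration; L1 matches the probability-mass reading of the iterate |
| `max_iter` | 1000 | iteration cap; non-convergence is reported, not hidden |
| `dense_node_cap` | 20 000 | explicit guard above which the direct solve and kernel materialization are refused in favour of per-seed iteration |
| `combine_rule` | max | integration rule: a pair is linked at its strongest evidence across sources. `sum-capped-at-1` and `weighted-mean` (with per-source coefficients) are available; the original integration rule of multi-source PPI pipelines is typically unstated, hence configurable |
| `top_k` | 300 | short-list cut carried forward for detailed study |
| `seed_policy` | excluded | seeds are dropped from the candidate list (discovery wants novel proteins); `flagged` keeps them marked for diagnostics |

Unweighted edges read from curated association lists default to weight 1.0.
Identifier matching is exact, case-sensitive string equality; no mapping
layer is provided.

## Ranking and tie handling

Candidates are sorted by descending score; equal scores break by ascending
node id. The tie rule is arbitrary but documented and deterministic, so
repeated runs are byte-identical — reproducibility over false precision.

## LOOCV, ROC and AUC

Each seed `s` is held out; the restart vector is rebuilt uniformly over the
remaining seeds; `s` is ranked among the non-seed nodes plus itself.
Remaining seeds are excluded from the ranking pool — they would otherwise
crowd the top ranks and distort the ROC (a documented choice; the
alternative, ranking against all proteins, is not exposed).

Each fold contributes one positive at rank `ρ` among `n_neg = N − |seeds|`
negatives, i.e. a step ROC jumping 0→1 at FPR `(ρ−1)/n_neg`. Folds are
combined by vertical averaging on the common FPR grid `k/n_neg`, with
duplicated x-coordinates at jumps so the trapezoidal area of the emitted
polyline equals the rank-formula AUC

    AUC = mean over folds of (n_neg − (ρ − 1)) / n_neg

*exactly* (to 1e-12), which in turn equals Mann–Whitney pairwise counting.
No per-gene p-values are computed — this is ranking, not testing — so no
multiple-testing correction applies.

For networks under `dense_node_cap`, per-fold scores are computed from
single-seed solves sharing one sparse LU factorization and combined by
linearity of the fixed point in `p0`; this is algebraically identical to
re-solving every fold and is cross-checked against the iterative path in
the tests.

## Null baselines

Two controls are provided:

* **uniform random seeds** of equal size — the no-signal reference; its
  LOOCV AUC centres on 0.5.
* **degree-matched null**: non-seed nodes sampled without replacement to
  match the seeds' degree distribution by quantile bin (default 10 bins;
  bins short of candidates borrow from the nearest bins with a warning).
  This guards against the walk merely chasing hubs.

On the *synthetic* benchmark the degree-matched null scores high (often
AUC ≈ 0.95): in a planted-partition graph, elevated degree is itself almost
a perfect marker of module membership, so degree-matched sampling
preferentially picks held-out module members. The meaningful comparison is
therefore paired — true seeds still beat their matched null in the large
majority of replicates — and the null is best read as a stringent,
adversarial baseline on this topology, not as "random performance".

## Synthetic benchmark

`generate_planted_module` draws an Erdős–Rényi background of
`n_background = 500` proteins containing a `module_size = 50` module whose
internal pairs are linked with `p_in = 0.30` against a background
`p_out = 0.01`, unit weights; `seed_fraction = 0.5` of the module is
revealed as seeds and the rest held out as recoverable truth. These
defaults emulate a sparse interactome slice (mean background degree ≈ 5, a
~20× density contrast inside the module — strong but not trivial signal,
comparable to a well-annotated pathway). `p_in = p_out` is allowed and is
the no-signal control. A preferential-attachment background
(`background_model="preferential-attachment"`, Barabási–Albert with
attachment count matched to the target background density) stresses the
hub-robustness of the ranking; no acceptance-grade thresholds are attached
to it.

`generate_multi_source` splits one master network into `n_sources` noisy
evidence layers (independent per-edge retention `1 − dropout`, weights
uniform in (0.5, 1]) to exercise integration; at `dropout = 0` every layer
reproduces the master topology.

What the generator does **not** emulate: realistic degree distributions of
curated interactomes (study bias, hub ascertainment), correlated noise
between evidence sources, weighted-confidence structure, or identifier
mess. Passing benchmarks here show the machinery is correct and recovers a
cohesive module under clean conditions; they do not certify performance on
a real interactome.

## Numerical and design choices

* Power iteration converges linearly with factor `≤ 1 − r`; at the default
  `r = 0.3` and `tol = 1e-10`, ~70 iterations suffice. Solver agreement
  (iterative vs. direct, kernel columns vs. single-seed solves) is enforced
  at 1e-8 / 1e-10 in the tests.
* Benchmark problem sizes (500-node networks, 20 replicates) were chosen so
  the full suite and the reproduction script each run in seconds on one
  CPU while leaving binomial sampling bands tight enough to be meaningful.
* Duplicate edge records merge keeping the **maximum** weight (consistent
  with the `max` integration default: evidence accumulates, it does not
  average away).
* All generators take explicit integer seeds (`numpy.random.default_rng`);
  identical spec + seed gives byte-identical networks and outputs.
* CLI outputs are written atomically (temp file + rename): a failed run
  leaves no partial files.

## Known limitations

* No identifier mapping: inputs must share one namespace.
* The LOOCV ranking pool (non-seeds + held-out seed) is fixed, not
  configurable.
* `kernel_matrix` materializes a dense N×N array; use per-seed solves past
  a few thousand nodes.
* AUC differences carry no significance test or confidence band; the
  paired-replicate comparison is descriptive.
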