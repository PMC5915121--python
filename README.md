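# netprio

Network-propagation prioritization of candidate genes on integrated
protein–protein interaction (PPI) networks.

Given heterogeneous interaction evidence (physical interactions, domain
co-occurrence, co-expression, homology-transferred interactions, curated
pathway associations) and a *seed set* of proteins known to belong to a
functional system — the motivating use case is a set of 116 known
angiogenesis proteins — `netprio`:

1. **integrates** per-source weighted edge lists into one undirected network,
2. **scores** every protein by random-walk-with-restart (RWR) proximity to
   the seeds,
3. **ranks** the non-seed candidates and cuts a short list (default top 300),
4. **validates** the ranking by leave-one-out cross-validation (LOOCV) with
   ROC/AUC, against a degree-matched random-seed null that guards against
   hub artifacts.

It is aimed at systems-biology practitioners who want a tested, reproducible
implementation of guilt-by-association candidate nomination, plus a synthetic
planted-module benchmark to calibrate expectations before touching real data.

## The model

Let `A` be the symmetric weighted adjacency of the integrated network and
`D` the diagonal of weighted degrees. With transition matrix
`W = A D^-1` (column-stochastic; a degree-normalized walk) or
`W = D^-1/2 A D^-1/2` (symmetric-degree; a true graph kernel), restart
probability `r ∈ (0, 1]`, and restart distribution `p0` uniform on the
seeds, the walker's update is

```
p(t+1) = (1 − r) · W · p(t) + r · p0
```

whose fixed point

```
p∞ = r · (I − (1 − r) · W)^(−1) · p0  =  K · p0,   K = r (I − (1−r) W)^(−1)
```

scores each node by its global, multi-path affinity to the seed set. Both a
power iteration (any graph size) and an exact sparse direct solve (small
graphs; also the internal oracle) are provided, plus the full kernel `K`.

In LOOCV each seed is removed from `p0` in turn and re-ranked among the
non-seed nodes plus itself; treating each held-out seed as its fold's sole
positive yields a ROC curve whose area equals the Mann–Whitney statistic

```
AUC = mean over seeds of (n_neg − (rank − 1)) / n_neg .
```

## Worked example

```sh
netprio simulate --n 200 --module 20 --rng 17 \
    --out-edges net.tsv --out-truth truth.json --out-seeds seeds.txt
netprio prioritize --edges net.tsv --seeds seeds.txt --top-k 50 --out ranked.tsv
netprio validate --edges net.tsv --seeds seeds.txt --bins 5 --rng 1 --out loocv.json
```

The last command prints (numbers from this exact invocation):

```
LOOCV AUC = 0.9800  (null AUC = 0.8018)
```

meaning held-out seeds are recovered almost perfectly (a held-out seed
outranks 98% of non-seed nodes on average), and clearly better than a random
seed set with the same degree profile. The same pipeline from Python:

```python
from netprio import (SeedSet, build_transition, generate_planted_module,
                     loocv, rank_candidates, rwr_direct, top_k)
from netprio.synthetic import SyntheticNetworkSpec

network, truth = generate_planted_module(SyntheticNetworkSpec(rng_seed=7))
seeds = SeedSet.from_members(truth.known_seeds, network)
model = build_transition(network, "column-stochastic", r=0.3)
ranked = top_k(rank_candidates(rwr_direct(model, seeds), seeds), 10)
```

See `examples/` for three short narrative scripts (ranking, LOOCV
validation, multi-source integration) that print and explain their output;
`docs/methods.md` describes the model, defaults and limitations.

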