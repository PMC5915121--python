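"""Integrate noisy multi-source evidence into one network.

One master network is split into four evidence layers, each dropping half
the edges at random and reweighting the rest — mimicking heterogeneous PPI
evidence (physical interactions, co-expression, domain co-occurrence...).
Integration under the three combine rules is compared against the master.
"""

from netprio import generate_multi_source, generate_planted_module, integrate
from netprio.synthetic import SyntheticNetworkSpec

spec = SyntheticNetworkSpec(n_background=300, module_size=30, rng_seed=5)
master, _ = generate_planted_module(spec)
sources = generate_multi_source(spec, n_sources=4, dropout=0.5)

print(f"master: {master.n_edges} edges")
for src in sources:
    print(f"  {src.source_name}: {len(src)} edges")

for rule, kwargs in [("max", {}), ("sum-capped-at-1", {}),
                     ("weighted-mean", {"coefficients": [0.25] * 4})]:
    merged = integrate(sources, rule, **kwargs)
    recovered = len(set(merged.edge_set()) & set(master.edge_set()))
    print(f"rule={rule:16s} edges={merged.n_edges:4d} "
          f"master edges recovered={recovered} "
          f"({recovered / master.n_edges:.0%})")
print("\nAt 50% dropout per source, an edge escapes all four layers with "
      "probability 0.5^4 ~ 6%, so ~94% of the master should be recovered.")
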