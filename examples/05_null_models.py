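"""Randomization null models: expression shuffling and edge switching.

Shuffling permutes each species' node scores while keeping the topology
bit-identical; edge switching rewires pairs of edges while preserving
every node's degree.  Comparing module quality between real and
randomized runs shows how much of the signal is genuine.
"""

import numpy as np

import crossmod as cm

network, truth = cm.generate_fixture(rng_seed=2)
bg = cm.BackgroundStats.from_network(network, rng_seed=2)
modules = cm.run_search(network, bg)

shuffled = cm.shuffle_expression(network, rng_seed=99)
bg_s = cm.BackgroundStats.from_network(shuffled, rng_seed=2)
null_modules = cm.run_search(shuffled, bg_s)

switched = cm.switch_edges(network, rng_seed=99)
assert dict(switched.graph.degree()) == dict(network.graph.degree())

def mean_activation(mods, net):
    nodes = {n for m in mods for n in m.nodes}
    return float(np.mean([net.combined_score(n) for n in nodes])) if nodes else 0.0

top = lambda ms: max((m.score for m in ms), default=float("nan"))
print(f"real data:      {len(modules)} modules, top score {top(modules):.2f}, "
      f"mean module-node activation {mean_activation(modules, network):.2f}")
print(f"shuffled null:  {len(null_modules)} modules, top score "
      f"{top(null_modules):.2f}, mean activation "
      f"{mean_activation(null_modules, shuffled):.2f}")
print("edge switching preserved every node degree:", True)
print("\nThe planted signal shows up as a higher top objective score and")
print("more activated module nodes on the real data; shuffled runs can")
print("still assemble modules by chance, but of visibly lower quality.")
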