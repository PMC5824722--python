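"""Loopy belief propagation against exact enumeration.

Builds a small random drug-protein-pathway-phenotype field, clamps the
drug layer, and compares BP marginals and log-partition with brute-force
enumeration: exact on acyclic models, close on weakly coupled loops.
"""

from adrnet import SyntheticSpec, brute_force_infer, build_model, gen_network, infer

spec = SyntheticSpec(
    layer_sizes=(3, 3, 2, 3),
    edge_probs={"R1": 0.5, "R2": 0.2, "R3": 0.2, "R4": 0.5, "R5": 0.5},
    seed=2,
)
net = gen_network(spec)
model = build_model(net, init="gaussian", init_scale=0.4, seed=3)

clamps = {d: i % 2 for i, d in enumerate(model.inputs())}
bp = infer(model, clamps)
exact = brute_force_infer(model, clamps)

worst = max(abs(bp.node_marginals[n] - exact.node_marginals[n]) for n in model.node_ids)
print(f"{len(model.node_ids)} nodes, {len(model.edge_keys)} edges, "
      f"drugs clamped to {clamps}")
print(f"BP converged in {bp.iterations} iterations")
print(f"max |BP - exact| over node marginals: {worst:.2e}")
print(f"log-partition: BP {bp.log_partition:.6f} vs exact {exact.log_partition:.6f}")
# On this weakly coupled loopy instance the Bethe approximation tracks the
# exact marginals to a few parts in a thousand or better.
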