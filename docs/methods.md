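# Methods

## The model

`adrnet` studies associations between sets of co-administered drugs and
adverse reactions through an explicit mechanistic scaffold: a 4-partite
network whose layers are Drug (E1), Protein (E2), Pathway (E3) and
Phenotype (E4), joined by five relation families — drug *hasTarget* /
*hasEnzyme* / *hasTransporter* protein (R1–R3), protein *isPresentIn*
pathway (R4), pathway *isImplicatedIn* phenotype (R5).  Edges never join
two nodes of the same layer.

The network is read as a pairwise conditional random field with one
binary variable per node.  Drug nodes are observed inputs `x` (1 =
administered), phenotype nodes are observed outcomes `y` (1 = reaction
reported), and the protein/pathway layers are hidden `h`: safety reports
say nothing about molecular state, so the two middle layers are
marginalized.  Each edge (j,k) carries a 2×2 table θ over the joint
configurations {(0,0),(0,1),(1,0),(1,1)}; the potential of a total
assignment is the sum of the selected table entries,

    Ψ(y,h,x;θ) = Σ_{(j,k)∈E} θ_jk[s_j, s_k],

and the object of interest is the conditional

    p(y|x,θ) = Σ_h e^Ψ / Σ_{y',h} e^Ψ .

Training maximizes the L2-regularized conditional log-likelihood
`L(θ) = Σ_i log p(y_i|x_i,θ) − ‖θ‖²/(2σ²)` by stochastic gradient ascent:
one update per report, constant step rate α, sample order reshuffled per
epoch.  The per-report gradient for each edge configuration is the
difference of clamped and free edge-marginal expectations minus the
regularizer, both expectations supplied by inference runs with (x, y) and
with only x fixed.

Binary node states are written {0, 1}; the labels carry no semantics —
only "state 1 = involved/administered/observed" does.

## Inference

Marginals and log-partition functions come from sum-product loopy belief
propagation on the pairwise graph: synchronous (flooding) updates, message
damping 0.5, messages kept in log space, convergence declared when the
largest absolute message change falls below 1e-10, capped at 200
iterations.  The tight tolerance costs a handful of extra iterations and
keeps acyclic instances exact to the 1e-9 level at which the test suite
compares BP against enumeration; a looser stop (1e-6) leaves residuals of
the same order as the stopping threshold.  Clamped nodes are absorbed
exactly before message passing (their edges become constants or unary
fields on the free neighbors), so the returned log-partition is the Bethe
approximation of `log Σ exp Ψ` over the free nodes only — exact on trees.
Non-convergence is flagged on the result and logged, never raised, so
training can continue past a hard instance.

Parallel edges between one node pair (a drug that both targets and is
metabolized by the same protein) are combined into a single pairwise
potential for message passing and the Bethe energy, then reported per
original edge.

`brute_force_infer` enumerates all assignments of up to 20 free nodes
directly against the model's tables — deliberately sharing no reduction
code with the BP path — and serves as the oracle throughout the tests.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| α (step rate) | 0.01 | SGA update size; constant, no decay |
| σ² | 10.0 | variance of the L2 prior on θ |
| epochs | 3 | full passes over the report database |
| init | `zero` / `gaussian(scale)` | parameter initialization |
| BP damping / tol / max-iter | 0.5 / 1e-10 / 200 | message schedule |
| O/E threshold | 2.0 (strict >) | silver-standard positive filter |

A per-relation-type parameter-tying mode (`tying="relation"`) is exposed
for regularization-starved data; the default is one table per edge.
Unary (per-node) tables exist behind a flag and default to off, so the
potential is purely edge-driven.

**Zero init is a degenerate starting point for this architecture.**  At
θ = 0 every hidden node's conditional is exactly uniform in both the
clamped and the free inference run, so the gradient of every coupling
incident to a hidden node vanishes identically and stays zero under SGA:
only outcome base-rate terms can move.  This is the hidden-state symmetry
familiar from latent-variable models; `init="gaussian"` breaks it and is
what any real training run should use.  The test suite demonstrates both
the freeze and, with symmetry broken, that trained predictions match the
Bayes-optimal scorer's ranking on held-out synthetic reports.

## Federation, sanitization, reconciliation

Each RDF source is queried with per-source mapping rules (triple-template
graph patterns with distinguished variables ?E1..?E4), because sources
express the same relation with different shapes: direct triples, reified
relation nodes, or blank-node hops.  Extracted identifiers pass through a
config-driven sanitizer that repairs, in order: trailing quote characters,
lost pathway-code prefixes (`…/path/0012` → `…/path/map0012`), lower-cased
locus names (`hsa_2147` → `HSA_2147`), and whitespace-aggregated local
names (`HSA_1551 1576` → two URIs sharing the namespace and stem).  The
default dialect table covers these four families; new sources add entries
in the rules config.

Reconciliation is union-find closure over two merge signals: a shared
code in the layer's designated terminology (drugs → ATC, proteins → HGNC,
pathways → KEGG, phenotypes → MeSH) and explicit direct x-ref links.
Because closure is transitive, the order of the two signals is
irrelevant.  A merged group carrying two distinct designated codes is
still merged — dropping it silently would hide a data-quality problem —
with the conflict logged and the smallest code winning.  Canonical node
ids are `terminology:code` when available, else the smallest member URI.
After assembly the network is pruned to its largest undirected connected
component, and a validator asserts the k-partite contract.

## Pharmacovigilance evaluation

Reports (id, drug labels, reaction labels) are mapped onto the network by
exact match after normalization (lower-casing, punctuation/whitespace
collapse); reports mapping no drug or no reaction are discarded and
counted.  A held-out report contributes, for each phenotype in the model:
a positive test pair if the phenotype appears in the report *and* the
observed/expected ratio of (the report's full drug combination, that
phenotype) in the training reports strictly exceeds the threshold; an
excluded pair if present but below; a negative pair if absent.  O/E uses
the independence expectation E = N(combo)·N(adr)/N computed on training
counts only.  The combination-level definition is one of several
defensible disproportionality readings (per-drug maximization is another);
it extends naturally to >2 drugs and is the package's choice.

Scores are the model's `P(y_adr = 1 | x)`.  Evaluation reports one ROC /
AUROC per phenotype (event-specific thresholds) plus a pooled curve over
all pairs (one shared probability threshold).  Phenotypes whose test
pairs are single-class are listed as unevaluated.  AUROC is the
Mann–Whitney statistic with midrank tie handling.  Two phenotypes that
are each perfectly ranked on disjoint calibrated score ranges pool to a
strictly lower combined AUROC — the reason event-specific thresholds
matter for signal detection.

## The synthetic generator

The generator emulates the full input surface: a random 4-partite network
(default layers 10/8/5/6; per-relation edge probabilities R1 0.30,
R2 0.10, R3 0.10, R4 0.40, R5 0.40; a spanning chain keeps the network one
component), per-source RDF renderings in three dialects with terminology
x-refs that reconcile the sources back onto the generator's node ids,
optional injection of the four identifier-error families at a stated rate,
a ground-truth field, and report databases sampled from it (drug exposures
i.i.d. Bernoulli(0.30) per report).

Sampling is exact: conditioned on the drugs, proteins and phenotypes are
mutually independent given the pathway configuration (no intra-layer
edges), so enumerating the 2^|E3| pathway states — feasible to |E3| = 20 —
samples (h, y) from the exact conditional.  A single-site Gibbs sampler
(burn-in 500, thinning 10) is the opt-in fallback for larger middle
layers.  Reports with an empty drug or reaction set are re-drawn so every
emitted report is well-formed; the re-draw count is recorded, and tests
that compare sampled frequencies to enumerated marginals condition on the
non-empty event.

Ground-truth couplings come in two styles.  `uniform` (the default) draws
every table entry i.i.d. on [−scale, +scale].  Note its consequence: the
expected interaction magnitude per edge is ≈ 1.4·scale/1.5 and much of the
draw lands on marginal terms, so at scale 1.5 two hidden layers compound
into a nearly uninformative channel — the Bayes-optimal scorer itself
ranks held-out samples barely above chance.  `interaction` puts the whole
scale on agreement/disagreement (±scale·[[1,−1],[−1,1]], random sign per
edge), keeping every edge a strong channel; learnability studies use it.
What passing tests on synthetic data do **not** show: real FAERS-scale
reporting biases, drug co-prescription correlation, terminology fuzziness
beyond the injected error families, or network scale — synthetic results
bound correctness of the machinery, not clinical performance.

## Problem sizes used in the checks

Oracle comparisons use ≤12-node models (enumeration at 2^free
assignments); predictive-recovery runs train on 3,000–5,000 sampled
reports and evaluate on 1,000 held-out reports over the 10/8/5/6 network;
the determinism check runs the full pipeline twice at 120 training
reports.  These sizes keep the whole suite in the minutes range on one
CPU while leaving every code path exercised.

## Known limitations

- Loopy BP degrades with strong frustrated couplings; non-convergent runs
  are flagged, and their marginals should be treated as approximate.
- Hidden-CRF training is non-convex; different initialization seeds can
  land in different optima.  The suite picks conditions where SGA reliably
  reaches the Bayes ceiling, not a guarantee for arbitrary instances.
- Label mapping is exact-after-normalization; no fuzzy terminology
  matching.
- The O/E silver standard filters positives only; absent reactions are
  taken as negatives, inheriting spontaneous-reporting under-reporting
  bias.
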