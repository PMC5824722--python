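"""Synthetic fixtures: networks, heterogeneous RDF sources, sampled reports.

Everything the pipeline consumes can be generated here without external
downloads: a random 4-partite drug-protein-pathway-phenotype network; RDF
renderings of that network across several sources, each in its own graph
dialect (direct triples, reified relation nodes, or blank-node hops) with
terminology x-refs tying the per-source URIs back to one node; optional
injection of the identifier error families seen in real linked-data dumps
(trailing quotes, lost ``map`` prefixes, lower-cased locus names,
whitespace-aggregated URIs); a ground-truth hidden-CRF; and safety-report
databases sampled exactly from that model.

The generator's defaults define the study conditions used throughout the
test suite: layers of 10/8/5/6 nodes, edge inclusion probabilities of
0.30/0.10/0.10 for the three drug-protein relations and 0.40 for the
protein-pathway and pathway-phenotype relations, ground-truth couplings
uniform on [-1.5, 1.5], and a drug exposure probability of 0.30 per
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import rdflib
import yaml
from rdflib import RDF, RDFS, Literal, URIRef

from .hcrf import HCRFModel, build_model
from .network import KPartiteNetwork, ReconciledEntity
from .pharmacovigilance import Report, ReportDB, save_reports

__all__ = [
    "SyntheticSpec",
    "gen_network",
    "gen_rdf_fixture",
    "gen_model",
    "sample_reports",
    "gen_fixture_bundle",
    "phenotypes_with_drug_path",
]

log = logging.getLogger(__name__)

_LAYERS = ("E1", "E2", "E3", "E4")
_TERM_OF_LAYER = {"E1": "ATC", "E2": "HGNC", "E3": "KEGG", "E4": "MESH"}
_CLASS_OF_LAYER = {"E1": "Drug", "E2": "Protein", "E3": "Pathway", "E4": "Phenotype"}
_DIALECTS = ("direct", "reified", "blank")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic scenario."""

    layer_sizes: tuple = (10, 8, 5, 6)
    edge_probs: dict = field(default_factory=lambda: {
        "R1": 0.30, "R2": 0.10, "R3": 0.10, "R4": 0.40, "R5": 0.40,
    })
    n_sources: int = 3
    dialects: tuple = ()  # defaults to cycling direct/reified/blank
    error_rate: float = 0.0
    coupling_scale: float = 1.5
    drug_exposure_prob: float = 0.30
    ensure_connected: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer sizes must be >= 1")
        for r, p in self.edge_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability {r}={p} outside [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate outside [0, 1]")
        if not self.dialects:
            self.dialects = tuple(
                _DIALECTS[i % len(_DIALECTS)] for i in range(self.n_sources)
            )

    def source_ids(self) -> list[str]:
        return [f"src{i}" for i in range(self.n_sources)]


# ---------------------------------------------------------------------------
# ground-truth network


def _codes(layer: str, idx: int) -> tuple[str, str, str]:
    """(terminology code, source-local URI name, display label) per node."""
    if layer == "E1":
        code = f"C{idx:03d}"
        return code, f"DB{idx:05d}", f"drug-{idx}"
    if layer == "E2":
        code = f"{1000 + idx}"
        return code, f"HSA_{code}", f"protein-{idx}"
    if layer == "E3":
        code = f"map{10 + idx:04d}"
        return code, f"path/{code}", f"pathway-{idx}"
    code = f"D{idx:06d}"
    return code, f"MESH_{code}", f"reaction-{idx}"


def _node_id(layer: str, idx: int) -> str:
    code, _, _ = _codes(layer, idx)
    return f"{_TERM_OF_LAYER[layer].lower()}:{code}"


def gen_network(spec: SyntheticSpec) -> KPartiteNetwork:
    """Random 4-partite network at the spec's edge probabilities.

    Node ids are canonical terminology terms (``atc:C003``,
    ``hgnc:1005``, ``kegg:map0012``, ``mesh:D000004``), so a fixture
    round-trip through extraction and reconciliation reproduces the ids
    exactly.  With ``ensure_connected`` a spanning chain through node 0 of
    each layer is added and any stray node is hooked onto it, keeping the
    network one undirected component.
    """
    rng = np.random.default_rng(spec.seed)
    net = KPartiteNetwork()
    layer_nodes: dict[str, list[str]] = {}
    for layer, size in zip(_LAYERS, spec.layer_sizes):
        ids = []
        for i in range(size):
            nid = _node_id(layer, i)
            _, _, label = _codes(layer, i)
            net.nodes[nid] = ReconciledEntity(
                nid, layer, {nid}, {label}, {"synthetic"}
            )
            ids.append(nid)
        layer_nodes[layer] = ids

    pairs = {
        "R1": ("E1", "E2"), "R2": ("E1", "E2"), "R3": ("E1", "E2"),
        "R4": ("E2", "E3"), "R5": ("E3", "E4"),
    }
    for r in ("R1", "R2", "R3", "R4", "R5"):
        lu, lv = pairs[r]
        p = spec.edge_probs.get(r, 0.0)
        draws = rng.random((len(layer_nodes[lu]), len(layer_nodes[lv])))
        for i, u in enumerate(layer_nodes[lu]):
            for j, v in enumerate(layer_nodes[lv]):
                if draws[i, j] < p:
                    net.edges[(r, u, v)] = {"synthetic"}

    if spec.ensure_connected:
        d0, p0 = layer_nodes["E1"][0], layer_nodes["E2"][0]
        w0, a0 = layer_nodes["E3"][0], layer_nodes["E4"][0]
        core = [("R1", d0, p0), ("R4", p0, w0), ("R5", w0, a0)]
        for ek in core:
            net.edges.setdefault(ek, {"synthetic"})
        comp = nx.node_connected_component(net.to_undirected(), d0)
        hub = {"E1": lambda n: ("R1", n, p0), "E2": lambda n: ("R1", d0, n),
               "E3": lambda n: ("R4", p0, n), "E4": lambda n: ("R5", w0, n)}
        for nid, node in sorted(net.nodes.items()):
            if nid not in comp:
                net.edges.setdefault(hub[node.entity_type](nid), {"synthetic"})
    return net


def phenotypes_with_drug_path(net: KPartiteNetwork) -> list[str]:
    """Phenotype nodes reachable by a full Drug->Protein->Pathway chain."""
    e2 = {v for (r, _, v) in net.edges if r in ("R1", "R2", "R3")}
    e3 = {v for (r, u, v) in net.edges if r == "R4" and u in e2}
    return sorted({v for (r, u, v) in net.edges if r == "R5" and u in e3})


# ---------------------------------------------------------------------------
# RDF fixture rendering


def _base(source_id: str) -> str:
    return f"http://example.org/{source_id}/"


def _corrupt(uri: str, rng: np.random.Generator) -> str:
    """Apply one applicable error family (invertible by the sanitizer)."""
    fams = ["quote"]
    if "HSA_" in uri:
        fams.append("case")
    if "/path/map" in uri:
        fams.append("prefix")
    fam = fams[int(rng.integers(len(fams)))]
    if fam == "case":
        i = uri.index("HSA_")
        return uri[:i] + "hsa_" + uri[i + 4 :]
    if fam == "prefix":
        return uri.replace("/path/map", "/path/")
    return uri + "%22"


def gen_rdf_fixture(
    net: KPartiteNetwork, spec: SyntheticSpec, out_dir: str | Path
) -> dict:
    """Render the network as per-source RDF files plus configs and manifest.

    Every edge is assigned a home source (and extra sources with
    probability 0.3); entity URIs are source-specific, with terminology
    x-refs guaranteeing that reconciliation collapses them back onto the
    generator's node ids.  With ``error_rate`` > 0, URI occurrences are
    corrupted with one of the error families the sanitizer knows how to
    repair; object lists sharing a subject and predicate may additionally
    be whitespace-aggregated into a single URI.

    Writes ``<src>.nt`` per source, ``rules.yaml`` (mapping rules matching
    each source's dialect), ``xrefs.tsv`` and ``manifest.json``; returns
    the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    sources = spec.source_ids()
    dialect = dict(zip(sources, spec.dialects))

    # assignment: every edge gets >=1 source; endpoints follow; leftovers random
    edge_sources: dict[tuple, list[str]] = {}
    entity_sources: dict[str, set[str]] = {n: set() for n in net.nodes}
    for ek in sorted(net.edges):
        home = sources[int(rng.integers(len(sources)))]
        srcs = [home] + [s for s in sources if s != home and rng.random() < 0.3]
        edge_sources[ek] = srcs
        for s in srcs:
            entity_sources[ek[1]].add(s)
            entity_sources[ek[2]].add(s)
    for n in sorted(net.nodes):
        if not entity_sources[n]:
            entity_sources[n].add(sources[int(rng.integers(len(sources)))])

    def uri(source_id: str, nid: str) -> str:
        node = net.nodes[nid]
        idx = net.layer(node.entity_type).index(nid)
        _, local, _ = _codes(node.entity_type, idx)
        return _base(source_id) + local

    def maybe_corrupt(u: str) -> str:
        if spec.error_rate > 0 and rng.random() < spec.error_rate:
            return _corrupt(u, rng)
        return u

    rel_pred = {
        "direct": {"R1": "target", "R2": "enzyme", "R3": "transporter"},
        "reified": {"R1": ("Target-Relation", "drug", "target"),
                    "R2": ("Enzyme-Relation", "drug", "enzyme"),
                    "R3": ("Transporter-Relation", "drug", "transporter")},
        "blank": {"R1": "target", "R2": "metabolism", "R3": "transport"},
    }

    per_source: dict[str, dict[str, int]] = {
        s: {t: 0 for t in (*_LAYERS, "R1", "R2", "R3", "R4", "R5")} for s in sources
    }
    xref_rows: list[tuple[str, str, str, str]] = []
    graphs = {s: rdflib.Graph() for s in sources}

    for nid in sorted(net.nodes):
        node = net.nodes[nid]
        term = _TERM_OF_LAYER[node.entity_type]
        code = nid.split(":", 1)[1]
        for s in sorted(entity_sources[nid]):
            g = graphs[s]
            b = _base(s)
            u = URIRef(maybe_corrupt(uri(s, nid)))
            g.add((u, RDF.type, URIRef(b + _CLASS_OF_LAYER[node.entity_type])))
            g.add((u, RDFS.label, Literal(sorted(node.labels)[0])))
            code_out = code
            if spec.error_rate > 0 and rng.random() < spec.error_rate:
                code_out = code + '"'  # only the quote family applies to codes
            g.add((u, URIRef(b + "x-" + term.lower()), Literal(code_out)))
            xref_rows.append((uri(s, nid), term, code, s))
            per_source[s][node.entity_type] += 1

    rel_counter = 0
    # group direct-dialect drug-protein edges for possible aggregation
    for ek in sorted(net.edges):
        r, su, ov = ek
        for s in edge_sources[ek]:
            per_source[s][r] += 1
    for s in sources:
        g = graphs[s]
        b = _base(s)
        dia = dialect[s]
        mine = [ek for ek in sorted(net.edges) if s in edge_sources[ek]]
        grouped: dict[tuple[str, str], list[str]] = {}
        for r, su, ov in mine:
            if r in ("R1", "R2", "R3"):
                if dia == "direct":
                    grouped.setdefault((su, rel_pred["direct"][r]), []).append(ov)
                elif dia == "reified":
                    cls, ps, po = rel_pred["reified"][r]
                    rel = URIRef(b + f"rel{rel_counter}")
                    rel_counter += 1
                    g.add((rel, RDF.type, URIRef(b + cls)))
                    g.add((rel, URIRef(b + ps), URIRef(maybe_corrupt(uri(s, su)))))
                    g.add((rel, URIRef(b + po), URIRef(maybe_corrupt(uri(s, ov)))))
                else:  # blank-node hop
                    bn = rdflib.BNode()
                    g.add((URIRef(maybe_corrupt(uri(s, su))), URIRef(b + rel_pred["blank"][r]), bn))
                    g.add((bn, URIRef(b + "link"), URIRef(maybe_corrupt(uri(s, ov)))))
            elif r == "R4":
                g.add((URIRef(maybe_corrupt(uri(s, su))), URIRef(b + "pathway"),
                       URIRef(maybe_corrupt(uri(s, ov)))))
            else:
                g.add((URIRef(maybe_corrupt(uri(s, su))), URIRef(b + "disease"),
                       URIRef(maybe_corrupt(uri(s, ov)))))
        # direct dialect: emit grouped objects, possibly aggregated into one URI
        for (su, pred), objs in sorted(grouped.items()):
            objs = sorted(objs)
            subj = URIRef(maybe_corrupt(uri(s, su)))
            if (len(objs) > 1 and spec.error_rate > 0
                    and rng.random() < spec.error_rate):
                full = [uri(s, o) for o in objs]
                agg = full[0]
                for f in full[1:]:
                    local = f.rsplit("/", 1)[-1]
                    suffix = local.split("_", 1)[1] if "_" in local else local
                    agg += "%20" + suffix
                g.add((subj, URIRef(b + pred), URIRef(agg)))
            else:
                for o in objs:
                    g.add((subj, URIRef(b + pred), URIRef(maybe_corrupt(uri(s, o)))))

    for s in sources:
        graphs[s].serialize(out_dir / f"{s}.nt", format="nt", encoding="utf-8")

    with open(out_dir / "xrefs.tsv", "w") as f:
        f.write("uri\tterminology\tcode\tsource\n")
        for row in sorted(xref_rows):
            f.write("\t".join(row) + "\n")

    rules_doc = _rules_config(spec)
    with open(out_dir / "rules.yaml", "w") as f:
        yaml.safe_dump(rules_doc, f, sort_keys=False)

    manifest = {
        "per_source": per_source,
        "layers": {t: net.layer(t) for t in _LAYERS},
        "layer_sizes": net.layer_sizes(),
        "edges": [list(ek) for ek in sorted(net.edges)],
        "edge_counts": net.edge_counts(),
        "dialects": dialect,
        "error_rate": spec.error_rate,
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest


def _rules_config(spec: SyntheticSpec) -> dict:
    """Mapping-rules document matching the fixture's per-source dialects."""
    sources = spec.source_ids()
    dialect = dict(zip(sources, spec.dialects))
    doc: dict = {
        "prefixes": {s: _base(s) for s in sources},
        "sources": [{"id": s, "label_predicate": "rdfs:label"} for s in sources],
        "rules": [],
        "xrefs": [],
    }
    for s in sources:
        for layer in _LAYERS:
            doc["rules"].append({
                "target": layer, "source": s,
                "pattern": [[f"?{layer}", "rdf:type", f"{s}:{_CLASS_OF_LAYER[layer]}"]],
            })
            doc["xrefs"].append({
                "source": s, "entity_type": layer,
                "predicate": f"{s}:x-{_TERM_OF_LAYER[layer].lower()}",
                "terminology": _TERM_OF_LAYER[layer],
            })
        dia = dialect[s]
        for r in ("R1", "R2", "R3"):
            if dia == "direct":
                pred = {"R1": "target", "R2": "enzyme", "R3": "transporter"}[r]
                pattern = [["?E1", f"{s}:{pred}", "?E2"]]
            elif dia == "reified":
                cls, ps, po = {
                    "R1": ("Target-Relation", "drug", "target"),
                    "R2": ("Enzyme-Relation", "drug", "enzyme"),
                    "R3": ("Transporter-Relation", "drug", "transporter"),
                }[r]
                pattern = [["?rel", "rdf:type", f"{s}:{cls}"],
                           ["?rel", f"{s}:{ps}", "?E1"],
                           ["?rel", f"{s}:{po}", "?E2"]]
            else:
                pred = {"R1": "target", "R2": "metabolism", "R3": "transport"}[r]
                pattern = [["?E1", f"{s}:{pred}", "?hop"],
                           ["?hop", f"{s}:link", "?E2"]]
            doc["rules"].append({"target": r, "source": s, "pattern": pattern})
        doc["rules"].append({
            "target": "R4", "source": s,
            "pattern": [["?E2", f"{s}:pathway", "?E3"]],
        })
        doc["rules"].append({
            "target": "R5", "source": s,
            "pattern": [["?E3", f"{s}:disease", "?E4"]],
        })
    return doc


# ---------------------------------------------------------------------------
# ground-truth model and report sampling


def gen_model(
    net: KPartiteNetwork,
    coupling_scale: float = 1.5,
    seed: int = 0,
    style: str = "uniform",
) -> HCRFModel:
    """Ground-truth model with per-edge tables of the given coupling scale.

    ``style="uniform"`` draws every table entry i.i.d. uniform on
    [-scale, +scale].  ``style="interaction"`` gives each edge a pure
    agreement/disagreement table ``±scale * [[1,-1],[-1,1]]`` with a
    random sign per edge: entries are still bounded by the scale, but the
    whole scale lands on the interaction term, so every edge is a strong
    (possibly inverting) channel.  Uniform entry draws spread the scale
    over marginal terms as well, leaving most edges nearly uninformative
    — use the interaction style when the study needs an end-to-end
    drug-to-reaction signal to recover.
    """
    model = build_model(net, init="zero", seed=seed)
    rng = np.random.default_rng(seed)
    if style == "uniform":
        for k in sorted(model.params):
            model.params[k] = rng.uniform(-coupling_scale, coupling_scale, size=(2, 2))
    elif style == "interaction":
        base = np.array([[1.0, -1.0], [-1.0, 1.0]]) * coupling_scale
        for k in sorted(model.params):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            model.params[k] = sign * base
    else:
        raise ValueError(f"unknown style {style!r}")
    return model


def _exact_sampler_tables(model: HCRFModel, x_bits: tuple) -> tuple:
    """Per-x conditional tables for exact layered sampling.

    Conditioned on the drug states, proteins and phenotypes are mutually
    independent given the pathway configuration (the network is 4-partite
    with no intra-layer edges), so enumerating the 2^|E3| pathway
    configurations is exact.
    """
    drugs = model.inputs()
    e2 = model.net.layer("E2")
    e3 = model.net.layer("E3")
    e4 = model.net.layer("E4")
    i2 = {n: i for i, n in enumerate(e2)}
    i3 = {n: i for i, n in enumerate(e3)}
    i4 = {n: i for i, n in enumerate(e4)}
    x = dict(zip(drugs, x_bits))

    C = 1 << len(e3)
    W = (np.arange(C)[:, None] >> np.arange(len(e3))) & 1  # (C, n3)

    f2 = np.zeros((len(e2), C, 2))
    f4 = np.zeros((len(e4), C, 2))
    for ek in model.edge_keys:
        r, u, v = ek
        t = model.theta(ek)
        if r in ("R1", "R2", "R3"):
            f2[i2[v]] += t[x[u], :][None, :]
        elif r == "R4":
            f2[i2[u]] += t[:, W[:, i3[v]]].T
        else:
            f4[i4[v]] += t[W[:, i3[u]], :]

    logw = np.zeros(C)
    for j in range(len(e2)):
        logw += np.logaddexp(f2[j, :, 0], f2[j, :, 1])
    for a in range(len(e4)):
        logw += np.logaddexp(f4[a, :, 0], f4[a, :, 1])
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum(), f4, e4


def sample_reports(
    model: HCRFModel,
    n: int,
    drug_exposure_prob: float = 0.30,
    seed: int = 0,
    method: str = "exact",
    gibbs_burn_in: int = 500,
    gibbs_thinning: int = 10,
) -> ReportDB:
    """Sample report entries (drug labels, reaction labels) from the model.

    Drug exposures are i.i.d. Bernoulli; hidden and outcome states are
    drawn exactly from P(h, y | x) by enumerating pathway configurations
    (requires <= 20 pathway nodes), or by Gibbs sampling when
    ``method="gibbs"``.  Reports with an empty drug or reaction set are
    re-drawn so every emitted report satisfies the report invariants; the
    re-draw count is logged and recorded on the returned database.
    """
    n3 = len(model.net.layer("E3"))
    if method == "exact" and n3 > 20:
        raise ValueError(
            f"{n3} pathway nodes exceed the exact-sampling limit; use method='gibbs'"
        )
    rng = np.random.default_rng(seed)
    drugs = model.inputs()

    def label_of(nid: str) -> str:
        labs = model.net.nodes[nid].labels
        return sorted(labs)[0] if labs else nid

    cache: dict = {}
    db = ReportDB()
    redraws = 0
    i = 0
    max_attempts = 1000 * max(n, 1)
    attempts = 0
    while i < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("report sampling stalled: empty reports keep recurring")
        x_bits = tuple((rng.random(len(drugs)) < drug_exposure_prob).astype(int))
        if method == "exact":
            tables = cache.get(x_bits)
            if tables is None:
                tables = cache[x_bits] = _exact_sampler_tables(model, x_bits)
            w, f4, e4 = tables
            c = int(rng.choice(len(w), p=w))
            p1 = 1.0 / (1.0 + np.exp(f4[:, c, 0] - f4[:, c, 1]))
            y_bits = (rng.random(len(e4)) < p1).astype(int)
        else:
            e4, y_bits = _gibbs_sample(
                model, dict(zip(drugs, x_bits)), rng, gibbs_burn_in, gibbs_thinning
            )
        drug_labels = frozenset(label_of(d) for d, b in zip(drugs, x_bits) if b)
        adr_labels = frozenset(label_of(a) for a, b in zip(e4, y_bits) if b)
        if not drug_labels or not adr_labels:
            redraws += 1
            continue
        db.reports.append(Report(f"r{i:06d}", drug_labels, adr_labels))
        i += 1
    db.redraws = redraws
    if redraws:
        log.info("re-drew %d empty reports", redraws)
    return db


def _gibbs_sample(model: HCRFModel, x: dict, rng, burn_in: int, thinning: int):
    """Single-site Gibbs over hidden and outcome nodes given x."""
    free = [n for n in model.node_ids if model.roles[n] != "input"]
    state = dict(x)
    for nd in free:
        state[nd] = int(rng.integers(2))
    nbrs: dict[str, list] = {nd: [] for nd in free}
    for ek in model.edge_keys:
        _, u, v = ek
        t = model.theta(ek)
        if u in nbrs:
            nbrs[u].append((v, t, True))
        if v in nbrs:
            nbrs[v].append((u, t, False))
    for sweep in range(burn_in + thinning):
        for nd in free:
            f = np.zeros(2)
            for other, t, is_subj in nbrs[nd]:
                s = state[other]
                f += t[:, s] if is_subj else t[s, :]
            p1 = 1.0 / (1.0 + np.exp(f[0] - f[1]))
            state[nd] = int(rng.random() < p1)
    e4 = model.outcomes()
    return e4, np.array([state[a] for a in e4], dtype=int)


def gen_fixture_bundle(
    spec: SyntheticSpec,
    out_dir: str | Path,
    n_train: int = 500,
    n_heldout: int = 100,
) -> dict:
    """Generate the full bundle: RDF sources, configs, truth model, reports.

    Writes per-source ``.nt`` files, ``rules.yaml``, ``xrefs.tsv``,
    ``manifest.json``, ``model_truth.json``, ``reports.tsv`` and
    ``reports_heldout.tsv``; returns the manifest.
    """
    out_dir = Path(out_dir)
    net = gen_network(spec)
    manifest = gen_rdf_fixture(net, spec, out_dir)
    truth = gen_model(net, spec.coupling_scale, seed=spec.seed + 2)
    with open(out_dir / "model_truth.json", "w") as f:
        f.write(truth.to_json(meta={"role": "ground truth", "seed": spec.seed + 2}))
    train_db = sample_reports(
        truth, n_train, spec.drug_exposure_prob, seed=spec.seed + 3
    )
    heldout_db = sample_reports(
        truth, n_heldout, spec.drug_exposure_prob, seed=spec.seed + 4
    )
    save_reports(train_db, out_dir / "reports.tsv")
    save_reports(heldout_db, out_dir / "reports_heldout.tsv")
    return manifest
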