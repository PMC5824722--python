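"""K-partite network assembly: reconciliation, pruning, path search.

Entities extracted from heterogeneous sources refer to the same biological
object under different URIs.  Reconciliation merges URIs into unique nodes
by transitive closure over two kinds of evidence: (i) two URIs carry the
same code in the terminology designated for their layer (drugs: ATC,
proteins: HGNC, pathways: KEGG, phenotypes: MeSH), or (ii) an explicit
``direct`` x-ref links one URI to the other.  The merged nodes form a
4-partite network (Drug -> Protein -> Pathway -> Phenotype) whose nodes and
edges are annotated with the set of contributing sources for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
import pathlib

import networkx as nx

from .extract import (
    ENTITY_TYPES,
    RELATION_LAYERS,
    RELATION_TYPES,
    EntityRecord,
    RelationRecord,
    XRef,
)

__all__ = [
    "DEFAULT_TERMINOLOGY_PRIORITY",
    "ReconciledEntity",
    "KPartiteNetwork",
    "Path",
    "NetworkError",
    "reconcile",
    "assemble_network",
    "largest_connected_component",
    "enumerate_paths",
    "validate_kpartite",
]

log = logging.getLogger(__name__)

#: Designated terminology per layer used for canonical node ids.
DEFAULT_TERMINOLOGY_PRIORITY = {"E1": "ATC", "E2": "HGNC", "E3": "KEGG", "E4": "MESH"}


class NetworkError(ValueError):
    pass


@dataclass
class ReconciledEntity:
    node_id: str
    entity_type: str
    member_uris: set[str]
    labels: set[str]
    sources: set[str]


@dataclass
class KPartiteNetwork:
    """4-layer network; edges keyed by (relation type, subject, object)."""

    nodes: dict[str, ReconciledEntity] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], set[str]] = field(default_factory=dict)

    def layer(self, entity_type: str) -> list[str]:
        return sorted(n for n, e in self.nodes.items() if e.entity_type == entity_type)

    def layer_sizes(self) -> dict[str, int]:
        return {t: len(self.layer(t)) for t in ENTITY_TYPES}

    def edge_counts(self) -> dict[str, int]:
        out = {r: 0 for r in RELATION_TYPES}
        for (r, _, _) in self.edges:
            out[r] += 1
        return out

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((u, v) for (_, u, v) in self.edges)
        return g

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "nodes": [
                {
                    "node_id": n.node_id,
                    "entity_type": n.entity_type,
                    "member_uris": sorted(n.member_uris),
                    "labels": sorted(n.labels),
                    "sources": sorted(n.sources),
                }
                for _, n in sorted(self.nodes.items())
            ],
            "edges": [
                {
                    "relation_type": r,
                    "subject": u,
                    "object": v,
                    "sources": sorted(srcs),
                }
                for (r, u, v), srcs in sorted(self.edges.items())
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KPartiteNetwork":
        doc = json.loads(text)
        net = cls()
        for n in doc["nodes"]:
            net.nodes[n["node_id"]] = ReconciledEntity(
                n["node_id"], n["entity_type"],
                set(n["member_uris"]), set(n["labels"]), set(n["sources"]),
            )
        for e in doc["edges"]:
            net.edges[(e["relation_type"], e["subject"], e["object"])] = set(e["sources"])
        return net

    def to_tsv(self, out_dir: str | pathlib.Path) -> None:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "nodes.tsv", "w") as f:
            f.write("node_id\tentity_type\tlabels\tmember_uris\tsources\n")
            for nid in sorted(self.nodes):
                n = self.nodes[nid]
                f.write(
                    f"{nid}\t{n.entity_type}\t{'|'.join(sorted(n.labels))}\t"
                    f"{'|'.join(sorted(n.member_uris))}\t{'|'.join(sorted(n.sources))}\n"
                )
        with open(out_dir / "edges.tsv", "w") as f:
            f.write("relation_type\tsubject\tobject\tsources\n")
            for (r, u, v) in sorted(self.edges):
                f.write(f"{r}\t{u}\t{v}\t{'|'.join(sorted(self.edges[(r, u, v)]))}\n")


@dataclass(frozen=True)
class Path:
    """One Drug -> Protein -> Pathway -> Phenotype chain with provenance."""

    nodes: tuple[str, str, str, str]
    relations: tuple[str, str, str]
    node_sources: tuple[frozenset, ...]

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "relations": list(self.relations),
            "node_sources": [sorted(s) for s in self.node_sources],
        }


# ---------------------------------------------------------------------------
# reconciliation


class _DSU:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.setdefault(x, x)
        if p != x:
            p = self.parent[x] = self.find(p)
        return p

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def reconcile(
    entities: list[EntityRecord],
    xrefs: list[XRef],
    terminology_priority: dict[str, str] | None = None,
    conflict_log: list | None = None,
) -> dict[str, str]:
    """Merge URIs into canonical node ids by union-find closure.

    Two URIs map to the same node iff they are connected through any chain
    of shared preferred-terminology codes or direct x-ref links.  The node
    id is ``<terminology>:<code>`` when the merged group carries a code in
    its layer's designated terminology, else the lexicographically smallest
    member URI.  Groups holding two distinct preferred codes are still
    merged (the conflict is logged) with the smallest code winning.

    The result covers entity URIs plus the targets of direct x-refs, and
    is invariant under permutation of the inputs.
    """
    prio = dict(DEFAULT_TERMINOLOGY_PRIORITY)
    if terminology_priority:
        prio.update(terminology_priority)

    type_of: dict[str, str] = {}
    for e in entities:
        prev = type_of.setdefault(e.uri, e.entity_type)
        if prev != e.entity_type:
            log.warning("URI %s typed both %s and %s; keeping %s", e.uri, prev,
                        e.entity_type, prev)

    dsu = _DSU()
    for uri in type_of:
        dsu.find(uri)

    term_anchor: dict[tuple[str, str], str] = {}
    code_of: dict[str, tuple[str, str]] = {}
    for x in sorted(xrefs, key=lambda x: (x.subject_uri, x.terminology, x.value)):
        if x.terminology == "direct":
            dsu.union(x.subject_uri, x.value)
        else:
            etype = type_of.get(x.subject_uri)
            if etype is None or prio.get(etype) != x.terminology:
                continue  # only the layer's designated terminology merges
            key = (x.terminology, x.value)
            if key in term_anchor:
                dsu.union(x.subject_uri, term_anchor[key])
            else:
                term_anchor[key] = x.subject_uri
            code_of.setdefault(x.subject_uri, key)

    groups: dict[str, list[str]] = {}
    for uri in dsu.parent:
        groups.setdefault(dsu.find(uri), []).append(uri)

    out: dict[str, str] = {}
    for members in groups.values():
        codes = sorted({code_of[u] for u in members if u in code_of})
        if codes:
            if len(codes) > 1:
                msg = f"merged group {sorted(members)} carries codes {codes}"
                log.warning("terminology conflict: %s", msg)
                if conflict_log is not None:
                    conflict_log.append(codes)
            term, code = codes[0]
            node_id = f"{term.lower()}:{code}"
        else:
            node_id = min(members)
        for u in members:
            out[u] = node_id
    return out


def assemble_network(
    entities: list[EntityRecord],
    xrefs: list[XRef],
    relations: list[RelationRecord],
    terminology_priority: dict[str, str] | None = None,
    stats: dict | None = None,
) -> KPartiteNetwork:
    """Reconcile entities and wire relations into a k-partite network.

    Parallel assertions of one relation by several sources collapse into a
    single edge whose ``sources`` is the union.  Relations whose endpoint
    URIs were never extracted are skipped and counted (``dangling``), as
    are self-loops or intra-layer edges created by aggressive merging
    (``dropped``); both tallies land in ``stats`` when provided.
    """
    uri2node = reconcile(entities, xrefs, terminology_priority)
    net = KPartiteNetwork()
    for e in entities:
        nid = uri2node[e.uri]
        node = net.nodes.get(nid)
        if node is None:
            node = net.nodes[nid] = ReconciledEntity(nid, e.entity_type, set(), set(), set())
        node.member_uris.add(e.uri)
        if e.label:
            node.labels.add(e.label)
        node.sources.add(e.source_id)

    dangling = dropped = 0
    for r in relations:
        u = uri2node.get(r.subject_uri)
        v = uri2node.get(r.object_uri)
        if u is None or v is None or u not in net.nodes or v not in net.nodes:
            dangling += 1
            continue
        lu, lv = net.nodes[u].entity_type, net.nodes[v].entity_type
        if u == v or (lu, lv) != RELATION_LAYERS[r.relation_type]:
            dropped += 1
            log.info("dropping edge %s %s->%s (layers %s->%s)", r.relation_type, u, v, lu, lv)
            continue
        net.edges.setdefault((r.relation_type, u, v), set()).add(r.source_id)

    if stats is not None:
        stats["dangling_relations"] = dangling
        stats["dropped_edges"] = dropped
        stats["n_nodes"] = len(net.nodes)
        stats["n_edges"] = len(net.edges)
    return net


def largest_connected_component(
    net: KPartiteNetwork, stats: dict | None = None
) -> KPartiteNetwork:
    """Induced subnetwork on the largest undirected component.

    Edge direction is ignored for connectivity.  Size ties break toward
    the component with the smallest sorted node-id tuple.  The number of
    discarded nodes is logged (and recorded in ``stats``).
    """
    if not net.nodes:
        return KPartiteNetwork()
    comps = [tuple(sorted(c)) for c in nx.connected_components(net.to_undirected())]
    comps.sort(key=lambda c: (-len(c), c))
    keep = set(comps[0])
    discarded = len(net.nodes) - len(keep)
    log.info("largest component keeps %d nodes, discards %d", len(keep), discarded)
    if stats is not None:
        stats["discarded_nodes"] = discarded
    sub = KPartiteNetwork(
        nodes={n: net.nodes[n] for n in keep},
        edges={k: set(v) for k, v in net.edges.items() if k[1] in keep and k[2] in keep},
    )
    return sub


def enumerate_paths(
    net: KPartiteNetwork,
    drug_ids: set[str],
    phenotype_ids: set[str],
    max_paths: int = 1000,
) -> list[Path]:
    """All Drug->Protein->Pathway->Phenotype paths between the given sets.

    Paths are produced in lexicographic order over (node sequence,
    relation sequence) and truncated at ``max_paths``.  Each path carries
    per-node provenance.  Unknown ids raise :class:`NetworkError`.
    """
    for nid in sorted(set(drug_ids) | set(phenotype_ids)):
        if nid not in net.nodes:
            raise NetworkError(f"unknown node id {nid!r}")

    hop1: dict[str, list[tuple[str, str]]] = {}
    hop2: dict[str, list[tuple[str, str]]] = {}
    hop3: dict[str, list[tuple[str, str]]] = {}
    for (r, u, v) in net.edges:
        if r in ("R1", "R2", "R3"):
            hop1.setdefault(u, []).append((v, r))
        elif r == "R4":
            hop2.setdefault(u, []).append((v, r))
        else:
            hop3.setdefault(u, []).append((v, r))
    for adj in (hop1, hop2, hop3):
        for k in adj:
            adj[k].sort()

    targets = set(phenotype_ids)
    out: list[Path] = []
    for d in sorted(drug_ids):
        for p, r1 in hop1.get(d, []):
            for w, r2 in hop2.get(p, []):
                for a, r3 in hop3.get(w, []):
                    if a not in targets:
                        continue
                    out.append(Path(
                        nodes=(d, p, w, a),
                        relations=(r1, r2, r3),
                        node_sources=tuple(
                            frozenset(net.nodes[n].sources) for n in (d, p, w, a)
                        ),
                    ))
                    if len(out) >= max_paths:
                        return out
    return out


def validate_kpartite(net: KPartiteNetwork) -> None:
    """Assert the k-partite contract; raises :class:`NetworkError`."""
    for nid, n in net.nodes.items():
        if n.entity_type not in ENTITY_TYPES:
            raise NetworkError(f"node {nid}: bad layer {n.entity_type}")
        if not n.member_uris:
            raise NetworkError(f"node {nid}: empty member set")
        if not n.sources:
            raise NetworkError(f"node {nid}: empty source set")
    for (r, u, v), srcs in net.edges.items():
        if r not in RELATION_TYPES:
            raise NetworkError(f"edge {(r, u, v)}: unknown relation type")
        if u not in net.nodes or v not in net.nodes:
            raise NetworkError(f"edge {(r, u, v)}: endpoint missing")
        lu, lv = net.nodes[u].entity_type, net.nodes[v].entity_type
        if lu == lv:
            raise NetworkError(f"edge {(r, u, v)}: intra-layer edge {lu}")
        if (lu, lv) != RELATION_LAYERS[r]:
            raise NetworkError(f"edge {(r, u, v)}: layer pair {(lu, lv)} invalid for {r}")
        if not srcs:
            raise NetworkError(f"edge {(r, u, v)}: empty source set")
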