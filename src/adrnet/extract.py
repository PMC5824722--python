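"""Mapping-rule driven extraction of typed entities and relations from RDF.

Each data source (an in-memory RDF graph standing in for a SPARQL
endpoint) describes the same pharmacological content with its own graph
patterns: a drug-target link may be a direct triple, a reified relation
node, or a blank-node hop.  A :class:`MappingRule` binds one entity type
(E1 Drug, E2 Protein, E3 Pathway, E4 Phenotype) or relation type
(R1 hasTarget, R2 hasEnzyme, R3 hasTransporter, R4 isPresentIn,
R5 isImplicatedIn) to the pattern a given source uses, so extraction is a
conjunctive triple-pattern query evaluated per source.

All URIs pass through :func:`adrnet.sanitize.sanitize_uri` on the way out,
and every record carries the source id for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import rdflib
import yaml

from .sanitize import SanitizeRules, sanitize_uri

__all__ = [
    "ENTITY_TYPES",
    "RELATION_TYPES",
    "RELATION_LAYERS",
    "MappingRule",
    "MappingRuleError",
    "MappingConfig",
    "EntityRecord",
    "XRef",
    "RelationRecord",
    "RdfSource",
    "parse_mapping_rules",
    "extract_entities",
    "extract_xrefs",
    "extract_relations",
    "run_extraction",
]

log = logging.getLogger(__name__)

ENTITY_TYPES = ("E1", "E2", "E3", "E4")
RELATION_TYPES = ("R1", "R2", "R3", "R4", "R5")
#: (subject layer, object layer) of each relation type.
RELATION_LAYERS = {
    "R1": ("E1", "E2"),
    "R2": ("E1", "E2"),
    "R3": ("E1", "E2"),
    "R4": ("E2", "E3"),
    "R5": ("E3", "E4"),
}
TERMINOLOGIES = ("ATC", "HGNC", "KEGG", "MESH", "direct")

_WELL_KNOWN_PREFIXES = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
}


class MappingRuleError(ValueError):
    """Malformed mapping-rules config."""


@dataclass(frozen=True)
class MappingRule:
    """One (target type, source) -> graph pattern binding.

    ``pattern`` is an ordered list of triple templates; each term is either
    a ``?``-prefixed variable (``?E1``..``?E4`` are the distinguished
    entity variables, anything else an intermediate hop) or a CURIE/URI.
    """

    target: str
    source_id: str
    pattern: tuple[tuple[str, str, str], ...]

    def distinguished(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.pattern:
            for term in t:
                if term.startswith("?E") and term[1:] in ENTITY_TYPES and term not in seen:
                    seen.append(term)
        return tuple(sorted(seen))

    def validate(self) -> None:
        if self.target not in ENTITY_TYPES + RELATION_TYPES:
            raise MappingRuleError(
                f"rule for source {self.source_id!r}: unknown target {self.target!r}"
            )
        if not self.pattern:
            raise MappingRuleError(
                f"rule {self.target}/{self.source_id}: empty pattern"
            )
        dv = self.distinguished()
        if self.target in ENTITY_TYPES:
            # context variables are allowed (e.g. a blank-node-hop dialect
            # identifies drugs as subjects of a drug->_:b->protein chain),
            # but the rule must bind its own entity variable
            if f"?{self.target}" not in dv:
                raise MappingRuleError(
                    f"entity rule {self.target}/{self.source_id} must bind "
                    f"?{self.target}; found {dv}"
                )
        else:
            want = tuple(sorted(f"?{t}" for t in RELATION_LAYERS[self.target]))
            if dv != want:
                raise MappingRuleError(
                    f"relation rule {self.target}/{self.source_id} must bind exactly "
                    f"{want}; found {dv}"
                )


@dataclass(frozen=True)
class XRefRule:
    source_id: str
    entity_type: str
    predicate: str
    terminology: str


@dataclass
class MappingConfig:
    """Parsed mapping-rules document: rules, x-ref map, prefixes, dialects."""

    rules: list[MappingRule]
    xref_rules: list[XRefRule]
    prefixes: dict[str, str]
    label_predicates: dict[str, str]  # source_id -> predicate (CURIE/URI)
    sanitize_rules: SanitizeRules

    def rules_for(self, source_id: str, target: str) -> list[MappingRule]:
        return [r for r in self.rules if r.source_id == source_id and r.target == target]

    def expand(self, term: str) -> str:
        """Expand a CURIE against the config's prefix table."""
        if "://" in term:
            return term
        if ":" not in term:
            raise MappingRuleError(f"term {term!r} is neither a URI nor a CURIE")
        pfx, local = term.split(":", 1)
        try:
            return self.prefixes[pfx] + local
        except KeyError:
            raise MappingRuleError(f"undeclared prefix {pfx!r} in term {term!r}") from None


@dataclass(frozen=True)
class EntityRecord:
    uri: str
    entity_type: str
    label: str | None
    source_id: str


@dataclass(frozen=True)
class XRef:
    subject_uri: str
    terminology: str
    value: str


@dataclass(frozen=True)
class RelationRecord:
    relation_type: str
    subject_uri: str
    object_uri: str
    source_id: str


@dataclass
class RdfSource:
    """One data source: an id plus its loaded RDF graph."""

    source_id: str
    graph: rdflib.Graph

    @classmethod
    def load(cls, source_id: str, paths: list[str | Path]) -> "RdfSource":
        g = rdflib.Graph()
        for p in paths:
            p = Path(p)
            fmt = {"nt": "nt", "ttl": "turtle", "turtle": "turtle"}.get(
                p.suffix.lstrip("."), "nt"
            )
            g.parse(p, format=fmt)
        return cls(source_id, g)


def parse_mapping_rules(config_text: str) -> MappingConfig:
    """Parse a YAML mapping-rules document.

    Schema::

        prefixes: {pfx: namespace-uri, ...}
        sources: [{id: ..., label_predicate: rdfs:label}, ...]
        rules:
          - {target: E1, source: drugbank,
             pattern: [["?E1", "rdf:type", "drugbank:Drug"]]}
        xrefs:
          - {source: drugbank, entity_type: E1,
             predicate: drugbank:x-atc, terminology: ATC}
        sanitize: {prefix_restore: [...], capitalization: [...]}
    """
    try:
        doc = yaml.safe_load(config_text) or {}
    except yaml.YAMLError as e:
        raise MappingRuleError(f"config does not parse: {e}") from e
    if not isinstance(doc, dict):
        raise MappingRuleError("config root must be a mapping")

    prefixes = dict(_WELL_KNOWN_PREFIXES)
    prefixes.update({str(k): str(v) for k, v in (doc.get("prefixes") or {}).items()})

    label_predicates: dict[str, str] = {}
    for s in doc.get("sources") or []:
        label_predicates[str(s["id"])] = str(s.get("label_predicate", "rdfs:label"))

    rules: list[MappingRule] = []
    for i, r in enumerate(doc.get("rules") or []):
        try:
            pattern = tuple(
                (str(a), str(b), str(c)) for a, b, c in (r.get("pattern") or [])
            )
            rule = MappingRule(str(r["target"]), str(r["source"]), pattern)
        except (KeyError, TypeError, ValueError) as e:
            raise MappingRuleError(f"rule #{i} is malformed: {r!r} ({e})") from e
        rule.validate()
        rules.append(rule)

    xref_rules: list[XRefRule] = []
    for i, r in enumerate(doc.get("xrefs") or []):
        try:
            xr = XRefRule(
                str(r["source"]), str(r["entity_type"]),
                str(r["predicate"]), str(r["terminology"]),
            )
        except (KeyError, TypeError) as e:
            raise MappingRuleError(f"xref rule #{i} is malformed: {r!r} ({e})") from e
        if xr.entity_type not in ENTITY_TYPES:
            raise MappingRuleError(f"xref rule #{i}: unknown entity type {xr.entity_type!r}")
        if xr.terminology not in TERMINOLOGIES:
            raise MappingRuleError(f"xref rule #{i}: unknown terminology {xr.terminology!r}")
        xref_rules.append(xr)

    return MappingConfig(
        rules=rules,
        xref_rules=xref_rules,
        prefixes=prefixes,
        label_predicates=label_predicates,
        sanitize_rules=SanitizeRules.from_config(doc.get("sanitize")),
    )


def _pattern_query(config: MappingConfig, rule: MappingRule, select: list[str]) -> str:
    """Render a basic graph pattern as a SPARQL SELECT."""
    def term(t: str) -> str:
        if t.startswith("?"):
            return t
        return f"<{config.expand(t)}>"

    body = " . ".join(" ".join(term(t) for t in triple) for triple in rule.pattern)
    return f"SELECT {' '.join(select)} WHERE {{ {body} }}"


def _label_of(source: RdfSource, config: MappingConfig, uri_ref: rdflib.term.Node) -> str | None:
    pred = config.label_predicates.get(source.source_id, "rdfs:label")
    for o in source.graph.objects(uri_ref, rdflib.URIRef(config.expand(pred))):
        return str(o)
    return None


def extract_entities(
    source: RdfSource,
    config: MappingConfig,
    entity_type: str,
    san_log: list | None = None,
) -> list[EntityRecord]:
    """All distinct entities of one type that a source's patterns match.

    Returns one record per distinct *sanitized* URI, sorted by URI.  A
    source without a rule for the type yields an empty list with a logged
    notice (not every source carries every layer).
    """
    rules = config.rules_for(source.source_id, entity_type)
    if not rules:
        log.info("source %s has no %s rule; skipping", source.source_id, entity_type)
        return []
    var = f"?{entity_type}"
    found: dict[str, EntityRecord] = {}
    for rule in rules:
        q = _pattern_query(config, rule, [var])
        for row in source.graph.query(q):
            raw = row[0]
            for uri in sanitize_uri(
                str(raw), source.source_id, config.sanitize_rules, san_log
            ):
                if uri not in found or found[uri].label is None:
                    found[uri] = EntityRecord(
                        uri=uri,
                        entity_type=entity_type,
                        label=_label_of(source, config, raw),
                        source_id=source.source_id,
                    )
    return [found[u] for u in sorted(found)]


def _bare_code(obj: rdflib.term.Node) -> str:
    """Terminology code from an x-ref object (literal or URI local name)."""
    s = str(obj)
    if isinstance(obj, rdflib.URIRef):
        idx = max(s.rfind("/"), s.rfind("#"), s.rfind(":"))
        s = s[idx + 1 :]
    return s


def extract_xrefs(
    source: RdfSource,
    config: MappingConfig,
    entities: list[EntityRecord],
    san_log: list | None = None,
) -> list[XRef]:
    """Cross-reference attributes for extracted entities.

    ``direct`` terminology yields a URI-valued x-ref (an explicit link to
    the same entity in another source); any other terminology yields the
    bare code (e.g. HGNC ``3535``).  Subjects and values are sanitized, and
    only x-refs whose sanitized subject is one of ``entities`` are kept.
    """
    by_type: dict[str, set[str]] = {}
    for e in entities:
        by_type.setdefault(e.entity_type, set()).add(e.uri)
    out: set[XRef] = set()
    for xr in config.xref_rules:
        if xr.source_id != source.source_id:
            continue
        known = by_type.get(xr.entity_type, set())
        if not known:
            continue
        pred = rdflib.URIRef(config.expand(xr.predicate))
        for s, _, o in source.graph.triples((None, pred, None)):
            subjects = sanitize_uri(str(s), source.source_id, config.sanitize_rules, san_log)
            subjects = [u for u in subjects if u in known]
            if not subjects:
                continue
            if xr.terminology == "direct":
                values = sanitize_uri(str(o), source.source_id, config.sanitize_rules, san_log)
            else:
                values = sanitize_uri(
                    _bare_code(o), source.source_id, config.sanitize_rules, san_log
                )
            for subj in subjects:
                for v in values:
                    out.add(XRef(subj, xr.terminology, v))
    return sorted(out, key=lambda x: (x.subject_uri, x.terminology, x.value))


def extract_relations(
    source: RdfSource,
    config: MappingConfig,
    relation_type: str,
    san_log: list | None = None,
) -> list[RelationRecord]:
    """All distinct relations of one type that a source's patterns match.

    Intermediate (blank-node hop / reification) bindings are discarded;
    endpoints are sanitized, and an aggregated endpoint that splits into
    several URIs produces the cross-product of cleaned endpoint pairs.
    """
    rules = config.rules_for(source.source_id, relation_type)
    if not rules:
        log.info("source %s has no %s rule; skipping", source.source_id, relation_type)
        return []
    subj_t, obj_t = RELATION_LAYERS[relation_type]
    pairs: set[tuple[str, str]] = set()
    for rule in rules:
        q = _pattern_query(config, rule, [f"?{subj_t}", f"?{obj_t}"])
        for row in source.graph.query(q):
            subs = sanitize_uri(str(row[0]), source.source_id, config.sanitize_rules, san_log)
            objs = sanitize_uri(str(row[1]), source.source_id, config.sanitize_rules, san_log)
            for s in subs:
                for o in objs:
                    pairs.add((s, o))
    return [
        RelationRecord(relation_type, s, o, source.source_id)
        for s, o in sorted(pairs)
    ]


def run_extraction(
    config: MappingConfig, sources: list[RdfSource]
) -> tuple[list[EntityRecord], list[XRef], list[RelationRecord], dict]:
    """Extract every entity/x-ref/relation type from every source.

    Returns the pooled record lists plus a report dict with per
    (source, type) counts and the sanitization rewrites applied.
    """
    entities: list[EntityRecord] = []
    xrefs: list[XRef] = []
    relations: list[RelationRecord] = []
    san_log: list = []
    counts: dict = {}
    for src in sources:
        per = counts.setdefault(src.source_id, {})
        src_entities: list[EntityRecord] = []
        for et in ENTITY_TYPES:
            recs = extract_entities(src, config, et, san_log)
            per[et] = len(recs)
            src_entities.extend(recs)
        entities.extend(src_entities)
        xr = extract_xrefs(src, config, src_entities, san_log)
        per["xrefs"] = len(xr)
        xrefs.extend(xr)
        for rt in RELATION_TYPES:
            recs = extract_relations(src, config, rt, san_log)
            per[rt] = len(recs)
            relations.extend(recs)
    report = {
        "counts": counts,
        "sanitized": [
            {"source": s, "raw": raw, "cleaned": cleaned} for s, raw, cleaned in san_log
        ],
    }
    return entities, xrefs, relations, report
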