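"""URI sanitization for noisy linked-data identifiers.

Biomedical RDF dumps produced by automated conversion pipelines carry
recurring identifier defects: trailing quote characters left by parse
errors, pathway codes stripped of their ``map`` prefix, lower-cased gene
locus names, and several local names aggregated into one URI separated by
whitespace.  The sanitizer repairs these with an ordered, config-driven
rule table so that downstream reconciliation sees canonical identifiers.

Rules are plain ``(regex, replacement)`` pairs grouped into two families:

``prefix_restore``
    re-attach a required local-name prefix (e.g. ``kegg:00010`` ->
    ``kegg:map00010``).
``capitalization``
    restore canonical casing of known namespace patterns (e.g.
    ``kegg:hsa_2147`` -> ``kegg:HSA_2147``).

Quote stripping and whitespace splitting are universal and always applied.
New sources with new dialect quirks extend the table via the mapping-rules
config; the defaults below cover the error patterns observed in public
biomedical RDF dumps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["SanitizationError", "SanitizeRules", "sanitize_uri"]


class SanitizationError(ValueError):
    """Raised when a raw identifier reduces to nothing after cleaning."""


#: Default dialect table.  Patterns match both CURIE (``kegg:...``) and
#: full-URI (``.../path/...``) spellings of the same identifiers.
DEFAULT_PREFIX_RESTORE: tuple[tuple[str, str], ...] = (
    (r"(?i)(kegg:)(\d{4,5})\b", r"\1map\2"),
    (r"(/path/)(\d{4,5})\b", r"\1map\2"),
)
DEFAULT_CAPITALIZATION: tuple[tuple[str, str], ...] = (
    (r"(?i)\bhsa_", "HSA_"),
)

# Percent-escapes that hide the raw error characters inside an otherwise
# syntactically valid IRI.
_DECODE = (("%5C", "\\"), ("%22", '"'), ("%20", " "))
_TRAILING_JUNK = '"\\\''


@dataclass(frozen=True)
class SanitizeRules:
    """Dialect table: ordered regex rewrites applied to every identifier."""

    prefix_restore: tuple[tuple[str, str], ...] = DEFAULT_PREFIX_RESTORE
    capitalization: tuple[tuple[str, str], ...] = DEFAULT_CAPITALIZATION

    @classmethod
    def from_config(cls, cfg: dict | None) -> "SanitizeRules":
        if not cfg:
            return cls()
        def pairs(key, default):
            raw = cfg.get(key)
            if raw is None:
                return default
            return tuple((str(a), str(b)) for a, b in raw)
        return cls(
            prefix_restore=pairs("prefix_restore", DEFAULT_PREFIX_RESTORE),
            capitalization=pairs("capitalization", DEFAULT_CAPITALIZATION),
        )

    def _apply_subs(self, s: str) -> str:
        for pat, rep in self.prefix_restore:
            s = re.sub(pat, rep, s)
        for pat, rep in self.capitalization:
            s = re.sub(pat, rep, s)
        return s


def _split_namespace(uri: str) -> tuple[str, str]:
    """Split at the last of '/', '#', ':' into (namespace-with-sep, local)."""
    idx = max(uri.rfind("/"), uri.rfind("#"), uri.rfind(":"))
    if idx < 0:
        return "", uri
    return uri[: idx + 1], uri[idx + 1 :]


def sanitize_uri(
    raw: str,
    source_id: str | None = None,
    rules: SanitizeRules | None = None,
    log: list | None = None,
) -> list[str]:
    """Clean one raw identifier, returning one or more canonical URIs.

    Applied in order: decode hidden escapes, strip trailing quote/backslash
    characters, restore required prefixes and canonical capitalization, and
    finally split whitespace-aggregated local names into separate URIs that
    share the leading namespace (bare numeric tokens inherit the stem of
    the first local name, so ``kegg:HSA_1551 1576`` yields
    ``kegg:HSA_1551`` and ``kegg:HSA_1576``).

    Raises :class:`SanitizationError` if nothing survives cleaning.  When
    ``log`` is given, every rewrite is appended as
    ``(source_id, raw, cleaned-list)``.
    """
    if rules is None:
        rules = SanitizeRules()
    s = raw
    for enc, dec in _DECODE:
        s = s.replace(enc, dec)
    s = s.strip().rstrip(_TRAILING_JUNK).strip()
    if not s:
        raise SanitizationError(f"identifier {raw!r} is empty after cleaning")
    s = rules._apply_subs(s)

    tokens = s.split()
    first = tokens[0].rstrip(_TRAILING_JUNK)
    namespace, local = _split_namespace(first)
    stem = local[: local.rfind("_") + 1] if "_" in local else ""
    out = [first]
    for tok in tokens[1:]:
        tok = tok.rstrip(_TRAILING_JUNK)
        if not tok:
            continue
        if any(c in tok for c in ":/#"):
            cand = tok  # a full identifier of its own
        elif stem and not tok.startswith(stem):
            cand = namespace + stem + tok
        else:
            cand = namespace + tok
        out.append(rules._apply_subs(cand))

    cleaned, seen = [], set()
    for u in out:
        if u and u not in seen:
            seen.add(u)
            cleaned.append(u)
    if not cleaned:
        raise SanitizationError(f"identifier {raw!r} is empty after cleaning")
    if log is not None and cleaned != [raw]:
        log.append((source_id, raw, list(cleaned)))
    return cleaned
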