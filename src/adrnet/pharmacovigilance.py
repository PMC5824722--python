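"""Safety-report handling, disproportionality filtering and ROC evaluation.

Spontaneous adverse-event reports (FAERS-style) list the drugs a patient
received and the reactions observed.  Reports are mapped onto the network
by normalized-label lookup, vectorized into binary input/outcome clamps
for the hidden-CRF, and evaluated against a "silver standard": held-out
report-ADR pairs whose observed/expected co-occurrence ratio in the
training reports exceeds a threshold (default strictly greater than 2)
count as positives, absent ADRs as negatives.  Scoring is per-ADR ROC /
AUROC with event-specific thresholds, plus one pooled curve that shares a
single probability threshold across all ADRs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .hcrf import HCRFModel, predict
from .network import KPartiteNetwork

__all__ = [
    "Report",
    "ReportDB",
    "SilverStandard",
    "ReportFormatError",
    "load_reports",
    "map_labels",
    "vectorize",
    "oe_ratio",
    "build_silver_standard",
    "roc_curve",
    "auroc",
    "evaluate",
    "assign_folds",
]

log = logging.getLogger(__name__)


class ReportFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Report:
    report_id: str
    drugs: frozenset
    reactions: frozenset


@dataclass
class ReportDB:
    """Reports plus (after :func:`map_labels`) their network projections."""

    reports: list = field(default_factory=list)
    label_map: dict = field(default_factory=dict)  # normalized label -> node_id
    skipped: int = 0
    redraws: int = 0
    #: per-report (report_id, frozenset of drug node_ids, frozenset of ADR
    #: node_ids); populated by map_labels.
    mapped: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reports)

    def require_mapped(self) -> None:
        if not self.mapped:
            raise ReportFormatError("report database has not been mapped to a network")


def _normalize(label: str) -> str:
    """Case-insensitive, punctuation- and whitespace-collapsed form."""
    return re.sub(r"[\W_]+", " ", label.lower()).strip()


def load_reports(path: str | Path) -> ReportDB:
    """Read a TSV report file: report_id, drugs, reactions (pipe-delimited).

    Rows with an empty drug or reaction field are skipped and counted;
    duplicate report ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"report_id", "drugs", "reactions"} - set(df.columns)
    if missing:
        raise ReportFormatError(f"missing column(s): {sorted(missing)}")
    db = ReportDB()
    seen: set = set()
    for row in df.itertuples(index=False):
        rid = row.report_id.strip()
        if rid in seen:
            raise ReportFormatError(f"duplicate report id {rid!r}")
        seen.add(rid)
        drugs = frozenset(t.strip() for t in row.drugs.split("|") if t.strip())
        reactions = frozenset(t.strip() for t in row.reactions.split("|") if t.strip())
        if not drugs or not reactions:
            db.skipped += 1
            continue
        db.reports.append(Report(rid, drugs, reactions))
    return db


def save_reports(db: ReportDB, path: str | Path) -> None:
    """Write the TSV format read by :func:`load_reports`."""
    with open(path, "w") as f:
        f.write("report_id\tdrugs\treactions\n")
        for r in db.reports:
            f.write(f"{r.report_id}\t{'|'.join(sorted(r.drugs))}\t"
                    f"{'|'.join(sorted(r.reactions))}\n")


def map_labels(db: ReportDB, net: KPartiteNetwork) -> tuple[ReportDB, dict]:
    """Match report labels against network node labels; drop unmappable reports.

    Matching is exact after normalization (lowercase, punctuation and
    whitespace collapsed).  Reports for which no drug or no reaction maps
    onto the network are discarded and counted.
    """
    label_map: dict = {}
    for nid, node in sorted(net.nodes.items()):
        if node.entity_type not in ("E1", "E4"):
            continue
        for lab in node.labels | {nid}:
            label_map.setdefault(_normalize(lab), nid)

    out = ReportDB(label_map=label_map, skipped=db.skipped)
    kept = discarded = 0
    for r in db.reports:
        dn = frozenset(
            label_map[_normalize(d)] for d in r.drugs if _normalize(d) in label_map
        )
        an = frozenset(
            label_map[_normalize(a)] for a in r.reactions if _normalize(a) in label_map
        )
        if not dn or not an:
            discarded += 1
            continue
        kept += 1
        out.reports.append(r)
        out.mapped.append((r.report_id, dn, an))
    stats = {"kept": kept, "discarded": discarded}
    return out, stats


def vectorize(db: ReportDB, model: HCRFModel) -> list[tuple[dict, dict]]:
    """One total (x_clamp, y_clamp) pair per mapped report.

    x covers every Drug node (1 if the report mentions it), y every
    Phenotype node.
    """
    db.require_mapped()
    drugs = model.inputs()
    adrs = model.outcomes()
    out = []
    for _, dn, an in db.mapped:
        x = {d: int(d in dn) for d in drugs}
        y = {a: int(a in an) for a in adrs}
        out.append((x, y))
    return out


def oe_ratio(train_db: ReportDB, drug_combo: set, adr: str) -> float:
    """Observed/expected co-occurrence of a drug combination and an ADR.

    O is the number of training reports containing the whole combination
    and the ADR; E is the independence expectation
    N(combo) * N(adr) / N.  Returns 0 when nothing is observed (including
    the degenerate E = 0 case).
    """
    train_db.require_mapped()
    n = len(train_db.mapped)
    if n == 0:
        raise ReportFormatError("empty training database")
    combo = frozenset(drug_combo)
    n_combo = n_adr = n_both = 0
    for _, dn, an in train_db.mapped:
        has_combo = combo <= dn
        has_adr = adr in an
        n_combo += has_combo
        n_adr += has_adr
        n_both += has_combo and has_adr
    if n_both == 0:
        return 0.0
    expected = n_combo * n_adr / n
    return n_both / expected


@dataclass
class SilverStandard:
    """Labeled (input drug set, ADR) pairs retained by the O/E filter."""

    pairs: list  # (frozenset drug node_ids, adr node_id, label in {0,1})
    oe_threshold: float
    n_excluded: int = 0


def build_silver_standard(
    train_db: ReportDB,
    heldout_db: ReportDB,
    threshold: float = 2.0,
    model: HCRFModel | None = None,
) -> SilverStandard:
    """Turn held-out reports into labeled test pairs.

    For each held-out report and each ADR in the model: an ADR present in
    the report is a positive only if its O/E ratio against the training
    reports (at the report's full drug combination) is strictly greater
    than ``threshold``; present-but-filtered pairs are excluded from both
    classes; absent ADRs are negatives.
    """
    train_db.require_mapped()
    heldout_db.require_mapped()
    if not heldout_db.mapped:
        raise ReportFormatError("empty held-out set")
    adrs = model.outcomes() if model is not None else sorted(
        {a for _, _, an in train_db.mapped for a in an}
    )
    pairs = []
    excluded = 0
    cache: dict = {}
    for _, dn, an in heldout_db.mapped:
        for adr in adrs:
            if adr in an:
                key = (dn, adr)
                ratio = cache.get(key)
                if ratio is None:
                    ratio = cache[key] = oe_ratio(train_db, dn, adr)
                if ratio > threshold:
                    pairs.append((dn, adr, 1))
                else:
                    excluded += 1
            else:
                pairs.append((dn, adr, 0))
    return SilverStandard(pairs=pairs, oe_threshold=threshold, n_excluded=excluded)


def roc_curve(scores, labels) -> list[tuple[float, float, float]]:
    """(fpr, tpr, threshold) triples over a descending threshold sweep.

    Starts at (0, 0) and ends at (1, 1); raises on single-class labels.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC curve undefined: labels contain a single class")
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float),
                                  drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))


def auroc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def evaluate(model: HCRFModel, silver: SilverStandard, **bp_opts) -> dict:
    """Per-ADR ROC/AUROC with event-specific thresholds, plus a pooled curve.

    Prediction scores P(adr = 1 | x) are computed once per distinct drug
    combination.  ADRs with test pairs of only one class are reported as
    unevaluated; the pooled curve concatenates every pair to probe a
    single shared probability threshold.
    """
    pred_cache: dict = {}
    drugs = model.inputs()

    def score(dn: frozenset, adr: str) -> float:
        p = pred_cache.get(dn)
        if p is None:
            x = {d: int(d in dn) for d in drugs}
            p = pred_cache[dn] = predict(model, x, **bp_opts)
        return p[adr]

    by_adr: dict = {}
    pooled_scores, pooled_labels = [], []
    for dn, adr, label in silver.pairs:
        s = score(dn, adr)
        by_adr.setdefault(adr, ([], []))
        by_adr[adr][0].append(s)
        by_adr[adr][1].append(label)
        pooled_scores.append(s)
        pooled_labels.append(label)

    per_adr = {}
    unevaluated = []
    for adr in model.outcomes():
        if adr not in by_adr:
            unevaluated.append(adr)
            continue
        ss, ll = by_adr[adr]
        if len(set(ll)) < 2:
            unevaluated.append(adr)
            continue
        per_adr[adr] = {
            "auroc": auroc(ss, ll),
            "curve": roc_curve(ss, ll),
            "n_pos": int(sum(ll)),
            "n_neg": int(len(ll) - sum(ll)),
        }

    pooled = None
    if len(set(pooled_labels)) >= 2:
        pooled = {
            "auroc": auroc(pooled_scores, pooled_labels),
            "curve": roc_curve(pooled_scores, pooled_labels),
            "n_pos": int(sum(pooled_labels)),
            "n_neg": int(len(pooled_labels) - sum(pooled_labels)),
        }
    return {"per_adr": per_adr, "pooled": pooled, "unevaluated": sorted(unevaluated)}


def assign_folds(db: ReportDB, k: int = 5, seed: int = 0) -> list[int]:
    """Fold index per report, by seeded shuffle (cross-validation harness)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(db.reports))
    folds = [0] * len(db.reports)
    for pos, ri in enumerate(order):
        folds[ri] = pos % k
    return folds


def evaluation_to_json(result: dict) -> str:
    return json.dumps(result, indent=1, sort_keys=True)
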