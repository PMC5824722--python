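"""Hidden conditional random field over the k-partite network.

The network is read as a pairwise undirected graphical model with one
binary variable per node.  Drug nodes are observed inputs ``x``, protein
and pathway nodes are hidden ``h`` (adverse-event reports say nothing
about them), and phenotype nodes are the structured outcome ``y``.  Each
edge (j,k) carries a 2x2 parameter table over the joint state
configurations L = {(0,0),(0,1),(1,0),(1,1)}, so the potential of a total
assignment is

    Psi(y, h, x; theta) = sum_{(j,k) in E} sum_{l in L} f_l(j,k) theta_l

with f_l the indicator of configuration l on the edge.  The conditional
p(y | x, theta) marginalizes the hidden layers, and training maximizes the
L2-regularized conditional log-likelihood

    L(theta) = sum_i log p(y_i | x_i, theta) - ||theta||^2 / (2 sigma^2)

by stochastic gradient ascent with constant step rate alpha.  Marginals
and log-partition functions come from sum-product loopy belief
propagation (damped, synchronous, log-space); an exact enumeration
routine serves as oracle on small instances.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, xlogy

from .network import KPartiteNetwork, validate_kpartite

__all__ = [
    "HCRFModel",
    "InferenceResult",
    "ModelError",
    "DivergenceError",
    "build_model",
    "potential",
    "infer",
    "brute_force_infer",
    "log_likelihood",
    "objective",
    "gradient",
    "train",
    "predict",
]

log = logging.getLogger(__name__)

ROLE_OF_LAYER = {"E1": "input", "E2": "hidden", "E3": "hidden", "E4": "outcome"}


class ModelError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass
class InferenceResult:
    node_marginals: dict  # node_id -> P(state = 1)
    edge_marginals: dict  # (rtype, u, v) -> 2x2 joint table [s_u, s_v]
    log_partition: float
    converged: bool
    iterations: int


class HCRFModel:
    """Parameter tables plus layer roles over a k-partite network.

    ``params`` maps a parameter key to a 2x2 table; with ``tying="none"``
    every edge owns its table (key = edge key), with ``tying="relation"``
    all edges of one relation type share one table.  Optional per-node
    unary tables (2 reals) are off by default so the potential is purely
    edge-driven.
    """

    def __init__(
        self,
        net: KPartiteNetwork,
        params: dict,
        sigma2: float = 10.0,
        tying: str = "none",
        unary: dict | None = None,
    ):
        self.net = net
        self.node_ids = sorted(net.nodes)
        self.roles = {n: ROLE_OF_LAYER[net.nodes[n].entity_type] for n in self.node_ids}
        self.edge_keys = sorted(net.edges)
        self.tying = tying
        self.params = params
        self.sigma2 = float(sigma2)
        self.unary = unary
        self._struct_cache: dict = {}

    # -- parameter access ---------------------------------------------
    def param_key(self, edge_key):
        return edge_key[0] if self.tying == "relation" else edge_key

    def theta(self, edge_key) -> np.ndarray:
        return self.params[self.param_key(edge_key)]

    def inputs(self) -> list[str]:
        return [n for n in self.node_ids if self.roles[n] == "input"]

    def outcomes(self) -> list[str]:
        return [n for n in self.node_ids if self.roles[n] == "outcome"]

    def hidden(self) -> list[str]:
        return [n for n in self.node_ids if self.roles[n] == "hidden"]

    # -- serialization -------------------------------------------------
    def to_json(self, meta: dict | None = None) -> str:
        net_json = self.net.to_json()
        doc = {
            "graph_sha256": hashlib.sha256(net_json.encode()).hexdigest(),
            "graph": json.loads(net_json),
            "tying": self.tying,
            "sigma2": self.sigma2,
            "params": {
                "|".join(k) if isinstance(k, tuple) else k: np.asarray(v).tolist()
                for k, v in sorted(self.params.items(), key=lambda kv: str(kv[0]))
            },
            "unary": None if self.unary is None else {
                n: np.asarray(v).tolist() for n, v in sorted(self.unary.items())
            },
            "meta": meta or {},
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HCRFModel":
        doc = json.loads(text)
        net = KPartiteNetwork.from_json(json.dumps(doc["graph"]))
        params = {}
        for k, v in doc["params"].items():
            key = tuple(k.split("|")) if "|" in k else k
            params[key] = np.asarray(v, dtype=float)
        unary = doc.get("unary")
        if unary is not None:
            unary = {n: np.asarray(v, dtype=float) for n, v in unary.items()}
        return cls(net, params, sigma2=doc["sigma2"], tying=doc["tying"], unary=unary)


def build_model(
    net: KPartiteNetwork,
    init: str = "zero",
    init_scale: float = 0.1,
    seed: int = 0,
    sigma2: float = 10.0,
    tying: str = "none",
    unary: bool = False,
) -> HCRFModel:
    """Create a model with one 2x2 table per edge (or per relation type).

    ``init="zero"`` gives all-zero tables; ``init="gaussian"`` draws each
    entry i.i.d. N(0, init_scale^2), reproducibly by ``seed``.
    """
    validate_kpartite(net)
    if not any(e.entity_type == "E1" for e in net.nodes.values()):
        raise ModelError("network has no Drug (E1) nodes: nothing to condition on")
    if not any(e.entity_type == "E4" for e in net.nodes.values()):
        raise ModelError("network has no Phenotype (E4) nodes: nothing to predict")
    if tying not in ("none", "relation"):
        raise ModelError(f"unknown tying mode {tying!r}")
    rng = np.random.default_rng(seed)
    if tying == "relation":
        keys = sorted({k[0] for k in net.edges})
    else:
        keys = sorted(net.edges)
    params = {}
    for k in keys:
        if init == "zero":
            params[k] = np.zeros((2, 2))
        elif init == "gaussian":
            params[k] = rng.normal(0.0, init_scale, size=(2, 2))
        else:
            raise ModelError(f"unknown init {init!r}")
    un = {n: np.zeros(2) for n in sorted(net.nodes)} if unary else None
    return HCRFModel(net, params, sigma2=sigma2, tying=tying, unary=un)


def potential(model: HCRFModel, assignment: dict) -> float:
    """Psi of a total assignment: sum of theta entries over all edges."""
    tot = 0.0
    for ek in model.edge_keys:
        _, u, v = ek
        tot += model.theta(ek)[assignment[u], assignment[v]]
    if model.unary is not None:
        for n in model.node_ids:
            tot += model.unary[n][assignment[n]]
    return float(tot)


# ---------------------------------------------------------------------------
# clamp reduction (shared by BP only; the brute-force oracle enumerates the
# raw model independently)


class _Structure:
    """Index maps for one clamp pattern: which edges become constants,
    unary fields, or free-free pair potentials."""

    def __init__(self, model: HCRFModel, clamp_keys: frozenset):
        self.free = [n for n in model.node_ids if n not in clamp_keys]
        self.index = {n: i for i, n in enumerate(self.free)}
        self.pairs: list[tuple[int, int]] = []
        self.pair_terms: list[list] = []  # per pair: [(param_key, flip), ...]
        pair_pos: dict[tuple[int, int], int] = {}
        self.half: list = []  # (free_idx, param_key, clamped_node, clamped_is_subject)
        self.full: list = []  # (param_key, u, v)
        self.route: dict = {}
        for ek in model.edge_keys:
            _, u, v = ek
            pk = model.param_key(ek)
            ucl, vcl = u in clamp_keys, v in clamp_keys
            if ucl and vcl:
                self.full.append((pk, u, v))
                self.route[ek] = ("full", u, v)
            elif ucl:
                self.half.append((self.index[v], pk, u, True))
                self.route[ek] = ("half_u", u, v)
            elif vcl:
                self.half.append((self.index[u], pk, v, False))
                self.route[ek] = ("half_v", u, v)
            else:
                i, j = self.index[u], self.index[v]
                a, b = (i, j) if i < j else (j, i)
                pos = pair_pos.get((a, b))
                if pos is None:
                    pos = pair_pos[(a, b)] = len(self.pairs)
                    self.pairs.append((a, b))
                    self.pair_terms.append([])
                self.pair_terms[pos].append((pk, i > j))
                self.route[ek] = ("pair", pos, i > j)
        self.degree = np.zeros(len(self.free))
        for a, b in self.pairs:
            self.degree[a] += 1
            self.degree[b] += 1


def _reduce(model: HCRFModel, clamps: dict):
    """Fields, pair potentials and the clamped-energy constant."""
    key = frozenset(clamps)
    st = model._struct_cache.get(key)
    if st is None:
        st = model._struct_cache[key] = _Structure(model, key)
    n = len(st.free)
    F = np.zeros((n, 2))
    const = 0.0
    if model.unary is not None:
        for node, tab in model.unary.items():
            if node in clamps:
                const += tab[clamps[node]]
            else:
                F[st.index[node]] += tab
    for pk, u, v in st.full:
        const += model.params[pk][clamps[u], clamps[v]]
    for j, pk, cn, is_subj in st.half:
        t = model.params[pk]
        F[j] += t[clamps[cn], :] if is_subj else t[:, clamps[cn]]
    W = []
    for terms in st.pair_terms:
        w = np.zeros((2, 2))
        for pk, flip in terms:
            w = w + (model.params[pk].T if flip else model.params[pk])
        W.append(w)
    return st, F, W, float(const)


def _bp(F, pairs, W, damping, tol, max_iter):
    """Damped synchronous sum-product in log space on a binary pairwise model.

    Returns (node beliefs, pair beliefs, Bethe log-partition, converged,
    iterations).  Exact on acyclic instances.
    """
    n = F.shape[0]
    P = len(pairs)
    if P == 0:
        lse = logsumexp(F, axis=1) if n else np.zeros(0)
        b = np.exp(F - lse[:, None]) if n else np.zeros((0, 2))
        return b, [], float(lse.sum()), True, 0

    src = np.empty(2 * P, dtype=int)
    dst = np.empty(2 * P, dtype=int)
    Wd = np.empty((2 * P, 2, 2))
    for p, (i, j) in enumerate(pairs):
        src[2 * p], dst[2 * p], Wd[2 * p] = i, j, W[p]
        src[2 * p + 1], dst[2 * p + 1], Wd[2 * p + 1] = j, i, W[p].T
    rev = np.arange(2 * P) ^ 1

    M = np.zeros((2 * P, 2))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S = F.copy()
        np.add.at(S, dst, M)
        pre = S[src] - M[rev]
        tmp = pre[:, :, None] + Wd
        new = np.logaddexp(tmp[:, 0, :], tmp[:, 1, :])
        new -= np.logaddexp(new[:, 0], new[:, 1])[:, None]
        Mn = damping * M + (1.0 - damping) * new
        delta = float(np.max(np.abs(Mn - M)))
        M = Mn
        if delta < tol:
            converged = True
            break

    S = F.copy()
    np.add.at(S, dst, M)
    lse = logsumexp(S, axis=1)
    b = np.exp(S - lse[:, None])

    # Bethe free energy: logZ = U + H with
    #   U = sum_pairs <W_ij>_{b_ij} + sum_i <F_i>_{b_i}
    #   H = sum_pairs H(b_ij) + sum_i (1 - deg_i) H(b_i)
    pair_b = []
    U = float(np.sum(b * F))
    H_pairs = 0.0
    deg = np.zeros(n)
    for p, (i, j) in enumerate(pairs):
        e = 2 * p
        B = Wd[e] + (S[i] - M[rev[e]])[:, None] + (S[j] - M[e])[None, :]
        B -= logsumexp(B)
        bb = np.exp(B)
        pair_b.append(bb)
        U += float(np.sum(bb * Wd[e]))
        H_pairs += float(-np.sum(xlogy(bb, bb)))
        deg[i] += 1
        deg[j] += 1
    node_entropy = -np.sum(xlogy(b, b), axis=1)
    H = H_pairs + float(np.sum((1.0 - deg) * node_entropy))
    return b, pair_b, U + H, converged, it


def infer(
    model: HCRFModel,
    clamps: dict | None = None,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> InferenceResult:
    """Sum-product loopy BP with clamped nodes fixed.

    Clamped nodes are absorbed exactly (their edges become constants or
    unary fields on the free neighbors), so the returned log-partition is
    ``log sum_free exp(Psi)`` with the clamped states held fixed — exact on
    acyclic instances, Bethe-approximate on loopy ones.  Non-convergence
    is reported via ``converged=False`` with a logged warning, never an
    exception.
    """
    clamps = dict(clamps or {})
    for n in clamps:
        if n not in model.net.nodes:
            raise ModelError(f"clamp on unknown node {n!r}")
    st, F, W, const = _reduce(model, clamps)
    b, pair_b, logZ, converged, iters = _bp(F, st.pairs, W, damping, tol, max_iter)
    if not converged:
        log.warning("BP did not converge within %d iterations", iters)

    node_marginals = {}
    for n, s in clamps.items():
        node_marginals[n] = float(s)
    for i, n in enumerate(st.free):
        node_marginals[n] = float(b[i, 1])

    edge_marginals = {}
    for ek in model.edge_keys:
        kind, *info = st.route[ek]
        if kind == "full":
            u, v = info
            t = np.zeros((2, 2))
            t[clamps[u], clamps[v]] = 1.0
        elif kind == "half_u":
            u, v = info
            t = np.zeros((2, 2))
            mv = b[st.index[v]]
            t[clamps[u], :] = mv
        elif kind == "half_v":
            u, v = info
            t = np.zeros((2, 2))
            mu = b[st.index[u]]
            t[:, clamps[v]] = mu
        else:
            pos, flip = info
            t = pair_b[pos].T.copy() if flip else pair_b[pos].copy()
        edge_marginals[ek] = t

    return InferenceResult(node_marginals, edge_marginals, logZ + const, converged, iters)


def brute_force_infer(model: HCRFModel, clamps: dict | None = None) -> InferenceResult:
    """Exact marginals and log-partition by enumeration of all free states.

    Independent of the BP path: enumerates assignments directly against
    the model's edge tables.  Refuses more than 20 free nodes.
    """
    clamps = dict(clamps or {})
    free = [n for n in model.node_ids if n not in clamps]
    nf = len(free)
    if nf > 20:
        raise ModelError(f"{nf} free nodes exceeds the enumeration limit of 20")
    idx = {n: i for i, n in enumerate(free)}
    n_assign = 1 << nf
    bits = (np.arange(n_assign)[:, None] >> np.arange(nf)) & 1 if nf else np.zeros((1, 0), int)

    def col(node):
        if node in clamps:
            return np.full(n_assign, clamps[node], dtype=int)
        return bits[:, idx[node]]

    E = np.zeros(n_assign)
    for ek in model.edge_keys:
        _, u, v = ek
        E += model.theta(ek)[col(u), col(v)]
    if model.unary is not None:
        for n in model.node_ids:
            E += model.unary[n][col(n)]
    logZ = float(logsumexp(E))
    prob = np.exp(E - logZ)

    node_marginals = {n: float(s) for n, s in clamps.items()}
    for n in free:
        node_marginals[n] = float(prob @ bits[:, idx[n]])
    edge_marginals = {}
    for ek in model.edge_keys:
        _, u, v = ek
        su, sv = col(u), col(v)
        t = np.zeros((2, 2))
        np.add.at(t, (su, sv), prob)
        edge_marginals[ek] = t
    return InferenceResult(node_marginals, edge_marginals, logZ, True, 0)


def log_likelihood(
    model: HCRFModel,
    x_clamp: dict,
    y_clamp: dict,
    infer_fn=infer,
    **bp_opts,
) -> float:
    """log p(y | x, theta): clamped log-partition minus free log-partition.

    The hidden layers are marginalized in both runs; the value is <= 0 up
    to Bethe approximation error on loopy graphs.
    """
    r_clamped = infer_fn(model, {**x_clamp, **y_clamp}, **bp_opts)
    r_free = infer_fn(model, dict(x_clamp), **bp_opts)
    return r_clamped.log_partition - r_free.log_partition


def objective(model: HCRFModel, db: list, sigma2: float | None = None, **bp_opts) -> float:
    """Regularized conditional log-likelihood over the report database."""
    sigma2 = model.sigma2 if sigma2 is None else sigma2
    tot = sum(log_likelihood(model, x, y, **bp_opts) for x, y in db)
    penalty = sum(float(np.sum(np.square(t))) for t in model.params.values())
    return tot - penalty / (2.0 * sigma2)


def _ll_gradient(model: HCRFModel, x_clamp: dict, y_clamp: dict, infer_fn=infer, **bp_opts):
    """Unregularized gradient: clamped minus free edge-configuration
    expectations, accumulated per parameter key."""
    r_clamped = infer_fn(model, {**x_clamp, **y_clamp}, **bp_opts)
    r_free = infer_fn(model, dict(x_clamp), **bp_opts)
    g = {k: np.zeros((2, 2)) for k in model.params}
    for ek in model.edge_keys:
        g[model.param_key(ek)] += r_clamped.edge_marginals[ek] - r_free.edge_marginals[ek]
    return g


def gradient(
    model: HCRFModel,
    x_clamp: dict,
    y_clamp: dict,
    sigma2: float | None = None,
    infer_fn=infer,
    **bp_opts,
) -> dict:
    """Analytic gradient of one report's regularized log-likelihood.

    For each edge configuration l: E_{h|y,x}[f_l] - E_{y,h|x}[f_l]
    - theta_l / sigma^2, with the expectations taken from the clamped and
    free inference runs.
    """
    sigma2 = model.sigma2 if sigma2 is None else sigma2
    g = _ll_gradient(model, x_clamp, y_clamp, infer_fn=infer_fn, **bp_opts)
    for k in g:
        g[k] = g[k] - model.params[k] / sigma2
    return g


def train(
    model: HCRFModel,
    db: list,
    alpha: float = 0.01,
    sigma2: float | None = None,
    epochs: int = 5,
    seed: int = 0,
    eval_objective: bool = True,
    infer_fn=infer,
    **bp_opts,
) -> tuple[HCRFModel, list[float]]:
    """Stochastic gradient ascent over the report database, in place.

    One update per report with constant step rate ``alpha``; the L2
    penalty enters each update scaled by 1/|db| so a full epoch applies it
    once.  Sample order is reshuffled each epoch by ``seed``.  Returns the
    model and a per-epoch trace of the full objective (skipped when
    ``eval_objective`` is false to halve the cost).
    """
    if not db:
        raise ModelError("empty training database")
    sigma2 = model.sigma2 if sigma2 is None else sigma2
    rng = np.random.default_rng(seed)
    n = len(db)
    trace: list[float] = []
    for ep in range(epochs):
        order = rng.permutation(n)
        for si in order:
            x, y = db[si]
            g = _ll_gradient(model, x, y, infer_fn=infer_fn, **bp_opts)
            for k, tab in model.params.items():
                tab += alpha * (g[k] - tab / (sigma2 * n))
                if not np.all(np.isfinite(tab)):
                    raise DivergenceError(
                        f"non-finite parameters at epoch {ep}, sample {si}"
                    )
        if eval_objective:
            trace.append(objective(model, db, sigma2, **bp_opts))
    return model, trace


def predict(model: HCRFModel, x_clamp: dict, infer_fn=infer, **bp_opts) -> dict:
    """P(y_j = 1 | x) for every Phenotype node, from the free inference run."""
    res = infer_fn(model, dict(x_clamp), **bp_opts)
    return {n: res.node_marginals[n] for n in model.outcomes()}
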