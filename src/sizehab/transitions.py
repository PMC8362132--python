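"""Mk-model fitting and stochastic character mapping of habitat use.

Provides the pruning log-likelihood, ML rate fitting under ER/SYM/ARD
constraints (log-rate parameterisation, multi-start), and stochastic maps
whose per-edge histories are sampled by endpoint-conditioned uniformization.
The summary retains per-map counts and a per-tip event rate used by hotspot
detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import expm

from sizehab.tree import Phylogeny

__all__ = [
    "MkModel",
    "StochasticMapSummary",
    "mk_loglik",
    "fit_mk",
    "stochastic_maps",
    "transition_matrices",
]

_LOG_RATE_BOUNDS = (-12.0, 8.0)


@dataclass
class MkModel:
    states: tuple[str, ...]
    Q: np.ndarray
    constraint: str = "ARD"  # ER | SYM | ARD
    root_prior: str = "equal"  # equal | stationary | fitzjohn
    loglik: Optional[float] = None
    converged: Optional[bool] = None
    n_starts: int = 0

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if Q.shape != (k, k):
            raise ValueError("Q shape does not match states")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < -1e-12):
            raise ValueError("negative off-diagonal rate in Q")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-8:
            raise ValueError("Q rows must sum to zero")
        self.Q = Q

    def stationary_distribution(self) -> np.ndarray:
        k = len(self.states)
        A = np.vstack([self.Q.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return np.maximum(pi, 0.0) / np.maximum(pi, 0.0).sum()


def transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """``expm(Q t)`` for every t in ``lengths`` — eigendecomposition fast
    path with an ``expm`` fallback for defective generators."""
    k = Q.shape[0]
    out = np.empty((len(lengths), k, k))
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e10:
            E = np.exp(np.multiply.outer(lengths, w))  # (m, k)
            out = np.einsum("ij,mj,jl->mil", V, E, Vinv).real
            out = np.clip(out, 0.0, None)
            out /= out.sum(axis=2, keepdims=True)
            return out
    except np.linalg.LinAlgError:
        pass
    for i, t in enumerate(lengths):
        P = expm(Q * t)
        if not np.all(np.isfinite(P)):
            raise FloatingPointError(f"non-finite expm for edge length {t}")
        out[i] = np.clip(P, 0.0, None)
        out[i] /= out[i].sum(axis=1, keepdims=True)
    return out


def _tip_partials(tree: Phylogeny, tip_states: dict[str, str], states: Sequence[str]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(states)}
    part = np.zeros((tree.n_nodes, len(states)))
    for i, lab in enumerate(tree.tip_labels):
        st = tip_states.get(lab)
        if st is None:
            raise ValueError(f"tip {lab!r} has no state")
        if st not in idx:
            raise ValueError(f"tip {lab!r} state {st!r} not in model states")
        part[i, idx[st]] = 1.0
    return part


def _pruning(
    tree: Phylogeny, tip_states: dict[str, str], model: MkModel
) -> tuple[np.ndarray, np.ndarray, float]:
    """Post-order conditional likelihoods.

    Returns (partials, per-edge transition matrices, log scaling factor).
    Partials are normalised per node; the dropped scale is accumulated.
    """
    P = transition_matrices(model.Q, tree.edge_length)
    part = _tip_partials(tree, tip_states, model.states)
    logscale = 0.0
    for nd in tree.postorder():
        if nd < tree.n_tips:
            continue
        acc = np.ones(len(model.states))
        for c in tree.children[nd]:
            acc *= P[c] @ part[c]
        s = acc.sum()
        if s <= 0 or not np.isfinite(s):
            # impossible data under this Q; caller treats as -inf
            return part, P, -np.inf
        part[nd] = acc / s
        logscale += np.log(s)
    return part, P, logscale


def _root_weights(part_root: np.ndarray, model: MkModel) -> np.ndarray:
    k = len(model.states)
    if model.root_prior == "equal":
        return np.full(k, 1.0 / k)
    if model.root_prior == "stationary":
        return model.stationary_distribution()
    if model.root_prior == "fitzjohn":
        s = part_root.sum()
        return part_root / s if s > 0 else np.full(k, 1.0 / k)
    raise ValueError(f"unknown root prior {model.root_prior!r}")


def mk_loglik(tree: Phylogeny, tip_states: dict[str, str], model: MkModel) -> float:
    """Pruning log-likelihood of tip states under the Mk model."""
    part, _, logscale = _pruning(tree, tip_states, model)
    if not np.isfinite(logscale):
        return -np.inf
    w = _root_weights(part[tree.root], model)
    lik = float(w @ part[tree.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


# ------------------------------------------------------------------ fit


def _rate_layout(k: int, constraint: str) -> list[tuple[int, int, int]]:
    """(row, col, parameter index) triples for the free rates."""
    triples = []
    if constraint == "ER":
        for i in range(k):
            for j in range(k):
                if i != j:
                    triples.append((i, j, 0))
    elif constraint == "SYM":
        p = 0
        for i in range(k):
            for j in range(i + 1, k):
                triples.append((i, j, p))
                triples.append((j, i, p))
                p += 1
    elif constraint == "ARD":
        p = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    triples.append((i, j, p))
                    p += 1
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    return triples


def n_free_rates(k: int, constraint: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[constraint]


def parsimony_changes(tree: Phylogeny, tip_states: dict[str, str]) -> int:
    """Fitch parsimony count of state changes (for rate initialisation)."""
    sets: dict[int, frozenset] = {}
    changes = 0
    for nd in tree.postorder():
        if nd < tree.n_tips:
            sets[nd] = frozenset([tip_states[tree.tip_labels[nd]]])
            continue
        inter = None
        union: frozenset = frozenset()
        for c in tree.children[nd]:
            inter = sets[c] if inter is None else inter & sets[c]
            union |= sets[c]
        if inter:
            sets[nd] = inter
        else:
            sets[nd] = union
            changes += 1
    return changes


def _build_q(log_rates: np.ndarray, k: int, layout: list[tuple[int, int, int]]) -> np.ndarray:
    Q = np.zeros((k, k))
    rates = np.exp(log_rates)
    for i, j, p in layout:
        Q[i, j] = rates[p]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def fit_mk(
    tree: Phylogeny,
    tip_states: dict[str, str],
    constraint: str = "ARD",
    seed: int = 0,
    states: Optional[tuple[str, ...]] = None,
    root_prior: str = "equal",
    n_starts: int = 5,
    max_rate: float = np.exp(_LOG_RATE_BOUNDS[1]),
) -> MkModel:
    """ML rates via multi-start bounded optimisation of the pruning loglik."""
    observed = sorted(set(tip_states[lab] for lab in tree.tip_labels))
    if len(observed) < 2:
        raise ValueError("need at least two observed states to fit an Mk model")
    if states is None:
        states = tuple(observed)
    else:
        missing = set(observed) - set(states)
        if missing:
            raise ValueError(f"observed states not in model states: {missing}")
    k = len(states)
    layout = _rate_layout(k, constraint)
    n_par = n_free_rates(k, constraint)
    total_len = float(tree.edge_length.sum())
    # start near the parsimony-implied rate; per-start jitter then spreads
    # the search over neighbouring orders of magnitude
    changes = max(parsimony_changes(tree, tip_states), 1)
    base = np.log(changes / max(total_len, 1e-9))
    hi = min(_LOG_RATE_BOUNDS[1], np.log(max_rate))
    bounds = [(_LOG_RATE_BOUNDS[0], hi)] * n_par

    def nll(x: np.ndarray) -> float:
        model = MkModel(states=states, Q=_build_q(x, k, layout),
                        constraint=constraint, root_prior=root_prior)
        ll = mk_loglik(tree, tip_states, model)
        return 1e10 if not np.isfinite(ll) else -ll

    rng = np.random.default_rng(seed)
    best = None
    any_converged = False
    for s in range(n_starts):
        x0 = np.full(n_par, base)
        if s > 0:
            x0 = x0 + rng.normal(0.0, 1.0, n_par)
        x0 = np.clip(x0, *_LOG_RATE_BOUNDS)
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e10:
        raise RuntimeError("Mk fit failed: no start produced a finite likelihood")
    if not any_converged:
        warnings.warn("Mk fit: no optimizer start reported convergence; "
                      "returning best-so-far")
    return MkModel(
        states=states,
        Q=_build_q(best.x, k, layout),
        constraint=constraint,
        root_prior=root_prior,
        loglik=-float(best.fun),
        converged=any_converged,
        n_starts=n_starts,
    )


# ------------------------------------------------------------- mapping


@dataclass
class StochasticMapSummary:
    """Average transition counts over stochastic character maps."""

    states: tuple[str, ...]
    n_maps: int
    mean_counts: np.ndarray  # k×k ordered from→to, zero diagonal
    per_map_counts: np.ndarray  # (n_maps, k, k)
    tip_event_rate: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.states):
            for j, b in enumerate(self.states):
                if i != j:
                    rows.append(
                        {"from_habitat": a, "to_habitat": b,
                         "mean_count": self.mean_counts[i, j]}
                    )
        return pd.DataFrame(rows)


def _sample_path(
    a: int,
    b: int,
    t: float,
    Q: np.ndarray,
    P_t: np.ndarray,
    R: np.ndarray,
    R_pows: list[np.ndarray],
    mu: float,
    rng: np.random.Generator,
    max_jumps: int = 200,
) -> list[tuple[float, int, int]]:
    """Endpoint-conditioned CTMC path via uniformization.

    Returns (time, from_state, to_state) for each real change.
    Falls back to rejection sampling if the jump-count series misbehaves.
    """
    if mu <= 0:
        return []
    p_ab = P_t[a, b]
    if p_ab <= 0:
        return _reject_path(a, b, t, Q, rng)

    def rpow(n: int) -> np.ndarray:
        while len(R_pows) <= n:
            R_pows.append(R_pows[-1] @ R)
        return R_pows[n]

    u = rng.random() * p_ab
    acc = 0.0
    log_poisson = -mu * t
    n_jumps = -1
    for n in range(max_jumps + 1):
        term = np.exp(log_poisson) * rpow(n)[a, b]
        acc += term
        if acc >= u:
            n_jumps = n
            break
        log_poisson += np.log(mu * t) - np.log(n + 1)
    if n_jumps < 0:
        return _reject_path(a, b, t, Q, rng)

    if n_jumps == 0:
        return []
    times = np.sort(rng.random(n_jumps)) * t
    events = []
    s = a
    for i in range(n_jumps):
        remaining = n_jumps - i - 1
        w = R[s] * rpow(remaining)[:, b]
        tot = w.sum()
        if tot <= 0:
            return _reject_path(a, b, t, Q, rng)
        nxt = rng.choice(len(w), p=w / tot)
        if nxt != s:
            events.append((float(times[i]), s, int(nxt)))
            s = int(nxt)
    return events


def _reject_path(
    a: int, b: int, t: float, Q: np.ndarray, rng: np.random.Generator,
    max_tries: int = 10000,
) -> list[tuple[float, int, int]]:
    k = Q.shape[0]
    for _ in range(max_tries):
        s = a
        clock = 0.0
        events = []
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            clock += rng.exponential(1.0 / rate)
            if clock >= t:
                break
            w = np.maximum(Q[s], 0.0)
            w[s] = 0.0
            nxt = int(rng.choice(k, p=w / w.sum()))
            events.append((clock, s, nxt))
            s = nxt
        if s == b:
            return events
    raise RuntimeError("rejection sampling failed to hit the required endpoint")


def stochastic_maps(
    tree: Phylogeny,
    tip_states: dict[str, str],
    model: MkModel,
    n_maps: int = 100,
    seed: int = 0,
) -> StochasticMapSummary:
    """Sample full character histories consistent with tips and model.

    Internal node states are drawn pre-order from their conditional
    distributions (via pruning partials); each edge history is then an
    endpoint-conditioned path.  Every state change is counted.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    k = len(model.states)
    part, P, logscale = _pruning(tree, tip_states, model)
    if not np.isfinite(logscale):
        raise ValueError("tip states impossible under the supplied model")
    root_w = _root_weights(part[tree.root], model) * part[tree.root]
    root_w = root_w / root_w.sum()
    mu = float(np.max(-np.diag(model.Q)))
    R = np.eye(k) + model.Q / mu if mu > 0 else np.eye(k)
    R_pows = [np.eye(k)]
    n_desc = tree.n_subtree_tips()
    tip_sets = {nd: tree.subtree_tips(nd) for nd in range(tree.n_nodes)}

    rng = np.random.default_rng(seed)
    preorder = tree.preorder()
    counts = np.zeros((n_maps, k, k))
    tip_events = np.zeros(tree.n_tips)
    for m in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=np.int64)
        node_state[tree.root] = rng.choice(k, p=root_w)
        for nd in preorder:
            if nd == tree.root:
                continue
            s = node_state[tree.parent[nd]]
            w = P[nd][s] * part[nd]
            node_state[nd] = rng.choice(k, p=w / w.sum())
            path = _sample_path(
                s, int(node_state[nd]), float(tree.edge_length[nd]),
                model.Q, P[nd], R, R_pows, mu, rng,
            )
            for _, x, yy in path:
                counts[m, x, yy] += 1
            if path:
                share = len(path) / n_desc[nd]
                for tip in tip_sets[nd]:
                    tip_events[tip] += share
    mean_counts = counts.mean(axis=0)
    np.fill_diagonal(mean_counts, 0.0)
    tip_rate = {
        tree.tip_labels[i]: float(tip_events[i] / n_maps) for i in range(tree.n_tips)
    }
    return StochasticMapSummary(
        states=tuple(model.states),
        n_maps=n_maps,
        mean_counts=mean_counts,
        per_map_counts=counts,
        tip_event_rate=tip_rate,
    )
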