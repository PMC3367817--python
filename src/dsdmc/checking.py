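"""Verification engine: deadlock/CTL checks, reachability probabilities,
time-bounded probabilities, expected rewards and absorption distributions.

Numerical queries are answered on the embedded jump chain with prob-0/prob-1
graph precomputation followed by Gauss-Seidel iteration; transient analysis
uses uniformization.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import poisson

from dsdmc.ctmc import CTMCModel

GS_TOL = 1e-10
GS_MAX_ITER = 1_000_000
UNIF_EPS = 1e-9
UNIF_RATE_SLACK = 1.02


class SolverError(RuntimeError):
    pass


@dataclass
class QueryResult:
    value: float | bool
    witness: list | None = None
    per_state: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Helpers


def _as_mask(m: CTMCModel, pred) -> np.ndarray:
    if isinstance(pred, str):
        mask = np.asarray(m.eval_label(pred), dtype=bool)
    elif callable(pred):
        mask = np.fromiter((bool(pred(s)) for s in m.states), dtype=bool, count=m.n_states)
    else:
        mask = np.asarray(pred, dtype=bool)
    if mask.shape != (m.n_states,):
        raise ValueError("predicate mask has wrong shape")
    return mask


def _backward_reachable(P: sparse.csr_matrix, seeds: np.ndarray) -> np.ndarray:
    """States with a path (possibly empty) into ``seeds``."""
    Pt = P.T.tocsr()
    reached = seeds.copy()
    frontier = list(np.nonzero(seeds)[0])
    while frontier:
        nxt = []
        for j in frontier:
            start, end = Pt.indptr[j], Pt.indptr[j + 1]
            for i in Pt.indices[start:end]:
                if not reached[i]:
                    reached[i] = True
                    nxt.append(i)
        frontier = nxt
    return reached


def _gauss_seidel(A: sparse.csr_matrix, b: np.ndarray, tol: float = GS_TOL) -> np.ndarray:
    """Solve ``A x = b`` by Gauss-Seidel (A = D + L + U)."""
    from scipy.sparse.linalg import spsolve_triangular

    n = A.shape[0]
    if n == 0:
        return np.zeros(0)
    lower = sparse.tril(A, k=0).tocsr()
    upper = sparse.triu(A, k=1).tocsr()
    x = np.zeros(n)
    for it in range(GS_MAX_ITER):
        x_new = spsolve_triangular(lower, b - upper @ x, lower=True)
        denom = np.maximum(np.abs(x_new), 1e-300)
        diff = np.max(np.abs(x_new - x) / denom)
        x = x_new
        if diff < tol:
            return x
    raise SolverError(f"Gauss-Seidel did not converge within {GS_MAX_ITER} iterations")


def _shortest_path(m: CTMCModel, source: int, target_mask: np.ndarray) -> list[int] | None:
    R = m.rate_matrix
    prev = np.full(m.n_states, -1, dtype=np.int64)
    seen = np.zeros(m.n_states, dtype=bool)
    seen[source] = True
    queue = deque([source])
    goal = -1
    if target_mask[source]:
        goal = source
    while queue and goal < 0:
        i = queue.popleft()
        for j in R.indices[R.indptr[i] : R.indptr[i + 1]]:
            if not seen[j]:
                seen[j] = True
                prev[j] = i
                if target_mask[j]:
                    goal = j
                    break
                queue.append(j)
    if goal < 0:
        return None
    path = [goal]
    while path[-1] != source:
        path.append(int(prev[path[-1]]))
    return list(reversed(path))


def _describe_path(m: CTMCModel, path: list[int]) -> list:
    """Alternating states and the reactions explaining each transition."""
    out: list = []
    net = m.network
    idx = {sp: i for i, sp in enumerate(m.var_species)}
    from collections import Counter

    deltas = []
    for r in net.reactions:
        d: dict[int, int] = {}
        for sp, k in Counter(r.reactants).items():
            if sp in idx:
                d[idx[sp]] = d.get(idx[sp], 0) - k
        for sp, k in Counter(r.products).items():
            if sp in idx:
                d[idx[sp]] = d.get(idx[sp], 0) + k
        deltas.append({k: v for k, v in d.items() if v})
    for a, b in zip(path, path[1:]):
        out.append(m.states[a])
        diff = {
            i: m.states[b][i] - m.states[a][i]
            for i in range(len(m.var_species))
            if m.states[b][i] != m.states[a][i]
        }
        label = next((str(net.reactions[k]) for k, d in enumerate(deltas) if d == diff), "?")
        out.append(label)
    out.append(m.states[path[-1]])
    return out


# ---------------------------------------------------------------------------
# Qualitative queries


def find_deadlocks(m: CTMCModel) -> set[int]:
    """Exactly the states with exit rate zero."""
    return set(int(i) for i in np.nonzero(m.deadlocks())[0])


def check_deadlock_invariant(m: CTMCModel, pred) -> QueryResult:
    """CTL ``A [ G (deadlock => pred) ]`` with a counterexample path."""
    mask = _as_mask(m, pred)
    dead = m.deadlocks()
    bad = dead & ~mask
    if not bad.any():
        return QueryResult(True)
    path = _shortest_path(m, m.initial, bad)
    assert path is not None
    return QueryResult(False, witness=_describe_path(m, path))


def check_reachable(m: CTMCModel, pred) -> QueryResult:
    """CTL ``E [ F pred ]``."""
    mask = _as_mask(m, pred)
    path = _shortest_path(m, m.initial, mask)
    if path is None:
        return QueryResult(False)
    return QueryResult(True, witness=_describe_path(m, path))


# ---------------------------------------------------------------------------
# Quantitative queries


def _reach_probabilities(m: CTMCModel, mask: np.ndarray) -> np.ndarray:
    """P(eventually reach ``mask``) for every state."""
    n = m.n_states
    P = m.embedded_jump_matrix().tocsr()
    can_reach = _backward_reachable(P, mask)
    prob0 = ~can_reach
    # P(reach)=1 iff no path into a prob-0 state
    prob1 = ~_backward_reachable(P, prob0) | mask
    x = np.zeros(n)
    x[prob1] = 1.0
    maybe = ~(prob0 | prob1)
    if maybe.any():
        ids = np.nonzero(maybe)[0]
        sub = P[ids][:, ids]
        b = np.asarray(P[ids][:, prob1].sum(axis=1)).ravel()
        A = sparse.eye(len(ids), format="csr") - sub
        x[ids] = _gauss_seidel(A.tocsr(), b)
    return np.clip(x, 0.0, 1.0)


def prob_reach(m: CTMCModel, pred) -> QueryResult:
    mask = _as_mask(m, pred)
    x = _reach_probabilities(m, mask)
    return QueryResult(float(x[m.initial]), per_state=x)


def prob_reach_within(m: CTMCModel, pred, t: float, eps: float = UNIF_EPS) -> QueryResult:
    """Time-bounded reachability by uniformization, target made absorbing."""
    if t < 0:
        raise ValueError("time bound must be nonnegative")
    mask = _as_mask(m, pred)
    if t == 0 or not mask.any():
        return QueryResult(float(mask[m.initial]))
    n = m.n_states
    keep = ~mask
    R = m.rate_matrix.tolil(copy=True)
    R[np.nonzero(mask)[0], :] = 0.0
    R = R.tocsr()
    exit_rates = np.asarray(R.sum(axis=1)).ravel()
    q = UNIF_RATE_SLACK * max(float(exit_rates.max()), 1e-300)
    # uniformized DTMC: P = I + (R - diag(E)) / q
    P = (R / q + sparse.diags(1.0 - exit_rates / q)).tocsr()
    kmax = int(poisson.ppf(1.0 - eps, q * t)) + 1
    dist = np.zeros(n)
    dist[m.initial] = 1.0
    pmf = poisson.pmf(np.arange(kmax + 1), q * t)
    total = float(pmf[0] * dist[mask].sum())
    for k in range(1, kmax + 1):
        dist = dist @ P
        total += float(pmf[k] * dist[mask].sum())
    return QueryResult(min(max(total, 0.0), 1.0), diagnostics={"uniformization_rate": q, "kmax": kmax})


def expected_time_to(m: CTMCModel, pred) -> QueryResult:
    """Expected accumulated time until first hitting the target; infinite
    (reported as an error) unless the target is reached almost surely."""
    mask = _as_mask(m, pred)
    x = _reach_probabilities(m, mask)
    if x[m.initial] < 1.0 - 1e-6:
        raise SolverError(
            f"target reached with probability {x[m.initial]:.6g} < 1; expected time is infinite"
        )
    P = m.embedded_jump_matrix().tocsr()
    n = m.n_states
    trans = ~mask
    ids = np.nonzero(trans)[0]
    if len(ids) == 0:
        return QueryResult(0.0)
    if (m.exit_rates[ids] == 0).any():
        raise SolverError("a deadlock outside the target is reachable; expected time is infinite")
    sub = P[ids][:, ids]
    b = 1.0 / m.exit_rates[ids]
    A = sparse.eye(len(ids), format="csr") - sub
    h = _gauss_seidel(A.tocsr(), b)
    full = np.zeros(n)
    full[ids] = h
    return QueryResult(float(full[m.initial]), per_state=full)


def absorption_distribution(
    m: CTMCModel, f: Callable[[tuple], float] | None = None
) -> QueryResult:
    """Absorption probability of every deadlock state (which must be the only
    bottom SCCs) plus the expectation of ``f`` over the final state."""
    P = m.embedded_jump_matrix().tocsr()
    n = m.n_states
    dead = m.deadlocks()
    n_comp, labels = connected_components(P, directed=True, connection="strong")
    # a bottom SCC has no edge leaving it
    coo = P.tocoo()
    leaves = np.zeros(n_comp, dtype=bool)
    for i, j in zip(coo.row, coo.col):
        if labels[i] != labels[j]:
            leaves[labels[i]] = True
    sizes = np.bincount(labels, minlength=n_comp)
    for c in range(n_comp):
        if not leaves[c]:
            members = np.nonzero(labels == c)[0]
            if sizes[c] > 1 or not dead[members[0]]:
                raise SolverError(
                    "model has a recurrent class that is not a single deadlock state"
                )
    trans_ids = np.nonzero(~dead)[0]
    dead_ids = np.nonzero(dead)[0]
    occupancy = np.zeros(len(trans_ids))
    pos = {int(i): k for k, i in enumerate(trans_ids)}
    if m.initial in pos:
        sub = P[trans_ids][:, trans_ids]
        delta = np.zeros(len(trans_ids))
        delta[pos[m.initial]] = 1.0
        A = (sparse.eye(len(trans_ids), format="csr") - sub.T).tocsr()
        occupancy = _gauss_seidel(A, delta)
        absorb = occupancy @ P[trans_ids][:, dead_ids]
    else:
        absorb = np.zeros(len(dead_ids))
        absorb[list(dead_ids).index(m.initial)] = 1.0
    absorb = np.asarray(absorb).ravel()
    dist = {int(d): float(p) for d, p in zip(dead_ids, absorb)}
    total = sum(dist.values())
    diagnostics = {"probability_mass": total}
    value = None
    if f is not None:
        value = float(sum(p * f(m.states[d]) for d, p in dist.items()))
    return QueryResult(
        value if value is not None else total,
        per_state=None,
        diagnostics={**diagnostics, "distribution": dist},
    )
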