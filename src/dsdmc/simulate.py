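"""Gillespie stochastic simulation, used as an independent oracle for the
numeric engine and for trajectory illustrations."""

from __future__ import annotations

import csv
import io
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from dsdmc.dsd_core import Species, SystemSpec
from dsdmc.network import ReactionNetwork


@dataclass
class Trajectory:
    seed: int
    var_species: list[Species]
    events: list[tuple[float, int, tuple[int, ...]]]  # (time, reaction id, new state)
    initial: tuple[int, ...]
    final: tuple[int, ...]
    capped: bool = False

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["time", "reaction"] + [str(sp) for sp in self.var_species])
        w.writerow([0.0, ""] + list(self.initial))
        for t, rid, state in self.events:
            w.writerow([t, rid] + list(state))
        return buf.getvalue()


def _compile(net: ReactionNetwork, spec: SystemSpec):
    constant = spec.constant_species
    var_species = [sp for sp in net.species if sp not in constant]
    vidx = {sp: i for i, sp in enumerate(var_species)}
    compiled = []
    for r in net.reactions:
        lhs = Counter(r.reactants)
        rhs = Counter(r.products)
        factor = r.rate_constant
        prop = []
        for sp, mult in lhs.items():
            if sp in constant:
                c = spec.species_counts.get(sp, 0)
                factor *= c * (c - 1) / 2 if mult == 2 else c
            else:
                prop.append((vidx[sp], mult))
        delta: dict[int, int] = {}
        for sp, mult in lhs.items():
            if sp not in constant:
                delta[vidx[sp]] = delta.get(vidx[sp], 0) - mult
        for sp, mult in rhs.items():
            if sp not in constant:
                delta[vidx[sp]] = delta.get(vidx[sp], 0) + mult
        compiled.append((factor, prop, sorted(delta.items())))
    return var_species, compiled


def ssa_run(
    net: ReactionNetwork,
    spec: SystemSpec | None = None,
    seed: int = 0,
    t_max: float = math.inf,
    max_events: int = 10_000_000,
    record: bool = True,
) -> Trajectory:
    """Exact stochastic simulation over the same propensity definitions as
    the CTMC construction; reproducible per seed."""
    spec = spec or net.initial
    rng = np.random.default_rng(seed)
    var_species, compiled = _compile(net, spec)
    state = [spec.species_counts.get(sp, 0) for sp in var_species]
    t = 0.0
    events: list[tuple[float, int, tuple[int, ...]]] = []
    initial = tuple(state)
    capped = False
    for _ in range(max_events):
        props = []
        for factor, prop, _delta in compiled:
            rate = factor
            for i, mult in prop:
                ni = state[i]
                rate *= ni * (ni - 1) / 2 if mult == 2 else ni
                if rate == 0.0:
                    break
            props.append(rate)
        total = sum(props)
        if total == 0.0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > t_max:
            t = t_max
            break
        t += dt
        u = rng.random() * total
        acc = 0.0
        rid = len(props) - 1
        for k, p in enumerate(props):
            acc += p
            if u <= acc:
                rid = k
                break
        for i, d in compiled[rid][2]:
            state[i] += d
        if record:
            events.append((t, rid, tuple(state)))
    else:
        capped = True
    return Trajectory(seed, var_species, events, initial, tuple(state), capped)


@dataclass
class ReachEstimate:
    estimate: float
    stderr: float
    n_runs: int
    n_capped: int = 0

    def interval(self, z: float = 3.0) -> tuple[float, float]:
        return (self.estimate - z * self.stderr, self.estimate + z * self.stderr)


def estimate_reach_probability(
    net: ReactionNetwork,
    spec: SystemSpec | None = None,
    pred: Callable[[Sequence[int]], bool] | None = None,
    n_runs: int = 1000,
    seed: int = 0,
    t_max: float = math.inf,
    max_events: int = 1_000_000,
) -> ReachEstimate:
    """Fraction of runs that hit ``pred`` (evaluated on every visited state),
    with binomial standard error."""
    if pred is None:
        raise ValueError("predicate required")
    spec = spec or net.initial
    rng = np.random.default_rng(seed)
    var_species, compiled = _compile(net, spec)
    init = [spec.species_counts.get(sp, 0) for sp in var_species]
    hits = 0
    capped = 0
    for _ in range(n_runs):
        state = list(init)
        t = 0.0
        hit = bool(pred(state))
        ended = False
        for _ in range(max_events):
            if hit:
                ended = True
                break
            props = []
            for factor, prop, _delta in compiled:
                rate = factor
                for i, mult in prop:
                    ni = state[i]
                    rate *= ni * (ni - 1) / 2 if mult == 2 else ni
                    if rate == 0.0:
                        break
                props.append(rate)
            total = sum(props)
            if total == 0.0:
                ended = True
                break
            dt = rng.exponential(1.0 / total)
            if t + dt > t_max:
                ended = True
                break
            t += dt
            u = rng.random() * total
            acc = 0.0
            rid = len(props) - 1
            for k, p in enumerate(props):
                acc += p
                if u <= acc:
                    rid = k
                    break
            for i, d in compiled[rid][2]:
                state[i] += d
            hit = hit or bool(pred(state))
        if not ended:
            capped += 1
        if hit:
            hits += 1
    p = hits / n_runs
    se = math.sqrt(p * (1.0 - p) / n_runs)
    return ReachEstimate(p, se, n_runs, capped)


def first_passage_times(
    net: ReactionNetwork,
    spec: SystemSpec | None = None,
    pred: Callable[[Sequence[int]], bool] | None = None,
    n_runs: int = 1000,
    seed: int = 0,
    max_events: int = 1_000_000,
) -> np.ndarray:
    """First hitting times of ``pred`` over an ensemble (NaN if never hit)."""
    if pred is None:
        raise ValueError("predicate required")
    spec = spec or net.initial
    rng = np.random.default_rng(seed)
    var_species, compiled = _compile(net, spec)
    init = [spec.species_counts.get(sp, 0) for sp in var_species]
    out = np.full(n_runs, np.nan)
    for run in range(n_runs):
        state = list(init)
        t = 0.0
        if pred(state):
            out[run] = 0.0
            continue
        for _ in range(max_events):
            props = []
            for factor, prop, _delta in compiled:
                rate = factor
                for i, mult in prop:
                    ni = state[i]
                    rate *= ni * (ni - 1) / 2 if mult == 2 else ni
                    if rate == 0.0:
                        break
                props.append(rate)
            total = sum(props)
            if total == 0.0:
                break
            t += rng.exponential(1.0 / total)
            u = rng.random() * total
            acc = 0.0
            rid = len(props) - 1
            for k, p in enumerate(props):
                acc += p
                if u <= acc:
                    rid = k
                    break
            for i, d in compiled[rid][2]:
                state[i] += d
            if pred(state):
                out[run] = t
                break
    return out
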