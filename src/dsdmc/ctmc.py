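"""Population-level CTMC construction with labels and reward structures.

States are population vectors over the non-constant species of a closed
reaction network.  A reaction with stochastic rate constant ``k`` fires with
propensity ``k * nA * nB`` for distinct reactants, ``k * nA * (nA-1) / 2``
for identical reactants and ``k * nA`` for a single reactant; species
declared ``constant`` contribute their fixed population to propensities but
are never incremented or decremented.  Parallel reactions between the same
pair of states sum their rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import sparse

from dsdmc.dsd_core import Species, SystemSpec, parse_species
from dsdmc.network import ReactionNetwork, classify_reactive


class StateCapExceeded(RuntimeError):
    pass


DEFAULT_STATE_CAP = 5_000_000

State = tuple[int, ...]


@dataclass
class CTMCModel:
    var_species: list[Species]  # species tracked in the state vector
    states: list[State]
    initial: int
    rate_matrix: sparse.csr_matrix  # R, zero diagonal
    exit_rates: np.ndarray  # E(s) = row sums of R
    network: ReactionNetwork
    labels: "LabelSet | None" = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        return self.rate_matrix.nnz

    def state_index(self) -> dict[State, int]:
        return {s: i for i, s in enumerate(self.states)}

    def deadlocks(self) -> np.ndarray:
        """Boolean mask of states with no outgoing transitions."""
        return self.exit_rates == 0.0

    def embedded_jump_matrix(self) -> sparse.csr_matrix:
        """P(s, s') = R(s, s') / E(s) on non-deadlock rows; deadlock rows 0."""
        inv = np.zeros_like(self.exit_rates)
        nz = self.exit_rates > 0
        inv[nz] = 1.0 / self.exit_rates[nz]
        return sparse.diags(inv) @ self.rate_matrix

    def eval_label(self, name: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("model has no labels attached")
        return self.labels.eval(name, self)

    # -- explicit-state export (PRISM explicit engine layout) ---------------

    def export_states(self) -> str:
        names = ",".join(f"s{i}" for i in range(len(self.var_species)))
        lines = [f"({names})"]
        for i, s in enumerate(self.states):
            lines.append(f"{i}:({','.join(map(str, s))})")
        return "\n".join(lines) + "\n"

    def export_transitions(self) -> str:
        coo = self.rate_matrix.tocoo()
        lines = [f"{self.n_states} {coo.nnz}"]
        order = np.lexsort((coo.col, coo.row))
        for k in order:
            lines.append(f"{coo.row[k]} {coo.col[k]} {coo.data[k]:.12g}")
        return "\n".join(lines) + "\n"

    def export_labels(self, names: Sequence[str] = ("init", "deadlock")) -> str:
        decls = " ".join(f'{i}="{n}"' for i, n in enumerate(names))
        per_state: dict[int, list[int]] = {}
        for li, name in enumerate(names):
            if name == "init":
                mask = np.zeros(self.n_states, dtype=bool)
                mask[self.initial] = True
            elif name == "deadlock":
                mask = self.deadlocks()
            else:
                mask = np.asarray(self.eval_label(name), dtype=bool)
            for i in np.nonzero(mask)[0]:
                per_state.setdefault(int(i), []).append(li)
        lines = [decls]
        for i in sorted(per_state):
            lines.append(f"{i}: " + " ".join(map(str, per_state[i])))
        return "\n".join(lines) + "\n"

    def export_guarded_commands(self) -> str:
        """Best-effort rendering of the network as guarded commands."""
        net = self.network
        idx = {sp: i for i, sp in enumerate(self.var_species)}
        counts = net.initial.species_counts
        lines = ["ctmc", "", "module network"]
        maxpop = sum(counts.values()) + 1
        for sp, i in idx.items():
            lines.append(
                f"  s{i} : [0..{maxpop}] init {counts.get(sp, 0)}; // {sp}"
            )
        for r in net.reactions:
            guard = []
            rate_terms = [f"{r.rate_constant:g}"]
            update = {}
            from collections import Counter

            lhs = Counter(r.reactants)
            rhs = Counter(r.products)
            for sp, n in lhs.items():
                if sp in net.initial.constant_species:
                    rate_terms.append(str(counts.get(sp, 0)))
                    continue
                i = idx[sp]
                guard.append(f"s{i} >= {n}")
                rate_terms.append(f"s{i}" if n == 1 else f"s{i}*(s{i}-1)/2")
                update[i] = update.get(i, 0) - n
            for sp, n in rhs.items():
                if sp in net.initial.constant_species:
                    continue
                i = idx[sp]
                update[i] = update.get(i, 0) + n
            ups = [
                f"(s{i}' = s{i}{'+' if d > 0 else ''}{d})"
                for i, d in sorted(update.items())
                if d != 0
            ] or ["true"]
            lines.append(
                f"  [] {' & '.join(guard) or 'true'} -> {'*'.join(rate_terms)} : "
                + " & ".join(ups) + ";"
            )
        lines += ["endmodule", ""]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Rewards


@dataclass(frozen=True)
class RewardStructure:
    state_reward: Callable[[State], float]
    transition_reward: Callable[[State, State], float]


def time_reward() -> RewardStructure:
    """Reward 1 per unit time in every state: accumulates elapsed time."""
    return RewardStructure(lambda s: 1.0, lambda s, t: 0.0)


# ---------------------------------------------------------------------------
# Labels


@dataclass
class LabelConfig:
    """Per-case-study label recipe.

    ``output``/``output_x``/``output_y`` list species (text form) whose
    populations are summed; ``copies`` is the N parameter of the design.
    ``all_done`` is a vectorized expression over label names evaluated per
    state (default: the success criterion used by the transducer-style
    designs)."""

    copies: int = 1
    output: tuple[str, ...] = ()
    output_x: tuple[str, ...] = ()
    output_y: tuple[str, ...] = ()
    all_done: str = "(output == N) & (gates_reactive == 0) & (strands_reactive == output)"


class LabelSet:
    def __init__(
        self,
        weights: dict[str, np.ndarray],
        offsets: dict[str, int],
        copies: int,
        all_done_expr: str,
    ):
        self.weights = weights
        self.offsets = offsets
        self.copies = copies
        self.all_done_expr = all_done_expr

    def names(self) -> list[str]:
        return sorted(self.weights) + ["all_done", "deadlock"]

    def eval(self, name: str, model: CTMCModel) -> np.ndarray:
        mat = np.asarray(model.states, dtype=np.int64)
        if name in self.weights:
            return mat @ self.weights[name] + self.offsets[name]
        if name == "deadlock":
            return model.deadlocks()
        if name == "all_done":
            env = {
                key: self.eval(key, model) for key in self.weights
            }
            env["N"] = self.copies
            env["np"] = np
            return np.asarray(eval(self.all_done_expr, {"__builtins__": {}}, env), dtype=bool)
        raise KeyError(f"unknown label {name!r}")

    def eval_state(self, name: str, model: CTMCModel, i: int) -> int | bool:
        return self.eval(name, model)[i]


def make_labels(
    net: ReactionNetwork, spec: SystemSpec, config: LabelConfig, var_species: list[Species]
) -> LabelSet:
    """Build the state-evaluable counting formulae.

    ``strands_reactive``/``gates_reactive`` sum the populations of species
    classified reactive (after overrides), split by shape.  The ``output*``
    labels sum designated signal species."""
    reactive = classify_reactive(net)
    idx = {sp: i for i, sp in enumerate(var_species)}
    n = len(var_species)

    def weights_for(pred) -> tuple[np.ndarray, int]:
        w = np.zeros(n, dtype=np.int64)
        off = 0
        for sp, flag in pred:
            if not flag:
                continue
            if sp in idx:
                w[idx[sp]] += 1
            else:
                off += spec.species_counts.get(sp, 0)  # constant species
        return w, off

    weights: dict[str, np.ndarray] = {}
    offsets: dict[str, int] = {}
    weights["strands_reactive"], offsets["strands_reactive"] = weights_for(
        (sp, reactive[sp] and sp.is_strand) for sp in net.species
    )
    weights["gates_reactive"], offsets["gates_reactive"] = weights_for(
        (sp, reactive[sp] and sp.is_gate) for sp in net.species
    )
    for label_name, texts in (
        ("output", config.output),
        ("output_x", config.output_x),
        ("output_y", config.output_y),
    ):
        targets = {parse_species(t) for t in texts}
        missing = {t for t in targets if t not in set(net.species)}
        if missing:
            raise ValueError(f"designated species not in network: {[str(m) for m in missing]}")
        weights[label_name], offsets[label_name] = weights_for(
            (sp, sp in targets) for sp in net.species
        )
    return LabelSet(weights, offsets, config.copies, config.all_done)


# ---------------------------------------------------------------------------
# State-space construction


def build_ctmc(
    net: ReactionNetwork,
    spec: SystemSpec | None = None,
    state_cap: int = DEFAULT_STATE_CAP,
    label_config: LabelConfig | None = None,
) -> CTMCModel:
    spec = spec or net.initial
    constant = spec.constant_species
    var_species = [sp for sp in net.species if sp not in constant]
    vidx = {sp: i for i, sp in enumerate(var_species)}
    nv = len(var_species)

    # compile reactions: (rate_factor, propensity spec, delta)
    compiled = []
    for r in net.reactions:
        from collections import Counter

        lhs = Counter(r.reactants)
        rhs = Counter(r.products)
        factor = r.rate_constant
        prop: list[tuple[int, int]] = []  # (species idx, multiplicity)
        ok = True
        for sp, m in lhs.items():
            if sp in constant:
                c = spec.species_counts.get(sp, 0)
                if m == 2:
                    factor *= c * (c - 1) / 2
                else:
                    factor *= c
                if factor == 0:
                    ok = False
            else:
                prop.append((vidx[sp], m))
        if not ok:
            continue
        delta: dict[int, int] = {}
        for sp, m in lhs.items():
            if sp not in constant:
                delta[vidx[sp]] = delta.get(vidx[sp], 0) - m
        for sp, m in rhs.items():
            if sp not in constant:
                delta[vidx[sp]] = delta.get(vidx[sp], 0) + m
        compiled.append((factor, tuple(prop), tuple(sorted(delta.items()))))

    init_state = tuple(spec.species_counts.get(sp, 0) for sp in var_species)
    index: dict[State, int] = {init_state: 0}
    states: list[State] = [init_state]
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    head = 0
    while head < len(states):
        s = states[head]
        acc: dict[int, float] = {}
        for factor, prop, delta in compiled:
            rate = factor
            for i, m in prop:
                ni = s[i]
                if m == 2:
                    rate *= ni * (ni - 1) / 2
                else:
                    rate *= ni
                if rate == 0.0:
                    break
            if rate == 0.0:
                continue
            t = list(s)
            valid = True
            for i, d in delta:
                t[i] += d
                if t[i] < 0:
                    valid = False
                    break
            if not valid:
                continue
            tt = tuple(t)
            j = index.get(tt)
            if j is None:
                j = len(states)
                if j >= state_cap:
                    raise StateCapExceeded(f"state space exceeded {state_cap} states")
                index[tt] = j
                states.append(tt)
            if j != head:
                acc[j] = acc.get(j, 0.0) + rate
        for j, rate in acc.items():
            rows.append(head)
            cols.append(j)
            vals.append(rate)
        head += 1

    n = len(states)
    R = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n, n), dtype=np.float64
    )
    exit_rates = np.asarray(R.sum(axis=1)).ravel()
    model = CTMCModel(
        var_species=var_species,
        states=states,
        initial=0,
        rate_matrix=R,
        exit_rates=exit_rates,
        network=net,
    )
    if label_config is not None:
        model.labels = make_labels(net, spec, label_config, var_species)
    return model
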