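"""Elementary reduction rules and the merged reaction semantics.

The elementary rules:

* ``RB`` -- a free strand binds a complementary exposed toehold (the only
  bimolecular and the only rate-limiting rule);
* ``RU`` -- a strand held by a single toehold duplex spontaneously unbinds;
* ``RC`` -- complementary exposed toeholds on opposite layers of one
  complex hybridize;
* ``RM`` -- maximal branch migration that displaces nothing;
* ``RD`` -- branch migration that completes a strand displacement.

Under the merged semantics a binding (RB) is followed by an instantaneous
closure under all non-RB rules, with RM folded into structural equivalence;
each distinct terminal configuration in which only further bindings are
possible yields one reaction at the bind rate of the initiating toehold.
Bindings whose only terminal is the reactants themselves are unproductive
and yield no reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from dsdmc.dsd_core import (
    Domain,
    Gate,
    Species,
    canonicalize,
    lower_piece_to_strand,
    migration_class,
    migration_moves,
    strand_species,
)


# ---------------------------------------------------------------------------
# Rates


DEFAULT_BIND = 3.0e-4  # /nM/s scale toehold association (measured regime)
DEFAULT_UNBIND = 0.1126  # /s toehold dissociation
DEFAULT_MIGRATE = 8000.0  # /s branch migration over one domain


@dataclass(frozen=True)
class RateModel:
    """Kinetic parameters.  Under the merged semantics only ``bind``
    parametrizes reaction rates; ``unbind``/``migrate`` only label
    elementary steps."""

    bind: float = DEFAULT_BIND
    unbind: float = DEFAULT_UNBIND
    migrate: float = DEFAULT_MIGRATE
    bind_overrides: tuple[tuple[str, float], ...] = ()
    unbind_overrides: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        rates = [self.bind, self.unbind, self.migrate]
        rates += [v for _, v in self.bind_overrides + self.unbind_overrides]
        if any(r <= 0 for r in rates):
            raise ValueError("all rates must be positive")

    def bind_rate(self, toehold: str) -> float:
        return dict(self.bind_overrides).get(toehold, self.bind)

    def unbind_rate(self, toehold: str) -> float:
        return dict(self.unbind_overrides).get(toehold, self.unbind)

    def scaled(self, c: float) -> "RateModel":
        return RateModel(
            self.bind * c,
            self.unbind,
            self.migrate,
            tuple((k, v * c) for k, v in self.bind_overrides),
            self.unbind_overrides,
        )


# ---------------------------------------------------------------------------
# Configurations

Config = tuple[Species, ...]


def make_config(species: Iterable[Species]) -> Config:
    return tuple(sorted(species))


def _gate_components_to_species(
    uppers: Sequence[tuple[Domain, ...]],
    lowers: Sequence[tuple[Domain, ...]],
    pairs,
) -> list[Species]:
    """Split a possibly disconnected pairing into canonical species."""
    # adjacency over pieces via pairs
    nodes = [("u", i) for i in range(len(uppers))] + [("l", i) for i in range(len(lowers))]
    adj = {n: set() for n in nodes}
    for (ui, _), (li, _) in pairs:
        adj[("u", ui)].add(("l", li))
        adj[("l", li)].add(("u", ui))
    seen = set()
    out = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            n = stack.pop()
            for m in adj[n]:
                if m not in comp:
                    comp.add(m)
                    stack.append(m)
        seen |= comp
        u_ids = sorted(i for t, i in comp if t == "u")
        l_ids = sorted(i for t, i in comp if t == "l")
        comp_pairs = [p for p in pairs if p[0][0] in u_ids]
        if not comp_pairs:
            if u_ids:
                out.append(strand_species(uppers[u_ids[0]]))
            else:
                out.append(lower_piece_to_strand(lowers[l_ids[0]]))
            continue
        umap = {i: k for k, i in enumerate(u_ids)}
        lmap = {i: k for k, i in enumerate(l_ids)}
        g = Gate(
            tuple(uppers[i] for i in u_ids),
            tuple(lowers[i] for i in l_ids),
            tuple(((umap[ui], uo), (lmap[li], lo)) for (ui, uo), (li, lo) in comp_pairs),
        )
        out.append(canonicalize(g))
    return out


def _remove_pair(gate: Gate, pair) -> list[Species]:
    pairs = tuple(p for p in gate.pairs if p != pair)
    return _gate_components_to_species(gate.uppers, gate.lowers, pairs)


def _move_pair(gate: Gate, old, new) -> list[Species]:
    pairs = tuple(p for p in gate.pairs if p != old) + (new,)
    return _gate_components_to_species(gate.uppers, gate.lowers, pairs)


# ---------------------------------------------------------------------------
# Elementary steps


@dataclass(frozen=True)
class ElementaryStep:
    rule: str  # RB | RU | RC | RM | RD
    before: Config
    after: Config
    rate: float
    toehold: str | None = None  # for RB/RU/RC

    def __str__(self) -> str:
        b = " | ".join(str(s) for s in self.before)
        a = " | ".join(str(s) for s in self.after)
        return f"({self.rule}) {b} -> {a}"


def _ru_steps(gate: Gate) -> list[tuple[str, list[Species]]]:
    """Detach any piece held by exactly one toehold pair."""
    out = []
    from collections import Counter

    upper_counts = Counter(u[0] for u, _ in gate.pairs)
    lower_counts = Counter(l[0] for _, l in gate.pairs)
    for pair in gate.pairs:
        (ui, uo), (li, lo) = pair
        d = gate.uppers[ui][uo]
        if not d.toehold:
            continue
        if upper_counts[ui] == 1:
            out.append((d.name, _remove_pair(gate, pair)))
        if lower_counts[li] == 1:
            out.append((d.name, _remove_pair(gate, pair)))
    return out


def _rc_steps(gate: Gate) -> list[tuple[str, list[Species]]]:
    """Hybridize complementary exposed toeholds within one complex.

    The new pair must be planar-compatible with the existing pairing,
    i.e. both positions lie in the same junction gap."""
    out = []
    for up in gate.unpaired_upper_positions():
        du = gate.upper_domain(up)
        if not du.toehold:
            continue
        for lp in gate.unpaired_lower_positions():
            if gate.lower_domain(lp) != du.comp:
                continue
            ok = all((u < up) == (l < lp) for u, l in gate.pairs)
            if not ok:
                continue
            pairs = gate.pairs + ((up, lp),)
            out.append((du.name, _gate_components_to_species(gate.uppers, gate.lowers, pairs)))
    return out


def _rd_steps(gate: Gate) -> list[list[Species]]:
    """Migration steps that strip a piece bare: completed displacements."""
    out = []
    before_keys = {gate.key()}
    attached = {g.key() for g in migration_moves(gate, keep_attached=True)}
    for g in migration_moves(gate, keep_attached=False):
        if g.key() in attached or g.key() in before_keys:
            continue
        # the move left some piece with no pairs: split off released strands
        out.append(_gate_components_to_species(g.uppers, g.lowers, g.pairs))
    return out


def fast_successors(sp: Species) -> list[Config]:
    """All single-step outcomes of the instantaneous rules (RU, RC, RD)
    applicable anywhere in the structural-equivalence class of ``sp``."""
    if sp.is_strand:
        return []
    outs: dict[Config, None] = {}
    for member in migration_class(sp.gate):
        for _, res in _ru_steps(member):
            outs.setdefault(make_config(res), None)
        for _, res in _rc_steps(member):
            outs.setdefault(make_config(res), None)
        for res in _rd_steps(member):
            outs.setdefault(make_config(res), None)
    return list(outs)


def at_rest(sp: Species) -> bool:
    """A species is at rest when only further bindings are possible."""
    return not fast_successors(sp)


# ---------------------------------------------------------------------------
# Binding enumeration


def _insert_upper_piece(
    gate: Gate, seq: tuple[Domain, ...], offset: int, lpos: tuple[int, int]
) -> Gate | None:
    """Insert ``seq`` as a new upper piece pairing position ``offset`` with
    unpaired lower position ``lpos``; returns None if not planar."""
    # determine insertion index among upper pieces
    lows_by_piece: list[list[tuple[int, int]]] = [[] for _ in gate.uppers]
    for (ui, _), l in gate.pairs:
        lows_by_piece[ui].append(l)
    idx = 0
    for i, lows in enumerate(lows_by_piece):
        if not lows:
            continue
        if max(lows) < lpos:
            idx = i + 1
        elif min(lows) < lpos < max(lows):
            return None  # site is enclosed by another piece: not planar
    new_uppers = gate.uppers[:idx] + (seq,) + gate.uppers[idx:]

    def shift(pos):
        return (pos[0] + 1, pos[1]) if pos[0] >= idx else pos

    new_pairs = tuple((shift(u), l) for u, l in gate.pairs) + (((idx, offset), lpos),)
    return Gate(new_uppers, gate.lowers, new_pairs)


@dataclass(frozen=True)
class BindingSite:
    toehold: str
    bound: Species  # resulting complex (canonical)


def rb_bindings(a: Species, b: Species) -> list[BindingSite]:
    """All distinct toehold-binding outcomes between two species.

    Gate-gate bindings are outside the supported fragment (they would form
    polymers) and yield nothing."""
    if a.is_gate and b.is_gate:
        return []
    if a.is_strand and b.is_strand:
        return _strand_strand_bindings(a, b)
    strand, gate_sp = (a, b) if a.is_strand else (b, a)
    out: dict[tuple, BindingSite] = {}
    for member in migration_class(gate_sp.gate):
        for rot in (member, member.rotate()):
            for lpos in rot.unpaired_lower_positions():
                dl = rot.lower_domain(lpos)
                if not dl.toehold:
                    continue
                for i, d in enumerate(strand.strand):
                    if d != dl.comp:
                        continue
                    g = _insert_upper_piece(rot, strand.strand, i, lpos)
                    if g is None:
                        continue
                    sp = canonicalize(g)
                    out.setdefault((d.name, sp.key()), BindingSite(d.name, sp))
    return list(out.values())


def _strand_strand_bindings(a: Species, b: Species) -> list[BindingSite]:
    out: dict[tuple, BindingSite] = {}
    for s1, s2 in ((a, b), (b, a)):
        page_lower = tuple(reversed(s2.strand))  # s2 drawn as the lower strand
        for i, du in enumerate(s1.strand):
            if not du.toehold:
                continue
            for j, dl in enumerate(page_lower):
                if dl != du.comp:
                    continue
                g = Gate((s1.strand,), (page_lower,), (((0, i), (0, j)),))
                sp = canonicalize(g)
                out.setdefault((du.name, sp.key()), BindingSite(du.name, sp))
    return list(out.values())


def elementary_steps(config: Iterable[Species], rates: RateModel | None = None) -> list[ElementaryStep]:
    """All elementary rule instances applicable to a configuration (a small
    multiset of species), including bimolecular bindings between members."""
    rates = rates or RateModel()
    config = make_config(config)
    steps: list[ElementaryStep] = []

    def rest(i, j=None):
        return [s for k, s in enumerate(config) if k != i and k != j]

    # bimolecular RB
    for i in range(len(config)):
        for j in range(i + 1, len(config)):
            for site in rb_bindings(config[i], config[j]):
                after = make_config(rest(i, j) + [site.bound])
                steps.append(
                    ElementaryStep("RB", config, after, rates.bind_rate(site.toehold), site.toehold)
                )
    # unimolecular rules, per structural-equivalence member
    for i, sp in enumerate(config):
        if sp.is_strand:
            continue
        seen: set[tuple] = set()
        for member in migration_class(sp.gate):
            for toe, res in _ru_steps(member):
                after = make_config(rest(i) + res)
                key = ("RU", after)
                if key not in seen:
                    seen.add(key)
                    steps.append(ElementaryStep("RU", config, after, rates.unbind_rate(toe), toe))
            for toe, res in _rc_steps(member):
                after = make_config(rest(i) + res)
                key = ("RC", after)
                if key not in seen:
                    seen.add(key)
                    steps.append(ElementaryStep("RC", config, after, rates.bind_rate(toe), toe))
            for res in _rd_steps(member):
                after = make_config(rest(i) + res)
                key = ("RD", after)
                if key not in seen:
                    seen.add(key)
                    steps.append(ElementaryStep("RD", config, after, rates.migrate))
        # RM: maximal migrations between distinct equivalence members exist
        # only as identity on canonical species; report none.
    return steps


# ---------------------------------------------------------------------------
# Merged reactions


class NonConfluenceError(RuntimeError):
    """A single binding reached two or more distinct terminal outcomes; the
    merged semantics does not define how to split its rate."""

    def __init__(self, reactants, terminals):
        self.reactants = reactants
        self.terminals = terminals
        msg = " | ".join(str(s) for s in reactants)
        tdesc = " ;; ".join(" | ".join(str(s) for s in t) for t in terminals)
        super().__init__(f"non-confluent fast closure from {msg}: {tdesc}")


@dataclass(frozen=True)
class Reaction:
    reactants: Config
    products: Config
    rate_constant: float
    toehold: str
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rate_constant <= 0:
            raise ValueError("rate constant must be positive")
        if self.reactants == self.products:
            raise ValueError("identity reactions are discarded")

    def __str__(self) -> str:
        lhs = " + ".join(str(s) for s in self.reactants)
        rhs = " + ".join(str(s) for s in self.products)
        return f"{self.rate_constant:g}: {lhs} -> {rhs}"


def _closure_terminals(start: Species) -> list[Config]:
    """Exhaustive closure of a freshly bound complex under the instantaneous
    rules; returns all terminal configurations (every member at rest)."""
    init = make_config([start])
    seen = {init}
    frontier = [init]
    terminals = []
    while frontier:
        cfg = frontier.pop()
        succs: list[Config] = []
        for i, sp in enumerate(cfg):
            others = cfg[:i] + cfg[i + 1 :]
            for res in fast_successors(sp):
                succs.append(make_config(others + res))
        if not succs:
            terminals.append(cfg)
            continue
        for nxt in succs:
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return terminals


def merged_reactions(
    species: Species | Sequence[Species],
    rates: RateModel | None = None,
) -> list[Reaction]:
    """Merged reactions of one species or an unordered pair of species."""
    rates = rates or RateModel()
    if isinstance(species, Species):
        return []  # every species at rest has no unimolecular behaviour
    pair = list(species)
    if len(pair) == 1:
        return []
    if len(pair) != 2:
        raise ValueError("merged_reactions takes one species or a pair")
    a, b = pair
    reactants = make_config([a, b])
    reactions = []
    for site in rb_bindings(a, b):
        terminals = [t for t in _closure_terminals(site.bound) if t != reactants]
        uniq: dict[Config, None] = {}
        for t in terminals:
            uniq.setdefault(t, None)
        if len(uniq) > 1:
            raise NonConfluenceError(reactants, list(uniq))
        if not uniq:
            continue  # unproductive binding
        (products,) = uniq
        reactions.append(
            Reaction(
                reactants,
                products,
                rates.bind_rate(site.toehold),
                site.toehold,
                provenance=("RB:" + site.toehold,),
            )
        )
    return reactions
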