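"""Species-closure reaction-network generation and reactivity classification."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from dsdmc.dsd_core import Species, SystemSpec, parse_species
from dsdmc.reduction import RateModel, Reaction, at_rest, merged_reactions


class SpeciesCapExceeded(RuntimeError):
    """The closure grew past ``species_cap`` -- the network is probably
    unbounded (polymerizing designs are outside the supported fragment)."""


DEFAULT_SPECIES_CAP = 10_000


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    initial: SystemSpec
    rates: RateModel
    overrides: dict[Species, bool] = field(default_factory=dict)

    def index(self) -> dict[Species, int]:
        return {sp: i for i, sp in enumerate(self.species)}

    @property
    def reactive(self) -> dict[Species, bool]:
        return classify_reactive(self)

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        lines = []
        for r in sorted(
            self.reactions,
            key=lambda r: (tuple(str(s) for s in r.reactants), tuple(str(s) for s in r.products)),
        ):
            lhs = " + ".join(str(s) for s in r.reactants)
            rhs = " + ".join(str(s) for s in r.products)
            lines.append(f"{r.rate_constant:g}: {lhs} -> {rhs}")
        return "\n".join(lines) + ("\n" if lines else "")

    def to_json(self) -> str:
        idx = self.index()
        reactive = self.reactive
        payload = {
            "species": [
                {
                    "id": i,
                    "text": str(sp),
                    "kind": sp.kind,
                    "initial_count": self.initial.species_counts.get(sp, 0),
                    "constant": sp in self.initial.constant_species,
                    "reactive": reactive[sp],
                }
                for i, sp in enumerate(self.species)
            ],
            "reactions": [
                {
                    "rate": r.rate_constant,
                    "toehold": r.toehold,
                    "reactants": [idx[s] for s in r.reactants],
                    "products": [idx[s] for s in r.products],
                }
                for r in self.reactions
            ],
        }
        return json.dumps(payload, indent=2)


def build_network(
    spec: SystemSpec,
    rates: RateModel | None = None,
    species_cap: int = DEFAULT_SPECIES_CAP,
    overrides: Mapping[str, bool] | None = None,
) -> ReactionNetwork:
    """Least fixpoint of the merged reactions from the initial species.

    ``overrides`` maps species text to a forced reactivity flag (used for
    the fairness adjustments of the catalyst case study)."""
    if not spec.expanded:
        raise ValueError("expand_modules before building the network")
    rates = rates or RateModel()
    for sp in spec.species_counts:
        if not at_rest(sp):
            raise ValueError(f"initial species is not at rest: {sp}")

    species: list[Species] = sorted(spec.species_counts)
    known = set(species)
    reactions: list[Reaction] = []
    done_pairs: set[tuple] = set()
    frontier = list(species)
    while frontier:
        batch, frontier = frontier, []
        for a in batch:
            for b in list(species):
                key = tuple(sorted((a.key(), b.key())))
                if key in done_pairs:
                    continue
                done_pairs.add(key)
                for r in merged_reactions([a, b], rates):
                    reactions.append(r)
                    for p in r.products:
                        if p not in known:
                            known.add(p)
                            species.append(p)
                            frontier.append(p)
                            if len(species) > species_cap:
                                raise SpeciesCapExceeded(
                                    f"network exceeded {species_cap} species"
                                )
    reactions.sort(key=lambda r: (r.reactants, r.products, r.toehold))
    net = ReactionNetwork(species=species, reactions=reactions, initial=spec, rates=rates)
    if overrides:
        parsed = {parse_species(k): v for k, v in overrides.items()}
        unknown = [k for k in parsed if k not in known]
        if unknown:
            raise ValueError(f"override species not in network: {unknown}")
        net.overrides = parsed
    return net


def classify_reactive(net: ReactionNetwork, mode: str = "structural") -> dict[Species, bool]:
    """Reactivity classification with explicit overrides applied on top.

    ``structural`` (default, matching the auto-generated counting formulae
    of the published analyses): a species is reactive iff it exposes at
    least one unsequestered toehold.  ``network``: a species is reactive
    iff it occurs as a reactant of some reaction of the closed network.
    The two differ on species whose exposed toeholds admit only
    unproductive bindings -- exactly the case the catalyst fairness
    overrides exist to patch."""
    if mode == "structural":
        flags = {
            sp: any(d.toehold for d in sp.exposed_domains()) for sp in net.species
        }
    elif mode == "network":
        flags = {sp: False for sp in net.species}
        for r in net.reactions:
            for sp in r.reactants:
                flags[sp] = True
    else:
        raise ValueError(f"unknown reactivity mode {mode!r}")
    flags.update(net.overrides)
    return flags
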