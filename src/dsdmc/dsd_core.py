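"""Data model, parser/printer and canonicalization for two-domain DSD species.

Species are either free strands or nicked double-stranded gates.  A gate is
stored explicitly as its multiset of strand pieces plus the base pairing
between them:

* ``uppers`` -- strand pieces drawn along the top of the complex, each a
  tuple of domains in page order (which for an upper strand coincides with
  5'->3' order);
* ``lowers`` -- strand pieces drawn along the bottom, in page order (a lower
  strand runs 3'->5' when read left to right, so its 5'->3' sequence is the
  reverse of the page text);
* ``pairs`` -- hybridized domain pairs ``((ui, uo), (li, lo))`` joining
  position ``uo`` of upper piece ``ui`` to position ``lo`` of lower piece
  ``li``.  Pairing is planar: sorted by upper position it is also sorted by
  lower position.

The textual dialect (ASCII rendering of the published syntax)::

    <t^ x>                      upper strand
    {t^* x*}                    lower strand
    {L'}<L>[S]<R>{R'}           gate segment (empty parts omitted)
    G1:G2   G1::G2              segments sharing the lower / upper strand
    D1 | D2                     parallel composition
    12 * D                      population count
    constant D                  population held constant
    new c D                     domain restriction
    def T(N,x,y) = D            module definition
    T(3,x0,x1)                  module instantiation

Gate equality is structural equivalence: invariance under 180-degree
rotation of the complex and under branch migration of overhangs across
junctions.  ``canonicalize`` picks a deterministic representative of that
orbit.
"""

from __future__ import annotations

import re
from collections import Counter, deque
from dataclasses import dataclass, field

from typing import Iterable, Iterator, Mapping, Sequence


# ---------------------------------------------------------------------------
# Domains


@dataclass(frozen=True, order=True)
class Domain:
    """A named nucleotide domain; ``toehold`` marks short domains (``^``),
    ``star`` marks Watson-Crick complementation (``*``)."""

    name: str
    toehold: bool = False
    star: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("domain name must be nonempty")

    @property
    def comp(self) -> "Domain":
        return Domain(self.name, self.toehold, not self.star)

    def __str__(self) -> str:
        return self.name + ("^" if self.toehold else "") + ("*" if self.star else "")


Seq = tuple[Domain, ...]


def _fmt_seq(seq: Iterable[Domain]) -> str:
    return " ".join(str(d) for d in seq)


# ---------------------------------------------------------------------------
# Gates

Pair = tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class Gate:
    """A connected nicked double-stranded complex (see module docstring)."""

    uppers: tuple[Seq, ...]
    lowers: tuple[Seq, ...]
    pairs: tuple[Pair, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(sorted(self.pairs)))

    # -- basic accessors ----------------------------------------------------

    def upper_domain(self, pos: tuple[int, int]) -> Domain:
        return self.uppers[pos[0]][pos[1]]

    def lower_domain(self, pos: tuple[int, int]) -> Domain:
        return self.lowers[pos[0]][pos[1]]

    def paired_uppers(self) -> set[tuple[int, int]]:
        return {u for u, _ in self.pairs}

    def paired_lowers(self) -> set[tuple[int, int]]:
        return {l for _, l in self.pairs}

    def unpaired_upper_positions(self) -> list[tuple[int, int]]:
        taken = self.paired_uppers()
        return [
            (i, o)
            for i, p in enumerate(self.uppers)
            for o in range(len(p))
            if (i, o) not in taken
        ]

    def unpaired_lower_positions(self) -> list[tuple[int, int]]:
        taken = self.paired_lowers()
        return [
            (i, o)
            for i, p in enumerate(self.lowers)
            for o in range(len(p))
            if (i, o) not in taken
        ]

    def validate(self) -> None:
        for (ui, uo), (li, lo) in self.pairs:
            du = self.uppers[ui][uo]
            dl = self.lowers[li][lo]
            if du.comp != dl:
                raise ValueError(f"mismatched pair {du} / {dl}")
        sorted_by_u = sorted(self.pairs)
        lows = [l for _, l in sorted_by_u]
        if lows != sorted(lows):
            raise ValueError("pairing is not planar")
        ups = {u for u, _ in self.pairs}
        if len(ups) != len(self.pairs) or len(set(lows)) != len(self.pairs):
            raise ValueError("position paired twice")
        pieces = [("u", i) for i in range(len(self.uppers))] + [
            ("l", i) for i in range(len(self.lowers))
        ]
        touched = {("u", u[0]) for u, _ in self.pairs} | {
            ("l", l[0]) for _, l in self.pairs
        }
        if set(pieces) != touched:
            raise ValueError("gate contains an unhybridized piece")
        if len(_components(self)) != 1:
            raise ValueError("gate is not connected")

    # -- symmetry -----------------------------------------------------------

    def rotate(self) -> "Gate":
        """180-degree in-plane rotation: the same molecule drawn the other
        way up.  Upper and lower pieces swap roles and page order reverses."""
        nu, nl = len(self.uppers), len(self.lowers)
        new_uppers = tuple(tuple(reversed(p)) for p in reversed(self.lowers))
        new_lowers = tuple(tuple(reversed(p)) for p in reversed(self.uppers))

        def rot_low(pos: tuple[int, int]) -> tuple[int, int]:
            i, o = pos
            return (nl - 1 - i, len(self.lowers[i]) - 1 - o)

        def rot_up(pos: tuple[int, int]) -> tuple[int, int]:
            i, o = pos
            return (nu - 1 - i, len(self.uppers[i]) - 1 - o)

        new_pairs = tuple((rot_low(l), rot_up(u)) for u, l in self.pairs)
        return Gate(new_uppers, new_lowers, new_pairs)

    def mirror(self) -> "Gate":
        """Formal upper/lower exchange (used to transport reduction rules
        between the two strand layers; not a structural equivalence)."""
        return Gate(self.lowers, self.uppers, tuple((l, u) for u, l in self.pairs))

    def key(self) -> tuple:
        return (self.uppers, self.lowers, self.pairs)

    def __str__(self) -> str:
        return format_gate(self)


def _components(gate: Gate) -> list[set[tuple[str, int]]]:
    adj: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for i in range(len(gate.uppers)):
        adj.setdefault(("u", i), set())
    for i in range(len(gate.lowers)):
        adj.setdefault(("l", i), set())
    for (ui, _), (li, _) in gate.pairs:
        adj[("u", ui)].add(("l", li))
        adj[("l", li)].add(("u", ui))
    seen: set[tuple[str, int]] = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            node = queue.popleft()
            for nxt in adj[node]:
                if nxt not in comp:
                    comp.add(nxt)
                    queue.append(nxt)
        seen |= comp
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# Species


@dataclass(frozen=True)
class Species:
    """Canonical strand or gate.  Construct via :func:`canonicalize` (or the
    parser); two structurally equivalent bodies compare equal."""

    kind: str  # "strand" | "gate"
    strand: Seq | None = None  # 5'->3' domain sequence
    gate: Gate | None = None

    def key(self) -> tuple:
        if self.kind == "strand":
            return ("strand", self.strand)
        assert self.gate is not None
        return ("gate",) + self.gate.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Species) and self.key() == other.key()

    def __lt__(self, other: "Species") -> bool:
        return _species_sort_key(self) < _species_sort_key(other)

    @property
    def is_strand(self) -> bool:
        return self.kind == "strand"

    @property
    def is_gate(self) -> bool:
        return self.kind == "gate"

    def domains(self) -> Iterator[Domain]:
        if self.is_strand:
            assert self.strand is not None
            yield from self.strand
        else:
            assert self.gate is not None
            for piece in self.gate.uppers + self.gate.lowers:
                yield from piece

    def exposed_domains(self) -> Iterator[Domain]:
        """Domains not sequestered in a duplex."""
        if self.is_strand:
            assert self.strand is not None
            yield from self.strand
        else:
            g = self.gate
            assert g is not None
            for pos in g.unpaired_upper_positions():
                yield g.upper_domain(pos)
            for pos in g.unpaired_lower_positions():
                yield g.lower_domain(pos)

    def __str__(self) -> str:
        if self.is_strand:
            return f"<{_fmt_seq(self.strand)}>"
        return format_gate(self.gate)

    def __repr__(self) -> str:
        return f"Species({self})"


def _domain_key(d: Domain) -> tuple:
    return (d.name, d.toehold, d.star)


def _species_sort_key(sp: Species) -> tuple:
    if sp.is_strand:
        return (0, len(sp.strand), tuple(_domain_key(d) for d in sp.strand))
    g = sp.gate
    return (
        1,
        sum(len(p) for p in g.uppers + g.lowers),
        tuple(tuple(_domain_key(d) for d in p) for p in g.uppers),
        tuple(tuple(_domain_key(d) for d in p) for p in g.lowers),
        g.pairs,
    )


def strand_species(seq: Sequence[Domain]) -> Species:
    if not seq:
        raise ValueError("strand must be nonempty")
    return Species("strand", strand=tuple(seq))


def lower_piece_to_strand(page_seq: Seq) -> Species:
    """A detached lower piece read off the page becomes a free strand whose
    5'->3' sequence is the reverse of the page text."""
    return strand_species(tuple(reversed(page_seq)))


# ---------------------------------------------------------------------------
# Branch-migration moves (shared with the reduction semantics)


def migration_moves(gate: Gate, keep_attached: bool = True) -> list[Gate]:
    """Single-domain branch-migration steps.  With ``keep_attached`` the
    losing piece must stay hybridized (these moves generate the structural
    equivalence class); without it, steps that strip a piece bare are the
    completion of a displacement."""
    out = []
    out.extend(_upper_migrations(gate, keep_attached))
    mirrored = gate.mirror()
    out.extend(g.mirror() for g in _upper_migrations(mirrored, keep_attached))
    return out


def _upper_migrations(gate: Gate, keep_attached: bool) -> list[Gate]:
    pair_by_lower = {l: u for u, l in gate.pairs}
    paired_upper = gate.paired_uppers()
    counts = Counter(u[0] for u in paired_upper)
    moves = []
    for (ui, uo), (li, lo) in gate.pairs:
        for direction in (+1, -1):
            anchor_l = (li, lo - direction)
            if not (0 <= anchor_l[1] < len(gate.lowers[li])):
                continue
            anchor_u = pair_by_lower.get(anchor_l)
            if anchor_u is None:
                continue
            vi, vo = anchor_u
            if vi == ui:
                continue  # same piece stealing from itself is a loop
            inv = (vi, vo + direction)
            if not (0 <= inv[1] < len(gate.uppers[vi])):
                continue
            if inv in paired_upper:
                continue
            if gate.uppers[vi][inv[1]] != gate.uppers[ui][uo]:
                continue
            if keep_attached and counts[ui] == 1:
                continue
            new_pairs = [p for p in gate.pairs if p != ((ui, uo), (li, lo))]
            new_pairs.append((inv, (li, lo)))
            moves.append(Gate(gate.uppers, gate.lowers, tuple(new_pairs)))
    return moves


def migration_class(gate: Gate) -> list[Gate]:
    """All configurations reachable by attachment-preserving migration."""
    seen = {gate.key(): gate}
    queue = deque([gate])
    while queue:
        g = queue.popleft()
        for nxt in migration_moves(g, keep_attached=True):
            if nxt.key() not in seen:
                seen[nxt.key()] = nxt
                queue.append(nxt)
    return list(seen.values())


def _serialize(gate: Gate) -> tuple:
    # prefer the orientation whose top strands carry fewer starred domains,
    # so signals read off the top (ties broken lexicographically)
    stars = sum(d.star for p in gate.uppers for d in p)
    return (
        stars,
        tuple(tuple(_domain_key(d) for d in p) for p in gate.uppers),
        tuple(tuple(_domain_key(d) for d in p) for p in gate.lowers),
        gate.pairs,
    )


_canon_cache: dict[tuple, Gate] = {}


def canonical_gate(gate: Gate) -> Gate:
    """Minimal representative of the orbit under rotation and branch
    migration."""
    k = gate.key()
    hit = _canon_cache.get(k)
    if hit is not None:
        return hit
    best = None
    best_key = None
    for member in migration_class(gate):
        for candidate in (member, member.rotate()):
            ck = _serialize(candidate)
            if best_key is None or ck < best_key:
                best_key = ck
                best = candidate
    assert best is not None
    for member in migration_class(gate):
        _canon_cache[member.key()] = best
        _canon_cache[member.rotate().key()] = best
    return best


def canonicalize(body: Species | Gate | Sequence[Domain]) -> Species:
    """Canonical :class:`Species` for a strand sequence or gate body."""
    if isinstance(body, Species):
        if body.is_strand:
            return body
        body = body.gate
    if isinstance(body, Gate):
        if not body.pairs:
            # a "gate" with no pairing is really a free strand
            if len(body.uppers) == 1 and not body.lowers:
                return strand_species(body.uppers[0])
            if len(body.lowers) == 1 and not body.uppers:
                return lower_piece_to_strand(body.lowers[0])
            raise ValueError("unpaired multi-piece gate")
        return Species("gate", gate=canonical_gate(body))
    return strand_species(tuple(body))


# ---------------------------------------------------------------------------
# Gate <-> segment form (printing and parsing)


def format_gate(gate: Gate) -> str:
    try:
        segs, connectors = gate_to_segments(gate)
    except ValueError:
        # configurations with closed internal loops have no segment notation;
        # fall back to an explicit (non-parseable) rendering
        ups = " ".join("<" + _fmt_seq(p) + ">" for p in gate.uppers)
        lows = " ".join("{" + _fmt_seq(p) + "}" for p in gate.lowers)
        pairs = ",".join(f"{u[0]}.{u[1]}~{l[0]}.{l[1]}" for u, l in gate.pairs)
        return f"complex({ups} / {lows} / {pairs})"
    parts = []
    for i, (ll, ul, dup, ur, lr) in enumerate(segs):
        txt = ""
        if ll:
            txt += "{" + _fmt_seq(ll) + "}"
        if ul:
            txt += "<" + _fmt_seq(ul) + ">"
        txt += "[" + _fmt_seq(dup) + "]"
        if ur:
            txt += "<" + _fmt_seq(ur) + ">"
        if lr:
            txt += "{" + _fmt_seq(lr) + "}"
        parts.append(txt)
    out = parts[0]
    for conn, part in zip(connectors, parts[1:]):
        out += conn + part
    return out


def gate_to_segments(gate: Gate):
    """Decompose the pairing into maximal duplex runs plus overhangs.

    Returns ``(segments, connectors)`` where each segment is
    ``(lower_left, upper_left, duplex_upper_seq, upper_right, lower_right)``.
    """
    pairs = sorted(gate.pairs)
    runs: list[list[Pair]] = [[pairs[0]]]
    for prev, cur in zip(pairs, pairs[1:]):
        (pu, pl), (cu, cl) = prev, cur
        contiguous = (
            cu[0] == pu[0]
            and cu[1] == pu[1] + 1
            and cl[0] == pl[0]
            and cl[1] == pl[1] + 1
        )
        if contiguous:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    segments = []
    connectors = []
    for ri, run in enumerate(runs):
        (u0, l0), (u1, l1) = run[0], run[-1]
        dup = tuple(gate.uppers[u0[0]][u0[1] : u1[1] + 1])
        # upper-left overhang: unpaired prefix of this run's upper piece
        # that has not been assigned to the previous run's right side.
        ul: Seq = ()
        ll: Seq = ()
        ur: Seq = ()
        lr: Seq = ()
        prev_run = runs[ri - 1] if ri > 0 else None
        next_run = runs[ri + 1] if ri + 1 < len(runs) else None

        # upper-left
        start = 0
        if prev_run and prev_run[-1][0][0] == u0[0]:
            start = prev_run[-1][0][1] + 1
        if not prev_run or prev_run[-1][0][0] != u0[0] or start <= u0[1]:
            lo = start if prev_run and prev_run[-1][0][0] == u0[0] else 0
            ul = tuple(gate.uppers[u0[0]][lo : u0[1]])
            if prev_run and prev_run[-1][0][0] == u0[0] and ul:
                # bubble on a continuous upper strand: keep it on our left
                pass
        # lower-left
        startl = 0
        if prev_run and prev_run[-1][1][0] == l0[0]:
            startl = prev_run[-1][1][1] + 1
        lo = startl if prev_run and prev_run[-1][1][0] == l0[0] else 0
        ll = tuple(gate.lowers[l0[0]][lo : l0[1]])
        # upper-right: suffix of the run's upper piece, unless the next run
        # continues on the same piece (then the gap belongs to its left side)
        if not next_run or next_run[0][0][0] != u1[0]:
            ur = tuple(gate.uppers[u1[0]][u1[1] + 1 :])
        # lower-right
        if not next_run or next_run[0][1][0] != l1[0]:
            lr = tuple(gate.lowers[l1[0]][l1[1] + 1 :])
        segments.append((ll, ul, dup, ur, lr))
        if next_run:
            same_lower = next_run[0][1][0] == l1[0]
            same_upper = next_run[0][0][0] == u1[0]
            if same_lower and same_upper:
                raise ValueError("internal loop is not expressible in segment form")
            if not same_lower and not same_upper:
                raise ValueError("gate is disconnected between duplex runs")
            connectors.append(":" if same_lower else "::")
    return segments, connectors


def gate_from_segments(
    segments: Sequence[tuple[Seq, Seq, Seq, Seq, Seq]],
    connectors: Sequence[str],
) -> Gate:
    """Build the explicit pairing representation from parsed segment form."""
    uppers: list[list[Domain]] = [[]]
    lowers: list[list[Domain]] = [[]]
    pairs: list[Pair] = []
    for idx, (ll, ul, dup, ur, lr) in enumerate(segments):
        if idx > 0:
            conn = connectors[idx - 1]
            if conn == ":":
                uppers.append([])  # nick in the upper strand
            else:
                lowers.append([])  # nick in the lower strand
        lowers[-1].extend(ll)
        uppers[-1].extend(ul)
        for d in dup:
            pairs.append(
                ((len(uppers) - 1, len(uppers[-1])), (len(lowers) - 1, len(lowers[-1])))
            )
            uppers[-1].append(d)
            lowers[-1].append(d.comp)
        uppers[-1].extend(ur)
        lowers[-1].extend(lr)
    gate = Gate(
        tuple(tuple(p) for p in uppers),
        tuple(tuple(p) for p in lowers),
        tuple(pairs),
    )
    gate.validate()
    return gate


# ---------------------------------------------------------------------------
# Parser


class DSDSyntaxError(ValueError):
    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+|\(\*.*?\*\))
  | (?P<int>\d+)
  | (?P<name>[A-Za-z_][A-Za-z0-9_.']*)
  | (?P<dcolon>::)
  | (?P<sym>[<>{}\[\]()|:*^=,])
""",
    re.VERBOSE | re.DOTALL,
)

_KEYWORDS = {"new", "def", "constant"}


@dataclass
class _Token:
    kind: str
    text: str
    line: int
    col: int


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    pos = 0
    line = 1
    linestart = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise DSDSyntaxError(
                f"unexpected character {text[pos]!r}", line, pos - linestart + 1
            )
        kind = m.lastgroup
        tok = m.group()
        if kind != "ws":
            tokens.append(_Token(kind, tok, line, pos - linestart + 1))
        newlines = tok.count("\n")
        if newlines:
            line += newlines
            linestart = pos + tok.rfind("\n") + 1
        pos = m.end()
    tokens.append(_Token("eof", "", line, pos - linestart + 1))
    return tokens


# Raw AST ------------------------------------------------------------------


@dataclass
class RawStrand:
    orientation: str  # "upper" | "lower"
    seq: list[Domain]


@dataclass
class RawGate:
    segments: list[tuple]
    connectors: list[str]


@dataclass
class Par:
    terms: list


@dataclass
class New:
    name: str
    body: object


@dataclass
class Pop:
    count: object  # int or parameter name
    body: object


@dataclass
class Const:
    body: object


@dataclass
class Inst:
    name: str
    args: list  # ints or names


@dataclass
class Lit:
    species: object  # RawStrand | RawGate


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, text: str) -> _Token:
        tok = self.next()
        if tok.text != text:
            raise DSDSyntaxError(f"expected {text!r}, found {tok.text!r}", tok.line, tok.col)
        return tok

    def error(self, msg: str):
        tok = self.peek()
        raise DSDSyntaxError(msg, tok.line, tok.col)

    # -- grammar ------------------------------------------------------------

    def parse_program(self):
        modules = {}
        while self.peek().text == "def":
            self.next()
            name_tok = self.next()
            if name_tok.kind != "name":
                raise DSDSyntaxError("expected module name", name_tok.line, name_tok.col)
            params = []
            self.expect("(")
            if self.peek().text != ")":
                while True:
                    p = self.next()
                    if p.kind != "name":
                        raise DSDSyntaxError("expected parameter name", p.line, p.col)
                    params.append(p.text)
                    if self.peek().text == ",":
                        self.next()
                        continue
                    break
            self.expect(")")
            self.expect("=")
            body = self.parse_system()
            if name_tok.text in modules:
                self.error(f"duplicate module definition {name_tok.text!r}")
            modules[name_tok.text] = (params, body)
        body = self.parse_system() if self.peek().kind != "eof" else Par([])
        tok = self.peek()
        if tok.kind != "eof":
            raise DSDSyntaxError(f"unexpected trailing input {tok.text!r}", tok.line, tok.col)
        return modules, body

    def parse_system(self):
        terms = [self.parse_term()]
        while self.peek().text == "|":
            self.next()
            terms.append(self.parse_term())
        return Par(terms) if len(terms) != 1 else terms[0]

    def parse_term(self):
        tok = self.peek()
        if tok.text == "new":
            self.next()
            name = self.next()
            if name.kind != "name":
                raise DSDSyntaxError("expected domain name after 'new'", name.line, name.col)
            return New(name.text, self.parse_term())
        if tok.text == "constant":
            self.next()
            return Const(self.parse_term())
        if tok.kind == "int":
            self.next()
            self.expect("*")
            return Pop(int(tok.text), self.parse_term())
        if tok.text == "(":
            self.next()
            body = self.parse_system()
            self.expect(")")
            return body
        if tok.kind == "name":
            # either a module instance or a count parameter `n * D`
            nxt = self.tokens[self.i + 1]
            if nxt.text == "(" and tok.text not in _KEYWORDS:
                return self.parse_instance()
            if nxt.text == "*":
                self.next()
                self.next()
                return Pop(tok.text, self.parse_term())
            self.error(f"unexpected name {tok.text!r}")
        if tok.text in ("<", "{", "["):
            return Lit(self.parse_species_body())
        self.error(f"unexpected token {tok.text!r}")

    def parse_instance(self):
        name = self.next().text
        self.expect("(")
        args: list = []
        if self.peek().text != ")":
            while True:
                tok = self.next()
                if tok.kind == "int":
                    args.append(int(tok.text))
                elif tok.kind == "name":
                    args.append(tok.text)
                else:
                    raise DSDSyntaxError("expected argument", tok.line, tok.col)
                if self.peek().text == ",":
                    self.next()
                    continue
                break
        self.expect(")")
        return Inst(name, args)

    # -- species ------------------------------------------------------------

    def parse_species_body(self):
        tok = self.peek()
        if tok.text == "<":
            seq = self.parse_bracketed("<", ">")
            # may still be a gate if a duplex follows (upper-left overhang)
            if self.peek().text in ("[", "{"):
                return self.parse_gate(first_ul=seq)
            return RawStrand("upper", seq)
        if tok.text == "{":
            seq = self.parse_bracketed("{", "}")
            if self.peek().text in ("[", "<"):
                return self.parse_gate(first_ll=seq)
            return RawStrand("lower", seq)
        if tok.text == "[":
            return self.parse_gate()
        self.error("expected species")

    def parse_bracketed(self, open_b: str, close_b: str) -> list[Domain]:
        self.expect(open_b)
        seq = self.parse_seq()
        self.expect(close_b)
        return seq

    def parse_seq(self) -> list[Domain]:
        seq = []
        while self.peek().kind == "name":
            tok = self.next()
            toehold = False
            star = False
            if self.peek().text == "^":
                self.next()
                toehold = True
            if self.peek().text == "*":
                self.next()
                star = True
            seq.append(Domain(tok.text, toehold, star))
        if not seq:
            self.error("expected at least one domain")
        return seq

    def parse_gate(self, first_ll=None, first_ul=None) -> RawGate:
        segments = []
        connectors = []
        ll = first_ll or []
        ul = first_ul or []
        if not ul and self.peek().text == "<":
            ul = self.parse_bracketed("<", ">")
        first = True
        while True:
            if not first:
                ll, ul = [], []
                if self.peek().text == "{":
                    ll = self.parse_bracketed("{", "}")
                if self.peek().text == "<":
                    ul = self.parse_bracketed("<", ">")
            dup = self.parse_bracketed("[", "]")
            ur: list[Domain] = []
            lr: list[Domain] = []
            if self.peek().text == "<":
                ur = self.parse_bracketed("<", ">")
            if self.peek().text == "{":
                lr = self.parse_bracketed("{", "}")
            segments.append((tuple(ll), tuple(ul), tuple(dup), tuple(ur), tuple(lr)))
            tok = self.peek()
            if tok.text == "::":
                self.next()
                connectors.append("::")
            elif tok.text == ":":
                self.next()
                connectors.append(":")
            else:
                break
            first = False
        return RawGate(segments, connectors)


def _raw_to_species(raw) -> Species:
    if isinstance(raw, RawStrand):
        seq = tuple(raw.seq)
        if raw.orientation == "lower":
            seq = tuple(reversed(seq))
        return strand_species(seq)
    assert isinstance(raw, RawGate)
    return canonicalize(gate_from_segments(raw.segments, raw.connectors))


def parse_species(text: str) -> Species:
    """Parse a single strand or gate."""
    parser = _Parser(text)
    raw = parser.parse_species_body()
    tok = parser.peek()
    if tok.kind != "eof":
        raise DSDSyntaxError(f"unexpected trailing input {tok.text!r}", tok.line, tok.col)
    return _raw_to_species(raw)


# ---------------------------------------------------------------------------
# Systems


@dataclass
class SystemSpec:
    """A (possibly unexpanded) DSD system.

    ``species_counts``/``constant_species``/``bound_domains`` are populated
    once the system is module-free (directly by the parser when no modules
    are instantiated, otherwise by :func:`expand_modules`)."""

    species_counts: dict[Species, int] = field(default_factory=dict)
    constant_species: set[Species] = field(default_factory=set)
    bound_domains: set[str] = field(default_factory=set)
    module_defs: dict[str, tuple[list[str], object]] = field(default_factory=dict)
    body: object = field(default_factory=lambda: Par([]))
    expanded: bool = False

    def species(self) -> list[Species]:
        return sorted(self.species_counts)

    def __str__(self) -> str:
        return format_system(self)


def parse_system(text: str) -> SystemSpec:
    """Parse DSD source into a :class:`SystemSpec`."""
    modules, body = _Parser(text).parse_program()
    spec = SystemSpec(module_defs=modules, body=body)
    _check_module_wellformedness(spec)
    if not _contains_instances(body):
        return expand_modules(spec)
    return spec


def _contains_instances(node) -> bool:
    if isinstance(node, Inst):
        return True
    if isinstance(node, Par):
        return any(_contains_instances(t) for t in node.terms)
    if isinstance(node, (New, Pop, Const)):
        return _contains_instances(node.body)
    return False


def _check_module_wellformedness(spec: SystemSpec) -> None:
    def instances(node) -> set[str]:
        if isinstance(node, Inst):
            return {node.name}
        if isinstance(node, Par):
            return set().union(*(instances(t) for t in node.terms)) if node.terms else set()
        if isinstance(node, (New, Pop, Const)):
            return instances(node.body)
        return set()

    graph = {name: instances(body) for name, (_, body) in spec.module_defs.items()}
    for callees in graph.values():
        for callee in callees:
            if callee not in spec.module_defs:
                raise ValueError(f"unknown module {callee!r}")
    for callee in instances(spec.body):
        if callee not in spec.module_defs:
            raise ValueError(f"unknown module {callee!r}")
    # recursion check via DFS
    state: dict[str, int] = {}

    def visit(name: str):
        if state.get(name) == 1:
            raise ValueError(f"recursive module definition involving {name!r}")
        if state.get(name) == 2:
            return
        state[name] = 1
        for callee in graph[name]:
            visit(callee)
        state[name] = 2

    for name in graph:
        visit(name)


class _Expander:
    def __init__(self, modules: Mapping[str, tuple[list[str], object]]):
        self.modules = modules
        self.fresh_counter = 0
        self.species: Counter[Species] = Counter()
        self.constants: set[Species] = set()
        self.fresh_names: set[str] = set()

    def run(self, node) -> None:
        self.walk(node, subst={}, count=1, constant=False)

    def walk(self, node, subst: dict, count: int, constant: bool) -> None:
        if isinstance(node, Par):
            for t in node.terms:
                self.walk(t, subst, count, constant)
        elif isinstance(node, New):
            self.fresh_counter += 1
            fresh = f"{node.name}.{self.fresh_counter}"
            self.fresh_names.add(fresh)
            self.walk(node.body, {**subst, node.name: fresh}, count, constant)
        elif isinstance(node, Pop):
            n = node.count
            if isinstance(n, str):
                if n not in subst:
                    raise ValueError(f"unbound count parameter {n!r}")
                n = subst[n]
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"population count must be a nonnegative integer, got {n!r}")
            self.walk(node.body, subst, count * n, constant)
        elif isinstance(node, Const):
            self.walk(node.body, subst, count, True)
        elif isinstance(node, Inst):
            params, body = self.modules[node.name]
            if len(params) != len(node.args):
                raise ValueError(
                    f"module {node.name!r} expects {len(params)} argument(s), "
                    f"got {len(node.args)}"
                )
            inner = {}
            for p, a in zip(params, node.args):
                if isinstance(a, str) and a in subst:
                    a = subst[a]
                inner[p] = a
            self.walk(body, inner, count, constant)
        elif isinstance(node, Lit):
            sp = _raw_to_species(_substitute(node.species, subst))
            if count > 0:
                self.species[sp] += count
            else:
                self.species.setdefault(sp, 0)
            if constant:
                self.constants.add(sp)
        else:  # pragma: no cover
            raise TypeError(f"unexpected AST node {node!r}")


def _substitute(raw, subst: dict):
    def sub_domain(d: Domain) -> Domain:
        repl = subst.get(d.name)
        if repl is None:
            return d
        if not isinstance(repl, str):
            raise ValueError(f"parameter {d.name!r} used as domain but bound to {repl!r}")
        return Domain(repl, d.toehold, d.star)

    def sub_seq(seq):
        return tuple(sub_domain(d) for d in seq)

    if isinstance(raw, RawStrand):
        return RawStrand(raw.orientation, [sub_domain(d) for d in raw.seq])
    assert isinstance(raw, RawGate)
    segs = [tuple(sub_seq(part) for part in seg) for seg in raw.segments]
    return RawGate(segs, list(raw.connectors))


def expand_modules(spec: SystemSpec) -> SystemSpec:
    """Inline all module instances, alpha-renaming each ``new``-bound domain
    to a globally fresh ``base.k`` name."""
    _check_module_wellformedness(spec)
    ex = _Expander(spec.module_defs)
    ex.run(spec.body)
    return SystemSpec(
        species_counts=dict(ex.species),
        constant_species=ex.constants,
        bound_domains=ex.fresh_names,
        module_defs=dict(spec.module_defs),
        body=spec.body,
        expanded=True,
    )


def format_system(spec: SystemSpec) -> str:
    if not spec.expanded and _contains_instances(spec.body):
        raise ValueError("cannot print an unexpanded system; call expand_modules first")
    parts = []
    for sp in sorted(spec.species_counts):
        n = spec.species_counts[sp]
        txt = str(sp)
        if n != 1:
            txt = f"{n} * {txt}"
        if sp in spec.constant_species:
            txt = f"constant {txt}"
        parts.append(txt)
    return "\n| ".join(parts)


# ---------------------------------------------------------------------------
# Well-formedness


@dataclass(frozen=True)
class Violation:
    domain: Domain
    species_a: Species
    species_b: Species

    def __str__(self) -> str:
        return (
            f"long domain {self.domain} exposed on {self.species_a} while its "
            f"complement is exposed on {self.species_b}"
        )


def check_well_formed(spec: SystemSpec) -> list[Violation]:
    """No long domain and its complement may be simultaneously unbound
    anywhere in the system (exposed complementary toeholds are fine)."""
    exposed: dict[Domain, Species] = {}
    violations = []
    species = list(spec.species_counts)
    for sp in species:
        for d in sp.exposed_domains():
            if d.toehold:
                continue
            exposed.setdefault(d, sp)
    seen = set()
    for d, sp in exposed.items():
        other = exposed.get(d.comp)
        if other is not None:
            key = frozenset((d, d.comp))
            if key in seen:
                continue
            seen.add(key)
            base = d if not d.star else d.comp
            violations.append(Violation(base, exposed[base], exposed[base.comp]))
    return violations
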