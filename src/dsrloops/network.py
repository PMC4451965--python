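"""Reaction networks, stoichiometry, and influence-sign matrices.

The input format is a plain-text reaction list, one reaction per line::

    # comment
    r1: A + 2 B -> C
    r2: C <-> A        # expands to r2_f (C -> A) and r2_r (A -> C)
    r3: 0 -> A         # inflow; "0" denotes an empty side

Species are ordered by first appearance in the document and reactions by
file order; both orders are preserved in every downstream matrix, graph
and report, so variable subscripts are reproducible run to run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import sympy

__all__ = [
    "NetworkError",
    "NetworkParseError",
    "InfluenceError",
    "Reaction",
    "ReactionNetwork",
    "StoichMatrix",
    "InfluenceMatrix",
    "parse_network",
    "stoichiometric_matrix",
    "mass_action_influence",
    "influence_from_table",
    "parse_influence_tsv",
    "influence_to_tsv",
]


class NetworkError(ValueError):
    """Invalid reaction-network input."""


class NetworkParseError(NetworkError):
    """A reaction-list document could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None) -> None:
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class InfluenceError(NetworkError):
    """Invalid influence-sign input (bad symbol, shape mismatch, ...)."""


_INT_RE = re.compile(r"[+-]?\d+\Z")


def _checked_coefficients(side: Mapping[str, int], role: str) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for name, coef in side.items():
        if not isinstance(coef, int) or isinstance(coef, bool) or coef < 0:
            raise NetworkError(
                f"{role} coefficient for {name!r} must be a nonnegative integer, got {coef!r}"
            )
        if coef:
            out[name] = coef
    return out


@dataclass(frozen=True)
class Reaction:
    """One irreversible reaction with nonnegative integer coefficients.

    A species may appear on both sides (a catalyst): it then has a
    reactant coefficient > 0 but may have net stoichiometry 0.  At most
    one side may be empty (inflow/outflow); an empty reaction is invalid.
    """

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.id or len(self.id.split()) != 1:
            raise NetworkError(f"bad reaction id {self.id!r}")
        object.__setattr__(self, "reactants", _checked_coefficients(self.reactants, "reactant"))
        object.__setattr__(self, "products", _checked_coefficients(self.products, "product"))
        if not self.reactants and not self.products:
            raise NetworkError(f"reaction {self.id!r} consumes and produces nothing")

    def species(self) -> Iterator[str]:
        """Species touched by this reaction, reactants first, in input order."""
        yield from self.reactants
        for name in self.products:
            if name not in self.reactants:
                yield name


class ReactionNetwork:
    """Ordered species plus ordered irreversible reactions."""

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction]) -> None:
        self.species: Tuple[str, ...] = tuple(species)
        self.reactions: Tuple[Reaction, ...] = tuple(reactions)
        if len(set(self.species)) != len(self.species):
            raise NetworkError("duplicate species names")
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate reaction ids")
        self._index = {name: i for i, name in enumerate(self.species)}
        for r in self.reactions:
            for name in r.species():
                if name not in self._index:
                    raise NetworkError(f"reaction {r.id!r} references unknown species {name!r}")

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def m(self) -> int:
        return len(self.reactions)

    @property
    def reaction_ids(self) -> Tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    def species_index(self, name: str) -> int:
        """0-based index of a species name."""
        return self._index[name]

    def alpha(self, i: int, j: int) -> int:
        """Reactant coefficient of species i in reaction j (0-based)."""
        return self.reactions[j].reactants.get(self.species[i], 0)

    def beta(self, i: int, j: int) -> int:
        """Product coefficient of species i in reaction j (0-based)."""
        return self.reactions[j].products.get(self.species[i], 0)

    def to_text(self) -> str:
        """Serialize back to the reaction-list format (parse round-trips)."""
        return "\n".join(
            f"{r.id}: {_side_text(r.reactants)} -> {_side_text(r.products)}"
            for r in self.reactions
        ) + "\n"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return self.species == other.species and self.reactions == other.reactions

    def __repr__(self) -> str:
        return f"ReactionNetwork({self.n} species, {self.m} reactions)"


def _side_text(side: Mapping[str, int]) -> str:
    if not side:
        return "0"
    return " + ".join(name if c == 1 else f"{c} {name}" for name, c in side.items())


def _parse_side(text: str, lineno: int) -> Dict[str, int]:
    stripped = text.strip()
    if not stripped:
        raise NetworkParseError("empty reaction side (use the literal '0')", lineno)
    if stripped == "0":
        return {}
    terms: List[List[str]] = [[]]
    for tok in stripped.split():
        if tok == "+":
            if not terms[-1]:
                raise NetworkParseError("misplaced '+'", lineno)
            terms.append([])
        else:
            terms[-1].append(tok)
    if not terms[-1]:
        raise NetworkParseError("dangling '+'", lineno)
    coeffs: Dict[str, int] = {}
    for term in terms:
        if len(term) == 1:
            coef_text, name = None, term[0]
        elif len(term) == 2:
            coef_text, name = term
        else:
            raise NetworkParseError(f"cannot parse term {' '.join(term)!r}", lineno)
        if coef_text is None:
            coef = 1
        else:
            if not _INT_RE.match(coef_text):
                raise NetworkParseError(f"non-integer coefficient {coef_text!r}", lineno)
            coef = int(coef_text)
            if coef < 0:
                raise NetworkParseError(f"negative coefficient {coef}", lineno)
            if coef == 0:
                raise NetworkParseError("zero coefficient (omit the species instead)", lineno)
        if _INT_RE.match(name):
            raise NetworkParseError(f"expected a species name, got number {name!r}", lineno)
        coeffs[name] = coeffs.get(name, 0) + coef
    return coeffs


def parse_network(text: str) -> ReactionNetwork:
    """Parse a reaction-list document.

    Reversible lines (``<->``) expand into a forward/reverse pair with
    ``_f``/``_r`` id suffixes, forward first.  Errors carry line numbers.
    """
    if not text or not text.strip():
        raise NetworkParseError("empty reaction document")
    species: List[str] = []
    seen: set = set()
    reactions: List[Reaction] = []
    ids: set = set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, sep, body = line.partition(":")
        if not sep:
            raise NetworkParseError("expected 'id: reactants -> products'", lineno)
        rid = head.strip()
        if not rid or len(rid.split()) != 1:
            raise NetworkParseError(f"bad reaction id {head.strip()!r}", lineno)
        reversible = "<->" in body
        arrow = "<->" if reversible else "->"
        left, sep2, right = body.partition(arrow)
        if not sep2 or "->" in right:
            raise NetworkParseError("expected exactly one '->' or '<->'", lineno)
        lhs = _parse_side(left, lineno)
        rhs = _parse_side(right, lineno)
        if not lhs and not rhs:
            raise NetworkParseError("reaction consumes and produces nothing", lineno)
        if reversible:
            expanded = [(f"{rid}_f", lhs, rhs), (f"{rid}_r", rhs, lhs)]
        else:
            expanded = [(rid, lhs, rhs)]
        for name in (*lhs, *rhs):
            if name not in seen:
                seen.add(name)
                species.append(name)
        for xid, xl, xr in expanded:
            if xid in ids:
                raise NetworkParseError(f"duplicate reaction id {xid!r}", lineno)
            ids.add(xid)
            try:
                reactions.append(Reaction(xid, xl, xr))
            except NetworkError as exc:
                raise NetworkParseError(str(exc), lineno) from exc
    if not reactions:
        raise NetworkParseError("no reactions found")
    return ReactionNetwork(species, reactions)


@dataclass(frozen=True)
class StoichMatrix:
    """Integer net-stoichiometry matrix (species x reactions) with exact rank."""

    entries: Tuple[Tuple[int, ...], ...]
    rank: int

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def m(self) -> int:
        return len(self.entries[0]) if self.entries else 0


def stoichiometric_matrix(net: ReactionNetwork) -> StoichMatrix:
    """Net stoichiometry, entry (i, j) = products - reactants; rank is exact."""
    rows = tuple(
        tuple(r.products.get(name, 0) - r.reactants.get(name, 0) for r in net.reactions)
        for name in net.species
    )
    rank = int(sympy.Matrix([list(row) for row in rows]).rank()) if rows else 0
    return StoichMatrix(rows, rank)


_SIGN_SYMBOLS = {
    "+": 1, "+1": 1, "1": 1,
    "-": -1, "-1": -1, "−": -1, "−1": -1,
    "0": 0,
}


def _coerce_sign(value: object) -> int:
    if isinstance(value, int) and not isinstance(value, bool) and value in (-1, 0, 1):
        return value
    if isinstance(value, str):
        stripped = value.strip()
        if stripped in _SIGN_SYMBOLS:
            return _SIGN_SYMBOLS[stripped]
    raise InfluenceError(f"illegal influence entry {value!r}; expected one of +, -, 0")


@dataclass(frozen=True)
class InfluenceMatrix:
    """Sign pattern of the rate Jacobian: +1, -1 or 0 per (species, reaction).

    Every nonzero entry owns one symbolic variable, identified by the
    1-based pair ``(i, j)`` and printed as ``g[i,j]``; the stored value is
    only the sign of the entry's monotone dependence.
    """

    signs: Tuple[Tuple[int, ...], ...]

    def __post_init__(self) -> None:
        for row in self.signs:
            for v in row:
                if v not in (-1, 0, 1):
                    raise InfluenceError(f"illegal influence sign {v!r}")

    @property
    def n(self) -> int:
        return len(self.signs)

    @property
    def m(self) -> int:
        return len(self.signs[0]) if self.signs else 0

    @property
    def nnz(self) -> int:
        return sum(1 for row in self.signs for v in row if v)

    def gamma_pairs(self) -> Tuple[Tuple[int, int], ...]:
        """The 1-based (species, reaction) identifiers of all variables."""
        return tuple(
            (i + 1, j + 1)
            for i, row in enumerate(self.signs)
            for j, v in enumerate(row)
            if v
        )

    def zeroed(self, pairs: Iterable[Tuple[int, int]]) -> "InfluenceMatrix":
        """Copy with the given 1-based (species, reaction) entries set to 0."""
        drop = set(pairs)
        return InfluenceMatrix(
            tuple(
                tuple(0 if (i + 1, j + 1) in drop else v for j, v in enumerate(row))
                for i, row in enumerate(self.signs)
            )
        )


def mass_action_influence(net: ReactionNetwork) -> InfluenceMatrix:
    """Influence signs under mass-action rates: +1 exactly where a species
    is a reactant (rates strictly increase in each reactant concentration)."""
    return InfluenceMatrix(
        tuple(
            tuple(1 if net.alpha(i, j) > 0 else 0 for j in range(net.m))
            for i in range(net.n)
        )
    )


def influence_from_table(
    net: ReactionNetwork, table: Sequence[Sequence[object]]
) -> InfluenceMatrix:
    """Build an influence matrix from a species x reaction table of signs.

    Rows/columns must follow the network's own ordering; entries may be
    ints in {-1, 0, 1} or the symbols ``+``, ``-``, ``0``.
    """
    rows = [list(r) for r in table]
    if len(rows) != net.n or any(len(r) != net.m for r in rows):
        got = f"{len(rows)}x{len(rows[0]) if rows else 0}"
        raise InfluenceError(f"influence table is {got}, expected {net.n}x{net.m}")
    return InfluenceMatrix(tuple(tuple(_coerce_sign(v) for v in row) for row in rows))


def parse_influence_tsv(net: ReactionNetwork, text: str) -> InfluenceMatrix:
    """Parse a TSV sign table; rows and columns are matched to the network
    by species name / reaction id, in any order.  '#' starts a comment."""
    lines = [
        line for line in (raw.split("#", 1)[0].rstrip() for raw in text.splitlines())
        if line.strip()
    ]
    if not lines:
        raise InfluenceError("empty influence table")
    header = [cell.strip() for cell in lines[0].split("\t")]
    col_ids = header[1:]
    if sorted(col_ids) != sorted(net.reaction_ids):
        raise InfluenceError(
            f"influence table columns {col_ids!r} do not match reaction ids {list(net.reaction_ids)!r}"
        )
    col_of = {rid: k for k, rid in enumerate(col_ids)}
    by_species: Dict[str, List[int]] = {}
    for line in lines[1:]:
        cells = [cell.strip() for cell in line.split("\t")]
        if len(cells) != len(header):
            raise InfluenceError(f"row {cells[0]!r} has {len(cells) - 1} cells, expected {len(col_ids)}")
        name = cells[0]
        if name not in net.species:
            raise InfluenceError(f"unknown species {name!r} in influence table")
        if name in by_species:
            raise InfluenceError(f"duplicate species row {name!r} in influence table")
        by_species[name] = [_coerce_sign(c) for c in cells[1:]]
    missing = [s for s in net.species if s not in by_species]
    if missing:
        raise InfluenceError(f"influence table is missing species rows {missing!r}")
    return InfluenceMatrix(
        tuple(
            tuple(by_species[name][col_of[rid]] for rid in net.reaction_ids)
            for name in net.species
        )
    )


def influence_to_tsv(net: ReactionNetwork, Z: InfluenceMatrix) -> str:
    """Serialize an influence matrix in the TSV format read back by
    :func:`parse_influence_tsv`."""
    if (Z.n, Z.m) != (net.n, net.m):
        raise InfluenceError(f"influence matrix is {Z.n}x{Z.m}, expected {net.n}x{net.m}")
    sym = {1: "+", -1: "-", 0: "0"}
    lines = ["species\t" + "\t".join(net.reaction_ids)]
    for name, row in zip(net.species, Z.signs):
        lines.append(name + "\t" + "\t".join(sym[v] for v in row))
    return "\n".join(lines) + "\n"
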