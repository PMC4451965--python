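"""Signed species-reaction graph: circuits, nuclei, relevant-loop extraction.

The graph is bipartite and directed: an edge from species X_i to reaction
r_j carries the influence sign z_ij, an edge from r_j to X_i carries the
net stoichiometric coefficient a_ij.  Positive circuits of this graph are
the candidate feedback loops; the ones that occur inside wrong-sign
2s-nuclei of wrong-sign polynomial terms are the loops that can actually
drive multistationarity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .injectivity import (
    Verdict,
    injectivity_polynomial,
    injectivity_verdict,
    wrong_sign,
    wrong_sign_terms,
)
from .network import (
    InfluenceError,
    InfluenceMatrix,
    ReactionNetwork,
    StoichMatrix,
    stoichiometric_matrix,
)
from .polynomial import Monomial, Pair, SignPolynomial, monomial_key

__all__ = [
    "SPECIES",
    "REACTION",
    "species_node",
    "reaction_node",
    "build_dsr_graph",
    "Circuit",
    "enumerate_circuits",
    "Nucleus",
    "nuclei_for_term",
    "nucleus_sign",
    "nucleus_expansion",
    "motif_signature",
    "LoopReport",
    "find_relevant_loops",
    "dsr_to_dot",
]

# Node kinds; "reaction" sorts before "species", which makes the canonical
# rotation of every circuit start at its smallest reaction node.
REACTION = "reaction"
SPECIES = "species"

Node = Tuple[str, int]


def species_node(i: int) -> Node:
    """Species node for 1-based species index i."""
    return (SPECIES, i)


def reaction_node(j: int) -> Node:
    """Reaction node for 1-based reaction index j."""
    return (REACTION, j)


def build_dsr_graph(A: StoichMatrix, Z: InfluenceMatrix) -> nx.DiGraph:
    """Directed bipartite graph whose edges mirror the nonzero supports of
    Z (species -> reaction, attr ``sign``) and A (reaction -> species,
    attrs ``sign`` and integer ``weight``)."""
    if (A.n, A.m) != (Z.n, Z.m):
        raise InfluenceError(
            f"shape mismatch: stoichiometry is {A.n}x{A.m}, influence is {Z.n}x{Z.m}"
        )
    G = nx.DiGraph(n=A.n, m=A.m)
    for i in range(1, A.n + 1):
        G.add_node(species_node(i))
    for j in range(1, A.m + 1):
        G.add_node(reaction_node(j))
    for i in range(A.n):
        for j in range(A.m):
            z = Z.signs[i][j]
            if z:
                G.add_edge(species_node(i + 1), reaction_node(j + 1), sign=z)
    for i in range(A.n):
        for j in range(A.m):
            a = A.entries[i][j]
            if a:
                G.add_edge(
                    reaction_node(j + 1), species_node(i + 1),
                    sign=1 if a > 0 else -1, weight=a,
                )
    return G


@dataclass(frozen=True)
class Circuit:
    """An elementary directed cycle in canonical rotation.

    ``nodes`` starts at the smallest node under (kind, index) ordering —
    always a reaction node; ``edge_signs[t]`` is the sign of the edge from
    ``nodes[t]`` to ``nodes[(t+1) % len]``.
    """

    nodes: Tuple[Node, ...]
    edge_signs: Tuple[int, ...]

    @classmethod
    def from_cycle(cls, G: nx.DiGraph, cycle: Sequence[Node]) -> "Circuit":
        size = len(cycle)
        if size < 2 or size % 2:
            raise ValueError(f"not an alternating species/reaction cycle: {cycle!r}")
        start = min(range(size), key=lambda t: cycle[t])
        nodes = tuple(cycle[start:]) + tuple(cycle[:start])
        for t in range(size):
            if nodes[t][0] == nodes[(t + 1) % size][0]:
                raise ValueError(f"cycle does not alternate node kinds: {cycle!r}")
        signs = tuple(
            G.edges[nodes[t], nodes[(t + 1) % size]]["sign"] for t in range(size)
        )
        return cls(nodes, signs)

    @property
    def sign(self) -> int:
        sign = 1
        for s in self.edge_signs:
            sign *= s
        return sign

    @property
    def species_count(self) -> int:
        return sum(1 for kind, _ in self.nodes if kind == SPECIES)

    def influence_pairs(self) -> Tuple[Pair, ...]:
        """The (species, reaction) influence edges traversed by the circuit."""
        size = len(self.nodes)
        return tuple(
            (self.nodes[t][1], self.nodes[(t + 1) % size][1])
            for t in range(size)
            if self.nodes[t][0] == SPECIES
        )

    def sort_key(self):
        return (len(self.nodes), self.nodes)


def enumerate_circuits(G: nx.DiGraph) -> List[Circuit]:
    """All elementary directed cycles, canonicalized and sorted."""
    circuits = [Circuit.from_cycle(G, cyc) for cyc in nx.simple_cycles(G)]
    circuits.sort(key=Circuit.sort_key)
    return circuits


@dataclass(frozen=True)
class Nucleus:
    """A node-disjoint union of circuits (stored sorted).

    ``sign`` is the sign of sigma * label: (-1)**a2 times the product of
    the circuit signs, a2 being the number of circuits with an even number
    of species nodes.
    """

    circuits: Tuple[Circuit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "circuits", tuple(sorted(self.circuits, key=Circuit.sort_key))
        )
        seen: Set[Node] = set()
        for c in self.circuits:
            if seen & set(c.nodes):
                raise ValueError("nucleus circuits must be node-disjoint")
            seen.update(c.nodes)

    @property
    def node_count(self) -> int:
        return sum(len(c.nodes) for c in self.circuits)

    @property
    def a1(self) -> int:
        return sum(1 for c in self.circuits if c.species_count % 2 == 1)

    @property
    def a2(self) -> int:
        return sum(1 for c in self.circuits if c.species_count % 2 == 0)

    @property
    def sign(self) -> int:
        sign = -1 if self.a2 % 2 else 1
        for c in self.circuits:
            sign *= c.sign
        return sign


def nucleus_sign(D: Nucleus, s: int) -> int:
    """Sign of sigma * label for a 2s-nucleus."""
    if D.node_count != 2 * s:
        raise ValueError(f"nucleus covers {D.node_count} nodes, expected {2 * s}")
    return D.sign


def _term_pairs(term: Iterable[Pair]) -> List[Pair]:
    pairs = sorted(term)
    if len({i for i, _ in pairs}) != len(pairs) or len({j for _, j in pairs}) != len(pairs):
        raise ValueError(f"term has repeated species or reaction indices: {pairs!r}")
    return pairs


def _close_nucleus(G: nx.DiGraph, pairs: Sequence[Pair], psi: Dict[int, int]) -> Nucleus:
    """Close the fixed influence edges with the matching ``psi`` (reaction ->
    species) and decompose the resulting degree-1 digraph into circuits."""
    phi = {i: j for i, j in pairs}
    circuits: List[Circuit] = []
    remaining = set(phi)
    while remaining:
        i0 = min(remaining)
        seq: List[Node] = []
        i = i0
        while True:
            remaining.discard(i)
            seq.append(species_node(i))
            j = phi[i]
            seq.append(reaction_node(j))
            i = psi[j]
            if i == i0:
                break
        circuits.append(Circuit.from_cycle(G, seq))
    return Nucleus(tuple(circuits))


def nuclei_for_term(G: nx.DiGraph, term: Iterable[Pair]) -> List[Nucleus]:
    """All 2s-nuclei realizing a degree-s term.

    The s influence edges named by the term are fixed; every perfect
    matching of existing reaction->species edges back onto the term's
    species closes them into a disjoint union of circuits covering all
    2s nodes.  Matchings are enumerated by backtracking over reactions in
    index order, so the output order is deterministic.
    """
    pairs = _term_pairs(term)
    for i, j in pairs:
        if not G.has_edge(species_node(i), reaction_node(j)):
            raise ValueError(f"g[{i},{j}] is not an influence edge of the graph")
    species = [i for i, _ in pairs]
    reactions = sorted(j for _, j in pairs)
    targets = {
        j: [i for i in species if G.has_edge(reaction_node(j), species_node(i))]
        for j in reactions
    }
    out: List[Nucleus] = []
    psi: Dict[int, int] = {}
    used: Set[int] = set()

    def backtrack(idx: int) -> None:
        if idx == len(reactions):
            out.append(_close_nucleus(G, pairs, dict(psi)))
            return
        j = reactions[idx]
        for i in targets[j]:
            if i not in used:
                used.add(i)
                psi[j] = i
                backtrack(idx + 1)
                used.discard(i)
                del psi[j]

    backtrack(0)
    return out


def nucleus_expansion(G: nx.DiGraph, s: int) -> SignPolynomial:
    """Sum of sigma * label over every 2s-nucleus of the graph, as a sign
    polynomial (integer stoichiometric labels multiply into coefficients).

    This is a graph-theoretic route to the injectivity polynomial and is
    kept as an independent cross-check of the determinant expansion.
    """
    if s == 0:
        return SignPolynomial.constant(1)
    n = G.graph["n"]
    z_adj = {
        i: sorted(j for (_, j) in (v for _, v in G.out_edges(species_node(i))))
        for i in range(1, n + 1)
        if G.out_degree(species_node(i)) > 0
    }
    species_list = sorted(z_adj)
    acc: Dict[Monomial, Fraction] = {}
    phi_pairs: List[Pair] = []
    used_reactions: Set[int] = set()

    def close_all(pairs: List[Pair]) -> None:
        species = [i for i, _ in pairs]
        reactions = sorted(j for _, j in pairs)
        targets = {
            j: [i for i in species if G.has_edge(reaction_node(j), species_node(i))]
            for j in reactions
        }
        psi: Dict[int, int] = {}
        used: Set[int] = set()

        def match(idx: int) -> None:
            if idx == len(reactions):
                D = _close_nucleus(G, pairs, dict(psi))
                coeff = Fraction(D.sign)
                for j, i in psi.items():
                    coeff *= abs(G.edges[reaction_node(j), species_node(i)]["weight"])
                mono = frozenset(pairs)
                acc[mono] = acc.get(mono, Fraction(0)) + coeff
                return
            j = reactions[idx]
            for i in targets[j]:
                if i not in used:
                    used.add(i)
                    psi[j] = i
                    match(idx + 1)
                    used.discard(i)
                    del psi[j]

        match(0)

    def assign(pos: int, need: int) -> None:
        if need == 0:
            close_all(list(phi_pairs))
            return
        for t in range(pos, len(species_list) - need + 1):
            i = species_list[t]
            for j in z_adj[i]:
                if j not in used_reactions:
                    phi_pairs.append((i, j))
                    used_reactions.add(j)
                    assign(t + 1, need - 1)
                    used_reactions.discard(j)
                    phi_pairs.pop()

    assign(0, s)
    return SignPolynomial(acc)


def motif_signature(circuit: Circuit) -> str:
    """Cyclic edge-sign tuple of a loop, read from a reaction node and
    canonicalized to the smallest rotation by a node pair ('+' < '-')."""
    if circuit.nodes[0][0] != REACTION:
        raise ValueError("circuit must start at a reaction node (canonical rotation does)")
    chars = tuple("+" if s > 0 else "-" for s in circuit.edge_signs)
    best = min(chars[k:] + chars[:k] for k in range(0, len(chars), 2))
    return "(" + ",".join(best) + ")"


@dataclass(frozen=True)
class LoopReport:
    """Outcome of the three-step procedure on one network + influence pattern."""

    network: ReactionNetwork
    rank: int
    verdict: Verdict
    polynomial: SignPolynomial
    wrong_terms: Tuple[Tuple[Tuple[Pair, ...], Fraction], ...]
    wrong_nuclei: Tuple[Tuple[Tuple[Pair, ...], Tuple[Nucleus, ...]], ...]
    relevant_loops: Tuple[Circuit, ...]
    all_positive_loops: Tuple[Circuit, ...]

    @property
    def term_counts(self) -> Dict[str, int]:
        pos = sum(1 for _, c in self.polynomial.items() if c > 0)
        return {"positive": pos, "negative": self.polynomial.n_terms - pos}

    def node_name(self, node: Node) -> str:
        kind, idx = node
        if kind == SPECIES:
            return self.network.species[idx - 1]
        return self.network.reactions[idx - 1].id

    def _loop_payload(self, c: Circuit) -> Dict[str, object]:
        return {
            "nodes": [self.node_name(v) for v in c.nodes],
            "edge_signs": ["+" if s > 0 else "-" for s in c.edge_signs],
            "species_count": c.species_count,
            "sign": c.sign,
            "signature": motif_signature(c),
        }

    def _nucleus_payload(self, D: Nucleus) -> Dict[str, object]:
        return {
            "sign": D.sign,
            "a1": D.a1,
            "a2": D.a2,
            "circuits": [self._loop_payload(c) for c in D.circuits],
        }

    def to_dict(self) -> Dict[str, object]:
        return {
            "schema_version": 1,
            "species": list(self.network.species),
            "reactions": list(self.network.reaction_ids),
            "rank": self.rank,
            "wrong_sign": wrong_sign(self.rank),
            "verdict": self.verdict.value,
            "term_counts": self.term_counts,
            "polynomial": self.polynomial.to_string(),
            "wrong_sign_terms": [
                {"monomial": [list(p) for p in key], "coefficient": str(c)}
                for key, c in self.wrong_terms
            ],
            "wrong_sign_nuclei": [
                {
                    "term": [list(p) for p in key],
                    "nuclei": [self._nucleus_payload(D) for D in nuclei],
                }
                for key, nuclei in self.wrong_nuclei
            ],
            "relevant_loops": [self._loop_payload(c) for c in self.relevant_loops],
            "all_positive_loops": [self._loop_payload(c) for c in self.all_positive_loops],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def _loop_line(self, c: Circuit) -> str:
        path = " -> ".join(self.node_name(v) for v in c.nodes)
        return f"{path} -> {self.node_name(c.nodes[0])}   signature {motif_signature(c)}"

    def to_text(self, all_loops: bool = False) -> str:
        counts = self.term_counts
        lines = [
            f"network: {self.network.n} species, {self.network.m} reactions",
            f"rank s = {self.rank}   wrong sign = {'+' if wrong_sign(self.rank) > 0 else '-'}",
            f"verdict: {self.verdict.value}",
            f"polynomial: {counts['positive']} positive / {counts['negative']} negative terms",
        ]
        if self.wrong_terms:
            lines.append("wrong-sign terms:")
            nuclei_by_key = dict(self.wrong_nuclei)
            for key, c in self.wrong_terms:
                body = "*".join(f"g[{i},{j}]" for i, j in key)
                kept = len(nuclei_by_key.get(key, ()))
                lines.append(f"  {c} * {body}   ({kept} wrong-sign nuclei)")
        else:
            lines.append("wrong-sign terms: none")
        if self.relevant_loops:
            lines.append(
                f"relevant positive feedback loops "
                f"({len(self.relevant_loops)} of {len(self.all_positive_loops)} positive loops):"
            )
            for c in self.relevant_loops:
                lines.append("  " + self._loop_line(c))
        else:
            lines.append("relevant positive feedback loops: none")
        if all_loops:
            lines.append("all positive feedback loops:")
            for c in self.all_positive_loops:
                lines.append("  " + self._loop_line(c))
        return "\n".join(lines) + "\n"


def find_relevant_loops(net: ReactionNetwork, Z: InfluenceMatrix) -> LoopReport:
    """Run the full procedure: wrong-sign terms of the injectivity
    polynomial -> their wrong-sign 2s-nuclei -> the positive circuits those
    nuclei contain (deduplicated).

    Loops are only extracted when the verdict is INCONCLUSIVE; an
    injective or degenerate network has no loops to blame.
    """
    A = stoichiometric_matrix(net)
    if (A.n, A.m) != (Z.n, Z.m):
        raise InfluenceError(
            f"shape mismatch: network is {A.n}x{A.m}, influence is {Z.n}x{Z.m}"
        )
    s = A.rank
    p = injectivity_polynomial(A, Z)
    verdict = injectivity_verdict(p, s)
    G = build_dsr_graph(A, Z)
    bad = wrong_sign(s)
    wrong = wrong_sign_terms(p, s)
    wrong_terms = tuple((monomial_key(m), c) for m, c in wrong)
    nuclei_rows: List[Tuple[Tuple[Pair, ...], Tuple[Nucleus, ...]]] = []
    loops: List[Circuit] = []
    if verdict is Verdict.INCONCLUSIVE:
        for m, _ in wrong:
            kept = tuple(D for D in nuclei_for_term(G, m) if D.sign == bad)
            nuclei_rows.append((monomial_key(m), kept))
            for D in kept:
                for c in D.circuits:
                    if c.sign > 0 and c not in loops:
                        loops.append(c)
    else:
        nuclei_rows = [(monomial_key(m), ()) for m, _ in wrong]
    loops.sort(key=Circuit.sort_key)
    all_pos = tuple(c for c in enumerate_circuits(G) if c.sign > 0)
    return LoopReport(
        network=net,
        rank=s,
        verdict=verdict,
        polynomial=p,
        wrong_terms=wrong_terms,
        wrong_nuclei=tuple(nuclei_rows),
        relevant_loops=tuple(loops),
        all_positive_loops=all_pos,
    )


def dsr_to_dot(G: nx.DiGraph, net: ReactionNetwork) -> str:
    """Render the signed graph in DOT; species are ellipses, reactions are
    boxes, negative edges are dashed and labelled '-'."""

    def name(node: Node) -> str:
        kind, idx = node
        label = net.species[idx - 1] if kind == SPECIES else net.reactions[idx - 1].id
        return label.replace('"', '\\"')

    lines = ["digraph dsr {", "  rankdir=LR;"]
    for i in range(1, G.graph["n"] + 1):
        lines.append(f'  "{name(species_node(i))}" [shape=ellipse];')
    for j in range(1, G.graph["m"] + 1):
        lines.append(f'  "{name(reaction_node(j))}" [shape=box];')
    for u, v, attrs in G.edges(data=True):
        sign = "+" if attrs["sign"] > 0 else "-"
        style = "solid" if attrs["sign"] > 0 else "dashed"
        lines.append(f'  "{name(u)}" -> "{name(v)}" [label="{sign}", style={style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
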