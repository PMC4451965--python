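"""Independent brute-force oracles, used only by the test suite.

Deliberately separate implementations: the permutation-sum determinant
enumerates permutations directly with an inversion-count parity, cycles
are enumerated by a plain DFS, and nuclei by filtering edge subsets.
None of this shares code with the package's optimized paths.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations


def brute_force_polynomial(A, basis, Z):
    """det of the row-replaced symbolic matrix as a dict {sorted-pairs: Fraction},
    computed as an explicit sum over permutations (zero entries pruned,
    parity from inversion counts)."""
    n, m = A.n, A.m
    # entry (i, k) is a list of addends (pair-or-None, Fraction)
    rows = []
    for i in range(n):
        row = []
        for k in range(n):
            addends = []
            for j in range(m):
                if A.entries[i][j] and Z.signs[k][j]:
                    addends.append(((k + 1, j + 1), Fraction(A.entries[i][j] * Z.signs[k][j])))
            row.append(addends)
        rows.append(row)
    for vec, pivot in zip(basis.vectors, basis.pivots):
        rows[pivot - 1] = [[(None, Fraction(v))] if v else [] for v in vec]

    acc: dict = {}

    def descend(r, used_cols, mono, coeff):
        if r == n:
            key = tuple(sorted(mono))
            acc[key] = acc.get(key, Fraction(0)) + coeff
            return
        for k in range(n):
            if k in used_cols:
                continue
            addends = rows[r][k]
            if not addends:
                continue
            inversions = sum(1 for c in used_cols if c > k)
            parity = -1 if inversions % 2 else 1
            for pair, c in addends:
                descend(
                    r + 1,
                    used_cols + [k],
                    mono + [pair] if pair is not None else mono,
                    coeff * c * parity,
                )

    descend(0, [], [], Fraction(1))
    return {key: c for key, c in acc.items() if c}


def poly_as_dict(p):
    """Package polynomial -> the oracle's dict representation."""
    return {tuple(sorted(mono)): c for mono, c in p.items()}


def dfs_simple_cycles(edges):
    """All elementary cycles of a digraph given as an edge set, as a set of
    canonically rotated node tuples.  Plain DFS: each cycle is rooted at
    its smallest node and only larger nodes may appear inside."""
    nodes = sorted({u for u, _ in edges} | {v for _, v in edges})
    adj = {u: sorted(v for (x, v) in edges if x == u) for u in nodes}
    found = set()

    def walk(root, path, on_path):
        for nxt in adj.get(path[-1], ()):
            if nxt == root:
                found.add(tuple(path))
            elif nxt > root and nxt not in on_path:
                walk(root, path + [nxt], on_path | {nxt})

    for root in nodes:
        walk(root, [root], {root})
    return found


def brute_force_nuclei(G, term, species_node, reaction_node):
    """All ways of adding len(term) reaction->species edges (chosen from the
    graph's full edge set by exhaustive subset filtering) so that the fixed
    influence edges close into a degree-1 digraph covering all nodes.
    Returns a set of frozensets of directed edges."""
    pairs = sorted(term)
    species = [species_node(i) for i, _ in pairs]
    reactions = sorted({reaction_node(j) for _, j in pairs})
    candidates = [
        (u, v)
        for u, v in G.edges
        if u in set(reactions) and v in set(species)
    ]
    fixed = [(species_node(i), reaction_node(j)) for i, j in pairs]
    results = set()
    for subset in combinations(candidates, len(pairs)):
        edge_set = list(fixed) + list(subset)
        outs = [u for u, _ in edge_set]
        ins = [v for _, v in edge_set]
        covered = set(outs) | set(ins)
        if (
            len(set(outs)) == len(edge_set)
            and len(set(ins)) == len(edge_set)
            and covered == set(species) | set(reactions)
        ):
            results.add(frozenset(edge_set))
    return results
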