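"""Exact injectivity analysis.

Builds the Gauss-reduced (RREF) basis of conservation laws, forms the
symbolic matrix obtained by replacing the corresponding pivot rows of
A @ Z^T with those basis vectors, expands its determinant exactly, and
classifies the resulting terms by sign.  A nonzero single-signed
polynomial certifies injectivity on every positive compatibility class,
which rules out multistationarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Dict, List, Tuple

import sympy

from .network import InfluenceError, InfluenceMatrix, StoichMatrix
from .polynomial import Monomial, SignPolynomial, monomial_key

__all__ = [
    "Verdict",
    "KernelBasis",
    "left_kernel_basis",
    "wrong_sign",
    "injectivity_polynomial",
    "wrong_sign_terms",
    "injectivity_verdict",
]


class Verdict(str, Enum):
    INJECTIVE = "INJECTIVE"          # nonzero, single-signed: no multistationarity
    INCONCLUSIVE = "INCONCLUSIVE"    # both signs present: multistationarity possible
    DEGENERATE = "DEGENERATE"        # polynomial identically zero

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class KernelBasis:
    """RREF basis of the left kernel of the stoichiometric matrix.

    ``vectors`` are rational rows with leading entry 1; ``pivots`` are the
    1-based positions of those leading entries, strictly increasing.
    """

    vectors: Tuple[Tuple[Fraction, ...], ...]
    pivots: Tuple[int, ...]

    @property
    def d(self) -> int:
        return len(self.vectors)


def left_kernel_basis(A: StoichMatrix) -> KernelBasis:
    """Reduced row echelon basis of {w : w @ A = 0}, over exact rationals."""
    mat = sympy.Matrix([list(row) for row in A.entries])
    null = mat.T.nullspace()
    if not null:
        return KernelBasis((), ())
    reduced, pivots = sympy.Matrix.hstack(*null).T.rref()
    vectors = tuple(
        tuple(_to_fraction(reduced[r, c]) for c in range(A.n))
        for r in range(len(pivots))
    )
    return KernelBasis(vectors, tuple(p + 1 for p in pivots))


def _to_fraction(value) -> Fraction:
    rat = sympy.Rational(value)
    return Fraction(int(rat.p), int(rat.q))


def wrong_sign(s: int) -> int:
    """The sign (-1)**(s+1); a term of this sign forces a positive loop."""
    return 1 if s % 2 else -1


def _symbolic_product_matrix(
    A: StoichMatrix, Z: InfluenceMatrix
) -> List[List[SignPolynomial]]:
    """Entry (i, k) of A @ Z^T as a linear form in the g[k+1, j+1]."""
    rows: List[List[SignPolynomial]] = []
    for i in range(A.n):
        row = []
        for k in range(A.n):
            terms: Dict[Monomial, Fraction] = {}
            for j in range(A.m):
                a = A.entries[i][j]
                z = Z.signs[k][j]
                if a and z:
                    terms[frozenset([(k + 1, j + 1)])] = Fraction(a * z)
            row.append(SignPolynomial(terms))
        rows.append(row)
    return rows


def _laplace_determinant(rows: List[List[SignPolynomial]]) -> SignPolynomial:
    """Determinant by Laplace expansion in row order, memoized on the set of
    still-available columns (the row index is determined by the popcount)."""
    n = len(rows)
    if n == 0:
        return SignPolynomial.constant(1)
    cache: Dict[int, SignPolynomial] = {}

    def minor(mask: int) -> SignPolynomial:
        if mask == 0:
            return SignPolynomial.constant(1)
        cached = cache.get(mask)
        if cached is not None:
            return cached
        r = n - bin(mask).count("1")
        acc = SignPolynomial.zero()
        sign = 1
        for k in range(n):
            bit = 1 << k
            if not mask & bit:
                continue
            entry = rows[r][k]
            if entry:
                acc = acc + (entry * minor(mask & ~bit)).scaled(sign)
            sign = -sign
        cache[mask] = acc
        return acc

    return minor((1 << n) - 1)


def injectivity_polynomial(A: StoichMatrix, Z: InfluenceMatrix) -> SignPolynomial:
    """The degree-s sign polynomial whose term signs decide injectivity.

    s = rank(A).  All arithmetic is exact; the empty polynomial is
    returned when the determinant vanishes identically.
    """
    if (A.n, A.m) != (Z.n, Z.m):
        raise InfluenceError(
            f"shape mismatch: stoichiometry is {A.n}x{A.m}, influence is {Z.n}x{Z.m}"
        )
    M = _symbolic_product_matrix(A, Z)
    basis = left_kernel_basis(A)
    for vec, pivot in zip(basis.vectors, basis.pivots):
        M[pivot - 1] = [SignPolynomial.constant(v) for v in vec]
    p = _laplace_determinant(M)
    for mono, _ in p.items():
        assert len(mono) == A.rank, "monomial degree must equal rank(A)"
        assert len({i for i, _ in mono}) == len(mono), "species indices must be distinct"
        assert len({j for _, j in mono}) == len(mono), "reaction indices must be distinct"
    return p


def wrong_sign_terms(p: SignPolynomial, s: int):
    """Terms of p whose coefficient sign is (-1)**(s+1), canonically ordered."""
    bad = wrong_sign(s)
    return [
        (m, c) for m, c in p.canonical_terms() if (1 if c > 0 else -1) == bad
    ]


def injectivity_verdict(p: SignPolynomial, s: int | None = None) -> Verdict:
    """Single-signed nonzero -> INJECTIVE; both signs -> INCONCLUSIVE;
    identically zero -> DEGENERATE."""
    if p.is_zero():
        return Verdict.DEGENERATE
    if len(p.signs()) == 1:
        return Verdict.INJECTIVE
    return Verdict.INCONCLUSIVE
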