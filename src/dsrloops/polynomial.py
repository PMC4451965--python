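"""Sparse exact multilinear polynomials in the influence variables g[i,j].

A monomial is a frozenset of 1-based (species, reaction) pairs; the
coefficient is an exact Fraction.  This is the carrier type for the
injectivity polynomial, where only term *signs* matter, so no floating
point is allowed anywhere on this path.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Tuple

Pair = Tuple[int, int]
Monomial = FrozenSet[Pair]

EMPTY_MONOMIAL: Monomial = frozenset()


def monomial_key(monomial: Iterable[Pair]) -> Tuple[Pair, ...]:
    """Canonical sort key / printable form of a monomial."""
    return tuple(sorted(monomial))


class SignPolynomial:
    """Immutable-ish sparse polynomial: monomial -> nonzero Fraction."""

    __slots__ = ("_terms",)

    def __init__(self, terms: Optional[Dict[Monomial, Fraction]] = None) -> None:
        self._terms: Dict[Monomial, Fraction] = {
            m: c for m, c in (terms or {}).items() if c
        }

    @classmethod
    def zero(cls) -> "SignPolynomial":
        return cls()

    @classmethod
    def constant(cls, value) -> "SignPolynomial":
        return cls({EMPTY_MONOMIAL: Fraction(value)})

    @classmethod
    def gamma(cls, i: int, j: int, coeff=1) -> "SignPolynomial":
        return cls({frozenset([(i, j)]): Fraction(coeff)})

    def items(self) -> Iterator[Tuple[Monomial, Fraction]]:
        return iter(self._terms.items())

    def canonical_terms(self) -> List[Tuple[Monomial, Fraction]]:
        """Terms sorted by canonical monomial order (deterministic)."""
        return sorted(self._terms.items(), key=lambda mc: monomial_key(mc[0]))

    def coefficient(self, monomial: Iterable[Pair]) -> Fraction:
        return self._terms.get(frozenset(monomial), Fraction(0))

    @property
    def n_terms(self) -> int:
        return len(self._terms)

    def degree(self) -> int:
        return max((len(m) for m in self._terms), default=0)

    def is_zero(self) -> bool:
        return not self._terms

    def __bool__(self) -> bool:
        return bool(self._terms)

    def signs(self) -> FrozenSet[int]:
        return frozenset(1 if c > 0 else -1 for c in self._terms.values())

    def __add__(self, other: "SignPolynomial") -> "SignPolynomial":
        out = dict(self._terms)
        for m, c in other._terms.items():
            out[m] = out.get(m, Fraction(0)) + c
        return SignPolynomial(out)

    def __neg__(self) -> "SignPolynomial":
        return SignPolynomial({m: -c for m, c in self._terms.items()})

    def __sub__(self, other: "SignPolynomial") -> "SignPolynomial":
        return self + (-other)

    def scaled(self, factor) -> "SignPolynomial":
        factor = Fraction(factor)
        return SignPolynomial({m: c * factor for m, c in self._terms.items()})

    def __mul__(self, other: "SignPolynomial") -> "SignPolynomial":
        out: Dict[Monomial, Fraction] = {}
        for m1, c1 in self._terms.items():
            for m2, c2 in other._terms.items():
                union = m1 | m2
                if len(union) != len(m1) + len(m2):
                    raise ValueError("monomials share a variable; product is not multilinear")
                out[union] = out.get(union, Fraction(0)) + c1 * c2
        return SignPolynomial(out)

    def without_gammas(self, pairs: Iterable[Pair]) -> "SignPolynomial":
        """Substitute g[i,j] = 0 for the given pairs (drops their monomials)."""
        drop = frozenset(pairs)
        return SignPolynomial({m: c for m, c in self._terms.items() if not (m & drop)})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignPolynomial):
            return NotImplemented
        return self._terms == other._terms

    __hash__ = None  # type: ignore[assignment]

    def to_string(self) -> str:
        """Render deterministically: terms in canonical order, variables as
        ``g[i,j]``, unit coefficients suppressed."""
        if not self._terms:
            return "0"
        parts: List[str] = []
        for m, c in self.canonical_terms():
            mag = abs(c)
            if m:
                body = "*".join(f"g[{i},{j}]" for i, j in monomial_key(m))
                term = body if mag == 1 else f"{mag}*{body}"
            else:
                term = str(mag)
            if not parts:
                parts.append(term if c > 0 else f"-{term}")
            else:
                parts.append(("+ " if c > 0 else "- ") + term)
        return " ".join(parts)

    def __repr__(self) -> str:
        return f"SignPolynomial({self.to_string()})"
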