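"""Four-symbol algebra for coupling strengths.

Every entry of a symbolic Jacobian, observability matrix or determinant
term is one of four symbols classifying how one state variable enters
another variable's equation:

====== ======= ==========================================================
symbol token   meaning
====== ======= ==========================================================
0      ``0``   the coupling is absent
1      ``1``   linear coupling (constant partial derivative)
1̄      ``1b``  nonlinear polynomial coupling, or a rational coupling whose
               denominator does not contain the differentiation variable
1̄̄      ``1bb`` rational coupling with the differentiation variable in the
               denominator
====== ======= ==========================================================

Products and sums of symbols follow explicit rewrite tables (below).
Both operations coincide with "take the most severe symbol", with 0
annihilating products; that shortcut is asserted in the test suite, but
the tables remain the source of truth.
"""

from __future__ import annotations

from enum import IntEnum

__all__ = ["ObsSymbol", "sym_mul", "sym_add", "ZERO", "ONE", "BAR", "DBL"]


class ObsSymbol(IntEnum):
    """Symbolic coupling strength, totally ordered by severity.

    The integer value doubles as the severity rank; :attr:`weight` is the
    in-strength weight used by the graph preselection criterion
    (1 for linear, 2 for polynomial, 3 for rational couplings).
    """

    ZERO = 0
    ONE = 1
    BAR = 2
    DBL = 3

    @property
    def weight(self) -> int:
        """In-strength weight: 0, 1, 2, 3 by increasing severity."""
        return int(self)

    @property
    def token(self) -> str:
        return _TOKENS[self]

    @classmethod
    def from_token(cls, token: str) -> "ObsSymbol":
        try:
            return _FROM_TOKEN[token.strip()]
        except KeyError:
            raise ValueError(
                f"unknown symbol token {token!r}; expected one of "
                f"{sorted(_FROM_TOKEN)}"
            ) from None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ObsSymbol.{self.name}"

    def __str__(self) -> str:
        return self.token


ZERO = ObsSymbol.ZERO
ONE = ObsSymbol.ONE
BAR = ObsSymbol.BAR
DBL = ObsSymbol.DBL

_TOKENS = {ZERO: "0", ONE: "1", BAR: "1b", DBL: "1bb"}
_FROM_TOKEN = {tok: sym for sym, tok in _TOKENS.items()}

# Product rewrite rules, extended to all ordered pairs by commutativity:
#   0 x a = 0
#   1 x a = a
#   1b x a = a        for a in {1b, 1bb}
#   1bb x a = 1bb     for a != 0
_MUL_TABLE = {
    (ZERO, ZERO): ZERO, (ZERO, ONE): ZERO, (ZERO, BAR): ZERO, (ZERO, DBL): ZERO,
    (ONE, ZERO): ZERO,  (ONE, ONE): ONE,   (ONE, BAR): BAR,   (ONE, DBL): DBL,
    (BAR, ZERO): ZERO,  (BAR, ONE): BAR,   (BAR, BAR): BAR,   (BAR, DBL): DBL,
    (DBL, ZERO): ZERO,  (DBL, ONE): DBL,   (DBL, BAR): DBL,   (DBL, DBL): DBL,
}

# Addition rewrite rules:
#   0 + a = a
#   1 + a = a         for a != 0
#   1b + a = a        for a not in {0, 1}
#   1bb + a = 1bb
_ADD_TABLE = {
    (ZERO, ZERO): ZERO, (ZERO, ONE): ONE,  (ZERO, BAR): BAR,  (ZERO, DBL): DBL,
    (ONE, ZERO): ONE,   (ONE, ONE): ONE,   (ONE, BAR): BAR,   (ONE, DBL): DBL,
    (BAR, ZERO): BAR,   (BAR, ONE): BAR,   (BAR, BAR): BAR,   (BAR, DBL): DBL,
    (DBL, ZERO): DBL,   (DBL, ONE): DBL,   (DBL, BAR): DBL,   (DBL, DBL): DBL,
}


def sym_mul(a: ObsSymbol, b: ObsSymbol) -> ObsSymbol:
    """Symbolic product of two coupling symbols.

    Zero annihilates; otherwise the more severe operand wins.
    """
    return _MUL_TABLE[a, b]


def sym_add(a: ObsSymbol, b: ObsSymbol) -> ObsSymbol:
    """Symbolic sum of two coupling symbols (the more severe one wins)."""
    return _ADD_TABLE[a, b]
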