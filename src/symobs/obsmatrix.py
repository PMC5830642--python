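"""Symbolic observability matrices.

A measurement configuration assigns to each measured variable ("sensor")
a coordinate count: the variable itself plus its successive time
derivatives.  A configuration written ``x2^2 x3 x5^2`` measures x2 with
its first derivative, x3 alone and x5 with its first derivative, for a
total of 5 reconstructed coordinates; the counts must sum to the system
dimension d.

For each sensor the construction emits a block of rows: the unit row
selecting the sensor itself, then the sensor's symbolic Jacobian row (the
first Lie derivative), then repeated symbolic propagation of the previous
row through the Jacobian for higher derivatives.  Stacking the blocks
yields the d x d symbolic observability matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigError, ContractError
from .models import SymbolicMatrix, SystemModel
from .semiring import ONE, ZERO, ObsSymbol, sym_add, sym_mul

__all__ = [
    "MeasurementConfig",
    "ObservabilityMatrix",
    "lie_row",
    "build_matrix",
]

_TOKEN = re.compile(r"^([A-Za-z_][A-Za-z_0-9]*)(?:\^(\d+))?$")


@dataclass(frozen=True)
class MeasurementConfig:
    """Sensors and their coordinate counts.

    ``entries`` holds ``(variable_index, count)`` pairs with 0-based
    variable indices, kept sorted by index (the canonical order).  A count
    of c means the variable plus its first c - 1 derivatives.
    """

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.entries:
            raise ConfigError("a measurement configuration cannot be empty")
        indices = [i for i, _ in self.entries]
        if len(set(indices)) != len(indices):
            raise ConfigError(f"duplicate sensor in configuration: {indices}")
        if any(i < 0 for i in indices):
            raise ConfigError("variable indices must be non-negative")
        if any(c < 1 for _, c in self.entries):
            raise ConfigError("coordinate counts must be >= 1")
        object.__setattr__(
            self, "entries", tuple(sorted(self.entries))
        )

    @property
    def m(self) -> int:
        """Number of measured variables."""
        return len(self.entries)

    @property
    def total(self) -> int:
        """Total number of reconstructed coordinates."""
        return sum(c for _, c in self.entries)

    @property
    def measured(self) -> frozenset[int]:
        return frozenset(i for i, _ in self.entries)

    # -- text form -----------------------------------------------------
    @classmethod
    def from_string(
        cls, text: str, variables: Sequence[str]
    ) -> "MeasurementConfig":
        """Parse ``"x2^2 x3 x5^2"`` against an ordered variable list."""
        entries = []
        tokens = text.split()
        if not tokens:
            raise ConfigError("empty configuration string")
        for token in tokens:
            match = _TOKEN.match(token)
            if not match:
                raise ConfigError(
                    f"bad token {token!r}; expected 'var' or 'var^k' with k >= 1"
                )
            name, count = match.group(1), int(match.group(2) or 1)
            if name not in variables:
                raise ConfigError(
                    f"unknown variable {name!r}; "
                    f"model variables are {', '.join(variables)}"
                )
            if count < 1:
                raise ConfigError(f"bad coordinate count in {token!r}")
            entries.append((list(variables).index(name), count))
        return cls(tuple(entries))

    def to_string(self, variables: Sequence[str]) -> str:
        parts = []
        for i, c in self.entries:
            parts.append(variables[i] if c == 1 else f"{variables[i]}^{c}")
        return " ".join(parts)

    def relabel(self, permutation: Sequence[int]) -> "MeasurementConfig":
        """Apply a variable permutation (new index = permutation[old])."""
        return MeasurementConfig(
            tuple((permutation[i], c) for i, c in self.entries)
        )


@dataclass(frozen=True)
class ObservabilityMatrix:
    """Stacked sensor blocks; ``block_index[r]`` is the (sensor index,
    derivative order) that produced row r."""

    matrix: SymbolicMatrix
    block_index: tuple[tuple[int, int], ...]


def lie_row(
    v: Sequence[ObsSymbol], J: SymbolicMatrix
) -> tuple[ObsSymbol, ...]:
    """Propagate a symbolic row one Lie-derivative order through J.

    Column j of the result is the symbolic sum over i of v_i (x) J_ij:
    the columnwise reduction of the Jacobian scaled row-by-row by v.
    """
    d = J.nrows
    if not J.is_square:
        raise ContractError(f"Jacobian must be square, got {J.shape}")
    v = tuple(v)
    if len(v) != d:
        raise ContractError(
            f"row length {len(v)} does not match Jacobian dimension {d}"
        )
    out = [ZERO] * d
    for i, v_i in enumerate(v):
        if v_i is ZERO:
            continue
        row = J.row(i)
        for j in range(d):
            entry = row[j]
            if entry is ZERO:
                continue
            out[j] = sym_add(out[j], sym_mul(v_i, entry))
    return tuple(out)


def unit_row(d: int, i: int) -> tuple[ObsSymbol, ...]:
    """The measurement row e_i: ONE at column i, ZERO elsewhere."""
    return tuple(ONE if j == i else ZERO for j in range(d))


def build_matrix(
    J: SymbolicMatrix, config: MeasurementConfig
) -> ObservabilityMatrix:
    """Build the symbolic observability matrix for a configuration.

    The sensor blocks are emitted in canonical (variable index) order;
    the determinant summary downstream is invariant under any row order.
    """
    if not J.is_square:
        raise ContractError(f"Jacobian must be square, got {J.shape}")
    d = J.nrows
    if any(i >= d for i, _ in config.entries):
        raise ConfigError(
            f"configuration refers to variable index beyond dimension {d}"
        )
    if config.total != d:
        raise ConfigError(
            f"coordinate counts sum to {config.total}, expected d = {d}"
        )
    rows: list[tuple[ObsSymbol, ...]] = []
    index: list[tuple[int, int]] = []
    for i, c in config.entries:
        current = unit_row(d, i)
        rows.append(current)
        index.append((i, 0))
        for order in range(1, c):
            current = J.row(i) if order == 1 else lie_row(current, J)
            rows.append(current)
            index.append((i, order))
    return ObservabilityMatrix(
        matrix=SymbolicMatrix(rows), block_index=tuple(index)
    )
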