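"""System models and symbolic Jacobian construction.

A :class:`SystemModel` holds an ordered list of state variables, the names
treated as constant parameters, optionally the right-hand sides of the ODEs
as sympy expressions, and the d x d symbolic Jacobian over the four-symbol
algebra.  When right-hand sides are given, the Jacobian is obtained by
symbolic differentiation followed by entrywise classification:

* identically zero partial             -> 0
* constant in all state variables      -> 1
* rational with the differentiation
  variable in the (cancelled) denominator -> 1bb
* anything else (non-constant polynomial, or rational whose denominator
  does not involve the differentiation variable) -> 1b

Only rational vector fields are supported; transcendental couplings are
rejected rather than guessed, since the symbol classes are defined for
polynomial and rational couplings only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import sympy
import yaml
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

from .errors import (
    ModelParseError,
    ModelSchemaError,
    UnsupportedModelError,
)
from .semiring import BAR, DBL, ONE, ZERO, ObsSymbol

__all__ = [
    "SymbolicMatrix",
    "SystemModel",
    "parse_model",
    "parse_expression",
    "classify_entry",
    "build_symbolic_jacobian",
    "linearize_symbols",
    "fixture",
]


class SymbolicMatrix:
    """Immutable rectangular matrix of :class:`ObsSymbol` entries."""

    __slots__ = ("_rows",)

    def __init__(self, rows: Iterable[Iterable[ObsSymbol]]):
        rows = tuple(tuple(ObsSymbol(entry) for entry in row) for row in rows)
        if not rows:
            raise ValueError("matrix must have at least one row")
        width = len(rows[0])
        if any(len(row) != width for row in rows):
            raise ValueError("matrix rows must all have the same length")
        if width == 0:
            raise ValueError("matrix must have at least one column")
        self._rows = rows

    # -- shape ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return len(self._rows)

    @property
    def ncols(self) -> int:
        return len(self._rows[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def is_square(self) -> bool:
        return self.nrows == self.ncols

    # -- access --------------------------------------------------------
    def __getitem__(self, index: tuple[int, int]) -> ObsSymbol:
        i, j = index
        return self._rows[i][j]

    def row(self, i: int) -> tuple[ObsSymbol, ...]:
        return self._rows[i]

    @property
    def rows(self) -> tuple[tuple[ObsSymbol, ...], ...]:
        return self._rows

    def __iter__(self):
        return iter(self._rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SymbolicMatrix):
            return NotImplemented
        return self._rows == other._rows

    def __hash__(self) -> int:
        return hash(self._rows)

    # -- serialization -------------------------------------------------
    def to_tokens(self) -> list[list[str]]:
        return [[entry.token for entry in row] for row in self._rows]

    @classmethod
    def from_tokens(cls, tokens: Sequence[Sequence[str]]) -> "SymbolicMatrix":
        return cls(
            [[ObsSymbol.from_token(tok) for tok in row] for row in tokens]
        )

    def __repr__(self) -> str:
        body = "\n".join(
            " ".join(f"{entry.token:>3}" for entry in row)
            for row in self._rows
        )
        return f"SymbolicMatrix {self.nrows}x{self.ncols}\n{body}"


@dataclass(frozen=True)
class SystemModel:
    """A d-dimensional ODE system abstracted to its symbolic Jacobian.

    Parameters never take part in the symbol classification: any free name
    in the right-hand sides that is not declared a state variable is a
    constant.
    """

    name: str
    variables: tuple[str, ...]
    parameters: tuple[str, ...] = ()
    rhs: tuple[sympy.Expr, ...] | None = None
    jacobian: SymbolicMatrix = None  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(set(self.variables)) != len(self.variables):
            raise ModelSchemaError(f"duplicate state variables in {self.name!r}")
        overlap = set(self.variables) & set(self.parameters)
        if overlap:
            raise ModelSchemaError(
                f"names {sorted(overlap)} declared both variable and parameter"
            )
        if self.rhs is not None and len(self.rhs) != self.d:
            raise ModelSchemaError(
                f"model {self.name!r}: {len(self.rhs)} equations for "
                f"{self.d} variables"
            )
        if self.jacobian is None:
            raise ModelSchemaError(f"model {self.name!r} has no Jacobian")
        if self.jacobian.shape != (self.d, self.d):
            raise ModelSchemaError(
                f"model {self.name!r}: Jacobian shape {self.jacobian.shape} "
                f"does not match dimension {self.d}"
            )

    @property
    def d(self) -> int:
        return len(self.variables)

    def variable_index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise ModelSchemaError(
                f"{name!r} is not a state variable of {self.name!r}"
            ) from None

    @property
    def state_symbols(self) -> tuple[sympy.Symbol, ...]:
        return tuple(sympy.Symbol(v) for v in self.variables)


_IDENT = re.compile(r"[A-Za-z_][A-Za-z_0-9]*")
_TRANSFORMS = standard_transformations + (convert_xor,)


def parse_expression(text: str, variables: Sequence[str]) -> sympy.Expr:
    """Parse one right-hand-side expression.

    ``^`` denotes power.  Identifiers that are not immediately applied as
    functions become sympy symbols, so parameter names such as ``I`` or
    ``E`` are never captured by sympy built-ins; applied functions (e.g.
    ``exp(...)``) are left to sympy and rejected later by the rational
    classification.
    """
    local: dict[str, sympy.Symbol] = {v: sympy.Symbol(v) for v in variables}
    for match in _IDENT.finditer(text):
        name = match.group(0)
        rest = text[match.end():].lstrip()
        if rest.startswith("("):  # looks like a function application
            continue
        local.setdefault(name, sympy.Symbol(name))
    try:
        expr = parse_expr(text, local_dict=local, transformations=_TRANSFORMS)
    except Exception as exc:
        raise ModelParseError(f"cannot parse expression {text!r}: {exc}") from exc
    if not isinstance(expr, sympy.Expr):
        raise ModelParseError(f"expression {text!r} is not a scalar expression")
    return expr


def classify_entry(
    derivative_expr: sympy.Expr,
    xj: sympy.Symbol | str,
    state_vars: Sequence[sympy.Symbol | str],
) -> ObsSymbol:
    """Classify one Jacobian entry ``d f_i / d x_j`` into a symbol.

    The expression is first brought to a canonical ratio of polynomials
    (common factors cancelled); the rational class then depends on whether
    ``x_j`` survives in the canonical denominator.
    """
    xj = sympy.Symbol(xj) if isinstance(xj, str) else xj
    states = tuple(
        sympy.Symbol(v) if isinstance(v, str) else v for v in state_vars
    )
    expr = sympy.sympify(derivative_expr)
    present = [s for s in states if s in expr.free_symbols]
    if not present:
        # constant in every state variable (possibly identically zero)
        return ZERO if expr.is_zero else ONE
    if not expr.is_rational_function(*present):
        raise UnsupportedModelError(
            f"entry {expr} is not a rational function of the state variables"
        )
    canonical = sympy.cancel(sympy.together(expr))
    if canonical.is_zero:
        return ZERO
    if not any(s in canonical.free_symbols for s in states):
        return ONE
    _, denom = canonical.as_numer_denom()
    if xj in denom.free_symbols:
        return DBL
    return BAR


def build_symbolic_jacobian(model: SystemModel) -> SymbolicMatrix:
    """Differentiate the right-hand sides and classify every entry."""
    if model.rhs is None:
        raise ModelSchemaError(
            f"model {model.name!r} has no right-hand sides to differentiate"
        )
    states = model.state_symbols
    rows = []
    for i, f_i in enumerate(model.rhs):
        row = []
        for j, xj in enumerate(states):
            try:
                row.append(classify_entry(sympy.diff(f_i, xj), xj, states))
            except UnsupportedModelError as exc:
                raise UnsupportedModelError(
                    f"entry ({i + 1},{j + 1}) of {model.name!r}: {exc}"
                ) from exc
        rows.append(row)
    return SymbolicMatrix(rows)


def linearize_symbols(J: SymbolicMatrix) -> SymbolicMatrix:
    """Replace every nonzero entry by 1 (linear-theory comparison mode)."""
    return SymbolicMatrix(
        [[ONE if entry is not ZERO else ZERO for entry in row] for row in J]
    )


def _model_from_mapping(doc: dict, source: str = "<document>") -> SystemModel:
    if not isinstance(doc, dict):
        raise ModelSchemaError(f"{source}: model document must be a mapping")
    unknown = set(doc) - {"name", "variables", "equations", "jacobian"}
    if unknown:
        raise ModelSchemaError(f"{source}: unknown fields {sorted(unknown)}")
    try:
        variables = tuple(str(v) for v in doc["variables"])
    except KeyError:
        raise ModelSchemaError(f"{source}: missing 'variables'") from None
    if len(set(variables)) != len(variables):
        raise ModelSchemaError(f"{source}: duplicate variable names")
    name = str(doc.get("name", "model"))

    has_eq = "equations" in doc
    has_jac = "jacobian" in doc
    if has_eq == has_jac:
        raise ModelSchemaError(
            f"{source}: provide exactly one of 'equations' or 'jacobian'"
        )

    if has_eq:
        equations = doc["equations"]
        if len(equations) != len(variables):
            raise ModelSchemaError(
                f"{source}: {len(equations)} equations for "
                f"{len(variables)} variables"
            )
        rhs = []
        for lineno, text in enumerate(equations, start=1):
            try:
                rhs.append(parse_expression(str(text), variables))
            except ModelParseError as exc:
                raise ModelParseError(f"{source}: equation {lineno}: {exc}") from exc
        rhs = tuple(rhs)
        free = set().union(*(e.free_symbols for e in rhs)) if rhs else set()
        parameters = tuple(
            sorted(str(s) for s in free if str(s) not in variables)
        )
        draft = SystemModel(
            name=name,
            variables=variables,
            parameters=parameters,
            rhs=rhs,
            jacobian=SymbolicMatrix(
                [[ZERO] * len(variables) for _ in variables]
            ),
        )
        jac = build_symbolic_jacobian(draft)
        return SystemModel(
            name=name,
            variables=variables,
            parameters=parameters,
            rhs=rhs,
            jacobian=jac,
        )

    tokens = doc["jacobian"]
    d = len(variables)
    if len(tokens) != d or any(len(row) != d for row in tokens):
        raise ModelSchemaError(
            f"{source}: jacobian must be a {d}x{d} token matrix"
        )
    try:
        jac = SymbolicMatrix.from_tokens(tokens)
    except ValueError as exc:
        raise ModelSchemaError(f"{source}: {exc}") from exc
    return SystemModel(
        name=name, variables=variables, parameters=(), rhs=None, jacobian=jac
    )


def parse_model(document: str) -> SystemModel:
    """Parse a model description (YAML or JSON text) into a SystemModel.

    The document has fields ``name``, ``variables`` (ordered list) and
    either ``equations`` (ordered list of expression strings) or
    ``jacobian`` (list of lists of tokens ``0``/``1``/``1b``/``1bb``).
    """
    try:
        doc = yaml.safe_load(document)
    except yaml.YAMLError as exc:
        raise ModelParseError(f"invalid model document: {exc}") from exc
    return _model_from_mapping(doc)


def fixture(name: str, jacobian_variant: str = "derived") -> SystemModel:
    """Return one of the bundled benchmark models by name.

    See :mod:`symobs.fixtures` for the available names.
    """
    from . import fixtures

    return fixtures.fixture(name, jacobian_variant=jacobian_variant)
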