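"""Seeded generation of synthetic systems for property testing.

``random_symbol_matrix`` draws a coupling-symbol matrix with a given
off-diagonal density and a mixture over the three nonzero symbol classes;
``realize_odes`` constructs a rational vector field whose classified
Jacobian is exactly that matrix.  The central property is the round trip

    build_symbolic_jacobian(realize_odes(J)) == J

which exercises differentiation, cancellation and classification against
a known ground truth without any external data.

Realisation recipe per entry (i, j), with fresh positive parameters:

* linear      ->  c * x_j
* polynomial  ->  c * x_j^2      (derivative 2*c*x_j, a non-constant
                                  polynomial touching no other column)
* rational    ->  c * x_j / (K + x_j)   (derivative c*K/(K + x_j)^2)

Generated systems make no claim to dynamical realism (stability,
attractors); they exist to pin down the classification algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy

from .models import SymbolicMatrix, SystemModel
from .semiring import BAR, DBL, ONE, ZERO, ObsSymbol

__all__ = ["GeneratorSpec", "random_symbol_matrix", "realize_odes"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random symbol-matrix ensemble.

    ``density`` is the probability that an off-diagonal entry is nonzero;
    ``weights`` is the mixture over (linear, polynomial, rational) for
    nonzero entries; the diagonal is always nonzero, mirroring the
    damping/decay terms every fixture equation carries.
    """

    d: int
    density: float = 0.3
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0
    ensure_connected: bool = False

    def __post_init__(self):
        if self.d < 2:
            raise ValueError("d must be >= 2")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if len(self.weights) != 3 or any(w < 0 for w in self.weights):
            raise ValueError("weights must be three non-negative numbers")
        if abs(sum(self.weights) - 1) > 1e-9:
            raise ValueError("weights must sum to 1")


_NONZERO = (ONE, BAR, DBL)


def random_symbol_matrix(spec: GeneratorSpec) -> SymbolicMatrix:
    """Draw a d x d symbol matrix; identical seed, identical matrix."""
    rng = np.random.default_rng(spec.seed)
    d = spec.d
    rows = []
    for i in range(d):
        row = []
        for j in range(d):
            if i == j or rng.random() < spec.density:
                row.append(_NONZERO[rng.choice(3, p=spec.weights)])
            else:
                row.append(ZERO)
        rows.append(row)
    if spec.ensure_connected:
        # guarantee a directed cycle through all variables so no variable
        # is dynamically isolated
        for i in range(d):
            j = (i + 1) % d
            if rows[i][j] is ZERO:
                rows[i][j] = _NONZERO[rng.choice(3, p=spec.weights)]
    return SymbolicMatrix(rows)


def realize_odes(J: SymbolicMatrix, name: str = "synthetic") -> SystemModel:
    """Construct a rational ODE system whose classified Jacobian equals J."""
    if not J.is_square:
        raise ValueError(f"matrix must be square, got {J.shape}")
    d = J.nrows
    variables = tuple(f"x{i + 1}" for i in range(d))
    states = [sympy.Symbol(v) for v in variables]
    parameters: list[str] = []
    rhs = []
    for i in range(d):
        terms = []
        for j in range(d):
            entry = J[i, j]
            if entry is ZERO:
                continue
            c = sympy.Symbol(f"c_{i + 1}_{j + 1}")
            parameters.append(c.name)
            if entry is ONE:
                terms.append(c * states[j])
            elif entry is BAR:
                terms.append(c * states[j] ** 2)
            else:  # DBL
                K = sympy.Symbol(f"K_{i + 1}_{j + 1}")
                parameters.append(K.name)
                terms.append(c * states[j] / (K + states[j]))
        rhs.append(sympy.Add(*terms) if terms else sympy.Integer(0))
    return SystemModel(
        name=name,
        variables=variables,
        parameters=tuple(sorted(parameters)),
        rhs=tuple(rhs),
        jacobian=J,
    )


def model_document(model: SystemModel) -> str:
    """Serialize a generated model in the standard model-file format."""
    lines = [f"name: {model.name}", "variables: [" + ", ".join(model.variables) + "]"]
    if model.rhs is not None:
        lines.append("equations:")
        for expr in model.rhs:
            text = sympy.sstr(expr).replace("**", "^")
            lines.append(f'  - "{text}"')
    else:
        lines.append("jacobian:")
        for row in model.jacobian.to_tokens():
            lines.append("  - [" + ", ".join(f'"{tok}"' for tok in row) + "]")
    return "\n".join(lines) + "\n"
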