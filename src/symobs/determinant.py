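"""Symbolic determinant summaries and the observability coefficient.

The symbolic determinant of a d x d symbol matrix is the multiset of its
nonzero permutation products, with no sign bookkeeping and hence no
cancellation: each permutation avoiding a 0 entry contributes one term of
d symbols.  Only aggregate statistics are needed downstream, collected in
:class:`DetSummary`: the term count T and the total occurrences N1, Nbar,
Ndbl of the symbols 1, 1b, 1bb across all terms.

The observability coefficient maps a summary to a scalar in [0, 1]:

    eta = N1 / D + Nbar / D^2 + Ndbl / D^3,   D = max(1, N1) + Nbar + Ndbl

with the rational-system condition applied first: if Nbar = 0 and
Ndbl > 0, Nbar is set equal to Ndbl, so purely rational nonlinearity is
penalised at both the quadratic and cubic level.  eta = 1 exactly when
every term is purely linear (and at least one term exists); eta = 0 when
the matrix is structurally singular (no nonzero permutation).

All arithmetic is exact rational; rounding to the conventional two
decimals happens only at reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations

from .errors import ContractError
from .models import SymbolicMatrix, SystemModel
from .obsmatrix import MeasurementConfig, ObservabilityMatrix, build_matrix
from .semiring import BAR, DBL, ONE, ZERO

__all__ = [
    "DetSummary",
    "CoefficientResult",
    "det_summary_bruteforce",
    "det_summary",
    "observability_coefficient",
    "coefficient_for",
    "round_half_up_2dp",
]

_BRUTEFORCE_LIMIT = 8


@dataclass(frozen=True)
class DetSummary:
    """Term count and per-symbol occurrence totals of a symbolic determinant."""

    T: int
    n1: int
    nbar: int
    ndbl: int

    def __post_init__(self):
        if min(self.T, self.n1, self.nbar, self.ndbl) < 0:
            raise ValueError("summary fields must be non-negative")


@dataclass(frozen=True)
class CoefficientResult:
    """Exact observability coefficient with its provenance."""

    eta: Fraction
    eta_2dp: float
    summary: DetSummary
    D: int

    def as_record(self, config_str: str | None = None) -> dict:
        record = {
            "eta_exact": f"{self.eta.numerator}/{self.eta.denominator}",
            "eta_2dp": self.eta_2dp,
            "T": self.summary.T,
            "N1": self.summary.n1,
            "Nbar": self.summary.nbar,
            "Ndblbar": self.summary.ndbl,
            "D": self.D,
        }
        if config_str is not None:
            record = {"config": config_str, **record}
        return record


def det_summary_bruteforce(M: SymbolicMatrix) -> DetSummary:
    """Enumerate all d! permutations (test oracle, d <= 8 only)."""
    if not M.is_square:
        raise ContractError(f"matrix must be square, got {M.shape}")
    d = M.nrows
    if d > _BRUTEFORCE_LIMIT:
        raise ContractError(
            f"brute-force enumeration is limited to d <= {_BRUTEFORCE_LIMIT}"
        )
    T = n1 = nbar = ndbl = 0
    rows = M.rows
    for perm in permutations(range(d)):
        c1 = cb = cd = 0
        for i, j in enumerate(perm):
            entry = rows[i][j]
            if entry is ZERO:
                break
            elif entry is ONE:
                c1 += 1
            elif entry is BAR:
                cb += 1
            else:
                cd += 1
        else:
            T += 1
            n1 += c1
            nbar += cb
            ndbl += cd
    return DetSummary(T=T, n1=n1, nbar=nbar, ndbl=ndbl)


def det_summary(M: SymbolicMatrix) -> DetSummary:
    """Permanent-style dynamic programme over column subsets.

    Rows are processed in ascending sparsity (the summary is invariant
    under row order) and the state space is the set of used-column
    bitmasks, carrying (term count, occurrence totals) per state.  Worst
    case d * 2^d states; structured observability matrices with many unit
    rows stay far below that.
    """
    if not M.is_square:
        raise ContractError(f"matrix must be square, got {M.shape}")
    # (col, symbol) pairs per row, sparsest rows first
    sparse_rows = sorted(
        (
            [(j, entry) for j, entry in enumerate(row) if entry is not ZERO]
            for row in M.rows
        ),
        key=len,
    )
    # state: mask of used columns -> [T, n1, nbar, ndbl]
    states: dict[int, list[int]] = {0: [1, 0, 0, 0]}
    for row in sparse_rows:
        if not row:
            return DetSummary(0, 0, 0, 0)
        nxt: dict[int, list[int]] = {}
        for mask, (t, a, b, c) in states.items():
            for j, entry in row:
                bit = 1 << j
                if mask & bit:
                    continue
                acc = nxt.get(mask | bit)
                if acc is None:
                    acc = [0, 0, 0, 0]
                    nxt[mask | bit] = acc
                acc[0] += t
                acc[1] += a + (t if entry is ONE else 0)
                acc[2] += b + (t if entry is BAR else 0)
                acc[3] += c + (t if entry is DBL else 0)
        if not nxt:
            return DetSummary(0, 0, 0, 0)
        states = nxt
    total = [0, 0, 0, 0]
    for acc in states.values():
        for k in range(4):
            total[k] += acc[k]
    return DetSummary(T=total[0], n1=total[1], nbar=total[2], ndbl=total[3])


def round_half_up_2dp(value: Fraction) -> float:
    """Round an exact rational to 2 decimals, halves away from zero."""
    if value < 0:
        return -round_half_up_2dp(-value)
    scaled = value * 100
    q, r = divmod(scaled.numerator, scaled.denominator)
    cents = q + (1 if 2 * r >= scaled.denominator else 0)
    return cents / 100


def observability_coefficient(summary: DetSummary) -> CoefficientResult:
    """Map a determinant summary to the coefficient eta in [0, 1]."""
    if summary.T == 0:
        return CoefficientResult(
            eta=Fraction(0), eta_2dp=0.0, summary=summary, D=1
        )
    n1, nbar, ndbl = summary.n1, summary.nbar, summary.ndbl
    if nbar == 0 and ndbl > 0:
        nbar = ndbl  # rational-system condition
    D = max(1, n1) + nbar + ndbl
    eta = (
        Fraction(n1, D)
        + Fraction(nbar, D**2)
        + Fraction(ndbl, D**3)
    )
    if not 0 <= eta <= 1:
        raise AssertionError(f"eta = {eta} escaped [0, 1]")  # pragma: no cover
    return CoefficientResult(
        eta=eta, eta_2dp=round_half_up_2dp(eta), summary=summary, D=D
    )


def coefficient_for(
    model: SystemModel, config: MeasurementConfig | str
) -> CoefficientResult:
    """Full pipeline: observability matrix, determinant summary, eta."""
    if isinstance(config, str):
        config = MeasurementConfig.from_string(config, model.variables)
    obs: ObservabilityMatrix = build_matrix(model.jacobian, config)
    return observability_coefficient(det_summary(obs.matrix))
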