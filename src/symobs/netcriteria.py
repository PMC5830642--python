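"""Graph criteria on the symbolic Jacobian and sensor preselection.

Two cheap structural criteria narrow the sensor search before any
observability matrix is built:

* the linear out-strength of variable i counts the other equations in
  which x_i appears linearly; a variable with zero linear out-strength is
  essential (it must be measured, since no other variable sees it
  linearly);
* the non-measured in-strength of variable i sums the severity weights
  (linear 1, polynomial 2, rational 3) of the couplings it receives from
  the candidate non-measured variables; among two otherwise equivalent
  candidates the one with the larger in-strength is preferred for
  removal, because its equation drags more nonlinearity into the
  determinant.

Two candidates that are mutually coupled purely linearly and linearly
seen by nobody else form an exclusive pair: at least one of them must be
measured.  Preselection removes the heavier member of every pair, removes
every unpaired candidate, branches on exact in-strength ties, and retains
any variable whose removal would leave it invisible from every measured
equation (reachability check).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .errors import ContractError
from .models import SymbolicMatrix, SystemModel
from .semiring import ONE, ZERO

__all__ = [
    "PreselectionReport",
    "linear_out_strength",
    "nonmeasured_in_strength",
    "exclusive_pairs",
    "preselect",
]


@dataclass(frozen=True)
class PreselectionReport:
    """Outcome of the two-criteria preselection (0-based variable indices).

    One entry of ``sensor_sets``/``removed`` per branch: ties in the pair
    resolution are not broken arbitrarily but enumerated.
    """

    sigma_out_lin: tuple[int, ...]
    essential: frozenset[int]
    removable: frozenset[int]
    exclusive_pairs: frozenset[frozenset[int]]
    sigma_in_nm: dict[int, int]
    removed: tuple[frozenset[int], ...]
    sensor_sets: tuple[frozenset[int], ...]
    reachability_check: tuple[dict[int, bool], ...]
    variables: tuple[str, ...] = field(default=(), compare=False)

    def sensor_names(self) -> list[list[str]]:
        return [
            sorted((self.variables[i] for i in s), key=self.variables.index)
            for s in self.sensor_sets
        ]

    def as_document(self) -> dict:
        """Serializable report keyed by variable names."""
        names = self.variables

        def name_set(indices) -> list[str]:
            return [names[i] for i in sorted(indices)]

        return {
            "sigma_out_lin": {
                names[i]: s for i, s in enumerate(self.sigma_out_lin)
            },
            "essential": name_set(self.essential),
            "removable": name_set(self.removable),
            "exclusive_pairs": [name_set(p) for p in
                                sorted(self.exclusive_pairs, key=sorted)],
            "sigma_in_nm": {
                names[i]: s for i, s in sorted(self.sigma_in_nm.items())
            },
            "branches": [
                {
                    "sensors": name_set(sensors),
                    "removed": name_set(removed),
                    "reachability": {
                        names[i]: ok for i, ok in sorted(check.items())
                    },
                }
                for sensors, removed, check in zip(
                    self.sensor_sets, self.removed, self.reachability_check
                )
            ],
        }


def linear_out_strength(J: SymbolicMatrix) -> tuple[int, ...]:
    """Number of *other* equations in which each variable appears linearly."""
    if not J.is_square:
        raise ContractError(f"Jacobian must be square, got {J.shape}")
    d = J.nrows
    return tuple(
        sum(1 for j in range(d) if j != i and J[j, i] is ONE)
        for i in range(d)
    )


def nonmeasured_in_strength(
    J: SymbolicMatrix, Vnm: frozenset[int] | set[int]
) -> dict[int, int]:
    """Severity-weighted in-strength received from the candidate set.

    Returns the strength for every variable of the system; the criterion
    only consults it on the candidates themselves.
    """
    if not J.is_square:
        raise ContractError(f"Jacobian must be square, got {J.shape}")
    if not Vnm:
        raise ContractError("the candidate non-measured set must be non-empty")
    d = J.nrows
    if any(k < 0 or k >= d for k in Vnm):
        raise ContractError(f"candidate indices out of range for d = {d}")
    return {
        i: sum(J[i, k].weight for k in Vnm if k != i)
        for i in range(d)
    }


def exclusive_pairs(
    J: SymbolicMatrix,
    candidates: frozenset[int] | set[int],
    sigma: tuple[int, ...] | list[int],
) -> frozenset[frozenset[int]]:
    """Pairs {i, j} of candidates that are exclusively linearly coupled.

    Both off-diagonal entries must be linear and both variables must have
    linear out-strength exactly 1 (their only linear appearance is in
    each other's equation), so at least one of them must be measured.
    """
    pairs = set()
    for i in candidates:
        for j in candidates:
            if (
                i < j
                and J[i, j] is ONE
                and J[j, i] is ONE
                and sigma[i] == 1
                and sigma[j] == 1
            ):
                pairs.add(frozenset((i, j)))
    return frozenset(pairs)


def preselect(model: SystemModel) -> PreselectionReport:
    """Apply both criteria and enumerate the minimal sensor sets.

    The candidate non-measured set for the in-strength computation is the
    full removable set, before any pair is resolved.
    """
    J = model.jacobian
    d = model.d
    sigma = linear_out_strength(J)
    essential = frozenset(i for i in range(d) if sigma[i] == 0)
    removable = frozenset(range(d)) - essential

    if not removable:
        sensors = frozenset(range(d))
        return PreselectionReport(
            sigma_out_lin=sigma,
            essential=essential,
            removable=removable,
            exclusive_pairs=frozenset(),
            sigma_in_nm={},
            removed=(frozenset(),),
            sensor_sets=(sensors,),
            reachability_check=({},),
            variables=model.variables,
        )

    sigma_in = nonmeasured_in_strength(J, removable)
    pairs = exclusive_pairs(J, removable, sigma)
    paired = frozenset(i for pair in pairs for i in pair)
    always_removed = removable - paired

    # one removal choice per pair: the member with the larger in-strength
    # must not be measured; exact ties branch on either member
    choices_per_pair: list[tuple[int, ...]] = []
    for pair in sorted(pairs, key=sorted):
        i, j = sorted(pair)
        if sigma_in[i] > sigma_in[j]:
            choices_per_pair.append((i,))
        elif sigma_in[j] > sigma_in[i]:
            choices_per_pair.append((j,))
        else:
            choices_per_pair.append((i, j))

    removed_branches: list[frozenset[int]] = []
    sensor_branches: list[frozenset[int]] = []
    checks: list[dict[int, bool]] = []
    for choice in product(*choices_per_pair) if choices_per_pair else ((),):
        removed = set(always_removed) | set(choice)
        sensors = set(range(d)) - removed
        # reachability: a removed variable must appear in the equation of
        # at least one measured variable, otherwise it is retained
        check: dict[int, bool] = {}
        for k in sorted(removed):
            check[k] = any(J[s, k] is not ZERO for s in sensors)
        for k, ok in check.items():
            if not ok:
                removed.discard(k)
                sensors.add(k)
        removed_branches.append(frozenset(removed))
        sensor_branches.append(frozenset(sensors))
        checks.append(check)

    # deduplicate branches that collapsed to the same sensor set
    seen: dict[frozenset[int], int] = {}
    keep = []
    for idx, sensors in enumerate(sensor_branches):
        if sensors not in seen:
            seen[sensors] = idx
            keep.append(idx)

    return PreselectionReport(
        sigma_out_lin=sigma,
        essential=essential,
        removable=removable,
        exclusive_pairs=pairs,
        sigma_in_nm={i: sigma_in[i] for i in sorted(removable)},
        removed=tuple(removed_branches[i] for i in keep),
        sensor_sets=tuple(sensor_branches[i] for i in keep),
        reachability_check=tuple(checks[i] for i in keep),
        variables=model.variables,
    )
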