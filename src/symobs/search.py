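"""Enumeration and ranking of reconstruction configurations.

A reconstruction configuration chooses m measured variables and assigns
each a coordinate count >= 1 with counts summing to d, so for a given m
there are C(d, m) * C(d-1, m-1) configurations; summed over the default
range m = 1 .. d-1 this gives 125 configurations at d = 5, 24309 at
d = 9 and about 5.2e6 at d = 13.  The full-measurement configuration
(m = d, no derivatives) is excluded from the default range.

Strategies:

* ``evaluate`` scores every enumerated configuration;
* ``leave_one_out_scan`` scores the d * (d-1) configurations that measure
  everything except one variable, with one first derivative added;
* ``reduced_search`` restricts enumeration to configurations containing
  every essential variable and at least one member of each exclusive
  pair, as determined by preselection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterator, Sequence

import pandas as pd

from .determinant import CoefficientResult, coefficient_for
from .errors import ContractError
from .models import SystemModel
from .netcriteria import PreselectionReport
from .obsmatrix import MeasurementConfig

__all__ = [
    "SearchSpec",
    "RankedResults",
    "count_configs",
    "enumerate_configs",
    "evaluate",
    "leave_one_out_scan",
    "reduced_search",
]

logger = logging.getLogger(__name__)

GOOD_OBSERVABILITY = 0.75  # conventional threshold for "good" observability


@dataclass(frozen=True)
class SearchSpec:
    """What to enumerate and what to keep.

    ``m_range`` bounds the number of measured variables (inclusive); the
    default ``None`` bounds mean 1 .. d-1.  ``min_eta`` is the reporting
    threshold; set ``retain_all`` to keep every evaluated configuration.
    ``required``/``forbidden`` constrain the measured set (0-based
    indices).
    """

    strategy: str = "exhaustive"
    m_min: int | None = None
    m_max: int | None = None
    max_count: int | None = None
    min_eta: float = GOOD_OBSERVABILITY
    required: frozenset[int] = frozenset()
    forbidden: frozenset[int] = frozenset()
    retain_all: bool = False

    def resolved_m_range(self, d: int) -> tuple[int, int]:
        m_min = 1 if self.m_min is None else self.m_min
        m_max = d - 1 if self.m_max is None else self.m_max
        if not 1 <= m_min <= m_max <= d:
            raise ContractError(
                f"invalid m range [{m_min}, {m_max}] for d = {d}"
            )
        return m_min, m_max


@dataclass(frozen=True)
class RankedResults:
    """Configurations sorted by eta (desc), then m (asc), then name."""

    results: tuple[tuple[MeasurementConfig, CoefficientResult], ...]
    provenance: dict = field(default_factory=dict, compare=False)
    variables: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for config, coeff in self.results:
            record = coeff.as_record(config.to_string(self.variables))
            record["m"] = config.m
            record["total"] = config.total
            rows.append(record)
        columns = [
            "config", "m", "total", "eta_exact", "eta_2dp",
            "T", "N1", "Nbar", "Ndblbar", "D",
        ]
        return pd.DataFrame(rows, columns=columns)


def count_configs(
    d: int, m_range: tuple[int, int] | None = None
) -> int:
    """Closed-form count of configurations: sum of C(d,m) * C(d-1,m-1)."""
    if d < 2:
        raise ContractError("counting requires d >= 2")
    m_min, m_max = (1, d - 1) if m_range is None else m_range
    if not 1 <= m_min <= m_max <= d:
        raise ContractError(f"invalid m range [{m_min}, {m_max}] for d = {d}")
    return sum(
        math.comb(d, m) * math.comb(d - 1, m - 1)
        for m in range(m_min, m_max + 1)
    )


def _compositions(total: int, parts: int, max_part: int | None) -> Iterator[tuple[int, ...]]:
    """All ways to write ``total`` as ``parts`` ordered integers >= 1."""
    if parts == 1:
        if total >= 1 and (max_part is None or total <= max_part):
            yield (total,)
        return
    upper = total - (parts - 1)
    if max_part is not None:
        upper = min(upper, max_part)
    for first in range(1, upper + 1):
        for rest in _compositions(total - first, parts - 1, max_part):
            yield (first,) + rest


def enumerate_configs(
    d: int, spec: SearchSpec | None = None
) -> Iterator[MeasurementConfig]:
    """Yield every configuration consistent with the spec exactly once.

    Canonical order: by m, then by the (sorted) measured subset, then by
    the coordinate-count composition in lexicographic order.
    """
    spec = spec or SearchSpec()
    m_min, m_max = spec.resolved_m_range(d)
    allowed = [i for i in range(d) if i not in spec.forbidden]
    if any(i in spec.forbidden for i in spec.required):
        raise ContractError("required and forbidden sets overlap")
    for m in range(m_min, m_max + 1):
        for subset in combinations(allowed, m):
            if not spec.required <= set(subset):
                continue
            for counts in _compositions(d, m, spec.max_count):
                yield MeasurementConfig(tuple(zip(subset, counts)))


def evaluate(
    model: SystemModel,
    spec: SearchSpec | None = None,
    configs: Iterator[MeasurementConfig] | None = None,
    progress_every: int = 0,
    callback: Callable[[int, MeasurementConfig, CoefficientResult], None] | None = None,
) -> RankedResults:
    """Score configurations and rank them.

    ``configs`` overrides enumeration (e.g. a pre-filtered stream); the
    optional ``callback`` and ``progress_every`` logging make very large
    spaces resumable/observable without materialising them.
    """
    spec = spec or SearchSpec()
    if configs is None:
        configs = enumerate_configs(model.d, spec)
    kept: list[tuple[MeasurementConfig, CoefficientResult]] = []
    evaluated = 0
    best = 0.0
    for config in configs:
        coeff = coefficient_for(model, config)
        evaluated += 1
        best = max(best, float(coeff.eta))
        if callback is not None:
            callback(evaluated, config, coeff)
        if spec.retain_all or coeff.eta >= spec.min_eta:
            kept.append((config, coeff))
        if progress_every and evaluated % progress_every == 0:
            logger.info(
                "evaluated %d configurations, best eta so far %.2f",
                evaluated, best,
            )
    kept.sort(
        key=lambda item: (
            -item[1].eta,
            item[0].m,
            item[0].to_string(model.variables),
        )
    )
    return RankedResults(
        results=tuple(kept),
        provenance={
            "strategy": spec.strategy,
            "model": model.name,
            "evaluated": evaluated,
            "min_eta": None if spec.retain_all else spec.min_eta,
        },
        variables=model.variables,
    )


def leave_one_out_scan(model: SystemModel) -> pd.DataFrame:
    """Score all m = d-1 configurations with one added first derivative.

    Cell (excluded j, derivative on i) holds the 2-decimal coefficient of
    the configuration measuring every variable except j, with variable i
    contributing its first derivative as the d-th coordinate.
    """
    d = model.d
    if d < 3:
        raise ContractError("leave-one-out scan requires d >= 3")
    names = model.variables
    table: dict[str, dict[str, float]] = {}
    for j in range(d):
        row: dict[str, float] = {}
        for i in range(d):
            if i == j:
                continue
            entries = tuple(
                (k, 2 if k == i else 1) for k in range(d) if k != j
            )
            coeff = coefficient_for(model, MeasurementConfig(entries))
            row[names[i]] = coeff.eta_2dp
        table[names[j]] = row
    frame = pd.DataFrame.from_dict(table, orient="index")
    frame = frame.reindex(index=names, columns=names)
    frame.index.name = "excluded"
    frame.columns.name = "derivative_on"
    return frame


def reduced_search(
    model: SystemModel,
    report: PreselectionReport,
    spec: SearchSpec | None = None,
) -> RankedResults:
    """Search only configurations compatible with the preselection.

    The measured set must contain every essential variable and at least
    one member of each exclusive pair; branches of the report are thereby
    merged (and duplicates cannot arise, since enumeration is global).
    """
    if report.variables and report.variables != model.variables:
        raise ContractError("preselection report comes from a different model")
    spec = spec or SearchSpec(strategy="preselect")
    essential = report.essential
    pairs = report.exclusive_pairs

    def admissible(config: MeasurementConfig) -> bool:
        measured = config.measured
        if not essential <= measured:
            return False
        return all(measured & pair for pair in pairs)

    stream = (
        config
        for config in enumerate_configs(model.d, spec)
        if admissible(config)
    )
    ranked = evaluate(model, spec, configs=stream)
    ranked.provenance["strategy"] = "preselect"
    return ranked
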