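"""Bundled benchmark models.

Three rational reaction-network models of increasing dimension, transcribed
as plain model documents and run through the ordinary parsing and
classification pipeline:

``goldbeter5d``
    Goldbeter's five-variable model of circadian PER protein oscillations
    in Drosophila: per mRNA (x1), three phosphorylation states of the PER
    protein (x2-x4) and nuclear PER (x5), with Michaelis-Menten kinetics
    throughout.

``rayleigh_benard9d``
    A nine-mode Fourier truncation of Rayleigh-Benard convection in a
    three-dimensional cell with square planform; all nonlinearities are
    quadratic.  The symbolic Jacobian is derived from the equations; a
    hand-published variant that differs in a few entries is available as
    ``jacobian_variant="printed"`` (see ``metadata["variant_differences"]``).

``dna13d``
    The Novak-Tyson cell-cycle model for DNA replication in fission yeast:
    twelve kinase/regulator concentrations plus the cell mass m (here the
    13th variable, named ``x13``).
"""

from __future__ import annotations

from .errors import ModelSchemaError
from .models import SystemModel, parse_model

__all__ = ["fixture", "FIXTURE_NAMES"]

GOLDBETER_5D = """
name: goldbeter5d
variables: [x1, x2, x3, x4, x5]
equations:
  - "v_s*K_I^4/(K_I^4 + x5^4) - v_m*x1/(K_m + x1)"
  - "k_s*x1 - V_1*x2/(K_1 + x2) + V_2*x3/(K_2 + x3)"
  - "V_1*x2/(K_1 + x2) + V_4*x4/(K_4 + x4) - x3*(V_2/(K_2 + x3) + V_3/(K_3 + x3))"
  - "V_3*x3/(K_3 + x3) - x4*(V_4/(K_4 + x4) + k_1 + v_d/(K_d + x4)) + k_2*x5"
  - "k_1*x4 - k_2*x5"
"""

RAYLEIGH_BENARD_9D = """
name: rayleigh_benard9d
variables: [x1, x2, x3, x4, x5, x6, x7, x8, x9]
equations:
  - "-sigma*b_1*x1 - x2*x4 + b_4*x4^2 + b_3*x3*x5 - sigma*b_2*x7"
  - "-sigma*x2 + x1*x4 - x2*x5 + x4*x5 - sigma*x9/2"
  - "-sigma*b_1*x3 + x2*x4 - b_4*x2^2 - b_3*x1*x5 + sigma*b_2*x8"
  - "-sigma*x4 - x2*x3 - x2*x5 + x4*x5 + sigma*x9/2"
  - "-sigma*b_5*x5 + x2^2/2 - x4^2/2"
  - "-b_6*x6 + x2*x9 - x4*x9"
  - "-b_1*x7 - R*x1 + 2*x5*x8 - x4*x9"
  - "-b_1*x8 + R*x3 - 2*x5*x7 + x2*x9"
  - "-x9 - R*x2 + R*x4 - 2*x2*x6 + 2*x4*x6 + x4*x7 - x2*x8"
"""

# Historically published symbol matrix for the 9D model.  It disagrees with
# direct differentiation of the equations in a few entries (see
# VARIANT_DIFFERENCES_9D); the derived matrix is the default because the
# published linear out-strengths (e.g. sigma_out_lin(6) = 0) are consistent
# with it and not with these entries.
RAYLEIGH_BENARD_9D_PRINTED = """
name: rayleigh_benard9d_printed
variables: [x1, x2, x3, x4, x5, x6, x7, x8, x9]
jacobian:
  - ["1",  "1b", "1b", "1b", "1b", "0",  "1",  "0",  "0"]
  - ["1b", "1b", "0",  "1b", "1b", "0",  "0",  "0",  "1"]
  - ["1b", "1b", "1",  "1b", "1b", "0",  "0",  "1",  "0"]
  - ["0",  "1b", "1b", "1b", "1b", "0",  "0",  "0",  "1"]
  - ["0",  "1b", "0",  "1b", "1",  "0",  "0",  "0",  "0"]
  - ["0",  "1b", "0",  "1b", "0",  "0",  "0",  "0",  "1b"]
  - ["1",  "0",  "0",  "1b", "1b", "1",  "1",  "1b", "1b"]
  - ["0",  "1b", "1",  "0",  "0",  "1b", "1b", "1b", "1b"]
  - ["0",  "1b", "0",  "1b", "1b", "1b", "1b", "1b", "1"]
"""

# (row, col, printed token, derived token), 1-based indices.
VARIANT_DIFFERENCES_9D = (
    (6, 6, "0", "1"),
    (7, 6, "1", "0"),
    (8, 5, "0", "1b"),
    (8, 6, "1b", "0"),
    (8, 8, "1b", "1"),
    (9, 5, "1b", "0"),
)

# x13 is the cell mass m of the original model; primed rate constants are
# written with a trailing p (k2p = k2', k6p = k6').
DNA_13D = """
name: dna13d
variables: [x1, x2, x3, x4, x5, x6, x7, x8, x9, x10, x11, x12, x13]
equations:
  - "k1 - (k2 + kwee + k7*x2)*x1 + k25*x8 + (k7r + k4)*x4"
  - "k3 - k4*x2 - kp*x2*(x1 + beta*x8 + alpha*x3)*x13/(Kmp + x2)
     - k7*x2*(x1 + x8) - k8*x2*x3 + (k8r + k6p)*x9
     + (k7r + k2 + k2p)*(x4 + x10)"
  - "k5 - (k6 + k8*x2)*x3 + (k8r + k4)*x9"
  - "k7*x2*x1 - (k7r + k4 + k2 + k2p)*x4"
  - "ki*(x1 + beta*x8)*(1 - x5)/(Kmi + 1 - x5) - kir*x5/(Kmir + x5)"
  - "ku2*(x1 + beta*x8)*(1 - x6)/(Kmu2 + 1 - x6) - kur2*x6/(Kmur2 + x6)"
  - "kwr*(1 - x7)/(Kmwr + 1 - x7) - kw*(x1 + beta*x8)*x7/(Kmw + x7)"
  - "kwee*x1 - (k25 + k2 + k7*x2)*x8 + (k7r + k4)*x10"
  - "k8*x2*x3 - (k8r + k4 + k6p)*x9"
  - "k7*x2*x8 - (k7r + k4 + k2 + k2p)*x10"
  - "ku*x5*(1 - x11)/(Kmu + 1 - x11) - kur*x11/(Kmur + x11)"
  - "kc*(x1 + beta*x8)*(1 - x12)/(Kmc + 1 - x12) - kcr*x12/(Kmcr + x12)"
  - "mu*x13"
"""

FIXTURE_NAMES = ("goldbeter5d", "rayleigh_benard9d", "dna13d")

_CACHE: dict[tuple[str, str], SystemModel] = {}


def fixture(name: str, jacobian_variant: str = "derived") -> SystemModel:
    """Return a bundled model by name.

    ``jacobian_variant`` applies to ``rayleigh_benard9d`` only: ``derived``
    (default) differentiates the equations, ``printed`` returns the
    historically published symbol matrix without right-hand sides.
    """
    if name not in FIXTURE_NAMES:
        raise LookupError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    if jacobian_variant not in ("derived", "printed"):
        raise LookupError(
            f"unknown jacobian_variant {jacobian_variant!r}; "
            "use 'derived' or 'printed'"
        )
    if jacobian_variant == "printed" and name != "rayleigh_benard9d":
        raise ModelSchemaError(
            "a 'printed' Jacobian variant exists only for rayleigh_benard9d"
        )
    key = (name, jacobian_variant)
    if key not in _CACHE:
        _CACHE[key] = _build(name, jacobian_variant)
    return _CACHE[key]


def _build(name: str, variant: str) -> SystemModel:
    if name == "goldbeter5d":
        return parse_model(GOLDBETER_5D)
    if name == "dna13d":
        return parse_model(DNA_13D)
    # rayleigh_benard9d
    if variant == "printed":
        model = parse_model(RAYLEIGH_BENARD_9D_PRINTED)
    else:
        model = parse_model(RAYLEIGH_BENARD_9D)
    model.metadata["variant"] = variant
    model.metadata["variant_differences"] = VARIANT_DIFFERENCES_9D
    return model
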