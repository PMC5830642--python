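"""Model ingestion, entry classification and the bundled fixtures."""

import sympy
import pytest

from symobs import (
    BAR,
    DBL,
    ONE,
    ZERO,
    ModelParseError,
    ModelSchemaError,
    SymbolicMatrix,
    UnsupportedModelError,
    build_symbolic_jacobian,
    classify_entry,
    fixture,
    linearize_symbols,
    parse_model,
)

GOLDBETER_TOKENS = [
    ["1bb", "0", "0", "0", "1bb"],
    ["1", "1bb", "1bb", "0", "0"],
    ["0", "1bb", "1bb", "1bb", "0"],
    ["0", "0", "1bb", "1bb", "1"],
    ["0", "0", "0", "1", "1"],
]

DNA_TOKENS = [
    ["1b", "1b", "0", "1", "0", "0", "0", "1", "0", "0", "0", "0", "0"],
    ["1b", "1bb", "1b", "1", "0", "0", "0", "1b", "1", "1", "0", "0", "1b"],
    ["0", "1b", "1b", "0", "0", "0", "0", "0", "1", "0", "0", "0", "0"],
    ["1b", "1b", "0", "1", "0", "0", "0", "0", "0", "0", "0", "0", "0"],
    ["1b", "0", "0", "0", "1bb", "0", "0", "1b", "0", "0", "0", "0", "0"],
    ["1b", "0", "0", "0", "0", "1bb", "0", "1b", "0", "0", "0", "0", "0"],
    ["1b", "0", "0", "0", "0", "0", "1bb", "1b", "0", "0", "0", "0", "0"],
    ["1", "1b", "0", "0", "0", "0", "0", "1b", "0", "1", "0", "0", "0"],
    ["0", "1b", "1b", "0", "0", "0", "0", "0", "1", "0", "0", "0", "0"],
    ["0", "1b", "0", "0", "0", "0", "0", "1b", "0", "1", "0", "0", "0"],
    ["0", "0", "0", "0", "1b", "0", "0", "0", "0", "0", "1bb", "0", "0"],
    ["1b", "0", "0", "0", "0", "0", "0", "1b", "0", "0", "0", "1bb", "0"],
    ["0", "0", "0", "0", "0", "0", "0", "0", "0", "0", "0", "0", "1"],
]

# Symbolic Jacobian of the 9D convection model as derived from its equations.
RB9_DERIVED_TOKENS = [
    ["1", "1b", "1b", "1b", "1b", "0", "1", "0", "0"],
    ["1b", "1b", "0", "1b", "1b", "0", "0", "0", "1"],
    ["1b", "1b", "1", "1b", "1b", "0", "0", "1", "0"],
    ["0", "1b", "1b", "1b", "1b", "0", "0", "0", "1"],
    ["0", "1b", "0", "1b", "1", "0", "0", "0", "0"],
    ["0", "1b", "0", "1b", "0", "1", "0", "0", "1b"],
    ["1", "0", "0", "1b", "1b", "0", "1", "1b", "1b"],
    ["0", "1b", "1", "0", "1b", "0", "1b", "1", "1b"],
    ["0", "1b", "0", "1b", "0", "1b", "1b", "1b", "1"],
]


class TestClassifyEntry:
    x1, x2, x5 = sympy.symbols("x1 x2 x5")
    k, K = sympy.symbols("k K")
    states = (x1, x2, x5)

    @pytest.mark.parametrize(
        "expr,xj,expected",
        [
            (sympy.Integer(0), "x1", ZERO),
            (sympy.Symbol("k"), "x1", ONE),
            (sympy.Symbol("k") * sympy.Symbol("x2"), "x1", BAR),
            # saturating term differentiated w.r.t. its own variable
            (sympy.Symbol("k") / (sympy.Symbol("K") + sympy.Symbol("x1")) ** 2,
             "x1", DBL),
            # rational, but the differentiation variable is not in the
            # denominator
            (sympy.Symbol("k") * sympy.Symbol("x2")
             / (sympy.Symbol("K") + sympy.Symbol("x2")), "x1", BAR),
        ],
    )
    def test_classes(self, expr, xj, expected):
        assert classify_entry(expr, xj, self.states) is expected

    def test_inhibition_term_is_rational(self):
        # d/dx5 of v K^4/(K^4 + x5^4)
        expr = sympy.diff(
            self.k * self.K**4 / (self.K**4 + self.x5**4), self.x5
        )
        assert classify_entry(expr, self.x5, self.states) is DBL

    def test_cancellation_precedes_denominator_test(self):
        # x1*x2/x1 cancels to a polynomial: BAR, not DBL
        expr = self.x1 * self.x2 / self.x1
        assert classify_entry(expr, self.x1, self.states) is BAR

    def test_parameter_scaling_invariance(self):
        for expr in (self.x2, self.x2**3, self.x1 / (self.K + self.x1)):
            base = classify_entry(expr, self.x1, self.states)
            assert classify_entry(17 * self.k * expr, self.x1, self.states) is base

    def test_transcendental_rejected(self):
        with pytest.raises(UnsupportedModelError):
            classify_entry(sympy.exp(self.x1), self.x1, self.states)
        with pytest.raises(UnsupportedModelError):
            classify_entry(self.x1 ** sympy.Rational(1, 2), self.x1, self.states)


class TestParseModel:
    def test_equations_document(self):
        model = parse_model(
            """
            name: toy
            variables: [u, v]
            equations:
              - "a*v - u^3"
              - "b*u - v"
            """
        )
        assert model.d == 2
        assert model.parameters == ("a", "b")
        assert model.jacobian.to_tokens() == [["1b", "1"], ["1", "1"]]

    def test_free_names_become_parameters(self):
        model = parse_model(
            "variables: [x1]\nequations:\n  - 'k1*x1'\n"
        )
        assert model.parameters == ("k1",)

    def test_jacobian_only_document(self):
        model = parse_model(
            "variables: [x1, x2]\njacobian: [['1', '0'], ['0', '1']]\n"
        )
        assert model.rhs is None
        assert model.jacobian == SymbolicMatrix.from_tokens([["1", "0"], ["0", "1"]])

    @pytest.mark.parametrize(
        "document,error",
        [
            ("variables: [x1, x1]\njacobian: [['1','0'],['0','1']]", ModelSchemaError),
            ("variables: [x1, x2]\njacobian: [['1','0','0'],['0','1','0']]",
             ModelSchemaError),
            ("variables: [x1]\nequations: ['x1*']", ModelParseError),
            ("variables: [x1]", ModelSchemaError),
            ("variables: [x1]\nequations: ['x1']\njacobian: [['1']]",
             ModelSchemaError),
        ],
    )
    def test_malformed_documents(self, document, error):
        with pytest.raises(error):
            parse_model(document)

    def test_parse_error_names_equation(self):
        with pytest.raises(ModelParseError, match="equation 2"):
            parse_model("variables: [x1, x2]\nequations: ['x2', '((x1']\n")


class TestFixtures:
    def test_goldbeter_jacobian_matches_published_matrix(self, goldbeter):
        assert goldbeter.jacobian.to_tokens() == GOLDBETER_TOKENS
        assert goldbeter.d == 5

    def test_dna_jacobian_matches_published_matrix(self, dna):
        assert dna.jacobian.to_tokens() == DNA_TOKENS
        assert dna.d == 13

    def test_rayleigh_benard_derived_jacobian(self, rayleigh_benard):
        assert rayleigh_benard.jacobian.to_tokens() == RB9_DERIVED_TOKENS

    def test_rayleigh_benard_printed_variant(self, rayleigh_benard):
        printed = fixture("rayleigh_benard9d", jacobian_variant="printed")
        assert printed.rhs is None
        diffs = printed.metadata["variant_differences"]
        for (i, j, printed_tok, derived_tok) in diffs:
            assert printed.jacobian[i - 1, j - 1].token == printed_tok
            assert rayleigh_benard.jacobian[i - 1, j - 1].token == derived_tok
        # all other entries agree
        flagged = {(i - 1, j - 1) for i, j, _, _ in diffs}
        for i in range(9):
            for j in range(9):
                if (i, j) not in flagged:
                    assert printed.jacobian[i, j] is rayleigh_benard.jacobian[i, j]

    def test_rebuild_jacobian_is_consistent(self, goldbeter, dna):
        for model in (goldbeter, dna):
            assert build_symbolic_jacobian(model) == model.jacobian

    def test_unknown_fixture(self):
        with pytest.raises(LookupError):
            fixture("lorenz63")


class TestLinearize:
    def test_dna_linearization_keeps_sparsity(self, dna):
        lin = linearize_symbols(dna.jacobian)
        for i in range(13):
            for j in range(13):
                original = dna.jacobian[i, j]
                assert lin[i, j] is (ZERO if original is ZERO else ONE)

    def test_all_zero_unchanged(self):
        mat = SymbolicMatrix.from_tokens([["0", "0"], ["0", "0"]])
        assert linearize_symbols(mat) == mat

    def test_single_rational_entry(self):
        mat = SymbolicMatrix.from_tokens([["1bb", "0"], ["0", "1"]])
        assert linearize_symbols(mat).to_tokens() == [["1", "0"], ["0", "1"]]
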