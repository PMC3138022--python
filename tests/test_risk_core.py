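import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcrscreen import (
    UNDEFINED,
    DomainError,
    HQVector,
    ValidationError,
    display_round,
    hazard_index,
    individual_metrics,
    max_hazard_quotient,
    mcr,
    missed_toxicity,
)
from mcrscreen.synthetic import fig1_fixture

SPREAD = (0.6, 0.8, 0.4, 0.5, 0.7)
DOMINATED = (2.7, 0.29, 0.008, 0.001, 0.001)


def vec(values):
    return HQVector.from_values(values)


class TestHQVector:
    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            HQVector([])

    def test_duplicate_chemical_rejected(self):
        with pytest.raises(ValidationError, match="Atrazine"):
            HQVector([("Atrazine", 0.1), ("Atrazine", 0.2)])

    @pytest.mark.parametrize("bad", [-0.1, math.nan, math.inf])
    def test_bad_entry_names_chemical(self, bad):
        with pytest.raises(ValidationError, match="Diuron"):
            HQVector([("Diuron", bad)])

    def test_accessors(self):
        v = HQVector([("a", 0.1), ("b", 0.2)])
        assert v.values == (0.1, 0.2)
        assert v.chemicals == ("a", "b")
        assert len(v) == 2


class TestHazardIndex:
    def test_worked_example_individual_1(self):
        assert hazard_index(vec(SPREAD)) == pytest.approx(3.0)

    def test_worked_example_individual_2(self):
        assert hazard_index(vec(DOMINATED)) == pytest.approx(3.0)

    def test_all_zero(self):
        assert hazard_index(vec([0.0])) == 0.0


class TestMaxHazardQuotient:
    def test_worked_example(self):
        value, _ = max_hazard_quotient(vec(SPREAD))
        assert value == 0.8

    def test_single_entry(self):
        value, name = max_hazard_quotient(HQVector([("only", 0.42)]))
        assert value == 0.42
        assert name == "only"

    def test_tie_broken_alphabetically(self):
        value, name = max_hazard_quotient(
            HQVector([("zeta", 0.5), ("alpha", 0.5), ("mid", 0.1)])
        )
        assert value == 0.5
        assert name == "alpha"


class TestMCR:
    def test_worked_example_individual_1(self):
        value = mcr(vec(SPREAD))
        assert value == pytest.approx(3.75)
        assert display_round(value) == 3.8

    def test_worked_example_individual_2(self):
        value = mcr(vec(DOMINATED))
        assert value == pytest.approx(3.0 / 2.7)
        assert display_round(value) == 1.1

    @pytest.mark.parametrize("n", [1, 2, 7, 20])
    def test_equitoxic_bound(self, n):
        assert mcr(vec([0.3] * n)) == pytest.approx(n)

    def test_all_zero_undefined(self):
        assert mcr(vec([0.0, 0.0])) is UNDEFINED


class TestMissedToxicity:
    def test_mcr_two_misses_half(self):
        assert missed_toxicity(2.0) == pytest.approx(0.50)

    def test_mcr_1_25_misses_fifth(self):
        assert missed_toxicity(1.25) == pytest.approx(0.20)

    def test_single_chemical_misses_nothing(self):
        assert missed_toxicity(1.0) == 0.0

    def test_below_one_rejected(self):
        with pytest.raises(DomainError):
            missed_toxicity(0.99)

    def test_marker_rejected(self):
        with pytest.raises(DomainError):
            missed_toxicity(UNDEFINED)


class TestIndividualMetrics:
    def test_worked_example_bundle(self):
        m = individual_metrics(vec(SPREAD))
        assert m.hi == pytest.approx(3.0)
        assert m.mhq == 0.8
        assert m.mcr == pytest.approx(3.75)
        # frozen: 1 - 1/3.75 by hand
        assert m.missed_fraction == pytest.approx(0.7333333333333333)
        assert m.n == 5

    def test_all_zero_vector(self):
        m = individual_metrics(vec([0.0, 0.0, 0.0]))
        assert m.hi == 0.0
        assert m.mcr is UNDEFINED
        assert m.missed_fraction is UNDEFINED
        assert not m.defined

    def test_marker_does_not_arithmetic(self):
        m = individual_metrics(vec([0.0]))
        with pytest.raises(TypeError):
            m.mcr + 1.0

    def test_fig1_fixture_consistency(self):
        spread, dominated = fig1_fixture()
        assert individual_metrics(spread).top_chemical == "chemB"
        assert individual_metrics(dominated).top_chemical == "chemA"


hq_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=1, max_size=20
)
positive_vectors = st.lists(
    st.floats(min_value=1e-9, max_value=1e6), min_size=1, max_size=20
)


class TestProperties:
    @given(positive_vectors)
    def test_invariants(self, values):
        m = individual_metrics(vec(values))
        n = len(values)
        assert 1.0 <= m.mcr <= n * (1 + 1e-12)
        assert m.mcr == m.hi / m.mhq  # exact correctly-rounded quotient
        assert m.hi == pytest.approx(m.mhq * m.mcr, rel=1e-15)
        assert m.missed_fraction == 1.0 - 1.0 / m.mcr

    @given(positive_vectors, st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, values, c):
        base = individual_metrics(vec(values))
        scaled = individual_metrics(vec([c * v for v in values]))
        assert scaled.mcr == pytest.approx(base.mcr, rel=1e-9)
        assert scaled.hi == pytest.approx(c * base.hi, rel=1e-9)
        assert scaled.mhq == pytest.approx(c * base.mhq, rel=1e-9)

    @given(positive_vectors, st.floats(min_value=0.1, max_value=1.0))
    def test_monotone_growth(self, values, frac):
        base = individual_metrics(vec(values))
        extra = frac * base.mhq
        grown = individual_metrics(vec(list(values) + [extra]))
        assert grown.hi > base.hi
        assert grown.mcr > base.mcr

    @given(hq_vectors)
    def test_oracle_equivalence(self, values):
        v = vec(values)
        # independent elementwise recomputation
        assert hazard_index(v) == math.fsum(values)
        assert max_hazard_quotient(v)[0] == max(values)


class TestDisplayRound:
    @pytest.mark.parametrize(
        "value,expected",
        [(3.75, 3.8), (1.1111111, 1.1), (1.25, 1.3), (0.05, 0.1), (2.0, 2.0)],
    )
    def test_half_up(self, value, expected):
        assert display_round(value) == expected

    def test_two_decimals(self):
        assert display_round(0.125, 2) == 0.13
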