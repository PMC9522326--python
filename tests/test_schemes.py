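"""Conformity-coefficient schemes: axioms, classes, weights, bounds."""

import math
from itertools import permutations

import numpy as np
import pytest

from polyconform import (
    ClassificationScheme,
    TabularScheme,
    adoption_probabilities,
    classify,
    d_bounds,
    g_weights,
    single_coefficient_scheme,
    two_coefficient_scheme_n4_m3,
    uniform_d_lower_bound,
    validate_scheme,
)
from polyconform.configurations import SampleConfiguration, enumerate_configurations
from polyconform.schemes import SchemeBoundError

from conftest import random_classification_scheme


class TestSingleCoefficientScheme:
    def test_majority_minority_coefficients(self):
        s = single_coefficient_scheme(0.5)
        np.testing.assert_allclose(s.coefficients(SampleConfiguration((2, 1, 0))), [0.5, -0.5, 0.0])
        np.testing.assert_allclose(s.coefficients(SampleConfiguration((1, 2, 0))), [-0.5, 0.5, 0.0])
        np.testing.assert_allclose(s.coefficients(SampleConfiguration((0, 2, 1))), [0.0, 0.5, -0.5])

    def test_forced_zeros(self):
        s = single_coefficient_scheme(-1.5)
        for x in [(3, 0, 0), (0, 0, 3), (1, 1, 1)]:
            np.testing.assert_array_equal(s.coefficients(SampleConfiguration(x)), np.zeros(3))

    def test_unbiased_limit_is_all_zero(self):
        s = single_coefficient_scheme(0.0)
        for x in s.configurations():
            np.testing.assert_array_equal(s.coefficients(x), np.zeros(3))

    @pytest.mark.parametrize("D", [-2.5, 1.5, -2.0 - 1e-6])
    def test_out_of_range_rejected(self, D):
        with pytest.raises(SchemeBoundError):
            single_coefficient_scheme(D)

    def test_many_variants_same_parameterization(self):
        s = single_coefficient_scheme(0.7, m=5)
        np.testing.assert_allclose(
            s.coefficients(SampleConfiguration((0, 2, 0, 1, 0))), [0, 0.7, 0, -0.7, 0]
        )
        assert validate_scheme(s).ok


class TestTwoCoefficientScheme:
    def test_table_values(self):
        s = two_coefficient_scheme_n4_m3(-0.3, 0.9)
        np.testing.assert_allclose(s.coefficients(SampleConfiguration((3, 1, 0))), [-0.3, 0.3, 0.0])
        np.testing.assert_allclose(s.coefficients(SampleConfiguration((2, 1, 1))), [0.9, -0.45, -0.45])
        np.testing.assert_allclose(s.coefficients(SampleConfiguration((1, 2, 1))), [-0.45, 0.9, -0.45])

    def test_equal_split_is_inert(self):
        s = two_coefficient_scheme_n4_m3(-0.3, 0.9)
        np.testing.assert_array_equal(s.coefficients(SampleConfiguration((2, 2, 0))), np.zeros(3))
        np.testing.assert_array_equal(s.coefficients(SampleConfiguration((4, 0, 0))), np.zeros(3))

    def test_zero_sum_over_all_fifteen_configurations(self):
        s = two_coefficient_scheme_n4_m3(-0.3, 0.9)
        configs = s.configurations()
        assert len(configs) == 15
        for x in configs:
            assert math.fsum(s.coefficients(x)) == pytest.approx(0.0, abs=1e-15)
        assert validate_scheme(s).ok

    @pytest.mark.parametrize("Dp,D", [(-3.5, 0.0), (1.5, 0.0), (0.0, 2.5), (0.0, -2.5)])
    def test_out_of_range_rejected(self, Dp, D):
        with pytest.raises(SchemeBoundError):
            two_coefficient_scheme_n4_m3(Dp, D)


class TestClassify:
    def test_hundred_role_model_example(self):
        x = (25, 20, 20, 10, 10, 10, 5, 0, 0, 0)
        part = classify(x)
        assert part.r == 7
        assert set(part.class_II) == {0, 1, 2}
        assert set(part.class_III) == {3, 4, 5, 6}
        assert set(part.class_I) == {7, 8, 9}

    def test_fixation_sample_is_all_class_one(self):
        part = classify((4, 0, 0))
        assert part.class_I == (0, 1, 2) and not part.class_II and not part.class_III

    def test_n4_unbalanced_sample(self):
        part = classify((3, 1, 0))
        assert part.class_II == (0,) and part.class_III == (1,) and part.class_I == (2,)

    def test_exact_average_count_joins_class_one(self):
        # r=2 present variants, average 6/2 = 3: a count of exactly 3 is class I
        part = classify((3, 3, 0))
        assert part.class_I == (0, 1, 2)

    def test_classes_partition_and_balance(self):
        for x in enumerate_configurations(6, 4):
            part = classify(x)
            assert sorted(part.class_I + part.class_II + part.class_III) == list(range(4))
            assert bool(part.class_II) == bool(part.class_III)


class TestGWeights:
    def test_hundred_role_model_worked_values(self):
        g = g_weights((25, 20, 20, 10, 10, 10, 5, 0, 0, 0))
        assert g[6] == pytest.approx(-0.4, abs=0)       # count 5: double the 10s
        assert g[3] == g[4] == g[5] == pytest.approx(-0.2, abs=0)
        assert g[0] == pytest.approx(25 / 65, abs=1e-16)
        assert g[1] == g[2] == pytest.approx(20 / 65, abs=1e-16)

    def test_masses_balance(self):
        for x in enumerate_configurations(7, 3):
            part = classify(x)
            g = g_weights(x)
            if part.class_II:
                assert math.fsum(g[list(part.class_II)]) == pytest.approx(1.0, abs=1e-12)
                assert math.fsum(g[list(part.class_III)]) == pytest.approx(-1.0, abs=1e-12)
            else:
                np.testing.assert_array_equal(g, np.zeros(3))


class TestDBounds:
    @pytest.mark.parametrize(
        "x,expected",
        [((3, 1, 0), (-3.0, 1.0)), ((2, 1, 0), (-2.0, 1.0)), ((2, 1, 1), (-2.0, 2.0))],
    )
    def test_known_intervals(self, x, expected):
        b = d_bounds(x)
        assert (b.lower, b.upper) == expected and not b.inert

    def test_inert_when_class_two_empty(self):
        b = d_bounds((2, 2, 0))
        assert b.inert and b.contains(1e9)

    def test_interior_values_yield_probabilities(self):
        # scan d across the open interval: probabilities stay within [0, 1]
        x = (2, 1, 1)
        b = d_bounds(x)
        for d in np.linspace(b.lower + 1e-6, b.upper - 1e-6, 25):
            s = ClassificationScheme(4, 3, {(2, 1, 1): float(d), (4, 0, 0): 0.0,
                                            (2, 2, 0): 0.0, (3, 1, 0): 0.0})
            probs = adoption_probabilities(x, s)
            assert np.all(probs >= 0) and np.all(probs <= 1)
            assert math.fsum(probs) == pytest.approx(1.0, abs=1e-12)

    def test_outside_values_rejected(self):
        with pytest.raises(SchemeBoundError):
            ClassificationScheme(4, 3, {(2, 1, 1): -2.5, (4, 0, 0): 0.0,
                                        (2, 2, 0): 0.0, (3, 1, 0): 0.0})

    def test_near_endpoint_warns_but_builds(self):
        with pytest.warns(UserWarning):
            ClassificationScheme(3, 3, -2.0 + 1e-12)


class TestUniformLowerBound:
    def test_three_role_models(self):
        assert uniform_d_lower_bound(3, 3) == -2.0

    def test_fifteen_role_models(self):
        assert uniform_d_lower_bound(15, 3) == -6.0

    def test_four_role_models(self):
        # max of -3 (from the (3,1,0) type) and -2 (from (2,1,1))
        assert uniform_d_lower_bound(4, 3) == -2.0

    def test_matches_exhaustive_scan(self):
        n, m = 9, 3
        best = max(
            d_bounds(x).lower
            for x in enumerate_configurations(n, m)
            if not d_bounds(x).inert
        )
        assert uniform_d_lower_bound(n, m) == best


class TestAdoptionProbabilities:
    def test_table_rows_n3(self):
        D = 0.4
        s = single_coefficient_scheme(D)
        np.testing.assert_allclose(
            adoption_probabilities((2, 1, 0), s), [2 / 3 + D / 3, 1 / 3 - D / 3, 0.0]
        )
        np.testing.assert_allclose(adoption_probabilities((1, 1, 1), s), [1 / 3] * 3)
        np.testing.assert_allclose(adoption_probabilities((3, 0, 0), s), [1.0, 0.0, 0.0])

    def test_bound_violation_names_configuration(self):
        bad = TabularScheme(3, 3, {(2, 1, 0): (1.5, -1.5, 0.0)}, complete_by_symmetry=True)
        with pytest.raises(SchemeBoundError, match=r"\(2, 1, 0\)"):
            adoption_probabilities((2, 1, 0), bad)


class TestValidateScheme:
    def test_constructed_schemes_are_valid(self, rng):
        assert validate_scheme(single_coefficient_scheme(0.5)).ok
        assert validate_scheme(two_coefficient_scheme_n4_m3(-0.3, 0.9)).ok
        assert validate_scheme(random_classification_scheme(rng, 5, 3)).ok

    def test_upper_bound_violation_detected(self):
        bad = TabularScheme(3, 3, {(2, 1, 0): (1.5, -1.5, 0.0)})
        report = validate_scheme(bad)
        assert any(v.kind == "bounds" and v.x == (2, 1, 0) for v in report.violations)

    def test_zero_sum_violation_detected(self):
        bad = TabularScheme(3, 3, {(2, 1, 0): (0.5, -0.2, 0.0)})
        report = validate_scheme(bad)
        assert any(v.kind == "zero_sum" for v in report.violations)

    def test_absent_variant_violation_detected(self):
        bad = TabularScheme(3, 3, {(2, 1, 0): (0.25, 0.0, -0.25)})
        report = validate_scheme(bad)
        assert any(v.kind == "absent_variant" for v in report.violations)


class TestClassificationConsistency:
    """The scalar-coefficient construction reproduces the named schemes."""

    def test_reduces_to_single_coefficient_at_n3(self):
        D = -0.8
        general = single_coefficient_scheme(D)
        np.testing.assert_array_equal(g_weights((2, 1, 0)), [1.0, -1.0, 0.0])
        for x in general.configurations():
            np.testing.assert_allclose(
                general.coefficients(x), g_weights(x.counts) * (0.0 if d_bounds(x.counts).inert else D),
                atol=1e-15,
            )

    def test_reduces_to_two_coefficient_at_n4(self):
        np.testing.assert_array_equal(g_weights((3, 1, 0)), [1.0, -1.0, 0.0])
        np.testing.assert_array_equal(g_weights((2, 1, 1)), [1.0, -0.5, -0.5])

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 3), (5, 3), (4, 4), (6, 4)])
    def test_random_tables_satisfy_all_axioms(self, rng, n, m):
        scheme = random_classification_scheme(rng, n, m)
        assert validate_scheme(scheme).ok

    @pytest.mark.parametrize("n,m", [(4, 3), (5, 3), (6, 3), (5, 4), (6, 4)])
    def test_permutation_equivariance_exhaustive(self, rng, n, m):
        scheme = random_classification_scheme(rng, n, m)
        for x in scheme.configurations():
            D = scheme.coefficients(x)
            for perm in permutations(range(m)):
                px = x.permuted(perm)
                np.testing.assert_array_equal(
                    scheme.coefficients(px), np.array([D[j] for j in perm])
                )
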