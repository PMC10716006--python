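"""MID normalization, correction-matrix construction and natural-abundance removal."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

import hepaflux as hf
from hepaflux.isotopes import (
    GLUCOSE_ALDONITRILE_PENTAACETATE,
    GLUCOSE_PENTAACETATE,
    NATURAL_ABUNDANCES,
    isotope_envelope,
    unlabeled_mid,
)

positive_vectors = st.lists(
    st.floats(min_value=1e-6, max_value=1e6), min_size=7, max_size=7
)


def envelope_by_symbolic_expansion(counts, abundances, K):
    """Independent oracle: expand the per-element isotope polynomials with sympy."""
    x = sympy.symbols("x")
    poly = sympy.Integer(1)
    for elem, n in counts.items():
        table = abundances[elem]
        poly *= sum(sympy.Float(a, 30) * x**k for k, a in enumerate(table)) ** n
    poly = sympy.expand(poly)
    return np.array([float(poly.coeff(x, k)) for k in range(K + 1)])


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([2, 2, 0, 0, 0, 0, 0], [0.5, 0.5, 0, 0, 0, 0, 0]),
            ([1, 0, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0, 0]),
        ],
    )
    def test_examples(self, raw, expected):
        mid = hf.normalize_mid(raw)
        np.testing.assert_allclose(mid.abundances, expected)

    @given(positive_vectors)
    @settings(max_examples=50, derandomize=True)
    def test_proportional_and_unit_sum(self, raw):
        mid = hf.normalize_mid(raw)
        raw = np.asarray(raw)
        assert abs(mid.abundances.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(mid.abundances, raw / raw.sum(), rtol=1e-12)

    @given(positive_vectors)
    @settings(max_examples=20, derandomize=True)
    def test_idempotent(self, raw):
        once = hf.normalize_mid(raw)
        twice = hf.normalize_mid(once.abundances)
        np.testing.assert_allclose(once.abundances, twice.abundances, atol=1e-15)

    @pytest.mark.parametrize("bad", [[0] * 7, [1, -1, 0, 0, 0, 0, 0]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(hf.InvalidMeasurementError):
            hf.normalize_mid(bad)


class TestCorrectionMatrix:
    def test_zero_abundance_gives_identity(self):
        formula = hf.FragmentFormula(
            {"C": 16, "H": 22, "O": 11},
            abundances={
                "C": np.array([1.0, 0.0]),
                "H": np.array([1.0, 0.0]),
                "O": np.array([1.0, 0.0, 0.0]),
            },
        )
        M = hf.build_correction_matrix(formula, K=6)
        np.testing.assert_allclose(M.matrix, np.eye(7), atol=1e-15)

    def test_one_carbon_binomial(self):
        a = 0.0107
        formula = hf.FragmentFormula({"C": 1}, abundances={"C": np.array([1 - a, a])})
        M = hf.build_correction_matrix(formula, K=1)
        np.testing.assert_allclose(M.matrix, [[1 - a, 0.0], [a, 1.0]], atol=1e-15)

    @pytest.mark.parametrize(
        "formula", [GLUCOSE_PENTAACETATE, GLUCOSE_ALDONITRILE_PENTAACETATE]
    )
    def test_column0_matches_symbolic_oracle(self, formula):
        M = hf.build_correction_matrix(formula, K=6)
        oracle = envelope_by_symbolic_expansion(formula.counts, NATURAL_ABUNDANCES, 6)
        np.testing.assert_allclose(M.matrix[:, 0], oracle, atol=1e-12)

    def test_structure_invariants(self):
        M = hf.build_correction_matrix(GLUCOSE_PENTAACETATE, K=6).matrix
        assert np.all(np.triu(M, 1) == 0)
        assert np.all(np.diag(M) > 0)
        assert np.all(M.sum(axis=0) <= 1 + 1e-12)
        # the inverse applied to column 0 recovers the pure-unlabeled unit vector
        e0 = np.linalg.solve(M, M[:, 0])
        np.testing.assert_allclose(e0, np.eye(7)[:, 0], atol=1e-12)

    def test_acetyl_carbons_matter(self):
        # the derivatization carbons contribute percent-level m+1 signal
        M = hf.build_correction_matrix(GLUCOSE_PENTAACETATE, K=6).matrix
        hexose_only = hf.build_correction_matrix(
            hf.FragmentFormula({"C": 6, "H": 12, "O": 6}), K=6
        ).matrix
        assert M[1, 0] - hexose_only[1, 0] > 0.016

    def test_too_few_tracer_positions_rejected(self):
        with pytest.raises(hf.ConfigurationError):
            hf.build_correction_matrix(hf.FragmentFormula({"C": 3}), K=6)


class TestCorrection:
    def setup_method(self):
        self.M = hf.build_correction_matrix(GLUCOSE_PENTAACETATE, K=6)

    def _convolve(self, x):
        y = self.M.matrix @ np.asarray(x, dtype=float)
        return y / y.sum()

    def test_round_trip_example(self):
        x = np.array([0.9, 0, 0, 0.06, 0, 0, 0.04])
        observed = hf.normalize_mid(self._convolve(x))
        corrected, residual, ok = hf.correct_natural_abundance(observed, self.M)
        np.testing.assert_allclose(corrected.abundances, x, atol=1e-10)
        assert ok and residual < 1e-10

    def test_unlabeled_envelope_corrects_to_unit_vector(self):
        observed = hf.normalize_mid(self._convolve(np.eye(7)[0]))
        corrected, _, _ = hf.correct_natural_abundance(observed, self.M)
        np.testing.assert_allclose(corrected.abundances, np.eye(7)[0], atol=1e-12)

    def test_identity_matrix_returns_input(self):
        identity = hf.CorrectionMatrix(np.eye(7))
        observed = hf.normalize_mid([5, 1, 1, 1, 0, 0, 0])
        corrected, _, _ = hf.correct_natural_abundance(observed, identity)
        np.testing.assert_allclose(corrected.abundances, observed.abundances, atol=1e-15)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.dirichlet(np.ones(7) * 0.5)
        observed = hf.normalize_mid(self._convolve(x))
        corrected, _, _ = hf.correct_natural_abundance(observed, self.M)
        np.testing.assert_allclose(corrected.abundances, x, atol=1e-10)

    def test_length_mismatch(self):
        observed = hf.normalize_mid([1, 1])
        with pytest.raises(hf.InvalidMeasurementError):
            hf.correct_natural_abundance(observed, self.M)


class TestExcess:
    def test_equal_mids_give_zero(self):
        mid = hf.normalize_mid([0.8, 0.1, 0.1, 0, 0, 0, 0])
        excess, clipped = hf.excess_mid(mid, mid)
        np.testing.assert_allclose(excess, 0.0, atol=1e-15)
        assert clipped == 0.0

    def test_m6_excess_over_unlabeled_baseline(self):
        arr = np.array([0.95, 0, 0, 0, 0, 0, 0.05])
        mid = hf.MID(arr, hf.Analyte.BLOOD_GLUCOSE, hf.Channel.CARBON_ONLY)
        excess, clipped = hf.excess_mid(mid)
        assert excess[6] == pytest.approx(0.05)
        assert clipped == pytest.approx(0.05)  # the matching m+0 deficit

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_matches_elementwise_subtraction(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.dirichlet(np.ones(7))
        b = rng.dirichlet(np.ones(7))
        mid_a = hf.MID(a, hf.Analyte.BLOOD_GLUCOSE, hf.Channel.CARBON_ONLY)
        mid_b = hf.MID(b, hf.Analyte.BLOOD_GLUCOSE, hf.Channel.CARBON_ONLY)
        excess, clipped = hf.excess_mid(mid_a, mid_b)
        diff = a - b
        np.testing.assert_allclose(excess, np.clip(diff, 0, None), atol=1e-15)
        assert clipped == pytest.approx(-diff[diff < 0].sum())


class TestDeuterium:
    def _mid(self, arr, channel, analyte=hf.Analyte.UDP_GLUCOSE):
        return hf.MID(np.asarray(arr, dtype=float), analyte, channel)

    def test_channel_subtraction(self):
        combined = self._mid([0.70, 0.30, 0, 0, 0, 0, 0], hf.Channel.COMBINED)
        carbon = self._mid([0.95, 0.05, 0, 0, 0, 0, 0], hf.Channel.CARBON_ONLY)
        assert hf.deuterium_enrichment(combined, carbon) == pytest.approx(0.25)

    def test_identical_channels_give_zero(self):
        combined = self._mid([0.9, 0.1, 0, 0, 0, 0, 0], hf.Channel.COMBINED)
        carbon = self._mid([0.9, 0.1, 0, 0, 0, 0, 0], hf.Channel.CARBON_ONLY)
        assert hf.deuterium_enrichment(combined, carbon) == 0.0

    def test_analyte_mismatch_rejected(self):
        combined = self._mid([1, 0, 0, 0, 0, 0, 0], hf.Channel.COMBINED,
                             hf.Analyte.BLOOD_GLUCOSE)
        carbon = self._mid([1, 0, 0, 0, 0, 0, 0], hf.Channel.CARBON_ONLY)
        with pytest.raises(hf.ChannelMismatchError):
            hf.deuterium_enrichment(combined, carbon)

    def test_recovers_injected_enrichment_through_convolution(self):
        # forward-convolve a pool with 0.12 2H and 0.03 13C at m+1, then invert
        h2, c13 = 0.12, 0.03
        M_comb = hf.build_correction_matrix(GLUCOSE_PENTAACETATE)
        M_carb = hf.build_correction_matrix(GLUCOSE_ALDONITRILE_PENTAACETATE)
        x_comb = np.zeros(7)
        x_comb[1] = h2 + c13
        x_comb[0] = 1 - x_comb.sum()
        x_carb = np.zeros(7)
        x_carb[1] = c13
        x_carb[0] = 1 - x_carb.sum()

        def observe(M, x, channel):
            y = M.matrix @ x
            obs = hf.normalize_mid(y / y.sum(), hf.Analyte.UDP_GLUCOSE, channel)
            corrected, _, _ = hf.correct_natural_abundance(obs, M)
            return corrected

        combined = observe(M_comb, x_comb, hf.Channel.COMBINED)
        carbon = observe(M_carb, x_carb, hf.Channel.CARBON_ONLY)
        assert hf.deuterium_enrichment(combined, carbon) == pytest.approx(h2, abs=1e-9)


def test_unlabeled_mid_is_unit_vector():
    mid = unlabeled_mid(hf.Analyte.BLOOD_GLUCOSE, hf.Channel.CARBON_ONLY)
    np.testing.assert_allclose(mid.abundances, np.eye(7)[0])


def test_envelope_truncation_keeps_columns_below_one():
    env = isotope_envelope(GLUCOSE_PENTAACETATE, max_shift=2)
    assert env.sum() < 1.0
    full = isotope_envelope(GLUCOSE_PENTAACETATE, max_shift=60)
    assert full.sum() == pytest.approx(1.0, abs=1e-12)
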