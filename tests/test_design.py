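"""Spectrum loading, effect parameterizations and case-frequency construction."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplopower.design import (
    CategorySpectrum,
    EffectSpec,
    InfeasibleEffectError,
    InputError,
    StudyDesign,
    build_case_frequencies,
    effect_as_or,
    load_spectrum,
    or_to_p1,
)
from haplopower.fixtures import EURO11_LABELS, EURO11_RAW_FREQS, write_spectrum_csv


class TestLoadSpectrum:
    def test_euro11_renormalized_with_warning(self, tmp_path, caplog):
        path = write_spectrum_csv(tmp_path / "s.csv", EURO11_LABELS, EURO11_RAW_FREQS)
        with caplog.at_level(logging.WARNING, logger="haplopower.design"):
            spec = load_spectrum(path)
        assert any("renormalizing" in r.message for r in caplog.records)
        assert spec.k == 11
        assert spec.freqs.sum() == pytest.approx(1.0, abs=1e-12)
        assert spec.freqs[0] == pytest.approx(0.41 / 1.10, rel=1e-12)
        assert spec.labels[0] == "H"

    def test_already_normalized_no_warning(self, tmp_path, caplog):
        path = write_spectrum_csv(tmp_path / "s.csv", ["a", "b"], [0.5, 0.5])
        with caplog.at_level(logging.WARNING, logger="haplopower.design"):
            spec = load_spectrum(path)
        assert not caplog.records
        np.testing.assert_allclose(spec.freqs, [0.5, 0.5])

    def test_uniform_renormalization(self, tmp_path):
        path = write_spectrum_csv(tmp_path / "s.csv", list("abc"), [0.2, 0.2, 0.2])
        spec = load_spectrum(path)
        np.testing.assert_allclose(spec.freqs, np.full(3, 1 / 3), atol=1e-15)

    @pytest.mark.parametrize(
        "content, match",
        [
            ("foo,bar\nh,0.5\nj,0.5\n", "header"),
            ("label,freq\nh,0.5\n", "at least 2"),
            ("label,freq\nh,0.5\nj,-0.1\n", "row 3"),
            ("label,freq\nh,0.5\nj,abc\n", "row 3"),
            ("label,freq\nh,0.5\nj,0\n", "row 3"),
        ],
    )
    def test_malformed_inputs_name_the_offender(self, tmp_path, content, match):
        path = tmp_path / "bad.csv"
        path.write_text(content)
        with pytest.raises(InputError, match=match):
            load_spectrum(path)

    def test_zero_frequency_rejected_in_constructor(self):
        with pytest.raises(InputError):
            CategorySpectrum(("a", "b"), np.array([1.0, 0.0]))


class TestBuildCaseFrequencies:
    def test_proportional_redistribution(self):
        spec = CategorySpectrum(("a", "b", "c"), np.array([0.4, 0.3, 0.3]))
        out = build_case_frequencies(spec, EffectSpec(risky_index=0, deviation=0.5))
        np.testing.assert_allclose(out, [0.6, 0.2, 0.2], atol=1e-15)

    def test_null_effect_is_identity(self, euro11):
        out = build_case_frequencies(euro11, EffectSpec(risky_index=2, deviation=0.0))
        np.testing.assert_allclose(out, euro11.freqs, atol=1e-15)

    def test_infeasible_effect_reports_max_deviation(self):
        spec = CategorySpectrum(("a", "b"), np.array([0.6, 0.4]))
        with pytest.raises(InfeasibleEffectError, match="0.6667"):
            build_case_frequencies(spec, EffectSpec(risky_index=0, deviation=1.0))

    @given(
        freqs=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=12),
        risky=st.integers(0, 11),
        delta=st.floats(0.0, 5.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_simplex_and_monotonicity_properties(self, freqs, risky, delta):
        """Output stays on the simplex; risky entry rises with delta, others fall."""
        freqs = np.asarray(freqs)
        spec = CategorySpectrum(
            tuple(f"c{i}" for i in range(len(freqs))), freqs / freqs.sum()
        )
        risky %= spec.k
        p0 = spec.freqs[risky]
        if p0 * (1 + delta) >= 1 - 1e-9:
            return
        out = build_case_frequencies(spec, EffectSpec(risky_index=risky, deviation=delta))
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out > 0)
        if delta > 1e-12:
            assert out[risky] > p0
            others = np.delete(np.arange(spec.k), risky)
            assert np.all(out[others] < spec.freqs[others])


class TestEffectParameterizations:
    def test_no_effect_is_or_one(self):
        assert effect_as_or(0.3, 0.3) == pytest.approx(1.0)

    def test_doubled_rare_frequency(self):
        # p0 = 0.11 doubled to p1 = 0.22
        assert effect_as_or(0.11, 0.22) == pytest.approx(2.282, abs=5e-4)

    @given(p0=st.floats(0.01, 0.99), p1=st.floats(0.01, 0.99))
    @settings(max_examples=200, derandomize=True)
    def test_or_round_trip(self, p0, p1):
        assert or_to_p1(effect_as_or(p0, p1), p0) == pytest.approx(p1, abs=1e-12)

    @given(p0=st.floats(0.01, 0.6), delta=st.floats(0.0, 0.6))
    @settings(max_examples=200, derandomize=True)
    def test_three_parameterizations_commute(self, p0, delta):
        """delta -> p1 -> OR -> p1 -> delta is the identity."""
        by_delta = EffectSpec(risky_index=0, deviation=delta)
        p1 = by_delta.case_freq(p0)
        by_p1 = EffectSpec(risky_index=0, target_case_freq=p1)
        by_or = EffectSpec(risky_index=0, odds_ratio=by_p1.as_or(p0))
        assert by_or.case_freq(p0) == pytest.approx(p1, abs=1e-12)
        assert by_or.delta(p0) == pytest.approx(delta, abs=1e-9)

    def test_exactly_one_parameter_required(self):
        with pytest.raises(InputError):
            EffectSpec(risky_index=0)
        with pytest.raises(InputError):
            EffectSpec(risky_index=0, deviation=0.5, odds_ratio=2.0)

    def test_boundary_frequencies_rejected(self):
        with pytest.raises(InputError):
            effect_as_or(0.0, 0.5)
        with pytest.raises(InputError):
            effect_as_or(0.5, 1.0)


class TestStudyDesign:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_cases=0, n_controls=10),
            dict(n_cases=10, n_controls=10, alpha=0.0),
            dict(n_cases=10, n_controls=10, method="bootstrap"),
            dict(n_cases=10, n_controls=10, method="permutation", n_perm=0),
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(InputError):
            StudyDesign(**kwargs)

    def test_ratio(self):
        assert StudyDesign(n_cases=100, n_controls=250).ratio == pytest.approx(2.5)
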