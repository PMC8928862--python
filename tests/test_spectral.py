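"""Unit and property tests of the eight-resonance triglyceride model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facmri.spectral import (
    AcquisitionSpec,
    FatModelSpec,
    TriglycerideParams,
    VoxelSignalParams,
    basis_coefficients,
    forward_signal,
    forward_signal_resonance_sum,
    resonance_amplitudes,
    resonance_frequencies,
)

# Independent tabulation of the spectral constants for the oracle below:
# shifts in ppm (water 4.70) and the amplitude rules per resonance group.
_ORACLE_SHIFTS = [5.28, 4.22, 2.75, 2.25, 2.02, 1.57, 1.30, 0.90]


def _oracle_signal(w, f, ndb, nmidb, psi_hz, r2star, times, b0=3.0, gamma=42.577, cl=17.3):
    """Straight-line eight-resonance sum, written independently of the
    package's basis/linearisation code path."""
    alphas = [
        2 * ndb, 4.0, 2 * nmidb, 6.0, 4 * (ndb - nmidb), 6.0,
        6 * (cl - 4) - 8 * ndb + 2 * nmidb, 9.0,
    ]
    norm = 1.0 / sum(alphas)
    out = []
    for t in times:
        acc = 0.0 + 0.0j
        for shift, alpha in zip(_ORACLE_SHIFTS, alphas):
            omega = 2 * np.pi * (shift - 4.70) * gamma * b0
            acc += alpha * np.exp(1j * omega * t)
        out.append((w + f * norm * acc) * np.exp((2j * np.pi * psi_hz - r2star) * t))
    return np.array(out)


class TestResonanceFrequencies:
    def test_water_reference_is_zero(self):
        spec = FatModelSpec(chemical_shifts_ppm=(4.70, 4.22, 2.75, 2.25, 2.02, 1.57, 1.30, 0.90))
        assert resonance_frequencies(spec)[0] == 0.0

    def test_bulk_methylene_frequency(self, model_spec):
        # group G at 1.30 ppm, 3 T: (1.30 - 4.70) * 42.577 * 3.0 Hz
        omega = resonance_frequencies(model_spec)
        assert omega[6] == pytest.approx(2 * np.pi * (-434.2854), rel=1e-12)

    def test_linear_in_field_strength(self, model_spec):
        double = FatModelSpec(field_strength_t=6.0)
        np.testing.assert_allclose(
            resonance_frequencies(double), 2 * resonance_frequencies(model_spec)
        )


class TestResonanceAmplitudes:
    def test_fully_saturated(self, model_spec):
        alphas, f = resonance_amplitudes(TriglycerideParams(0.0, 0.0), model_spec)
        np.testing.assert_allclose(alphas, [0, 4, 0, 6, 0, 6, 79.8, 9])
        assert alphas.sum() == pytest.approx(104.8)
        assert f == pytest.approx(1 / 104.8)

    def test_reference_composition(self, model_spec):
        alphas, _ = resonance_amplitudes(TriglycerideParams(2.56, 0.48), model_spec)
        np.testing.assert_allclose(
            alphas, [5.12, 4, 0.96, 6, 8.32, 6, 60.28, 9], atol=1e-12
        )
        assert alphas.sum() == pytest.approx(99.68)

    @settings(deadline=None)
    @given(
        ndb=st.floats(0.0, 6.0),
        frac=st.floats(0.0, 1.0),
    )
    def test_amplitude_sum_identity(self, ndb, frac):
        """sum(alpha) = 104.8 - 2 ndb for every valid composition at cl=17.3."""
        spec = FatModelSpec()
        nmidb = frac * ndb
        alphas, _ = resonance_amplitudes(TriglycerideParams(ndb, nmidb), spec)
        assert alphas.sum() == pytest.approx(104.8 - 2 * ndb, abs=1e-9)

    def test_impossible_composition_raises(self, model_spec):
        with pytest.raises(ValueError, match="negative resonance amplitude"):
            resonance_amplitudes(TriglycerideParams(14.0, 0.0), model_spec)


class TestBasisCoefficients:
    def test_values_at_time_zero(self, model_spec):
        p_f, p_ndb, p_nmidb = basis_coefficients([0.0], model_spec)
        assert p_f[0] == pytest.approx(104.8)
        assert p_ndb[0] == pytest.approx(-2.0)
        assert p_nmidb[0] == pytest.approx(0.0, abs=1e-12)

    def test_consistent_with_amplitudes_at_time_zero(self, model_spec):
        ndb, nmidb = 2.24, 0.26
        p_f, p_ndb, p_nmidb = basis_coefficients([0.0], model_spec)
        alphas, _ = resonance_amplitudes(TriglycerideParams(ndb, nmidb), model_spec)
        combined = p_f[0] + ndb * p_ndb[0] + nmidb * p_nmidb[0]
        assert combined == pytest.approx(alphas.sum())

    def test_triangle_inequality_bound(self, model_spec, rng):
        times = rng.uniform(0, 30e-3, size=200)
        p_f, _, _ = basis_coefficients(times, model_spec)
        assert np.all(np.abs(p_f) <= 104.8 + 1e-9)

    def test_printed_variant_adds_olefinic_term(self, model_spec, acq):
        base = basis_coefficients(acq, model_spec)[0]
        literal = basis_coefficients(acq, model_spec, include_constant_ea=True)[0]
        omega_a = resonance_frequencies(model_spec)[0]
        np.testing.assert_allclose(
            literal - base, np.exp(1j * omega_a * acq.echo_times), atol=1e-12
        )


class TestForwardSignal:
    def _params(self, **kw):
        defaults = dict(
            water=20 + 5j, fat=75 - 10j,
            triglyceride=TriglycerideParams(2.5, 0.4),
            field_map_hz=-30.0, r2star=35.0,
        )
        defaults.update(kw)
        return VoxelSignalParams(**defaults)

    def test_extrapolation_to_time_zero_is_water_plus_fat(self, model_spec):
        p = self._params()
        s0 = forward_signal(p, [0.0], model_spec)[0]
        assert s0 == pytest.approx(p.water + p.fat)

    def test_water_only_is_monoexponential(self, model_spec, acq):
        p = self._params(fat=0j)
        s = forward_signal(p, acq, model_spec)
        t = acq.echo_times
        expected = p.water * np.exp((2j * np.pi * p.field_map_hz - p.r2star) * t)
        np.testing.assert_allclose(s, expected, rtol=1e-12)

    def test_matches_independent_resonance_sum_oracle(self, model_spec, acq):
        """The linearised path reproduces a hand-written 8-resonance sum."""
        p = self._params(water=0j, fat=100 + 0j,
                         triglyceride=TriglycerideParams(2.24, 0.26),
                         field_map_hz=40.0, r2star=40.0)
        s = forward_signal(p, acq, model_spec)
        oracle = _oracle_signal(0, 100, 2.24, 0.26, 40.0, 40.0, acq.echo_times)
        np.testing.assert_allclose(s, oracle, rtol=1e-10)

    def test_both_package_paths_agree_on_random_voxels(self, model_spec, acq, rng):
        for _ in range(50):
            p = VoxelSignalParams(
                water=complex(*rng.normal(0, 50, 2)),
                fat=complex(*rng.normal(0, 50, 2)),
                triglyceride=TriglycerideParams(rng.uniform(0, 4), 0.0),
                field_map_hz=rng.uniform(-300, 300),
                r2star=rng.uniform(0, 200),
            )
            a = forward_signal(p, acq, model_spec)
            b = forward_signal_resonance_sum(p, acq, model_spec)
            np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12)

    def test_field_map_aliasing(self, model_spec, acq):
        """Shifting psi by 1/dTE rescales all echoes by one unit-magnitude
        constant, so such field maps are indistinguishable."""
        p = self._params()
        shifted = self._params(field_map_hz=p.field_map_hz + 1.0 / acq.delta_te_s)
        s = forward_signal(p, acq, model_spec)
        s_shift = forward_signal(shifted, acq, model_spec)
        ratios = s_shift / s
        assert np.allclose(np.abs(ratios), 1.0, atol=1e-12)
        assert np.allclose(ratios, ratios[0], atol=1e-12)


class TestInvariants:
    def test_shift_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="strictly decreasing"):
            FatModelSpec(chemical_shifts_ppm=(5.28, 4.22, 2.75, 2.75, 2.02, 1.57, 1.30, 0.90))

    def test_triglyceride_bounds(self):
        with pytest.raises(ValueError):
            TriglycerideParams(-0.1, 0.0)
        with pytest.raises(ValueError):
            TriglycerideParams(1.0, 1.2)

    def test_acquisition_needs_enough_echoes(self):
        with pytest.raises(ValueError, match="4 echoes"):
            AcquisitionSpec(n_echoes=3)

    def test_acquisition_rejects_duplicate_echo_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AcquisitionSpec(n_echoes=4, echo_times_s=(1e-3, 2e-3, 2e-3, 3e-3))
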