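"""Fourier closed forms (vs quadrature oracle) and forced-response tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from erkfreq import (FourierSeries, PulseTrainSpec, forced_response,
                     fourier_rectangular, fourier_triangular,
                     pulse_train_response, sinusoid_prediction)


def _quadrature_coefficients(fn, period, n, breakpoints):
    """Independent Fourier-coefficient oracle by adaptive quadrature."""
    w = 2 * np.pi * n / period
    an = 2 / period * quad(lambda t: fn(t) * np.cos(w * t), 0, period,
                           points=breakpoints, limit=200)[0]
    bn = 2 / period * quad(lambda t: fn(t) * np.sin(w * t), 0, period,
                           points=breakpoints, limit=200)[0]
    return an, bn


def test_rectangular_coefficients_match_quadrature():
    spec = PulseTrainSpec("rectangular", amplitude=0.08, period=1200.0,
                          tau=180.0)
    series = fourier_rectangular(spec, n_harmonics=500)
    assert series.mean == pytest.approx(0.012, abs=1e-15)  # A tau / T
    fn = lambda t: 0.08 if t % 1200.0 < 180.0 else 0.0
    for n in (1, 2, 3, 7, 50, 500):
        an, bn = _quadrature_coefficients(fn, 1200.0, n, [180.0])
        assert series.an[n - 1] == pytest.approx(an, abs=1e-10)
        assert series.bn[n - 1] == pytest.approx(bn, abs=1e-10)


def test_triangular_coefficients_match_quadrature():
    spec = PulseTrainSpec("triangular", amplitude=4.2, period=3600.0)
    series = fourier_triangular(spec, n_harmonics=100)
    assert series.mean == pytest.approx(2.1)
    fn = lambda t: 4.2 * (t / 1800.0 if t % 3600 < 1800 else 2 - t / 1800.0)
    for n in (1, 2, 3, 9, 199):
        an, bn = _quadrature_coefficients(fn, 3600.0, n, [1800.0])
        assert series.an[n - 1] == pytest.approx(an, abs=1e-10)
        assert series.bn[n - 1] == pytest.approx(bn, abs=1e-10)


def test_half_duty_rectangle_reduces_to_odd_sine_series():
    spec = PulseTrainSpec("rectangular", amplitude=1.0, period=100.0, tau=50.0)
    s = fourier_rectangular(spec, n_harmonics=10)
    n = np.arange(1, 11)
    assert np.allclose(s.an, 0.0, atol=1e-15)
    odd = n % 2 == 1
    assert np.allclose(s.bn[odd], 2.0 / (np.pi * n[odd]), atol=1e-15)
    assert np.allclose(s.bn[~odd], 0.0, atol=1e-15)


def test_triangle_harmonic_ratio_and_reconstruction():
    spec = PulseTrainSpec("triangular", amplitude=4.2, period=3600.0)
    s = fourier_triangular(spec, n_harmonics=200)
    assert abs(s.an[0] / s.an[2]) == pytest.approx(9.0)  # (2*2-1)^2
    # kink convergence is O(1/m_max): ~2A/(pi^2 m_max) worst case, so the
    # 1e-4*A target needs the series taken past harmonic ~2000
    s_fine = fourier_triangular(spec, n_harmonics=1200)
    t = np.linspace(0.0, 3600.0, 2000)
    err = np.max(np.abs(s_fine.reconstruct(t) - spec.waveform(t)))
    assert err < 1e-4 * 4.2


@given(amplitude=st.floats(0.01, 5.0), period=st.floats(100.0, 10000.0),
       duty=st.floats(0.05, 0.95))
def test_rectangle_mean_and_reconstruction_mean_agree(amplitude, period, duty):
    spec = PulseTrainSpec("rectangular", amplitude, period, tau=duty * period)
    s = fourier_rectangular(spec, n_harmonics=50)
    assert s.mean == pytest.approx(amplitude * duty, rel=1e-12)
    t = np.linspace(0.0, period, 20001)[:-1]
    assert np.mean(s.reconstruct(t)) == pytest.approx(s.mean, abs=1e-6 * amplitude)


def test_invalid_pulse_specs_rejected():
    with pytest.raises(ValueError):
        PulseTrainSpec("rectangular", 1.0, 100.0, tau=100.0)  # tau == T
    with pytest.raises(ValueError):
        PulseTrainSpec("sawtooth", 1.0, 100.0)
    with pytest.raises(ValueError):
        fourier_rectangular(
            PulseTrainSpec("rectangular", 1.0, 100.0, tau=10.0), n_harmonics=0)
    with pytest.raises(ValueError):
        fourier_triangular(
            PulseTrainSpec("rectangular", 1.0, 100.0, tau=10.0))


def test_no_harmonics_returns_constant_baseline(egf, statespace_at):
    ss = statespace_at("egf", 0.012)
    series = FourierSeries(a0=0.024, an=np.zeros(3), bn=np.zeros(3),
                           period=1200.0)
    resp = forced_response(ss, series)
    assert np.allclose(resp.erk_star, ss.equilibrium.erk_star)
    assert resp.metrics["gain_modulation"] == pytest.approx(1.0)


def test_baseline_must_match_series_mean(egf, statespace_at):
    ss = statespace_at("egf", 0.05)
    series = fourier_rectangular(
        PulseTrainSpec("rectangular", 0.08, 1200.0, tau=180.0))
    with pytest.raises(ValueError, match="mean"):
        forced_response(ss, series)  # 0.05 != 0.012


def test_gain_modulation_decreases_with_pulse_frequency(egf):
    """Fixed-width 0.08 Kd pulses: faster trains are less modulated."""
    gm = []
    for period in (1200.0, 720.0, 360.0):
        spec = PulseTrainSpec("rectangular", 0.08, period, tau=180.0)
        gm.append(pulse_train_response(egf, spec).metrics["gain_modulation"])
    assert gm[0] > gm[1] > gm[2] > 1.0


def test_triangle_equilibrium_level_is_frequency_independent(egf):
    """Same amplitude -> same mean dose -> identical baseline ERK*."""
    levels = set()
    for period in (7200.0, 3600.0, 900.0):
        spec = PulseTrainSpec("triangular", 4.2, period)
        resp = pulse_train_response(egf, spec)
        levels.add(round(resp.metrics["equilibrium_level"], 12))
    assert len(levels) == 1


def test_metrics_converged_in_harmonic_count(egf):
    spec = PulseTrainSpec("rectangular", 0.08, 1200.0, tau=180.0)
    m1 = pulse_train_response(egf, spec, n_harmonics=200).metrics
    m2 = pulse_train_response(egf, spec, n_harmonics=400).metrics
    for key in ("peak", "gain_modulation"):
        assert abs(m2[key] - m1[key]) / m1[key] < 0.005


def test_ngf_baseline_exceeds_egf_at_matched_protocol(egf, ngf):
    spec = PulseTrainSpec("rectangular", 0.08, 1200.0, tau=180.0)
    r_egf = pulse_train_response(egf, spec)
    r_ngf = pulse_train_response(ngf, spec)
    assert (r_ngf.metrics["equilibrium_level"]
            >= r_egf.metrics["equilibrium_level"])


def test_sinusoid_zero_amplitude_is_flat(egf):
    resp = sinusoid_prediction(egf, mean_dose=0.03, amplitude=0.0, omega=1e-3)
    assert np.allclose(resp.erk_star, resp.metrics["dc_level"])


def test_sinusoid_prediction_dc_band_and_frequency(egf):
    """Slow low-dose sine: DC ERK* in the 0.11-0.16 band, same frequency out."""
    resp = sinusoid_prediction(egf, mean_dose=0.03, amplitude=0.02, omega=1e-3)
    assert 0.11 <= resp.metrics["dc_level"] <= 0.16
    # a pure harmonic out: crossings of the DC level are half a period apart
    y = resp.erk_star - resp.metrics["dc_level"]
    crossings = resp.t[np.where(np.diff(np.sign(y)) != 0)[0]]
    gaps = np.diff(crossings)
    assert np.allclose(gaps, np.pi / 1e-3, rtol=1e-2)


def test_sinusoid_amplitude_exceeding_mean_rejected(egf):
    with pytest.raises(ValueError):
        sinusoid_prediction(egf, mean_dose=0.01, amplitude=0.02, omega=1e-3)
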