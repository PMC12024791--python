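"""Linearization, transfer-function reduction and Bode analysis tests."""

import numpy as np
import pytest

from erkfreq import (Equilibrium, StateSpace, bode_metrics, dose_response,
                     frequency_response, linearize, solve_equilibrium,
                     time_derivative, to_transfer_function)


def _finite_difference_jacobian(x, u, p):
    a = np.zeros((16, 16))
    for j in range(16):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        a[:, j] = (time_derivative(np.clip(xp, 0, None), u, p)
                   - time_derivative(np.clip(xm, 0, None), u, p)) / (2 * h)
    return a


def test_jacobian_matches_central_differences(egf, statespace_at):
    ss = statespace_at("egf", 0.1)
    eq = ss.equilibrium
    a_fd = _finite_difference_jacobian(eq.x, eq.u, egf)
    mask = np.abs(a_fd) > 1e-12
    rel = np.abs(ss.a[mask] - a_fd[mask]) / np.abs(a_fd[mask])
    assert rel.max() < 1e-5


def test_linearization_structure(statespace_at):
    ss = statespace_at("egf", 0.25)
    assert ss.d[0, 0] == 0.0  # output is a state, not a direct feedthrough
    for i in range(7):  # conservation: each pair's rows are exact negatives
        assert np.array_equal(ss.a[2 * i], -ss.a[2 * i + 1])
        assert ss.b[2 * i, 0] == -ss.b[2 * i + 1, 0]


def test_linearize_rejects_unconverged_equilibrium(egf):
    bogus = Equilibrium(x=np.ones(16), u=0.1, residual=1.0, stable=True)
    with pytest.raises(ValueError):
        linearize(bogus, egf)


@pytest.mark.parametrize("dose", [0.01, 0.1, 0.25])
def test_minimal_orders_are_3_over_8_for_egf(statespace_at, dose):
    tf = to_transfer_function(statespace_at("egf", dose))
    assert tf.orders == (3, 8)
    assert tf.n_constants == 13
    assert tf.den[0] == 1.0
    assert np.all(tf.poles.real < 0)  # stable at every interior dose tested


def test_ngf_relative_degree_is_five(statespace_at):
    tf = to_transfer_function(statespace_at("ngf", 0.25))
    assert tf.orders[1] - tf.orders[0] == 5
    assert np.all(tf.poles.real < 0)


def test_rational_form_equals_resolvent_evaluation(statespace_at):
    """zpk-reduced T(iw) against direct C(iwI-A)^{-1}B linear solves."""
    ss = statespace_at("egf", 0.05)
    tf = to_transfer_function(ss)
    rng = np.random.default_rng(7)
    omega = 10 ** rng.uniform(-6, 1, size=50)
    direct = ss.transfer_at(1j * omega)
    rel = np.abs(tf(1j * omega) - direct) / np.abs(direct)
    assert rel.max() < 1e-8


def test_dc_gain_equals_dose_response_slope(egf, statespace_at):
    """T(0) is the derivative of equilibrium ERK* with respect to dose."""
    dose, du = 0.05, 1e-4
    tf = to_transfer_function(statespace_at("egf", dose))
    hi = solve_equilibrium(egf, dose + du).erk_star
    lo = solve_equilibrium(egf, dose - du).erk_star
    slope = (hi - lo) / (2 * du)
    assert tf(0.0) == pytest.approx(slope, rel=1e-3)


def test_high_frequency_asymptotics(bode_at):
    """Fifth-order roll-off: slope -> -5 and phase drop -> 450 degrees."""
    bd = bode_at("egf", 0.01)
    hf = bd.omega > 10.0
    slope = np.polyfit(np.log10(bd.omega[hf]), np.log10(bd.modulation[hf]), 1)[0]
    assert slope == pytest.approx(-5.0, abs=0.05)
    assert bd.phase_deg[-1] - bd.phase_deg[0] == pytest.approx(-450, abs=5)


@pytest.mark.parametrize("mode,dose,low_phase", [
    ("egf", 0.01, 0.0),     # in-phase amplifier
    ("egf", 0.5, 180.0),    # negative-feedback suppressor
    ("ngf", 0.25, 360.0),   # extra loop winds one more half-turn
])
def test_low_frequency_phase_anchors(bode_at, mode, dose, low_phase):
    bd = bode_at(mode, dose)
    assert bd.phase_deg[0] == pytest.approx(low_phase, abs=5)


def test_phase_is_continuous(bode_at):
    bd = bode_at("ngf", 0.25)
    assert np.max(np.abs(np.diff(bd.phase_deg))) < 90.0
    assert np.all(bd.modulation > 0)


def test_pure_gain_system_has_no_phase_change():
    """Poles far above the sweep leave a frequency-flat gain with ~0 phase."""
    a = -1e6 * np.eye(3)
    b = np.ones((3, 1))
    c = np.ones((1, 3))
    ss = StateSpace(a=a, b=b, c=c, d=np.zeros((1, 1)))
    bd = frequency_response(ss)
    m = bode_metrics(bd)
    assert m["total_phase_change_deg"] == pytest.approx(0.0, abs=1.0)
    assert bd.modulation.max() / bd.modulation.min() < 1.001


def test_all_poles_stable_along_dose_response(egf):
    """Periodic forcing needs a stable equilibrium at every dose used.

    Checked on the eigenvalues of A directly (every retained pole is an
    eigenvalue); only the structural zero modes from conservation sit on
    the imaginary axis.
    """
    curve = dose_response(egf, doses=np.logspace(-3, np.log10(2.5), 15),
                          probe_multistability=False)
    for eq in curve.equilibria:
        eig = np.linalg.eigvals(linearize(eq, egf).a)
        nonstructural = eig[np.abs(eig) > 1e-9]
        assert np.all(nonstructural.real < 0)


def test_bode_sweep_span_enforced(statespace_at):
    bd = frequency_response(statespace_at("egf", 0.1),
                            omega=np.logspace(-4, 0, 50))
    with pytest.raises(ValueError):
        bode_metrics(bd)
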