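"""Fourier decomposition of periodic ligand waveforms and linearized responses.

A periodic ligand waveform f(t) with period T is decomposed as

    f(t) = a0/2 + sum_n an cos(2 pi n t / T) + sum_n bn sin(2 pi n t / T).

A linear system with frequency response M(w), phi(w) maps each harmonic to an
attenuated, phase-shifted copy at the same frequency, and the mean a0/2 to
the equilibrium output under the constant input a0/2.  The reconstructed
ERK* output is therefore

    F(t) = ERK*e(a0/2) + sum_n M(wn) [an cos(wn t + phi(wn))
                                      + bn sin(wn t + phi(wn))],

with wn = 2 pi n / T.  This holds in the small-perturbation regime around the
mean-dose equilibrium; the nonlinear oracle in :mod:`erkfreq.simulate` bounds
its accuracy.

Closed-form coefficients are provided for the two pulse shapes used
experimentally: a rectangular train of amplitude A, width tau and period T
(mean A tau / T) and a symmetric triangular train of amplitude A (mean A/2,
odd cosine harmonics only, magnitude 4A/((2n-1)^2 pi^2)).

The headline figure of merit is the gain modulation: the steady-cycle peak
ERK* divided by the equilibrium ERK* at the mean dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibrium import Equilibrium, solve_equilibrium
from .freqdomain import StateSpace, linearize
from .parameters import PathwayParameters

__all__ = [
    "PulseTrainSpec", "FourierSeries", "ForcedResponse",
    "fourier_rectangular", "fourier_triangular", "forced_response",
    "sinusoid_prediction",
    "DEFAULT_HARMONICS_RECTANGULAR", "DEFAULT_HARMONICS_TRIANGULAR",
]

DEFAULT_HARMONICS_RECTANGULAR = 200
DEFAULT_HARMONICS_TRIANGULAR = 100


@dataclass(frozen=True)
class PulseTrainSpec:
    """Periodic ligand waveform: rectangular, triangular or sinusoid.

    Amplitude ``A`` is in Kd units, ``period`` in seconds; ``tau`` is the
    pulse width (rectangular only).  ``phase_origin`` shifts the first pulse
    onset in time.
    """

    shape: str
    amplitude: float
    period: float
    tau: float | None = None
    phase_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("rectangular", "triangular", "sinusoid"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.shape == "rectangular":
            if self.tau is None or not 0 < self.tau < self.period:
                raise ValueError("rectangular trains need 0 < tau < period")

    @property
    def mean(self) -> float:
        """Mean ligand dose of the waveform, Kd units."""
        if self.shape == "rectangular":
            return self.amplitude * self.tau / self.period
        if self.shape == "triangular":
            return self.amplitude / 2.0
        return self.amplitude  # sinusoid oscillates about its DC level

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Exact waveform evaluated at times ``t`` (seconds)."""
        tt = np.mod(np.asarray(t, float) - self.phase_origin, self.period)
        if self.shape == "rectangular":
            return np.where(tt < self.tau, self.amplitude, 0.0)
        if self.shape == "triangular":
            # rises linearly 0 -> A over the first half period, then back
            half = self.period / 2.0
            return self.amplitude * np.where(
                tt < half, tt / half, 2.0 - tt / half)
        raise ValueError("waveform() supports rectangular and triangular "
                         "shapes; sinusoids are analytic")


@dataclass(frozen=True)
class FourierSeries:
    """Truncated Fourier series of a T-periodic waveform."""

    a0: float
    an: np.ndarray
    bn: np.ndarray
    period: float

    @property
    def mean(self) -> float:
        return self.a0 / 2.0

    @property
    def n_harmonics(self) -> int:
        return len(self.an)

    def harmonic_frequencies(self) -> np.ndarray:
        """Angular frequencies wn = 2 pi n / T for n = 1..N, rad/s."""
        n = np.arange(1, self.n_harmonics + 1)
        return 2.0 * np.pi * n / self.period

    def reconstruct(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        wn = self.harmonic_frequencies()
        phases = np.outer(t, wn)
        return (self.a0 / 2.0
                + np.cos(phases) @ self.an + np.sin(phases) @ self.bn)

    def truncated(self, n: int) -> "FourierSeries":
        if not 1 <= n <= self.n_harmonics:
            raise ValueError("truncation order out of range")
        return FourierSeries(self.a0, self.an[:n], self.bn[:n], self.period)


def fourier_rectangular(spec: PulseTrainSpec,
                        n_harmonics: int = DEFAULT_HARMONICS_RECTANGULAR
                        ) -> FourierSeries:
    """Closed-form Fourier coefficients of a rectangular pulse train.

    a0/2 = A tau / T;  an = (A / pi n) sin(2 pi n tau / T);
    bn = (A / pi n) (1 - cos(2 pi n tau / T)).
    """
    if spec.shape != "rectangular":
        raise ValueError("spec.shape must be 'rectangular'")
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    A, tau, T = spec.amplitude, spec.tau, spec.period
    n = np.arange(1, n_harmonics + 1)
    theta = 2.0 * np.pi * n * tau / T
    an = A / (np.pi * n) * np.sin(theta)
    bn = A / (np.pi * n) * (1.0 - np.cos(theta))
    return FourierSeries(a0=2.0 * A * tau / T, an=an, bn=bn, period=T)


def fourier_triangular(spec: PulseTrainSpec,
                       n_harmonics: int = DEFAULT_HARMONICS_TRIANGULAR
                       ) -> FourierSeries:
    """Closed-form Fourier coefficients of a symmetric triangular pulse train.

    Only odd cosine harmonics appear: for harmonic m = 2k-1,
    a_m = -4A / (m^2 pi^2); the mean is A/2.  ``n_harmonics`` counts the odd
    terms kept, i.e. the series extends to harmonic 2*n_harmonics - 1.
    """
    if spec.shape != "triangular":
        raise ValueError("spec.shape must be 'triangular'")
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    A, T = spec.amplitude, spec.period
    m_max = 2 * n_harmonics - 1
    m = np.arange(1, m_max + 1)
    an = np.where(m % 2 == 1, -4.0 * A / (m**2 * np.pi**2), 0.0)
    bn = np.zeros_like(an)
    return FourierSeries(a0=A, an=an, bn=bn, period=T)


@dataclass(frozen=True)
class ForcedResponse:
    """Steady periodic ERK* output under a periodic ligand waveform."""

    t: np.ndarray
    erk_star: np.ndarray
    input_kd: np.ndarray
    baseline: Equilibrium = field(repr=False, default=None)
    metrics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t,
            "input_kd": self.input_kd,
            "erk_star": self.erk_star,
        })


def _harmonic_response(ss: StateSpace, series: FourierSeries,
                       t: np.ndarray) -> np.ndarray:
    """Sum of transformed harmonics about zero baseline."""
    wn = series.harmonic_frequencies()
    t_vals = ss.transfer_at(1j * wn)
    mod = np.abs(t_vals)
    phi = np.angle(t_vals)
    arg = np.outer(t, wn) + phi  # broadcast phase per harmonic
    return (np.cos(arg) @ (mod * series.an)
            + np.sin(arg) @ (mod * series.bn))


def forced_response(ss: StateSpace, series: FourierSeries,
                    baseline_eq: Equilibrium | None = None,
                    dt: float = 1.0, n_periods: int = 5,
                    input_waveform: PulseTrainSpec | None = None
                    ) -> ForcedResponse:
    """Reconstruct the linearized periodic ERK* response.

    ``ss`` must be linearized at ``baseline_eq``, the equilibrium for the
    waveform's mean dose a0/2 (defaults to the equilibrium attached to
    ``ss``).  Metrics are computed over the last full period of an
    ``n_periods``-period reconstruction sampled every ``dt`` seconds:
    ``equilibrium_level`` (baseline ERK*e), ``peak`` (cycle maximum) and
    ``gain_modulation`` (peak / equilibrium_level).
    """
    baseline_eq = baseline_eq if baseline_eq is not None else ss.equilibrium
    if baseline_eq is None:
        raise ValueError("a baseline equilibrium is required")
    if not baseline_eq.stable:
        raise ValueError("baseline equilibrium is unstable; a steady "
                         "periodic response does not exist")
    if abs(baseline_eq.u - series.mean) > 1e-9 * max(1.0, series.mean):
        raise ValueError(
            f"baseline equilibrium dose {baseline_eq.u} does not match the "
            f"waveform mean {series.mean}")

    t = np.arange(0.0, n_periods * series.period + dt / 2, dt)
    erk = baseline_eq.erk_star + _harmonic_response(ss, series, t)

    cycle = t >= (n_periods - 1) * series.period
    equilibrium_level = baseline_eq.erk_star
    peak = float(np.max(erk[cycle]))
    metrics = {
        "equilibrium_level": float(equilibrium_level),
        "peak": peak,
        "gain_modulation": peak / equilibrium_level,
        "trough": float(np.min(erk[cycle])),
        "mean_dose_kd": float(series.mean),
        "period_s": float(series.period),
        "n_harmonics": int(series.n_harmonics),
    }
    if input_waveform is not None:
        u_t = input_waveform.waveform(t)
    else:
        u_t = series.reconstruct(t)
    return ForcedResponse(t=t, erk_star=erk, input_kd=u_t,
                          baseline=baseline_eq, metrics=metrics)


def pulse_train_response(p: PathwayParameters, spec: PulseTrainSpec,
                         n_harmonics: int | None = None,
                         dt: float = 1.0, n_periods: int = 5
                         ) -> ForcedResponse:
    """End-to-end pipeline: equilibrium at the mean dose, linearize, transform.

    Convenience wrapper used by the scenario layer and the analysis scripts.
    """
    if spec.shape == "rectangular":
        series = fourier_rectangular(
            spec, n_harmonics or DEFAULT_HARMONICS_RECTANGULAR)
    elif spec.shape == "triangular":
        series = fourier_triangular(
            spec, n_harmonics or DEFAULT_HARMONICS_TRIANGULAR)
    else:
        raise ValueError("use sinusoid_prediction() for sinusoidal inputs")
    eq = solve_equilibrium(p, series.mean)
    ss = linearize(eq, p)
    return forced_response(ss, series, eq, dt=dt, n_periods=n_periods,
                           input_waveform=spec)


def sinusoid_prediction(p: PathwayParameters, mean_dose: float,
                        amplitude: float, omega: float,
                        dt: float | None = None) -> ForcedResponse:
    """Predicted ERK* response to u(t) = mean_dose + amplitude sin(omega t).

    A single-harmonic forced response about the mean-dose equilibrium;
    reports the DC level, peak and phase lag in degrees.
    """
    if amplitude < 0 or mean_dose < 0:
        raise ValueError("mean_dose and amplitude must be non-negative")
    if amplitude > mean_dose:
        raise ValueError("amplitude exceeding the mean makes the ligand "
                         "waveform negative")
    if omega <= 0:
        raise ValueError("omega must be positive")
    period = 2.0 * np.pi / omega
    series = FourierSeries(a0=2.0 * mean_dose, an=np.zeros(1),
                           bn=np.array([amplitude]), period=period)
    eq = solve_equilibrium(p, mean_dose)
    ss = linearize(eq, p)
    dt = period / 2000 if dt is None else dt
    resp = forced_response(ss, series, eq, dt=dt, n_periods=2)
    t_val = ss.transfer_at(1j * omega)
    resp.metrics.update({
        "dc_level": eq.erk_star,
        "modulation": float(np.abs(t_val)),
        "phase_lag_deg": float(-np.degrees(np.angle(t_val))),
        "output_amplitude": float(np.abs(t_val)) * amplitude,
    })
    return resp
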