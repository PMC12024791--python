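"""Linearization, transfer function and Bode analysis.

The model is linearized at a steady state (xe, ue) into the standard
state-space quadruple (A, B, C, D) with A = dF/dx, B = dF/du, C selecting
ERK* and D = 0.  Entries are computed by complex-step differentiation, which
is exact to machine precision for this rational vector field.

The ligand-to-ERK* transfer function T(s) = C (sI - A)^{-1} B + D is extracted
in zero-pole-gain form: poles from the eigenvalues of A, transmission zeros
from the generalized eigenvalue problem of the Rosenbrock system pencil, and
the gain by matching a resolvent evaluation of T at a probe frequency.  The
seven structural integrator modes introduced by conservation, the PFB mode
that is unobservable under EGF, and any other pole/zero pair closer than
``cancel_tol`` (relative) are cancelled, leaving a minimal rational function —
degree 3 over degree 8 for this model at interior doses, i.e. thirteen
polynomial constants.  Naive determinant expansion of the 16x16 resolvent is
deliberately avoided; the eigenvalue route is numerically stable.

Phase curves are unwrapped continuously and anchored at the high-frequency
end: the unwrapped phase is shifted by a multiple of 360 deg so that its
high-frequency limit sits nearest -90 deg times the relative degree (the
asymptote of any rational transfer function with positive leading
coefficients), the relative degree being estimated from the high-frequency
log-log magnitude slope.  With this convention the low-frequency phase lands
in [0, 360) deg and phase totals are anchor-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .equilibrium import RESIDUAL_TOL, Equilibrium
from .model import ERKSTAR, N_STATES, time_derivative
from .parameters import PathwayParameters

__all__ = [
    "StateSpace", "RationalTF", "BodeData",
    "linearize", "to_transfer_function", "frequency_response", "bode_metrics",
    "default_frequency_grid", "MinimalOrderError",
]

#: Default relative tolerance for pole-zero cancellation.  Chosen of the order
#: of sqrt(machine epsilon): loose enough to absorb the eigenvalue error of the
#: structural and unobservable modes, tight enough to keep physically distinct
#: pole/zero pairs that approach each other at weak feedback (at low dose the
#: NFB pair sits at relative distance ~1e-6 and must survive the reduction).
CANCEL_TOL = 1e-8

#: Poles/zeros below this magnitude (rad/s) are treated as structural zeros.
ORIGIN_FLOOR = 1e-9


class MinimalOrderError(RuntimeError):
    """Raised when pole-zero cancellation cannot reach a coprime form."""


@dataclass(frozen=True)
class StateSpace:
    """Linearized system at an equilibrium: dx/dt = A x + B u, y = C x + D u."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    equilibrium: Equilibrium = field(repr=False, default=None)

    def transfer_at(self, s: complex | np.ndarray) -> complex | np.ndarray:
        """Evaluate T(s) = C (sI - A)^{-1} B + D by direct linear solve."""
        s_arr = np.atleast_1d(np.asarray(s, dtype=complex))
        eye = np.eye(self.a.shape[0])
        vals = np.array([
            (self.c @ np.linalg.solve(si * eye - self.a, self.b))[0, 0]
            + self.d[0, 0]
            for si in s_arr
        ])
        return vals if np.ndim(s) else vals[0]


@dataclass(frozen=True)
class RationalTF:
    """Minimal rational transfer function in both zpk and polynomial form.

    ``num``/``den`` are polynomial coefficients, highest degree first, with
    the denominator normalized to leading coefficient 1.
    """

    zeros: np.ndarray
    poles: np.ndarray
    gain: float
    num: np.ndarray
    den: np.ndarray

    @property
    def orders(self) -> tuple[int, int]:
        return (len(self.num) - 1, len(self.den) - 1)

    @property
    def n_constants(self) -> int:
        """Total printed polynomial constants (numerator + denominator)."""
        return len(self.num) + len(self.den)

    def __call__(self, s: complex | np.ndarray) -> complex | np.ndarray:
        return np.polyval(self.num, s) / np.polyval(self.den, s)

    def to_dict(self) -> dict:
        return {
            "num": list(map(float, self.num)),
            "den": list(map(float, self.den)),
            "zeros": [[z.real, z.imag] for z in self.zeros],
            "poles": [[p.real, p.imag] for p in self.poles],
            "gain": float(self.gain),
        }


@dataclass(frozen=True)
class BodeData:
    """Modulation and unwrapped phase on a frequency grid."""

    omega: np.ndarray
    modulation: np.ndarray
    phase_deg: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "omega_rad_s": self.omega,
            "modulation": self.modulation,
            "phase_deg": self.phase_deg,
        })


def linearize(eq: Equilibrium, p: PathwayParameters) -> StateSpace:
    """Jacobian linearization at a converged equilibrium (complex-step)."""
    if eq.residual > RESIDUAL_TOL:
        raise ValueError(
            f"equilibrium residual {eq.residual:.2e} exceeds {RESIDUAL_TOL}")
    h = 1e-30
    a = np.empty((N_STATES, N_STATES))
    for j in range(N_STATES):
        xc = eq.x.astype(complex)
        xc[j] += 1j * h
        a[:, j] = time_derivative(xc, eq.u, p).imag / h
    b = (time_derivative(eq.x.astype(complex), complex(eq.u, h), p).imag
         / h)[:, None]
    c = np.zeros((1, N_STATES))
    c[0, ERKSTAR] = 1.0
    d = np.zeros((1, 1))  # the output ERK* does not contain the input
    return StateSpace(a=a, b=b, c=c, d=d, equilibrium=eq)


def _transmission_zeros(ss: StateSpace) -> np.ndarray:
    """Finite generalized eigenvalues of the Rosenbrock pencil [[A,B],[C,D]]."""
    n = ss.a.shape[0]
    pencil = np.block([[ss.a, ss.b], [ss.c, ss.d]])
    weight = np.eye(n + 1)
    weight[n, n] = 0.0
    gz = sla.eig(pencil, weight, right=False)
    return gz[np.isfinite(gz)]


def _pair_conjugates(values: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Symmetrize a numerically-real-or-conjugate set so np.poly returns real."""
    vals = np.sort_complex(np.asarray(values, complex))
    out = []
    used = np.zeros(len(vals), bool)
    for i, v in enumerate(vals):
        if used[i]:
            continue
        if abs(v.imag) <= tol * max(1.0, abs(v)):
            out.append(complex(v.real, 0.0))
            used[i] = True
            continue
        # find the conjugate partner
        d = np.abs(vals - v.conjugate())
        d[used] = np.inf
        d[i] = np.inf
        j = int(np.argmin(d))
        mean = 0.5 * (v + vals[j].conjugate())
        out.extend([mean, mean.conjugate()])
        used[i] = used[j] = True
    return np.array(out)


def to_transfer_function(ss: StateSpace,
                         cancel_tol: float = CANCEL_TOL) -> RationalTF:
    """Reduce the linearized system to a minimal rational transfer function.

    Pole/zero pairs are cancelled when their distance is below ``cancel_tol``
    relative to their magnitude, or when both lie within ``ORIGIN_FLOOR`` of
    the origin (the structural integrator modes of the conserved pairs).

    Raises
    ------
    MinimalOrderError
        if a retained zero coincides with a retained pole within 10x the
        cancellation tolerance (ambiguously coprime result).
    """
    poles = list(sla.eigvals(ss.a))
    zeros_all = _transmission_zeros(ss)

    kept_zeros = []
    for z in zeros_all:
        dist = np.array([abs(z - pp) for pp in poles])
        i = int(np.argmin(dist))
        near_origin = abs(z) < ORIGIN_FLOOR and abs(poles[i]) < ORIGIN_FLOOR
        if near_origin or dist[i] < cancel_tol * max(abs(z), abs(poles[i])):
            poles.pop(i)
        else:
            kept_zeros.append(z)
    kept_poles = poles

    near = [
        (z, pp) for z in kept_zeros for pp in kept_poles
        if abs(z - pp) < 10 * cancel_tol * max(abs(z), abs(pp))
    ]
    if near:
        raise MinimalOrderError(
            "near-cancelling pole/zero pairs remain after reduction: "
            + ", ".join(f"z={z:.6e} vs p={pp:.6e}" for z, pp in near))

    zeros = _pair_conjugates(np.array(kept_zeros))
    poles_arr = _pair_conjugates(np.array(kept_poles))

    # gain from a resolvent evaluation at a probe point away from poles/zeros
    s0 = 1j * 3.7e-3
    t0 = ss.transfer_at(s0)
    ratio = (np.prod(s0 - zeros) / np.prod(s0 - poles_arr)
             if len(zeros) else 1.0 / np.prod(s0 - poles_arr))
    gain = float((t0 / ratio).real)

    num = np.real(gain * np.poly(zeros)) if len(zeros) else np.array([gain])
    den = np.real(np.poly(poles_arr))
    return RationalTF(zeros=zeros, poles=poles_arr, gain=gain,
                      num=num, den=den)


def default_frequency_grid(lo: float = 1e-6, hi: float = 1e2,
                           points_per_decade: int = 100) -> np.ndarray:
    """Log-spaced frequency grid, rad/s.

    The upper limit extends two decades above the headline sweep so the
    unwrapped phase approaches its high-frequency asymptote to better than a
    degree; at 1 rad/s it is still ~12 deg short.
    """
    n_decades = np.log10(hi / lo)
    return np.logspace(np.log10(lo), np.log10(hi),
                       int(round(n_decades * points_per_decade)) + 1)


def _estimate_relative_degree(omega: np.ndarray, mod: np.ndarray) -> int:
    """Relative degree from the high-frequency log-log magnitude slope."""
    mask = omega >= omega[-1] / 10.0
    if mask.sum() < 2:
        mask = np.zeros_like(omega, bool)
        mask[-2:] = True
    slope = np.polyfit(np.log10(omega[mask]), np.log10(mod[mask]), 1)[0]
    return max(int(round(-slope)), 0)


def frequency_response(ss: StateSpace,
                       omega: np.ndarray | None = None) -> BodeData:
    """Modulation M(w) = |T(iw)| and continuously unwrapped phase, degrees.

    The grid must be sorted ascending and strictly positive.  If unwrapping
    jumps by more than 90 deg between adjacent points the grid is refined
    internally and a warning is issued.
    """
    omega = default_frequency_grid() if omega is None else np.asarray(omega, float)
    if np.any(omega <= 0) or np.any(np.diff(omega) <= 0):
        raise ValueError("omega grid must be positive and sorted ascending")

    for _ in range(3):
        t_vals = ss.transfer_at(1j * omega)
        phase = np.unwrap(np.angle(t_vals))
        if np.max(np.abs(np.diff(phase))) <= np.pi / 2:
            break
        warnings.warn("frequency grid too coarse for continuous phase "
                      "unwrapping; refining internally")
        fine = np.sqrt(omega[:-1] * omega[1:])
        omega = np.sort(np.concatenate([omega, fine]))

    mod = np.abs(t_vals)
    phase_deg = np.degrees(phase)
    rel_deg = _estimate_relative_degree(omega, mod)
    target = -90.0 * rel_deg
    phase_deg += 360.0 * round((target - phase_deg[-1]) / 360.0)
    return BodeData(omega=omega, modulation=mod, phase_deg=phase_deg)


def bode_metrics(bd: BodeData,
                 window: tuple[float, float] | None = None) -> dict:
    """Summary metrics of a Bode sweep.

    Returns the peak modulation (optionally restricted to a frequency
    ``window``), the frequency at which it occurs, the low-frequency phase and
    the total unwrapped phase change across the sweep (reported as an absolute
    magnitude, rounded to the nearest degree for the headline value).
    """
    if bd.omega[0] > 1e-6 or bd.omega[-1] < 1.0:
        raise ValueError("Bode sweep must span at least 1e-6 to 1 rad/s")
    mask = np.ones_like(bd.omega, bool)
    if window is not None:
        mask = (bd.omega >= window[0]) & (bd.omega <= window[1])
    mod = bd.modulation[mask]
    omg = bd.omega[mask]
    i_peak = int(np.argmax(mod))
    if i_peak in (0, len(mod) - 1):
        neighbour = mod[1] if i_peak == 0 else mod[-2]
        # a peak on a flat low-frequency plateau is genuine (DC gain maximum);
        # warn only if the curve is still changing at the boundary
        if abs(mod[i_peak] - neighbour) > 1e-4 * mod[i_peak]:
            warnings.warn("peak modulation on the grid boundary; the "
                          "frequency window is likely too narrow")
    total = abs(bd.phase_deg[-1] - bd.phase_deg[0])
    return {
        "peak_modulation": float(mod[i_peak]),
        "peak_omega_rad_s": float(omg[i_peak]),
        "low_freq_phase_deg": float(bd.phase_deg[0]),
        "high_freq_phase_deg": float(bd.phase_deg[-1]),
        "total_phase_change_deg": float(round(total)),
        "total_phase_change_deg_raw": float(total),
    }
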