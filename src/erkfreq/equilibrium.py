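"""Steady states of the pathway under constant ligand dose.

Conservation makes seven of the sixteen rate equations redundant, so the root
problem is solved in reduced coordinates: one active fraction per conserved
pair plus dusp and DUSP — nine unknowns.  This removes the seven structural
zero eigenvalues from the Newton iteration.  Solutions are polished with a
damped Newton step on a complex-step Jacobian until the full-state residual
is below ``RESIDUAL_TOL``.

Dose–response curves are traced by continuation: each converged solution
seeds the solve at the next dose, which keeps the curve on the branch that is
continuously connected to the unstimulated basal state.  A light multi-start
probe flags doses where a second distinct root is detected (relevant for the
NGF mode, whose positive feedback could in principle support multistability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import ERKSTAR, basal_state, time_derivative
from .parameters import PathwayParameters

__all__ = [
    "RESIDUAL_TOL", "Equilibrium", "DoseResponseCurve",
    "solve_equilibrium", "dose_response", "default_dose_grid",
    "EquilibriumError",
]

#: Required infinity-norm of the full dynamics vector at a reported steady state.
RESIDUAL_TOL = 1e-9

#: Indices of the active species + dusp + DUSP (the reduced unknowns).
_ACTIVE = np.array([1, 3, 5, 7, 9, 11, 13, 14, 15])
_NEG_FLOOR = -1e-9


class EquilibriumError(RuntimeError):
    """Raised when the steady-state solver fails to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the model at constant ligand input.

    Attributes
    ----------
    x : full 16-species state.
    u : constant ligand dose, Kd units.
    residual : infinity norm of the dynamics vector at (x, u).
    stable : all reduced-Jacobian eigenvalues have negative real part.
    """

    x: np.ndarray
    u: float
    residual: float
    stable: bool

    @property
    def erk_star(self) -> float:
        return float(self.x[ERKSTAR])


def _expand(z: np.ndarray, p: PathwayParameters) -> np.ndarray:
    """Reduced coordinates -> full state (inactive = total - active)."""
    totals = p.totals.as_array()
    x = np.empty(16, dtype=np.asarray(z).dtype)
    for i in range(7):
        x[2 * i] = totals[i] - z[i]
        x[2 * i + 1] = z[i]
    x[14] = z[7]
    x[15] = z[8]
    return x


def _reduced_residual(z: np.ndarray, u: float, p: PathwayParameters) -> np.ndarray:
    return time_derivative(_expand(z, p), u, p, validate=False)[_ACTIVE]


def reduced_jacobian(z: np.ndarray, u: float, p: PathwayParameters) -> np.ndarray:
    """9x9 Jacobian of the reduced residual by complex-step differentiation."""
    h = 1e-30
    jac = np.empty((9, 9))
    for j in range(9):
        zc = z.astype(complex)
        zc[j] += 1j * h
        jac[:, j] = _reduced_residual(zc, u, p).imag / h
    return jac


def _newton_polish(z: np.ndarray, u: float, p: PathwayParameters,
                   max_iter: int = 30) -> np.ndarray:
    """Damped Newton refinement of a near-root to full residual tolerance."""
    for _ in range(max_iter):
        r = _reduced_residual(z, u, p)
        rn = np.max(np.abs(r))
        if rn < 1e-14:
            break
        try:
            step = np.linalg.solve(reduced_jacobian(z, u, p), -r)
        except np.linalg.LinAlgError:
            break  # singular Jacobian: leave the iterate as-is

        lam = 1.0
        for _ in range(25):
            z_new = z + lam * step
            try:
                r_new = _reduced_residual(np.clip(z_new, _NEG_FLOOR, None), u, p)
            except ValueError:
                lam /= 2
                continue
            if np.max(np.abs(r_new)) < rn:
                z = z_new
                break
            lam /= 2
        else:
            break
    return z


def _attempt(z0: np.ndarray, u: float, p: PathwayParameters):
    # hybr trial points may overflow the Hill terms; the limits are benign
    with np.errstate(over="ignore", invalid="ignore"):
        sol = root(_reduced_residual, z0, args=(u, p), method="hybr",
                   tol=1e-13)
        z = _newton_polish(sol.x, u, p)
        res = float(np.max(np.abs(_reduced_residual(z, u, p))))
    return z, res


def _reduced_guess(guess: np.ndarray | None, p: PathwayParameters) -> np.ndarray:
    x = basal_state(p) if guess is None else np.asarray(guess, dtype=float)
    z = x[_ACTIVE].copy()
    # keep the Newton start strictly interior
    z[:7] = np.clip(z[:7], 1e-4, None)
    return z


def solve_equilibrium(p: PathwayParameters, u_const: float,
                      guess: np.ndarray | None = None) -> Equilibrium:
    """Solve the nonlinear steady state at constant ligand dose ``u_const``.

    Falls back to dose continuation from the basal state when a direct solve
    fails or converges to a negative-concentration root.

    Raises
    ------
    EquilibriumError
        if no root with residual < 1e-9 and non-negative species is found.
    """
    if u_const < 0:
        raise ValueError("ligand dose must be non-negative")
    z0 = _reduced_guess(guess, p)
    z, res = _attempt(z0, u_const, p)
    if res > RESIDUAL_TOL or np.min(_expand(z, p)) < _NEG_FLOOR:
        # continuation from the basal state in gentle dose steps
        z = _reduced_guess(None, p)
        for uu in np.linspace(min(1e-3, u_const), u_const, 40):
            z, res = _attempt(z, uu, p)
        if res > RESIDUAL_TOL or np.min(_expand(z, p)) < _NEG_FLOOR:
            raise EquilibriumError(
                f"steady-state solve failed at dose {u_const} "
                f"(residual {res:.2e})", residual=res)
    x = _expand(z, p)
    x[np.abs(x) < 1e-15] = np.abs(x[np.abs(x) < 1e-15])  # clear signed zeros
    eig = np.linalg.eigvals(reduced_jacobian(z, u_const, p))
    return Equilibrium(x=x, u=float(u_const), residual=res,
                       stable=bool(np.all(eig.real < 0)))


@dataclass(frozen=True)
class DoseResponseCurve:
    """Equilibrium ERK* as a function of constant ligand dose."""

    doses: np.ndarray
    erk_star: np.ndarray
    stable: np.ndarray
    multistable: np.ndarray
    ligand_mode: str
    equilibria: tuple = field(repr=False, default=())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_kd": self.doses,
            "erk_star": self.erk_star,
            "stable": self.stable,
            "ligand_mode": self.ligand_mode,
        })


def default_dose_grid() -> np.ndarray:
    """60 log-spaced doses from 1e-3 to 2.5 Kd."""
    return np.logspace(np.log10(1e-3), np.log10(2.5), 60)


def dose_response(p: PathwayParameters,
                  doses: np.ndarray | None = None,
                  probe_multistability: bool = True) -> DoseResponseCurve:
    """Trace the equilibrium branch continued from the basal state.

    ``doses`` must be sorted ascending and non-negative.  When
    ``probe_multistability`` is on, each dose is re-solved from a
    high-activation start and flagged if a distinct second root appears.
    """
    doses = default_dose_grid() if doses is None else np.asarray(doses, float)
    if np.any(np.diff(doses) < 0) or np.any(doses < 0):
        raise ValueError("doses must be sorted ascending and non-negative")

    eqs: list[Equilibrium] = []
    multistable = np.zeros(doses.size, dtype=bool)
    guess = None
    for i, u in enumerate(doses):
        try:
            eq = solve_equilibrium(p, u, guess=guess)
        except EquilibriumError as err:
            raise EquilibriumError(
                f"dose-response continuation failed at dose {u}: {err}",
                residual=err.residual) from err
        eqs.append(eq)
        guess = eq.x
        if probe_multistability:
            z_hi = np.full(9, 0.9)
            z_hi[7:] = p.duspbasal * (1 + p.duspind)
            z_alt, res_alt = _attempt(z_hi, u, p)
            if (res_alt < RESIDUAL_TOL
                    and np.min(_expand(z_alt, p)) > _NEG_FLOOR
                    and abs(_expand(z_alt, p)[ERKSTAR] - eq.erk_star) > 1e-6):
                multistable[i] = True

    return DoseResponseCurve(
        doses=doses,
        erk_star=np.array([e.erk_star for e in eqs]),
        stable=np.array([e.stable for e in eqs]),
        multistable=multistable,
        ligand_mode=p.ligand_mode,
        equilibria=tuple(eqs),
    )
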