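"""Species, reaction fluxes and time derivative of the ERK pathway model.

The state vector holds 16 species: seven inactive/active pairs

    x1=R,   x2=R*    (receptor)
    x3=Ras, x4=Ras*
    x5=Raf, x6=Raf*
    x7=MEK, x8=MEK*
    x9=ERK, x10=ERK*
    x11=NFB, x12=NFB*  (negative feedback protein)
    x13=PFB, x14=PFB*  (positive feedback protein, NGF only)

plus the DUSP expression tier, x15=dusp (transcript) and x16=DUSP (protein),
which is not conserved.  The phosphatases (PtaseR, PtaseRaf, PtaseMEK,
PtaseNFB, PtasePFB) and GAP are constant abundances folded into the rate laws,
which is why the 19-species reaction scheme reduces to 16 dynamical states.

Each activation flux is a net forward-minus-reverse rate with Michaelis
saturation on the substrate of each direction; three Hill-type gates shape the
feedbacks: NFB* suppresses Raf activation through KNFB^2/(KNFB^2+NFB*^2),
receptor activity gates NFB activation through R*^2/(K3R^2+R*^2), and ERK*
induces dusp transcription through ERK*^2/(Kdusp+ERK*^2).  The dusp/DUSP tier
uses first-order production/decay with half-life time constants Tdusp, TDUSP
(the log 2 factors convert half-lives to rates).

All functions accept complex-valued states so derivatives can be taken by
complex-step differentiation.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .parameters import PathwayParameters

__all__ = [
    "SPECIES", "N_STATES", "ERKSTAR", "PAIR_SLICES",
    "FluxVector", "reaction_fluxes", "time_derivative", "basal_state",
    "pair_sums",
]

SPECIES = (
    "R", "R*", "Ras", "Ras*", "Raf", "Raf*", "MEK", "MEK*",
    "ERK", "ERK*", "NFB", "NFB*", "PFB", "PFB*", "dusp", "DUSP",
)
N_STATES = 16
#: Index of the model output ERK* in the state vector.
ERKSTAR = 9
#: (inactive, active) index pairs subject to conservation.
PAIR_SLICES = tuple((2 * i, 2 * i + 1) for i in range(7))

LOG2 = np.log(2.0)


class FluxVector(NamedTuple):
    """Reaction rates of the model, in the conventional naming.

    v1 receptor activation; v6 Ras activation; v5 Raf activation (NFB*-gated);
    v5a Raf activation by PFB*; v4 MEK activation; v2 ERK activation;
    v3a NFB activation (R*-gated); v7a PFB activation; v8/v9 dusp transcript
    production/decay; v10/v11 DUSP protein production/decay.
    """

    v1: float
    v6: float
    v5: float
    v5a: float
    v4: float
    v2: float
    v3a: float
    v7a: float
    v8: float
    v9: float
    v10: float
    v11: float


def _check_domain(x: np.ndarray, u: float) -> None:
    if np.iscomplexobj(x) or isinstance(u, complex):
        return  # complex-step probe: sign checks are meaningless
    if np.any(np.asarray(x) < 0):
        raise ValueError("state entries must be non-negative")
    if u < 0:
        raise ValueError("ligand input must be non-negative")


def reaction_fluxes(x: np.ndarray, u: float, p: PathwayParameters,
                    validate: bool = True) -> FluxVector:
    """Evaluate the twelve reaction fluxes at state ``x`` and ligand dose ``u``.

    Parameters
    ----------
    x : array of 16 species values (may be complex for derivative probes).
    u : ligand concentration in Kd units.
    p : parameter set.
    validate : reject negative states/inputs; root-finders disable this for
        their own trial iterates.
    """
    if validate:
        _check_domain(x, u)
    (R, Rs, Ras, Rass, Raf, Rafs, MEK, MEKs,
     ERK, ERKs, NFB, NFBs, PFB, PFBs, dusp, DUSP) = x

    v1 = p.k1R * R * u - p.kd1R * p.PtaseR * Rs
    v6 = (p.k6R * Rs * Ras / (p.K6 + Ras)
          - p.kd6 * p.GAP * Rass / (p.D6 + Rass))
    v5 = (p.k5 * Rass * Raf / (p.K5 + Raf)
          * p.KNFB**2 / (p.KNFB**2 + NFBs**2)
          - p.kd5 * p.PtaseRaf * Rafs / (p.D5 + Rafs))
    v5a = p.kPFB * PFBs * Raf / (p.KPFB + Raf)
    # Reverse Michaelis term saturates in MEK (not MEK*).
    v4 = (p.k4 * Rafs * MEK / (p.K4 + MEK)
          - p.kd4 * p.PtaseMEK * MEKs / (p.D4 + MEK))
    v2 = (p.k2 * MEKs * ERK / (p.K2 + ERK)
          - p.kd2 * DUSP * ERKs / (p.D2 + ERKs))
    v3a = (p.k3F * ERKs * NFB / (p.K3 + NFB)
           * Rs**2 / (p.K3R**2 + Rs**2)
           - p.kd3 * p.PtaseNFB * NFBs / (p.D3 + NFBs))
    v7a = (p.k7 * ERKs * Rs * PFB / (p.K7 + PFB)
           - p.kd7 * p.PtasePFB * PFBs / (p.D7 + PFBs))
    hill_den = (p.Kdusp**2 if p.v8_hill_squared else p.Kdusp) + ERKs**2
    v8 = p.duspbasal * (1 + p.duspind * ERKs**2 / hill_den) * LOG2 / p.Tdusp
    v9 = dusp * LOG2 / p.Tdusp
    v10 = dusp * LOG2 / p.TDUSP
    v11 = DUSP * LOG2 / p.TDUSP
    return FluxVector(v1, v6, v5, v5a, v4, v2, v3a, v7a, v8, v9, v10, v11)


def time_derivative(x: np.ndarray, u: float, p: PathwayParameters,
                    validate: bool = True) -> np.ndarray:
    """Signed assembly of the fluxes into dx/dt for all 16 states."""
    v = reaction_fluxes(x, u, p, validate=validate)
    raf_net = v.v5 + v.v5a
    out = np.empty(16, dtype=np.result_type(np.asarray(x).dtype, float))
    out[0] = -v.v1
    out[1] = v.v1
    out[2] = -v.v6
    out[3] = v.v6
    out[4] = -raf_net
    out[5] = raf_net
    out[6] = -v.v4
    out[7] = v.v4
    out[8] = -v.v2
    out[9] = v.v2
    out[10] = -v.v3a
    out[11] = v.v3a
    out[12] = -v.v7a
    out[13] = v.v7a
    out[14] = v.v8 - v.v9
    out[15] = v.v10 - v.v11
    return out


def basal_state(p: PathwayParameters) -> np.ndarray:
    """Fully inactive resting state.

    Every activation pair sits entirely in its inactive form; dusp and DUSP
    are at their zero-ERK* fixed point (dusp = DUSP = duspbasal), so the state
    is an exact equilibrium of the unstimulated (u=0) model.
    """
    x = np.zeros(16)
    t = p.totals
    x[0], x[2], x[4], x[6], x[8], x[10], x[12] = (
        t.R, t.Ras, t.Raf, t.MEK, t.ERK, t.NFB, t.PFB)
    x[14] = x[15] = p.duspbasal
    return x


def pair_sums(x: np.ndarray) -> np.ndarray:
    """Sum of each conserved (inactive, active) pair; constant along trajectories."""
    x = np.asarray(x)
    return np.stack([x[..., i] + x[..., j] for i, j in PAIR_SLICES], axis=-1)
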