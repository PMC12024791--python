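"""Unit and property tests for the pathway fluxes and time derivative."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from erkfreq import (PathwayParameters, Totals, basal_state, pair_sums,
                     reaction_fluxes, time_derivative)

fractions = st.floats(0.0, 1.0, allow_nan=False)
doses = st.floats(0.0, 5.0, allow_nan=False)


def _state(active, dusp=1.0, DUSP=1.0):
    """Full state from 7 active fractions (totals 1) plus dusp/DUSP."""
    x = np.empty(16)
    for i, a in enumerate(active):
        x[2 * i] = 1.0 - a
        x[2 * i + 1] = a
    x[14], x[15] = dusp, DUSP
    return x


def test_receptor_flux_vanishes_without_ligand_or_active_receptor(egf):
    x = _state([0.0] * 7)
    v = reaction_fluxes(x, 0.0, egf)
    assert v.v1 == 0.0


def test_basal_dusp_production_rate(egf):
    # with no active ERK the dusp transcription runs at its basal rate,
    # duspbasal * ln2 / Tdusp = 1.28362e-4 s^-1 (hand arithmetic, Tdusp = 90 min)
    x = _state([0.5, 0.5, 0.5, 0.5, 0.0, 0.5, 0.5])
    v = reaction_fluxes(x, 0.1, egf)
    assert v.v8 == pytest.approx(1.28362e-4, rel=1e-4)


def test_raf_activation_suppressed_at_high_negative_feedback(egf):
    # the KNFB^2/(KNFB^2+NFB*^2) gate kills the forward term as NFB* grows
    x_hi = _state([0.5] * 7)
    x_hi[11] = 1e6
    v_hi = reaction_fluxes(x_hi, 0.1, egf)
    reverse = -egf.kd5 * egf.PtaseRaf * x_hi[5] / (egf.D5 + x_hi[5])
    assert v_hi.v5 == pytest.approx(reverse, rel=1e-9)


@given(active=st.lists(fractions, min_size=7, max_size=7),
       dusp=st.floats(0, 8), DUSP=st.floats(0, 8), u=doses)
def test_derivative_conserves_each_pair(active, dusp, DUSP, u):
    p = PathwayParameters.ngf()
    f = time_derivative(_state(active, dusp, DUSP), u, p)
    for i in range(7):
        assert f[2 * i] + f[2 * i + 1] == pytest.approx(0.0, abs=1e-18)


@given(active=st.lists(fractions, min_size=7, max_size=7), u=doses)
def test_dusp_tier_derivatives_are_production_minus_decay(active, u):
    p = PathwayParameters.egf()
    x = _state(active, dusp=0.7, DUSP=1.3)
    v = reaction_fluxes(x, u, p)
    f = time_derivative(x, u, p)
    assert f[14] == pytest.approx(v.v8 - v.v9, abs=1e-18)
    assert f[15] == pytest.approx(v.v10 - v.v11, abs=1e-18)
    # production/decay fluxes are non-negative on non-negative states
    assert min(v.v8, v.v9, v.v10, v.v11) >= 0.0


@given(active=st.lists(fractions, min_size=7, max_size=7), u=doses)
def test_ligand_modes_differ_only_through_positive_feedback(active, u):
    x = _state(active)
    v_egf = reaction_fluxes(x, u, PathwayParameters.egf())
    v_ngf = reaction_fluxes(x, u, PathwayParameters.ngf())
    assert v_egf.v5a == 0.0
    for name in v_egf._fields:
        if name != "v5a":
            assert getattr(v_egf, name) == getattr(v_ngf, name)


def test_basal_state_is_unstimulated_fixed_point(egf, ngf):
    for p in (egf, ngf):
        f = time_derivative(basal_state(p), 0.0, p)
        assert np.max(np.abs(f)) < 1e-15


def test_pair_sums_track_configured_totals():
    p = PathwayParameters.egf(totals=Totals(R=2.0))
    sums = pair_sums(basal_state(p))
    assert sums[0] == 2.0 and np.all(sums[1:] == 1.0)


def test_negative_state_rejected(egf):
    x = basal_state(egf)
    x[3] = -0.1
    with pytest.raises(ValueError):
        reaction_fluxes(x, 0.0, egf)
    with pytest.raises(ValueError):
        time_derivative(basal_state(egf), -1.0, egf)


def test_parameter_validation():
    with pytest.raises(ValueError):
        PathwayParameters.egf(k2=-1.0)
    with pytest.raises(ValueError):
        PathwayParameters.egf(K5=0.0)  # saturating denominator constant
    with pytest.raises(ValueError):
        PathwayParameters(ligand_mode="egf", kPFB=0.75 / 60)  # EGF has no PFB
    with pytest.raises(ValueError):
        Totals(ERK=0.0)


def test_bundled_parameter_files_reproduce_published_constants():
    for mode in ("egf", "ngf"):
        assert (PathwayParameters.bundled(mode)
                == PathwayParameters.for_mode(mode))


def test_parameter_yaml_roundtrip_and_strictness(tmp_path, ngf):
    path = tmp_path / "params.yaml"
    ngf.to_yaml(path)
    assert PathwayParameters.from_yaml(path) == ngf
    path.write_text(path.read_text() + "k_unknown: 1.0\n")
    with pytest.raises(ValueError, match="unknown parameter"):
        PathwayParameters.from_yaml(path)
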