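#!/usr/bin/env python
"""Bode plots across receptor occupancy: amplifier to suppressor.

Linearizes the pathway at equilibria spanning low (0.01 Kd), medium
(0.25/0.48 Kd) and high (2.1 Kd) mean ligand dose and reduces each to its
minimal rational transfer function.  Findings: at 0.01 Kd the circuit is a
low-pass amplifier (gain ~10, zero low-frequency phase, 450 degrees of total
phase rotation — a five-stage kinetic chain); by 0.5 Kd it suppresses all
fluctuations (modulation < 1, 180-degree low-frequency phase); the NGF
circuit at 0.25 Kd carries 810 degrees of total phase, two extra quarter
turns from the feedback loops.
"""

from pathlib import Path

from erkfreq import run_scenario

OUT = Path(__file__).resolve().parents[1] / "results"


def _describe(tag: str, report: dict) -> None:
    m = report["metrics"]
    print(f"{tag}: ERK*e={report['equilibrium_erk_star']:.3f}  "
          f"orders={tuple(report['orders'])}  "
          f"peak M={report['peak_modulation_1e-5_1e-2']:.3g}  "
          f"low-f phase={m['low_freq_phase_deg']:.0f} deg  "
          f"total phase change={m['total_phase_change_deg']:.0f} deg")


def main() -> None:
    _describe("EGF 0.01 Kd", run_scenario("fig3_bode_low", OUT / "fig3"))
    _describe("EGF 0.48 Kd", run_scenario("fig3_bode_mid", OUT / "fig3"))
    fig5 = run_scenario("fig5_bode_moderate", OUT / "fig5")
    _describe("EGF 0.25 Kd", fig5["egf"])
    _describe("NGF 0.25 Kd", fig5["ngf"])
    _describe("EGF 2.10 Kd", run_scenario("fig8_bode_high", OUT / "fig8"))
    print(f"Bode tables and transfer functions written under {OUT}")


if __name__ == "__main__":
    main()
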