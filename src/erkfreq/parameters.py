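"""Rate constants and conserved totals for the ERK pathway model.

The model describes ligand-driven activation of the EGFR/TrkA -> Ras -> Raf ->
MEK -> ERK cascade with three regulatory layers: an unidentified negative
feedback protein (NFB, active for both EGF and NGF), an unidentified positive
feedback protein (PFB, active only under NGF), and ERK*-induced expression of
the phosphatase DUSP.  All first-order rate constants are in s^-1; Michaelis
and Hill constants, phosphatase/GAP abundances and conserved totals are
dimensionless fractions.  Ligand concentration is expressed in units of the
receptor dissociation constant Kd (the forward and reverse receptor rate
constants are equal, so a dose of 1 Kd gives half receptor occupancy at
equilibrium).

The two ligand modes differ in a single constant: ``kPFB`` is zero for EGF and
0.75/60 s^-1 for NGF, switching the positive feedback loop on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["Totals", "PathwayParameters", "RATE_CONSTANTS"]

#: Literature rate constants shared by both ligand modes (s^-1 or unitless).
RATE_CONSTANTS: dict[str, float] = {
    "k1R": 0.5 / 60,
    "kd1R": 0.5 / 60,
    "PtaseR": 1.0,
    "k2": 2.0 / 60,
    "K2": 1.0,
    "kd2": 0.25 / 60,
    "D2": 0.1,
    "k3F": 0.0286 / 60,
    "K3": 0.01,
    "K3R": 0.85,
    "kd3": 0.0057 / 60,
    "D3": 0.5,
    "PtaseNFB": 1.0,
    "k4": 2.0 / 60,
    "K4": 1.0,
    "kd4": 0.5 / 60,
    "D4": 1.0,
    "PtaseMEK": 1.0,
    "k5": 10.0 / 60,
    "K5": 1.0,
    "kd5": 3.75 / 60,
    "D5": 1.0,
    "KNFB": 0.05,
    "PtaseRaf": 1.0,
    "KPFB": 0.01,
    "k6R": 40.0 / 60,
    "K6": 1.0,
    "kd6": 7.5 / 60,
    "D6": 1.0,
    "GAP": 1.0,
    "k7": 0.1 / 60,
    "K7": 0.1,
    "kd7": 0.005 / 60,
    "D7": 0.1,
    "PtasePFB": 1.0,
    "duspbasal": 1.0,
    "duspind": 6.0,
    "Kdusp": 0.1,
    "Tdusp": 90.0 * 60,
    "TDUSP": 90.0 * 60,
}

KPFB_BY_MODE = {"egf": 0.0, "ngf": 0.75 / 60}

# Constants that must be strictly positive (they appear in denominators).
_POSITIVE = {
    "K2", "D2", "K3", "K3R", "D3", "K4", "D4", "K5", "D5", "KNFB",
    "KPFB", "K6", "D6", "K7", "D7", "Kdusp", "Tdusp", "TDUSP",
}


@dataclass(frozen=True)
class Totals:
    """Conserved total for each activation pair, as unitless fractions.

    All model outputs are activation fractions, so every pair total
    defaults to 1.0; they are configurable to allow reconciliation with other
    parameterizations.
    """

    R: float = 1.0
    Ras: float = 1.0
    Raf: float = 1.0
    MEK: float = 1.0
    ERK: float = 1.0
    NFB: float = 1.0
    PFB: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"total {f.name} must be strictly positive")

    def as_array(self):
        import numpy as np

        return np.array([self.R, self.Ras, self.Raf, self.MEK, self.ERK,
                         self.NFB, self.PFB])


@dataclass(frozen=True)
class PathwayParameters:
    """Complete parameter set for the ERK pathway model.

    Construct with :meth:`egf` or :meth:`ngf` for the standard ligand modes,
    or load a flat key-value YAML file with :meth:`from_yaml`.

    ``v8_hill_squared`` switches the DUSP-induction Hill denominator from the
    default ``Kdusp + ERK*^2`` to ``Kdusp^2 + ERK*^2``; it is off by default
    and exists only for sensitivity analysis.
    """

    ligand_mode: str = "egf"
    kPFB: float = 0.0
    totals: Totals = field(default_factory=Totals)
    v8_hill_squared: bool = False

    # Shared rate constants; defaults are the literature values.
    k1R: float = RATE_CONSTANTS["k1R"]
    kd1R: float = RATE_CONSTANTS["kd1R"]
    PtaseR: float = RATE_CONSTANTS["PtaseR"]
    k2: float = RATE_CONSTANTS["k2"]
    K2: float = RATE_CONSTANTS["K2"]
    kd2: float = RATE_CONSTANTS["kd2"]
    D2: float = RATE_CONSTANTS["D2"]
    k3F: float = RATE_CONSTANTS["k3F"]
    K3: float = RATE_CONSTANTS["K3"]
    K3R: float = RATE_CONSTANTS["K3R"]
    kd3: float = RATE_CONSTANTS["kd3"]
    D3: float = RATE_CONSTANTS["D3"]
    PtaseNFB: float = RATE_CONSTANTS["PtaseNFB"]
    k4: float = RATE_CONSTANTS["k4"]
    K4: float = RATE_CONSTANTS["K4"]
    kd4: float = RATE_CONSTANTS["kd4"]
    D4: float = RATE_CONSTANTS["D4"]
    PtaseMEK: float = RATE_CONSTANTS["PtaseMEK"]
    k5: float = RATE_CONSTANTS["k5"]
    K5: float = RATE_CONSTANTS["K5"]
    kd5: float = RATE_CONSTANTS["kd5"]
    D5: float = RATE_CONSTANTS["D5"]
    KNFB: float = RATE_CONSTANTS["KNFB"]
    PtaseRaf: float = RATE_CONSTANTS["PtaseRaf"]
    KPFB: float = RATE_CONSTANTS["KPFB"]
    k6R: float = RATE_CONSTANTS["k6R"]
    K6: float = RATE_CONSTANTS["K6"]
    kd6: float = RATE_CONSTANTS["kd6"]
    D6: float = RATE_CONSTANTS["D6"]
    GAP: float = RATE_CONSTANTS["GAP"]
    k7: float = RATE_CONSTANTS["k7"]
    K7: float = RATE_CONSTANTS["K7"]
    kd7: float = RATE_CONSTANTS["kd7"]
    D7: float = RATE_CONSTANTS["D7"]
    PtasePFB: float = RATE_CONSTANTS["PtasePFB"]
    duspbasal: float = RATE_CONSTANTS["duspbasal"]
    duspind: float = RATE_CONSTANTS["duspind"]
    Kdusp: float = RATE_CONSTANTS["Kdusp"]
    Tdusp: float = RATE_CONSTANTS["Tdusp"]
    TDUSP: float = RATE_CONSTANTS["TDUSP"]

    def __post_init__(self) -> None:
        if self.ligand_mode not in ("egf", "ngf", "custom"):
            raise ValueError(f"unknown ligand_mode {self.ligand_mode!r}")
        for name in RATE_CONSTANTS:
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"rate constant {name} must be non-negative")
            if name in _POSITIVE and value <= 0:
                raise ValueError(f"constant {name} must be strictly positive")
        if self.kPFB < 0:
            raise ValueError("kPFB must be non-negative")
        if self.ligand_mode in KPFB_BY_MODE:
            expected = KPFB_BY_MODE[self.ligand_mode]
            if abs(self.kPFB - expected) > 1e-15:
                raise ValueError(
                    f"kPFB={self.kPFB!r} inconsistent with ligand_mode="
                    f"{self.ligand_mode!r} (expected {expected!r}); use "
                    "ligand_mode='custom' to override"
                )

    @classmethod
    def egf(cls, **overrides) -> "PathwayParameters":
        """Literature parameter set for EGF stimulation (no positive feedback)."""
        return cls(ligand_mode="egf", kPFB=KPFB_BY_MODE["egf"], **overrides)

    @classmethod
    def ngf(cls, **overrides) -> "PathwayParameters":
        """Literature parameter set for NGF stimulation (positive feedback on)."""
        return cls(ligand_mode="ngf", kPFB=KPFB_BY_MODE["ngf"], **overrides)

    @classmethod
    def for_mode(cls, ligand_mode: str, **overrides) -> "PathwayParameters":
        if ligand_mode not in KPFB_BY_MODE:
            raise ValueError(f"unknown ligand_mode {ligand_mode!r}")
        return cls(ligand_mode=ligand_mode, kPFB=KPFB_BY_MODE[ligand_mode],
                   **overrides)

    # ---------------------------------------------------------------- I/O

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in RATE_CONSTANTS}
        d["kPFB"] = self.kPFB
        d["ligand_mode"] = self.ligand_mode
        for f in dataclasses.fields(Totals):
            d[f"total_{f.name}"] = getattr(self.totals, f.name)
        return d

    def to_yaml(self, path: str | Path) -> None:
        """Write the parameter set as a flat key-value YAML file."""
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PathwayParameters":
        """Load a flat key-value YAML parameter file (strict: unknown keys fatal)."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        mode = raw.pop("ligand_mode", "custom")
        totals_kw = {}
        for f in dataclasses.fields(Totals):
            key = f"total_{f.name}"
            if key in raw:
                totals_kw[f.name] = float(raw.pop(key))
        known = set(RATE_CONSTANTS) | {"kPFB"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
        kw = {k: float(v) for k, v in raw.items()}
        return cls(ligand_mode=mode, totals=Totals(**totals_kw), **kw)

    @classmethod
    def bundled(cls, ligand_mode: str) -> "PathwayParameters":
        """Load the bundled default parameter file for a ligand mode."""
        ref = resources.files("erkfreq.data") / f"table1_{ligand_mode}.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)
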