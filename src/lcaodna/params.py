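"""Semi-empirical LCAO parameter set.

The model has three ingredients: per-orbital on-site energies for H 1s and
C/N/O 2s, 2p; dimensionless Slater–Koster channel constants χ for ssσ, spσ,
ppσ, ppπ couplings; and a damping factor ``b`` applied once per participating
H 1s orbital.  Two distance laws are used for the coupling magnitude
V_χ(d):

* ``harrison`` — V_χ = χ ħ²/(m d²), valid at covalent-bond distances and used
  for bonded atoms inside a molecule;
* ``exponential`` — V_χ = χ ħ²/(m d0²) exp(−β (d − d0)), used beyond covalent
  range (hydrogen bonds, base-pair steps), with d0 a reference covalent
  length and β the decay rate.

The default numbers are the nucleic-acid-base parameterization fitted to
experimental ionization and excitation energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .constants import HBAR2_OVER_M

#: Default on-site energies (eV), keyed by (element, orbital shell).
DEFAULT_ONSITE = {
    ("H", "s"): -13.64,
    ("C", "s"): -13.18,
    ("C", "p"): -6.70,
    ("N", "s"): -14.51,
    ("N", "p"): -9.55,
    ("O", "s"): -15.03,
    ("O", "p"): -11.52,
}

#: Default dimensionless Slater–Koster channel constants.
DEFAULT_CHI = {"ss_sigma": -1.32, "sp_sigma": -1.42, "pp_sigma": 2.22, "pp_pi": -0.73}


@dataclass(frozen=True)
class LcaoParameters:
    """Complete parameter set for the all-valence LCAO Hamiltonian.

    Attributes
    ----------
    onsite:
        Map (element, shell) → on-site energy in eV, shell ∈ {"s", "p"}.
    chi:
        Map channel → dimensionless constant, channel ∈
        {"ss_sigma", "sp_sigma", "pp_sigma", "pp_pi"}.
    b:
        Damping factor applied multiplicatively once per H 1s orbital taking
        part in a coupling (so b² for H–H).
    d0:
        Reference covalent bond length (Å) of the exponential distance law.
    beta:
        Decay rate (Å⁻¹) of the exponential distance law; default 2/d0.
    hbar2_over_m:
        ħ²/mₑ in eV·Å².
    """

    onsite: dict = field(default_factory=lambda: dict(DEFAULT_ONSITE))
    chi: dict = field(default_factory=lambda: dict(DEFAULT_CHI))
    b: float = 0.70
    d0: float = 1.35
    beta: float = 2.0 / 1.35
    hbar2_over_m: float = HBAR2_OVER_M

    def __post_init__(self):
        for key, value in self.onsite.items():
            if value >= 0:
                raise ValueError(f"on-site energy {key} must be negative, got {value}")
        if not (self.chi["pp_sigma"] > 0 and self.chi["ss_sigma"] < 0
                and self.chi["sp_sigma"] < 0 and self.chi["pp_pi"] < 0):
            raise ValueError("chi constants have unphysical signs")
        if not 0 < self.b <= 1:
            raise ValueError(f"b must be in (0, 1], got {self.b}")
        if self.d0 <= 0 or self.beta <= 0:
            raise ValueError("d0 and beta must be positive")

    def with_(self, **kwargs) -> "LcaoParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "LcaoParameters":
        """Load a parameter file.

        Schema (all keys optional, defaults fill the rest)::

            onsite: {H_1s: -13.64, C_2s: -13.18, C_2p: -6.70, ...}
            chi: {ss_sigma: -1.32, sp_sigma: -1.42, pp_sigma: 2.22, pp_pi: -0.73}
            b: 0.70
            d0: 1.35
            beta: 1.4815
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        onsite = dict(DEFAULT_ONSITE)
        for key, value in (raw.get("onsite") or {}).items():
            element, shell = key.split("_")
            onsite[(element, shell[-1])] = float(value)
        chi = dict(DEFAULT_CHI)
        chi.update({k: float(v) for k, v in (raw.get("chi") or {}).items()})
        kwargs = {}
        for name in ("b", "d0", "beta"):
            if name in raw:
                kwargs[name] = float(raw[name])
        if "d0" in kwargs and "beta" not in kwargs:
            kwargs["beta"] = 2.0 / kwargs["d0"]
        return cls(onsite=onsite, chi=chi, **kwargs)

    def to_yaml(self, path) -> None:
        """Write the parameter set in the schema read by :meth:`from_yaml`."""
        onsite = {}
        for (element, shell), value in self.onsite.items():
            label = f"{element}_{'1s' if element == 'H' else '2' + shell}"
            onsite[label] = value
        payload = {
            "onsite": onsite,
            "chi": dict(self.chi),
            "b": self.b,
            "d0": self.d0,
            "beta": self.beta,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
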