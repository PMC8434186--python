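"""Physical constants and element tables used throughout the package.

Energies are in eV, lengths in Å, times in fs unless stated otherwise.
"""

#: ħ²/mₑ in eV·Å² — sets the scale of Harrison-type two-center couplings.
HBAR2_OVER_M = 7.6199682

#: 1 hartree in eV.
HARTREE_EV = 27.211386

#: 1 bohr in Å.
BOHR_A = 0.529177

#: ħ in eV·fs — converts tight-binding energies to oscillation periods.
HBAR_EV_FS = 0.6582119569

#: Elements the all-valence parameterization supports.
SUPPORTED_ELEMENTS = ("H", "C", "N", "O")

#: Covalent radii (Å) for bond detection (Cordero consensus values).
COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66}

#: Valence electrons contributed by each neutral atom.
VALENCE_ELECTRONS = {"H": 1, "C": 4, "N": 5, "O": 6}

#: Valence orbitals carried by each element: 1s for H, 2s+2p for C/N/O.
ORBITALS = {
    "H": ("s",),
    "C": ("s", "px", "py", "pz"),
    "N": ("s", "px", "py", "pz"),
    "O": ("s", "px", "py", "pz"),
}

#: Minimum credible interatomic distance (Å); anything closer is a clash.
MIN_DISTANCE = 0.4
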