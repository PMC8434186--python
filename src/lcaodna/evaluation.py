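"""Benchmarking: computed π ionization / π→π* excitation energies versus
reference data, and root-mean-square percentage errors.

The benchmark convention: the ionization energy is −E of the highest
occupied π molecular orbital and the excitation energy is the gap from that
orbital to the lowest unoccupied π orbital (for most of the set these are
simply the HOMO and LUMO; pyridazine's n-type HOMO and the azoles' σ*
LUMOs are the exceptions, and the π-channel convention matches what the
experimental π bands measure).  RMSPE is always taken against the
experimental column; coupled-cluster values are reported alongside but
never enter the error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import fixtures
from .lcao import frontier_by_character, oscillator_strength, solve_molecule
from .params import LcaoParameters

SUBSETS = {
    "nucleobases": ["adenine", "guanine", "thymine", "cytosine", "uracil"],
    "purines": ["adenine", "guanine", "purine_9h", "purine_7h", "aminopurine_2"],
    "pyrimidines": ["thymine", "cytosine", "uracil", "pyrazine", "pyrimidine",
                    "pyridazine", "pyrazine_14_dioxide"],
    "azoles": ["imidazole_1h", "pyrazole_1h", "benzimidazole_1h",
               "indazole_1h", "indazole_2h", "azaindole_7"],
}
SUBSETS["all"] = (SUBSETS["nucleobases"] + SUBSETS["purines"][2:]
                  + SUBSETS["pyrimidines"][3:] + SUBSETS["azoles"])


@dataclass(frozen=True)
class BenchmarkRecord:
    """One molecule/quantity comparison against one reference value."""

    molecule: str
    quantity: str
    calculated: float
    reference: float
    reference_kind: str

    def __post_init__(self):
        if self.calculated <= 0 or self.reference <= 0:
            raise ValueError("ionization/excitation comparisons need positive values")


def rmspe(calc, ref) -> float:
    """Root-mean-square percentage error, 100·sqrt(mean(((c−r)/r)²))."""
    calc = np.asarray(calc, float)
    ref = np.asarray(ref, float)
    if calc.shape != ref.shape or calc.size == 0:
        raise ValueError("calc and ref must be equal-length non-empty lists")
    if np.any(ref == 0):
        raise ValueError("reference values must be nonzero")
    return 100.0 * math.sqrt(float(np.mean(((calc - ref) / ref) ** 2)))


def load_reference_table() -> pd.DataFrame:
    """The packaged reference-energy table (tidy TSV)."""
    path = resources.files("lcaodna") / "data" / "reference_energies.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def pi_energies(name: str, params: LcaoParameters | None = None):
    """(π ionization, π→π* excitation, oscillator strength, Spectrum) for a
    packaged molecule."""
    mol = fixtures.heterocycle(name)
    spec = solve_molecule(mol, params)
    try:
        k_h = frontier_by_character(spec, "pi", occupied=True)
        k_l = frontier_by_character(spec, "pi", occupied=False)
    except LookupError:  # no π system resolved; fall back to plain frontier
        k_h, k_l = spec.homo_index, spec.lumo_index
    ionization = -float(spec.energies[k_h])
    excitation = float(spec.energies[k_l] - spec.energies[k_h])
    f, _ = oscillator_strength(spec, mol, k_h, k_l)
    return ionization, excitation, f, spec


def benchmark_report(subset: str = "all",
                     params: LcaoParameters | None = None) -> pd.DataFrame:
    """Benchmark table: one row per molecule with calculated π ionization,
    π→π* excitation and oscillator strength next to the experimental and
    coupled-cluster reference values.

    Molecules without a packaged geometry are skipped with a ``skipped``
    marker row rather than failing the whole report.
    """
    names = SUBSETS.get(subset)
    if names is None:
        raise KeyError(f"unknown subset {subset!r}; choose from {sorted(SUBSETS)}")
    ref = load_reference_table()
    ref = ref[ref.channel.isin(["pi", "pi_pistar"])]

    def lookup(molecule, quantity, kind):
        sel = ref[(ref.molecule == molecule) & (ref.quantity == quantity)
                  & (ref.kind == kind)]
        return float(sel.value_ev.iloc[0]) if len(sel) else np.nan

    rows = []
    for name in names:
        try:
            ion, exc, f, _ = pi_energies(name, params)
        except KeyError:
            rows.append({"molecule": name, "skipped": True})
            continue
        rows.append({
            "molecule": name, "skipped": False,
            "I_calc": round(ion, 2), "E_calc": round(exc, 2), "f_calc": round(f, 3),
            "I_exp": lookup(name, "ionization", "experiment"),
            "E_exp": lookup(name, "excitation", "experiment"),
            "I_cc": lookup(name, "ionization", "cc"),
            "E_cc": lookup(name, "excitation", "cc"),
        })
    table = pd.DataFrame(rows)
    for quantity, calc_col, exp_col in (("ionization", "I_calc", "I_exp"),
                                        ("excitation", "E_calc", "E_exp")):
        ok = table[~table.get("skipped", False)].dropna(subset=[exp_col]) \
            if calc_col in table else table.iloc[0:0]
        value = rmspe(ok[calc_col], ok[exp_col]) if len(ok) else np.nan
        table.attrs[f"rmspe_{quantity}_pct"] = value
    return table


def benchmark_records(subset: str = "all",
                      params: LcaoParameters | None = None) -> list:
    """Flat list of :class:`BenchmarkRecord` (experiment rows only)."""
    table = benchmark_report(subset, params)
    records = []
    for _, row in table.iterrows():
        if row.get("skipped"):
            continue
        for quantity, calc_col, exp_col in (("ionization", "I_calc", "I_exp"),
                                            ("excitation", "E_calc", "E_exp")):
            if not np.isnan(row[exp_col]):
                records.append(BenchmarkRecord(row.molecule, quantity,
                                               row[calc_col], row[exp_col],
                                               "experiment"))
    return records
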