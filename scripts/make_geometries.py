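"""Regenerate the packaged heterocycle geometries (src/lcaodna/data/*.xyz).

Each molecule is embedded from SMILES (ETKDGv3, fixed seed) and relaxed with
MMFF94 using RDKit, then written as plain XYZ.  RDKit is only needed to run
this script; the package itself reads the stored text files.

Usage:  python scripts/make_geometries.py
"""

from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

SMILES = {
    # purines and amino-purines
    "purine_9h": ("c1ncc2nc[nH]c2n1", "C5H4N4"),
    "purine_7h": ("c1ncc2[nH]cnc2n1", "C5H4N4"),
    "aminopurine_2": ("Nc1ncc2nc[nH]c2n1", "C5H5N5"),
    # diazines and the N,N'-dioxide
    "pyrazine": ("c1cnccn1", "C4H4N2"),
    "pyrimidine": ("c1cncnc1", "C4H4N2"),
    "pyridazine": ("c1ccnnc1", "C4H4N2"),
    "pyrazine_14_dioxide": ("[O-][n+]1cc[n+]([O-])cc1", "C4H4N2O2"),
    # azoles
    "imidazole_1h": ("c1c[nH]cn1", "C3H4N2"),
    "pyrazole_1h": ("c1cc[nH]n1", "C3H4N2"),
    # fused bicyclics
    "benzimidazole_1h": ("c1ccc2[nH]cnc2c1", "C7H6N2"),
    "indazole_1h": ("c1ccc2[nH]ncc2c1", "C7H6N2"),
    "indazole_2h": ("c1ccc2c[nH]nc2c1", "C7H6N2"),
    "azaindole_7": ("c1ccc2cc[nH]c2n1", "C7H6N2"),
}

OUT = Path(__file__).resolve().parents[1] / "src" / "lcaodna" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for name, (smi, expected) in SMILES.items():
        mol = Chem.AddHs(Chem.MolFromSmiles(smi))
        formula = CalcMolFormula(mol).replace("+", "").replace("-", "")
        assert formula == expected, f"{name}: {formula} != {expected}"
        ps = AllChem.ETKDGv3()
        ps.randomSeed = 20210830
        if AllChem.EmbedMolecule(mol, ps) != 0:
            raise RuntimeError(f"embedding failed for {name}")
        if AllChem.MMFFOptimizeMolecule(mol, maxIters=5000) != 0:
            raise RuntimeError(f"MMFF did not converge for {name}")
        conf = mol.GetConformer()
        lines = [str(mol.GetNumAtoms()), f"{name} MMFF94 geometry"]
        for atom in mol.GetAtoms():
            p = conf.GetAtomPosition(atom.GetIdx())
            lines.append(f"{atom.GetSymbol():<2s} {p.x:14.8f} {p.y:14.8f} {p.z:14.8f}")
        (OUT / f"{name}.xyz").write_text("\n".join(lines) + "\n")
        print(f"wrote {name}.xyz ({formula})")


if __name__ == "__main__":
    main()
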