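"""3D structure generation, atom-level property weights and core alignment.

One minimized conformer is generated per compound (ETKDG embedding followed
by MMFF94 minimization with a 0.005 kcal/(mol*A) gradient threshold and a
1000-iteration cap), Gasteiger partial charges and per-atom property weights
are attached, and every molecule is rigidly superimposed onto a template
(DMP by default) through the shared benzene-1,2-dicarboxylate core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolDescriptors

__all__ = [
    "Molecule3D",
    "AlignmentSpec",
    "ConformerError",
    "AlignmentError",
    "CORE_SMARTS",
    "embed_and_minimize",
    "assign_atom_weights",
    "align_to_template",
    "align_ensemble",
    "write_sdf",
]

#: benzene-1,2-dicarboxylate diester core: 6 ring C, 2 carbonyl C, 4 O.
CORE_SMARTS = "c1ccc(C(=O)[OX2])c(C(=O)[OX2])c1"

#: Lennard-Jones well depths (kcal/mol) per element; vdW radii come from the
#: periodic table. Values in the range used by small-molecule force fields.
LJ_EPSILON = {
    "H": 0.042,
    "C": 0.107,
    "N": 0.095,
    "O": 0.116,
    "S": 0.314,
    "P": 0.314,
    "F": 0.109,
    "Cl": 0.314,
    "Br": 0.434,
}

_PT = Chem.GetPeriodicTable()


class ConformerError(RuntimeError):
    """Embedding or minimization failed for a compound."""


class AlignmentError(RuntimeError):
    """The alignment core pattern did not match a compound."""


@dataclass
class Molecule3D:
    """A single annotated conformer.

    Coordinates are in Angstrom, charges in elementary charge units.
    ``hydrophobic`` holds per-atom Crippen logP contributions, ``vdw_radius``
    the per-atom van der Waals radius (steric weights are its cube),
    ``donor``/``acceptor`` the H-bond flags used by similarity fields.
    """

    abbrev: str
    smiles: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    charges: np.ndarray | None = None
    hydrophobic: np.ndarray | None = None
    vdw_radius: np.ndarray | None = None
    donor: np.ndarray | None = None  # bool
    acceptor: np.ndarray | None = None  # bool
    provenance: dict = field(default_factory=dict)
    mol: Chem.Mol | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for e in self.elements if e != "H")

    @property
    def formal_charge(self) -> int:
        return Chem.GetFormalCharge(self.mol) if self.mol is not None else 0

    def with_coords(self, coords: np.ndarray) -> "Molecule3D":
        out = replace(self, coords=np.asarray(coords, dtype=float))
        if out.mol is not None:
            out.mol = Chem.Mol(out.mol)
            conf = out.mol.GetConformer()
            for i, xyz in enumerate(out.coords):
                conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        return out


@dataclass(frozen=True)
class AlignmentSpec:
    """Template + substructure pattern used for rigid superposition."""

    template_abbrev: str = "DMP"
    core_smarts: str = CORE_SMARTS

    def core_query(self) -> Chem.Mol:
        query = Chem.MolFromSmarts(self.core_smarts)
        if query is None:
            raise AlignmentError(f"invalid core SMARTS: {self.core_smarts!r}")
        return query


def embed_and_minimize(
    smiles: str,
    seed: int,
    abbrev: str = "",
    max_iterations: int = 1000,
    force_tol: float = 0.005,
    n_retries: int = 5,
) -> Molecule3D:
    """Embed one conformer and minimize it with MMFF94.

    Deterministic for a given (smiles, seed). The gradient convergence
    threshold and iteration cap mirror the modeling protocol
    (0.005 kcal/(mol*A), 1000 iterations).
    """
    base = Chem.MolFromSmiles(smiles)
    if base is None:
        raise ConformerError(f"invalid SMILES for {abbrev or 'compound'}: {smiles!r}")
    mol = Chem.AddHs(base)
    conf_id = -1
    used_seed = seed
    for attempt in range(n_retries):
        params = AllChem.ETKDGv3()
        used_seed = seed + 1000 * attempt
        params.randomSeed = used_seed
        conf_id = AllChem.EmbedMolecule(mol, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise ConformerError(
            f"embedding failed for {abbrev or smiles} after {n_retries} seeds"
        )
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is None:
        raise ConformerError(f"MMFF94 cannot parameterize {abbrev or smiles}")
    ff = AllChem.MMFFGetMoleculeForceField(mol, props)
    energy_before = ff.CalcEnergy()
    status = ff.Minimize(maxIts=max_iterations, forceTol=force_tol)
    energy_after = ff.CalcEnergy()
    coords = mol.GetConformer().GetPositions().astype(float)
    mol3d = Molecule3D(
        abbrev=abbrev,
        smiles=smiles,
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
        provenance={
            "smiles": smiles,
            "seed": used_seed,
            "force_field": "MMFF94",
            "max_iterations": max_iterations,
            "force_tol_kcal_mol_A": force_tol,
            "converged": status == 0,
            "energy_before": float(energy_before),
            "energy_after": float(energy_after),
            "charge_model": "Gasteiger",
        },
        mol=mol,
    )
    return assign_atom_weights(mol3d)


def assign_atom_weights(mol3d: Molecule3D) -> Molecule3D:
    """Attach charges, hydrophobicity, vdW radii and H-bond flags.

    Gasteiger charges (sum equals the formal charge), Crippen atomic logP
    contributions as hydrophobicity weights, and simple H-bond rules:
    acceptors are N/O atoms (so all four ester oxygens qualify), donors are
    N/O atoms bearing at least one hydrogen.
    """
    if mol3d.mol is None:
        raise ConformerError("assign_atom_weights requires an RDKit molecule handle")
    mol = mol3d.mol
    AllChem.ComputeGasteigerCharges(mol)
    charges = np.array(
        [float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()], dtype=float
    )
    if not np.all(np.isfinite(charges)):
        bad = [a.GetSymbol() for a, c in zip(mol.GetAtoms(), charges) if not np.isfinite(c)]
        raise ConformerError(f"Gasteiger charges undefined for atoms: {bad}")
    contribs = rdMolDescriptors._CalcCrippenContribs(mol)
    hydrophobic = np.array([c[0] for c in contribs], dtype=float)
    vdw = np.array([_PT.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms()], dtype=float)
    donor = np.array(
        [a.GetAtomicNum() in (7, 8) and a.GetTotalNumHs(includeNeighbors=True) > 0
         for a in mol.GetAtoms()],
        dtype=bool,
    )
    acceptor = np.array([a.GetAtomicNum() in (7, 8) for a in mol.GetAtoms()], dtype=bool)
    total = float(charges.sum())
    formal = float(Chem.GetFormalCharge(mol))
    if abs(total - formal) > 1e-3:
        raise ConformerError(
            f"charge sum {total:.5f} deviates from formal charge {formal} for {mol3d.abbrev}"
        )
    return replace(
        mol3d,
        charges=charges,
        hydrophobic=hydrophobic,
        vdw_radius=vdw,
        donor=donor,
        acceptor=acceptor,
    )


def lj_epsilon(elements: list[str]) -> np.ndarray:
    return np.array([LJ_EPSILON.get(e, 0.1) for e in elements], dtype=float)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) minimizing ||P @ R.T + t - Q||."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    return R, t


def _core_matches(mol: Chem.Mol, query: Chem.Mol, label: str) -> list[tuple[int, ...]]:
    matches = mol.GetSubstructMatches(query, uniquify=True, maxMatches=64)
    if not matches:
        raise AlignmentError(f"core pattern does not match {label}")
    return sorted(matches)


def align_to_template(
    mol3d: Molecule3D, template: Molecule3D, spec: AlignmentSpec | None = None
) -> tuple[Molecule3D, float]:
    """Least-squares superposition of the core atoms onto the template core.

    The two ester arms of the core are symmetry-equivalent; among all
    substructure matches the atom mapping with minimal core RMSD is used
    (ties broken by canonical match order). The whole molecule is carried by
    the core's rigid transform. Returns (aligned molecule, core RMSD).
    """
    spec = spec or AlignmentSpec()
    query = spec.core_query()
    t_match = _core_matches(template.mol, query, f"template {template.abbrev}")[0]
    t_core = template.coords[list(t_match)]
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for match in _core_matches(mol3d.mol, query, mol3d.abbrev or mol3d.smiles):
        core = mol3d.coords[list(match)]
        R, t = _kabsch(core, t_core)
        rmsd = float(np.sqrt(np.mean(np.sum((core @ R.T + t - t_core) ** 2, axis=1))))
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, R, t)
    assert best is not None
    rmsd, R, t = best
    aligned = mol3d.with_coords(mol3d.coords @ R.T + t)
    aligned.provenance = dict(mol3d.provenance, core_rmsd=rmsd, template=template.abbrev)
    return aligned, rmsd


def align_ensemble(
    mols: dict[str, Molecule3D], spec: AlignmentSpec | None = None
) -> dict[str, Molecule3D]:
    """Align every molecule onto the spec's template molecule.

    The template itself must be present in ``mols``; it is aligned onto
    itself (identity up to numerical noise) so all outputs share one frame.
    """
    spec = spec or AlignmentSpec()
    if spec.template_abbrev not in mols:
        raise AlignmentError(f"template {spec.template_abbrev!r} not among input molecules")
    template = mols[spec.template_abbrev]
    return {a: align_to_template(m, template, spec)[0] for a, m in mols.items()}


def write_sdf(mols: list[Molecule3D], path: str | Path) -> None:
    """Write an aligned ensemble as a multi-molecule SDF with charge props."""
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            if m.mol is None:
                raise ConformerError(f"no RDKit molecule for {m.abbrev}")
            out = Chem.Mol(m.mol)
            out.SetProp("_Name", m.abbrev or m.smiles)
            if m.charges is not None:
                out.SetProp("atom.dprop.PartialCharge",
                            " ".join(f"{c:.6f}" for c in m.charges))
            writer.write(out)
    finally:
        writer.close()
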