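"""Physico-chemical descriptors used by the permeability models.

The published trees split on a small descriptor set: atomic-contribution
logP (aLogP), topological polar surface area (tPSA), the CPSA-family ratio
fPSA3, rotatable-bond count, H-bond-acceptor count, the lowest eigenvalue
of the mass-weighted Burden connectivity matrix (BCUTS), and monoisotopic
molecular weight. Everything here is 2D except fPSA3, which needs a 3D
conformer with partial charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors, rdPartialCharges

from .dataset_io import LabeledDataset, embed_3d

#: Column names of the descriptor matrix, in model vocabulary.
DESCRIPTOR_COLUMNS = ("aLogP", "tPSA", "fPSA3", "rotBonds", "hBondAcceptors", "BCUTS", "MW")

GASTEIGER_ITERATIONS = 75
SASA_POINTS_PER_ATOM = 960
SASA_PROBE_RADIUS = 1.4  # water probe, Angstrom


@dataclass
class DescriptorVector:
    """Model-relevant descriptors for one molecule.

    ``bcuts`` is the lowest eigenvalue of the Burden matrix with atomic-mass
    diagonal weighting (the variant whose values the published worked
    examples print); ``extras`` holds any additional named descriptors.
    """

    alogp: float
    tpsa: float
    fpsa3: float | None
    rot_bonds: int
    hba: int
    bcuts: float
    mw: float
    extras: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {
            "aLogP": self.alogp,
            "tPSA": self.tpsa,
            "fPSA3": np.nan if self.fpsa3 is None else self.fpsa3,
            "rotBonds": self.rot_bonds,
            "hBondAcceptors": self.hba,
            "BCUTS": self.bcuts,
            "MW": self.mw,
        }
        row.update(self.extras)
        return row


def _as_mol(mol: Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES {mol!r}")
        return parsed
    return mol


def calc_alogp(mol: Chem.Mol | str) -> float:
    """Atomic-contribution (Crippen-type) octanol/water logP.

    A sum of typed-atom contributions, hence exactly additive over
    disconnected fragments.
    """
    return float(Crippen.MolLogP(_as_mol(mol)))


def calc_tpsa(mol: Chem.Mol | str, include_s_p: bool = False) -> float:
    """Ertl fragment-contribution topological polar surface area (A^2)."""
    return float(Descriptors.TPSA(_as_mol(mol), includeSandP=include_s_p))


def calc_rotatable_bonds(mol: Chem.Mol | str, exclude_amide: bool = True) -> int:
    """Count single, non-ring bonds between two non-terminal heavy atoms.

    Amide C-N bonds are excluded by default (the convention of the toolkit
    behind the published models); pass ``exclude_amide=False`` to count them.
    """
    mol = _as_mol(mol)
    strictness = (
        rdMolDescriptors.NumRotatableBondsOptions.Strict
        if exclude_amide
        else rdMolDescriptors.NumRotatableBondsOptions.NonStrict
    )
    return int(rdMolDescriptors.CalcNumRotatableBonds(mol, strictness))


# Pyrrole-type aromatic N contributes its lone pair to the ring; amide N is
# conjugated into the carbonyl. Neither accepts hydrogen bonds.
_AMIDE_N = Chem.MolFromSmarts("[#7;$([#7X3][#6X3]=[OX1])]")
_PYRROLE_N = Chem.MolFromSmarts("[n;$([nX3;H1]),$([nX3](-*)(-*)-*)]")


def calc_hbond_acceptors(mol: Chem.Mol | str) -> int:
    """H-bond acceptor count: N or O, not positively charged, excluding
    pyrrole-type aromatic nitrogen and amide nitrogen."""
    mol = _as_mol(mol)
    excluded = {i for (i, *_) in mol.GetSubstructMatches(_AMIDE_N)}
    excluded |= {i for (i, *_) in mol.GetSubstructMatches(_PYRROLE_N)}
    count = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() not in (7, 8):
            continue
        if atom.GetFormalCharge() > 0:
            continue
        if atom.GetIdx() in excluded:
            continue
        count += 1
    return count


def burden_matrix(mol: Chem.Mol | str) -> np.ndarray:
    """Burden connectivity matrix over heavy atoms, mass on the diagonal.

    Off-diagonal entries follow Burden's convention: 0.1 x bond order
    (1.5 for aromatic) for bonded pairs, +0.01 when either atom is terminal,
    and 0.001 for all non-bonded pairs.
    """
    mol = Chem.RemoveHs(_as_mol(mol))
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("molecule has no heavy atoms")
    B = np.full((n, n), 0.001)
    for i in range(n):
        B[i, i] = mol.GetAtomWithIdx(i).GetMass()
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        v = 0.1 * (1.5 if bond.GetIsAromatic() else bond.GetBondTypeAsDouble())
        if (
            mol.GetAtomWithIdx(i).GetDegree() == 1
            or mol.GetAtomWithIdx(j).GetDegree() == 1
        ):
            v += 0.01
        B[i, j] = B[j, i] = v
    return B


def burden_eigenvalues(mol: Chem.Mol | str) -> np.ndarray:
    """Sorted (ascending) eigenvalues of the mass-weighted Burden matrix.

    Disconnected inputs are handled per connected component (block-diagonal
    spectrum), so the extreme eigenvalues of a multi-fragment input are
    exactly the extremes over its fragments.
    """
    mol = _as_mol(mol)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    eigs = np.concatenate([np.linalg.eigvalsh(burden_matrix(f)) for f in frags])
    return np.sort(eigs)


def calc_bcut_low(mol: Chem.Mol | str) -> float:
    """Lowest eigenvalue of the mass-weighted Burden matrix (the published
    models' "BCUTS" splitting descriptor)."""
    return float(burden_eigenvalues(mol)[0])


def calc_bcut_high(mol: Chem.Mol | str) -> float:
    """Highest eigenvalue of the mass-weighted Burden matrix."""
    return float(burden_eigenvalues(mol)[-1])


def calc_molecular_weight(mol: Chem.Mol | str) -> float:
    """Monoisotopic molecular weight (Da), implicit hydrogens included."""
    return float(Descriptors.ExactMolWt(_as_mol(mol)))


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def atomic_sasa(
    mol3d: Chem.Mol,
    probe_radius: float = SASA_PROBE_RADIUS,
    n_points: int = SASA_POINTS_PER_ATOM,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley style.

    Each atom's vdW sphere is inflated by the probe radius and sampled with a
    deterministic spherical lattice; points buried in any neighbour sphere do
    not count.
    """
    if mol3d.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer; run embed_3d first")
    xyz = mol3d.GetConformer().GetPositions()
    pt = Chem.GetPeriodicTable()
    radii = (
        np.array([pt.GetRvdw(a.GetAtomicNum()) for a in mol3d.GetAtoms()])
        + probe_radius
    )
    sphere = _sphere_points(n_points)
    sasa = np.zeros(len(radii))
    for i in range(len(radii)):
        pts = xyz[i] + radii[i] * sphere
        # point exposed iff outside every other inflated sphere
        d2 = ((pts[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2)
        buried = d2 < (radii[None, :] ** 2)
        buried[:, i] = False
        exposed = ~buried.any(axis=1)
        sasa[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return sasa


def calc_fpsa3(mol3d: Chem.Mol) -> float:
    """FPSA-3 of the CPSA family: charge-weighted partial positive surface
    area divided by total molecular surface area.

    Partial charges are Gasteiger-Marsili; the surface is the solvent-
    accessible area of the supplied conformer. Returns 0.0 when no atom
    carries positive charge.
    """
    if mol3d.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer; run embed_3d first")
    mol = Chem.Mol(mol3d)
    rdPartialCharges.ComputeGasteigerCharges(mol, nIter=GASTEIGER_ITERATIONS)
    charges = np.array(
        [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()]
    )
    charges = np.nan_to_num(charges, nan=0.0)
    sasa = atomic_sasa(mol)
    total = sasa.sum()
    if total <= 0:
        return 0.0
    pos = charges > 0
    return float((charges[pos] * sasa[pos]).sum() / total)


def compute_descriptors(
    record_smiles: str, embed_seed: int = 42, with_3d: bool = True
) -> DescriptorVector:
    """All model descriptors for one standardized SMILES."""
    mol = _as_mol(record_smiles)
    fpsa3: float | None = None
    if with_3d:
        from .dataset_io import CompoundRecord

        rec = CompoundRecord(id="_", name="_", smiles=record_smiles)
        mol3d = embed_3d(rec, seed=embed_seed)
        fpsa3 = calc_fpsa3(mol3d)
    return DescriptorVector(
        alogp=calc_alogp(mol),
        tpsa=calc_tpsa(mol),
        fpsa3=fpsa3,
        rot_bonds=calc_rotatable_bonds(mol),
        hba=calc_hbond_acceptors(mol),
        bcuts=calc_bcut_low(mol),
        mw=calc_molecular_weight(mol),
    )


def calc_descriptor_matrix(
    ds: LabeledDataset, embed_seed: int = 42, with_3d: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Descriptor matrix (one row per compound, indexed by id) + failure report.

    Per-descriptor failures become missing values with reasons recorded in the
    report, never silent zeros; a descriptor failing on more than 10% of the
    compounds adds a warning to the report.
    """
    rows: dict[str, dict[str, float]] = {}
    failures: list[dict[str, str]] = []
    for rec in ds.records:
        try:
            mol = _as_mol(rec.smiles)
        except ValueError as exc:
            failures.append({"id": rec.id, "descriptor": "*", "reason": str(exc)})
            rows[rec.id] = {c: np.nan for c in DESCRIPTOR_COLUMNS}
            continue
        row: dict[str, float] = {}
        per_desc = {
            "aLogP": lambda: calc_alogp(mol),
            "tPSA": lambda: calc_tpsa(mol),
            "rotBonds": lambda: calc_rotatable_bonds(mol),
            "hBondAcceptors": lambda: calc_hbond_acceptors(mol),
            "BCUTS": lambda: calc_bcut_low(mol),
            "MW": lambda: calc_molecular_weight(mol),
        }
        for name, fn in per_desc.items():
            try:
                row[name] = float(fn())
            except Exception as exc:  # noqa: BLE001 - reported, not swallowed
                row[name] = np.nan
                failures.append({"id": rec.id, "descriptor": name, "reason": str(exc)})
        if with_3d:
            try:
                row["fPSA3"] = calc_fpsa3(embed_3d(rec, seed=embed_seed))
            except Exception as exc:  # noqa: BLE001
                row["fPSA3"] = np.nan
                failures.append({"id": rec.id, "descriptor": "fPSA3", "reason": str(exc)})
        else:
            row["fPSA3"] = np.nan
        rows[rec.id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index")[list(DESCRIPTOR_COLUMNS)]
    matrix.index.name = "id"
    report: dict = {"failures": failures, "warnings": []}
    n = max(len(ds.records), 1)
    for col in DESCRIPTOR_COLUMNS:
        n_fail = int(matrix[col].isna().sum())
        if col == "fPSA3" and not with_3d:
            continue
        if n_fail / n > 0.10:
            report["warnings"].append(
                f"descriptor {col} failed on {n_fail}/{n} compounds"
            )
    return matrix, report
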