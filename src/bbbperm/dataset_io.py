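"""Compound tables, structure standardization, and permeation-class labels.

The quantitative endpoint throughout this package is logPS, the log of the
in-situ brain-perfusion permeability-surface-area product (mL s^-1 g^-1).
Compounds with logPS >= -2 are strong blood-brain-barrier permeants (CNSp+),
compounds with logPS <= -3 are weak permeants (CNSp-), and compounds strictly
between the cutoffs are exempt from classification learning.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

DEFAULT_CUTOFF_POS = -2.0
DEFAULT_CUTOFF_NEG = -3.0


class PermClass(enum.Enum):
    """Blood-brain-barrier permeation class of a compound."""

    CNSP_POS = "CNSp+"
    CNSP_NEG = "CNSp-"
    EXEMPT = "exempt"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule with its structure, logPS endpoint, and class label."""

    id: str
    name: str
    smiles: str
    logps: float | None = None
    perm_class: PermClass = PermClass.UNLABELED


@dataclass
class RejectedRow:
    """A row that could not be turned into a CompoundRecord, with the reason."""

    source: str
    reason: str


@dataclass
class LabeledDataset:
    """An ordered compound collection plus the logPS class cutoffs.

    ``cutoff_pos``/``cutoff_neg`` are closed bounds: logPS >= cutoff_pos is
    CNSp+, logPS <= cutoff_neg is CNSp-, and the open interval between them
    is exempt.
    """

    records: list[CompoundRecord]
    cutoff_pos: float = DEFAULT_CUTOFF_POS
    cutoff_neg: float = DEFAULT_CUTOFF_NEG
    rejects: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cutoff_neg < self.cutoff_pos:
            raise ValueError(
                f"cutoff_neg ({self.cutoff_neg}) must be < cutoff_pos ({self.cutoff_pos})"
            )

    def class_counts(self) -> dict[PermClass, int]:
        counts = {c: 0 for c in PermClass}
        for rec in self.records:
            counts[rec.perm_class] += 1
        return counts

    def classification_subset(self) -> list[CompoundRecord]:
        """Records used for two-class learning: CNSp+ and CNSp- only."""
        return [
            r
            for r in self.records
            if r.perm_class in (PermClass.CNSP_POS, PermClass.CNSP_NEG)
        ]

    def manifest(self) -> dict:
        counts = self.class_counts()
        return {
            "n_records": len(self.records),
            "cutoff_pos": self.cutoff_pos,
            "cutoff_neg": self.cutoff_neg,
            "counts": {c.value: n for c, n in counts.items()},
            "n_rejects": len(self.rejects),
            "rejects": [{"source": r.source, "reason": r.reason} for r in self.rejects],
        }


class FormatError(ValueError):
    """Input table malformed (missing column, nothing parseable, bad schema)."""


def _record_from_fields(
    ident: str, name: str, smiles: str, logps_raw: str | float | None
) -> CompoundRecord:
    if not smiles or not str(smiles).strip():
        raise ValueError("empty SMILES")
    if Chem.MolFromSmiles(str(smiles)) is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    logps: float | None
    if logps_raw is None or (isinstance(logps_raw, str) and not logps_raw.strip()):
        logps = None
    else:
        logps = float(logps_raw)
    return CompoundRecord(id=str(ident), name=str(name), smiles=str(smiles), logps=logps)


def _read_csv(path: Path) -> tuple[list[CompoundRecord], list[RejectedRow]]:
    records: list[CompoundRecord] = []
    rejects: list[RejectedRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "name", "smiles", "logps"}
        have = set(reader.fieldnames or [])
        missing = required - have
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(sorted(missing))}")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    _record_from_fields(row["id"], row["name"], row["smiles"], row["logps"])
                )
            except (ValueError, TypeError) as exc:
                rejects.append(RejectedRow(source=f"{path.name}:{i}", reason=str(exc)))
    return records, rejects


def _read_sdf(path: Path) -> tuple[list[CompoundRecord], list[RejectedRow]]:
    records: list[CompoundRecord] = []
    rejects: list[RejectedRow] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rejects.append(RejectedRow(source=f"{path.name}#{i}", reason="unparseable molblock"))
            continue
        props = mol.GetPropsAsDict()
        ident = str(props.get("id", mol.GetProp("_Name") if mol.HasProp("_Name") else i))
        name = str(props.get("name", ident))
        logps = props.get("logPS", props.get("logps"))
        try:
            records.append(
                _record_from_fields(ident, name, Chem.MolToSmiles(mol), logps)
            )
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRow(source=f"{path.name}#{i}", reason=str(exc)))
    return records, rejects


def _read_smiles_file(path: Path) -> tuple[list[CompoundRecord], list[RejectedRow]]:
    records: list[CompoundRecord] = []
    rejects: list[RejectedRow] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smiles = parts[0]
            ident = parts[1] if len(parts) > 1 else f"mol{i}"
            try:
                records.append(_record_from_fields(ident, ident, smiles, None))
            except ValueError as exc:
                rejects.append(RejectedRow(source=f"{path.name}:{i}", reason=str(exc)))
    return records, rejects


def read_compound_table(
    path: str | Path,
    fmt: str = "csv",
    cutoff_pos: float = DEFAULT_CUTOFF_POS,
    cutoff_neg: float = DEFAULT_CUTOFF_NEG,
) -> LabeledDataset:
    """Read a compound table and label it by the logPS cutoffs.

    Parameters
    ----------
    path:
        CSV (columns id, name, smiles, logps), SDF v2000 (logPS as a named
        property), or SMILES file ("SMILES<TAB>id" per line).
    fmt:
        One of ``"csv"``, ``"sdf"``, ``"smiles"``.

    Unparseable rows are collected into ``dataset.rejects``, never silently
    dropped; zero parseable records is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"csv": _read_csv, "sdf": _read_sdf, "smiles": _read_smiles_file}
    if fmt not in readers:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(readers)}")
    records, rejects = readers[fmt](path)
    if not records:
        raise FormatError(f"no parseable records in {path}")
    ds = LabeledDataset(
        records=records, cutoff_pos=cutoff_pos, cutoff_neg=cutoff_neg, rejects=rejects
    )
    return assign_permeation_classes(ds)


_ORGANIC = 6  # carbon


def standardize_structure(record: CompoundRecord) -> CompoundRecord:
    """Strip counterions and emit a canonical, stereo-preserving SMILES.

    Salts are reduced to their largest organic fragment (most heavy atoms;
    ties broken by molecular weight), which is then neutralized where
    possible (a stripped carboxylate becomes the parent acid). A record
    whose fragments are all inorganic is rejected.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"record {record.id}: unparseable SMILES {record.smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [
        f for f in frags if any(a.GetAtomicNum() == _ORGANIC for a in f.GetAtoms())
    ]
    if not organic:
        raise ValueError(f"record {record.id}: all fragments inorganic")
    from rdkit.Chem import Descriptors
    from rdkit.Chem.MolStandardize import rdMolStandardize

    best = max(organic, key=lambda f: (f.GetNumHeavyAtoms(), Descriptors.MolWt(f)))
    best = rdMolStandardize.Uncharger().uncharge(best)
    canonical = Chem.MolToSmiles(best)  # canonical, stereo included by default
    return replace(record, smiles=canonical)


def assign_permeation_classes(ds: LabeledDataset) -> LabeledDataset:
    """Label every record from its logPS value and the dataset cutoffs.

    logPS >= cutoff_pos -> CNSp+; logPS <= cutoff_neg -> CNSp-; strictly
    between -> exempt; missing -> unlabeled. Idempotent.
    """
    labeled = []
    for rec in ds.records:
        if rec.logps is None:
            cls = PermClass.UNLABELED
        elif rec.logps >= ds.cutoff_pos:
            cls = PermClass.CNSP_POS
        elif rec.logps <= ds.cutoff_neg:
            cls = PermClass.CNSP_NEG
        else:
            cls = PermClass.EXEMPT
        labeled.append(replace(rec, perm_class=cls))
    return LabeledDataset(
        records=labeled,
        cutoff_pos=ds.cutoff_pos,
        cutoff_neg=ds.cutoff_neg,
        rejects=list(ds.rejects),
    )


def embed_3d(
    record: CompoundRecord, seed: int = 42, n_embeddings: int = 10
) -> Chem.Mol:
    """Return the molecule with its lowest-energy 3D conformer (coordinates in A).

    ``n_embeddings`` distance-geometry embeddings are generated under a fixed
    seed and MMFF94-minimized; the single lowest-energy conformer is kept, so
    the result is deterministic for a given (record, seed).
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"record {record.id}: unparseable SMILES")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_embeddings, params=params)
    if len(conf_ids) == 0:
        raise RuntimeError(f"3D embedding failed for {record.name or record.id}")
    energies = embedding_energies(mol)
    best = min(energies, key=energies.get)
    keep = Chem.Mol(mol, confId=best)
    out = Chem.Mol(mol)
    out.RemoveAllConformers()
    out.AddConformer(keep.GetConformer(best), assignId=True)
    return out


def embedding_energies(mol: Chem.Mol) -> dict[int, float]:
    """MMFF94 energy (kcal/mol) of every conformer on ``mol`` after minimization."""
    props = AllChem.MMFFGetMoleculeProperties(mol)
    energies: dict[int, float] = {}
    for conf in mol.GetConformers():
        cid = conf.GetId()
        if props is not None:
            AllChem.MMFFOptimizeMolecule(mol, confId=cid)
            ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
            energies[cid] = ff.CalcEnergy()
        else:  # UFF fallback for atoms outside MMFF coverage
            AllChem.UFFOptimizeMolecule(mol, confId=cid)
            ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
            energies[cid] = ff.CalcEnergy()
    return energies


def write_labeled_csv(ds: LabeledDataset, path: str | Path) -> None:
    """Write the dataset back out as CSV plus a JSON run manifest alongside."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "smiles", "logps", "perm_class"])
        for rec in ds.records:
            writer.writerow(
                [rec.id, rec.name, rec.smiles,
                 "" if rec.logps is None else rec.logps, rec.perm_class.value]
            )
    manifest_path = path.with_suffix(".manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(ds.manifest(), fh, indent=2, sort_keys=True)


def records_from_smiles(pairs: Iterable[tuple[str, str]]) -> list[CompoundRecord]:
    """Convenience: build unlabeled records from (id, smiles) pairs."""
    return [CompoundRecord(id=i, name=i, smiles=s) for i, s in pairs]
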