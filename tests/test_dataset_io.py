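"""Compound-table reading, standardization, and logPS class assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem
from rdkit.Chem import AllChem

from bbbperm.dataset_io import (
    CompoundRecord,
    FormatError,
    LabeledDataset,
    PermClass,
    assign_permeation_classes,
    embed_3d,
    embedding_energies,
    read_compound_table,
    standardize_structure,
    write_labeled_csv,
)


class TestReadCompoundTable:
    def test_csv_identity_read(self, tiny_csv):
        ds = read_compound_table(tiny_csv, "csv")
        assert len(ds.records) == 3
        assert [r.id for r in ds.records] == ["c1", "c2", "c3"]
        assert ds.records[0].logps == -0.5

    def test_empty_smiles_goes_to_rejects(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("id,name,smiles,logps\nc1,ok,CCO,-1\nc2,bad,,-2\n")
        ds = read_compound_table(path, "csv")
        assert len(ds.records) == 1
        assert len(ds.rejects) == 1
        assert "SMILES" in ds.rejects[0].reason

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("id,name,logps\nc1,x,-1\n")
        with pytest.raises(FormatError, match="smiles"):
            read_compound_table(path, "csv")

    def test_zero_parseable_records_is_hard_error(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("id,name,smiles,logps\nc1,bad,not_a_smiles,-1\n")
        with pytest.raises(FormatError):
            read_compound_table(path, "csv")

    def test_sdf_with_logps_property_labels_exempt(self, tmp_path):
        mol = Chem.MolFromSmiles("c1ccccc1O")
        mol.SetProp("_Name", "phenol")
        mol.SetProp("logPS", "-2.5")
        path = tmp_path / "one.sdf"
        with Chem.SDWriter(str(path)) as writer:
            writer.write(mol)
        ds = read_compound_table(path, "sdf")
        assert len(ds.records) == 1
        assert ds.records[0].perm_class is PermClass.EXEMPT

    def test_smiles_file(self, tmp_path):
        path = tmp_path / "mols.smi"
        path.write_text("CCO\teth\nc1ccccc1\tbenz\n")
        ds = read_compound_table(path, "smiles")
        assert [r.id for r in ds.records] == ["eth", "benz"]
        assert all(r.perm_class is PermClass.UNLABELED for r in ds.records)

    def test_write_round_trip(self, tiny_csv, tmp_path):
        ds = read_compound_table(tiny_csv, "csv")
        out = tmp_path / "out.csv"
        write_labeled_csv(ds, out)
        ds2 = read_compound_table(out, "csv")
        assert [r.id for r in ds2.records] == [r.id for r in ds.records]
        assert [r.perm_class for r in ds2.records] == [r.perm_class for r in ds.records]


class TestStandardize:
    def test_sodium_salt_reduced_to_parent_acid(self):
        rec = CompoundRecord(id="x", name="sodium acetate", smiles="CC(=O)[O-].[Na+]")
        out = standardize_structure(rec)
        assert out.smiles == "CC(=O)O"

    def test_single_fragment_is_canonical_identity(self):
        rec = CompoundRecord(id="x", name="toluene", smiles="Cc1ccccc1")
        out = standardize_structure(rec)
        assert out.smiles == Chem.CanonSmiles("Cc1ccccc1")
        assert standardize_structure(out).smiles == out.smiles

    def test_stereocenter_preserved(self):
        rec = CompoundRecord(id="x", name="L-alanine", smiles="C[C@H](N)C(=O)O")
        out = standardize_structure(rec)
        assert "@" in out.smiles

    def test_all_inorganic_rejected(self):
        rec = CompoundRecord(id="x", name="salt", smiles="[Na+].[Cl-]")
        with pytest.raises(ValueError, match="inorganic"):
            standardize_structure(rec)

    def test_largest_fragment_by_heavy_atoms(self):
        rec = CompoundRecord(id="x", name="mix", smiles="CCO.c1ccccc1CCCN")
        out = standardize_structure(rec)
        assert out.smiles == Chem.CanonSmiles("c1ccccc1CCCN")


class TestAssignClasses:
    @pytest.mark.parametrize(
        "logps,expected",
        [
            (-1.5, PermClass.CNSP_POS),
            (-2.0, PermClass.CNSP_POS),  # boundary closed: >= -2
            (-2.5, PermClass.EXEMPT),
            (-3.0, PermClass.CNSP_NEG),  # boundary closed: <= -3
            (-3.4, PermClass.CNSP_NEG),
            (None, PermClass.UNLABELED),
        ],
    )
    def test_cutoff_rules(self, logps, expected):
        ds = LabeledDataset(records=[CompoundRecord("a", "a", "CCO", logps)])
        out = assign_permeation_classes(ds)
        assert out.records[0].perm_class is expected

    @given(
        st.lists(
            st.one_of(st.none(), st.floats(-6, 1, allow_nan=False)), min_size=1, max_size=40
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_partition_and_idempotence(self, logps_values):
        records = [
            CompoundRecord(f"c{i}", f"c{i}", "CCO", v) for i, v in enumerate(logps_values)
        ]
        ds = assign_permeation_classes(LabeledDataset(records=records))
        counts = ds.class_counts()
        assert sum(counts.values()) == len(records)
        again = assign_permeation_classes(ds)
        assert [r.perm_class for r in again.records] == [r.perm_class for r in ds.records]

    def test_invalid_cutoff_order_rejected(self):
        with pytest.raises(ValueError):
            LabeledDataset(records=[], cutoff_pos=-3.0, cutoff_neg=-2.0)


class TestEmbed3d:
    def test_methane_is_tetrahedral(self):
        mol = embed_3d(CompoundRecord("m", "methane", "C"), seed=7)
        conf = mol.GetConformer()
        xyz = conf.GetPositions()
        carbon = xyz[0]
        hs = xyz[1:]
        angles = []
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = hs[i] - carbon, hs[j] - carbon
                cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                angles.append(np.degrees(np.arccos(cos)))
        assert np.allclose(angles, 109.47, atol=2.0)

    def test_same_seed_same_coordinates(self):
        rec = CompoundRecord("b", "butanol", "CCCCO")
        m1 = embed_3d(rec, seed=13)
        m2 = embed_3d(rec, seed=13)
        assert np.allclose(
            m1.GetConformer().GetPositions(), m2.GetConformer().GetPositions()
        )

    def test_returned_conformer_has_minimal_energy(self):
        # oracle: regenerate the same 10 embeddings and list all energies
        rec = CompoundRecord("h", "hexane", "CCCCCC")
        chosen = embed_3d(rec, seed=5, n_embeddings=10)
        props = AllChem.MMFFGetMoleculeProperties(chosen)
        ff = AllChem.MMFFGetMoleculeForceField(chosen, props)
        chosen_energy = ff.CalcEnergy()

        mol = Chem.AddHs(Chem.MolFromSmiles(rec.smiles))
        params = AllChem.ETKDGv3()
        params.randomSeed = 5
        AllChem.EmbedMultipleConfs(mol, numConfs=10, params=params)
        energies = embedding_energies(mol)
        assert chosen_energy <= min(energies.values()) + 1e-3

    def test_unembeddable_record_raises_with_name(self):
        with pytest.raises(ValueError):
            embed_3d(CompoundRecord("z", "broken", "not-a-smiles"))
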