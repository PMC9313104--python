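"""Structure model, PDB round trips, altloc/insertion handling, slab inference."""

import numpy as np
import pytest

from ppiface.core_model import (
    AtomSite,
    ComplexModel,
    EmptySelectionError,
    InsertionCodeError,
    LigandError,
    MembraneSlab,
    MissingChainError,
    infer_membrane_slab,
    load_receptor_config,
    read_complex_pdb,
    write_complex_pdb,
)
from ppiface.ligand_fate import FateLabel
from ppiface.synthetic_fixtures import plant_compound_pose, plant_peptide_pose


def _pdb_line(serial, name, resn, chain, resseq, xyz, elem, record="ATOM", alt=" ", icode=" ", occ=1.0):
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {name:<4s}{alt:1s}{resn:<3s} {chain:1s}"
        f"{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {elem:>2s}"
    )


def test_peptide_pose_pdb_round_trip(scaffold, tmp_path):
    """read -> write -> read preserves atoms, chains, numbering, coords (3 dp)."""
    model = plant_peptide_pose(scaffold, "good", seed=4, model_id="rt")
    path = tmp_path / "rt.pdb"
    write_complex_pdb(model, path)
    back = read_complex_pdb(
        path, scaffold.receptor_chains, ligand_chain="P", conformation="E1P"
    )
    assert isinstance(back, ComplexModel)
    assert len(back.receptor_atoms) == len(model.receptor_atoms)
    assert len(back.ligand_atoms) == len(model.ligand_atoms)
    assert len(back.membrane_atoms) == len(model.membrane_atoms)
    assert back.receptor_residues() == model.receptor_residues()
    assert back.ligand_residues() == model.ligand_residues()
    got = np.array(sorted(a.coords for a in back.ligand_atoms))
    want = np.array(sorted(a.coords for a in model.ligand_atoms))
    assert np.allclose(got, want, atol=5e-4)


def test_compound_pose_round_trip_hetatm_count(scaffold, tmp_path):
    """A 12-atom HETATM compound survives the round trip as 12 hetero sites."""
    model = plant_compound_pose(scaffold, FateLabel.DISPLACED, seed=1, model_id="het")
    path = tmp_path / "het.pdb"
    write_complex_pdb(model, path)
    back = read_complex_pdb(path, scaffold.receptor_chains, ligand_resnames=["LIG"])
    assert len(back.ligand_atoms) == 12
    assert all(a.is_hetero for a in back.ligand_atoms)
    assert back.ligand_chain is None and not back.ligand_is_peptide


def test_missing_declared_chain_is_named(tmp_path):
    lines = [
        _pdb_line(1, "CA", "ALA", "A", 1, (0, 0, 0), "C"),
        _pdb_line(2, "CA", "ALA", "P", 1, (5, 0, 0), "C"),
        "END",
    ]
    path = tmp_path / "m.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(MissingChainError, match="'C'"):
        read_complex_pdb(path, {"A": "alpha_subunit", "C": "beta_subunit"}, ligand_chain="P")


def test_zero_ligand_atoms_is_an_error(tmp_path):
    path = tmp_path / "nolig.pdb"
    path.write_text(_pdb_line(1, "CA", "ALA", "A", 1, (0, 0, 0), "C") + "\nEND\n")
    with pytest.raises(LigandError):
        read_complex_pdb(path, {"A": "alpha_subunit"}, ligand_resnames=["LIG"])


def test_altloc_resolves_to_highest_occupancy(tmp_path):
    lines = [
        _pdb_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), "C", alt="A", occ=0.4),
        _pdb_line(2, "CA", "ALA", "A", 1, (9.0, 0.0, 0.0), "C", alt="B", occ=0.6),
        _pdb_line(3, "CA", "ALA", "P", 1, (5.0, 0.0, 0.0), "C"),
        "END",
    ]
    path = tmp_path / "alt.pdb"
    path.write_text("\n".join(lines) + "\n")
    model = read_complex_pdb(path, {"A": "alpha_subunit"}, ligand_chain="P")
    (ca,) = [a for a in model.receptor_atoms if a.name == "CA"]
    assert ca.coords[0] == pytest.approx(9.0)


def test_hydrogens_are_dropped(tmp_path):
    lines = [
        _pdb_line(1, "CA", "ALA", "A", 1, (0, 0, 0), "C"),
        _pdb_line(2, "H", "ALA", "A", 1, (1, 0, 0), "H"),
        _pdb_line(3, "CA", "ALA", "P", 1, (5, 0, 0), "C"),
        "END",
    ]
    path = tmp_path / "h.pdb"
    path.write_text("\n".join(lines) + "\n")
    model = read_complex_pdb(path, {"A": "alpha_subunit"}, ligand_chain="P")
    assert [a.name for a in model.receptor_atoms] == ["CA"]


def test_insertion_codes_rejected(tmp_path):
    lines = [
        _pdb_line(1, "CA", "ALA", "A", 1, (0, 0, 0), "C", icode="A"),
        _pdb_line(2, "CA", "ALA", "P", 1, (5, 0, 0), "C"),
        "END",
    ]
    path = tmp_path / "ins.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(InsertionCodeError):
        read_complex_pdb(path, {"A": "alpha_subunit"}, ligand_chain="P")


def test_multi_model_file_yields_a_list(tmp_path):
    block = [
        _pdb_line(1, "CA", "ALA", "A", 1, (0, 0, 0), "C"),
        _pdb_line(2, "CA", "ALA", "P", 1, (3, 0, 0), "C"),
    ]
    lines = ["MODEL        1", *block, "ENDMDL", "MODEL        2", *block, "ENDMDL", "END"]
    path = tmp_path / "multi.pdb"
    path.write_text("\n".join(lines) + "\n")
    models = read_complex_pdb(path, {"A": "alpha_subunit"}, ligand_chain="P")
    assert isinstance(models, list) and len(models) == 2
    assert models[0].model_id.endswith("#1") and models[1].model_id.endswith("#2")


def test_model_invariants():
    atom = AtomSite(1, "CA", "C", 1, "ALA", "A", (0.0, 0.0, 0.0))
    lig = AtomSite(2, "CA", "C", 1, "ALA", "P", (1.0, 0.0, 0.0))
    with pytest.raises(LigandError):
        ComplexModel("m", {"A": "alpha_subunit"}, [atom], [], ligand_chain="P")
    with pytest.raises(ValueError):
        ComplexModel("m", {"A": "alpha_subunit"}, [atom], [lig], ligand_chain="A")
    with pytest.raises(ValueError):
        MembraneSlab(3.0, -3.0)
    with pytest.raises(ValueError):
        AtomSite(1, "CA", "C", 1, "ALA", "A", (float("nan"), 0.0, 0.0))


class TestSlabInference:
    def test_min_max_of_selected_atoms(self, scaffold):
        model = plant_peptide_pose(scaffold, "good", seed=0)
        slab = infer_membrane_slab(model, "P*")
        assert (slab.z_min, slab.z_max) == (scaffold.slab.z_min, scaffold.slab.z_max)

    def test_round_trip_recovers_planted_slab(self, scaffold, tmp_path):
        model = plant_peptide_pose(scaffold, "good", seed=0)
        path = tmp_path / "slab.pdb"
        write_complex_pdb(model, path)
        back = read_complex_pdb(path, scaffold.receptor_chains, ligand_chain="P")
        slab = infer_membrane_slab(back)
        assert (slab.z_min, slab.z_max) == (-34.0, -4.0)

    def test_empty_selection_raises(self, scaffold):
        model = plant_peptide_pose(scaffold, "good", seed=0)
        with pytest.raises(EmptySelectionError):
            infer_membrane_slab(model, "ZZ*")

    def test_order_invariance(self, scaffold):
        model = plant_peptide_pose(scaffold, "good", seed=0)
        shuffled = ComplexModel(
            model_id=model.model_id,
            receptor_chains=model.receptor_chains,
            receptor_atoms=model.receptor_atoms,
            ligand_atoms=model.ligand_atoms,
            ligand_chain=model.ligand_chain,
            membrane_atoms=list(reversed(model.membrane_atoms)),
        )
        assert infer_membrane_slab(model) == infer_membrane_slab(shuffled)


def test_config_missing_key_raises(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("ligand_chain: P\n")
    with pytest.raises(KeyError, match="receptor_chains"):
        load_receptor_config(path)


def test_config_parses_slab(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(
        "receptor_chains:\n  A: alpha_subunit\n  B: beta_subunit\n"
        "ligand_chain: P\nslab: [-34, -4]\n"
    )
    cfg = load_receptor_config(path)
    assert cfg["slab"] == MembraneSlab(-34.0, -4.0)
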