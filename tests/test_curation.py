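"""Curated-table loading, ligand-contact labeling, dataset assembly."""

import numpy as np
import pandas as pd
import pytest

from fapocket import CageSpec, detect_pockets, make_cage, write_pdb
from fapocket.curation import (
    build_dataset,
    label_pockets,
    load_ligand_exclusion_list,
    load_training_table,
    table_summary,
)
from fapocket.detect import AlphaSphere, Pocket
from fapocket.structure import Atom, Residue
from fapocket.synthetic import positive_cage_spec


def _write_table(path, rows):
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class TestLoadTrainingTable:
    def test_packaged_human_table_counts(self):
        from fapocket.data import table_path

        records = load_training_table(table_path("human"))
        summary = table_summary(records)
        assert summary["n_records"] == 340
        assert summary["n_distinct_species"] == 1

    def test_packaged_all_species_table_counts(self):
        from fapocket.data import table_path

        records = load_training_table(table_path("all_species"))
        summary = table_summary(records)
        assert summary["n_records"] == 70
        assert summary["n_distinct_species"] == 52

    def test_duplicates_collapsed(self, tmp_path):
        path = tmp_path / "dup.tsv"
        row = {"pdb_id": "1ABC", "chain": "A", "ligand_code": "PLM",
               "species": "x", "label": 1}
        _write_table(path, [row, row,
                            {**row, "pdb_id": "2DEF"}])
        records = load_training_table(path)
        assert len(records) == 2

    def test_malformed_pdb_id_skipped(self, tmp_path):
        path = tmp_path / "bad.tsv"
        _write_table(path, [
            {"pdb_id": "1ABC", "chain": "A", "ligand_code": "PLM",
             "species": "x", "label": 1},
            {"pdb_id": "nope!", "chain": "A", "ligand_code": "PLM",
             "species": "x", "label": 1},
        ])
        assert len(load_training_table(path)) == 1

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "nolabel.tsv"
        _write_table(path, [{"pdb_id": "1ABC", "chain": "A"}])
        with pytest.raises(ValueError, match="label"):
            load_training_table(path)

    def test_column_map_remaps_names(self, tmp_path):
        path = tmp_path / "mapped.tsv"
        _write_table(path, [{"PDB": "1ABC", "y": 1, "lig": "PLM"}])
        records = load_training_table(
            path, column_map={"pdb_id": "PDB", "label": "y", "ligand_code": "lig"}
        )
        assert records[0].pdb_id == "1ABC"


class TestLigandExclusionList:
    def test_load_and_uppercase(self, tmp_path):
        path = tmp_path / "lig.txt"
        path.write_text("plm\nMYR\n# comment\n\nola\n")
        assert load_ligand_exclusion_list(path) == {"PLM", "MYR", "OLA"}

    def test_empty_list_raises(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("# nothing\n")
        with pytest.raises(ValueError):
            load_ligand_exclusion_list(path)


def _pocket_at(centers):
    spheres = [AlphaSphere(center=np.asarray(c, float), radius=4.0,
                           defining_atoms=(), apolar=True) for c in centers]
    return Pocket(id=1, spheres=spheres)


def _ligand_at(coords):
    res = Residue(name="PLM", chain_id="L", number=1, kind="ligand")
    for i, c in enumerate(coords):
        res.atoms.append(Atom(element="C", name=f"C{i+1}", coords=np.asarray(c, float)))
    return res


class TestLabelPockets:
    def test_coincident_center_single_sphere_rule(self):
        pocket = _pocket_at([(0, 0, 0)])
        ligand = _ligand_at([(0, 0, 0)])
        assert label_pockets([pocket], ligand, min_contact_spheres=1) == [1]

    def test_far_ligand_is_negative(self):
        pocket = _pocket_at([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        ligand = _ligand_at([(20, 0, 0)])
        assert label_pockets([pocket], ligand) == [0]

    def test_no_heavy_atoms_raises(self):
        pocket = _pocket_at([(0, 0, 0)])
        ligand = Residue(name="PLM", chain_id="L", number=1, kind="ligand")
        with pytest.raises(ValueError):
            label_pockets([pocket], ligand)

    def test_cage_labels_match_distance_oracle(self):
        """Contact labels equal an explicit distance-matrix computation."""
        cage = make_cage(positive_cage_spec(7))
        ligand = cage.ligands[0]
        apo = cage.without_ligands()
        pockets = detect_pockets(apo)
        got = label_pockets(pockets, ligand)
        lig = ligand.heavy_coords()
        expected = []
        for p in pockets:
            n = 0
            for s in p.spheres:
                dmin = min(np.linalg.norm(s.center - la) for la in lig)
                if dmin <= 3.0:
                    n += 1
            expected.append(1 if n >= 3 else 0)
        assert got == expected
        assert got[0] == 1  # the cavity pocket is the top-ranked one


class TestBuildDataset:
    @pytest.fixture()
    def structure_dir(self, tmp_path):
        d = tmp_path / "structs"
        d.mkdir()
        specs = {
            "1POS": positive_cage_spec(41),
            "2POS": positive_cage_spec(43),
            "3NEG": CageSpec(cavity_radius=4.6, seed=44),
            "4NEG": CageSpec(cavity_radius=4.7, seed=45),
        }
        for pdb_id, spec in specs.items():
            write_pdb(make_cage(spec), d / f"{pdb_id}.pdb")
        return d

    def _records(self, tmp_path, rows):
        path = tmp_path / "table.tsv"
        _write_table(path, rows)
        return load_training_table(path)

    def test_smoke_both_classes(self, tmp_path, structure_dir):
        records = self._records(tmp_path, [
            {"pdb_id": "1POS", "chain": "A", "ligand_code": "PLM", "species": "s", "label": 1},
            {"pdb_id": "2POS", "chain": "A", "ligand_code": "PLM", "species": "s", "label": 1},
            {"pdb_id": "3NEG", "chain": "A", "ligand_code": "", "species": "s", "label": 0},
            {"pdb_id": "4NEG", "chain": "A", "ligand_code": "", "species": "s", "label": 0},
        ])
        X, y, provenance, report = build_dataset(records, structure_dir)
        assert X.shape[0] >= 4
        assert set(np.unique(y)) == {0, 1}
        assert len(provenance) == X.shape[0]
        assert report.empty

    def test_missing_structure_reported(self, tmp_path, structure_dir):
        records = self._records(tmp_path, [
            {"pdb_id": "9ZZZ", "chain": "A", "ligand_code": "PLM", "species": "s", "label": 1},
            {"pdb_id": "3NEG", "chain": "A", "ligand_code": "", "species": "s", "label": 0},
        ])
        X, y, provenance, report = build_dataset(records, structure_dir)
        assert list(report["pdb_id"]) == ["9ZZZ"]
        assert "missing" in report["reason"][0]

    def test_ligand_code_absent_reported(self, tmp_path, structure_dir):
        records = self._records(tmp_path, [
            {"pdb_id": "1POS", "chain": "A", "ligand_code": "XYZ", "species": "s", "label": 1},
            {"pdb_id": "3NEG", "chain": "A", "ligand_code": "", "species": "s", "label": 0},
        ])
        X, y, provenance, report = build_dataset(records, structure_dir)
        assert list(report["pdb_id"]) == ["1POS"]
        assert (y == 0).all()

    def test_deterministic(self, tmp_path, structure_dir):
        records = self._records(tmp_path, [
            {"pdb_id": "1POS", "chain": "A", "ligand_code": "PLM", "species": "s", "label": 1},
            {"pdb_id": "3NEG", "chain": "A", "ligand_code": "", "species": "s", "label": 0},
        ])
        X1, y1, _, _ = build_dataset(records, structure_dir)
        X2, y2, _, _ = build_dataset(records, structure_dir)
        assert X1.tobytes() == X2.tobytes()
        assert (y1 == y2).all()


class TestDatasetInvariants:
    def test_provenance_bijects_with_rows(self, small_cage_dataset):
        X, y, provenance = small_cage_dataset
        assert len(provenance) == X.shape[0] == len(y)
        assert (provenance["label"].to_numpy() == y).all()

    def test_ligand_removal_never_shrinks_cavity(self):
        """Detecting with the ligand stripped can only add alpha spheres."""
        cage = make_cage(positive_cage_spec(19))
        apo_pockets = detect_pockets(cage.without_ligands())
        holo_pockets = detect_pockets(cage, include_ligands=True)
        assert apo_pockets[0].n_spheres >= (
            holo_pockets[0].n_spheres if holo_pockets else 0
        )
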