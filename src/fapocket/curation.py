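"""Training-set curation: tables, ligand-contact labeling, dataset assembly.

Training follows the two-table scheme: a table of real fatty-acid-binding
structures whose ligand-contacting pockets are labeled 1, and a table of
non-binding structures all of whose pockets are labeled 0.  Ligand atoms are
removed from the detection input (the cavity must be found as empty space,
matching the apo condition at prediction time); a pocket counts as
FA-binding when enough of its alpha-sphere centers lie near a ligand heavy
atom.  Non-contacting pockets of positive structures are discarded rather
than auto-labeled 0, to avoid label noise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectionParams, Pocket, detect_pockets
from .features import compute_features, features_to_matrix
from .ss import assign_ss_structure
from .structure import Residue, Structure, read_pdb

logger = logging.getLogger(__name__)

DEFAULT_COLUMN_MAP = {
    "pdb_id": "pdb_id",
    "chain": "chain",
    "ligand_code": "ligand_code",
    "species": "species",
    "label": "label",
}

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")

#: contact-rule defaults: sphere center within 3.0 Å of a ligand heavy atom,
#: at least 3 such spheres.
DEFAULT_CONTACT_DISTANCE = 3.0
DEFAULT_MIN_CONTACT_SPHERES = 3


@dataclass(frozen=True)
class TrainingRecord:
    pdb_id: str
    chain: str
    ligand_code: str
    species: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.label == 1 and not self.ligand_code:
            raise ValueError(f"{self.pdb_id}: positive record without ligand code")


def load_training_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[TrainingRecord]:
    """Load a curated structure table (TSV with header; '#' comments).

    Columns are mapped by name through `column_map` (defaults to the
    canonical names).  Rows with malformed PDB IDs are skipped with a log
    entry; duplicate (pdb_id, chain, ligand_code) rows are collapsed with a
    warning.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    for field in ("pdb_id", "label"):
        if cmap[field] not in df.columns:
            raise ValueError(f"{path}: missing mandatory column '{cmap[field]}'")

    records: list[TrainingRecord] = []
    seen: set[tuple] = set()
    n_dup = n_bad = 0
    for _, row in df.iterrows():
        pdb_id = str(row[cmap["pdb_id"]]).strip().upper()
        if not _PDB_ID_RE.match(pdb_id):
            logger.info("skipping row with malformed pdb_id %r", pdb_id)
            n_bad += 1
            continue
        chain = str(row.get(cmap["chain"], "")).strip() or "*"
        ligand = str(row.get(cmap["ligand_code"], "")).strip().upper()
        key = (pdb_id, chain, ligand)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        records.append(TrainingRecord(
            pdb_id=pdb_id,
            chain=chain,
            ligand_code=ligand,
            species=str(row.get(cmap["species"], "")).strip(),
            label=int(row[cmap["label"]]),
        ))
    if n_dup:
        logger.warning("%s: collapsed %d duplicate rows", path, n_dup)
    if n_bad:
        logger.warning("%s: skipped %d rows with malformed pdb_id", path, n_bad)
    return records


def table_summary(records: list[TrainingRecord]) -> dict:
    species = {r.species for r in records if r.species}
    return {
        "n_records": len(records),
        "n_distinct_species": len(species),
        "n_positive": sum(r.label for r in records),
        "n_negative": sum(1 - r.label for r in records),
    }


def load_ligand_exclusion_list(path: str | Path) -> set[str]:
    """Ligand chemical-component codes to exclude, one per line ('#' comments)."""
    codes = set()
    for line in Path(path).read_text().splitlines():
        code = line.split("#")[0].strip().upper()
        if code:
            if len(code) > 3:
                raise ValueError(f"{path}: ligand code {code!r} longer than 3 chars")
            codes.add(code)
    if not codes:
        raise ValueError(f"{path}: empty ligand exclusion list")
    return codes


def label_pockets(
    pockets: list[Pocket],
    ligand: Residue,
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
    min_contact_spheres: int = DEFAULT_MIN_CONTACT_SPHERES,
) -> list[int]:
    """1 per pocket iff >= min_contact_spheres sphere centers lie within
    contact_distance of any ligand heavy atom; else 0.

    The pockets must have been detected with the ligand's atoms excluded.
    """
    lig_coords = ligand.heavy_coords()
    if lig_coords.size == 0:
        raise ValueError(f"ligand {ligand.name} has no heavy atoms")
    labels = []
    for pocket in pockets:
        centers = pocket.centers()
        d = np.sqrt(((centers[:, None, :] - lig_coords[None, :, :]) ** 2).sum(axis=2))
        n_contact = int((d.min(axis=1) <= contact_distance).sum())
        labels.append(1 if n_contact >= min_contact_spheres else 0)
    return labels


def dataset_from_structures(
    entries: list[tuple[Structure, int]],
    params: DetectionParams = DetectionParams(),
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
    min_contact_spheres: int = DEFAULT_MIN_CONTACT_SPHERES,
    volume_seed: int = 0,
):
    """Build (X, y, provenance) from in-memory (structure, record_label) pairs.

    For label-1 structures the bound ligands are stripped before detection
    and only ligand-contacting pockets enter (as 1s).  For label-0
    structures all detected pockets enter as 0s (their ligands, if any, are
    stripped too).
    """
    feats, labels, prov = [], [], []
    for structure, record_label in entries:
        ligs = list(structure.ligands)
        apo = structure.without_ligands()
        pockets = detect_pockets(apo, params)
        if not pockets:
            continue
        ss = assign_ss_structure(apo)
        if record_label == 1:
            if not ligs:
                raise ValueError(f"{structure.id}: positive structure has no ligand")
            per_lig = [
                label_pockets(pockets, lig, contact_distance, min_contact_spheres)
                for lig in ligs
            ]
            pocket_labels = [max(col) for col in zip(*per_lig)]
        else:
            pocket_labels = [0] * len(pockets)
        for pocket, lab in zip(pockets, pocket_labels):
            if record_label == 1 and lab == 0:
                continue  # non-contacting pockets of positives are discarded
            feats.append(compute_features(pocket, apo, ss, seed=volume_seed))
            labels.append(lab)
            prov.append({
                "structure_id": structure.id,
                "pocket_id": pocket.id,
                "label": lab,
                "source_label": record_label,
                "n_spheres": pocket.n_spheres,
            })
    X = features_to_matrix(feats) if feats else np.empty((0, 14))
    y = np.array(labels, dtype=int)
    provenance = pd.DataFrame(
        prov, columns=["structure_id", "pocket_id", "label", "source_label", "n_spheres"]
    )
    logger.info(
        "dataset: %d pockets (%d positive, %d negative)",
        len(y), int(y.sum()), int((1 - y).sum()),
    )
    return X, y, provenance


def build_dataset(
    records: list[TrainingRecord],
    structure_dir: str | Path,
    params: DetectionParams = DetectionParams(),
    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
    min_contact_spheres: int = DEFAULT_MIN_CONTACT_SPHERES,
    volume_seed: int = 0,
):
    """Build (X, y, provenance, skip_report) from table records + PDB files.

    Structures are looked up as <structure_dir>/<pdb_id>.pdb (case-insensitive
    on the ID).  Missing files or positive records whose ligand code is not
    present in the structure are skipped and listed in the report — never
    silently.
    """
    structure_dir = Path(structure_dir)
    entries: list[tuple[Structure, int]] = []
    skipped: list[dict] = []
    for rec in records:
        candidates = [
            structure_dir / f"{rec.pdb_id}.pdb",
            structure_dir / f"{rec.pdb_id.lower()}.pdb",
        ]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            skipped.append({"pdb_id": rec.pdb_id, "reason": "structure file missing"})
            continue
        structure = read_pdb(path)
        if rec.label == 1:
            matching = [l for l in structure.ligands if l.name.upper() == rec.ligand_code]
            if not matching:
                skipped.append({
                    "pdb_id": rec.pdb_id,
                    "reason": f"ligand {rec.ligand_code} absent from structure",
                })
                continue
            structure = structure.without_ligands(
                codes={l.name.upper() for l in structure.ligands} - {rec.ligand_code}
            )
        entries.append((structure, rec.label))
    X, y, provenance = dataset_from_structures(
        entries, params, contact_distance, min_contact_spheres, volume_seed
    )
    report = pd.DataFrame(skipped, columns=["pdb_id", "reason"])
    if len(report):
        logger.warning("build_dataset skipped %d records", len(report))
    return X, y, provenance, report
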