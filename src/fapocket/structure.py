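"""Hierarchical structure model and PDB I/O.

Reads PDB files into a clean Atom/Residue/Structure hierarchy with polymer
chains, ligand instances and waters separated.  Hydrogens are dropped
everywhere (the pipeline operates on heavy atoms); for altloc duplicates the
highest-occupancy conformer is kept.  Author residue numbering is preserved
— all downstream residue-stretch reports use author numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

from .constants import VDW_DEFAULT, VDW_RADII, WATER_NAMES

logger = logging.getLogger(__name__)


class PDBParseError(ValueError):
    """Raised for unparseable PDB records or files with no usable atoms."""


@dataclass
class Atom:
    """A heavy atom with element-assigned van der Waals radius."""

    element: str
    name: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    vdw_radius: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


@dataclass
class Residue:
    name: str
    chain_id: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    kind: str = "polymer"  # polymer | ligand | water

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    """A parsed structure: ordered polymer chains, ligands, waters."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    ligands: list[Residue] = field(default_factory=list)
    waters: list[Residue] = field(default_factory=list)
    model_index: int = 0
    remarks: list[str] = field(default_factory=list)

    def polymer_residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def polymer_atoms(self) -> list[tuple[Atom, Residue]]:
        return [(a, r) for r in self.polymer_residues() for a in r.atoms]

    def all_atoms(self) -> list[tuple[Atom, Residue]]:
        out = self.polymer_atoms()
        out.extend((a, r) for r in self.ligands for a in r.atoms)
        return out

    def n_atoms(self) -> int:
        return len(self.all_atoms())

    def without_ligands(self, codes: set[str] | None = None) -> "Structure":
        """Copy with ligands removed (all of them, or just `codes`)."""
        kept = [
            lig for lig in self.ligands
            if codes is not None and lig.name.upper() not in codes
        ]
        return Structure(
            id=self.id,
            chains=self.chains,
            ligands=kept,
            waters=self.waters,
            model_index=self.model_index,
            remarks=list(self.remarks),
        )


def _prescan_pdb(path: Path) -> int:
    """Validate coordinate records column-wise; return their count.

    Raises PDBParseError naming the first bad line.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}: truncated coordinate record at line {lineno}")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path}: malformed coordinates at line {lineno}"
                ) from exc
    return n


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def _dedup_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: max occupancy, ties prefer altloc
    'A', then lexicographic altloc."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in atoms:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
            continue
        # higher occupancy wins; tie -> altloc 'A'; tie -> lexicographically
        # smallest altloc
        if (atom.occupancy, atom.altloc == "A") > (prev.occupancy, prev.altloc == "A"):
            by_name[atom.name] = atom
        elif (atom.occupancy, atom.altloc == "A") == (prev.occupancy, prev.altloc == "A"):
            if atom.altloc < prev.altloc:
                by_name[atom.name] = atom
    return [by_name[name] for name in order]


def read_pdb(path: str | Path, model_policy: str | int = "first") -> Structure:
    """Parse a PDB file into a Structure.

    Hydrogens are dropped; waters go to ``structure.waters``; non-water
    HETATM residues become ligands.  Only one model is loaded: the first by
    default, or the 0-based index given as ``model_policy``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_records = _prescan_pdb(path)
    if n_records == 0:
        raise PDBParseError(f"{path}: no ATOM or HETATM records")

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models")
    model_index = 0 if model_policy == "first" else int(model_policy)
    if model_index >= len(st):
        raise PDBParseError(f"{path}: model index {model_index} out of range")
    model = st[model_index]

    structure = Structure(id=st.name or path.stem, model_index=model_index)
    chain_map: dict[str, Chain] = {}
    n_usable = 0
    for g_chain in model:
        for g_res in g_chain:
            atoms = []
            is_het = g_res.het_flag == "H"
            for g_atom in g_res:
                if g_atom.element.is_hydrogen:
                    continue
                element = g_atom.element.name.upper()
                if not element or element == "X":
                    element = _infer_element(g_atom.name)
                altloc = g_atom.altloc if g_atom.altloc != "\x00" else ""
                atoms.append(Atom(
                    element=element,
                    name=g_atom.name,
                    coords=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
                    occupancy=g_atom.occ,
                    altloc=altloc,
                    is_hetero=is_het,
                ))
            atoms = _dedup_altlocs(atoms)
            if not atoms:
                continue
            n_usable += len(atoms)
            icode = g_res.seqid.icode.strip()
            residue = Residue(
                name=g_res.name,
                chain_id=g_chain.name,
                number=g_res.seqid.num,
                icode=icode,
                atoms=atoms,
            )
            if g_res.name.upper() in WATER_NAMES:
                residue.kind = "water"
                structure.waters.append(residue)
            elif is_het:
                residue.kind = "ligand"
                structure.ligands.append(residue)
            else:
                residue.kind = "polymer"
                if g_chain.name not in chain_map:
                    chain_map[g_chain.name] = Chain(chain_id=g_chain.name)
                    structure.chains.append(chain_map[g_chain.name])
                chain_map[g_chain.name].residues.append(residue)
    if n_usable == 0:
        raise PDBParseError(f"{path}: zero usable (heavy) atoms")
    assign_vdw_radii(structure)
    return structure


def assign_vdw_radii(
    structure: Structure, radius_table: dict[str, float] | None = None
) -> Structure:
    """Assign van der Waals radii from an element table (in place).

    Unknown elements get the default carbon-like radius and a logged warning.
    """
    table = radius_table if radius_table is not None else VDW_RADII
    unknown: set[str] = set()
    for atom, _res in structure.all_atoms():
        radius = table.get(atom.element.upper())
        if radius is None:
            radius = VDW_DEFAULT
            unknown.add(atom.element)
        atom.vdw_radius = radius
    for res in structure.waters:
        for atom in res.atoms:
            atom.vdw_radius = table.get(atom.element.upper(), VDW_DEFAULT)
    if unknown:
        logger.warning(
            "elements not in vdW table, defaulted to %.2f Å: %s",
            VDW_DEFAULT, ", ".join(sorted(unknown)),
        )
    return structure


def _format_atom_line(
    record: str, serial: int, name: str, resname: str, chain_id: str,
    resnum: int, icode: str, coords: np.ndarray, occupancy: float,
    bfactor: float, element: str,
) -> str:
    name_field = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name_field:<4s} {resname:<3s} "
        f"{chain_id:1s}{resnum:>4d}{icode or ' ':1s}   "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{occupancy:6.2f}{bfactor:6.2f}          {element:>2s}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as a PDB file (polymer chains, then ligands)."""
    lines: list[str] = [f"REMARK 250 {r}" for r in structure.remarks]
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                lines.append(_format_atom_line(
                    "ATOM", serial, atom.name, res.name, res.chain_id,
                    res.number, res.icode, atom.coords, atom.occupancy,
                    0.0, atom.element,
                ))
                serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    for res in structure.ligands:
        for atom in res.atoms:
            lines.append(_format_atom_line(
                "HETATM", serial, atom.name, res.name, res.chain_id,
                res.number, res.icode, atom.coords, atom.occupancy,
                0.0, atom.element,
            ))
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pocket_pdb(
    structure: Structure, pockets: Sequence, path: str | Path
) -> None:
    """Write the structure plus its pockets' alpha spheres.

    Each sphere becomes a HETATM pseudo-atom (resname STP, element C) in
    chain 'Z', one residue per pocket; the sphere radius is stored in the
    B-factor column.  The output is re-readable by :func:`read_pdb`.
    """
    out = Structure(
        id=structure.id, chains=structure.chains, ligands=list(structure.ligands),
        waters=structure.waters, model_index=structure.model_index,
        remarks=list(structure.remarks),
    )
    for pocket in pockets:
        res = Residue(name="STP", chain_id="Z", number=pocket.id, kind="ligand")
        for i, sphere in enumerate(pocket.spheres, start=1):
            res.atoms.append(Atom(
                element="C", name=f"S{i:03d}"[:4], coords=sphere.center,
                occupancy=1.0, is_hetero=True, vdw_radius=VDW_DEFAULT,
            ))
        out.ligands.append(res)
    # stash radii in B-factor by rewriting lines after the fact
    write_pdb(out, path)
    _rewrite_sphere_bfactors(path, pockets)


def _rewrite_sphere_bfactors(path: str | Path, pockets: Sequence) -> None:
    radii = [s.radius for p in pockets for s in p.spheres]
    if not radii:
        return
    lines = Path(path).read_text().splitlines()
    it = iter(radii)
    for i, line in enumerate(lines):
        if line.startswith("HETATM") and line[17:20] == "STP":
            r = next(it)
            lines[i] = line[:60] + f"{r:6.2f}" + line[66:]
    Path(path).write_text("\n".join(lines) + "\n")
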