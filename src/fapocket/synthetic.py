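"""Synthetic inputs for the whole pipeline.

Two generators make the workflow runnable with no downloads:

* :func:`make_cage` builds protein-like atom clouds ("cages"): pseudo-ALA
  residues jittered over a spherical shell that encloses a buried cavity
  with a cone-shaped mouth, optionally with an acyl-chain or ring
  pseudo-ligand placed inside the cavity.  A cavity of radius r yields
  alpha spheres of radius ≈ r, so cavity radii in the 4.5–6 Å range land in
  the detector's default 4.0–6.2 Å window.

* :func:`simulate_features` draws labeled pocket feature matrices from
  class-conditional Gaussians around realistic per-descriptor baselines,
  with a controllable mean separation on a controllable fraction of
  informative columns — a statistical stand-in for the curated FA-bound /
  unbound pocket sets.

* :func:`make_training_table` emits curated-table stand-ins with the
  real tables' shape (340 human rows; 70 rows over 52 species).

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .structure import Atom, Chain, Residue, Structure

# ---------------------------------------------------------------------------
# cavity-bearing cage structures

ELEMENT_MIX_APOLAR = {"C": 0.85, "S": 0.05, "N": 0.05, "O": 0.05}
ELEMENT_MIX_POLAR = {"C": 0.40, "N": 0.30, "O": 0.30}

#: FA-like chemical component codes used by the synthetic tables and the
#: exclusion-list stand-in (acyl-chain carboxylic acids and close relatives).
FA_LIGAND_CODES = (
    "PLM", "MYR", "OLA", "STE", "DAO", "LAU", "OCA", "ACD",
    "EPA", "DHA", "LNL", "HXA", "ELA", "VCA", "PAM", "DKA",
)

#: decoy (non-FA) ligand codes for negative pools.
DECOY_LIGAND_CODES = ("BNZ", "IPH", "TOL", "NAP", "IMD", "PYR")


@dataclass(frozen=True)
class CageSpec:
    n_shell_atoms: int = 200
    shell_radius: float = 9.0
    shell_thickness: float = 4.0
    cavity_radius: float = 5.0
    mouth_half_angle: float = 15.0
    element_mix: tuple[tuple[str, float], ...] = (("C", 1.0),)
    ligand_kind: str = "none"  # none | acyl | ring
    ligand_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity_radius >= self.shell_radius:
            raise ValueError("cavity_radius must be smaller than shell_radius")
        total = sum(f for _, f in self.element_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"element_mix fractions sum to {total}, not 1")
        if self.mouth_half_angle >= 90.0:
            raise ValueError(
                "mouth_half_angle >= 90° opens more than a hemisphere — "
                "no enclosed cavity remains"
            )
        if self.ligand_kind not in ("none", "acyl", "ring"):
            raise ValueError(f"unknown ligand kind {self.ligand_kind!r}")
        if self.ligand_kind == "ring" and self.ligand_size < 3:
            raise ValueError("ring needs >= 3 members")
        if self.ligand_kind == "acyl" and self.ligand_size < 2:
            raise ValueError("acyl chain needs >= 2 carbons")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    polar = np.arccos(1 - 2 * i / n)
    azim = np.pi * (1 + 5**0.5) * i
    return np.column_stack([
        np.sin(polar) * np.cos(azim),
        np.sin(polar) * np.sin(azim),
        np.cos(polar),
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    return rot


def _acyl_chain(n_carbons: int) -> np.ndarray:
    """Zigzag carbon chain along z: 1.5 Å bonds, ~1.25 Å axial advance."""
    z = (np.arange(n_carbons) - (n_carbons - 1) / 2) * 1.25
    x = 0.41 * np.where(np.arange(n_carbons) % 2 == 0, 1.0, -1.0)
    return np.column_stack([x, np.zeros(n_carbons), z])


def _ring(n_members: int) -> np.ndarray:
    """Planar regular polygon with 1.4 Å edges in the xy-plane."""
    r = 1.4 / (2 * np.sin(np.pi / n_members))
    theta = 2 * np.pi * np.arange(n_members) / n_members
    return np.column_stack([r * np.cos(theta), r * np.sin(theta),
                            np.zeros(n_members)])


def make_cage(spec: CageSpec) -> Structure:
    """Deterministic cavity-bearing pseudo-protein.

    Atoms sit on concentric quasi-uniform (Fibonacci-lattice) layers 2 Å
    apart, from just outside the cavity out to ``shell_radius``, each layer
    randomly rotated and jittered by 0.25 Å, so the shell is densely packed
    (no spurious voids) while the interior stays empty.  The mouth cone
    around +z pierces the innermost layer only: the cavity is buried, with
    an aperture of the requested half-angle.  Atoms are grouped five at a
    time into pseudo-ALA residues (N, CA, C, O, CB) threaded by
    nearest-neighbor ordering, so backbone-dihedral / secondary-structure
    code runs on the output.  Atom *elements* are drawn from
    ``element_mix`` (the pseudo-residues are geometric, not chemical).  The
    optional ligand sits inside the cavity as a HETATM residue.
    """
    rng = np.random.default_rng(spec.seed)
    inner = max(spec.cavity_radius + 0.9,
                spec.shell_radius - spec.shell_thickness)

    layer_radii = []
    r = inner
    while r <= spec.shell_radius:
        layer_radii.append(r)
        r += 2.0
    if not layer_radii:
        layer_radii = [inner]
    areas = np.array([ri * ri for ri in layer_radii])
    counts = np.maximum(
        (spec.n_shell_atoms * areas / areas.sum()).astype(int), 8
    )
    cos_mouth = np.cos(np.radians(spec.mouth_half_angle))
    layers = []
    for li, (ri, ci) in enumerate(zip(layer_radii, counts)):
        base = _fibonacci_sphere(int(ci)) @ _random_rotation(rng).T
        if li == 0:  # aperture through the cavity lining only
            base = base[base[:, 2] < cos_mouth]
        pts = base * ri + rng.normal(scale=0.25, size=(len(base), 3))
        norms = np.linalg.norm(pts, axis=1)
        low = norms < spec.cavity_radius
        pts[low] *= (spec.cavity_radius / norms[low])[:, None]
        layers.append(pts)
    points = np.vstack(layers)

    # greedy nearest-neighbor threading, then 5-atom pseudo-residues
    order = [0]
    remaining = set(range(1, len(points)))
    while remaining:
        last = points[order[-1]]
        nxt = min(remaining, key=lambda i: float(np.sum((points[i] - last) ** 2)))
        order.append(nxt)
        remaining.remove(nxt)
    points = points[order]

    elements, probs = zip(*spec.element_mix)
    atom_names = ("N", "CA", "C", "O", "CB")
    chain = Chain(chain_id="A")
    for ri in range(len(points) // 5):
        residue = Residue(name="ALA", chain_id="A", number=ri + 1, kind="polymer")
        for k, name in enumerate(atom_names):
            residue.atoms.append(Atom(
                element=str(rng.choice(elements, p=probs)),
                name=name,
                coords=points[5 * ri + k],
                is_hetero=False,
            ))
        chain.residues.append(residue)

    structure = Structure(
        id=f"cage-{spec.ligand_kind}-{spec.seed}",
        chains=[chain],
        remarks=[
            f"synthetic cage seed={spec.seed} cavity={spec.cavity_radius:.2f} "
            f"shell={spec.shell_radius:.2f} mouth={spec.mouth_half_angle:.1f} "
            f"ligand={spec.ligand_kind}{spec.ligand_size if spec.ligand_kind != 'none' else ''}",
        ],
    )

    if spec.ligand_kind != "none":
        if spec.ligand_kind == "acyl":
            coords = _acyl_chain(spec.ligand_size)
            resname = "PLM"
        else:
            coords = _ring(spec.ligand_size)
            resname = "BNZ"
        if np.linalg.norm(coords, axis=1).max() >= spec.cavity_radius:
            raise ValueError(
                f"{spec.ligand_kind}({spec.ligand_size}) does not fit inside "
                f"a cavity of radius {spec.cavity_radius} Å"
            )
        ligand = Residue(name=resname, chain_id="L", number=1, kind="ligand")
        for j, xyz in enumerate(coords, start=1):
            ligand.atoms.append(Atom(
                element="C", name=f"C{j}", coords=xyz, is_hetero=True,
            ))
        structure.ligands.append(ligand)

    from .structure import assign_vdw_radii

    assign_vdw_radii(structure)
    return structure


# study-condition cage classes: FA-binding cages are apolar-shelled with a
# roomier cavity; decoys are polar-shelled with a tighter cavity.

def positive_cage_spec(seed: int) -> CageSpec:
    rng = np.random.default_rng(seed)
    return CageSpec(
        n_shell_atoms=240,
        cavity_radius=float(rng.uniform(5.0, 5.6)),
        element_mix=tuple(ELEMENT_MIX_APOLAR.items()),
        ligand_kind="acyl",
        ligand_size=8,
        seed=seed,
    )


def negative_cage_spec(seed: int, ligand_kind: str = "ring") -> CageSpec:
    rng = np.random.default_rng(seed)
    return CageSpec(
        n_shell_atoms=240,
        cavity_radius=float(rng.uniform(4.5, 4.9)),
        element_mix=tuple(ELEMENT_MIX_POLAR.items()),
        ligand_kind=ligand_kind,
        ligand_size=6,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# labeled feature matrices

#: per-descriptor baseline (mean, sd) used by the feature simulator.
FEATURE_BASELINES = {
    "n_spheres": (40.0, 10.0),
    "mean_radius": (5.0, 0.3),
    "max_radius": (6.0, 0.15),
    "apolar_fraction": (0.45, 0.12),
    "volume": (600.0, 150.0),
    "compactness": (6.0, 1.0),
    "hydrophobicity": (0.0, 1.5),
    "polar_residue_fraction": (0.30, 0.08),
    "charged_residue_fraction": (0.25, 0.08),
    "aromatic_residue_fraction": (0.12, 0.05),
    "helix_fraction": (0.40, 0.10),
    "strand_fraction": (0.20, 0.08),
    "coil_fraction": (0.40, 0.10),
    "n_lining_residues": (25.0, 6.0),
}

_FRACTION_COLS = tuple(
    i for i, name in enumerate(FEATURE_NAMES) if name.endswith("fraction")
)
_SS_COLS = tuple(FEATURE_NAMES.index(n)
                 for n in ("helix_fraction", "strand_fraction", "coil_fraction"))


@dataclass(frozen=True)
class FeatureSimSpec:
    n_pos: int = 200
    n_neg: int = 200
    effect_size: float = 3.0  # mean shift per informative column, pooled-sd units
    informative_fraction: float = 0.5
    noise_cov: str = "diagonal"  # "diagonal" | "exchangeable:<rho>"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.informative_fraction <= 1:
            raise ValueError("informative_fraction must lie in (0, 1]")


def _noise(rng, n: int, p: int, noise_cov: str) -> np.ndarray:
    if noise_cov == "diagonal":
        return rng.normal(size=(n, p))
    kind, _, rho_s = noise_cov.partition(":")
    if kind != "exchangeable":
        raise ValueError(f"unknown noise_cov {noise_cov!r}")
    rho = float(rho_s)
    shared = rng.normal(size=(n, 1))
    idio = rng.normal(size=(n, p))
    return np.sqrt(rho) * shared + np.sqrt(1 - rho) * idio


def simulate_features(spec: FeatureSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional Gaussian feature matrix (X, y).

    Informative columns (a seed-fixed subset of the declared fraction of the
    14 descriptors) differ between classes by ``effect_size`` pooled
    standard deviations; the rest are identically distributed.  Fraction
    columns are clipped to [0, 1] afterwards and the H/E/C triple is
    renormalized to sum to one, so rows satisfy the feature-schema
    invariants.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(FEATURE_NAMES)
    m = max(1, round(spec.informative_fraction * p))
    informative = np.sort(rng.choice(p, size=m, replace=False))

    means = np.array([FEATURE_BASELINES[n][0] for n in FEATURE_NAMES])
    sds = np.array([FEATURE_BASELINES[n][1] for n in FEATURE_NAMES])
    shift = np.zeros(p)
    shift[informative] = spec.effect_size * sds[informative]

    n = spec.n_pos + spec.n_neg
    y = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    Z = _noise(rng, n, p, spec.noise_cov)
    X = means + sds * Z + np.outer(y, shift)

    X[:, _FRACTION_COLS] = np.clip(X[:, list(_FRACTION_COLS)], 0.0, 1.0)
    ss = X[:, list(_SS_COLS)]
    ss_sum = ss.sum(axis=1, keepdims=True)
    ss_sum[ss_sum == 0] = 1.0
    X[:, list(_SS_COLS)] = ss / ss_sum
    count_cols = [FEATURE_NAMES.index("n_spheres"),
                  FEATURE_NAMES.index("n_lining_residues")]
    X[:, count_cols] = np.maximum(X[:, count_cols], 1.0)
    X[:, FEATURE_NAMES.index("volume")] = np.maximum(
        X[:, FEATURE_NAMES.index("volume")], 1.0
    )

    perm = rng.permutation(n)
    return X[perm], y[perm]


# ---------------------------------------------------------------------------
# curated-table stand-ins

_GENERA = (
    "Saccharomyces", "Homo", "Mus", "Rattus", "Danio", "Gallus", "Bos",
    "Sus", "Equus", "Canis", "Xenopus", "Drosophila", "Arabidopsis",
)
_EPITHETS = ("cerevisiae", "norvegicus", "melanogaster", "thaliana")


def _species_names(n: int) -> list[str]:
    names = []
    for genus in _GENERA:
        for epithet in _EPITHETS:
            names.append(f"{genus} {epithet}")
            if len(names) == n:
                return names
    raise ValueError(f"cannot build {n} species names")


def _fake_pdb_ids(rng: np.random.Generator, n: int) -> list[str]:
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"))
    ids: set[str] = set()
    while len(ids) < n:
        first = str(rng.integers(1, 10))
        rest = "".join(rng.choice(letters, size=3))
        ids.add(first + rest)
    return sorted(ids)


def make_training_table(kind: str = "human", seed: int = 2021) -> pd.DataFrame:
    """Synthetic stand-in for the curated training tables.

    ``kind='human'``: 340 rows, all Homo sapiens.  ``kind='all_species'``:
    70 rows spanning exactly 52 distinct species.  Positive rows carry an
    FA-like ligand code; negative rows have an empty ligand code.
    """
    rng = np.random.default_rng(seed)
    if kind == "human":
        n, n_pos = 340, 204
        species = ["Homo sapiens"] * n
    elif kind == "all_species":
        n, n_pos = 70, 45
        distinct = _species_names(52)
        extra = list(rng.choice(distinct, size=n - 52, replace=True))
        species = distinct + extra
        rng.shuffle(species)
    else:
        raise ValueError(f"unknown table kind {kind!r}")
    ids = _fake_pdb_ids(rng, n)
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n - n_pos, int)])
    rng.shuffle(labels)
    chains = rng.choice(list("ABCD"), size=n)
    rows = []
    for pdb_id, chain, sp, label in zip(ids, chains, species, labels):
        rows.append({
            "pdb_id": pdb_id,
            "chain": chain,
            "ligand_code": str(rng.choice(FA_LIGAND_CODES)) if label else "",
            "species": sp,
            "label": int(label),
        })
    return pd.DataFrame(rows)


def write_training_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# synthetic stand-in for a curated FA-binding structure table\n")
        df.to_csv(fh, sep="\t", index=False)


def write_ligand_exclusion_list(path, codes=FA_LIGAND_CODES) -> None:
    with open(path, "w") as fh:
        fh.write("# synthetic stand-in: FA-like ligand codes excluded from negative pools\n")
        fh.write("\n".join(codes) + "\n")


# ---------------------------------------------------------------------------
# ideal backbone builder (for secondary-structure tests and fixtures)

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.0
_ANGLE_CA_C_N = 117.2
_ANGLE_C_N_CA = 121.7


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Next atom position from three predecessors (natural extension)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_ideal_chain(
    n_residues: int, phi: float = -57.0, psi: float = -47.0,
    name: str = "ideal", residue_name: str = "ALA",
) -> Structure:
    """Backbone-only chain with uniform (φ, ψ) and trans peptide bonds.

    Standard bond lengths/angles; useful as an exactly invertible fixture:
    recomputing dihedrals from the coordinates returns (φ, ψ) to well under
    a degree.
    """
    if n_residues < 2:
        raise ValueError("need >= 2 residues")
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = coords[-1]
        n_next = _place(prev["N"], prev["CA"], prev["C"], _BOND_C_N,
                        _ANGLE_CA_C_N, psi)
        ca_next = _place(prev["CA"], prev["C"], n_next, _BOND_N_CA,
                         _ANGLE_C_N_CA, 180.0)
        c_next = _place(prev["C"], n_next, ca_next, _BOND_CA_C,
                        _ANGLE_N_CA_C, phi)
        coords.append({"N": n_next, "CA": ca_next, "C": c_next})
    chain = Chain(chain_id="A")
    for i, pos in enumerate(coords, start=1):
        res = Residue(name=residue_name, chain_id="A", number=i, kind="polymer")
        for atom_name in ("N", "CA", "C"):
            res.atoms.append(Atom(
                element=atom_name[0], name=atom_name, coords=pos[atom_name],
            ))
        res.atoms.append(Atom(element="O", name="O",
                              coords=pos["C"] + np.array([0.0, 0.0, 1.23])))
        chain.residues.append(res)
    structure = Structure(id=name, chains=[chain])
    from .structure import assign_vdw_radii

    return assign_vdw_radii(structure)
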