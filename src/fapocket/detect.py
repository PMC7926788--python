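"""Alpha-sphere cavity detection.

A cavity is the structural "hole" in a protein; a *pocket* is the
computational construct used to analyze it: here, a single-linkage cluster
of alpha spheres.  An alpha sphere is a sphere tangent to four atom centers
that contains no atom center — exactly the circumspheres of Delaunay
tetrahedra of the atom cloud, band-pass filtered by radius.  Spheres of
intermediate radius (the default window is 4.0–6.2 Å, i.e. fpocket's ``-m``
floor raised to 4 as the fatty-acid-pocket setting, with fpocket's default
ceiling) line clefts and cavities rather than bulk solvent or packing
interstices.  Clustering distance defaults to 6.0 Å (the ``-D 6`` setting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree

from .constants import APOLAR_ELEMENTS
from .structure import Atom, Residue, Structure

#: Strict-inside tolerance for the "contains no atom center" test (Å).
INSIDE_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when four points are too close to coplanar for a circumsphere."""


@dataclass(frozen=True)
class DetectionParams:
    """Geometry parameters of the detector.

    min/max_alpha_radius bound the kept circumsphere radii (Å, inclusive);
    cluster_distance is the single-linkage cutoff between sphere centers (Å);
    pockets with fewer than min_spheres_per_pocket spheres are dropped; a
    sphere is apolar when at least apolar_probe_count of its four defining
    atoms are carbon or sulfur.
    """

    min_alpha_radius: float = 4.0
    max_alpha_radius: float = 6.2
    cluster_distance: float = 6.0
    min_spheres_per_pocket: int = 15
    apolar_probe_count: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.min_alpha_radius < self.max_alpha_radius:
            raise ValueError("need 0 < min_alpha_radius < max_alpha_radius")
        if self.cluster_distance <= 0:
            raise ValueError("cluster_distance must be positive")
        if self.min_spheres_per_pocket < 1:
            raise ValueError("min_spheres_per_pocket must be >= 1")


@dataclass
class AlphaSphere:
    center: np.ndarray  # (3,) Å
    radius: float
    defining_atoms: tuple  # 4 (Atom, Residue) pairs
    apolar: bool


@dataclass
class Pocket:
    id: int
    spheres: list[AlphaSphere]
    lining_residues: list[Residue] = field(default_factory=list)
    span: dict = field(default_factory=dict)  # chain_id -> (min, max) author numbers
    apolar_fraction: float = 0.0

    @property
    def n_spheres(self) -> int:
        return len(self.spheres)

    @property
    def mean_radius(self) -> float:
        return float(np.mean([s.radius for s in self.spheres]))

    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.spheres])

    def centroid(self) -> np.ndarray:
        return self.centers().mean(axis=0)


def circumsphere(p1, p2, p3, p4) -> tuple[np.ndarray, float]:
    """Center and radius of the sphere through four non-coplanar points.

    Solves the 3x3 linear system  2(p_i - p_4)·c = |p_i|^2 - |p_4|^2.
    """
    pts = np.array([p1, p2, p3, p4], dtype=float)
    a = 2.0 * (pts[:3] - pts[3])
    # 6 * signed tetrahedron volume = det of edge matrix
    vol6 = abs(np.linalg.det(pts[:3] - pts[3]))
    if vol6 / 6.0 <= 1e-9:
        raise DegenerateGeometryError("four points are (near-)coplanar")
    b = np.sum(pts[:3] ** 2, axis=1) - np.sum(pts[3] ** 2)
    center = np.linalg.solve(a, b)
    radius = float(np.linalg.norm(pts[0] - center))
    return center, radius


def _circumspheres_batch(points: np.ndarray, simplices: np.ndarray):
    """Vectorized circumcenters/radii for Delaunay tetrahedra.

    Degenerate (near-zero volume) tetrahedra get radius = inf so the radius
    band filter removes them.
    """
    p = points[simplices]  # (m, 4, 3)
    a = 2.0 * (p[:, :3, :] - p[:, 3:4, :])  # (m, 3, 3)
    b = (p[:, :3, :] ** 2).sum(axis=2) - (p[:, 3, :] ** 2).sum(axis=1, keepdims=True)
    det = np.linalg.det(a)
    ok = np.abs(det) > 1e-12
    centers = np.full((len(simplices), 3), np.nan)
    if ok.any():
        centers[ok] = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
    radii = np.where(ok, np.linalg.norm(p[:, 0, :] - centers, axis=1), np.inf)
    return centers, radii


def generate_alpha_spheres(
    structure: Structure,
    params: DetectionParams = DetectionParams(),
    include_ligands: bool = False,
) -> list[AlphaSphere]:
    """Alpha spheres of the structure's heavy-atom cloud.

    One candidate per Delaunay tetrahedron; kept iff the circumsphere radius
    lies in [min_alpha_radius, max_alpha_radius] (inclusive) and no atom
    center lies strictly inside.  Output is sorted by center coordinates so
    the result is independent of atom ordering.
    """
    pairs = structure.all_atoms() if include_ligands else structure.polymer_atoms()
    if len(pairs) < 4:
        raise ValueError(f"{structure.id}: need >= 4 heavy atoms, have {len(pairs)}")
    points = np.array([a.coords for a, _ in pairs])
    tri = Delaunay(points)
    centers, radii = _circumspheres_batch(points, tri.simplices)
    in_band = (radii >= params.min_alpha_radius) & (radii <= params.max_alpha_radius)
    centers, radii = centers[in_band], radii[in_band]
    simplices = tri.simplices[in_band]

    # Delaunay guarantees empty circumspheres up to floating point; re-check
    # explicitly so the invariant holds under the declared tolerance.
    tree = cKDTree(points)
    nearest, _ = tree.query(centers, k=1)
    empty = nearest >= radii - INSIDE_TOL

    spheres = []
    for c, r, simplex in zip(centers[empty], radii[empty], simplices[empty]):
        atoms = tuple(pairs[i] for i in simplex)
        n_apolar = sum(1 for a, _ in atoms if a.element.upper() in APOLAR_ELEMENTS)
        spheres.append(AlphaSphere(
            center=c, radius=float(r), defining_atoms=atoms,
            apolar=n_apolar >= params.apolar_probe_count,
        ))
    spheres.sort(key=lambda s: (s.center[0], s.center[1], s.center[2], s.radius))
    return spheres


def cluster_spheres(
    spheres: list[AlphaSphere], cluster_distance: float
) -> list[Pocket]:
    """Single-linkage clustering of sphere centers at `cluster_distance`.

    Pockets are the connected components of the graph with an edge wherever
    two centers are within the cutoff, ranked by sphere count descending
    (ties: mean radius descending).  Returned pockets are pre-filter: no
    minimum-size cut, no lining residues yet.
    """
    if not spheres:
        return []
    centers = np.array([s.center for s in spheres])
    tree = cKDTree(centers)
    pairs = tree.query_pairs(r=cluster_distance, output_type="ndarray")
    n = len(spheres)
    data = np.ones(len(pairs))
    graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    groups: list[list[AlphaSphere]] = [[] for _ in range(n_comp)]
    for sphere, lab in zip(spheres, labels):
        groups[lab].append(sphere)
    groups.sort(key=lambda g: (-len(g), -float(np.mean([s.radius for s in g]))))
    return [Pocket(id=i + 1, spheres=g) for i, g in enumerate(groups)]


def finalize_pockets(
    structure: Structure,
    pockets: list[Pocket],
    params: DetectionParams = DetectionParams(),
) -> list[Pocket]:
    """Apply the minimum-size filter and annotate lining residues and spans.

    The lining residues are the union of the residues owning the spheres'
    defining atoms; the span per chain is (min, max) of author residue
    numbers.  apolar_fraction is the fraction of apolar spheres.
    """
    kept = [p for p in pockets if p.n_spheres >= params.min_spheres_per_pocket]
    for rank, pocket in enumerate(kept, start=1):
        pocket.id = rank
        seen: dict[tuple, Residue] = {}
        for sphere in pocket.spheres:
            for _atom, res in sphere.defining_atoms:
                seen.setdefault(res.key, res)
        pocket.lining_residues = sorted(
            seen.values(), key=lambda r: (r.chain_id, r.number, r.icode)
        )
        span: dict[str, tuple[int, int]] = {}
        for res in pocket.lining_residues:
            if res.kind != "polymer":
                continue
            lo, hi = span.get(res.chain_id, (res.number, res.number))
            span[res.chain_id] = (min(lo, res.number), max(hi, res.number))
        pocket.span = span
        pocket.apolar_fraction = sum(s.apolar for s in pocket.spheres) / pocket.n_spheres
    return kept


def detect_pockets(
    structure: Structure,
    params: DetectionParams = DetectionParams(),
    include_ligands: bool = False,
) -> list[Pocket]:
    """Full detection: alpha spheres -> clustering -> finalized pockets."""
    spheres = generate_alpha_spheres(structure, params, include_ligands)
    pockets = cluster_spheres(spheres, params.cluster_distance)
    return finalize_pockets(structure, pockets, params)


def pockets_to_table(structure: Structure, pockets: list[Pocket]):
    """Pocket report as a DataFrame (one row per pocket per chain span)."""
    import pandas as pd

    rows = []
    for p in pockets:
        chains = sorted(p.span) or [""]
        for chain_id in chains:
            lo, hi = p.span.get(chain_id, ("", ""))
            rows.append({
                "structure_id": structure.id,
                "pocket_id": p.id,
                "n_spheres": p.n_spheres,
                "mean_radius": round(p.mean_radius, 3),
                "apolar_fraction": round(p.apolar_fraction, 3),
                "chain": chain_id,
                "span_start": lo,
                "span_end": hi,
                "lining_residues": ";".join(
                    f"{r.chain_id}{r.number}{r.icode}" for r in p.lining_residues
                ),
            })
    return pd.DataFrame(rows, columns=[
        "structure_id", "pocket_id", "n_spheres", "mean_radius",
        "apolar_fraction", "chain", "span_start", "span_end", "lining_residues",
    ])
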