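"""Geometry of alpha-sphere detection, checked against independent oracles."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from fapocket import (
    AlphaSphere,
    CageSpec,
    DetectionParams,
    Structure,
    circumsphere,
    cluster_spheres,
    detect_pockets,
    finalize_pockets,
    generate_alpha_spheres,
    make_cage,
)
from fapocket.detect import DegenerateGeometryError
from fapocket.structure import Atom, Chain, Residue


def _structure_from_points(points, element="C"):
    chain = Chain(chain_id="A")
    res = Residue(name="ALA", chain_id="A", number=1)
    for i, p in enumerate(points):
        res.atoms.append(Atom(element=element, name=f"X{i}", coords=np.asarray(p),
                              vdw_radius=1.7))
    chain.residues.append(res)
    return Structure(id="pts", chains=[chain])


class TestCircumsphere:
    def test_regular_tetrahedron_analytic(self):
        center, radius = circumsphere(
            (1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)
        )
        np.testing.assert_allclose(center, [0, 0, 0], atol=1e-12)
        assert radius == pytest.approx(np.sqrt(3), abs=1e-12)

    def test_coplanar_raises(self):
        with pytest.raises(DegenerateGeometryError):
            circumsphere((0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0))

    def test_equidistance_on_random_points(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pts = rng.uniform(-5, 5, size=(4, 3))
            vol = abs(np.linalg.det(pts[:3] - pts[3])) / 6
            if vol < 1e-6:
                continue
            center, radius = circumsphere(*pts)
            for p in pts:
                assert abs(np.linalg.norm(p - center) - radius) < 1e-9


class TestGenerateAlphaSpheres:
    def test_single_tetrahedron_in_band(self):
        # regular tetrahedron with circumradius exactly 5
        base = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], float)
        pts = base * (5.0 / np.sqrt(3))
        st = _structure_from_points(pts)
        spheres = generate_alpha_spheres(st, DetectionParams())
        assert len(spheres) == 1
        assert spheres[0].radius == pytest.approx(5.0, abs=1e-9)
        assert spheres[0].apolar  # all four atoms are carbon

    def test_radius_filter_boundary(self):
        base = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], float)
        pts = base * (5.0 / np.sqrt(3))
        st = _structure_from_points(pts)
        params = DetectionParams(min_alpha_radius=5.5, max_alpha_radius=6.2)
        assert generate_alpha_spheres(st, params) == []

    def test_too_few_atoms_raises(self):
        st = _structure_from_points([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        with pytest.raises(ValueError, match=">= 4"):
            generate_alpha_spheres(st)

    def test_matches_exhaustive_enumeration(self, canonical_cage):
        """Implementation equals brute force over every Delaunay tetrahedron
        with an explicit all-atoms inside-test."""
        params = DetectionParams()
        got = generate_alpha_spheres(canonical_cage, params)
        points = np.array([a.coords for a, _ in canonical_cage.polymer_atoms()])
        tri = Delaunay(points)
        expected = []
        for simplex in tri.simplices:
            p = points[simplex]
            try:
                center, radius = circumsphere(*p)
            except DegenerateGeometryError:
                continue
            if not params.min_alpha_radius <= radius <= params.max_alpha_radius:
                continue
            dists = np.linalg.norm(points - center, axis=1)
            if (dists < radius - 1e-6).any():
                continue
            expected.append((tuple(np.round(center, 6)), round(radius, 6)))
        got_set = {(tuple(np.round(s.center, 6)), round(s.radius, 6)) for s in got}
        assert got_set == set(expected)

    def test_soundness_no_atom_strictly_inside(self, canonical_cage):
        points = np.array([a.coords for a, _ in canonical_cage.polymer_atoms()])
        for s in generate_alpha_spheres(canonical_cage):
            dists = np.linalg.norm(points - s.center, axis=1)
            assert not (dists < s.radius - 1e-6).any()

    def test_min_radius_monotonicity(self, canonical_cage):
        counts = []
        for lo in (4.0, 4.5, 5.0, 5.5):
            params = DetectionParams(min_alpha_radius=lo)
            counts.append(len(generate_alpha_spheres(canonical_cage, params)))
        assert counts == sorted(counts, reverse=True)


def _dummy_spheres(centers, radius=5.0):
    return [AlphaSphere(center=np.asarray(c, float), radius=radius,
                        defining_atoms=(), apolar=True) for c in centers]


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


class TestClusterSpheres:
    def test_edge_within_distance_merges(self):
        pockets = cluster_spheres(_dummy_spheres([(0, 0, 0), (5, 0, 0)]), 6.0)
        assert len(pockets) == 1

    def test_beyond_distance_splits(self):
        pockets = cluster_spheres(_dummy_spheres([(0, 0, 0), (7, 0, 0)]), 6.0)
        assert len(pockets) == 2

    def test_empty_input(self):
        assert cluster_spheres([], 6.0) == []

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(5)
        centers = rng.uniform(0, 30, size=(50, 3))
        spheres = _dummy_spheres(centers)
        pockets = cluster_spheres(spheres, 6.0)
        uf = _UnionFind(50)
        for i in range(50):
            for j in range(i + 1, 50):
                if np.linalg.norm(centers[i] - centers[j]) <= 6.0:
                    uf.union(i, j)
        oracle = {}
        for i in range(50):
            oracle.setdefault(uf.find(i), set()).add(tuple(np.round(centers[i], 6)))
        got = {
            frozenset(tuple(np.round(s.center, 6)) for s in p.spheres)
            for p in pockets
        }
        assert got == {frozenset(v) for v in oracle.values()}

    def test_ranking_by_size(self):
        centers = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (100, 0, 0)]
        pockets = cluster_spheres(_dummy_spheres(centers), 6.0)
        assert [p.n_spheres for p in pockets] == [3, 1]
        assert pockets[0].id == 1

    def test_cluster_distance_monotonicity(self, canonical_cage):
        spheres = generate_alpha_spheres(canonical_cage)
        counts = [len(cluster_spheres(spheres, d)) for d in (3.0, 6.0, 9.0, 12.0)]
        assert counts == sorted(counts, reverse=True)


class TestFinalizePockets:
    def test_small_pockets_dropped(self):
        pockets = cluster_spheres(_dummy_spheres([(0, 0, 0), (1, 0, 0)]), 6.0)
        st = _structure_from_points([(0, 0, 10)] * 4)
        assert finalize_pockets(st, pockets, DetectionParams()) == []

    def test_span_from_author_numbers(self):
        """Lining span is reported as (min, max) author residue numbers."""
        chain = Chain(chain_id="A")
        atoms_per_res = {}
        for num in (281, 350, 434):
            res = Residue(name="LEU", chain_id="A", number=num)
            res.atoms.append(Atom(element="C", name="CA",
                                  coords=np.array([float(num), 0, 0])))
            chain.residues.append(res)
            atoms_per_res[num] = (res.atoms[0], res)
        st = Structure(id="span", chains=[chain])
        sphere = AlphaSphere(
            center=np.zeros(3), radius=5.0,
            defining_atoms=(atoms_per_res[281], atoms_per_res[350],
                            atoms_per_res[434], atoms_per_res[281]),
            apolar=True,
        )
        pocket_list = cluster_spheres([sphere] * 15, 6.0)
        out = finalize_pockets(st, pocket_list, DetectionParams())
        assert out[0].span == {"A": (281, 434)}

    def test_all_carbon_cage_fully_apolar(self, canonical_pockets):
        for p in canonical_pockets:
            assert p.apolar_fraction == 1.0

    def test_lining_residues_are_union_of_defining(self, canonical_pockets):
        for p in canonical_pockets:
            expected = {res.key for s in p.spheres for _a, res in s.defining_atoms}
            assert {r.key for r in p.lining_residues} == expected


class TestDeterminismAndRecovery:
    def test_atom_order_invariance(self, canonical_cage):
        import copy

        shuffled = copy.deepcopy(canonical_cage)
        rng = np.random.default_rng(9)
        allres = [r for c in shuffled.chains for r in c.residues]
        rng.shuffle(allres)
        shuffled.chains[0].residues = allres
        a = detect_pockets(canonical_cage)
        b = detect_pockets(shuffled)
        key = lambda ps: [
            frozenset(tuple(np.round(s.center, 6)) for s in p.spheres) for p in ps
        ]
        assert key(a) == key(b)

    @pytest.mark.parametrize("cavity_radius,seed", [(4.5, 21), (5.0, 22), (6.0, 23)])
    def test_cavity_recovery(self, cavity_radius, seed):
        """The top-ranked pocket centroid lands near the built-in cavity."""
        cage = make_cage(CageSpec(
            n_shell_atoms=200, shell_radius=9.0, cavity_radius=cavity_radius,
            mouth_half_angle=15.0, element_mix=(("C", 1.0),), seed=seed,
        ))
        pockets = detect_pockets(cage)
        assert pockets
        assert np.linalg.norm(pockets[0].centroid()) <= 2.0
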