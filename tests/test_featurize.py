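import itertools

import numpy as np
import pytest

import gpd
from gpd.featurize import (PATH_CAP, ContactGraph, assemble_graph_features,
                           backbone_dihedrals, betweenness_centrality,
                           contact_graph, distance_map, movement_vectors,
                           rotation_quaternions, secondary_structure_8class,
                           shortest_path_matrix)
from gpd.fixtures import GeometrySpec, build_backbone_from_dihedrals
from gpd.structure_io import residue_frames


# ----------------------------------------------------------------------
# dihedrals
# ----------------------------------------------------------------------

class TestDihedrals:
    def test_ideal_helix_round_trip(self):
        b = gpd.helix_backbone(20)
        phi, psi, _ = backbone_dihedrals(b)
        np.testing.assert_allclose(phi[1:], np.deg2rad(-57.0), atol=1e-6)
        np.testing.assert_allclose(psi[:-1], np.deg2rad(-47.0), atol=1e-6)

    def test_terminal_sentinel_encoding(self, helix):
        phi, psi, enc = backbone_dihedrals(helix)
        assert np.isnan(phi[0]) and np.isnan(psi[-1])
        np.testing.assert_array_equal(enc[0, :2], [0.0, 0.0])
        np.testing.assert_array_equal(enc[-1, 2:], [0.0, 0.0])
        # interior encodings lie on the unit circle
        interior = enc[1:-1]
        np.testing.assert_allclose(interior[:, 0]**2 + interior[:, 1]**2,
                                   1.0, atol=1e-12)

    def test_rigid_invariance(self, helix, rigid_transforms):
        phi0, psi0, _ = backbone_dihedrals(helix)
        R, t = rigid_transforms[0]
        phi1, psi1, _ = backbone_dihedrals(helix.transformed(R, t))
        np.testing.assert_allclose(phi1[1:], phi0[1:], atol=1e-9)
        np.testing.assert_allclose(psi1[:-1], psi0[:-1], atol=1e-9)


# ----------------------------------------------------------------------
# secondary structure vs a reference DSSP (mdtraj)
# ----------------------------------------------------------------------

def _as_mdtraj(b):
    md = pytest.importorskip("mdtraj")
    top = md.Topology()
    ch = top.add_chain()
    xyz = []
    for i in range(len(b)):
        res = top.add_residue(b.residue_names[i], ch)
        for name, el, coord in (("N", "N", b.coords_N[i]),
                                ("CA", "C", b.coords_CA[i]),
                                ("C", "C", b.coords_C[i]),
                                ("O", "O", b.coords_O[i])):
            top.add_atom(name, md.element.get_by_symbol(el), res)
            xyz.append(coord / 10.0)       # Å -> nm
    return md.Trajectory(np.array(xyz)[None], top)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_H_and_matches_reference(self):
        import mdtraj as md
        b = gpd.helix_backbone(20)
        mine = secondary_structure_8class(b)
        ref = md.compute_dssp(_as_mdtraj(b), simplified=False)[0]
        ref = ["L" if c in (" ", "C", "") else c for c in ref]
        assert all(c == "H" for c in mine[3:-3])
        assert mine[3:-3] == ref[3:-3]

    def test_short_peptide_all_loop(self):
        spec = GeometrySpec(np.full(4, -1.0), np.full(4, -0.8))
        b = build_backbone_from_dihedrals(spec)
        assert secondary_structure_8class(b) == ["L"] * 4

    def test_isolated_extended_strand_has_no_E(self):
        import mdtraj as md
        spec = GeometrySpec(np.full(12, np.deg2rad(-139.0)),
                            np.full(12, np.deg2rad(135.0)))
        b = build_backbone_from_dihedrals(spec)
        mine = secondary_structure_8class(b)
        assert "E" not in mine
        ref = md.compute_dssp(_as_mdtraj(b), simplified=False)[0]
        assert "E" not in ref


# ----------------------------------------------------------------------
# contact graph, centrality, shortest paths
# ----------------------------------------------------------------------

def _graph_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return ContactGraph(n_nodes=n, adjacency=adj)


def _brute_force_betweenness(g):
    """Enumerate all shortest paths between every unordered pair."""
    n = g.n_nodes
    adj = g.adjacency
    result = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        # BFS collecting all shortest s-t paths
        paths, frontier = [], [[s]]
        found = False
        while frontier and not found:
            nxt = []
            for p in frontier:
                for v in np.nonzero(adj[p[-1]])[0]:
                    if v in p:
                        continue
                    q = p + [int(v)]
                    if v == t:
                        paths.append(q)
                        found = True
                    else:
                        nxt.append(q)
            frontier = nxt
        if not paths:
            continue
        for k in range(n):
            if k in (s, t):
                continue
            through = sum(1 for p in paths if k in p[1:-1])
            result[k] += through / len(paths)
    return result


class TestContactGraph:
    def test_cutoff_boundary(self):
        for d, expect in ((11.9, True), (12.1, False)):
            b = gpd.BackboneStructure(
                chain_id="A", residue_numbers=np.array([1, 2]),
                residue_names=["GLY", "GLY"],
                coords_N=np.array([[-1.2, 0.9, 0], [d - 1.2, 0.9, 0]]),
                coords_CA=np.array([[0.0, 0, 0], [d, 0, 0]]),
                coords_C=np.array([[1.5, 0, 0], [d + 1.5, 0, 0]]),
                coords_O=np.full((2, 3), np.nan),
            )
            assert contact_graph(b).adjacency[0, 1] == expect

    def test_consecutive_residues_always_adjacent(self, toy_dataset):
        b = toy_dataset[0][0]
        adj = contact_graph(b).adjacency
        assert all(adj[i, i + 1] for i in range(len(b) - 1))

    def test_invalid_cutoff(self, helix):
        with pytest.raises(ValueError):
            contact_graph(helix, cutoff=0.0)


class TestBetweenness:
    def test_path_graph(self):
        g = _graph_from_edges(3, [(0, 1), (1, 2)])
        np.testing.assert_allclose(betweenness_centrality(g), [0, 1, 0])

    def test_complete_graph_all_zero(self):
        g = _graph_from_edges(4, list(itertools.combinations(range(4), 2)))
        np.testing.assert_allclose(betweenness_centrality(g), 0.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            n = int(rng.integers(3, 9))
            g = gpd.random_graph(n, float(rng.uniform(0.2, 0.9)), seed=trial)
            np.testing.assert_allclose(betweenness_centrality(g),
                                       _brute_force_betweenness(g),
                                       atol=1e-12)


class TestShortestPaths:
    def test_path_graph_distance(self):
        g = _graph_from_edges(3, [(0, 1), (1, 2)])
        assert shortest_path_matrix(g)[0, 2] == 2

    def test_disconnected_pair_gets_cap(self):
        g = _graph_from_edges(2, [])
        assert shortest_path_matrix(g)[0, 1] == PATH_CAP
        assert shortest_path_matrix(g, cap=7)[0, 1] == 7

    def test_matches_bfs_oracle(self):
        import collections
        rng = np.random.default_rng(1)
        for trial in range(50):
            n = int(rng.integers(3, 13))
            g = gpd.random_graph(n, float(rng.uniform(0.1, 0.8)),
                                 seed=1000 + trial)
            d = shortest_path_matrix(g)
            for s in range(n):
                dist = {s: 0}
                dq = collections.deque([s])
                while dq:
                    u = dq.popleft()
                    for v in np.nonzero(g.adjacency[u])[0]:
                        if v not in dist:
                            dist[int(v)] = dist[u] + 1
                            dq.append(int(v))
                for t in range(n):
                    assert d[s, t] == dist.get(t, PATH_CAP)


# ----------------------------------------------------------------------
# geometric edge features
# ----------------------------------------------------------------------

class TestDistanceMap:
    def test_closed_form_and_symmetry(self, toy_dataset):
        b = toy_dataset[0][0]
        d = distance_map(b)
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.all(np.diag(d) == 0)
        i, j = 3, 17
        np.testing.assert_allclose(
            d[i, j], np.linalg.norm(b.coords_CA[i] - b.coords_CA[j]))


class TestMovementVectors:
    def test_constructed_direction(self, helix):
        frames = residue_frames(helix)
        b = helix
        # place CA_j along the first frame axis of residue 0
        coords = b.coords_CA.copy()
        coords[5] = coords[0] + 5.0 * frames[0].axes[:, 0]
        b2 = gpd.BackboneStructure(
            chain_id="A", residue_numbers=b.residue_numbers,
            residue_names=list(b.residue_names), coords_N=b.coords_N,
            coords_CA=coords, coords_C=b.coords_C, coords_O=b.coords_O)
        vm = movement_vectors(b2, frames)
        np.testing.assert_allclose(vm[0, 5], [1, 0, 0], atol=1e-9)

    def test_unit_norm_and_rigid_invariance(self, helix, rigid_transforms):
        vm0 = movement_vectors(helix, residue_frames(helix))
        off = ~np.eye(len(helix), dtype=bool)
        np.testing.assert_allclose(
            np.linalg.norm(vm0[off], axis=-1), 1.0, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(vm0[~off], axis=-1), 0.0)
        R, t = rigid_transforms[1]
        moved = helix.transformed(R, t)
        vm1 = movement_vectors(moved, residue_frames(moved))
        np.testing.assert_allclose(vm1, vm0, atol=1e-6)


class TestRotationQuaternions:
    def test_diagonal_is_identity(self, helix):
        q = rotation_quaternions(residue_frames(helix))
        np.testing.assert_allclose(q[np.arange(len(helix)),
                                     np.arange(len(helix))],
                                   [[1, 0, 0, 0]] * len(helix), atol=1e-12)

    def test_round_trip_to_rotation_matrix(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(4)
        mats = Rotation.random(20, rng=rng).as_matrix()
        frames = [gpd.ResidueFrame(origin=np.zeros(3), axes=m) for m in mats]
        q = rotation_quaternions(frames)
        for i in range(20):
            for j in range(20):
                back = Rotation.from_quat(
                    np.r_[q[i, j, 1:], q[i, j, 0]]).as_matrix()
                np.testing.assert_allclose(
                    back, frames[i].axes.T @ frames[j].axes, atol=1e-8)
        # canonical sign and unit norm
        assert np.all(q[..., 0] >= 0)
        np.testing.assert_allclose(np.linalg.norm(q, axis=-1), 1.0, atol=1e-12)

    def test_non_orthonormal_frame_rejected(self):
        bad = gpd.ResidueFrame(origin=np.zeros(3), axes=np.eye(3) * 2.0)
        with pytest.raises(ValueError, match="orthonormal"):
            rotation_quaternions([bad])


# ----------------------------------------------------------------------
# assembly
# ----------------------------------------------------------------------

class TestAssembly:
    def test_stated_block_arithmetic(self, toy_dataset):
        b = toy_dataset[0][0]
        sub = gpd.BackboneStructure(
            chain_id="A", residue_numbers=b.residue_numbers[:10],
            residue_names=list(b.residue_names[:10]),
            coords_N=b.coords_N[:10], coords_CA=b.coords_CA[:10],
            coords_C=b.coords_C[:10], coords_O=b.coords_O[:10])
        gf = assemble_graph_features(sub, d_noise=16)
        assert gf.nodes.shape == (10, 51)
        assert gf.edges.shape == (10, 10, 9)

    def test_same_seed_reproduces_noise(self, helix):
        a = assemble_graph_features(helix, rng_seed=5)
        b = assemble_graph_features(helix, rng_seed=5)
        np.testing.assert_array_equal(a.nodes, b.nodes)

    def test_no_constraints_means_zero_predesign(self, helix):
        gf = assemble_graph_features(helix)
        np.testing.assert_array_equal(gf.nodes[:, gf.predesign_slice], 0.0)

    def test_constraint_encoding_and_errors(self, helix):
        gf = assemble_graph_features(helix, predesign={3: "W"})
        block = gf.nodes[:, gf.predesign_slice]
        assert block[3].sum() == 1.0 and block[3, 18] == 1.0
        with pytest.raises(ValueError, match="illegal"):
            assemble_graph_features(helix, predesign={0: "B"})
        with pytest.raises(IndexError):
            assemble_graph_features(helix, predesign={99: "A"})

    def test_centrality_depends_only_on_adjacency(self):
        # permuting coordinates rigidly leaves graph features unchanged
        g = gpd.random_graph(8, 0.5, seed=2)
        c0 = betweenness_centrality(g)
        c1 = betweenness_centrality(
            ContactGraph(n_nodes=8, adjacency=g.adjacency.copy()))
        np.testing.assert_array_equal(c0, c1)
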