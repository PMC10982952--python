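"""SE(3)-invariant graph featurization of a protein backbone.

A chain becomes a graph: one node per residue, edges between residue pairs
whose CA atoms lie within a distance cutoff (12 Å by default).

Node features (per residue):
  * backbone dihedrals phi/psi encoded as (sin, cos) pairs — 4 values,
    with the (0, 0) sentinel at undefined chain termini;
  * 8-class secondary structure (internal Kabsch–Sander/DSSP assignment);
  * betweenness centrality on the contact graph (unnormalized);
  * a 22-token pre-designed-sequence slot (20 amino acids + unknown +
    padding), all-zeros where no residue is constrained;
  * a standard-normal noise block of width ``d_noise`` that widens the
    designed sequence space (zeros when disabled).

Edge features (per ordered residue pair):
  * CA–CA distance (Å);
  * the movement vector: the unit CA(i)->CA(j) direction expressed in
    residue i's local frame;
  * the quaternion of the relative rotation O_i^T O_j between the two
    residue frames (canonical sign, scalar part >= 0);
  * shortest-path length on the contact graph (hop count, capped).

All exported features are invariant under rigid motion of the coordinates
because the per-residue frames are equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.spatial.distance import cdist
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path
from scipy.spatial.transform import Rotation

from .structure_io import (AA_TO_INDEX, VOCAB_SIZE, BackboneStructure,
                           residue_frames)

# Node/edge feature block widths (noise width is a parameter).
DIHEDRAL_DIM = 4
SS_DIM = 8
CENTRALITY_DIM = 1
PREDESIGN_DIM = VOCAB_SIZE
EDGE_DIM = 9            # distance 1 + movement 3 + quaternion 4 + path 1
DEFAULT_D_NOISE = 16
DEFAULT_CUTOFF = 12.0
PATH_CAP = 32           # sentinel hop count for unreachable pairs

SS_CLASSES = ("H", "G", "I", "T", "E", "B", "S", "L")
SS_TO_INDEX = {c: i for i, c in enumerate(SS_CLASSES)}


@dataclass
class ContactGraph:
    """Symmetric, loop-free residue contact graph."""

    n_nodes: int
    adjacency: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool).copy()
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(zip(*np.nonzero(np.triu(self.adjacency))))
        return g


@dataclass
class GraphFeatures:
    """Assembled model input: node matrix, edge tensor, validity mask."""

    nodes: np.ndarray        # (N, d_node_in)
    edges: np.ndarray        # (N, N, EDGE_DIM)
    mask: np.ndarray         # (N,) bool
    d_noise: int

    # Column layout of the node matrix (start offsets).
    @property
    def predesign_slice(self) -> slice:
        start = DIHEDRAL_DIM + SS_DIM + CENTRALITY_DIM
        return slice(start, start + PREDESIGN_DIM)

    @property
    def noise_slice(self) -> slice:
        start = DIHEDRAL_DIM + SS_DIM + CENTRALITY_DIM + PREDESIGN_DIM
        return slice(start, start + self.d_noise)

    def set_predesign(self, tokens) -> None:
        """Overwrite the pre-designed-sequence block.

        ``tokens`` maps position -> vocabulary index (or None to clear all
        positions to the all-zeros 'no constraint' state).
        """
        block = self.nodes[:, self.predesign_slice]
        block[:] = 0.0
        if tokens:
            for pos, tok in tokens.items():
                if not (0 <= pos < self.nodes.shape[0]):
                    raise IndexError(f"predesign position {pos} out of range")
                block[pos, tok] = 1.0

    def set_noise(self, rng=None) -> None:
        """Resample (or zero, if rng is None) the noise block."""
        block = self.nodes[:, self.noise_slice]
        if rng is None:
            block[:] = 0.0
        else:
            block[:] = rng.standard_normal(block.shape)


# --------------------------------------------------------------------------
# dihedrals
# --------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3):
    """Torsion angle (radians) of four points, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return np.arctan2(np.cross(b1, v) @ w, v @ w)


def backbone_dihedrals(b: BackboneStructure):
    """Per-residue (phi, psi) and their sin/cos encoding.

    phi(i) uses C(i-1)-N(i)-CA(i)-C(i); psi(i) uses N(i)-CA(i)-C(i)-N(i+1).
    Undefined terminal angles are NaN and encode as the (0, 0) sentinel,
    which no real angle can produce.
    """
    n = len(b)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    if n < 2:
        import warnings
        warnings.warn("single-residue chain: all dihedrals undefined")
    for i in range(n):
        if i > 0:
            phi[i] = _dihedral(b.coords_C[i - 1], b.coords_N[i],
                               b.coords_CA[i], b.coords_C[i])
        if i < n - 1:
            psi[i] = _dihedral(b.coords_N[i], b.coords_CA[i],
                               b.coords_C[i], b.coords_N[i + 1])
    enc = np.zeros((n, 4))
    for k, ang in enumerate((phi, psi)):
        defined = ~np.isnan(ang)
        enc[defined, 2 * k] = np.sin(ang[defined])
        enc[defined, 2 * k + 1] = np.cos(ang[defined])
    return phi, psi, enc


# --------------------------------------------------------------------------
# secondary structure (internal Kabsch–Sander / DSSP)
# --------------------------------------------------------------------------

_KS_Q1Q2_F = 0.084 * 332.0   # kcal/mol coupling of the electrostatic model
_HBOND_CUTOFF = -0.5         # kcal/mol


def _amide_hydrogens(b: BackboneStructure) -> np.ndarray:
    """Place amide H 1.0 Å from N opposite the previous carbonyl O.

    The first residue (and proline, which has no amide H) get NaN.
    """
    n = len(b)
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if b.residue_names[i] == "PRO":
            continue
        co = b.coords_C[i - 1] - b.coords_O[i - 1]
        norm = np.linalg.norm(co)
        if norm < 1e-8 or not np.all(np.isfinite(co)):
            continue
        H[i] = b.coords_N[i] + co / norm
    return H


def _ks_hbonds(b: BackboneStructure) -> np.ndarray:
    """hb[d, a] = True if the N-H of residue d donates to the C=O of a.

    Kabsch–Sander electrostatic energy
    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) < -0.5 kcal/mol.
    Missing carbonyl O atoms are rebuilt in the peptide plane.
    """
    n = len(b)
    O = b.coords_O.copy()
    for i in np.nonzero(b.missing_O)[0]:
        # virtual O: opposite the N(i+1) direction in the peptide plane
        if i + 1 < n:
            direction = b.coords_C[i] - 0.5 * (b.coords_CA[i] + b.coords_N[i + 1])
        else:
            direction = b.coords_C[i] - b.coords_CA[i]
        direction /= np.linalg.norm(direction)
        O[i] = b.coords_C[i] + 1.231 * direction
    H = _amide_hydrogens(b)
    hb = np.zeros((n, n), dtype=bool)
    for d in range(n):
        if np.any(np.isnan(H[d])):
            continue
        for a in range(n):
            if abs(d - a) < 2:      # no bonds within a residue or neighbors
                continue
            r_on = np.linalg.norm(O[a] - b.coords_N[d])
            r_ch = np.linalg.norm(b.coords_C[a] - H[d])
            r_oh = np.linalg.norm(O[a] - H[d])
            r_cn = np.linalg.norm(b.coords_C[a] - b.coords_N[d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                energy = -9.9       # clashing atoms: treat as bonded (DSSP)
            else:
                energy = _KS_Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            hb[d, a] = energy < _HBOND_CUTOFF
    return hb


def secondary_structure_8class(b: BackboneStructure) -> list:
    """DSSP-style 8-class assignment: H, G, I, T, E, B, S, L(oop).

    Pattern rules over Kabsch–Sander hydrogen bonds: two consecutive
    n-turns make a minimal helix (n=4 -> H, 3 -> G, 5 -> I); parallel or
    antiparallel bridges make B, extended ladders make E; remaining n-turn
    spans make T; a CA pseudo-angle above 70° makes a bend S.  Unassigned
    residues are loop.  Degenerate inputs yield all loop.
    """
    n = len(b)
    if n < 3:
        return ["L"] * n
    try:
        hb = _ks_hbonds(b)
    except (ValueError, FloatingPointError):
        return ["L"] * n

    # acceptor(i) -> donor(i+k): n-turn of length k at i
    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            turn[k][i] = hb[i + k, i]

    def _hb(a, d):
        """CO of a accepts from NH of d (guarding the index range)."""
        return 0 <= a < n and 0 <= d < n and hb[d, a]

    bridge = np.zeros((n, n), dtype=np.int8)     # 1 parallel, -1 antiparallel
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (_hb(i - 1, j) and _hb(j, i + 1)) or \
                   (_hb(j - 1, i) and _hb(i, j + 1))
            anti = (_hb(i, j) and _hb(j, i)) or \
                   (_hb(i - 1, j + 1) and _hb(j - 1, i + 1))
            if para:
                bridge[i, j] = bridge[j, i] = 1
            elif anti:
                bridge[i, j] = bridge[j, i] = -1

    ss = np.array(["L"] * n, dtype="U1")

    # bends (lowest priority, assigned first and overwritten later)
    ca = b.coords_CA
    for i in range(2, n - 2):
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            ss[i] = "S"

    # turns
    for k in (3, 4, 5):
        for i in range(n - k):
            if turn[k][i]:
                ss[i + 1:i + k] = "T"

    # pi then 3-10 then strands then alpha (alpha has top priority)
    for k, label in ((5, "I"), (3, "G")):
        for i in range(1, n - k):
            if turn[k][i - 1] and turn[k][i]:
                ss[i:i + k] = label

    # bridges and ladders
    in_ladder = np.zeros(n, dtype=bool)
    pairs = [(i, j) for i in range(n) for j in range(i + 3, n) if bridge[i, j]]
    for (i, j) in pairs:
        extended = any(
            bridge[i + di, j + dj] == bridge[i, j]
            for di in (-1, 1) for dj in (-1, 1)
            if 0 <= i + di < n and 0 <= j + dj < n)
        if extended:
            in_ladder[i] = in_ladder[j] = True
    for (i, j) in pairs:
        for k in (i, j):
            ss[k] = "E" if in_ladder[k] else ("B" if ss[k] not in ("E",) else ss[k])

    for i in range(1, n - 4):
        if turn[4][i - 1] and turn[4][i]:
            ss[i:i + 4] = "H"

    return list(ss)


# --------------------------------------------------------------------------
# contact graph and graph features
# --------------------------------------------------------------------------

def distance_map(b: BackboneStructure) -> np.ndarray:
    """Pairwise CA–CA Euclidean distances (Å)."""
    return cdist(b.coords_CA, b.coords_CA)


def contact_graph(b: BackboneStructure, cutoff: float = DEFAULT_CUTOFF) -> ContactGraph:
    """Residues are in contact when their CA atoms are within ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(b) < 2:
        raise ValueError("need at least 2 residues")
    d = distance_map(b)
    adj = d <= cutoff
    np.fill_diagonal(adj, False)
    return ContactGraph(n_nodes=len(b), adjacency=adj)


def betweenness_centrality(g: ContactGraph) -> np.ndarray:
    """Unnormalized betweenness over unordered node pairs.

    C_b(k) = sum over pairs i<j (i,j != k) of the fraction of i-j shortest
    paths passing through k.  Isolated nodes score 0.
    """
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return np.array([bc[i] for i in range(g.n_nodes)])


def shortest_path_matrix(g: ContactGraph, cap: int = PATH_CAP) -> np.ndarray:
    """Unweighted hop counts; unreachable pairs get the ``cap`` sentinel."""
    d = _csgraph_shortest_path(g.adjacency.astype(np.int8), method="D",
                               unweighted=True)
    d[np.isinf(d)] = cap
    d = np.minimum(d, cap)
    return d.astype(int)


def movement_vectors(b: BackboneStructure, frames) -> np.ndarray:
    """v_m(i, j) = O_i^T (CA_j - CA_i) / ||CA_j - CA_i||.

    The unit inter-residue direction expressed in residue i's local frame;
    zero on the diagonal.  Invariant under rigid motion.
    """
    n = len(b)
    ca = b.coords_CA
    diff = ca[None, :, :] - ca[:, None, :]          # (i, j, 3) = CA_j - CA_i
    norm = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(norm[off] < 1e-8):
        raise ValueError("coincident CA positions")
    unit = np.zeros_like(diff)
    unit[off] = diff[off] / norm[off][:, None]
    axes = np.stack([f.axes for f in frames])        # (N, 3, 3)
    return np.einsum("iab,ija->ijb", axes, unit)


def rotation_quaternions(frames) -> np.ndarray:
    """Unit quaternion (scalar-first, scalar >= 0) of O_i^T O_j per pair."""
    axes = np.stack([f.axes for f in frames])
    for k, O in enumerate(axes):
        if not np.allclose(O @ O.T, np.eye(3), atol=1e-6):
            raise ValueError(f"frame {k} is not orthonormal")
    n = len(frames)
    rel = np.einsum("iba,jbc->ijac", axes, axes)     # O_i^T O_j
    q_xyzw = Rotation.from_matrix(rel.reshape(-1, 3, 3)).as_quat()
    q = np.concatenate([q_xyzw[:, 3:4], q_xyzw[:, :3]], axis=1)
    flip = q[:, 0] < 0
    q[flip] *= -1.0
    return q.reshape(n, n, 4)


def assemble_graph_features(b: BackboneStructure,
                            predesign: dict | None = None,
                            rng_seed: int = 0,
                            d_noise: int = DEFAULT_D_NOISE,
                            noise_enabled: bool = True,
                            cutoff: float = DEFAULT_CUTOFF,
                            path_cap: int = PATH_CAP) -> GraphFeatures:
    """Build the full model input for one backbone.

    ``predesign`` maps 0-based positions to amino-acid letters; positions
    without a constraint keep the all-zeros pre-design block.  The noise
    block is standard normal from ``rng_seed`` (zeros when disabled).
    """
    n = len(b)
    _, _, dihedral_enc = backbone_dihedrals(b)
    ss = secondary_structure_8class(b)
    ss_onehot = np.zeros((n, SS_DIM))
    for i, c in enumerate(ss):
        ss_onehot[i, SS_TO_INDEX[c]] = 1.0
    g = contact_graph(b, cutoff)
    centrality = betweenness_centrality(g)[:, None]

    predesign_block = np.zeros((n, PREDESIGN_DIM))
    if predesign:
        for pos, letter in predesign.items():
            if not (0 <= pos < n):
                raise IndexError(f"constraint position {pos} out of range")
            if letter not in AA_TO_INDEX:
                raise ValueError(f"illegal residue letter {letter!r}")
            predesign_block[pos, AA_TO_INDEX[letter]] = 1.0

    noise = np.zeros((n, d_noise))
    if noise_enabled and d_noise > 0:
        noise = np.random.default_rng(rng_seed).standard_normal((n, d_noise))

    nodes = np.concatenate(
        [dihedral_enc, ss_onehot, centrality, predesign_block, noise], axis=1)

    frames = residue_frames(b)
    dmap = distance_map(b)[:, :, None]
    vm = movement_vectors(b, frames)
    quat = rotation_quaternions(frames)
    paths = shortest_path_matrix(g, cap=path_cap)[:, :, None].astype(float)
    edges = np.concatenate([dmap, vm, quat, paths], axis=2)

    return GraphFeatures(nodes=nodes, edges=edges,
                         mask=np.ones(n, dtype=bool), d_noise=d_noise)
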