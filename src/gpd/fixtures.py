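"""Synthetic backbone and data generators.

Everything here is a pure function of its arguments and seed, so the rest of
the package can be exercised without downloading structures:

* :func:`build_backbone_from_dihedrals` grows an ideal-geometry chain from
  (phi, psi, omega) by sequential internal-coordinate placement (NeRF).
* :func:`make_toy_dataset` emits small helix/loop proteins whose sequences
  are deterministically correlated with local structure, so a small model
  can learn an above-chance structure->sequence mapping.
* :func:`random_graph`, :func:`perturb_rigid` and :func:`synthetic_ensemble`
  support the graph-feature oracles, rigid-invariance suites and dynamic
  cross-correlation tests.

Ideal peptide stereochemistry used throughout (standard values):
bond lengths N-CA 1.458 Å, CA-C 1.525 Å, C-N 1.329 Å, C=O 1.231 Å;
bond angles N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°, CA-C-O 120.8°.
The carbonyl O lies in the peptide plane, trans to the next amide N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import BackboneStructure, ONE_TO_THREE

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = np.deg2rad(111.2)
ANGLE_CA_C_N = np.deg2rad(116.2)
ANGLE_C_N_CA = np.deg2rad(121.7)
ANGLE_CA_C_O = np.deg2rad(120.8)

ALPHA_HELIX = (np.deg2rad(-57.0), np.deg2rad(-47.0))
BETA_STRAND = (np.deg2rad(-139.0), np.deg2rad(135.0))

# Residue pools for the toy structure->sequence signal: helix-former letters
# in helical segments, turn/loop-former letters elsewhere (disjoint pools).
HELIX_LETTERS = "ALEKMQIF"
LOOP_LETTERS = "GPSN"


@dataclass
class GeometrySpec:
    """Per-residue torsions (radians) for an ideal-geometry chain."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray = None

    def __post_init__(self):
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        if self.omega is None:
            self.omega = np.full_like(self.phi, np.pi)
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        n = len(self.phi)
        if n < 2:
            raise ValueError("a chain needs at least 2 residues")
        if len(self.psi) != n or len(self.omega) != n:
            raise ValueError("phi, psi, omega must have equal length")
        if not (np.all(np.isfinite(self.phi)) and np.all(np.isfinite(self.psi))
                and np.all(np.isfinite(self.omega))):
            raise ValueError("torsions must be finite")

    def __len__(self):
        return len(self.phi)


def _place_atom(a, b, c, bond, angle, torsion):
    """NeRF: position atom d given predecessors a-b-c, the c-d bond length,
    the b-c-d angle and the a-b-c-d torsion."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone_from_dihedrals(spec: GeometrySpec,
                                  sequence: str | None = None,
                                  chain_id: str = "A") -> BackboneStructure:
    """Grow an ideal-geometry backbone realizing the given torsions.

    phi[0] and psi[-1] do not influence the heavy-atom trace (they would
    need atoms beyond the termini); a virtual next-residue N is used to
    place the final carbonyl O.
    """
    n = len(spec)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))

    # First residue in a canonical pose.
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    C[0] = CA[0] + BOND_CA_C * np.array(
        [-np.cos(ANGLE_N_CA_C), np.sin(ANGLE_N_CA_C), 0.0])

    for i in range(n - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i],
                               BOND_C_N, ANGLE_CA_C_N, spec.psi[i])
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1],
                                BOND_N_CA, ANGLE_C_N_CA, spec.omega[i])
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1],
                               BOND_CA_C, ANGLE_N_CA_C, spec.phi[i + 1])
        # Carbonyl O of residue i: peptide plane, trans to N(i+1).
        O[i] = _place_atom(N[i], CA[i], C[i],
                           BOND_C_O, ANGLE_CA_C_O, spec.psi[i] + np.pi)
    virtual_n = _place_atom(N[n - 1], CA[n - 1], C[n - 1],
                            BOND_C_N, ANGLE_CA_C_N, spec.psi[n - 1])
    O[n - 1] = _place_atom(N[n - 1], CA[n - 1], C[n - 1],
                           BOND_C_O, ANGLE_CA_C_O, spec.psi[n - 1] + np.pi)
    del virtual_n

    if sequence is None:
        names = ["GLY"] * n
    else:
        if len(sequence) != n:
            raise ValueError("sequence length must match spec length")
        names = [ONE_TO_THREE[a] for a in sequence]
    return BackboneStructure(
        chain_id=chain_id,
        residue_numbers=np.arange(1, n + 1),
        residue_names=names,
        coords_N=N, coords_CA=CA, coords_C=C, coords_O=O,
    )


def helix_backbone(n_residues: int = 20, sequence: str | None = None) -> BackboneStructure:
    """Ideal alpha-helix (phi=-57°, psi=-47°)."""
    phi = np.full(n_residues, ALPHA_HELIX[0])
    psi = np.full(n_residues, ALPHA_HELIX[1])
    return build_backbone_from_dihedrals(GeometrySpec(phi, psi), sequence)


def _segment_layout(length, rng):
    """Alternating helix/loop segment labels for one protein."""
    labels = np.empty(length, dtype="U1")
    pos = 0
    kind = "H" if rng.random() < 0.7 else "L"
    while pos < length:
        seg = rng.integers(6, 12) if kind == "H" else rng.integers(3, 6)
        labels[pos:pos + seg] = kind
        pos += seg
        kind = "L" if kind == "H" else "H"
    return labels


def make_toy_dataset(n_proteins: int, length: int, seed: int) -> list:
    """Small training set of (BackboneStructure, sequence) pairs.

    Each protein alternates helical and loop segments (with per-protein
    segment layouts and small torsion jitter so backbones are mutually
    distinguishable).  Helix positions draw letters from helix-former
    residues, loops from turn-formers, making letter usage depend on local
    structure.  Fully reproducible from the seed.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_proteins):
        labels = _segment_layout(length, rng)
        phi = np.where(labels == "H", ALPHA_HELIX[0], BETA_STRAND[0])
        psi = np.where(labels == "H", ALPHA_HELIX[1], BETA_STRAND[1])
        phi = phi + rng.normal(0.0, 0.08, size=length)
        psi = psi + rng.normal(0.0, 0.08, size=length)
        seq = "".join(
            HELIX_LETTERS[rng.integers(len(HELIX_LETTERS))] if lab == "H"
            else LOOP_LETTERS[rng.integers(len(LOOP_LETTERS))]
            for lab in labels)
        b = build_backbone_from_dihedrals(GeometrySpec(phi, psi), seq)
        out.append((b, seq))
    return out


def random_graph(n: int, edge_prob: float, seed: int):
    """Erdős–Rényi contact graph with seeded determinism."""
    from .featurize import ContactGraph

    if not (0.0 <= edge_prob <= 1.0):
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    upper = rng.random((n, n)) < edge_prob
    adj = np.triu(upper, k=1)
    adj = adj | adj.T
    return ContactGraph(n_nodes=n, adjacency=adj)


def perturb_rigid(b: BackboneStructure, seed: int) -> BackboneStructure:
    """Apply a uniformly random rotation and a random translation."""
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(0.0, 10.0, size=3)
    return b.transformed(R, t)


def synthetic_ensemble(n_atoms: int, n_frames: int,
                       correlation_spec=None, seed: int = 0) -> np.ndarray:
    """(T, N, 3) coordinate ensemble with planted displacement correlations.

    Atoms fluctuate independently (isotropic unit Gaussian) around fixed
    mean positions, except for pairs listed in ``correlation_spec`` as
    (i, j, rho): atom j's displacement is rho * (atom i's displacement)
    plus a sqrt(1-rho^2)-scaled independent part, so the planted pair's
    dynamic cross-correlation approaches rho at large T.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 20.0, size=(n_atoms, 3))
    disp = rng.normal(0.0, 1.0, size=(n_frames, n_atoms, 3))
    if correlation_spec:
        for i, j, rho in correlation_spec:
            if not (-1.0 <= rho <= 1.0):
                raise ValueError("correlation must be in [-1, 1]")
            indep = rng.normal(0.0, 1.0, size=(n_frames, 3))
            disp[:, j, :] = rho * disp[:, i, :] + np.sqrt(1 - rho ** 2) * indep
    return base[None, :, :] + disp
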