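"""Virtual-screening filters and trajectory summaries for designed enzymes.

The screening funnel mirrors the design workflow used for CalB (Candida
antarctica lipase B): candidate sequences are filtered on

* the non-polar substrate-pocket rule (seven positions near the substrate
  hydrophobic pocket must hold non-polar residues);
* folding ability — radius of gyration below the native structure's,
  conserved-site CA RMSD < 1.5 Å, externally computed pLDDT > 80;
* solubility — net charge (#Arg + #Lys - #Asp - #Glu) under a configurable
  rule, surface hydrophobicity from burial-weighted non-polar content, and
  optionally an externally computed SAP column.

Burial n_i of residue i sums a distance sigmoid and an orientation term
over virtual C-beta atoms:

    n_i = sum_j 1/(1 + exp(d_ij - m)) * ((cos(pi - phi_ij) + a)/(1 + a))^b

with m = 1, a = 0.5, b = 2 as printed in the source method (m is
configurable; see the methods note for why this midpoint is unusually
sharp).  Hydrophobicity weights 1 - sigmoid(n_i - median(n)) emphasize
surface residues.

Trajectory summaries: the dynamic cross-correlation matrix (DCCM) of CA
displacement fluctuations and hydrogen-bond occupancy under 3.0 Å / 120°
donor-hydrogen-acceptor cutoffs (0.3 nm as commonly quoted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import BackboneStructure
from .metrics import kabsch_rotation

NONPOLAR_EQ15 = frozenset("VILMWF")
NONPOLAR_EXTENDED = frozenset("VILMWFAGCP")
POCKET_POSITIONS = (277, 280, 281, 285, 139, 188, 38)


# --------------------------------------------------------------------------
# CalB fixed positions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalBFixedSites:
    """The published CalB fixed-position lists (author numbering)."""

    catalytic_triad: tuple = (105, 187, 224)
    oxyanion_hole: tuple = (40, 106)
    substrate_pocket: tuple = (141, 144, 149, 285,     # hydrophobic
                               134, 138, 157)          # hydrophilic
    saturation_mutagenesis: tuple = (38, 39, 107, 108, 109, 110, 111, 133,
                                     180, 181, 182, 190, 209, 230, 79, 130,
                                     131, 132, 135, 228)
    msa_conserved: tuple = (103, 104, 190, 69, 180, 209, 216, 239, 188, 258,
                            150, 136, 294, 127, 74, 98, 169, 64)
    md_important: tuple = tuple(range(268, 281)) + (225, 154)

    @property
    def union(self) -> frozenset:
        return frozenset(self.catalytic_triad) | frozenset(self.oxyanion_hole) \
            | frozenset(self.substrate_pocket) \
            | frozenset(self.saturation_mutagenesis) \
            | frozenset(self.msa_conserved) | frozenset(self.md_important)


def calb_fixed_positions() -> CalBFixedSites:
    """The 62 conserved CalB residue positions held fixed during design."""
    return CalBFixedSites()


# --------------------------------------------------------------------------
# folding-ability measures
# --------------------------------------------------------------------------

def radius_of_gyration(coords: np.ndarray) -> float:
    """Unweighted Rg (Å): root-mean-square distance from the centroid."""
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[0] < 1:
        raise ValueError("need at least one (x, y, z) point")
    centered = c - c.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1))))


def conserved_site_rmsd(pred: BackboneStructure, native: BackboneStructure,
                        positions) -> float:
    """Kabsch-superposed CA RMSD over listed author-numbered positions."""
    maps = (pred.number_to_index(), native.number_to_index())
    missing = [p for p in positions if p not in maps[0] or p not in maps[1]]
    if missing:
        raise ValueError(f"positions absent from structures: {sorted(missing)}")
    P = np.array([pred.coords_CA[maps[0][p]] for p in positions])
    Q = np.array([native.coords_CA[maps[1][p]] for p in positions])
    R, t = kabsch_rotation(P, Q)
    return float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))


# --------------------------------------------------------------------------
# solubility measures
# --------------------------------------------------------------------------

def net_charge(sequence: str) -> int:
    """#Arg + #Lys - #Asp - #Glu (formal charge at neutral pH)."""
    return (sequence.count("R") + sequence.count("K")
            - sequence.count("D") - sequence.count("E"))


def virtual_cbeta(b: BackboneStructure) -> np.ndarray:
    """Ideal-geometry C-beta rebuilt from N/CA/C for every residue
    (including glycine), using the standard tetrahedral construction."""
    n_ca = b.coords_N - b.coords_CA
    c_ca = b.coords_C - b.coords_CA
    cross = np.cross(n_ca, c_ca)
    # constants give ~1.52 Å CA-CB with tetrahedral angles
    return b.coords_CA - 0.58273431 * cross + 0.56802827 * n_ca \
        - 0.54067466 * c_ca


def burial_counts(b: BackboneStructure, m: float = 1.0, a: float = 0.5,
                  b_exp: float = 2.0) -> np.ndarray:
    """Per-residue burial n_i from C-beta packing (see module docstring)."""
    cb = virtual_cbeta(b)
    ca = b.coords_CA
    diff = cb[None, :, :] - cb[:, None, :]
    d = np.linalg.norm(diff, axis=-1)
    v = cb - ca                                 # CA -> CB directions
    vn = v / np.linalg.norm(v, axis=1, keepdims=True)
    cos_phi = np.clip(vn @ vn.T, -1.0, 1.0)
    # cos(pi - phi) = -cos(phi)
    orient = ((-cos_phi + a) / (1.0 + a)) ** b_exp
    with np.errstate(over="ignore"):
        sig = 1.0 / (1.0 + np.exp(d - m))
    term = sig * orient
    np.fill_diagonal(term, 0.0)
    return term.sum(axis=1)


def hydrophobicity(sequence: str, n: np.ndarray) -> float:
    """Burial-weighted non-polar surface content in [0, 1].

    Weights w_i = 1 - sigmoid(n_i - n0), n0 = median(n), are largest for
    surface residues; the score is the w-weighted fraction of non-polar
    (V, I, L, M, W, F) residues.
    """
    n = np.asarray(n, dtype=float)
    if len(sequence) != len(n):
        raise ValueError("sequence and burial lengths differ")
    w = 1.0 - 1.0 / (1.0 + np.exp(-(n - np.median(n))))
    if w.sum() <= 0:
        raise ValueError("all surface weights vanish")
    delta = np.array([1.0 if aa in NONPOLAR_EQ15 else 0.0 for aa in sequence])
    return float((delta * w).sum() / w.sum())


def pocket_nonpolar_rule(sequence: str, positions=POCKET_POSITIONS,
                         number_to_index: dict | None = None,
                         nonpolar=NONPOLAR_EXTENDED) -> bool:
    """True iff all pocket positions hold non-polar residues.

    ``number_to_index`` maps author numbering to 0-based sequence index
    (identity-with-offset-1 when omitted).  The non-polar set defaults to
    the extended set (V, I, L, M, W, F plus A, G, C, P) and is
    configurable.
    """
    for pos in positions:
        idx = number_to_index[pos] if number_to_index else pos - 1
        if not (0 <= idx < len(sequence)):
            raise IndexError(f"pocket position {pos} outside the sequence")
        if sequence[idx] not in nonpolar:
            return False
    return True


# --------------------------------------------------------------------------
# the screening funnel
# --------------------------------------------------------------------------

@dataclass
class ScreenThresholds:
    """Filter settings; ``None`` disables a filter.

    Defaults follow the published criteria: Rg below the native value,
    conserved-site RMSD < 1.5 Å, pLDDT > 80.  The net-charge rule and the
    hydrophobicity threshold are deliberately configuration, not constants.
    """

    native_rg: float | None = None
    site_rmsd_max: float | None = 1.5
    plddt_min: float | None = 80.0
    net_charge_max: float | None = 0.0
    hydrophobicity_max: float | None = None
    sap_max: float | None = None
    pocket_rule: bool = False
    pocket_positions: tuple = POCKET_POSITIONS
    nonpolar_set: frozenset = NONPOLAR_EXTENDED


_FILTER_COLUMNS = {
    "pocket": "sequence",
    "rg": "rg",
    "site_rmsd": "site_rmsd",
    "plddt": "plddt",
    "net_charge": "sequence",
    "hydrophobicity": "hydrophobicity",
    "sap": "sap",
}


def apply_screen(table: pd.DataFrame, thresholds: ScreenThresholds):
    """Flag candidates per filter and count survivors stage by stage.

    Returns (flagged table, summary).  Stages run in workflow order:
    pocket rule, folding ability (Rg, conserved-site RMSD, pLDDT), then
    solubility (net charge, hydrophobicity, SAP).  ``pass_all`` is the AND
    of enabled filters; the summary counts candidates surviving each
    successive stage.
    """
    t = thresholds
    stages = []
    if t.pocket_rule:
        stages.append(("pocket", lambda df: df["sequence"].map(
            lambda s: pocket_nonpolar_rule(s, t.pocket_positions,
                                           nonpolar=t.nonpolar_set))))
    if t.native_rg is not None:
        stages.append(("rg", lambda df: df["rg"] < t.native_rg))
    if t.site_rmsd_max is not None:
        stages.append(("site_rmsd", lambda df: df["site_rmsd"] < t.site_rmsd_max))
    if t.plddt_min is not None:
        stages.append(("plddt", lambda df: df["plddt"] > t.plddt_min))
    if t.net_charge_max is not None:
        stages.append(("net_charge", lambda df: df["sequence"].map(net_charge)
                       <= t.net_charge_max))
    if t.hydrophobicity_max is not None:
        stages.append(("hydrophobicity",
                       lambda df: df["hydrophobicity"] <= t.hydrophobicity_max))
    if t.sap_max is not None:
        stages.append(("sap", lambda df: df["sap"] <= t.sap_max))

    out = table.copy()
    for name, _fn in stages:
        col = _FILTER_COLUMNS[name]
        if col not in out.columns:
            raise ValueError(f"filter {name!r} needs missing column {col!r}")

    alive = pd.Series(True, index=out.index)
    summary = {"input": len(out)}
    for name, fn in stages:
        flags = fn(out).astype(bool)
        out[f"pass_{name}"] = flags
        alive = alive & flags
        summary[name] = int(alive.sum())
    out["pass_all"] = alive
    return out, summary


# --------------------------------------------------------------------------
# trajectory summaries
# --------------------------------------------------------------------------

def dccm(ensemble: np.ndarray) -> np.ndarray:
    """Dynamic cross-correlation matrix of displacement fluctuations.

    C_ij = <dR_i . dR_j> / sqrt(<|dR_i|^2><|dR_j|^2>) with dR the deviation
    from the time mean over a (T, N, 3) pre-aligned ensemble.
    """
    x = np.asarray(ensemble, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("ensemble must be (T>=2, N, 3)")
    d = x - x.mean(axis=0)
    cov = np.einsum("tic,tjc->ij", d, d) / x.shape[0]
    var = np.diag(cov)
    zero = np.nonzero(var <= 0)[0]
    if len(zero):
        raise ValueError(f"atoms with zero displacement variance: {zero.tolist()}")
    return cov / np.sqrt(np.outer(var, var))


def hbond_fraction(ensemble: np.ndarray, donor: int, hydrogen: int,
                   acceptor: int, d_cut: float = 3.0,
                   angle_cut_deg: float = 120.0) -> float:
    """Fraction of frames forming the donor-H...acceptor hydrogen bond.

    A frame counts when the donor-acceptor distance is <= ``d_cut``
    (3.0 Å, i.e. 0.3 nm) and the donor-hydrogen-acceptor angle is >=
    ``angle_cut_deg`` (120°).  Coordinates are Å.
    """
    x = np.asarray(ensemble, dtype=float)
    n_atoms = x.shape[1]
    for idx in (donor, hydrogen, acceptor):
        if not (0 <= idx < n_atoms):
            raise IndexError(f"atom index {idx} out of range")
    d_da = np.linalg.norm(x[:, donor] - x[:, acceptor], axis=1)
    v1 = x[:, donor] - x[:, hydrogen]
    v2 = x[:, acceptor] - x[:, hydrogen]
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = (d_da <= d_cut) & (ang >= angle_cut_deg)
    return float(ok.mean())
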