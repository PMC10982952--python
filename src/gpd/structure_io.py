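"""Backbone structure I/O: PDB parsing, per-residue frames, FASTA output.

The design method operates on backbone atoms only (N, CA, C, O).  A parsed
chain is held as a :class:`BackboneStructure`; every residue carries all of
N/CA/C (a missing carbonyl O is tolerated and flagged, since O is only needed
for secondary-structure assignment and can be rebuilt from the peptide plane).

Each residue also defines a local orthonormal coordinate system (the
"residue gas" frame) built from the CA->C and CA->N bond vectors.  Frames are
equivariant under rigid motion of the backbone, which is what makes the
derived edge features (movement vectors, relative-rotation quaternions)
invariant.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import biotite.sequence.io.fasta as fasta

# 20 canonical amino acids, one-letter, alphabetical by letter.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
UNK_TOKEN = 20   # unknown residue type
PAD_TOKEN = 21   # padding
VOCAB_SIZE = 22

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Consecutive CA-CA distances outside this window flag a chain break.
CA_CA_MIN = 2.8
CA_CA_MAX = 4.5


@dataclass
class BackboneStructure:
    """One protein chain's backbone: per-residue N/CA/C/O coordinates (Å).

    ``residue_numbers`` keeps author numbering (used by the active-site
    position lists); internally residues are addressed by 0-based index.
    """

    chain_id: str
    residue_numbers: np.ndarray          # (N,) int, author numbering
    residue_names: list                  # (N,) 3-letter codes
    coords_N: np.ndarray                 # (N, 3) float
    coords_CA: np.ndarray
    coords_C: np.ndarray
    coords_O: np.ndarray                 # NaN rows where O is missing
    insertion_codes: list = field(default_factory=list)
    missing_O: np.ndarray = None         # (N,) bool

    def __post_init__(self):
        n = len(self.residue_numbers)
        for name in ("coords_N", "coords_CA", "coords_C", "coords_O"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
            setattr(self, name, arr)
        if self.missing_O is None:
            self.missing_O = np.any(np.isnan(self.coords_O), axis=1)
        if not self.insertion_codes:
            self.insertion_codes = [""] * n
        for name in ("coords_N", "coords_CA", "coords_C"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite coordinates in {name}")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r, "X") for r in self.residue_names)

    def chain_breaks(self) -> np.ndarray:
        """Indices i where the CA(i)-CA(i+1) distance falls outside the
        peptide-bond window [2.8, 4.5] Å.  Recorded, never fatal."""
        if len(self) < 2:
            return np.array([], dtype=int)
        d = np.linalg.norm(np.diff(self.coords_CA, axis=0), axis=1)
        return np.where((d < CA_CA_MIN) | (d > CA_CA_MAX))[0]

    def number_to_index(self) -> dict:
        """Author residue number -> 0-based index (first occurrence wins)."""
        out = {}
        for i, num in enumerate(self.residue_numbers):
            out.setdefault(int(num), i)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        def tx(c):
            out = c @ R.T + t
            return out
        return BackboneStructure(
            chain_id=self.chain_id,
            residue_numbers=self.residue_numbers.copy(),
            residue_names=list(self.residue_names),
            coords_N=tx(self.coords_N),
            coords_CA=tx(self.coords_CA),
            coords_C=tx(self.coords_C),
            coords_O=tx(self.coords_O),
            insertion_codes=list(self.insertion_codes),
            missing_O=self.missing_O.copy(),
        )

    def to_pdb_text(self) -> str:
        """Serialize backbone atoms as minimal ATOM records (round-trips
        through :func:`parse_backbone`)."""
        lines = []
        serial = 1
        for i in range(len(self)):
            atoms = [("N", self.coords_N[i]), ("CA", self.coords_CA[i]),
                     ("C", self.coords_C[i])]
            if not self.missing_O[i]:
                atoms.append(("O", self.coords_O[i]))
            for name, xyz in atoms:
                lines.append(
                    "ATOM  {serial:>5d} {name:^4s}{alt:1s}{res:>3s} {ch:1s}"
                    "{num:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    "{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                        serial=serial, name=name, alt=" ",
                        res=self.residue_names[i], ch=self.chain_id,
                        num=int(self.residue_numbers[i]),
                        icode=self.insertion_codes[i] or " ",
                        x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
                        el=name[0]))
                serial += 1
        lines.append("END")
        return "\n".join(lines) + "\n"


@dataclass
class ResidueFrame:
    """Local orthonormal coordinate system of one residue.

    Columns of ``axes`` derive from CA->C (normalized), CA->N
    (orthogonalized against the first) and their cross product, giving a
    proper rotation matrix (det +1).
    """

    origin: np.ndarray   # CA position, (3,)
    axes: np.ndarray     # (3, 3), orthonormal, det +1


def parse_backbone(pdb_text: str, chain: str) -> BackboneStructure:
    """Parse one chain's backbone from PDB-format text.

    Altloc conflicts resolve to the highest-occupancy conformer; insertion
    codes are preserved in residue ordering.  A residue missing any of
    N/CA/C is a hard error naming the residue; missing O is flagged.
    """
    pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb.get_structure(pdb_file, model=1, altloc="occupancy",
                              extra_fields=["occupancy"])
    atoms = atoms[atoms.chain_id == chain]
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError(f"chain {chain!r} is empty or absent")

    res_numbers, res_names, icodes = [], [], []
    coords = {"N": [], "CA": [], "C": [], "O": []}
    for res in struc.residue_iter(atoms):
        num = int(res.res_id[0])
        name = str(res.res_name[0])
        icode = str(res.ins_code[0]) if hasattr(res, "ins_code") else ""
        pos = {}
        for at in ("N", "CA", "C", "O"):
            sel = res[res.atom_name == at]
            if sel.array_length() > 0:
                pos[at] = np.asarray(sel.coord[0], dtype=float)
        for at in ("N", "CA", "C"):
            if at not in pos:
                raise ValueError(
                    f"residue {name} {num}{icode.strip()} in chain {chain} "
                    f"is missing backbone atom {at}")
        res_numbers.append(num)
        res_names.append(name)
        icodes.append(icode.strip())
        for at in ("N", "CA", "C"):
            coords[at].append(pos[at])
        coords["O"].append(pos.get("O", np.full(3, np.nan)))

    return BackboneStructure(
        chain_id=chain,
        residue_numbers=np.asarray(res_numbers, dtype=int),
        residue_names=res_names,
        coords_N=np.asarray(coords["N"]),
        coords_CA=np.asarray(coords["CA"]),
        coords_C=np.asarray(coords["C"]),
        coords_O=np.asarray(coords["O"]),
        insertion_codes=icodes,
    )


def residue_frames(b: BackboneStructure) -> list:
    """Per-residue local frames from the backbone geometry.

    The raw construction uses [CA->C, CA->N, CA->C x CA->N]; the columns are
    orthonormalized (first normalized, second Gram-Schmidt-orthogonalized,
    third their cross product) so the result is a proper rotation and
    relative rotations between residues are well defined.
    """
    frames = []
    for i in range(len(b)):
        u = b.coords_C[i] - b.coords_CA[i]
        v = b.coords_N[i] - b.coords_CA[i]
        cross = np.cross(u, v)
        if np.linalg.norm(cross) < 1e-8:
            raise ValueError(
                f"N, CA, C of residue index {i} "
                f"(number {int(b.residue_numbers[i])}) are collinear")
        e1 = u / np.linalg.norm(u)
        w = v - (v @ e1) * e1
        e2 = w / np.linalg.norm(w)
        e3 = np.cross(e1, e2)
        axes = np.stack([e1, e2, e3], axis=1)
        frames.append(ResidueFrame(origin=b.coords_CA[i].copy(), axes=axes))
    return frames


def write_fasta(seqset, path) -> None:
    """Write a SequenceSet to FASTA; headers carry design id and seed."""
    if not seqset.sequences:
        with open(path, "w") as fh:
            pass
        return
    ff = fasta.FastaFile()
    for i, seq in enumerate(seqset.sequences):
        bad = set(seq) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"sequence {i} contains non-standard letters: "
                             f"{sorted(bad)}")
        meta = seqset.metadata[i] if i < len(seqset.metadata) else {}
        header = f"design_{i}"
        if "seed" in meta:
            header += f" seed={meta['seed']}"
        if "temperature" in meta:
            header += f" temperature={meta['temperature']}"
        ff[header] = seq
    ff.write(str(path))


def read_fasta(path) -> dict:
    """Read a FASTA file as {header: sequence}."""
    return dict(fasta.FastaFile.read(str(path)).items())
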