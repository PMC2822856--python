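"""Reading PDB structures, reduced centroid models, and rigid-body fits.

The in-memory :class:`Structure` keeps only what downstream scoring needs:
the 20 standard amino acids, heavy atoms, one conformer per atom. Multi-model
PDB files can be read in trajectory mode, in which case every MODEL block
becomes one coordinate frame (the container used for MD snapshots).

Residues are reduced to single interaction centres under one of three
schemes: ``CA`` (alpha carbon), ``CB`` (beta carbon, virtual for glycine) or
``CM`` (unweighted centre of the heavy side-chain atoms).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from .aminoacids import BACKBONE_ATOMS, STANDARD_AA3, THREE_TO_ONE, aa_index
from .errors import EmptyStructureError, InputError, ParseError, ReductionError

logger = logging.getLogger(__name__)

SCHEMES = ("CA", "CB", "CM")

#: backbone atoms used for RMSD/RMSF selections
RMSF_BACKBONE = ("CA", "C", "N", "O")

# Virtual C-beta construction: bond length and direction coefficients for
# the standard tetrahedral placement from N, CA, C (L-chirality).
CBETA_BOND_LENGTH = 1.522
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)

ResidueKey = tuple[str, int, str]  # (chain id, residue number, insertion code)
AtomKey = tuple[str, int, str, str]  # residue key + atom name


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Angstrom, first frame
    occupancy: float = 1.0
    altloc: str = ""


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str  # 3-letter
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.name]


@dataclass
class Structure:
    """Filtered structure; ``frames[k]`` maps atom keys to coordinates."""

    residues: list[Residue]
    frames: list[dict[AtomKey, np.ndarray]]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for res in self.residues:
            seen.setdefault(res.chain_id, None)
        return list(seen)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def chain_residues(self, chain_id: str) -> list[Residue]:
        out = [r for r in self.residues if r.chain_id == chain_id]
        if not out:
            raise InputError(f"no such chain: {chain_id!r}")
        return out

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain_residues(chain_id))


@dataclass(frozen=True)
class CentroidEntry:
    chain_id: str
    number: int
    icode: str
    name: str  # 3-letter

    coord: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def type_index(self) -> int:
        return aa_index(self.name)


@dataclass
class CentroidModel:
    """One interaction centre per residue under a fixed scheme."""

    scheme: str
    entries: list[CentroidEntry]

    @property
    def coords(self) -> np.ndarray:
        return np.array([e.coord for e in self.entries], dtype=float)

    @property
    def type_indices(self) -> np.ndarray:
        return np.array([e.type_index for e in self.entries], dtype=int)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.chain_id, None)
        return list(seen)

    def select_chains(self, chain_ids) -> "CentroidModel":
        wanted = set(chain_ids)
        entries = [e for e in self.entries if e.chain_id in wanted]
        if not entries:
            raise InputError(f"no residues in chains {sorted(wanted)}")
        return CentroidModel(self.scheme, entries)


def _validate_atom_lines(pdb_text: str) -> None:
    """Fail early, naming the line, on unparseable ATOM coordinate fields."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError(f"malformed ATOM record at line {lineno}: too short")
        try:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except ValueError:
            raise ParseError(
                f"malformed ATOM record at line {lineno}: bad coordinate field"
            ) from None


def _select_altloc(atoms) -> object:
    """Highest occupancy wins; ties broken by alphabetically first altloc."""
    def sort_key(a):
        occ = a.get_occupancy()
        return (-(occ if occ is not None else 1.0), a.get_altloc())

    return sorted(atoms, key=sort_key)[0]


def read_structure(pdb_text: str, trajectory: bool = False) -> Structure:
    """Parse PDB-format text into a filtered :class:`Structure`.

    Waters, hetero groups, hydrogens and non-standard residues are dropped.
    For altloc duplicates the highest-occupancy conformer is kept (ties:
    alphabetically first altloc). By default only the first MODEL is read;
    with ``trajectory=True`` every MODEL becomes a coordinate frame.
    """
    _validate_atom_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure("s", io.StringIO(pdb_text))
    except Exception as exc:  # Bio.PDB raises several exception types
        raise ParseError(f"PDB parse failed: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise EmptyStructureError("no MODEL/ATOM content")
    if not trajectory:
        models = models[:1]

    residues: list[Residue] = []
    frames: list[dict[AtomKey, np.ndarray]] = []
    for model_index, model in enumerate(models):
        frame: dict[AtomKey, np.ndarray] = {}
        for chain in model:
            for bres in chain:
                hetflag, resseq, icode = bres.get_id()
                if hetflag.strip():
                    continue  # water / hetero group
                resname = bres.get_resname().strip()
                if resname not in STANDARD_AA3:
                    continue
                icode = icode.strip()
                key = (chain.id, resseq, icode)
                # group altlocs by atom name, pick one conformer each
                by_name: dict[str, list] = {}
                for atom in bres.get_unpacked_list():
                    element = (atom.element or "").strip().upper()
                    if element in ("H", "D"):
                        continue
                    by_name.setdefault(atom.get_name().strip(), []).append(atom)
                if not by_name:
                    continue
                atoms: dict[str, Atom] = {}
                for name, alts in by_name.items():
                    chosen = _select_altloc(alts)
                    coord = np.asarray(chosen.get_coord(), dtype=float)
                    if not np.all(np.isfinite(coord)):
                        raise ParseError(f"non-finite coordinates for atom {name} in {key}")
                    atoms[name] = Atom(
                        name=name,
                        element=(chosen.element or "").strip().upper(),
                        coord=coord,
                        occupancy=chosen.get_occupancy() or 1.0,
                        altloc=chosen.get_altloc().strip(),
                    )
                    frame[key + (name,)] = atoms[name].coord
                if model_index == 0:
                    residues.append(Residue(chain.id, resseq, icode, resname, atoms))
        frames.append(frame)

    if not residues:
        raise EmptyStructureError("no standard amino-acid residues retained")
    # strict in-chain ordering by (number, insertion code), preserving
    # first-appearance chain order
    chain_rank: dict[str, int] = {}
    for r in residues:
        chain_rank.setdefault(r.chain_id, len(chain_rank))
    residues.sort(key=lambda r: (chain_rank[r.chain_id], r.number, r.icode))
    return Structure(residues=residues, frames=frames)


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta position constructed from backbone N, CA, C.

    Uses the standard tetrahedral direction for an L-amino acid, scaled to a
    CA-CB bond length of 1.522 A.
    """
    b = ca - n
    cvec = c - ca
    b /= np.linalg.norm(b)
    cvec /= np.linalg.norm(cvec)
    a = np.cross(b, cvec)
    direction = _CB_COEFF[0] * a + _CB_COEFF[1] * b + _CB_COEFF[2] * cvec
    direction /= np.linalg.norm(direction)
    return ca + CBETA_BOND_LENGTH * direction


def reduce(structure: Structure, scheme: str) -> CentroidModel:
    """Reduce every residue to one interaction centre.

    CA: alpha carbon. CB: beta carbon (virtual for glycine). CM: unweighted
    mean of heavy side-chain atoms; glycine, and residues with a fully
    missing side chain, fall back to the virtual C-beta (logged warning for
    the latter).
    """
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise InputError(f"unknown centroid scheme {scheme!r}; expected one of {SCHEMES}")

    entries: list[CentroidEntry] = []
    for res in structure.residues:
        for bb in ("N", "CA", "C"):
            if bb not in res.atoms:
                raise ReductionError(
                    f"residue {res.name} {res.key} is missing backbone atom {bb}"
                )
        n = res.atoms["N"].coord
        ca = res.atoms["CA"].coord
        c = res.atoms["C"].coord

        if scheme == "CA":
            coord = ca
        elif scheme == "CB":
            coord = res.atoms["CB"].coord if "CB" in res.atoms else virtual_cbeta(n, ca, c)
        else:  # CM
            side = [
                a.coord for name, a in res.atoms.items()
                if name not in BACKBONE_ATOMS
            ]
            if side:
                coord = np.mean(side, axis=0)
            else:
                coord = virtual_cbeta(n, ca, c)
                if res.name != "GLY":
                    logger.warning(
                        "residue %s %s has no side-chain atoms; using virtual C-beta",
                        res.name, res.key,
                    )
        entries.append(
            CentroidEntry(res.chain_id, res.number, res.icode, res.name, np.asarray(coord))
        )
    return CentroidModel(scheme=scheme, entries=entries)


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # (3, 3), proper rotation (det +1)
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns the proper rotation/translation (Kabsch) minimising the RMSD of
    ``coords_b @ R.T + t`` to ``coords_a``, and the post-fit RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InputError(f"coordinate sets must both be n x 3; got {a.shape} and {b.shape}")
    if a.shape[0] < 3:
        raise InputError("superposition requires at least 3 points")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - cb @ rot.T
    fitted = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def backbone_atom_keys(structure: Structure, chains=None, residues=None) -> list[AtomKey]:
    """Ordered keys of backbone atoms (CA, C, N, O) for a selection.

    ``chains`` limits to chain ids, ``residues`` to residue keys; both
    default to everything present.
    """
    wanted_chains = set(chains) if chains is not None else None
    wanted_res = set(residues) if residues is not None else None
    keys: list[AtomKey] = []
    for res in structure.residues:
        if wanted_chains is not None and res.chain_id not in wanted_chains:
            continue
        if wanted_res is not None and res.key not in wanted_res:
            continue
        for name in RMSF_BACKBONE:
            if name in res.atoms:
                keys.append(res.key + (name,))
    return keys


def trajectory_rmsd(structure: Structure, chains=None, ref_frame: int = 0) -> list[float]:
    """Backbone RMSD of every frame after superposition onto a reference frame."""
    if structure.n_frames < 2:
        raise InputError("trajectory RMSD requires at least 2 frames")
    keys = backbone_atom_keys(structure, chains=chains)
    ref = _gather(structure.frames[ref_frame], keys)
    out = []
    for frame in structure.frames:
        coords = _gather(frame, keys)
        out.append(superpose(ref, coords).rmsd)
    return out


def _gather(frame: dict[AtomKey, np.ndarray], keys: list[AtomKey]) -> np.ndarray:
    try:
        return np.array([frame[k] for k in keys], dtype=float)
    except KeyError as exc:
        raise InputError(f"atom {exc.args[0]} absent from a trajectory frame") from None


def backbone_rmsf(structure: Structure, chains=None, residues=None) -> dict[ResidueKey, float]:
    """Per-residue backbone RMSF across trajectory frames.

    Frames must already be superposed onto a common reference. For each
    residue the fluctuation of each backbone atom (CA, C, N, O) about its
    across-frame mean position is computed, and the per-atom values are
    averaged. Raises if a selected residue's backbone is absent from any
    frame.
    """
    if structure.n_frames < 2:
        raise InputError("RMSF requires at least 2 frames")
    wanted_chains = set(chains) if chains is not None else None
    wanted_res = set(residues) if residues is not None else None

    out: dict[ResidueKey, float] = {}
    for res in structure.residues:
        if wanted_chains is not None and res.chain_id not in wanted_chains:
            continue
        if wanted_res is not None and res.key not in wanted_res:
            continue
        atom_rmsfs = []
        for name in RMSF_BACKBONE:
            if name not in res.atoms:
                continue
            key = res.key + (name,)
            try:
                traj = np.array([frame[key] for frame in structure.frames])
            except KeyError:
                raise InputError(
                    f"residue {res.key} backbone atom {name} absent from a frame"
                ) from None
            dev = traj - traj.mean(axis=0)
            atom_rmsfs.append(float(np.sqrt(np.mean(np.sum(dev**2, axis=1)))))
        if not atom_rmsfs:
            raise InputError(f"residue {res.key} has no backbone atoms")
        out[res.key] = float(np.mean(atom_rmsfs))
    if not out:
        raise InputError("empty selection")
    return out
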