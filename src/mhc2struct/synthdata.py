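"""Synthetic PDB fixtures and affinity datasets.

Everything downstream of the PDB parser can be exercised without downloads:

* :func:`make_toy_complex` emits a small peptide:MHC-like complex in which
  each peptide residue makes an exactly specified number of 4-A contacts;
* :func:`make_potential_training_set` emits batches of dumbbell chains whose
  counted residue-pair distances follow a fully controlled distribution, so
  the statistical pair potential derived from them has a closed-form
  expectation (zero everywhere for the type-independent null model, -ln 2 in
  the short-range LYS-ASP bins for the enriched model);
* :func:`make_affinity_dataset` draws binder/non-binder scores from two unit
  Gaussians separated by d, giving an expected AUC of Phi(d / sqrt 2).

All geometry is idealized and self-consistent rather than physically
relaxed; every generator is deterministic per seed, and the seed is recorded
in REMARK lines of emitted PDB text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aminoacids import ONE_TO_THREE
from .errors import InfeasibleGeometryError, InputError
from .evaluate import BindingRecord

# --------------------------------------------------------------------------
# PDB text emission

_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _format_atom(serial: int, name: str, resname: str, chain: str, resseq: int,
                 coord) -> str:
    x, y, z = coord
    return (
        f"ATOM  {serial % 100000:5d} {name:^4s} {resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        f"          {_ATOM_ELEMENTS[name]:>2s}"
    )


# --------------------------------------------------------------------------
# Toy peptide:MHC complexes with exact DIST4 contact counts

#: peptide backbone template, offsets from the residue's CA (A)
_PEP_OFFSETS = {
    "N": (-1.46, 0.0, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.52, 0.0, 0.0),
    "O": (2.12, 1.06, 0.0),
    "CB": (-0.55, -1.42, -0.80),
}
_PEP_SPACING = 7.0  # CA-CA spacing along x; stretched so contact shells stay disjoint
_CONTACT_HEIGHT = 3.90  # z of a contact pseudo-atom above the peptide CA
_CONTACT_RING = 0.40  # radius of the ring contact atoms sit on
MAX_CONTACTS_PER_RESIDUE = 12


@dataclass
class ToyComplexSpec:
    """Recipe for a synthetic peptide:MHC complex.

    ``contact_counts[j]`` is the exact number of MHC pseudo-atoms placed
    within 4 A of peptide residue j (and > 4 A from every other peptide
    atom), so ``find_contacts(..., schema="DIST4")`` recovers the list
    verbatim. Gaussian noise of ``noise_sigma`` is applied only to the
    far-away MHC scaffold residues, never to the contact geometry.
    """

    peptide: str
    contact_counts: list[int] = field(default_factory=list)
    peptide_chain: str = "C"
    mhc_chains: tuple[str, ...] = ("A", "B")
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.peptide = self.peptide.upper()
        if not 9 <= len(self.peptide) <= 16:
            raise InputError(f"peptide length must be 9..16, got {len(self.peptide)}")
        bad = sorted(set(self.peptide) - set(ONE_TO_THREE))
        if bad:
            raise InputError(f"non-standard amino-acid code(s): {bad}")
        if not self.contact_counts:
            self.contact_counts = [0] * len(self.peptide)
        if len(self.contact_counts) != len(self.peptide):
            raise InputError("contact_counts must match peptide length")
        if any(c < 0 for c in self.contact_counts):
            raise InputError("contact counts must be non-negative")
        if max(self.contact_counts) > MAX_CONTACTS_PER_RESIDUE:
            raise InfeasibleGeometryError(
                f"at most {MAX_CONTACTS_PER_RESIDUE} contacts per residue can be "
                "placed without perturbing neighbouring counts"
            )
        if not self.mhc_chains:
            raise InputError("at least one MHC chain id required")
        if self.peptide_chain in self.mhc_chains:
            raise InputError("peptide chain id collides with an MHC chain id")


def make_toy_complex(spec: ToyComplexSpec) -> str:
    """Emit PDB text realizing a :class:`ToyComplexSpec`.

    The peptide is laid out as a stretched strand along x. For each peptide
    residue, the requested number of contact pseudo-residues (glycines whose
    CA sits 3.9 A above the residue's CA) is added to the MHC chains; their
    remaining backbone atoms sit > 6 A from every peptide atom, as do the
    MHC scaffold residues at z = -12.
    """
    rng = np.random.default_rng(spec.seed)
    lines = [
        "REMARK 250 SYNTHETIC PEPTIDE:MHC COMPLEX (mhc2struct synthdata)",
        f"REMARK 250 SEED={spec.seed}",
    ]
    serial = 1

    # MHC scaffold: 4 glycines per chain, far below the peptide plane
    scaffold: list[tuple[str, int, dict[str, np.ndarray]]] = []
    for ci, chain in enumerate(spec.mhc_chains):
        for k in range(4):
            base = np.array([5.0 * k, 8.0 * ci, -12.0])
            noise = rng.normal(0.0, spec.noise_sigma, 3) if spec.noise_sigma > 0 else 0.0
            if spec.noise_sigma > 0:
                norm = np.linalg.norm(noise)
                if norm > 2.0:  # keep the >= 6 A clearance from the peptide
                    noise = noise * (2.0 / norm)
            atoms = {
                name: base + np.array(off) + noise
                for name, off in _PEP_OFFSETS.items()
                if name != "CB"
            }
            scaffold.append((chain, k + 1, atoms))

    # contact pseudo-residues, alternating between the MHC chains
    contacts: list[tuple[str, int, dict[str, np.ndarray]]] = []
    next_resseq = {chain: 100 for chain in spec.mhc_chains}
    placed = 0
    for j, count in enumerate(spec.contact_counts):
        ca = np.array([_PEP_SPACING * j, 0.0, 0.0])
        for k in range(count):
            phi = 2.0 * math.pi * k / MAX_CONTACTS_PER_RESIDUE
            point = ca + np.array(
                [_CONTACT_RING * math.cos(phi), _CONTACT_RING * math.sin(phi),
                 _CONTACT_HEIGHT]
            )
            chain = spec.mhc_chains[placed % len(spec.mhc_chains)]
            atoms = {
                "CA": point,
                "N": point + np.array([0.0, 0.0, 2.2]),
                "C": point + np.array([0.0, 1.5, 2.2]),
                "O": point + np.array([0.0, 2.3, 2.7]),
            }
            contacts.append((chain, next_resseq[chain], atoms))
            next_resseq[chain] += 1
            placed += 1

    # emit MHC chains grouped by chain id, then the peptide chain
    for chain in spec.mhc_chains:
        for cid, resseq, atoms in scaffold + contacts:
            if cid != chain:
                continue
            for name in ("N", "CA", "C", "O"):
                if name in atoms:
                    lines.append(_format_atom(serial, name, "GLY", chain, resseq, atoms[name]))
                    serial += 1
        lines.append("TER")

    for j, aa1 in enumerate(spec.peptide):
        resname = ONE_TO_THREE[aa1]
        ca = np.array([_PEP_SPACING * j, 0.0, 0.0])
        for name, off in _PEP_OFFSETS.items():
            if name == "CB" and resname == "GLY":
                continue
            lines.append(
                _format_atom(serial, name, resname, spec.peptide_chain, j + 1, ca + np.array(off))
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Pair-potential training sets with controlled pair-distance statistics

#: distance range (A) spanned by the controlled dumbbell separations
TRAINING_D_RANGE = (3.0, 7.0)
#: boundary between the "short-range" and "long-range" regimes (A)
TRAINING_SHORT_MAX = 4.0
#: separations are sampled this far inside the range ends so that cluster
#: jitter can never spill pairs into a neighbouring, sparsely hit bin
_D_MARGIN = 0.1
#: half-width of the exclusion band around the regime boundary, keeping all
#: pairs of one chain on a single side of it
_D_BAND = 0.05

# Enriched mode: the head cluster is all-LYS and tail residues are ASP with
# probability b(D). b_short is a design constant; b_long is solved from the
# sampling measures m_s, m_l of the two regimes so that the short-range
# LYS-ASP pair density is exactly twice the pooled density, making the
# derived potential there -ln 2 in expectation:
#   b_short / mean_b = 2  with  mean_b = (m_s b_short + m_l b_long) / (m_s + m_l)
_ENRICHED_B_SHORT = 0.75
_M_SHORT = (TRAINING_SHORT_MAX - _D_BAND) - (TRAINING_D_RANGE[0] + _D_MARGIN)
_M_LONG = (TRAINING_D_RANGE[1] - _D_MARGIN) - (TRAINING_SHORT_MAX + _D_BAND)
_ENRICHED_B_LONG = _ENRICHED_B_SHORT * (_M_SHORT + _M_LONG - 2 * _M_SHORT) / (2 * _M_LONG)

_CLUSTER_SIZE = 10
_N_FILLER = 9
_CHAIN_GRID_SPACING = 45.0
_RES_OFFSETS = {
    "N": (-0.30, 0.0, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (0.30, 0.0, 0.0),
    "CB": (0.0, 0.30, 0.0),
}


def _emit_chain(lines: list[str], serial: int, chain_id: str, origin: np.ndarray,
                d: float, head: list[str], tail: list[str], rng) -> int:
    """One 29-residue dumbbell chain: 10 head + 9 remote filler + 10 tail.

    Only head x tail residue pairs pass the sequence-separation filter at a
    countable distance; all of them sit at separation ~d. Fillers are placed
    20.5 A off-axis so their countable pairs exceed the 20 A counting range.
    """
    centres = (
        [np.array([0.0, 0.0, 0.0])] * _CLUSTER_SIZE
        + [np.array([d / 2.0, 20.5, 0.0])] * _N_FILLER
        + [np.array([d, 0.0, 0.0])] * _CLUSTER_SIZE
    )
    names = head + ["ALA"] * _N_FILLER + tail
    for idx, (resname, centre) in enumerate(zip(names, centres)):
        jitter = rng.uniform(-0.02, 0.02, 3)
        base = origin + centre + jitter
        for name, off in _RES_OFFSETS.items():
            lines.append(_format_atom(serial, name, resname, chain_id, idx + 1, base + np.array(off)))
            serial += 1
    lines.append("TER")
    return serial


def make_potential_training_set(
    n_chains: int,
    type_dependent: bool = False,
    seed: int = 0,
    chains_per_structure: int = 25,
) -> list[str]:
    """Dumbbell-chain training structures for pair-potential derivation.

    Each chain carries two tight 10-residue clusters whose inter-cluster
    pairs (the only ones that pass the sequence-separation filter within
    counting range) all sit at a controlled separation d ~ Uniform(3, 7) A.

    With ``type_dependent=False`` (null model) cluster residues are typed
    independently of d (uniform LYS/ASP), so the derived potential tends to
    0 in every populated bin. With ``type_dependent=True`` the head cluster
    is all-LYS and tail residues are ASP with probability 0.75 below 4 A and
    0.25 above, which makes the short-range LYS-ASP pair density exactly
    twice the pooled density: the derived potential there is -ln 2.

    Chains are packed on a wide grid (several per PDB text) so that
    inter-chain atom pairs always exceed the 20 A counting range.
    """
    if n_chains < 1:
        raise InputError("n_chains must be at least 1")
    rng = np.random.default_rng(seed)
    d_lo, d_hi = TRAINING_D_RANGE
    chain_ids = "ABCDEFGHIJKLMNOPQRSTUVWXY"[:chains_per_structure]
    grid_side = int(math.ceil(math.sqrt(chains_per_structure)))

    texts: list[str] = []
    emitted = 0
    while emitted < n_chains:
        batch = min(chains_per_structure, n_chains - emitted)
        lines = [
            "REMARK 250 SYNTHETIC PAIR-POTENTIAL TRAINING STRUCTURE (mhc2struct synthdata)",
            f"REMARK 250 SEED={seed}",
        ]
        serial = 1
        for g in range(batch):
            origin = np.array(
                [(g % grid_side) * _CHAIN_GRID_SPACING,
                 (g // grid_side) * _CHAIN_GRID_SPACING, 0.0]
            )
            if type_dependent:
                d = float(rng.uniform(d_lo + _D_MARGIN, d_hi - _D_MARGIN))
                while abs(d - TRAINING_SHORT_MAX) < _D_BAND:
                    d = float(rng.uniform(d_lo + _D_MARGIN, d_hi - _D_MARGIN))
                b = _ENRICHED_B_SHORT if d < TRAINING_SHORT_MAX else _ENRICHED_B_LONG
                head = ["LYS"] * _CLUSTER_SIZE
                tail = ["ASP" if rng.random() < b else "LYS" for _ in range(_CLUSTER_SIZE)]
            else:
                d = float(rng.uniform(d_lo + _D_MARGIN, d_hi - _D_MARGIN))
                head = [("LYS", "ASP")[rng.integers(2)] for _ in range(_CLUSTER_SIZE)]
                tail = [("LYS", "ASP")[rng.integers(2)] for _ in range(_CLUSTER_SIZE)]
            serial = _emit_chain(lines, serial, chain_ids[g], origin, d, head, tail, rng)
        lines.append("END")
        texts.append("\n".join(lines) + "\n")
        emitted += batch
    return texts


# --------------------------------------------------------------------------
# Affinity datasets with known expected AUC

def expected_auc(separation: float) -> float:
    """Closed-form AUC of two unit-variance Gaussians separated by d."""
    return 0.5 * (1.0 + math.erf(separation / 2.0))  # Phi(d / sqrt 2)


def make_affinity_dataset(
    n_pos: int = 2939,
    n_neg: int = 943,
    separation: float = 0.669,
    seed: int = 0,
    ic50_threshold: float = 1000.0,
    max_ic50: float = 50000.0,
) -> list[BindingRecord]:
    """Scored binder/non-binder records with a known expected AUC.

    Binder scores are drawn from N(separation, 1) and non-binder scores from
    N(0, 1), so the expected AUC is Phi(separation / sqrt 2). Default class
    sizes mirror a large MHC-II benchmark (2939 binders, 943 non-binders);
    the default separation corresponds to an expected AUC of ~0.68. IC50
    values are drawn log-uniformly strictly below / at-or-above the
    threshold to match the labels.
    """
    if n_pos < 1 or n_neg < 1:
        raise InputError("both class counts must be at least 1")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records: list[BindingRecord] = []
    for i in range(n_pos + n_neg):
        binder = i < n_pos
        score = float(rng.normal(separation if binder else 0.0, 1.0))
        if binder:
            log_ic50 = rng.uniform(0.0, math.log10(ic50_threshold))
        else:
            log_ic50 = rng.uniform(math.log10(ic50_threshold), math.log10(max_ic50))
        peptide = "".join(rng.choice(alphabet, 15))
        records.append(BindingRecord(peptide=peptide, ic50=float(10.0**log_ic50), score=score))
    return records
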