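"""Peptide-MHC atomic contact detection and per-core-position tabulation.

Four counting schemas are supported:

* ``DIST4``        - any heavy-atom pair within 4.0 A;
* ``HB``           - hydrogen bonds only;
* ``HB_VDW``       - hydrogen bonds or van der Waals contacts;
* ``HB_VDW_PHOB``  - hydrogen bonds, van der Waals or hydrophobic contacts.

Crystal structures lack hydrogens, so the geometric criteria are
heavy-atom-only and contain no angular terms (this implementation's choice;
thresholds are exposed through :class:`ContactCriteria`):

* hydrogen bond: N/O donor-acceptor heavy atoms within 3.5 A;
* van der Waals: distance <= r_vdw(a) + r_vdw(b) + 0.5 A (Bondi radii);
* hydrophobic: carbon-carbon pair within 4.5 A.

An atom pair is counted once no matter how many interaction types it
satisfies, and a residue's contact count is the number of atom pairs its
atoms participate in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .aminoacids import VDW_RADII
from .errors import InputError
from .structio import AtomKey, ResidueKey, Structure

SCHEMAS = ("DIST4", "HB", "HB_VDW", "HB_VDW_PHOB")

#: interaction types evaluated under each schema
_SCHEMA_TYPES = {
    "DIST4": ("dist4",),
    "HB": ("hb",),
    "HB_VDW": ("hb", "vdw"),
    "HB_VDW_PHOB": ("hb", "vdw", "phob"),
}


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric thresholds (A) for the interaction types."""

    dist4: float = 4.0
    hbond: float = 3.5
    vdw_slack: float = 0.5
    hydrophobic: float = 4.5
    default_vdw_radius: float = 1.70

    def vdw_radius(self, element: str) -> float:
        return VDW_RADII.get(element.upper(), self.default_vdw_radius)


@dataclass
class Contact:
    peptide_atom: AtomKey
    mhc_atom: AtomKey
    types: frozenset[str]
    distance: float


@dataclass
class ContactSet:
    """Qualifying peptide-MHC atom pairs for one structure and schema."""

    schema: str
    pairs: list[Contact]
    per_residue: dict[ResidueKey, int]  # peptide residue -> distinct pair count
    peptide_residues: list[ResidueKey]  # chain order
    peptide_sequence: str  # 1-letter, same order


def _interaction_types(
    elem_a: str, elem_b: str, distance: float, criteria: ContactCriteria
) -> set[str]:
    types: set[str] = set()
    if distance <= criteria.dist4:
        types.add("dist4")
    polar = {"N", "O"}
    if elem_a in polar and elem_b in polar and distance <= criteria.hbond:
        types.add("hb")
    if distance <= criteria.vdw_radius(elem_a) + criteria.vdw_radius(elem_b) + criteria.vdw_slack:
        types.add("vdw")
    if elem_a == "C" and elem_b == "C" and distance <= criteria.hydrophobic:
        types.add("phob")
    return types


def find_contacts(
    structure: Structure,
    peptide_chain: str,
    mhc_chains,
    schema: str,
    criteria: ContactCriteria | None = None,
) -> ContactSet:
    """Detect peptide-MHC heavy-atom contacts under a counting schema."""
    schema = schema.upper()
    if schema not in SCHEMAS:
        raise InputError(f"unknown contact schema {schema!r}; expected one of {SCHEMAS}")
    criteria = criteria or ContactCriteria()
    allowed = _SCHEMA_TYPES[schema]

    pep_residues = structure.chain_residues(peptide_chain)
    mhc_atoms: list[tuple[AtomKey, str, np.ndarray]] = []
    for cid in mhc_chains:
        for res in structure.chain_residues(cid):
            for atom in res.atoms.values():
                mhc_atoms.append((res.key + (atom.name,), atom.element, atom.coord))
    pep_atoms: list[tuple[ResidueKey, AtomKey, str, np.ndarray]] = []
    for res in pep_residues:
        for atom in res.atoms.values():
            pep_atoms.append((res.key, res.key + (atom.name,), atom.element, atom.coord))

    dist = cdist(
        np.array([a[3] for a in pep_atoms]), np.array([a[2] for a in mhc_atoms])
    )
    # longest reach of any criterion; pairs beyond it cannot qualify
    reach = max(
        criteria.dist4,
        criteria.hbond,
        criteria.hydrophobic,
        2 * max(VDW_RADII.values()) + criteria.vdw_slack,
    )

    pairs: list[Contact] = []
    per_residue: dict[ResidueKey, int] = {r.key: 0 for r in pep_residues}
    ii, jj = np.nonzero(dist <= reach)
    for i, j in zip(ii, jj):
        res_key, pep_key, pep_elem, _ = pep_atoms[i]
        mhc_key, mhc_elem, _ = mhc_atoms[j]
        d = float(dist[i, j])
        types = _interaction_types(pep_elem, mhc_elem, d, criteria)
        hit = types.intersection(allowed)
        if hit:
            pairs.append(Contact(pep_key, mhc_key, frozenset(hit), d))
            per_residue[res_key] += 1

    return ContactSet(
        schema=schema,
        pairs=pairs,
        per_residue=per_residue,
        peptide_residues=[r.key for r in pep_residues],
        peptide_sequence="".join(r.one_letter for r in pep_residues),
    )


CORE_LENGTH = 9


@dataclass
class ContactCountSet:
    """Per-core-position, per-amino-acid contact statistics.

    Q[i][s]     - number of structures with amino acid s at core position i
                  (i is 1-based, s is a 1-letter code);
    N[i]        - per-structure contact counts: list over structures of
                  (s, count) at position i;
    N_av[i][s]  - mean contact count of s at i across the structures it
                  occurs in;
    N_av        - grand mean contacts per core residue over all structures;
    E[i]        - amino acids observed at position i;
    w           - average contacts per core residue (the single-structure
                  free parameter; equals N_av).
    """

    n_structures: int
    Q: dict[int, dict[str, int]]
    N: dict[int, list[tuple[str, float]]]
    N_av_pos: dict[int, dict[str, float]]
    grand_mean: float
    core_length: int = CORE_LENGTH

    @property
    def E(self) -> dict[int, set[str]]:
        return {i: {s for s, q in self.Q[i].items() if q > 0} for i in self.Q}

    @property
    def w(self) -> float:
        return self.grand_mean

    @property
    def is_single(self) -> bool:
        return self.n_structures == 1


def locate_core(contact_set: ContactSet, core: str) -> list[ResidueKey]:
    """Residue keys of the leftmost match of a 9-mer core in the peptide."""
    if len(core) != CORE_LENGTH:
        raise InputError(f"core must be {CORE_LENGTH} residues, got {len(core)}")
    offset = contact_set.peptide_sequence.find(core.upper())
    if offset < 0:
        raise InputError(
            f"core {core!r} is not a substring of peptide "
            f"{contact_set.peptide_sequence!r}"
        )
    return contact_set.peptide_residues[offset : offset + CORE_LENGTH]


def count_core_contacts(items: list[tuple[ContactSet, str]]) -> ContactCountSet:
    """Aggregate contact counts over aligned 9-mer cores.

    ``items`` pairs each structure's :class:`ContactSet` with its core
    sequence (1-letter). The core is located in the peptide chain by
    leftmost match. Contact counts per core residue feed the PSSM builders.
    """
    if not items:
        raise InputError("no contact sets given")
    Q: dict[int, dict[str, int]] = {i: {} for i in range(1, CORE_LENGTH + 1)}
    N: dict[int, list[tuple[str, float]]] = {i: [] for i in range(1, CORE_LENGTH + 1)}
    all_counts: list[float] = []

    for contact_set, core in items:
        core = core.upper()
        keys = locate_core(contact_set, core)
        for pos, (s, key) in enumerate(zip(core, keys), start=1):
            n = float(contact_set.per_residue.get(key, 0))
            Q[pos][s] = Q[pos].get(s, 0) + 1
            N[pos].append((s, n))
            all_counts.append(n)

    n_av_pos: dict[int, dict[str, float]] = {}
    for pos in range(1, CORE_LENGTH + 1):
        by_aa: dict[str, list[float]] = {}
        for s, n in N[pos]:
            by_aa.setdefault(s, []).append(n)
        n_av_pos[pos] = {s: float(np.mean(v)) for s, v in by_aa.items()}

    return ContactCountSet(
        n_structures=len(items),
        Q=Q,
        N=N,
        N_av_pos=n_av_pos,
        grand_mean=float(np.mean(all_counts)),
    )
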