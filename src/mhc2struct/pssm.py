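"""Position-specific scoring matrices for 9-mer binding cores.

A PSSM here is a 20 amino acids x 9 core positions table. Two matrices for
HLA-DRB1*0101 are packaged:

* ``contact_dr0101`` - derived from atomic contact counts in six crystal
  complexes (natural-log units, unobserved cells = ln(0.05) = -3.00);
* ``md_dr0101``      - binding free energy contributions relative to alanine
  (kcal/mol) from MM-PBSA evaluation of MD snapshots.

For both, larger values mean stronger predicted binding, so core scanning
maximises the summed score.

Contact-derived matrices are built from :class:`~mhc2struct.contacts.
ContactCountSet` statistics. The per-cell score is ln(p(i,s) + r) with the
underflow constant r (default 0.05) added throughout, so that an amino acid
with zero observed contact probability scores exactly ln(r). p(i,s) is a
contact-enrichment quantity that can exceed 1:

* single structure: p(i,s) = N(s,i) / w for the amino acid observed at
  position i (w = average contacts per core residue), 0 for all others;
* several structures: p(i,s) = [Q(i,s) / sum_{s' in E(i)} Q(i,s')] x
  [N_av(s,i) / N_av], the frequency-times-enrichment composition of the
  defined symbols.
"""

from __future__ import annotations


from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .aminoacids import AA_ORDER_3, aa_index, to_three
from .contacts import CORE_LENGTH, ContactCountSet
from .errors import InputError, ParseError

PACKAGED_MATRICES = ("contact_dr0101", "md_dr0101")

DEFAULT_R = 0.05


@dataclass
class PSSM:
    """20 x 9 score matrix with provenance metadata."""

    values: np.ndarray  # (20, 9), rows in AA_ORDER_3 order
    allele: str = ""
    source: str = ""
    r: float | None = None
    name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, CORE_LENGTH):
            raise InputError(f"PSSM must be 20 x {CORE_LENGTH}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("PSSM contains non-finite values")

    def score(self, aa: str, position: int) -> float:
        """Score for an amino acid (1- or 3-letter) at core position 1..9."""
        if not 1 <= position <= CORE_LENGTH:
            raise InputError(f"core position must be 1..{CORE_LENGTH}, got {position}")
        return float(self.values[aa_index(aa), position - 1])


def build_pssm_single(counts: ContactCountSet, r: float = DEFAULT_R) -> PSSM:
    """PSSM from the contact counts of a single structure."""
    if not counts.is_single:
        raise InputError("build_pssm_single requires counts from exactly one structure")
    w = counts.w
    if w <= 0:
        raise InputError("no contacts anywhere (w = 0)")
    p = np.zeros((20, CORE_LENGTH))
    for pos in range(1, CORE_LENGTH + 1):
        [(s, n)] = counts.N[pos]
        p[aa_index(s), pos - 1] = n / w
    return PSSM(
        values=np.log(p + r), source="contact", r=r,
        description=f"contact PSSM from 1 structure, r={r}",
    )


def build_pssm_multi(counts: ContactCountSet, r: float = DEFAULT_R) -> PSSM:
    """PSSM from contact counts pooled over two or more structures."""
    if counts.n_structures < 2:
        raise InputError("build_pssm_multi requires counts from at least 2 structures")
    n_av = counts.grand_mean
    if n_av <= 0:
        raise InputError("no contacts anywhere (N_av = 0)")
    p = np.zeros((20, CORE_LENGTH))
    for pos in range(1, CORE_LENGTH + 1):
        q_sum = sum(counts.Q[pos].values())
        for s in counts.E[pos]:
            freq = counts.Q[pos][s] / q_sum
            enrich = counts.N_av_pos[pos][s] / n_av
            p[aa_index(s), pos - 1] = freq * enrich
    return PSSM(
        values=np.log(p + r), source="contact", r=r,
        description=f"contact PSSM from {counts.n_structures} structures, r={r}",
    )


def build_pssm(counts: ContactCountSet, r: float = DEFAULT_R) -> PSSM:
    """Dispatch to the single- or multi-structure builder."""
    if counts.is_single:
        return build_pssm_single(counts, r=r)
    return build_pssm_multi(counts, r=r)


def matrix_to_text(pssm: PSSM) -> str:
    """TSV serialization of a PSSM with 2-decimal values."""
    lines = []
    if pssm.allele:
        lines.append(f"#allele={pssm.allele}")
    if pssm.source:
        lines.append(f"#source={pssm.source}")
    if pssm.r is not None:
        lines.append(f"#r={pssm.r}")
    if pssm.description:
        lines.append(f"#description={pssm.description}")
    lines.append("aa\t" + "\t".join(str(i) for i in range(1, CORE_LENGTH + 1)))
    for row, aa in enumerate(AA_ORDER_3):
        vals = "\t".join(f"{pssm.values[row, col]:.2f}" for col in range(CORE_LENGTH))
        lines.append(f"{aa}\t{vals}")
    return "\n".join(lines) + "\n"


def write_matrix(pssm: PSSM, path) -> None:
    """Serialize a PSSM as TSV with 2-decimal values."""
    with open(path, "w") as fh:
        fh.write(matrix_to_text(pssm))


def _parse_matrix(text: str, name: str = "") -> PSSM:
    meta: dict[str, str] = {}
    rows: dict[str, list[float]] = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key] = val
            continue
        fields = line.split("\t")
        if fields[0] == "aa":
            continue
        aa = to_three(fields[0])
        if len(fields) != CORE_LENGTH + 1:
            raise ParseError(f"matrix row {aa} has {len(fields) - 1} columns, expected {CORE_LENGTH}")
        rows[aa] = [float(v) for v in fields[1:]]
    missing = [aa for aa in AA_ORDER_3 if aa not in rows]
    if missing:
        raise ParseError(f"matrix is missing rows: {missing}")
    values = np.array([rows[aa] for aa in AA_ORDER_3])
    r = float(meta["r"]) if "r" in meta else None
    return PSSM(
        values=values,
        allele=meta.get("allele", ""),
        source=meta.get("source", ""),
        r=r,
        name=name,
        description=meta.get("description", ""),
    )


def load_matrix(name_or_path: str) -> PSSM:
    """Load a packaged matrix by name (``contact_dr0101``/``md_dr0101``) or a TSV file."""
    if name_or_path in PACKAGED_MATRICES:
        text = (resources.files("mhc2struct.data") / f"{name_or_path}.tsv").read_text()
        return _parse_matrix(text, name=name_or_path)
    path = Path(name_or_path)
    if not path.exists():
        raise InputError(
            f"unknown matrix {name_or_path!r}; packaged matrices: "
            f"{', '.join(PACKAGED_MATRICES)}"
        )
    return _parse_matrix(path.read_text(), name=path.stem)


def read_matrix(path) -> PSSM:
    """Read a PSSM TSV written by :func:`write_matrix`."""
    return _parse_matrix(Path(path).read_text(), name=Path(path).stem)
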