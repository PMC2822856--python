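"""Scanning peptides for their best-scoring 9-mer binding core.

MHC class II peptides (typically 13-25 residues) bind through a 9-residue
core register. Every length-9 window of a peptide is scored by summing the
matrix values over positions 1..9, and the highest-scoring window is taken
as the predicted core (ties go to the smallest offset).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .aminoacids import ONE_TO_THREE
from .contacts import CORE_LENGTH
from .errors import InputError
from .pssm import PSSM


@dataclass(frozen=True)
class PredictionResult:
    peptide: str
    core: str
    offset: int  # 0-based start of the core within the peptide
    score: float
    matrix: str


def _validate_peptide(peptide: str) -> str:
    peptide = peptide.strip().upper()
    if len(peptide) < CORE_LENGTH:
        raise InputError(f"peptide too short ({len(peptide)} < {CORE_LENGTH}): {peptide!r}")
    bad = sorted(set(peptide) - set(ONE_TO_THREE))
    if bad:
        raise InputError(f"non-standard amino-acid code(s) {bad} in {peptide!r}")
    return peptide


def best_core(peptide: str, matrix: PSSM) -> PredictionResult:
    """Highest-scoring 9-mer window of a peptide under a PSSM."""
    peptide = _validate_peptide(peptide)
    best_offset, best_score = 0, -float("inf")
    for offset in range(len(peptide) - CORE_LENGTH + 1):
        window = peptide[offset : offset + CORE_LENGTH]
        score = sum(matrix.score(aa, pos) for pos, aa in enumerate(window, start=1))
        if score > best_score:
            best_offset, best_score = offset, score
    return PredictionResult(
        peptide=peptide,
        core=peptide[best_offset : best_offset + CORE_LENGTH],
        offset=best_offset,
        score=float(best_score),
        matrix=matrix.name or matrix.source,
    )


@dataclass
class BatchResult:
    results: pd.DataFrame  # peptide, core, offset, score, matrix
    rejects: pd.DataFrame  # peptide, reason


def predict_batch(peptides, matrix: PSSM) -> BatchResult:
    """Best-core predictions for many peptides, preserving input order.

    Invalid peptides (too short, non-standard characters) are routed to the
    rejects table with a reason instead of aborting the batch.
    """
    rows, rejects = [], []
    for pep in peptides:
        try:
            res = best_core(pep, matrix)
        except InputError as exc:
            reason = "too short" if "too short" in str(exc) else "non-standard character"
            rejects.append({"peptide": pep.strip().upper(), "reason": reason})
            continue
        rows.append(
            {
                "peptide": res.peptide,
                "core": res.core,
                "offset": res.offset,
                "score": res.score,
                "matrix": res.matrix,
            }
        )
    if not rows:
        raise InputError("no valid peptides in input")
    return BatchResult(
        results=pd.DataFrame(rows),
        rejects=pd.DataFrame(rejects, columns=["peptide", "reason"]),
    )


def read_peptides(text: str) -> list[str]:
    """Parse peptides from FASTA or one-per-line plain text."""
    text = text.strip()
    if not text:
        raise InputError("empty peptide input")
    if text.startswith(">"):
        records = SeqIO.parse(io.StringIO(text), "fasta")
        return [str(rec.seq) for rec in records]
    return [line.strip() for line in text.splitlines() if line.strip()]
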