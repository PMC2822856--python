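"""Distance-dependent statistical pair potential.

The potential is a knowledge-based pseudo-energy: for each residue-type pair
(a, b) and distance bin, u = -ln(P_obs / P_exp), where P_obs is the observed
distribution of (a, b) centroid distances in a training set of structures and
P_exp is the pooled distance distribution over all pairs (the type-independent
expectation). Favourable interactions therefore come out negative. A complex
is scored by summing u over all peptide x MHC residue pairs within a distance
cutoff; the negated sum is used for ranking so that larger = stronger
predicted binding.

Defaults follow the derivation conditions: 0.25 A bins, 20 A counting range,
minimum intra-chain sequence separation of 10 residues, steric penalty 2.0
below 1.0 A, and a 7.5 A scoring cutoff for the CM (side-chain centre of
mass) scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .aminoacids import AA_ORDER_3, aa_index
from .errors import InputError
from .structio import CentroidModel

N_AA = 20

#: value assigned to bins where a pair type was never observed but other
#: pairs were (a finite repulsive cap instead of +infinity)
ZERO_OBSERVATION_VALUE = 3.0


@dataclass
class PairCounts:
    """Binned observation counts of residue-pair centroid distances.

    ``counts[a, b, k]`` is symmetric in (a, b): every observed unordered
    pair increments both ordered cells, so ratios of counts are unaffected.
    """

    scheme: str
    bin_width: float
    max_distance: float
    separation_min: int
    counts: np.ndarray  # (20, 20, n_bins)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def total_counts(self) -> np.ndarray:  # per-bin pooled counts
        return self.counts.sum(axis=(0, 1))

    @property
    def pair_totals(self) -> np.ndarray:  # per-pair totals over bins
        return self.counts.sum(axis=2)

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())


@dataclass
class PairPotential:
    """20 x 20 x bins table of potential values (natural-log units)."""

    scheme: str
    bin_width: float
    max_distance: float
    u: np.ndarray  # (20, 20, n_bins)
    steric_cutoff: float = 1.0
    steric_penalty: float = 2.0
    scoring_cutoff: float = 7.5
    provenance: dict = field(default_factory=dict)

    def value(self, aa1: str, aa2: str, distance: float) -> float:
        """Potential for a residue pair at a given centroid distance (A).

        Distances below the steric cutoff return the steric penalty;
        distances at or beyond ``max_distance`` contribute 0.
        """
        if distance < self.steric_cutoff:
            return self.steric_penalty
        if distance >= self.max_distance:
            return 0.0
        k = int(distance / self.bin_width)
        return float(self.u[aa_index(aa1), aa_index(aa2), k])


def count_pairs(
    models: list[CentroidModel],
    bin_width: float = 0.25,
    max_distance: float = 20.0,
    separation_min: int = 10,
) -> PairCounts:
    """Count residue-pair distance observations over centroid models.

    Intra-chain pairs are counted only when the residues are at least
    ``separation_min`` apart in the chain's sequence order (non-local
    interactions); inter-chain pairs within a structure carry no separation
    filter. Distances d < ``max_distance`` fall in bin floor(d/bin_width).
    """
    if not models:
        raise InputError("empty structure list")
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    scheme = models[0].scheme
    if any(m.scheme != scheme for m in models):
        raise InputError("all centroid models must share one scheme")

    n_bins = int(math.ceil(max_distance / bin_width))
    counts = np.zeros((N_AA, N_AA, n_bins))

    for model in models:
        coords = model.coords
        types = model.type_indices
        chain_ids = np.array([e.chain_id for e in model.entries])
        # sequence index within each chain, in entry order
        seq_index = np.zeros(len(chain_ids), dtype=int)
        for cid in model.chains:
            mask = chain_ids == cid
            seq_index[mask] = np.arange(mask.sum())

        dist = cdist(coords, coords)
        same_chain = chain_ids[:, None] == chain_ids[None, :]
        sep_ok = np.abs(seq_index[:, None] - seq_index[None, :]) >= separation_min
        include = np.triu(np.ones_like(same_chain), k=1).astype(bool)
        include &= (~same_chain) | sep_ok
        include &= dist < max_distance

        ii, jj = np.nonzero(include)
        kk = (dist[ii, jj] / bin_width).astype(int)
        np.add.at(counts, (types[ii], types[jj], kk), 1.0)
        np.add.at(counts, (types[jj], types[ii], kk), 1.0)

    return PairCounts(
        scheme=scheme,
        bin_width=bin_width,
        max_distance=max_distance,
        separation_min=separation_min,
        counts=counts,
    )


def derive_potential(
    counts: PairCounts,
    steric_cutoff: float = 1.0,
    steric_penalty: float = 2.0,
    scoring_cutoff: float = 7.5,
    zero_observation_value: float = ZERO_OBSERVATION_VALUE,
) -> PairPotential:
    """Turn pair counts into a potential: u = -ln(P_obs / P_exp).

    P_obs(k | a, b) = counts[a,b,k] / pair_totals[a,b]; P_exp(k) =
    total_counts[k] / grand_total (type-independent expectation). Bins where
    the pair type was never seen but the pooled bin is populated get a finite
    repulsive cap; bins below the steric cutoff carry the steric penalty;
    bins with no pooled data at all are left at 0 (no information).
    """
    grand = counts.grand_total
    if grand == 0:
        raise InputError("count table is empty")

    c = counts.counts
    pair_tot = counts.pair_totals[:, :, None]  # (20, 20, 1)
    total_k = counts.total_counts[None, None, :]  # (1, 1, n_bins)

    u = np.zeros_like(c)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (c / pair_tot) / (total_k / grand)
    populated = (c > 0) & (pair_tot > 0) & (total_k > 0)
    u[populated] = -np.log(ratio[populated])

    zero_obs = (c == 0) & (pair_tot.repeat(c.shape[2], axis=2) > 0) & (
        np.broadcast_to(total_k, c.shape) > 0
    )
    u[zero_obs] = zero_observation_value

    steric_bins = int(math.ceil(steric_cutoff / counts.bin_width))
    u[:, :, :steric_bins] = steric_penalty

    return PairPotential(
        scheme=counts.scheme,
        bin_width=counts.bin_width,
        max_distance=counts.max_distance,
        u=u,
        steric_cutoff=steric_cutoff,
        steric_penalty=steric_penalty,
        scoring_cutoff=scoring_cutoff,
        provenance={
            "n_observations": grand,
            "separation_min": counts.separation_min,
        },
    )


@dataclass(frozen=True)
class ComplexScore:
    raw: float  # sum of u over interacting pairs (lower = more favourable)
    ranking: float  # negated sum (higher = stronger predicted binding)
    n_pairs: int


def score_complex(
    peptide: CentroidModel,
    mhc: CentroidModel,
    potential: PairPotential,
    cutoff: float | None = None,
) -> ComplexScore:
    """Score a peptide:MHC complex with a derived potential.

    Sums u over all peptide-residue x MHC-residue pairs with centroid
    distance <= cutoff (default: the potential's scoring cutoff, 7.5 A for
    CM). Only inter-molecular pairs contribute.
    """
    if peptide.scheme != potential.scheme or mhc.scheme != potential.scheme:
        raise InputError(
            f"scheme mismatch: potential is {potential.scheme}, models are "
            f"{peptide.scheme}/{mhc.scheme}"
        )
    if cutoff is None:
        cutoff = potential.scoring_cutoff

    dist = cdist(peptide.coords, mhc.coords)
    ii, jj = np.nonzero(dist <= cutoff)
    pep_types = peptide.type_indices
    mhc_types = mhc.type_indices
    total = 0.0
    for i, j in zip(ii, jj):
        total += potential.value(
            AA_ORDER_3[pep_types[i]], AA_ORDER_3[mhc_types[j]], float(dist[i, j])
        )
    return ComplexScore(raw=float(total), ranking=float(-total), n_pairs=len(ii))


def write_potential(potential: PairPotential, path) -> None:
    """Serialize a potential as TSV (one row per pair type and bin)."""
    lines = [
        f"#scheme={potential.scheme}",
        f"#bin_width={potential.bin_width}",
        f"#max_distance={potential.max_distance}",
        f"#steric_cutoff={potential.steric_cutoff}",
        f"#steric_penalty={potential.steric_penalty}",
        f"#scoring_cutoff={potential.scoring_cutoff}",
        "aa1\taa2\tbin_index\tbin_lo_A\tu",
    ]
    for a in range(N_AA):
        for b in range(a, N_AA):
            for k in range(potential.u.shape[2]):
                val = potential.u[a, b, k]
                if val == 0.0:
                    continue
                lines.append(
                    f"{AA_ORDER_3[a]}\t{AA_ORDER_3[b]}\t{k}\t"
                    f"{k * potential.bin_width:.2f}\t{val:.6f}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_potential(path) -> PairPotential:
    """Read a potential written by :func:`write_potential`."""
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
            elif not line.startswith("aa1\t"):
                rows.append(line.split("\t"))
    bin_width = float(meta["bin_width"])
    max_distance = float(meta["max_distance"])
    n_bins = int(math.ceil(max_distance / bin_width))
    u = np.zeros((N_AA, N_AA, n_bins))
    for aa1, aa2, k, _lo, val in rows:
        a, b, kk, v = aa_index(aa1), aa_index(aa2), int(k), float(val)
        u[a, b, kk] = v
        u[b, a, kk] = v
    return PairPotential(
        scheme=meta["scheme"],
        bin_width=bin_width,
        max_distance=max_distance,
        u=u,
        steric_cutoff=float(meta["steric_cutoff"]),
        steric_penalty=float(meta["steric_penalty"]),
        scoring_cutoff=float(meta["scoring_cutoff"]),
    )
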