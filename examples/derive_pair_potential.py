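"""Derive a distance-dependent statistical pair potential and score a complex.

Generates a synthetic training set in which short-range (< 4 A) LYS-ASP
pairs are exactly twice as frequent as the type-independent expectation,
derives the potential u = -ln(P_obs / P_exp), and shows that the LYS-ASP
short-range well comes out at -ln 2 = -0.693 while type-independent bins
stay near zero.
"""

import math

import numpy as np

from mhc2struct import (
    count_pairs,
    derive_potential,
    make_potential_training_set,
    read_structure,
    reduce,
)
from mhc2struct.aminoacids import aa_index

print("generating 800 training chains with an enriched K-D short-range signal...")
texts = make_potential_training_set(800, type_dependent=True, seed=42)
models = [reduce(read_structure(t), "CM") for t in texts]

counts = count_pairs(models, bin_width=0.5, max_distance=20.0, separation_min=10)
potential = derive_potential(counts)

k, d = aa_index("LYS"), aa_index("ASP")
print(f"\n{'bin (A)':<12}{'u(K,D)':>8}")
for b in range(6, 14):
    lo = b * 0.5
    print(f"{lo:.1f}-{lo + 0.5:<6.1f}{potential.u[k, d, b]:>8.3f}")
print(f"\n-ln 2 = {-math.log(2):.3f}: the designed short-range well is recovered.")
print(f"steric penalty below 1 A: u = {potential.value('LYS', 'ASP', 0.5)}")

# the same potential scores peptide:MHC complexes by summing u over all
# inter-chain residue pairs within the 7.5 A cutoff
from mhc2struct import score_complex
from mhc2struct.structio import CentroidEntry, CentroidModel

pep = CentroidModel("CM", [CentroidEntry("C", 1, "", "LYS", np.zeros(3))])
mhc = CentroidModel(
    "CM",
    [CentroidEntry("A", 1, "", "ASP", np.array([3.7, 0.0, 0.0])),   # in the well
     CentroidEntry("A", 2, "", "ASP", np.array([0.0, 6.2, 0.0]))],  # long range
)
result = score_complex(pep, mhc, potential, cutoff=7.5)
print(
    f"\none LYS against two ASP centroids (3.7 A and 6.2 A): raw sum "
    f"{result.raw:.3f} over {result.n_pairs} pairs\n"
    f"(ranking score {result.ranking:.3f}; higher = stronger predicted binding)"
)
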