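# Methods

This note documents the models implemented in `mhc2struct`, the numerical
choices behind them, what the synthetic fixtures emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structure handling and reduced models

PDB text is parsed with Bio.PDB behind the `structio` surface. Only the 20
standard amino acids and heavy atoms are retained; waters, hetero groups
(including MSE, which is dropped rather than remapped to MET — a
conservative choice) and hydrogens are discarded. For alternate locations
the highest-occupancy conformer wins, ties going to the alphabetically
first altloc. A pre-scan of ATOM records validates the fixed-width
coordinate fields so parse errors can name the offending line. By default
only the first MODEL is read; multi-model files serve as trajectory
containers in an opt-in trajectory mode. Within a chain, residues are
ordered by (residue number, insertion code), insertion codes sorting
alphabetically after the bare number.

Residues reduce to one interaction centre per residue:

* **Cα** — the alpha carbon;
* **Cβ** — the beta carbon; for glycine a virtual Cβ is constructed from
  N, CA, C using the standard tetrahedral direction for an L-amino acid at
  a CA–Cβ bond length of 1.522 Å (direction coefficients as used widely in
  backbone-only structure modelling);
* **Cm** — the unweighted mean of the heavy side-chain atoms. Glycine has
  none and uses the virtual Cβ; any other residue with a fully missing side
  chain also falls back to the virtual Cβ, with a logged warning, so every
  residue stays scoreable.

Superposition is the closed-form Kabsch fit (SVD with determinant
correction, so the rotation is always proper); the test suite checks it
against an independent numerical minimisation over rotation vectors.
Backbone RMSF is computed per residue over the atoms CA, C, N, O: each
atom's root-mean-square deviation from its across-frame mean position,
then the arithmetic mean over the four atoms. Frames are assumed to be
pre-superposed; the suite demonstrates that a rigid shift of one frame
inflates RMSF, which is why the requirement is documented rather than
hidden. The RMSD utility takes an explicit chain selection instead of
guessing which atoms a trajectory was aligned on.

## Statistical pair potential

Counting: for every pair of residues in a structure with centroid distance
d < 20 Å, the count for (type a, type b, bin ⌊d/0.25 Å⌋) is incremented
symmetrically. Intra-chain pairs require a sequence-index separation of at
least 10 (the potential is meant to capture non-local contacts of the kind
a peptide makes with another chain); inter-chain pairs within a structure
carry no separation filter. Whether a training set of single-chain globular
proteins ever exercises the inter-chain branch is moot, but the behaviour
is defined and tested.

Derivation: u(a,b,k) = −ln[(c_abk / c_ab·) / (c_··k / c_···)] — the
observed distance distribution of each pair type against the pooled
distribution over all types. The sign convention makes enrichment
(attraction) negative, which matches the physical expectation that a
favourable K–D salt bridge shows an energy *minimum* at short range. The
negated sum is exposed as the ranking score so that bigger = stronger
predicted binding, as users of binding predictors expect.

Numerical choices:

* bins below the 1.0 Å steric cutoff are set to the steric penalty 2.0;
* bins where a pair type was never observed but other pairs were get a
  finite repulsive cap of +3.0 (≈ −ln of a 0.05 pseudo-ratio) instead of
  +∞, keeping scores finite;
* bins with no pooled data at all stay at 0 (no information);
* a distance exactly on a bin edge goes to the upper bin via floor
  division; d ≥ 20 Å is ignored during counting, and scoring uses its own
  cutoff (default 7.5 Å, the operative value for Cm centres; Cα/Cβ
  potentials are conventionally scored to 20 Å).

Scoring a complex sums u over all peptide-residue × MHC-residue pairs with
d ≤ cutoff. Homology modelling of complexes for peptides without solved
structures (and the average-over-models protocol that goes with it) is out
of scope; `score_complex` consumes user-supplied 3D complexes.

## Contact-map PSSM

Contact schemas: DIST4 (any heavy-atom pair ≤ 4.0 Å), HB (N/O–N/O ≤ 3.5 Å,
no angular term since crystal structures lack hydrogens), HB_VDW (adds
pairs within r_vdw(a) + r_vdw(b) + 0.5 Å using Bondi radii), and
HB_VDW_PHOB (adds carbon–carbon pairs ≤ 4.5 Å). These geometric definitions
and thresholds are this implementation's choices and are config-exposed
through `ContactCriteria`; schema nesting (HB ⊆ HB_VDW ⊆ HB_VDW_PHOB) holds
by construction, and an atom pair is counted once however many types it
satisfies. A residue's contact count is the number of atom pairs its atoms
participate in. The 9-mer core is located in the peptide chain by leftmost
sequence match.

Matrix construction uses score(s, i) = ln(p(i, s) + r), natural log,
r = 0.05. The constant is added always (not only at p = 0) for smoothness;
both conventions reproduce the −3.00 of unobserved cells. p(i, s) is:

* one structure: N(s,i) / w for the amino acid observed at position i,
  where w is the average number of contacts per core residue; 0 otherwise;
* several structures: [Q(i,s) / Σ_{s'∈E(i)} Q(i,s')] × [N_av(s,i) / N_av],
  an occurrence-frequency term times a contact-enrichment term. This
  composition is the dimensionally consistent combination of the defined
  symbols (Q: occurrences of s at i; E(i): amino acids seen at i; N_av(s,i):
  mean contacts of s at i; N_av: grand mean contacts per core residue), and
  it degenerates exactly to the single-structure rule when one structure is
  duplicated n times — asserted as a test.

Because p is an enrichment ratio it may exceed 1, consistent with packaged
matrix cells up to +2.36. The packaged `contact_dr0101` values are shipped
verbatim; regenerating them from the original crystal structures would
require the original (undisclosed) geometric contact criteria, so the
builders are validated against synthetic structures with known contact
counts instead.

## Core scanning and evaluation

Every window of length 9 is scored by summing matrix values over positions
1–9; the maximum wins and ties break to the smallest offset. Peptides
shorter than 9 are rejected (batch mode routes them to a rejects table with
a reason rather than aborting). Both packaged matrices are maximised —
the MD matrix is signed so that positive favours binding.

Binders are IC50 < 1000 nM, strictly; exactly 1000 nM is a non-binder. AUC
is the Mann–Whitney statistic with tied scores credited 0.5, computed from
midranks, which equals the trapezoidal area under the tie-aware ROC; the
suite checks it against quadratic pair counting and scikit-learn. The
Hanley–McNeil standard error uses Q1 = A/(2−A), Q2 = 2A²/(1+A); the
identity SE(A, n₊, n₋) = SE(1−A, n₋, n₊) holds exactly and is asserted.
For correlations against affinity, IC50 is mapped through
1 − ln(IC50)/ln(50000), clamped to [0, 1] (the transform ceiling is
config-exposed since conventions vary).

## Synthetic fixtures: what they emulate and what they do not

`make_toy_complex` emits a peptide laid out as a stretched strand (7 Å
CA–CA spacing) with MHC scaffold glycines far below and, per peptide
residue, an exact number of contact pseudo-residues whose CA sits 3.9 Å
above that residue's CA on a 0.4 Å ring — inside the 4 Å DIST4 criterion
for exactly one atom pair, while every other MHC atom stays > 4 Å (scaffold
and contact-residue backbones > 6 Å) from every peptide atom. Contact
counts are therefore achieved *exactly*, which is what makes the contact
tabulation and PSSM builders testable. The geometry is self-consistent but
deliberately unphysical (no peptide-bond continuity, stretched pseudo-
residues); optional Gaussian noise is applied only to the remote scaffold,
never to the contact geometry.

`make_potential_training_set` emits 29-residue "dumbbell" chains: two tight
10-residue clusters separated by a controlled distance d ∈ (3.1, 6.9) Å,
with 9 filler residues placed 20.5 Å off-axis. Only head×tail pairs pass
the sequence-separation filter within the 20 Å counting range, so each
chain contributes exactly 100 counted pairs at separation ≈ d; chains are
packed on a 45 Å grid (25 per PDB text) so inter-chain pairs exceed the
counting range. In the null model, cluster residue types (LYS/ASP) are
drawn independently of d, so the derived potential tends to 0 in every
populated bin. In the type-dependent model the head is all-LYS and tail
residues are ASP with probability 0.75 below 4 Å and a long-range
probability solved from the sampling measures so that the short-range
LYS–ASP pair density is exactly twice the pooled density — the derived
potential there is −ln 2 in expectation, a closed-form target the tests
check to ±0.1. Problem sizes in the suite (3000 chains for the null check,
1600 for the enriched check) were fixed by a pre-registered power analysis
of the estimator's clustering variance: at those sizes the across-seed
standard deviation of a bin's u is ≈ 0.02–0.03, leaving a > 3σ margin
inside the ±0.1 band.

`make_affinity_dataset` draws binder scores from N(d, 1) and non-binder
scores from N(0, 1), so the expected AUC is Φ(d/√2) in closed form; IC50s
are drawn log-uniformly strictly below / at-or-above the 1000 nM threshold.
Defaults (2939 binders, 943 non-binders, d = 0.669 ⇒ expected AUC ≈ 0.682)
mirror the composition of a large published HLA-DRB1*0101 benchmark.

Passing tests on these fixtures establishes that the counting, derivation,
scanning and evaluation machinery is arithmetically correct and
statistically calibrated. They do **not** establish predictive performance
on real peptides: real training structures have correlated geometry and
composition, real contact maps depend on the chosen geometric criteria,
and the published benchmark AUCs additionally depend on an external
3,882-peptide dataset and homology-modelled complexes, none of which are
bundled. Those headline numbers are therefore documented but not
recomputed.

## Known limitations

* mmCIF input, hydrogen placement and symmetry expansion are unsupported.
* Hydrogen-bond detection has no angular term and treats all N/O atoms as
  donors/acceptors.
* Flanking (±1) peptide residues contribute to binding in reality but no
  scoring scheme for them is implemented; scanning is a plain window
  enumeration with no special treatment of termini.
* The pair potential's expected distribution is the pooled bin distribution
  of the same count table; very sparse training sets will produce many
  capped (+3.0) bins.
* `PairCounts` stores ordered (symmetric) counts; all ratios are invariant
  to this convention but raw totals are twice the unordered pair count.
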