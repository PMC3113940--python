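# Methods

This note documents the models and algorithmic choices behind
`stabscan`: what is computed, which decisions were genuinely open and
how they were settled, and what the synthetic validation world does and
does not establish about real data.

## Residue descriptors

Each parsed residue carries four descriptors:

* **s** — amino-acid type, one of the 20 standard residues.  Residues
  lacking any of N, Cα, C, or with non-standard names, are excluded
  before any other computation (including solvent occlusion).
* **t** — backbone torsion domain.  (φ, ψ) is mapped onto a fixed
  seven-domain partition of the Ramachandran plane (`helical`,
  `extended`, `polyproline`, `left_helical`, `gamma`, `epsilon`,
  `other`; boundaries are constants in `stabscan.constants`).  Chain
  termini and chain breaks (no peptide bond within 1.9 Å) receive
  `undefined`, which is outside the potential alphabet: such residues
  are skipped (and tallied) when deriving or evaluating torsion-bearing
  terms.  The partition is a documented stand-in: the literature
  formalism this family of potentials descends from does not publish a
  normative alphabet.
* **a** — relative solvent accessibility in percent: Shrake–Rupley
  SASA (probe 1.4 Å, 960 sphere points per atom, Biopython
  implementation) divided by the residue type's reference area in an
  extended Gly-X-Gly tripeptide (Tien et al. 2013 theoretical values),
  clipped to [0, 100].  Doubling the point count moves values by well
  under 2 percentage points on test fixtures.  Note that any
  fixed-orientation sphere quadrature is only rotationally invariant to
  its angular resolution; rotating a structure perturbs `a` by up to
  ~1 percentage point at 960 points, while torsion labels and pair
  distances are rotation-exact.
* **d** — distance between side-chain geometric centres (unweighted
  mean of side-chain heavy atoms; Cα for glycine or when no side-chain
  atom is resolved).  Pairs are recorded up to 8 Å; pairs fewer than 2
  positions apart along the same chain are excluded, the standard
  convention for tertiary distance potentials.

Author residue numbering and insertion codes are preserved verbatim in
all I/O; internal indexing is 0-based.  Only MODEL 1 of multi-model
files is read and alternate locations resolve to the highest-occupancy
conformer.

## Statistical potentials

Frequencies are accumulated over a structure collection with the
default discretization: accessibility bins at 0–5–15–30–50–100 %,
distance bins of 0.5 Å over 3.0–8.0 Å, the seven-state torsion
alphabet, 20 amino-acid states.  A two-group coupling energy is the
inverse-Boltzmann log-ratio

    W(v, w) = −kT ln [ P(v, w) / (P(v) P(w)) ]

and a three-group coupling is the residual three-way dependence beyond
all pairwise ones,

    W(v, w, x) = −kT ln [ P(vwx) P(v) P(w) P(x) / (P(vw) P(vx) P(wx)) ].

Probabilities come from smoothed counts: a pseudocount (default 1) is
added to every joint cell and all marginals derive from the smoothed
joint, so energies are finite on arbitrarily sparse data and exactly
uniform counts give identically zero energies.  With the pseudocount
set to zero, counts whose joint factorizes exactly into marginals give
zero energies — the zero-information null.  kT is fixed at
0.593 kcal/mol (298 K); the constant only rescales energies linearly
and is absorbed by the trained weights.

The thirteen terms and their descriptor-group composition
(`stabscan.potentials.TERM_GROUPS`): single-residue couplings st, as
and ast; distance couplings sd, sds, asd, std; cross-residue couplings
over contact pairs stt = (s_i, t_i, t_j), sst = (s_i, s_j, t_j),
aas = (a_i, a_j, s_j), ass = (a_i, s_i, s_j); and the two composite
distance couplings asdas = ((a,s)_i, d, (a,s)_j) and
stdst = ((s,t)_i, d, (s,t)_j), implemented as triplet couplings of the
composite pair states.  Pair terms are counted and evaluated over both
orientations of every recorded pair, which keeps derivation and
evaluation mutually consistent.  The exact composition of the mixed
cross-residue terms is an interpretation fixed by this package, not a
reproduction of any published table.  Higher-order couplings are
deliberately not implemented.

The mutation-level ΔΔW substitutes the amino-acid type at one position
while holding t, a, d and all partners at wild-type values.  Because
contributions not involving the mutated position cancel, the
implementation sums only the changed contributions; its equality with
a full mutant-vs-wild rescoring of the structure (to 1e-9 kcal/mol) is
enforced by tests for all thirteen terms.

## Prediction model

ΔΔG_P = Σ_{i=1..13} α_i(A) ΔΔW_i + α_14(A) ΔV₊ + α_15(A) ΔV₋ + α_16(A),
with α_i(A) = f_i / (1 + exp(−r_i (A − c_i))) + b_i.  Parameters per
coefficient: inflection c_i (percent accessibility), slope r_i (per
percent), scaling f_i, shift b_i.  All sixteen coefficients, including
the independent term, are accessibility-dependent.  Residue volumes are
the Zamyatnin/Chothia-style crystallographic means (Å³).  Mutant
structural descriptors are inherited from the wild type — the model
never relaxes the backbone, which is also why mutations involving
proline are only flagged (predicted but marked low-confidence) rather
than modelled: proline rewrites the local backbone.  Self-mutations are
rejected: the independent term would give them a nonzero ΔΔG_P.

## Training

The objective is σ = sqrt((1/N) Σ (ΔΔG_M − ΔΔG_P)²) over a filtered
mutant table.  The filter drops mutations involving proline on either
side, mutations with measured destabilization above +5 kcal/mol (likely
to involve rearrangements outside the model), and records flagged as
heme-protein or pseudo-wild-type measurements.

The model is linear in the raw terms and nonlinear only through the
sigmoids, so fitting is bounded nonlinear least squares (scipy `trf`)
with an analytic Jacobian over the active parameters.  Bounds:
c ∈ [0, 100], r ∈ [−5, 5], f, b ∈ [−60, 60]; per-kind scaling
(c scaled by 10, r by 0.1) conditions the trust region.  Each of the
default 8 restarts draws a data-driven initialization — vertical shifts
from an ordinary least-squares solve of the linearized (r = 0) model,
inflections uniform in [5, 60] %, slopes uniform in [−0.35, 0.35] — and
the best restart wins.  Tolerances 1e-11 with at most 600 residual
evaluations per restart; on zero-noise closed-loop data the fit reaches
σ ≈ 1e-16, and fits are bit-reproducible given the seed.  The recorded
history is the best objective after each restart, nonincreasing by
construction.

**Parameter reduction.**  Active-parameter uncertainty is measured as
the coefficient of variation across warm-started refits on bootstrap
resamples (default 20).  While any slot exceeds the threshold (default
1.0), the worst is frozen — a scaling factor f to 0, collapsing its
sigmoid to the constant b; any other slot to its bootstrap mean — and
the model is refit; the active count strictly decreases.  On data
generated with coefficients truly constant in accessibility, the
procedure freezes exactly those coefficients' slope and scale.  Which
parameters freeze on real data depends on the dataset; the procedure is
ours and makes no claim of matching any historical parameter set.

**Validation protocol.**  k-fold cross-validation (default 5) with a
seeded random partition (a protein-grouped option keeps all mutants of
one structure in the same fold).  Per run it reports Pearson R and RMSE
σ on the training set (R_d, σ_d) and the held-out set (R_c, σ_c), both
in full and after trimming the ⌈10 %·N⌉ pairs with the largest absolute
error.  A second training round removes from the training folds all
records whose error exceeds 1.5 kcal/mol in *every* initial run (the
intersection of per-run outlier sets) and refits; validation folds are
untouched so the second-round averages are directly comparable.
Supporting metrics: RMSE binned in 0.25 kcal/mol intervals along the
predicted or measured axis (bins under 10 pairs dismissed), the
fraction of predicted-stabilizing mutations that are truly stabilizing,
and two reference baselines — a seeded shuffle of the measured values
scored against the originals, and the constant mean predictor, whose
RMSE equals the population standard deviation of the measurements.

## The synthetic world

Experimental ΔΔG compilations of the scale needed for training are not
redistributable, so validation runs against a generating model with
known ground truth:

* **Toy structures** are ideal-geometry backbones grown residue by
  residue from motif (φ, ψ) values — helix (−57, −47), sheet
  (−135, 135), or alternating blocks — with seeded Gaussian jitter of
  5° (clipped at 12° so motif residues stay inside their torsion
  domain).  Side chains are single pseudo-centroid atoms at
  tetrahedral-direction, volume-scaled distances from Cα.  Output is
  valid PDB text, byte-deterministic given the seed.
* **Ground-truth parameters** (`default_truth_parameters`) contrast a
  buried-core and an exposed-surface regime, make the volume terms
  strongest in the core, and keep four coefficients (aas, ast, std,
  stdst) genuinely constant in accessibility so the reduction procedure
  has real targets.  They were calibrated once so that simulated ΔΔG
  values are majority-destabilizing (~80 % positive) over roughly
  −2 to +5 kcal/mol with a modest stabilizing tail, echoing the shape
  of experimental mutant compilations.
* **Simulated datasets** draw distinct mutations uniformly (prolines
  excluded on both sides), add Gaussian noise (default sd
  0.3 kcal/mol), and exclude at the source anything beyond the
  +5 kcal/mol training cutoff, so the tables pass the dataset filter
  unchanged.

What this world does *not* emulate: tertiary packing (toy chains are
single secondary-structure elements, so genuinely buried cores are
rare and the accessibility range is compressed), real side-chain
geometry and rotamers, correlated experimental error, and the
heterogeneity of real mutant compilations.  Passing the closed-loop
and recovery tests therefore demonstrates the correctness of the
machinery — descriptors, potentials, combination, optimization,
protocol — not the predictive accuracy of any particular trained model
on real proteins, which depends entirely on the structures and
measurements supplied.

## Sequence optimality

Γ_i sums the strictly negative predicted ΔΔG values over the 19
substitutions at position i; a prediction of exactly zero contributes
nothing.  Weakness flagging uses Γ ≤ threshold (default −5 kcal/mol);
stratification tables use strict Γ < threshold, so the two conventions
match their customary uses.  Stratification accepts arbitrary
user-supplied position labels (e.g. catalytic vs. other) and an
optional core/surface split at 10 % relative accessibility (a = 10 %
counts as surface).  Secondary-structure labels for plotting are an
optional external annotation; the package does not assign secondary
structure.

## Problem sizes

The shipped tests and the acceptance script run the pipeline at sizes
chosen for routine single-CPU execution: a shared world of 3 × 30- or
6 × 40-residue structures; cross-validation on 1200 simulated mutants;
parameter recovery on 2000 training and 500 held-out mutants at noise
sd 0.3, where the fit reaches held-out R ≈ 0.999 against the noiseless
truth and RMSE at the noise floor.  All sizes are arguments, and scale
linearly in mutants and roughly quadratically in residues per
structure.  Mutant sets much smaller than ~1000 can leave accessibility
gaps in a fold's training data, and sigmoid coefficients are
unconstrained outside the observed accessibility range — held-out
mutants falling into such a gap can then be predicted wildly.  This is
the usual failure mode of extrapolating a flexible weighting function
and is visible as a large spread between trimmed and untrimmed
validation RMSE.

## Known limitations

* Fixed backbone: mutations that rearrange the structure (notably
  prolines) are outside the model; they are flagged, not modelled.
* The torsion alphabet, binning, pseudocount and term composition are
  this package's documented choices; potentials derived here are not
  numerically comparable to any published potential set.
* Sparse structure collections give noisy potentials; the pseudocount
  keeps them finite but shrinks contrasts toward zero.
* The bootstrap reduction measures dispersion relative to magnitude;
  parameters whose true value is near zero are frozen readily, which
  is intended but means "frozen" is not evidence of irrelevance.
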