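# Methods

## Model

The package scores peptide binding to an MHC class II groove through
structural observables of the 9-residue core.  Two observables are counted
per frame of a conformational ensemble and per core position:

* **Contacts** — pairs of heavy atoms, one from the core residue and one
  from either receptor chain, with Euclidean distance ≤ 4.0 Å.  The
  boundary is inclusive (`d ≤ cutoff` counts); hydrogens are excluded by
  default because crystal-derived frames rarely carry them, which keeps the
  count deterministic across inputs with and without hydrogens (a flag
  enables all-atom counting).
* **Main-chain hydrogen bonds** — bonds whose peptide-side partner is a
  backbone atom: the amide N donating to any receptor acceptor, or the
  carbonyl O accepting from any receptor donor.  A bond requires
  donor–acceptor distance ≤ 3.9 Å, hydrogen–acceptor distance ≤ 2.5 Å and
  donor–H–acceptor angle ≥ 90°; the two auxiliary angle criteria
  (H–A–antecedent, D–A–antecedent) are implemented but off by default.
  These defaults mirror the geometry commonly used by hydrogen-bond
  detection programs for protein structures and are configurable through
  `HBondCriteria`.

Missing amide hydrogens are placed geometrically: 1.00 Å from N, in the
C(i−1)–N–CA plane, opposing the bisector of the two bonds.  Prolines and
chain-start residues cannot donate.  Receptor side-chain donors without an
explicit or placeable hydrogen fall back to the donor–acceptor distance
criterion alone; this is the only point where the criteria are relaxed, it
is applied identically in the test oracles, and it errs toward counting a
plausible bond rather than silently dropping donors.

Averaging over runs α (one per peptide) and the N_f selected frames gives
O_ij, and E_ij = −ln(O_ij / Σ_j O_ij) the scoring energy; Σ_j exp(−E_ij) = 1
per position by construction.  N_f is read as the per-run selected-frame
count and must be identical across runs — within-position normalization
makes any constant-N_f convention equivalent, and requiring equality keeps
mixed-strategy accumulations from silently reweighting runs.  Because E is
scale-free in O, global rescaling of the observables (with the pseudocount
scaled accordingly) leaves E unchanged.

Frame selection strategies: `all`, `last_half` (last ⌈N/2⌉ in order),
`best_energy_half` (⌈N/2⌉ lowest per-frame energies; ties broken toward the
lower frame index via a stable sort), `best_energy_one`.  Energies come
from a two-column sidecar table rather than PDB REMARK parsing, which is
dialect-prone.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| contact cutoff | 4.0 | Å | standard non-bonded contact threshold for protein interfaces |
| D–A max | 3.9 | Å | donor–acceptor cap of common geometric H-bond criteria |
| H–A max | 2.5 | Å | hydrogen–acceptor cap |
| D–H–A min | 90 | degrees | permissive angular floor |
| pseudocount | 1e-6 × per-position max cell | observable units | keeps E finite for unseen (i, j) cells without perturbing observed ones |
| dihedral bins | 36 × 10° over [−180, 180) | degrees | fixed circular binning; no smoothing |
| KL pseudocount | 1/(n_samples · n_bins) | probability | regularizes empty bins; D(p‖p) stays exactly 0 |
| bootstrap replicas | 50 | — | reporting convention; SD is the sample SD (ddof = 1) over replicate match fractions |

Sign conventions: activity is nM-like (lower = stronger), so the
experimental sign of a mutation is sign(activity_mut − activity_wt) and +1
means weakened binding; the matrix side uses sign(E_mut − E_wt) in the same
orientation.  Predicted ties count as non-matches; pairs with exactly equal
activities carry no usable sign and are excluded from denominators (logged).
External score tables carry a per-function orientation flag (`asc` = lower
score is better, the default; `desc` flips the sign) because a silently
misoriented function is the largest failure risk in consensus scoring.

Sequence-side machinery: 9-mer windows are scored additively under a
published sequence PSSM, ranked descending with ties to the smaller start;
a peptide passes the two-method core consensus only when both top windows
agree in start and sequence; the flank filter discards peptides needing
more than two residues appended to the template at either terminus.
Nonstandard amino-acid letters are rejected at ingest rather than silently
remapped.  Alternate locations keep the highest-occupancy conformer (ties:
altloc letter order); waters and heteroatoms are dropped on read by
default.  Receptor atoms are all counted regardless of any distance-based
restraints that may have been applied during the simulation that produced
the frames.

## Numerical choices

Contact counting uses a k-d tree with a slightly inflated query radius
followed by an exact Euclidean refilter, so results are identical to a
brute-force all-pairs scan — the acceleration is an implementation detail
with no numerical consequence, and the test suite asserts exact agreement
on randomized frames.  Dihedrals are reported in [−180, 180) (a torsion of
exactly 180° is reported as −180°).  Dihedral distributions of symmetric
side chains are compared raw; folding χ2-equivalent flips is offered as an
analysis choice, not a default.  The KL threshold for calling two dihedral
distributions "similar" is exposed as a parameter with no default claim.

## What the synthetic generators emulate

`make_toy_complex` stands in for simulation trajectories: a strictly linear
extended peptide scaffold (motivated by the extended conformation of
groove-bound peptides, with no claim of structural realism) with receptor
probe atoms placed to realize exact planted per-position contact and
hydrogen-bond counts.  Probe geometry is audited at build time with a plain
double loop over all pairs: every distance criterion must clear the cutoff
by more than 12 × jitter_sd (per-component jitter is clipped at 3σ, so no
pairwise distance can change by more than that margin), hence the planted
counts are exact in every jittered frame, not just in expectation.
Hydrogen-bond acceptor probes necessarily sit inside the contact cutoff of
nearby backbone atoms, so the returned contact ground truth is the audited
pair count (planted probes plus those extras); with no hydrogen-bond
plantings it equals the planted contact counts exactly.  Each residue also
carries a CB scaffold anchor regardless of type (including glycine) purely
as a probe attachment point.

`make_planted_cohort` draws peptides position-wise from frequencies
exp(−E_planted), with geometric (uniformly log-spaced) per-position
preference profiles — the strongly peaked kind that anchor pockets impose —
and assigns activities exp(slope · span · normalized core score + ε)
spanning roughly 1–10,000 nM, the window of the affinity assays this
emulates.  Cohort ensembles realize contact counts that decrease one-by-one
with the planted preference rank at each position, mirroring the premise
that interaction counts track binding preference; the coupling is a
generator design choice, so the premise itself is testable (a zero slope
yields chance-level sign matching).  Mutation-pair generation draws the
mutant among residues whose planted energy differs from the wild type's by
at least 0.5, keeping planted effect sizes bounded away from zero so sign
recovery is well defined.  `make_score_tables` emulates six external
scoring functions whose mean per-frame score differences carry the
experimental sign with stated per-function probabilities (effect 1.0, frame
noise 0.1, so the mean sign essentially never flips at 10 frames).

What passing these tests does **not** show about real data: the toy
geometry has no side-chain packing, no competing near-cutoff pairs, no
correlated frame-to-frame motion, and the planted activity model is exactly
log-linear in the matrix score — real activity differences include
non-additive and flanking-region effects the matrices do not model.
Recovery results on synthetic cohorts therefore validate the pipeline's
arithmetic and conventions, not the biological adequacy of the observables.

## Problem sizes

The end-to-end recovery check uses 500 single-frame toy ensembles (one per
cohort peptide), 200 noise-free and 2,000-per-rung noisy mutation pairs,
5,000 pairs for the consensus closed-form comparison, and 10,000 bootstrap
replicas for SD calibration — sizes at which the Monte-Carlo error bands in
those checks are decisive while the whole suite stays desk-scale.

## Known limitations

* Multi-model PDB only; no mmCIF or trajectory formats (XTC/DCD), and no
  structure modelling or mutation — external tools' outputs are consumed
  as inputs.
* Hydrogen-bond detection considers peptide main-chain partners only; side
  chain–side chain bonds, salt bridges and π interactions are out of scope.
* The matrices are core-only; flanking residues contribute no observables.
* Only sign-level inference is claimed for mutations; no affinity
  regression and no multiple-testing correction.
* The published 10-structure benchmark table bundled with the package is
  input data for the summarization operation; the package does not
  recompute those per-structure means from trajectories.
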