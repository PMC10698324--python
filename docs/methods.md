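# Methods

## The genotype–phenotype maps

**HP lattice proteins.**  A genotype is a binary sequence over {H, P} of
length L = W·H; a phenotype is a *compact* conformation — a directed
Hamiltonian path of the W×H grid graph.  The energy of a sequence threaded
onto a conformation is −1 per contact (lattice-adjacent, chain-nonadjacent
residue pair) whose two residues are both H, and 0 otherwise; energies are
exact integers.  A sequence's phenotype is its unique energy-minimizing
conformation; if two or more conformations tie at the minimum the sequence is
assigned the UNFOLDED sentinel and treated as non-folding.  Conformations are
reduced under the lattice point group (8 elements for square grids, 4
otherwise), and a walk and its N→C reversal count as *different* structures
(reversal-distinct convention), so that directionality is retained as it is
in RNA.  On the 5×5 lattice this yields 1081 structures, each with
(W−1)(H−1) = 16 contacts.

The Boltzmann ensemble of a sequence is taken over exactly the compact
catalogue:

F_p = exp(−G_p / k_B T) / Σ_q exp(−G_q / k_B T).

Whether non-compact conformations belong in the ensemble is a genuine
modelling choice; this package adopts the compact-only state space, matching
its definition of the map itself, and records that convention in the GP-map
file metadata (`ensemble_states`).  The reduced temperature k_B T is the one
free parameter, in units of the HP contact energy.  The default is
k_B T = 0.5, a middle ground between the frozen extreme (k_B T = 0.1, where
a typical folding L = 25 sequence holds >99% of its ensemble in the ground
state) and the plastic extreme (k_B T = 1, where the ground state holds
<5%); 0.1 and 1.0 are exposed everywhere a temperature is accepted.

**RNA secondary structures.**  Phenotypes are dot-bracket strings compared
exactly (same base pairs in the same positions).  The package does not
implement a thermodynamic folding engine; it defines a one-call engine
contract — `subopt(seq, delta)`, every structure within `delta` kcal/mol of
the sequence's minimum free energy — and ships a deterministic
fixture-backed mock plus an adapter to ViennaRNA's `RNAsubopt` (run with no
isolated base pairs at the default 37 °C parameters).  All tests run on the
mock.  Two windows matter:

* **Uniqueness window, 0.02 kcal/mol.**  Nearest-neighbour engines report
  energies in 0.1 kcal/mol steps, so a window this narrow returns exactly
  one structure iff the mfe structure is unique; degenerate sequences are
  non-folding, as in the HP map.
* **Ensemble cutoff, 15 kcal/mol.**  Boltzmann frequencies are computed from
  the suboptimal list with the partition sum over the listed structures
  only.  Any structure excluded by the cutoff would have frequency at most
  exp(−15/k_B T) ≈ 3×10⁻¹¹ at 37 °C; this bound is attached to every
  truncated ensemble rather than silently dropped.  The truncated-denominator
  normalization (not a full partition function) is deliberate: it is the
  operation actually applied to the engine's output, and the error it
  introduces is controlled by the recorded bound.

k_B = 0.0019872 kcal/(mol·K), so k_B T = 0.616 ≈ 0.62 kcal/mol at 37 °C.

## Definitions computed

For a phenotype p with neutral set of size x and y = (a−1)·L single-site
substitutions per sequence (y = L for HP, 3L for RNA):

* φ_qp — the fraction of the x·y substitutions applied to p's neutral set
  whose mutant folds into q.  Rows internally carry q = p (robustness) and
  UNFOLDED, so each row sums to 1; analysis views (ranking, correlation)
  exclude both, since the question concerns changes to new folded
  structures.
* f_q — neutral-set size over sequence-space size (exact mode) or sample
  fraction (sampled mode).
* p_qp — mean Boltzmann frequency of q over p's neutral set.  Exact on
  enumerable maps; otherwise the mean over 10³ with-replacement draws (the
  HP sampling size) or over a site-scanning sample (RNA-scale).  q = p is
  retained in the distribution so normalization is testable; ranking views
  drop it, mirroring φ.
* p_q — mean Boltzmann frequency of q over arbitrary sequences (10⁵ draws
  at HP scale).  Degenerate sequences are included in the average, reading
  "arbitrary sequences" literally; an `include_mfe=False` variant zeroes each
  folding sequence's own mfe term for sensitivity checks.

**Predictor scoring.**  For each initial p, the top-k outcomes by φ_qp
(k = 30 by default, shrinking gracefully when fewer positive candidates
exist) are intersected with the predictor's own top-k; ties break by
ascending phenotype id, a documented determinism choice.  The capture metric
is invariant under any strictly monotone transform of the predictor.  The
second metric is the Pearson correlation of log φ_qp against log score over
pairs where both are positive (a log–log scatter can only show positive
values); the count of pairs is reported, and fewer than 3 pairs yields a
null correlation rather than an error.

## Exact computation at L = 25

The full 5×5 map (2²⁵ sequences × 1081 structures) is built by a blocked
numba kernel: the H-H contact count of structure c splits into a low-13-bit
table, a high-12-bit table and a popcount-mask cross term rebuilt per
(structure, high-bits) pair, and running max/argmax/tie arrays for one
high-bit block stay cache-resident.  The build takes well under a minute on
one core and is bit-identical to the dense numpy path on every lattice small
enough to cross-check.  Sequence spaces above 2²⁶ ids are refused with a
pointer to the sampling interfaces.

## Neutral-set sampling

Walks scan sites cyclically; at each visited site a random alternative
symbol is proposed and accepted iff the mutant still folds to p; every 50th
state is emitted; 100 independently seeded walks of 10⁵ steps are pooled
(2×10⁵ sequences at the defaults).  For RNA, sites paired in p can propose a
swap of the whole pair to another complementary pair (AU/UA/CG/GC/GU/UG),
improving movement across neutral-network components.  This sampler is a
documented *variant* of the site-scanning family of methods and is not
claimed bit-identical to any particular published schedule; outputs carry
the full walk configuration and seeds.  φ and p_qp estimates for one p come
from two samples with distinct sub-seeds so their errors are independent.
Estimates below 10 expected counts (φ < 10/(x·y), p_qp < 10/x — about 10⁻⁴
at the default schedule) are flagged unreliable, as are sampled phenotypic
frequencies seen fewer than 5 times.

## Synthetic test worlds

The toy landscape assigns each of S abstract structures an additive
random-field energy, E(s in q) = Σ_i ε(q, i, s_i) with ε ~ N(0, σ²) drawn
once from a seed; it regenerates bit-identically from (seed, a, n, S, σ) and
exposes the HP fold/ensemble contract, so the entire downstream pipeline runs
on it unchanged.  σ/k_B T tunes plasticity: σ = 0 makes every sequence
degenerate (all ensembles uniform), large σ/k_B T freezes each ensemble onto
its ground state.  The p_qp-over-f_q advantage is largest at moderate
plasticity and decays toward the frozen extreme; because these miniature
landscapes are only a few hundred sequences, the gap is noisy from seed to
seed, and the regression test asserts the decay trend at a fixed seed.

What the toy landscape does *not* emulate: the additive energies have none
of the hard constraints of real folding (no basepairing complementarity, no
contact geometry), every structure's energy distribution is identical by
construction, and neutral sets are typically tiny.  Tests passing on it show
the pipeline's bookkeeping and estimators are correct, not that any
biophysical conclusion transfers.

## Problem sizes and numerical choices

Tests and the acceptance script run on sizes chosen to keep the whole suite
in the minutes range while preserving exactness where it matters: oracle
equivalence on all grids with W·H ≤ 16, the scaled-down two-hypothesis
comparison on the complete 4×4 map, the headline 1081 count from the full
2²⁵ enumeration, and 2000-sequence samples for ground-state statistics
(medians are stable to ~0.01% across seeds at that size).  Partition sums
use a max-shift so exp never overflows; exact ensemble normalization is
asserted to 10⁻¹⁰ and oracle agreement to 10⁻¹² relative.  All estimators
require explicit seeds (CLI default 1) and are bit-reproducible; sub-seeds
derive from `numpy.random.SeedSequence` spawning.

## Known limitations

* Non-compact HP conformations, 3D lattices and side-chain models are out of
  scope, as are insertions/deletions and multi-point mutations.
* The RNA branch depends entirely on the engine supplied; no nearest-neighbour
  parameters live in this package.
* p_qp retains sampling error at RNA scale; only the HP branch is exact
  end-to-end.
* The site-scanning sampler offers no uniformity guarantee over a neutral
  set; purity (every emitted sequence folds to p) is guaranteed, coverage is
  not.
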