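# Methods

## Problem and model

Given N protein structures reduced to their Cα traces and an alignment size
w ≥ 3, the goal is N substructures of w residues (one per structure, not
necessarily contiguous in sequence) minimizing the average pairwise
superposition RMSD. The search treats structures purely through their
intra-molecular Cα–Cα distance matrices; superposition RMSD is used only to
gate and to score finished alignments. Because every sampling score is a
function of internal distances, the whole search is invariant under rigid
motions of any input structure.

The stochastic search is Gibbs sampling over a Markov chain whose states are
candidate alignments. It is restarted once per amino-acid-triplet
fingerprint; the fingerprint restricts the seed vocabulary of that restart,
which both partitions the search space and provides 8000 independent
restarts of a local optimizer. Each restart can only return a local optimum;
the global picture comes from ranking the results of all restarts.

## Superposition RMSD: two routes

* Fast path: Theobald's quaternion characteristic-polynomial method. The
  minimal RMSD is sqrt((G − 2λ_max)/k), where G is the summed squared norm
  of both centered sets and λ_max the largest eigenvalue of the 4×4
  quaternion key matrix, found by Newton–Raphson on its quartic
  characteristic polynomial starting from the upper bound G/2.
* Reference route: Kabsch — SVD of the 3×3 covariance with determinant sign
  correction, explicit rotation, explicit residual. Proper rotations only,
  so mirror images score strictly positive.

Numerical policy: the Newton iterate must descend monotonically and land on
a nonnegative root (the key matrix is traceless, so λ_max ≥ 0); any
violation, non-convergence within 50 steps, or a residual (G − 2λ)/k below
10⁻⁶ Ų routes the computation to the SVD path. The last rule matters: near
a perfect superposition the residual is a difference of large near-equal
numbers and the polynomial root carries too little relative precision,
while the SVD route forms the residual from explicitly rotated points and
is accurate to machine precision there. Two special cases have closed
forms and skip both routes: a single point (RMSD 0) and a point pair
(|d₁ − d₂|/2), whose doubly degenerate key-matrix spectrum makes the
polynomial iteration semi-convergent. The two routes agree to better than
10⁻⁶ Å on random coordinate sets (tested at k = 1…30) and the fast path
returns ≤ 10⁻⁸ Å on exact rigid copies.

## Scores and their flooring

All sampling scores are inverses of products of |ΔDist| factors. A perfect
geometric match makes the product exactly zero, so each factor and each
per-structure-pair product is floored at ε = 10⁻⁶ before inversion:
geometrically identical candidates become maximally — and finitely — likely,
with score 1/ε^(N−1). Products over many factors are accumulated in log
space, and transition probabilities are a softmax over log-scores (maximum
subtracted before exponentiating), so no feasible input can overflow,
underflow to zero, or produce NaN. The value of ε sets how strongly
"identical" beats "very close": with ε = 10⁻⁶ a single exactly-matching
structure pair outweighs typical decoy discrepancies by ~10⁵.

The extension score multiplies the geometric term by a substitution-matrix
similarity. Raw log-odds matrices contain non-positive entries, which a
product of similarities cannot accept, so BLOSUM62 is mapped through
s′ = 2^s — strictly positive and order-preserving. The matrix, the
transform (`pow2`, `shift`, `raw`) and NCBI-format matrix files are all
configurable; the choice only reweights the symbol factor relative to the
geometry factor.

## Sampler mechanics

* Stopping rule: a chain stops once the alignment is unchanged for
  k = max{k′ : ((N−1)/N)^k′ > α} consecutive steps — the point at which
  "some structure was simply never picked" has probability below α. α
  defaults to 0.05; k(N=6) = 16.
* One uniformly chosen structure is resampled per step; "unchanged" means
  the resampled element equals the one it replaces, and any change resets
  the stall counter. A hard cap of 10⁵ steps guards the pathological
  near-flat-score case where the expected stall time diverges; hitting it
  logs a warning and returns the current state.
* Fingerprint matching is by symbol multiset by default: the 10 Å clique
  condition is orderless, so ordered matching would re-visit each
  multiset up to 6 times. Enumeration is deduplicated to the 1540 sorted
  triplets (the full 8000 ordered enumeration, and positional matching,
  remain available behind `ordered_fingerprints`). Seed triples are
  reported in ascending index order.
* The initial chain state draws one feasible candidate uniformly per
  structure. Each fingerprint gets a single bootstrap attempt — the outer
  fingerprint loop already provides thousands of restarts.
* Seed alignments pass to extension only if their average pairwise RMSD is
  within the 1 Å gate; the gate is checked once, at seed stage. Extension
  candidates are unused residues within 10 Å of any residue of the current
  row (strictly-below for seed cliques, at-or-below for extension); rows
  never repeat a residue, and every row stays connected in the 10 Å graph
  by construction.
* Refinement deletes the argmax-badness column (ties → lowest index) and
  restores width with one extension step; the same column may be deleted
  and re-added in later rounds. If the step finds no candidates the column
  is reinstated and refinement ends early. IterRefine defaults to 10.
* All randomness flows from one `numpy.random.Generator` seeded by
  `rng_seed`, making every run — and every written report — bit-for-bit
  reproducible.

Overlap filtering is greedy in rank order: overlap is counted per residue
identity (structure id + residue index) against previously *kept*
alignments, averaged over structures, and an alignment strictly above the
AvgOverlap threshold is dropped. This makes the filter idempotent and
monotone in the threshold. The default threshold is 50%; 100% disables
filtering. Coverage of a known reference motif (`query_motif_coverage`) is
evaluated on the query structure's row only.

## Synthetic fixtures: what they emulate and what they don't

Two generators provide ground truth:

* **Planted-motif sets** — N self-avoiding random coils (3.8 Å Cα spacing,
  ≥ 2.5 Å nonconsecutive separation), each with a copy of one ideal
  α-helix Cα trace (rise 1.5 Å, radius 2.3 Å, 100° turn) spliced in at a
  random position: uniformly random rotation, clash-avoiding translation,
  isotropic Gaussian coordinate noise of scale σ. Copies share the
  template's residue symbols. At σ = 0.1 Å, two 8-residue copies superpose
  below 0.35 Å in 100/100 draws, which is the margin the recovery tests
  are built on.
* **Seed-decoy sets** — clusters of residue triples, >10 Å apart so each
  cluster is exactly one feasible seed: one planted triangle identical
  across structures (the unique zero-pair-distance combination) plus
  decoy triangles drawn under a mutual-dissimilarity constraint (pairwise
  |Δside| product ≥ 0.5 against every other triangle in the set). Without
  that constraint, coincidentally similar decoys create competing optima
  and the fixture no longer tests what it claims to.

These fixtures deliberately idealize: decoys are geometric coils, not
folded proteins; motif copies have identical symbols (no substitutions);
noise is isotropic and residue-independent. Passing the recovery tests
therefore demonstrates that the sampler finds a conserved substructure
when one cleanly exists — not that it matches curated biological motifs,
which additionally face conformational variability, partial conservation
and symbol divergence.

## Problem sizes used by the test suite and acceptance script

Bootstrap recovery runs 50 chains on 4 structures × 6 seeds each;
end-to-end recovery runs 10 searches on 5 structures of 108 residues
(100-residue coil + 8-residue motif, σ = 0.1 Å, w = 8), restricted to the
fingerprints the planted motif realizes — the natural targeted-search mode
for a fixture whose motif symbols are known. The superposition cross-check
uses 500–1000 random pairs at k = 3…30. These sizes give stable rates
(recovery rates vary by a few percent across fixture draws) while a full
run of everything stays in the tens of seconds.

## Known limitations

* A Gibbs restart converges to a local optimum; recovery probability per
  restart depends on α and on how dominant the true motif's geometry is.
  The stopping rule itself leaves an ~α chance per chain that one
  structure is never resampled during the stall window.
* Column correspondence is established by sampling order; two alignments
  of the same residues with different column orders are the same motif but
  are not canonicalized.
* One substructure per structure per alignment; paralogous double motifs
  within one structure surface as separate alignments, if at all.
* Cα-only geometry: side-chain orientation, surface accessibility and
  physicochemical environments are outside the model.
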