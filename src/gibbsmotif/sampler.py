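"""The stochastic search: bootstrap, extension and refinement phases.

The search looks for N substructures of w residues, one per structure, whose
mutual geometry is maximally conserved. One outer iteration is tied to a
*fingerprint* — an amino-acid triplet such as AAC — and runs three phases:

1. **bootstrap** — Gibbs sampling over *seeds* (residue triples matching the
   fingerprint, mutually within the candidate radius) finds one seed per
   structure minimizing internal-distance discrepancies. A Markov chain
   resamples one structure's seed at a time from probabilities proportional
   to its similarity with the rest of the current alignment.
2. **extension** — a seed alignment whose average pairwise RMSD passes the
   1 Å gate grows one column at a time up to width w, each column chosen by
   the same Gibbs scheme over residues near the current rows, scored by
   substitution similarity × distance-profile similarity.
3. **refinement** — the column with the highest badness is deleted and one
   extension step replaces it, for a fixed number of rounds.

The chain stops when the alignment has not changed for k consecutive steps,
where k is the largest integer with ((N−1)/N)^k > α: the probability that
some structure was simply never picked in k steps has dropped below α, so a
stall of that length is evidence of convergence rather than of unlucky
structure choice. Lower α means longer, more precise chains.

All randomness flows from a single seeded NumPy generator, so a run is
reproducible bit for bit from its parameters.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .pdbio import ProteinStructure
from .scoring import (
    EPSILON,
    Seed,
    SubstitutionTable,
    SubstructureAlignment,
    load_substitution_table,
    probabilities_from_log_scores,
)
from .superpose import average_pairwise_rmsd

__all__ = [
    "SearchParams",
    "ALPHABET",
    "enumerate_fingerprints",
    "unique_fingerprint_multisets",
    "enumerate_seed_candidates",
    "gibbs_iterations_bound",
    "bootstrap_phase",
    "extend_alignment",
    "refine_alignment",
    "find_motifs",
    "alignment_average_rmsd",
]

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in lexicographic order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_LOG_EPS = math.log(EPSILON)

#: Hard cap on Gibbs chain length; a chain this long without a stall means a
#: near-flat score landscape, where waiting for the stall rule diverges.
MAX_CHAIN_STEPS = 100_000


@dataclass
class SearchParams:
    """Tunable parameters of the motif search.

    Parameters
    ----------
    w : int
        Size of the final alignment (number of residues per substructure),
        at least 3. Family-specific: no universal default exists.
    alpha : float
        Stopping probability of the Gibbs chains in (0, 1); default 0.05.
        Lower values give longer chains (more precise, slower).
    iter_refine : int
        Number of refinement rounds; default 10.
    avg_overlap : float
        Overlap-filter threshold in percent; 100 disables the filter.
    seed_rmsd_gate : float
        Seed alignments above this average pairwise RMSD (Å) are not
        extended; default 1.0.
    candidate_radius : float
        Spatial radius (Å) for seed cliques and extension candidates;
        default 10.0.
    rng_seed : int
        Seed of the single random generator driving the whole search.
    max_fingerprints : int
        Truncate the fingerprint enumeration (20³ = 8000 triplets) for
        faster exploratory runs.
    ordered_fingerprints : bool
        If False (default) a seed matches a fingerprint as a multiset of
        symbols and the enumeration is deduplicated to the 1540 sorted
        triplets; if True the match is positional over all 8000 ordered
        triplets.
    matrix_name, matrix_transform : str
        Substitution table for the extension phase (see
        :func:`gibbsmotif.scoring.load_substitution_table`).
    """

    w: int
    alpha: float = 0.05
    iter_refine: int = 10
    avg_overlap: float = 50.0
    seed_rmsd_gate: float = 1.0
    candidate_radius: float = 10.0
    rng_seed: int = 0
    max_fingerprints: int = 8000
    ordered_fingerprints: bool = False
    matrix_name: str = "BLOSUM62"
    matrix_transform: str = "pow2"

    def __post_init__(self) -> None:
        if self.w < 3:
            raise ValueError("alignment size w must be >= 3")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.iter_refine < 0:
            raise ValueError("iter_refine must be nonnegative")
        if not 0.0 <= self.avg_overlap <= 100.0:
            raise ValueError("avg_overlap must lie in [0, 100]")
        if self.candidate_radius <= 0:
            raise ValueError("candidate_radius must be positive")
        if not 1 <= self.max_fingerprints <= 8000:
            raise ValueError("max_fingerprints must lie in 1..8000")


# ---------------------------------------------------------------------------
# fingerprints and candidates


def enumerate_fingerprints(cap: int = 8000) -> list[str]:
    """The first *cap* amino-acid triplets in lexicographic order.

    The full enumeration has 20³ = 8000 ordered triplets, one per outer
    search iteration.
    """
    if not 1 <= cap <= 8000:
        raise ValueError("cap must lie in 1..8000")
    fps = ["".join(t) for t in itertools.product(ALPHABET, repeat=3)]
    return fps[:cap]


def unique_fingerprint_multisets(fingerprints: Iterable[str]) -> list[str]:
    """Deduplicate fingerprints up to symbol order, keeping first occurrence.

    Under multiset matching, AAC, ACA and CAA select the same seeds; the
    full ordered enumeration collapses to 1540 sorted triplets.
    """
    seen: set[str] = set()
    out = []
    for f in fingerprints:
        key = "".join(sorted(f))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def enumerate_seed_candidates(
    s: ProteinStructure,
    fingerprint: str,
    radius: float = 10.0,
    ordered: bool = False,
) -> list[Seed]:
    """All feasible seeds of *s* for one fingerprint.

    A triple is feasible when every pairwise Cα distance is below *radius*
    and its symbols match the fingerprint — as a multiset by default, or
    positionally when *ordered* is set. Exhaustive over the structure.
    """
    if len(fingerprint) != 3 or any(c not in ALPHABET for c in fingerprint):
        raise ValueError(f"bad fingerprint {fingerprint!r}")
    want = sorted(fingerprint)
    eligible = [i for i, r in enumerate(s.residues) if r.symbol in fingerprint]
    seeds: list[Seed] = []
    d = s.dist
    for i, j, k in itertools.combinations(eligible, 3):
        if d[i, j] >= radius or d[i, k] >= radius or d[j, k] >= radius:
            continue
        syms = [s.residues[i].symbol, s.residues[j].symbol, s.residues[k].symbol]
        if sorted(syms) != want:
            continue
        if not ordered:
            seeds.append(Seed(s.id, (i, j, k)))
        else:
            for perm in set(itertools.permutations((i, j, k))):
                if all(
                    s.residues[p].symbol == f
                    for p, f in zip(perm, fingerprint)
                ):
                    seeds.append(Seed(s.id, perm))
    return seeds


def gibbs_iterations_bound(n_structures: int, alpha: float) -> int:
    """Largest k with ((N−1)/N)**k > α, or 0 when no positive k qualifies.

    ((N−1)/N)**k is the probability that one given structure is never
    selected in k uniform single-structure resampling steps.
    """
    if n_structures < 2:
        raise ValueError("need at least 2 structures")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    r = (n_structures - 1) / n_structures
    if r <= alpha:
        return 0
    k = int(math.floor(math.log(alpha) / math.log(r)))
    while r**k <= alpha:
        k -= 1
    while r ** (k + 1) > alpha:
        k += 1
    return max(k, 0)


# ---------------------------------------------------------------------------
# bootstrap phase


def _seed_dist_triples(cands: Sequence[Seed], s: ProteinStructure) -> np.ndarray:
    """(m, 3) internal-distance profiles of a structure's candidate seeds."""
    out = np.empty((len(cands), 3))
    for m, c in enumerate(cands):
        i, j, k = c.residue_indices
        out[m] = (s.dist[i, j], s.dist[i, k], s.dist[j, k])
    return out


def _bootstrap_log_scores(
    triples_j: np.ndarray, current_triples: list[np.ndarray], j: int
) -> np.ndarray:
    """Log seed similarity of every candidate of structure j vs the rest."""
    acc = np.zeros(triples_j.shape[0])
    for i, tri in enumerate(current_triples):
        if i == j:
            continue
        logs = np.log(np.maximum(np.abs(triples_j - tri[None, :]), EPSILON))
        acc += np.maximum(logs.sum(axis=1), _LOG_EPS)
    return -acc


def bootstrap_phase(
    structures: Sequence[ProteinStructure],
    fingerprint: str,
    params: SearchParams,
    rng: np.random.Generator,
    candidates: Sequence[Sequence[Seed]] | None = None,
) -> list[Seed] | None:
    """Gibbs sampling over seed alignments for one fingerprint.

    Returns one seed per structure, or None when some structure has no
    feasible candidate (the outer loop then moves to the next fingerprint).
    Starting from a uniformly random seed per structure, each step picks a
    structure uniformly and resamples its seed from probabilities
    proportional to seed similarity; the chain stops once the alignment has
    not changed for ``gibbs_iterations_bound(N, alpha)`` consecutive steps.
    """
    n = len(structures)
    if candidates is None:
        candidates = [
            enumerate_seed_candidates(
                s, fingerprint, params.candidate_radius, params.ordered_fingerprints
            )
            for s in structures
        ]
    if any(len(c) == 0 for c in candidates):
        return None

    triples = [
        _seed_dist_triples(cands, s) for cands, s in zip(candidates, structures)
    ]
    state = [int(rng.integers(len(c))) for c in candidates]
    current = [triples[i][state[i]] for i in range(n)]

    k_stop = gibbs_iterations_bound(n, params.alpha)
    stall = 0
    steps = 0
    while stall < k_stop and steps < MAX_CHAIN_STEPS:
        j = int(rng.integers(n))
        log_scores = _bootstrap_log_scores(triples[j], current, j)
        probs = probabilities_from_log_scores(log_scores)
        pick = int(rng.choice(len(probs), p=probs))
        if pick == state[j]:
            stall += 1
        else:
            state[j] = pick
            current[j] = triples[j][pick]
            stall = 0
        steps += 1
    if steps >= MAX_CHAIN_STEPS:
        logger.warning("bootstrap chain hit step cap for fingerprint %s", fingerprint)
    return [candidates[i][state[i]] for i in range(n)]


# ---------------------------------------------------------------------------
# extension phase


def alignment_average_rmsd(
    al: SubstructureAlignment, structures: Sequence[ProteinStructure]
) -> float:
    """Average pairwise superposition RMSD of an alignment's substructures."""
    by_id = {s.id: s for s in structures}
    blocks = [
        by_id[sid].coords[list(row)]
        for sid, row in zip(al.structure_ids, al.rows)
    ]
    return average_pairwise_rmsd(blocks)


def _extension_candidates(
    s: ProteinStructure, row: Sequence[int], radius: float
) -> list[int]:
    """Unused residues within *radius* of any residue of the current row."""
    near = (s.dist[list(row)] <= radius).any(axis=0)
    near[list(row)] = False
    return [int(i) for i in np.flatnonzero(near)]


def _extension_log_scores(
    cand_j: Sequence[int],
    j: int,
    current: Sequence[int],
    al: SubstructureAlignment,
    structures: Sequence[ProteinStructure],
    table: SubstitutionTable,
) -> np.ndarray:
    """Log extension score of every candidate of structure j vs the rest."""
    by_id = {s.id: s for s in structures}
    sj = by_id[al.structure_ids[j]]
    row_j = al.rows[j]
    prof = sj.dist[np.ix_(cand_j, row_j)]  # (m, w')
    acc = np.zeros(len(cand_j))
    for k in range(al.n):
        if k == j:
            continue
        sk = by_id[al.structure_ids[k]]
        a_k = current[k]
        d_k = sk.dist[a_k, al.rows[k]]  # (w',)
        logs = np.log(np.maximum(np.abs(prof - d_k[None, :]), EPSILON))
        acc -= np.maximum(logs.sum(axis=1), _LOG_EPS)
        sym_k = sk.residues[a_k].symbol
        acc += np.array(
            [table.log_score(sj.residues[c].symbol, sym_k) for c in cand_j]
        )
    return acc


def _extension_step(
    structures: Sequence[ProteinStructure],
    al: SubstructureAlignment,
    params: SearchParams,
    rng: np.random.Generator,
    table: SubstitutionTable,
) -> list[int] | None:
    """One Gibbs sweep choosing the next aligned residue of every structure.

    Returns one residue index per structure, or None when some structure has
    no unused residue within the candidate radius of its current row.
    """
    n = al.n
    cands = [
        _extension_candidates(s, row, params.candidate_radius)
        for s, row in zip(structures, al.rows)
    ]
    if any(len(c) == 0 for c in cands):
        return None
    state = [int(rng.integers(len(c))) for c in cands]
    current = [cands[i][state[i]] for i in range(n)]
    k_stop = gibbs_iterations_bound(n, params.alpha)
    stall = 0
    steps = 0
    while stall < k_stop and steps < MAX_CHAIN_STEPS:
        j = int(rng.integers(n))
        log_scores = _extension_log_scores(cands[j], j, current, al, structures, table)
        probs = probabilities_from_log_scores(log_scores)
        pick = int(rng.choice(len(probs), p=probs))
        if pick == state[j]:
            stall += 1
        else:
            state[j] = pick
            current[j] = cands[j][pick]
            stall = 0
        steps += 1
    if steps >= MAX_CHAIN_STEPS:
        logger.warning("extension chain hit step cap")
    return current


def extend_alignment(
    structures: Sequence[ProteinStructure],
    al: SubstructureAlignment,
    params: SearchParams,
    rng: np.random.Generator,
    table: SubstitutionTable | None = None,
) -> SubstructureAlignment | None:
    """Grow an alignment column by column up to width w.

    The input must have width ≥ 3 and average pairwise RMSD within the seed
    gate. Returns None when some structure runs out of nearby unused
    residues before reaching full width.
    """
    if al.width < 3:
        raise ValueError("alignment must have width >= 3 before extension")
    gate = alignment_average_rmsd(al, structures)
    if gate > params.seed_rmsd_gate:
        raise ValueError(
            f"seed alignment RMSD {gate:.3f} Å exceeds gate {params.seed_rmsd_gate} Å"
        )
    if table is None:
        table = load_substitution_table(params.matrix_name, params.matrix_transform)
    out = al.copy()
    while out.width < params.w:
        added = _extension_step(structures, out, params, rng, table)
        if added is None:
            return None
        for row, res in zip(out.rows, added):
            row.append(res)
    return out


# ---------------------------------------------------------------------------
# refinement phase


def refine_alignment(
    structures: Sequence[ProteinStructure],
    al: SubstructureAlignment,
    params: SearchParams,
    rng: np.random.Generator,
    table: SubstitutionTable | None = None,
) -> SubstructureAlignment:
    """Iteratively replace the worst column of a full-width alignment.

    Each round deletes the column with maximal badness (ties: lowest column
    index) and restores full width with one extension step; if the step
    finds no candidates the deleted column is reinstated and refinement
    stops early.
    """
    from .scoring import badness  # local import keeps module load light

    if table is None:
        table = load_substitution_table(params.matrix_name, params.matrix_transform)
    out = al.copy()
    for _ in range(params.iter_refine):
        scores = [badness(out, structures, k) for k in range(out.width)]
        k_worst = int(np.argmax(scores))  # argmax takes the first (lowest) index
        removed = [row.pop(k_worst) for row in out.rows]
        added = _extension_step(structures, out, params, rng, table)
        if added is None:
            for row, res in zip(out.rows, removed):
                row.insert(k_worst, res)
            break
        for row, res in zip(out.rows, added):
            row.append(res)
    return out


# ---------------------------------------------------------------------------
# driver


def find_motifs(
    structures: Sequence[ProteinStructure],
    params: SearchParams,
    fingerprints: Sequence[str] | None = None,
) -> list[SubstructureAlignment]:
    """Run the full search: one bootstrap/extension/refinement pass per
    fingerprint, collecting every alignment that survives all phases.

    *fingerprints* overrides the default enumeration (useful for targeted
    or truncated runs). The result is unranked; hand it to
    :func:`gibbsmotif.postprocess.sort_alignments` and
    :func:`gibbsmotif.postprocess.filter_overlapping`.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    ids = [s.id for s in structures]
    if len(set(ids)) != len(ids):
        raise ValueError("structure ids must be unique")
    shortest = min(len(s) for s in structures)
    if params.w > shortest:
        raise ValueError(
            f"w={params.w} exceeds the shortest structure ({shortest} residues)"
        )

    rng = np.random.default_rng(params.rng_seed)
    table = load_substitution_table(params.matrix_name, params.matrix_transform)
    if fingerprints is None:
        fingerprints = enumerate_fingerprints(params.max_fingerprints)
        if not params.ordered_fingerprints:
            fingerprints = unique_fingerprint_multisets(fingerprints)
            logger.info(
                "multiset matching: %d effective fingerprints", len(fingerprints)
            )

    results: list[SubstructureAlignment] = []
    for fp in fingerprints:
        seeds = bootstrap_phase(structures, fp, params, rng)
        if seeds is None:
            logger.debug("%s: no feasible candidates in some structure", fp)
            continue
        al = SubstructureAlignment(
            structure_ids=list(ids),
            rows=[list(s.residue_indices) for s in seeds],
        )
        seed_rmsd = alignment_average_rmsd(al, structures)
        if seed_rmsd > params.seed_rmsd_gate:
            logger.debug("%s: seed RMSD %.3f above gate", fp, seed_rmsd)
            continue
        extended = extend_alignment(structures, al, params, rng, table)
        if extended is None:
            logger.debug("%s: extension ran out of candidates", fp)
            continue
        refined = refine_alignment(structures, extended, params, rng, table)
        refined.score = alignment_average_rmsd(refined, structures)
        logger.info("%s: alignment with avg RMSD %.3f Å", fp, refined.score)
        results.append(refined)
    return results
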