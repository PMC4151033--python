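"""Closed-form similarity scores driving the Gibbs sampler.

All scores are built from intra-structure Cα–Cα distances only, so every one
of them is invariant under rigid transforms of any input structure. The
building block is a *pair distance*: a product of absolute differences of
internal distances, zero exactly when the two local geometries match.
Similarities are inverses of pair-distance products, so geometrically
identical candidates are maximally likely. Because a perfect match makes the
product exactly zero, every factor and every product is floored at
``EPSILON = 1e-6`` before inversion: perfect candidates become maximally,
finitely likely.

Products of many factors across structures and columns under- or overflow in
linear space, so all similarities are accumulated as log-scores; the
normalization to transition probabilities subtracts the maximum before
exponentiating (a softmax over log-scores). Linear-scale wrappers are
provided for direct use and testing.

Score inventory
---------------
* seed phase — ``pair_dist_seeds`` (product over the 3 internal distance
  pairs of a residue triple) and ``seed_similarity`` (inverse product over
  the other structures' seeds).
* extension phase — ``sim_symb`` (product of positive substitution-matrix
  similarities), ``sim_dist`` (inverse product of column-wise distance-profile
  discrepancies), and their product ``extension_score``.
* refinement phase — ``pair_dist_aligned`` (per-column discrepancy of one
  structure pair) and ``badness`` (its sum over all structure pairs),
  identifying the worst-aligned column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .pdbio import STANDARD_AA, ProteinStructure

__all__ = [
    "EPSILON",
    "Seed",
    "SubstructureAlignment",
    "SubstitutionTable",
    "load_substitution_table",
    "pair_dist_seeds",
    "seed_similarity",
    "sim_symb",
    "sim_dist",
    "extension_score",
    "pair_dist_aligned",
    "badness",
    "transition_probabilities",
]

#: Floor applied to every |Dist - Dist| factor and every pair-distance
#: product before inversion.
EPSILON = 1e-6
_LOG_EPS = math.log(EPSILON)


@dataclass(frozen=True)
class Seed:
    """An ordered triple of residues from one structure.

    Feasible seeds have all three pairwise Cα distances below the candidate
    radius and symbols matching the fingerprint of the current iteration.
    """

    structure_id: str
    residue_indices: tuple[int, int, int]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.residue_indices)
        if len(idx) != 3 or len(set(idx)) != 3:
            raise ValueError("seed needs three distinct residue indices")
        object.__setattr__(self, "residue_indices", idx)


@dataclass
class SubstructureAlignment:
    """An N×w′ residue-index matrix: one row per structure, one column per
    aligned residue tuple. Column order is the order columns were added
    (bootstrap columns first, then extension columns)."""

    structure_ids: list[str]
    rows: list[list[int]]
    score: float | None = field(default=None)

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(self.rows) != len(self.structure_ids):
            raise ValueError("one row per structure required")
        if len(widths) > 1:
            raise ValueError("ragged alignment: rows of unequal width")
        for r in self.rows:
            if len(set(r)) != len(r):
                raise ValueError("repeated residue within a row")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def copy(self) -> "SubstructureAlignment":
        return SubstructureAlignment(
            list(self.structure_ids), [list(r) for r in self.rows], self.score
        )


class SubstitutionTable:
    """Strictly positive amino-acid similarity table.

    Wraps a substitution matrix (BLOSUM62 by default) mapped to positive
    values, since a product of similarities requires every factor > 0 while
    raw log-odds entries are ≤ 0 for many pairs. Transforms:

    ``pow2``   s' = 2**s (default; preserves ordering, strictly positive)
    ``shift``  s' = s - min(s) + 1
    ``raw``    use entries as-is (rejected unless all positive)
    """

    def __init__(self, name: str, scores: dict[tuple[str, str], float]):
        self.name = name
        self._scores = scores
        alphabet = sorted({a for a, _ in scores})
        for a in alphabet:
            for b in alphabet:
                if scores[(a, b)] != scores[(b, a)]:
                    raise ValueError(f"asymmetric table at ({a},{b})")
                if scores[(a, b)] <= 0:
                    raise ValueError(f"non-positive similarity at ({a},{b})")
            if any(scores[(a, a)] < scores[(a, b)] for b in alphabet):
                raise ValueError(f"diagonal not dominant in row {a}")
        self._log = {k: math.log(v) for k, v in scores.items()}

    def score(self, x: str, y: str) -> float:
        try:
            return self._scores[(x, y)]
        except KeyError:
            raise KeyError(f"unknown symbol pair ({x},{y})") from None

    def log_score(self, x: str, y: str) -> float:
        try:
            return self._log[(x, y)]
        except KeyError:
            raise KeyError(f"unknown symbol pair ({x},{y})") from None


def _apply_transform(raw: dict[tuple[str, str], float], transform: str):
    if transform == "pow2":
        return {k: 2.0**v for k, v in raw.items()}
    if transform == "shift":
        lo = min(raw.values())
        return {k: v - lo + 1.0 for k, v in raw.items()}
    if transform == "raw":
        return dict(raw)
    raise ValueError(f"unknown transform {transform!r}")


def load_substitution_table(
    name: str = "BLOSUM62", transform: str = "pow2", path: str | None = None
) -> SubstitutionTable:
    """Load a substitution matrix and map it to strict positivity.

    *name* is any matrix shipped with Biopython (BLOSUM62, BLOSUM50, ...);
    *path* reads an NCBI-format matrix text file instead. Entries are
    restricted to the 20 standard amino acids.
    """
    if path is not None:
        mat = substitution_matrices.read(path)
    else:
        mat = substitution_matrices.load(name)
    raw = {
        (a, b): float(mat[a, b])
        for a in STANDARD_AA
        for b in STANDARD_AA
    }
    label = f"{name if path is None else path}:{transform}"
    return SubstitutionTable(label, _apply_transform(raw, transform))


# ---------------------------------------------------------------------------
# seed (bootstrap) scores


def _seed_internal_dists(seed: Seed, s: ProteinStructure) -> tuple[float, float, float]:
    i, j, k = seed.residue_indices
    d = s.dist
    return float(d[i, j]), float(d[i, k]), float(d[j, k])


def pair_dist_seeds(
    a: Seed, b: Seed, structures: Sequence[ProteinStructure]
) -> float:
    """Product over the three internal distance pairs of |Dist_a − Dist_b|.

    Zero exactly when the two triples have identical internal geometry.
    """
    by_id = {s.id: s for s in structures}
    da = _seed_internal_dists(a, by_id[a.structure_id])
    db = _seed_internal_dists(b, by_id[b.structure_id])
    out = 1.0
    for x, y in zip(da, db):
        out *= abs(x - y)
    return out


def _log_pair_dist_seeds(da, db) -> float:
    """Log of the floored pair distance between two internal-distance triples."""
    acc = 0.0
    for x, y in zip(da, db):
        acc += math.log(max(abs(x - y), EPSILON))
    return max(acc, _LOG_EPS)


def seed_similarity(
    x: Seed,
    current: Sequence[Seed],
    j: int,
    structures: Sequence[ProteinStructure],
) -> float:
    """Inverse of the product of floored pair distances between candidate
    *x* and every seed of the current alignment except row *j* (the row
    being resampled). Strictly positive and finite; maximal, equal to
    ``1/EPSILON**(N-1)``, for a candidate geometrically identical to all
    other seeds."""
    return math.exp(log_seed_similarity(x, current, j, structures))


def log_seed_similarity(
    x: Seed,
    current: Sequence[Seed],
    j: int,
    structures: Sequence[ProteinStructure],
) -> float:
    if not 0 <= j < len(current):
        raise IndexError(f"replaced row {j} out of range")
    by_id = {s.id: s for s in structures}
    dx = _seed_internal_dists(x, by_id[x.structure_id])
    acc = 0.0
    for i, s_i in enumerate(current):
        if i == j:
            continue
        di = _seed_internal_dists(s_i, by_id[s_i.structure_id])
        acc += _log_pair_dist_seeds(dx, di)
    return -acc


# ---------------------------------------------------------------------------
# extension scores


def sim_symb(
    x_symbol: str,
    candidate_symbols: Sequence[str],
    j: int,
    table: SubstitutionTable,
) -> float:
    """Product of substitution similarities between *x_symbol* and every
    other structure's current candidate symbol."""
    return math.exp(log_sim_symb(x_symbol, candidate_symbols, j, table))


def log_sim_symb(
    x_symbol: str,
    candidate_symbols: Sequence[str],
    j: int,
    table: SubstitutionTable,
) -> float:
    if not 0 <= j < len(candidate_symbols):
        raise IndexError(f"replaced row {j} out of range")
    return sum(
        table.log_score(x_symbol, sym)
        for k, sym in enumerate(candidate_symbols)
        if k != j
    )


def pair_dist_extension(
    x: int,
    a_k: int,
    j: int,
    k: int,
    alignment: SubstructureAlignment,
    structures: Sequence[ProteinStructure],
) -> float:
    """Distance-profile discrepancy between candidate *x* (structure *j*)
    and candidate *a_k* (structure *k*): the product over the w′ aligned
    columns of |Dist(x, R_{j,h}) − Dist(a_k, R_{k,h})|, each distance taken
    within its own structure and columns paired positionally."""
    by_id = {s.id: s for s in structures}
    sj = by_id[alignment.structure_ids[j]]
    sk = by_id[alignment.structure_ids[k]]
    row_j, row_k = alignment.rows[j], alignment.rows[k]
    if len(row_j) != len(row_k):
        raise ValueError("width mismatch between rows")
    out = 1.0
    for h in range(len(row_j)):
        out *= abs(float(sj.dist[x, row_j[h]]) - float(sk.dist[a_k, row_k[h]]))
    return out


def sim_dist(
    x: int,
    candidates: Sequence[int],
    j: int,
    alignment: SubstructureAlignment,
    structures: Sequence[ProteinStructure],
) -> float:
    """Inverse product, over structures k ≠ j, of the floored distance-profile
    discrepancy between *x* and structure k's current candidate."""
    return math.exp(log_sim_dist(x, candidates, j, alignment, structures))


def log_sim_dist(
    x: int,
    candidates: Sequence[int],
    j: int,
    alignment: SubstructureAlignment,
    structures: Sequence[ProteinStructure],
) -> float:
    by_id = {s.id: s for s in structures}
    sj = by_id[alignment.structure_ids[j]]
    row_j = alignment.rows[j]
    prof_x = sj.dist[x, row_j]
    acc = 0.0
    for k, a_k in enumerate(candidates):
        if k == j:
            continue
        sk = by_id[alignment.structure_ids[k]]
        row_k = alignment.rows[k]
        if len(row_k) != len(row_j):
            raise ValueError("width mismatch between rows")
        prof_k = sk.dist[a_k, row_k]
        logs = np.log(np.maximum(np.abs(prof_x - prof_k), EPSILON))
        acc += max(float(logs.sum()), _LOG_EPS)
    return -acc


def extension_score(
    x: int,
    x_symbol: str,
    candidates: Sequence[int],
    candidate_symbols: Sequence[str],
    j: int,
    alignment: SubstructureAlignment,
    structures: Sequence[ProteinStructure],
    table: SubstitutionTable,
) -> float:
    """Full extension-phase similarity: SimSymb × SimDist."""
    return math.exp(
        log_sim_symb(x_symbol, candidate_symbols, j, table)
        + log_sim_dist(x, candidates, j, alignment, structures)
    )


# ---------------------------------------------------------------------------
# refinement scores


def pair_dist_aligned(
    alignment: SubstructureAlignment,
    structures: Sequence[ProteinStructure],
    i: int,
    j: int,
    k: int,
) -> float:
    """Column-k discrepancy between rows *i* and *j*: the product over the
    other columns h of |Dist(R[i,k], R[i,h]) − Dist(R[j,k], R[j,h])|."""
    n, w = alignment.n, alignment.width
    if not (0 <= i < n and 0 <= j < n and 0 <= k < w):
        raise IndexError("row or column index out of range")
    by_id = {s.id: s for s in structures}
    si = by_id[alignment.structure_ids[i]]
    sj = by_id[alignment.structure_ids[j]]
    row_i, row_j = alignment.rows[i], alignment.rows[j]
    out = 1.0
    for h in range(w):
        if h == k:
            continue
        out *= abs(
            float(si.dist[row_i[k], row_i[h]]) - float(sj.dist[row_j[k], row_j[h]])
        )
    return out


def badness(
    alignment: SubstructureAlignment,
    structures: Sequence[ProteinStructure],
    k: int,
) -> float:
    """Badness of column *k*: the sum of its pairwise discrepancies over all
    structure pairs. The refinement phase deletes the argmax column."""
    total = 0.0
    for i in range(alignment.n):
        for j in range(i + 1, alignment.n):
            total += pair_dist_aligned(alignment, structures, i, j, k)
    return total


# ---------------------------------------------------------------------------
# normalization


def transition_probabilities(scores: Sequence[float]) -> np.ndarray:
    """Normalize positive similarity scores into a probability vector."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("no scores to normalize")
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("scores must be positive and finite")
    return s / s.sum()


def probabilities_from_log_scores(log_scores: Sequence[float]) -> np.ndarray:
    """Softmax: probabilities proportional to exp(log_scores), computed
    after subtracting the maximum so that very large or very small
    similarity products never overflow."""
    ls = np.asarray(log_scores, dtype=float)
    if ls.size == 0:
        raise ValueError("no scores to normalize")
    if not np.all(np.isfinite(ls)):
        raise ValueError("log-scores must be finite")
    e = np.exp(ls - ls.max())
    return e / e.sum()
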