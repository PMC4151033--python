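"""Synthetic structure sets with a planted rigid motif.

Real benchmark sets require curated downloads; the generator here produces
Cα-only structures with exactly known ground truth, which is what every
phase of the search is tested against. Each structure is a self-avoiding
random-coil decoy with a copy of one compact motif template spliced in at a
random list position. All copies share the template's residue symbols and
differ from it by a uniformly random rotation, a clash-avoiding translation
and isotropic Gaussian coordinate noise — so the planted substructures are
mutually superposable to within the noise scale, while the decoy background
shares no conserved geometry.

The template is an ideal α-helix Cα trace (rise 1.5 Å, radius 2.3 Å, 100°
turn per residue): compact enough that adjacent triples satisfy the 10 Å
seed-clique constraint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .pdbio import ProteinStructure, Residue
from .sampler import ALPHABET

__all__ = [
    "PlantedMotifFixture",
    "helix_template",
    "random_coil_structure",
    "generate_planted_motif_set",
    "generate_seed_decoy_set",
    "motif_fingerprints",
]

#: Consecutive Cα spacing of the coil, Å.
CA_SPACING = 3.8
#: Minimal distance between nonconsecutive coil residues, Å.
SELF_AVOID = 2.5
#: Minimal motif-to-coil atom distance when placing the motif copy, Å.
CLASH_GAP = 4.0


@dataclass
class PlantedMotifFixture:
    """A structure set with known planted-motif ground truth.

    ``truth[i]`` holds the ordered residue indices of the motif copy inside
    ``structures[i]`` (always a consecutive run, in template order).
    """

    structures: list[ProteinStructure]
    truth: list[list[int]]
    motif_size: int
    noise_sigma: float
    rng_seed: int

    @property
    def motif_symbols(self) -> str:
        s = self.structures[0]
        return "".join(s.residues[i].symbol for i in self.truth[0])


def helix_template(
    n: int, rise: float = 1.5, radius: float = 2.3, turn_deg: float = 100.0
) -> np.ndarray:
    """Ideal α-helix Cα trace of *n* residues, shape (n, 3)."""
    t = np.arange(n) * np.deg2rad(turn_deg)
    return np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), np.arange(n) * rise]
    )


def _coil_coords(length: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with ~3.8 Å steps."""
    pts = [np.zeros(3)]
    while len(pts) < length:
        placed = False
        for _ in range(200):
            step = rng.normal(size=3)
            step *= rng.uniform(3.65, 3.95) / np.linalg.norm(step)
            cand = pts[-1] + step
            prev = np.asarray(pts[:-1])
            if len(prev) == 0 or np.min(
                np.linalg.norm(prev - cand, axis=1)
            ) >= SELF_AVOID:
                pts.append(cand)
                placed = True
                break
        if not placed:  # walk trapped itself: back up one step and retry
            pts.pop()
            if not pts:
                pts = [np.zeros(3)]
    return np.asarray(pts)


def random_coil_structure(
    length: int, rng: np.random.Generator, id: str = "coil"
) -> ProteinStructure:
    """Random-coil decoy: self-avoiding walk, uniformly random symbols."""
    if length < 1:
        raise ValueError("length must be >= 1")
    coords = _coil_coords(length, rng)
    symbols = rng.choice(list(ALPHABET), size=length)
    residues = [
        Residue(symbol=str(symbols[i]), seq_index=i + 1, chain_id="A", coords=coords[i])
        for i in range(length)
    ]
    return ProteinStructure(id=id, residues=residues)


def _place_motif(
    motif: np.ndarray, coil: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rotate the motif uniformly and translate it clear of the coil."""
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    m = (motif - motif.mean(axis=0)) @ rot.T
    center = coil.mean(axis=0)
    span = np.max(np.linalg.norm(coil - center, axis=1)) if len(coil) else 0.0
    for attempt in itertools.count():
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = span + CLASH_GAP + 2.0 + attempt * 0.5
        cand = m + center + direction * dist
        d = np.linalg.norm(coil[:, None, :] - cand[None, :, :], axis=2)
        if d.min() >= CLASH_GAP:
            return cand


def generate_planted_motif_set(
    n_structures: int,
    motif_size: int,
    decoy_length: int,
    noise_sigma: float,
    rng: np.random.Generator | int,
) -> PlantedMotifFixture:
    """Build *n_structures* coils, each with one noisy rigid copy of the
    same helical motif spliced in at a random list position.

    *decoy_length* is the coil length; the total structure length is
    ``decoy_length + motif_size``. Motif symbols are drawn once and shared
    by every copy; *noise_sigma* (Å) is the per-coordinate Gaussian noise.
    """
    if motif_size < 3:
        raise ValueError("motif_size must be >= 3")
    if decoy_length < motif_size:
        raise ValueError("decoy_length must be >= motif_size")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    template = helix_template(motif_size)
    motif_syms = rng.choice(list(ALPHABET), size=motif_size)

    structures: list[ProteinStructure] = []
    truth: list[list[int]] = []
    for si in range(n_structures):
        coil = _coil_coords(decoy_length, rng)
        copy = _place_motif(template, coil, rng)
        copy = copy + rng.normal(scale=noise_sigma, size=copy.shape)
        insert_at = int(rng.integers(decoy_length + 1))
        coil_syms = rng.choice(list(ALPHABET), size=decoy_length)

        coords = np.vstack([coil[:insert_at], copy, coil[insert_at:]])
        symbols = (
            list(coil_syms[:insert_at]) + list(motif_syms) + list(coil_syms[insert_at:])
        )
        residues = [
            Residue(
                symbol=str(symbols[i]),
                seq_index=i + 1,
                chain_id="A",
                coords=coords[i],
            )
            for i in range(len(symbols))
        ]
        structures.append(ProteinStructure(id=f"synth{si}", residues=residues))
        truth.append(list(range(insert_at, insert_at + motif_size)))
    return PlantedMotifFixture(
        structures=structures,
        truth=truth,
        motif_size=motif_size,
        noise_sigma=float(noise_sigma),
        rng_seed=int(seed) if seed is not None else -1,
    )


def generate_seed_decoy_set(
    n_structures: int = 4,
    n_decoys: int = 5,
    rng: np.random.Generator | int = 0,
    symbols: str = "AAC",
) -> tuple[list[ProteinStructure], list[list[int]]]:
    """Structures made of well-separated residue triples for bootstrap tests.

    Each structure holds ``n_decoys + 1`` clusters of three residues carrying
    *symbols*, every cluster internally within 10 Å and clusters more than
    10 Å apart, so each cluster yields exactly one feasible seed. Cluster 0
    is the *planted* one: the same 3-4-5 triangle in every structure (zero
    mutual pair distance). Decoy clusters are random triangles drawn under a
    mutual-dissimilarity constraint — every decoy's internal-distance
    profile keeps a pair-distance product of at least 0.5 from the planted
    triangle and from every other decoy in the set — so the planted
    combination is the *unique* zero-distance optimum, which is the premise
    every bootstrap-recovery test relies on.
    Returns the structures and, per structure, the planted residue indices.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    planted = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]])

    def sides(tri: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(tri[:, None] - tri[None], axis=2)
        return np.array([d[0, 1], d[0, 2], d[1, 2]])

    drawn_sides = [sides(planted)]
    structures: list[ProteinStructure] = []
    truth: list[list[int]] = []
    for si in range(n_structures):
        coords: list[np.ndarray] = []
        syms: list[str] = []
        for ci in range(n_decoys + 1):
            base = np.array([ci * 40.0, si * 7.0, 0.0])
            if ci == 0:
                tri = planted
            else:
                while True:
                    tri = rng.uniform(-4, 4, size=(3, 3))
                    od = sides(tri)
                    if od.min() <= 1.0 or od.max() >= 8.0:
                        continue
                    if all(
                        np.prod(np.abs(od - prev)) >= 0.5 for prev in drawn_sides
                    ):
                        drawn_sides.append(od)
                        break
            for p, sym in zip(tri, symbols):
                coords.append(base + p)
                syms.append(sym)
        residues = [
            Residue(symbol=syms[i], seq_index=i + 1, chain_id="A", coords=coords[i])
            for i in range(len(coords))
        ]
        structures.append(ProteinStructure(f"seedset{si}", residues))
        truth.append([0, 1, 2])
    return structures, truth


def motif_fingerprints(fixture: PlantedMotifFixture, radius: float = 10.0) -> list[str]:
    """Sorted-triplet fingerprints realizable by the planted motif: every
    symbol multiset of a motif triple whose pairwise distances fit inside
    the candidate radius (useful for targeted search runs)."""
    s = fixture.structures[0]
    idx = fixture.truth[0]
    fps = set()
    for i, j, k in itertools.combinations(idx, 3):
        if s.dist[i, j] < radius and s.dist[i, k] < radius and s.dist[j, k] < radius:
            fps.add(
                "".join(
                    sorted(
                        s.residues[i].symbol + s.residues[j].symbol + s.residues[k].symbol
                    )
                )
            )
    return sorted(fps)
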