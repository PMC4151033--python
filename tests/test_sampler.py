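"""Fingerprint enumeration, stopping rule and the three Gibbs phases."""

import itertools

import numpy as np
import pytest

from gibbsmotif.pdbio import ProteinStructure, Residue
from gibbsmotif.sampler import (
    ALPHABET,
    SearchParams,
    alignment_average_rmsd,
    bootstrap_phase,
    enumerate_fingerprints,
    enumerate_seed_candidates,
    extend_alignment,
    find_motifs,
    gibbs_iterations_bound,
    refine_alignment,
    unique_fingerprint_multisets,
)
from gibbsmotif.scoring import SubstructureAlignment, load_substitution_table, pair_dist_seeds
from gibbsmotif.synthetic import (
    generate_planted_motif_set,
    generate_seed_decoy_set,
    motif_fingerprints,
    random_coil_structure,
)

from .conftest import random_structure


class TestFingerprints:
    def test_full_enumeration_distinct(self):
        fps = enumerate_fingerprints(8000)
        assert len(fps) == 8000
        assert len(set(fps)) == 8000

    def test_lexicographic_head(self):
        assert enumerate_fingerprints(1) == ["AAA"]
        assert enumerate_fingerprints(3)[:3] == ["AAA", "AAC", "AAD"]

    def test_two_letter_subset_count(self):
        fps = enumerate_fingerprints(8000)
        assert sum(1 for f in fps if set(f) <= {"A", "C"}) == 8  # 2^3

    def test_cap_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_fingerprints(0)
        with pytest.raises(ValueError):
            enumerate_fingerprints(8001)

    def test_multiset_dedup_count(self):
        # multisets of size 3 over 20 letters: C(22,3) = 1540
        assert len(unique_fingerprint_multisets(enumerate_fingerprints(8000))) == 1540


class TestSeedCandidates:
    def test_forced_unique_clique(self):
        structures, _ = generate_seed_decoy_set(n_structures=1, n_decoys=0, rng=0)
        seeds = enumerate_seed_candidates(structures[0], "AAC", 10.0)
        assert [s.residue_indices for s in seeds] == [(0, 1, 2)]

    def test_missing_symbol_gives_empty(self, rng):
        s = random_coil_structure(20, rng)
        # fabricate a fingerprint using a symbol absent from the structure
        absent = next(c for c in ALPHABET if c not in s.sequence)
        assert enumerate_seed_candidates(s, absent * 3, 10.0) == []

    def test_agrees_with_cubic_bruteforce(self, rng):
        s = random_coil_structure(30, rng)
        fp = "".join(sorted(rng.choice(list(s.sequence), 3)))
        got = {x.residue_indices for x in enumerate_seed_candidates(s, fp, 10.0)}
        want = set()
        for i, j, k in itertools.combinations(range(30), 3):
            syms = sorted(s.residues[t].symbol for t in (i, j, k))
            if "".join(syms) != "".join(sorted(fp)):
                continue
            if max(s.dist[i, j], s.dist[i, k], s.dist[j, k]) < 10.0:
                want.add((i, j, k))
        assert got == want

    def test_ordered_mode_respects_symbol_positions(self):
        coords = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0]])
        res = [
            Residue(symbol=s, seq_index=i + 1, chain_id="A", coords=coords[i])
            for i, s in enumerate("ACA")
        ]
        s = ProteinStructure("ord", res)
        ordered = enumerate_seed_candidates(s, "ACA", 10.0, ordered=True)
        assert {x.residue_indices for x in ordered} == {(0, 1, 2), (2, 1, 0)}


class TestStoppingRule:
    def test_derived_examples(self):
        assert gibbs_iterations_bound(6, 0.05) == 16
        assert gibbs_iterations_bound(2, 0.25) == 1

    def test_zero_when_alpha_at_or_above_ratio(self):
        assert gibbs_iterations_bound(2, 0.5) == 0
        assert gibbs_iterations_bound(4, 0.9) == 0

    def test_matches_bruteforce_scan(self):
        for n in range(2, 30):
            for alpha in (0.01, 0.05, 0.1, 0.3, 0.7):
                r = (n - 1) / n
                brute = 0
                k = 1
                while r**k > alpha:
                    brute = k
                    k += 1
                assert gibbs_iterations_bound(n, alpha) == brute

    def test_invalid_domain(self):
        with pytest.raises(ValueError):
            gibbs_iterations_bound(1, 0.05)
        with pytest.raises(ValueError):
            gibbs_iterations_bound(5, 0.0)


class TestBootstrap:
    def test_unique_candidates_forced(self):
        structures, truth = generate_seed_decoy_set(n_structures=3, n_decoys=0, rng=1)
        params = SearchParams(w=3, alpha=0.05)
        out = bootstrap_phase(structures, "AAC", params, np.random.default_rng(0))
        assert [list(s.residue_indices) for s in out] == truth

    def test_structure_without_candidates_returns_none(self, rng):
        structures, _ = generate_seed_decoy_set(n_structures=3, n_decoys=2, rng=2)
        no_match = random_coil_structure(10, rng, id="nomatch")
        params = SearchParams(w=3)
        out = bootstrap_phase(
            structures + [no_match], "WWW", params, np.random.default_rng(0)
        )
        assert out is None

    def test_recovers_planted_optimum(self):
        structures, truth = generate_seed_decoy_set(n_structures=4, n_decoys=5, rng=3)
        params = SearchParams(w=3, alpha=0.05)
        hits = 0
        for run in range(30):
            out = bootstrap_phase(
                structures, "AAC", params, np.random.default_rng(100 + run)
            )
            if [list(s.residue_indices) for s in out] == truth:
                hits += 1
        assert hits >= 27  # planted zero-distance combination dominates

    def test_alpha_controls_chain_length_and_accuracy(self):
        """Longer chains (smaller alpha) recover the planted optimum at
        least as often — monotonicity smoke test."""
        structures, truth = generate_seed_decoy_set(n_structures=4, n_decoys=5, rng=3)
        rates = []
        for alpha in (0.3, 0.05):
            params = SearchParams(w=3, alpha=alpha)
            hits = sum(
                [list(s.residue_indices) for s in
                 bootstrap_phase(structures, "AAC", params, np.random.default_rng(200 + r))] == truth
                for r in range(30)
            )
            rates.append(hits)
        assert rates[1] >= rates[0]

    def test_stall_rule_runs_at_least_k_steps_after_last_change(self):
        """Instrument the RNG to count steps; the chain must take at least
        gibbs_iterations_bound(N, alpha) draws after its last state change."""
        # 6 candidates per structure, so integers(4) is only the structure pick
        structures, _ = generate_seed_decoy_set(n_structures=4, n_decoys=5, rng=5)
        params = SearchParams(w=3, alpha=0.05)
        k = gibbs_iterations_bound(4, params.alpha)

        class CountingRng:
            """Delegates to a real generator, counting structure picks."""

            def __init__(self, seed):
                self._rng = np.random.default_rng(seed)
                self.structure_picks = 0

            def integers(self, *args, **kwargs):
                if args == (4,):
                    self.structure_picks += 1
                return self._rng.integers(*args, **kwargs)

            def choice(self, *args, **kwargs):
                return self._rng.choice(*args, **kwargs)

        rng = CountingRng(0)
        bootstrap_phase(structures, "AAC", params, rng)
        assert rng.structure_picks >= k


def identical_structures_fixture(n=3, length=30, seed=4):
    base = random_coil_structure(length, np.random.default_rng(seed), id="base")
    return [
        ProteinStructure(f"copy{i}", list(base.residues)) for i in range(n)
    ]


class TestExtension:
    def test_full_width_returned_unchanged(self, rng):
        structures = identical_structures_fixture()
        al = SubstructureAlignment(
            [s.id for s in structures], [[0, 1, 2]] * 3
        )
        params = SearchParams(w=3)
        out = extend_alignment(structures, al, params, np.random.default_rng(0))
        assert out.rows == al.rows

    def test_isolated_row_returns_none(self):
        # each cluster is a 3-residue island: no unused residue within 10 A
        structures, _ = generate_seed_decoy_set(n_structures=2, n_decoys=0, rng=6)
        al = SubstructureAlignment([s.id for s in structures], [[0, 1, 2]] * 2)
        params = SearchParams(w=5)
        assert extend_alignment(structures, al, params, np.random.default_rng(0)) is None

    def test_gate_violation_raises(self):
        structures, _ = generate_seed_decoy_set(n_structures=2, n_decoys=1, rng=7)
        # planted row vs decoy row: geometries differ well beyond 1 A
        al = SubstructureAlignment(
            [s.id for s in structures], [[0, 1, 2], [3, 4, 5]]
        )
        params = SearchParams(w=4)
        if alignment_average_rmsd(al, structures) > params.seed_rmsd_gate:
            with pytest.raises(ValueError, match="gate"):
                extend_alignment(structures, al, params, np.random.default_rng(0))

    def test_identical_structures_extend_to_identical_rows(self):
        structures = identical_structures_fixture(n=3, length=30, seed=8)
        # seed: first three residues of the coil (consecutive -> within 10 A)
        al = SubstructureAlignment([s.id for s in structures], [[0, 1, 2]] * 3)
        params = SearchParams(w=8)
        ok = 0
        for run in range(50):
            out = extend_alignment(
                structures, al, params, np.random.default_rng(300 + run)
            )
            assert out is not None and out.width == 8
            if out.rows[0] == out.rows[1] == out.rows[2]:
                assert alignment_average_rmsd(out, structures) <= 1e-8
                ok += 1
        assert ok >= 45  # index-identical columns are floored-maximal


class TestRefinement:
    def test_zero_iterations_is_identity(self):
        structures = identical_structures_fixture()
        al = SubstructureAlignment([s.id for s in structures], [[0, 1, 2, 3]] * 3)
        params = SearchParams(w=4, iter_refine=0)
        out = refine_alignment(structures, al, params, np.random.default_rng(0))
        assert out.rows == al.rows

    def test_corrupted_column_has_maximal_badness(self):
        from gibbsmotif.scoring import badness

        structures = identical_structures_fixture(n=3, length=30, seed=9)
        rows = [[0, 1, 2, 3, 4]] * 2 + [[0, 1, 20, 3, 4]]  # column 2 corrupted
        al = SubstructureAlignment([s.id for s in structures], [list(r) for r in rows])
        scores = [badness(al, structures, k) for k in range(5)]
        assert int(np.argmax(scores)) == 2

    def test_perfect_alignment_tiebreak_and_restoration(self):
        """All badness scores are zero, so column 0 goes by tie-break; the
        replacement column restores a zero-RMSD alignment in nearly every
        run (the stall rule leaves an ~alpha chance that one structure is
        never resampled before the chain stops)."""
        structures = identical_structures_fixture(n=3, length=30, seed=10)
        al = SubstructureAlignment([s.id for s in structures], [[0, 1, 2, 3]] * 3)
        params = SearchParams(w=4, iter_refine=1)
        restored = 0
        for run in range(20):
            out = refine_alignment(structures, al, params, np.random.default_rng(run))
            assert out.width == 4
            if alignment_average_rmsd(out, structures) <= 1e-8:
                restored += 1
        assert restored >= 17


class TestDriver:
    def test_requires_two_structures_and_fitting_w(self, rng):
        s = random_coil_structure(20, rng)
        with pytest.raises(ValueError):
            find_motifs([s], SearchParams(w=5))
        structures, _ = generate_seed_decoy_set(n_structures=2, n_decoys=1, rng=11)
        with pytest.raises(ValueError):
            find_motifs(structures, SearchParams(w=50))

    def test_deterministic_given_seed(self):
        fx = generate_planted_motif_set(3, 6, 30, 0.1, rng=12)
        fps = motif_fingerprints(fx)[:5]
        params = SearchParams(w=6, rng_seed=77)
        r1 = find_motifs(fx.structures, params, fingerprints=fps)
        r2 = find_motifs(fx.structures, params, fingerprints=fps)
        assert [a.rows for a in r1] == [a.rows for a in r2]
        assert [a.score for a in r1] == [a.score for a in r2]

    def test_alignment_invariants(self):
        """Every returned alignment: N rows of width w, no repeats within a
        row, and each row connected in the candidate-radius graph."""
        fx = generate_planted_motif_set(3, 6, 30, 0.1, rng=13)
        fps = motif_fingerprints(fx)[:8]
        params = SearchParams(w=6, rng_seed=5)
        results = find_motifs(fx.structures, params, fingerprints=fps)
        assert results, "planted fixture should yield at least one alignment"
        by_id = {s.id: s for s in fx.structures}
        for al in results:
            assert al.n == 3 and al.width == 6
            for sid, row in zip(al.structure_ids, al.rows):
                assert len(set(row)) == len(row)
                s = by_id[sid]
                # connectivity under the 10 A radius graph (BFS)
                adj = {
                    i: [j for j in row if j != i and s.dist[i, j] <= 10.0]
                    for i in row
                }
                seen = {row[0]}
                changed = True
                while changed:
                    changed = False
                    for i in list(seen):
                        for j in adj[i]:
                            if j not in seen:
                                seen.add(j)
                                changed = True
                assert seen == set(row)
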