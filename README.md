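# gibbsmotif

Multiple **local** alignment of protein 3D structures: given N structures
P₁…P_N and a size w ≥ 3, find N substructures of w residues — one per
structure — whose Cα geometries are maximally conserved. Conserved local
substructures often correspond to structural motifs or binding sites shared
by proteins that are otherwise unrelated in sequence or fold, so the tool is
aimed at people hunting for common active sites, interface patches or
recurring super-secondary fragments across a family of structures.

## Method

Alignment quality is the average, over all N(N−1)/2 structure pairs, of the
root-mean-square deviation after optimal rigid-body superposition,

    RMSD(C, D) = min over rotations/translations of sqrt( (1/k) Σᵢ ‖Cᵢ − Dᵢ‖² ),

computed with a quaternion characteristic-polynomial (QCP) fast path and a
Kabsch-SVD reference route. Lower average pairwise RMSD = better alignment.

Finding the optimal set of substructures exactly is intractable, so the
search is stochastic — Markov-chain Monte Carlo with Gibbs sampling, one
outer iteration per amino-acid-triplet *fingerprint* (20³ = 8000 triplets):

1. **Bootstrap.** Candidate *seeds* are residue triples matching the
   fingerprint with all pairwise Cα distances under 10 Å. A Gibbs chain over
   one seed per structure repeatedly picks a structure uniformly at random
   and resamples its seed with probability proportional to
   Sim(X) = 1 / Π PairDist(X, Sᵢ), where PairDist multiplies the absolute
   differences of the two triples' internal distances. The chain stops after
   k unchanged steps, k = max{k′ : ((N−1)/N)^k′ > α}.
2. **Extension.** A seed alignment with average pairwise RMSD ≤ 1 Å grows
   one column at a time up to width w. Candidates are unused residues within
   10 Å of the current substructure; the Gibbs score is the product of a
   positive substitution-matrix similarity (2^BLOSUM62) and the inverse
   distance-profile discrepancy against the other structures' candidates.
3. **Refinement.** For IterRefine rounds, the column with the highest
   *badness* (summed inter-structure discrepancy of its distance profile) is
   deleted and one extension step replaces it.

Surviving alignments are sorted by ascending average RMSD and greedily
filtered: an alignment whose residues were already reported by better-ranked
alignments (above the AvgOverlap threshold, in percent) is discarded.

All scores use intra-structure distances only, so no score ever depends on
how the input structures happen to be oriented.

## Worked example

The package ships a generator for synthetic structure sets with a planted
motif, so the tool can be exercised without downloading anything:

```python
from pathlib import Path
from gibbsmotif import generate_planted_motif_set, write_calpha_pdb

fx = generate_planted_motif_set(
    n_structures=3, motif_size=6, decoy_length=30, noise_sigma=0.1, rng=5
)
out = Path("demo"); out.mkdir(exist_ok=True)
for s in fx.structures:
    (out / f"{s.id}.pdb").write_text(write_calpha_pdb(s))
print(fx.truth[0])   # planted residue indices in synth0: [21, ..., 26]
```

Each structure is a 30-residue random coil plus a noisy rigid copy of the
same 6-residue helical motif. Running the search:

```
$ gibbsmotif demo/*.pdb --w 6 --rng-seed 1 --max-fingerprints 2000 --out demo_out
1 alignment(s) reported (7 found); wrote alignments.tsv, alignments.json, manifest.json to demo_out/

$ head -2 demo_out/alignments.tsv
rank    avg_rmsd_A      perc_overlap    alignment
1       0.190804        0.00    synth0=22,23,24,27,26,25;synth1=29,30,31,34,33,32;synth2=5,6,7,10,9,8
```

The one reported alignment has average pairwise RMSD 0.19 Å — consistent
with the 0.1 Å coordinate noise used when planting — and its residue numbers
(22–27 in `synth0`, 29–34 in `synth1`, 5–10 in `synth2`) are exactly the
planted motif copies. `perc_overlap` is the overlap each alignment had with
better-ranked ones (0 for the top hit); `manifest.json` records every
parameter and the RNG seed, so the identical command reproduces the report
byte for byte.

The library surface mirrors the pipeline (`read_calpha_structure`,
`find_motifs`, `sort_alignments`, `filter_overlapping`,
`query_motif_coverage`, …) for use without the CLI.

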