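"""Ranking, overlap filtering and evaluation of reported alignments.

Alignments are ranked by ascending average pairwise RMSD and then scanned
greedily: an alignment whose residues were already mostly reported by
better-ranked alignments is redundant and is discarded. Overlap is counted
per structure and per residue identity (structure id + residue index), not
per column, and averaged across structures.

``query_motif_coverage`` is the evaluation metric for runs against a known
reference motif: the percentage of the motif's residues recovered in the
reported row of the query structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .pdbio import ProteinStructure
from .scoring import SubstructureAlignment

__all__ = [
    "RankedAlignmentList",
    "sort_alignments",
    "overlap_percentage",
    "filter_overlapping",
    "query_motif_coverage",
    "report_tsv",
    "report_json",
    "report_fasta",
]


@dataclass
class RankedAlignmentList:
    """Alignments sorted by ascending average RMSD, with the overlap
    percentage each one had against the alignments kept before it."""

    alignments: list[SubstructureAlignment] = field(default_factory=list)
    overlaps: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.alignments)

    def __iter__(self):
        return iter(self.alignments)


def sort_alignments(
    alignments: Sequence[SubstructureAlignment],
) -> RankedAlignmentList:
    """Stable ascending sort by average pairwise RMSD (ties keep discovery
    order). Every alignment must carry a computed score."""
    for al in alignments:
        if al.score is None:
            raise ValueError("alignment has no computed score")
    ranked = sorted(alignments, key=lambda a: a.score)  # sorted() is stable
    return RankedAlignmentList(alignments=list(ranked), overlaps=[0.0] * len(ranked))


def overlap_percentage(
    al: SubstructureAlignment, kept: Sequence[SubstructureAlignment]
) -> float:
    """Mean, over rows, of the percentage of the row's residues already
    reported for the same structure by any alignment in *kept*."""
    if not kept:
        return 0.0
    seen: dict[str, set[int]] = {}
    for prev in kept:
        if set(prev.structure_ids) != set(al.structure_ids):
            raise ValueError("alignments cover different structure sets")
        for sid, row in zip(prev.structure_ids, prev.rows):
            seen.setdefault(sid, set()).update(row)
    percs = []
    for sid, row in zip(al.structure_ids, al.rows):
        hits = sum(1 for r in row if r in seen.get(sid, ()))
        percs.append(100.0 * hits / len(row))
    return sum(percs) / len(percs)


def filter_overlapping(
    ranked: RankedAlignmentList, threshold: float
) -> RankedAlignmentList:
    """Greedy non-redundancy scan in rank order.

    An alignment is kept iff its overlap with the already-kept set does not
    exceed *threshold* percent (strictly above discards); threshold 100
    keeps everything. Idempotent: filtering a filtered list is a no-op.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    kept: list[SubstructureAlignment] = []
    overlaps: list[float] = []
    for al in ranked:
        perc = overlap_percentage(al, kept)
        if perc > threshold:
            continue
        kept.append(al)
        overlaps.append(perc)
    return RankedAlignmentList(alignments=kept, overlaps=overlaps)


def query_motif_coverage(
    reported_row: Sequence[int], query_motif: Sequence[int]
) -> float:
    """Percentage of the query motif's residues present in a reported row
    (both given as residue indices on the query structure)."""
    motif = set(query_motif)
    if not motif:
        raise ValueError("query motif must be nonempty")
    return 100.0 * len(set(reported_row) & motif) / len(motif)


# ---------------------------------------------------------------------------
# report writers


def _row_residue_numbers(
    al: SubstructureAlignment, structures: Sequence[ProteinStructure]
) -> list[list[int]]:
    by_id = {s.id: s for s in structures}
    return [
        [by_id[sid].residues[i].seq_index for i in row]
        for sid, row in zip(al.structure_ids, al.rows)
    ]


def report_tsv(
    ranked: RankedAlignmentList, structures: Sequence[ProteinStructure]
) -> str:
    """One line per alignment: rank, average RMSD, overlap percentage, and
    per structure the original residue numbers of its substructure."""
    lines = ["rank\tavg_rmsd_A\tperc_overlap\talignment"]
    for rank, (al, perc) in enumerate(zip(ranked.alignments, ranked.overlaps), 1):
        nums = _row_residue_numbers(al, structures)
        cell = ";".join(
            f"{sid}={','.join(str(n) for n in row)}"
            for sid, row in zip(al.structure_ids, nums)
        )
        lines.append(f"{rank}\t{al.score:.6f}\t{perc:.2f}\t{cell}")
    return "\n".join(lines) + "\n"


def report_json(
    ranked: RankedAlignmentList, structures: Sequence[ProteinStructure]
) -> str:
    """Full nested record of the ranked alignment list."""
    by_id = {s.id: s for s in structures}
    records = []
    for rank, (al, perc) in enumerate(zip(ranked.alignments, ranked.overlaps), 1):
        rows = []
        for sid, row in zip(al.structure_ids, al.rows):
            s = by_id[sid]
            rows.append(
                {
                    "structure": sid,
                    "residue_indices": list(row),
                    "residue_numbers": [s.residues[i].seq_index for i in row],
                    "sequence": "".join(s.residues[i].symbol for i in row),
                }
            )
        records.append(
            {
                "rank": rank,
                "avg_rmsd_A": al.score,
                "perc_overlap": perc,
                "rows": rows,
            }
        )
    return json.dumps({"alignments": records}, indent=2) + "\n"


def report_fasta(
    ranked: RankedAlignmentList, structures: Sequence[ProteinStructure]
) -> str:
    """Motif sequences of every reported alignment as multi-FASTA."""
    by_id = {s.id: s for s in structures}
    chunks = []
    for rank, al in enumerate(ranked.alignments, 1):
        for sid, row in zip(al.structure_ids, al.rows):
            s = by_id[sid]
            seq = "".join(s.residues[i].symbol for i in row)
            chunks.append(f">aln{rank}|{sid}\n{seq}\n")
    return "".join(chunks)
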