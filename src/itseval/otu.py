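"""Pairwise distances, greedy 97% OTU clustering, and the OTU table.

Species-level OTUs are built by greedy abundance-sorted centroid clustering:
uniques are visited from most to least abundant and each joins the first
existing centroid within the similarity threshold, else founds a new OTU.
This is deterministic given the dereplication order and is the standard
de novo strategy for amplicon OTUs.

Distances come from a global Needleman-Wunsch alignment (match +1,
mismatch -1, gap -2) with the classic amplicon conventions: terminal gaps are
excluded, and a run of contiguous gaps counts as a single difference event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .readpipe import UniqueSeq

__all__ = [
    "OTU",
    "OTUTable",
    "pairwise_distance",
    "cluster_otus",
    "build_otu_table",
    "remove_global_singletons",
]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    # Each gap base costs -2; the small extra opening cost only breaks ties
    # among equal-score alignments toward contiguous gap runs, so
    # "one run = one event" is well defined.  It is far below the smallest
    # genuine score difference (1) yet above the aligner's float32
    # resolution at amplicon-scale scores.
    a.open_gap_score = -2 - 1e-3
    a.extend_gap_score = -2
    return a


_ALIGNER = _aligner()


def pairwise_distance(a: str, b: str) -> float:
    """Alignment-based distance between two sequences, in [0, 1].

    distance = (mismatches + internal gap events) / alignment columns,
    with terminal gaps excluded from both counts and a contiguous gap run in
    either sequence counting as one event.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 0.0
    aln = _ALIGNER.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    both = [i for i in range(len(ga)) if ga[i] != "-" and gb[i] != "-"]
    start, end = both[0], both[-1] + 1  # exclude terminal gap columns
    mismatches = 0
    gap_events = 0
    in_gap_a = in_gap_b = False
    for i in range(start, end):
        ca, cb = ga[i], gb[i]
        if ca == "-":
            if not in_gap_a:
                gap_events += 1
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            if not in_gap_b:
                gap_events += 1
            in_gap_b, in_gap_a = True, False
        else:
            in_gap_a = in_gap_b = False
            if ca != cb:
                mismatches += 1
    n_cols = end - start
    return (mismatches + gap_events) / n_cols


@dataclass
class OTU:
    """A cluster of unique sequences; the centroid is its representative."""

    otu_id: str
    representative: str
    members: list[UniqueSeq] = field(default_factory=list)

    @property
    def abundance(self) -> int:
        return sum(m.abundance for m in self.members)

    def sample_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            for sid, c in (m.sample_counts or {"": m.abundance}).items():
                counts[sid] = counts.get(sid, 0) + c
        return counts


def cluster_otus(uniques: Sequence[UniqueSeq], similarity: float = 0.97
                 ) -> list[OTU]:
    """Greedy centroid clustering at the given similarity threshold.

    ``uniques`` must be sorted by decreasing abundance (ties lexicographic),
    as produced by :func:`itseval.readpipe.dereplicate`; the most abundant
    member of each OTU is therefore its founding centroid and representative.
    """
    if not (0 < similarity <= 1):
        raise ValueError("similarity must be in (0, 1]")
    cutoff = 1.0 - similarity
    otus: list[OTU] = []
    for u in uniques:
        placed = False
        for otu in otus:
            if pairwise_distance(u.sequence, otu.representative) <= cutoff:
                otu.members.append(u)
                placed = True
                break
        if not placed:
            otus.append(OTU(otu_id=f"OTU{len(otus) + 1:04d}",
                            representative=u.sequence, members=[u]))
    return otus


@dataclass
class OTUTable:
    """Samples x OTUs count matrix with per-OTU representative sequences."""

    counts: pd.DataFrame  # index: sample ids; columns: OTU ids
    representatives: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.representatives)
        if missing:
            raise ValueError(f"no representative for {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")


def build_otu_table(otus: Sequence[OTU],
                    samples: Sequence[str] | None = None) -> OTUTable:
    """Assemble the samples x OTUs matrix from clustered OTUs."""
    per_otu = {o.otu_id: o.sample_counts() for o in otus}
    if samples is None:
        samples = sorted({s for c in per_otu.values() for s in c})
    counts = pd.DataFrame(
        {oid: [c.get(s, 0) for s in samples] for oid, c in per_otu.items()},
        index=list(samples), dtype=int)
    reps = {o.otu_id: o.representative for o in otus}
    return OTUTable(counts=counts, representatives=reps)


def remove_global_singletons(table: OTUTable) -> OTUTable:
    """Drop OTUs represented by a single read over the entire dataset."""
    totals = table.counts.sum(axis=0)
    keep = totals[totals != 1].index
    return OTUTable(
        counts=table.counts[keep].copy(),
        representatives={k: table.representatives[k] for k in keep})
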