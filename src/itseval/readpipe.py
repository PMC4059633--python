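"""Read processing: demultiplexing, quality trimming, dereplication, and a
simplified de novo chimera detector.

Demultiplexing follows the multiplexed 454 layout — each read begins with
adaptor + MID + forward primer and ends with the reverse complement of
adaptor + MID + reverse primer.  A read is assigned to a sample only when the
MIDs at both ends match with at most ``mid_max_err`` substitutions and both
primers with at most ``primer_max_err`` substitutions (no indels: fixed-length
Hamming matching, the dominant convention for 10-base MIDs).

Quality trimming applies, in order: truncation at the first 50-base sliding
window whose mean Phred drops below 35; removal of reads with ambiguous
bases; removal of reads with homopolymers longer than 8 bases; removal of
reads shorter than 200 or longer than 600 bases after truncation.

The chimera stage is a deliberately simplified two-parent single-crossover
detector (not a UCHIME reimplementation): a query is flagged when some
concatenation of a prefix of one abundant parent and a suffix of another
explains the query strictly better than either parent alone.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import FusionPrimer, PipelineConfig, Read, hamming, reverse_complement

__all__ = [
    "DemuxRule",
    "DemuxResult",
    "UniqueSeq",
    "demultiplex",
    "quality_trim",
    "dereplicate",
    "flag_chimeras",
]

_AMBIG = set("RYSWKMBDHVN")


@dataclass(frozen=True)
class DemuxRule:
    """Error tolerances for sample assignment."""

    mid_max_err: int = 1
    primer_max_err: int = 2
    require_both_ends: bool = True

    def __post_init__(self) -> None:
        if self.mid_max_err < 0 or self.primer_max_err < 0:
            raise ValueError("error tolerances must be >= 0")


@dataclass
class DemuxResult:
    assigned: list[Read]
    unassigned: list[Read]
    log: list[dict]  # read_id, sample, mid/primer error counts per end


@dataclass
class UniqueSeq:
    """A dereplicated sequence with its abundance and provenance."""

    sequence: str
    abundance: int
    member_ids: list[str] = field(default_factory=list)
    sample_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_counts and sum(self.sample_counts.values()) != self.abundance:
            raise ValueError("per-sample counts must sum to the abundance")


def _match_end(segment: str, mid: str, primer_seq: str, rule: DemuxRule
               ) -> Optional[tuple[int, int]]:
    """(mid_errors, primer_errors) if ``segment`` = MID+primer within
    tolerance, else None.  ``segment`` must already exclude the adaptor."""
    m = len(mid)
    p = len(primer_seq)
    if len(segment) < m + p:
        return None
    mid_err = hamming(segment[:m], mid)
    if mid_err > rule.mid_max_err:
        return None
    primer_err = hamming(segment[m:m + p], primer_seq)
    if primer_err > rule.primer_max_err:
        return None
    return mid_err, primer_err


def demultiplex(reads: Iterable[Read],
                samples: Sequence[tuple[str, FusionPrimer, FusionPrimer]],
                rule: DemuxRule | None = None) -> DemuxResult:
    """Assign reads to samples by their MID+primer decorations at both ends.

    ``samples`` lists (sample_id, forward fusion primer, reverse fusion
    primer).  Assigned reads have adaptor, MID and primer clipped from both
    ends and ``sample_id`` set.  When several samples qualify, the one with
    the fewest total erroneous bases wins (ties to the first listed).
    """
    rule = rule or DemuxRule()
    ids = [s[0] for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in demultiplexing table")
    # MIDs should be separated by more than twice the tolerance, else a read
    # could sit within tolerance of two samples.
    mids = [s[1].mid for s in samples]
    for (i, a), (j, b) in itertools.combinations(enumerate(mids), 2):
        if len(a) == len(b) and hamming(a, b) <= 2 * rule.mid_max_err:
            warnings.warn(
                f"MIDs of samples {ids[i]!r} and {ids[j]!r} are only "
                f"{hamming(a, b)} substitutions apart", stacklevel=2)

    assigned: list[Read] = []
    unassigned: list[Read] = []
    log: list[dict] = []
    for read in reads:
        best = None  # (total_err, sample_idx, errs, clip_coords)
        for idx, (sid, fwd, rev) in enumerate(samples):
            a_len = len(fwd.adaptor)
            front = _match_end(read.bases[a_len:], fwd.mid, fwd.primer.sequence, rule)
            if front is None:
                continue
            # reverse decoration appears reverse-complemented at the 3' end
            a2_len = len(rev.adaptor)
            tail_len = a2_len + 10 + len(rev.primer)
            clip_start = a_len + 10 + len(fwd.primer.sequence)
            if len(read.bases) < clip_start + tail_len:
                continue  # too short to contain the reverse decoration
            tail = reverse_complement(read.bases[len(read.bases) - tail_len:
                                                 len(read.bases) - a2_len])
            back = _match_end(tail, rev.mid, rev.primer.sequence, rule)
            if back is None:
                continue
            total = front[0] + front[1] + back[0] + back[1]
            entry = (total, idx, front, back,
                     (clip_start, len(read.bases) - tail_len))
            if best is None or entry[:2] < best[:2]:
                best = entry
        if best is None:
            unassigned.append(read)
            log.append({"read_id": read.id, "sample": "",
                        "mid_errors_fwd": "", "mid_errors_rev": "",
                        "primer_errors_fwd": "", "primer_errors_rev": ""})
        else:
            _, idx, front, back, (lo, hi) = best
            clipped = read.slice(lo, hi)
            clipped.sample_id = samples[idx][0]
            assigned.append(clipped)
            log.append({"read_id": read.id, "sample": samples[idx][0],
                        "mid_errors_fwd": front[0], "mid_errors_rev": back[0],
                        "primer_errors_fwd": front[1], "primer_errors_rev": back[1]})
    return DemuxResult(assigned=assigned, unassigned=unassigned, log=log)


def _truncate_at_low_quality(read: Read, window: int, threshold: float) -> Read:
    """Cut the read at the start of the first sliding window (step 1) whose
    mean Phred falls below the threshold."""
    if read.quals is None or len(read.quals) < window:
        return read
    q = np.asarray(read.quals, dtype=float)
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    bad = np.nonzero(means < threshold)[0]
    if len(bad) == 0:
        return read
    return read.slice(0, int(bad[0]))


def _max_homopolymer(seq: str) -> int:
    return max((len(list(g)) for _, g in itertools.groupby(seq)), default=0)


def quality_trim(reads: Iterable[Read], cfg: PipelineConfig | None = None
                 ) -> list[Read]:
    """Apply the window truncation and the four removal filters in order."""
    cfg = cfg or PipelineConfig()
    warned = False
    out = []
    for read in reads:
        if read.quals is None and not warned:
            warnings.warn("reads carry no quality scores; window truncation "
                          "skipped", stacklevel=2)
            warned = True
        read = _truncate_at_low_quality(read, cfg.qual_window, cfg.qual_threshold)
        if any(b in _AMBIG for b in read.bases):
            continue
        if _max_homopolymer(read.bases) > cfg.max_homopolymer:
            continue
        if not (cfg.min_len <= len(read) <= cfg.max_len):
            continue
        out.append(read)
    return out


def dereplicate(reads: Iterable[Read]) -> list[UniqueSeq]:
    """Collapse exact duplicates, archiving abundance and per-sample counts.

    Output is sorted by decreasing abundance, ties broken lexicographically
    by sequence — the order downstream greedy clustering relies on.
    """
    groups: dict[str, UniqueSeq] = {}
    for read in reads:
        u = groups.get(read.bases)
        if u is None:
            u = groups[read.bases] = UniqueSeq(sequence=read.bases, abundance=0)
        u.abundance += 1
        u.member_ids.append(read.id)
        key = read.sample_id or ""
        u.sample_counts[key] = u.sample_counts.get(key, 0) + 1
    return sorted(groups.values(), key=lambda u: (-u.abundance, u.sequence))


def _edit_matrix(a: str, b: str, free_b_start: bool = False) -> np.ndarray:
    """Unit-cost edit-distance DP matrix, D[i, j] = dist(a[:i], b[:j]).

    With ``free_b_start`` the leading bases of ``b`` are free (row 0 is all
    zeros), i.e. ``a``-prefixes are matched against arbitrary substrings
    of ``b`` ending at j."""
    n, m = len(a), len(b)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    D = np.empty((n + 1, m + 1), dtype=np.int32)
    D[0] = 0 if free_b_start else np.arange(m + 1)
    cols = np.arange(m)
    for i in range(1, n + 1):
        sub = (bb != ord(a[i - 1])).astype(np.int32)
        t = np.minimum(D[i - 1, 1:] + 1, D[i - 1, :-1] + sub)
        # resolve the left-to-right insertion dependency with a prefix scan
        D[i, 0] = i
        D[i, 1:] = np.minimum.accumulate(t - cols) + cols
        D[i, 1:] = np.minimum(D[i, 1:], D[i, 0] + 1 + cols)
    return D


def flag_chimeras(uniques: Sequence[UniqueSeq], min_parent_fold: float = 2.0,
                  min_div: float = 0.8, max_model_div: float = 5.0,
                  ) -> tuple[list[UniqueSeq], list[UniqueSeq]]:
    """Split uniques into (clean, flagged) by a two-parent crossover test.

    For each query, candidate parents are uniques at least
    ``min_parent_fold`` times more abundant.  The query is flagged when the
    best prefix-of-A + suffix-of-B model (single crossover, any crossover
    point) beats the better single parent by at least ``min_div`` percent of
    the query length, and the model itself diverges from the query by at most
    ``max_model_div`` percent — true chimeras are near-exact mosaics of their
    parents, and the cap stops unrelated sequence triples from being called.
    Distances are unit-cost edit distances with free parent ends (the query
    is matched against parent substrings), so reads that are mere truncated
    copies of a parent are never called chimeric.
    """
    order = sorted(range(len(uniques)),
                   key=lambda i: (-uniques[i].abundance, uniques[i].sequence))
    clean: list[UniqueSeq] = []
    flagged: list[UniqueSeq] = []
    for qi in order:
        q = uniques[qi]
        parents = [u for u in uniques
                   if u is not q and u.abundance >= min_parent_fold * q.abundance]
        if len(parents) < 2:
            clean.append(q)
            continue
        n = len(q.sequence)
        # per-parent: infix distance (query vs best parent substring), and
        # row minima of the forward/backward DP matrices (best match of each
        # query prefix/suffix against any parent substring)
        fwd_min, bwd_min, full = {}, {}, {}
        for p in parents:
            F = _edit_matrix(q.sequence, p.sequence, free_b_start=True)
            R = _edit_matrix(q.sequence[::-1], p.sequence[::-1], free_b_start=True)
            full[p.sequence] = int(F[n].min())
            fwd_min[p.sequence] = F.min(axis=1)
            bwd_min[p.sequence] = R.min(axis=1)[::-1]
        # the model must beat the best single parent overall, not merely the
        # two parents it is built from — otherwise two fragments of one taxon
        # fake a chimera for a query that is nearly identical to a third
        best_single = min(full.values())
        is_chimera = False
        for pa, pb in itertools.permutations(parents, 2):
            ks = slice(1, n)  # both segments non-empty
            model = int((fwd_min[pa.sequence][ks] + bwd_min[pb.sequence][ks]).min())
            if (model < best_single
                    and (best_single - model) >= min_div / 100.0 * n
                    and model <= max_model_div / 100.0 * n):
                is_chimera = True
                break
        (flagged if is_chimera else clean).append(q)
    return clean, flagged
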