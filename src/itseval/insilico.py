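"""In-silico primer evaluation with a weighted mismatch score.

A primer is aligned end-gap-free against every window of a target sequence and
the alignment minimizing a weighted score is reported.  Mismatches and gaps
falling in the 3' region of the primer (its final ``three_region_len`` bases,
default 5) are penalized more heavily than those elsewhere, because 3'
perturbations are far more disruptive to polymerase extension:

    score = 0.40 * non-3' mismatches + 1.00 * 3' mismatches
          + 1.00 * non-3' gaps       + 3.00 * 3' gaps
          + 3.00 if the final 3' base of the primer is mismatched

The terminal-base mismatch is counted both as an ordinary 3' mismatch (1.00)
and as the additional 3.00 penalty, so a perfect site whose only defect is the
last primer base scores 4.00.  Scores near 0 indicate broad amplification
potential across the target set; the per-primer summary mirrors the usual
report (mean score +/- SE and the percentage of targets with a terminal-base
mismatch).

Reverse primers are scored against the reverse complement of each target, so
"3' end" always refers to the biologically extending end of the oligo;
coordinates in hits are mapped back to the plus strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import Primer, iupac_match, reverse_complement

__all__ = [
    "ScoringWeights",
    "PrimerHit",
    "PrimerScoreSummary",
    "Amplicon",
    "best_hit",
    "find_hits",
    "summarize_primer",
    "virtual_pcr",
]


@dataclass(frozen=True)
class ScoringWeights:
    """Weights of the in-silico score; defaults are the standard ones."""

    non3_mismatch: float = 0.40
    three_mismatch: float = 1.00
    non3_gap: float = 1.00
    three_gap: float = 3.00
    terminal_penalty: float = 3.00
    three_region_len: int = 5

    def __post_init__(self) -> None:
        if self.three_region_len < 1:
            raise ValueError("three_region_len must be >= 1")
        for name in ("non3_mismatch", "three_mismatch", "non3_gap",
                     "three_gap", "terminal_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PrimerHit:
    """One primer-vs-target alignment with categorized event counts.

    ``start``/``end`` are 0-based half-open plus-strand target coordinates of
    the aligned window; ``strand`` is '+' for forward primers, '-' for reverse
    primers (scored on the reverse complement).
    """

    target_id: str
    strand: str
    start: int
    end: int
    n_mm_non3: int
    n_mm_3: int
    n_gap_non3: int
    n_gap_3: int
    terminal_mismatch: bool
    score: float


@dataclass(frozen=True)
class PrimerScoreSummary:
    primer_name: str
    n_targets: int
    mean_score: float
    se_score: float
    pct_terminal_mismatch: float


@dataclass(frozen=True)
class Amplicon:
    """A virtual-PCR product: the insert flanked by a forward and reverse hit."""

    target_id: str
    fwd_hit: PrimerHit
    rev_hit: PrimerHit
    sequence: str
    length: int


# Traceback moves
_DIAG, _VERT, _HORZ = 0, 1, 2

#: Maximum number of single-base gap events allowed in one alignment.
MAX_GAPS = 1


def _align(primer: str, target: str, w: ScoringWeights,
           max_gaps: int = MAX_GAPS):
    """Semi-global DP minimizing the weighted score.

    The primer must be fully aligned with no end gaps: its first and last
    bases align to target bases.  Vertical moves delete a primer base (a gap
    in the target); horizontal moves insert a target base inside the primer
    span (a gap in the primer).  Each gap base is one gap event, categorized
    by the primer position it touches; at most ``max_gaps`` events per
    alignment.  Returns the final DP layer stack and the backtrace.
    """
    P, T = len(primer), len(target)
    three_start = P - w.three_region_len  # primer index from which 3' pricing applies
    INF = math.inf

    def sub_cost(i: int, j: int) -> float:
        if iupac_match(primer[i], target[j]):
            return 0.0
        c = w.three_mismatch if i >= three_start else w.non3_mismatch
        if i == P - 1:
            c += w.terminal_penalty
        return c

    def gap_cost(i: int) -> float:  # gap event touching primer position i
        return w.three_gap if i >= three_start else w.non3_gap

    G = max_gaps
    # D[g][i][j]: best cost with exactly <= structure (g gap events used),
    # primer[:i] consumed, ending at target position j.
    prev = [[0.0] * (T + 1) for _ in range(G + 1)]  # row 0: free leading target
    back: list[list[list[int]]] = []  # back[i-1][g][j]
    for i in range(1, P + 1):
        cur = [[INF] * (T + 1) for _ in range(G + 1)]
        row = [[-1] * (T + 1) for _ in range(G + 1)]
        for g in range(G + 1):
            for j in range(1, T + 1):
                best, mv = prev[g][j - 1] + sub_cost(i - 1, j - 1), _DIAG
                if g > 0 and 1 < i < P:
                    # vertical: skip primer base i-1; not allowed at the ends
                    c = prev[g - 1][j] + gap_cost(i - 1)
                    if c < best:
                        best, mv = c, _VERT
                cur[g][j] = best
                row[g][j] = mv
            # horizontal: insert target base strictly inside the primer span
            if g > 0 and 1 <= i <= P - 1:
                for j in range(2, T + 1):
                    c = cur[g - 1][j - 1] + gap_cost(i)
                    if c < cur[g][j]:
                        cur[g][j] = c
                        row[g][j] = _HORZ
        back.append(row)
        prev = cur
    return prev, back


def _traceback(primer: str, target: str, w: ScoringWeights,
               back, end_g: int, end_j: int):
    """Recover event counts and window start from the backtrace."""
    P = len(primer)
    three_start = P - w.three_region_len
    g, i, j = end_g, P, end_j
    n_mm_non3 = n_mm_3 = n_gap_non3 = n_gap_3 = 0
    terminal_mismatch = False
    while i > 0:
        mv = back[i - 1][g][j]
        if mv == _DIAG:
            if not iupac_match(primer[i - 1], target[j - 1]):
                if i - 1 >= three_start:
                    n_mm_3 += 1
                else:
                    n_mm_non3 += 1
                if i == P:
                    terminal_mismatch = True
            i, j = i - 1, j - 1
        elif mv == _VERT:
            if i - 1 >= three_start:
                n_gap_3 += 1
            else:
                n_gap_non3 += 1
            i, g = i - 1, g - 1
        else:  # _HORZ
            if i >= three_start:
                n_gap_3 += 1
            else:
                n_gap_non3 += 1
            j, g = j - 1, g - 1
    return j, n_mm_non3, n_mm_3, n_gap_non3, n_gap_3, terminal_mismatch


def _best_on_strand(primer: str, target: str, w: ScoringWeights,
                    max_gaps: int = MAX_GAPS):
    layers, back = _align(primer, target, w, max_gaps)
    # leftmost window among ties: smallest qualifying end position; prefer
    # fewer gap events at equal score and position.  Deleted primer bases
    # shorten the window, so ends from len(primer) - max_gaps qualify.
    j_min = max(1, len(primer) - max_gaps)
    best, end_g, end_j = math.inf, 0, len(primer)
    for j in range(j_min, len(target) + 1):
        for g in range(len(layers)):
            if layers[g][j] < best:
                best, end_g, end_j = layers[g][j], g, j
    return best, end_g, end_j, back


def _hit_from(primer: Primer, target_seq: str, target_id: str, strand: str,
              plus_len: int, w: ScoringWeights, score: float, end_g: int,
              end_j: int, back) -> PrimerHit:
    start_j, mm_n, mm_3, gap_n, gap_3, term = _traceback(
        primer.sequence, target_seq, w, back, end_g, end_j)
    if strand == "+":
        start, end = start_j, end_j
    else:  # map [start_j, end_j) on the reverse complement back to plus strand
        start, end = plus_len - end_j, plus_len - start_j
    return PrimerHit(
        target_id=target_id, strand=strand, start=start, end=end,
        n_mm_non3=mm_n, n_mm_3=mm_3, n_gap_non3=gap_n, n_gap_3=gap_3,
        terminal_mismatch=term, score=round(score, 10),
    )


def best_hit(primer: Primer, target: str, weights: ScoringWeights | None = None,
             target_id: str = "") -> PrimerHit:
    """Minimum-weighted-score binding site of ``primer`` on ``target``.

    Forward primers are searched on the plus strand; reverse primers on the
    reverse complement.  Ties between equal-score windows break to the
    leftmost window on the searched strand.
    """
    w = weights or ScoringWeights()
    if not target:
        raise ValueError("empty target sequence")
    if len(target) < len(primer):
        raise ValueError(
            f"target ({len(target)} nt) shorter than primer {primer.name!r} "
            f"({len(primer)} nt)")
    strand = "+" if primer.direction == "forward" else "-"
    search = target.upper() if strand == "+" else reverse_complement(target)
    score, end_g, end_j, back = _best_on_strand(primer.sequence, search, w)
    return _hit_from(primer, search, target_id, strand, len(target), w,
                     score, end_g, end_j, back)


def find_hits(primer: Primer, target: str, weights: ScoringWeights | None = None,
              max_score: float = 0.0, target_id: str = "") -> list[PrimerHit]:
    """All non-overlapping binding sites with score <= ``max_score``.

    Qualifying windows are selected greedily by (score, position); windows
    overlapping an already-selected better site are suppressed.
    """
    w = weights or ScoringWeights()
    if not target or len(target) < len(primer):
        return []
    strand = "+" if primer.direction == "forward" else "-"
    search = target.upper() if strand == "+" else reverse_complement(target)
    layers, back = _align(primer.sequence, search, w)
    cands = []
    for j in range(max(1, len(primer) - MAX_GAPS), len(search) + 1):
        best_g = min(range(len(layers)), key=lambda g: layers[g][j])
        if layers[best_g][j] <= max_score:
            cands.append((layers[best_g][j], j, best_g))
    hits: list[PrimerHit] = []
    taken: list[tuple[int, int]] = []  # on the searched strand
    for score, j, g in sorted(cands):
        start_j = _traceback(primer.sequence, search, w, back, g, j)[0]
        if any(start_j < e and j > s for s, e in taken):
            continue
        taken.append((start_j, j))
        hits.append(_hit_from(primer, search, target_id, strand, len(target),
                              w, score, g, j, back))
    hits.sort(key=lambda h: h.start)
    return hits


def summarize_primer(primer: Primer, targets, weights: ScoringWeights | None = None,
                     ) -> PrimerScoreSummary:
    """Mean +/- SE of best-hit scores and the terminal-mismatch percentage.

    ``targets`` is an iterable of sequences or of (id, sequence) pairs.
    SE is the sample standard deviation over sqrt(n) (0 for n = 1).
    """
    w = weights or ScoringWeights()
    scores: list[float] = []
    n_term = 0
    for item in targets:
        tid, seq = item if isinstance(item, tuple) else ("", item)
        hit = best_hit(primer, seq, w, target_id=tid)
        scores.append(hit.score)
        n_term += hit.terminal_mismatch
    n = len(scores)
    if n == 0:
        raise ValueError("empty target set")
    mean = sum(scores) / n
    if n > 1:
        var = sum((s - mean) ** 2 for s in scores) / (n - 1)
        se = math.sqrt(var) / math.sqrt(n)
    else:
        se = 0.0
    return PrimerScoreSummary(
        primer_name=primer.name, n_targets=n, mean_score=mean, se_score=se,
        pct_terminal_mismatch=100.0 * n_term / n,
    )


def virtual_pcr(fwd: Primer, rev: Primer, target: str,
                weights: ScoringWeights | None = None, max_score: float = 0.0,
                target_id: str = "", include_primers: bool = False,
                ) -> list[Amplicon]:
    """Predicted amplicons for a primer pair on one template.

    Every (forward, reverse) hit pair with both scores <= ``max_score`` and
    the forward site upstream of the reverse site yields one amplicon.  The
    amplicon sequence is the insert between the primers, or the full product
    when ``include_primers`` is set.
    """
    if fwd.direction != "forward" or rev.direction != "reverse":
        raise ValueError("virtual_pcr needs one forward and one reverse primer")
    if max_score < 0:
        raise ValueError("max_score must be >= 0")
    w = weights or ScoringWeights()
    fhits = find_hits(fwd, target, w, max_score, target_id)
    rhits = find_hits(rev, target, w, max_score, target_id)
    amplicons = []
    for fh in fhits:
        for rh in rhits:
            if fh.end > rh.start:
                continue
            if include_primers:
                seq = target[fh.start:rh.end]
            else:
                seq = target[fh.end:rh.start]
            amplicons.append(Amplicon(target_id=target_id, fwd_hit=fh,
                                      rev_hit=rh, sequence=seq, length=len(seq)))
    return amplicons
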