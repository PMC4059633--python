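"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package internals: the primer
scorer enumerates every ungapped and single-gap placement explicitly, and the
clustering oracle assigns sequences by literal rule evaluation.
"""

from __future__ import annotations

import math

from itseval.core import iupac_match
from itseval.insilico import ScoringWeights


def brute_force_best_score(primer: str, target: str,
                           w: ScoringWeights | None = None) -> float:
    """Minimum weighted score over all ungapped and single-gap alignments.

    Enumerates: every ungapped window; every window with one primer base
    deleted (internal positions only); every window with one extra target
    base inserted inside the primer span.  Each alignment is scored directly
    from the formula.
    """
    w = w or ScoringWeights()
    P, T = len(primer), len(target)
    three = P - w.three_region_len

    def mm_cost(i: int, tc: str) -> float:
        if iupac_match(primer[i], tc):
            return 0.0
        c = w.three_mismatch if i >= three else w.non3_mismatch
        if i == P - 1:
            c += w.terminal_penalty
        return c

    best = math.inf
    # ungapped windows
    for s in range(T - P + 1):
        best = min(best, sum(mm_cost(i, target[s + i]) for i in range(P)))
    # one primer base deleted (positions 1..P-2; ends must align)
    for s in range(T - (P - 1) + 1):
        for d in range(1, P - 1):
            cost = w.three_gap if d >= three else w.non3_gap
            j = s
            for i in range(P):
                if i == d:
                    continue
                cost += mm_cost(i, target[j])
                j += 1
            best = min(best, cost)
    # one extra target base between primer positions g-1 and g (g in 1..P-1)
    for s in range(T - (P + 1) + 1):
        for g in range(1, P):
            cost = w.three_gap if g >= three else w.non3_gap
            j = s
            for i in range(P):
                if i == g:
                    j += 1
                cost += mm_cost(i, target[j])
                j += 1
            best = min(best, cost)
    return best


def brute_force_greedy_partition(sequences, distance, cutoff: float):
    """Greedy centroid partition computed by literal rule evaluation.

    ``sequences`` must already be in visiting order.  Returns a list of
    lists of indices (clusters in founding order).
    """
    centroids: list[int] = []
    clusters: list[list[int]] = []
    for idx, seq in enumerate(sequences):
        for c, cen in enumerate(centroids):
            if distance(seq, sequences[cen]) <= cutoff:
                clusters[c].append(idx)
                break
        else:
            centroids.append(idx)
            clusters.append([idx])
    return clusters
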