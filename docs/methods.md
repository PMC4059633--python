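# Methods

This note records the models, parameter choices and numerical decisions
behind `itseval`, in the order the pipeline uses them.

## Weighted in-silico primer score

A primer is aligned semi-globally (end-gap-free on the primer: its first and
last bases must align to target bases) against a target strand, minimizing

```
score = 0.40 · (non-3′ mismatches) + 1.00 · (3′ mismatches)
      + 1.00 · (non-3′ gaps)       + 3.00 · (3′ gaps)
      + 3.00   if the final 3′ base of the primer is mismatched
```

where the 3′ region is the primer's final 5 bases. The terminal base, when
mismatched, is counted both as an ordinary 3′ mismatch and as the extra
3.00 penalty, so an otherwise perfect site whose only defect is the last
primer base scores 4.00. IUPAC degeneracy counts as a match. Reverse
primers are scored on the reverse complement of the target, so "3′" always
refers to the extending end of the oligo; hit coordinates are mapped back
to the plus strand.

**Gap budget.** The search space allows at most one single-base gap event
per alignment (`MAX_GAPS = 1`). This matches the independent test oracle,
which enumerates all ungapped and single-gap placements and scores them
directly from the formula; the dynamic program agrees with that enumeration
exactly on randomized inputs. One consequence worth knowing: a terminal-base
mismatch does not always cost 4.00. Primers with self-similar 3′ tails
(e.g. ITS86F's `…TTTGAA`, ITS1F's `…GTAA`) can absorb a mutated terminal
base with a single 3′ gap at cost 3.00, and the score minimizer must take
that cheaper alignment. The tests assert 4.00 only on constructions where
the enumeration confirms no gapped rescue exists, and assert the 3.00
rescue explicitly where it does.

Summaries report mean ± SE (sample SD over √n, 0 for n = 1) of best-hit
scores and the percentage of targets with a terminal-base mismatch. The
virtual PCR pairs every forward and reverse site at or below a score
cutoff, requiring the forward site upstream of the reverse site.

## qPCR efficiency

Ct is linear in log10 of template amount; an OLS fit of Ct against
log10(dilution factor) gives the standard curve and
`E = (10^(−1/slope) − 1) × 100`. A perfect doubling per cycle corresponds
to slope −1/log10(2) ≈ −3.3219 and E = 100 %. Series need ≥3 points;
non-negative slopes are reported as failed amplification (`efficiency =
None`) rather than a bogus number; the no-template control never enters the
fit and only triggers a warning when within 5 cycles of sample Cts. The
simulator generates `ct(d) = ct0 − log10(d)/log10(1 + E/100) + N(0, σ)`,
so a noiseless series recovers the true efficiency exactly.

## Demultiplexing

Reads follow the 454 fusion-primer layout: adaptor + 10-base MID + primer +
insert + reverse-complemented reverse decorations. Assignment requires both
ends: the MID within ≤1 substitution and the primer within ≤2 substitutions
at each end (fixed-length Hamming matching, no indels — the dominant
convention for 10-base MIDs). When several samples qualify, the fewest
total erroneous bases wins. Assigned reads are clipped to the insert.
Primer-dimer artifacts lack the reverse-end decorations and are therefore
structurally unassignable. MID sets are generated with pairwise Hamming
distance ≥3 (> 2 × the tolerance), and the demultiplexer warns if given a
closer pair.

## Quality trimming

In order: (1) truncate at the start of the first 50-base sliding window
(step 1) whose mean Phred falls below 35; (2) discard reads with any
ambiguous base; (3) discard reads with a homopolymer longer than 8;
(4) discard reads shorter than 200 or longer than 600 bases. The order
matters — a low-quality tail is cut before the ambiguity and length checks
see it — and the whole procedure is idempotent.

## Chimera detection

A deliberately simplified two-parent single-crossover detector, not a
UCHIME reimplementation. For each dereplicated query, candidate parents
are uniques at least 2× more abundant. The query is flagged when some
prefix-of-A + suffix-of-B model (any crossover point) beats the **best
single parent over all candidates** by at least 0.8 % of the query length,
and the model itself diverges from the query by at most 5 %.

Two guards are deliberate design choices beyond the basic rule:

- *Global best-single baseline.* Comparing the model only against the two
  parents it is built from lets two truncated fragments of one taxon fake a
  chimera for a query that is one edit from a third parent; measured on a
  simulated noisy run this produced 56 false positives against 11 true
  chimeras, and the global baseline removes them entirely.
- *Model-divergence cap (5 %).* For three mutually unrelated sequences, the
  best split concatenation is almost always slightly closer than either
  parent alone, so the improvement test alone would flag unrelated
  singletons. True chimeras are near-exact mosaics of their parents (model
  divergence ≈ 0 at realistic error rates), so the cap costs no
  sensitivity.

Distances are unit-cost edit distances with free parent ends (the query is
matched against parent substrings), so truncated copies of a parent are
never called chimeric. The DP is vectorized over parent positions with a
prefix-scan to resolve the insertion recurrence.

## OTU clustering and distances

Pairwise distance comes from a global Needleman–Wunsch alignment (match +1,
mismatch −1, gap −2) with the usual amplicon conventions: terminal gaps are
excluded and a contiguous gap run counts as a single difference event;
distance = (mismatches + internal gap events) / alignment columns. Because
equal open/extend costs leave gap placement ambiguous among co-optimal
alignments, gap opening carries an extra 1e−3 — far below the smallest
genuine score difference (1) for any realistic alignment, but above the
aligner's float32 resolution — purely to break ties toward contiguous runs
so the event count is well defined.

OTUs are built greedily at 97 % similarity: uniques are visited in
decreasing abundance (ties lexicographic) and join the first centroid
within distance 0.03, else found a new OTU; the founding unique is the
representative. Clustering is deterministic given the dereplication order
and matches a literal rule-evaluation oracle in the tests. OTUs with a
single read across the whole dataset (global singletons) are removed after
table construction.

## Diversity

Rarefaction subsamples exactly (multivariate hypergeometric, i.e. without
replacement) and reports mean and population SD of richness over the
requested iterations; samples shallower than the depth raise a dedicated
`SampleTooShallow` signal and are listed as excluded rather than silently
dropped. Good's coverage is `1 − singletons/N`. Inverse Simpson is offered
as plugin `1/Σp²` and unbiased `N(N−1)/Σnᵢ(nᵢ−1)` (undefined when every
OTU is a singleton). Bray–Curtis is `1 − 2Σmin/(Σx+Σy)`; pairs involving
an all-zero sample are NaN with a warning. Community distributions are
compared by Pearson chi-squared on a 2×k contingency table without
continuity correction; categories empty in both groups are dropped with a
warning.

## Simulator

Each mock taxon is an operon `SSU(80) · ITS1F site · ITS1(250–450) ·
ITS2/ITS3 locus · 5.8S filler(60) · ITS86F site · ITS2 region(250–450) ·
ITS4 site · LSU(80)`; ITS2 and ITS3 are exact reverse complements sharing
one 5.8S locus. Random sequence is generated with homopolymer runs capped
at 4 so clean reads survive the homopolymer filter by construction.
Planted primer-site substitutions are recorded in a truth table together
with the score the formula predicts for them. Default community: 20 taxa,
geometric rank-abundance (ratio 0.75, dominant taxon ≈25 %).

Reads: 28 samples × 500 reads by default; per-base substitution (0.005),
homopolymer over/under-call at run boundaries (0.002), ambiguous-base
(0.001) errors; two-parent single-crossover chimeras (0.03, crossover
uniformly in the middle 30–70 %); primer-dimer artifacts (length
≈ N(116, 10), forward decorations plus the reverse primer complement but no
reverse MID/adaptor). Quality declines linearly from Phred 38 with
Gaussian jitter, clipped to [2, 40]. Everything is a deterministic function
of the configs and their seeds.

## Problem sizes and runtime

The acceptance-scale runs (1,000 oracle pairs; 100 noisy qPCR replicates;
28 × 500-read closed loop) were chosen to finish in well under a minute
each on one CPU while still exercising every stage at realistic multiplex
width; `scripts/acceptance.py` completes in ≈30 s.
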