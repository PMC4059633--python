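# itseval — fungal ITS metabarcoding primer evaluation

`itseval` compares fungal ITS primers and primer pairs the way a wet-lab /
bioinformatics evaluation would, but on fully synthetic data with known
truth. It provides:

- **In-silico primer scoring** — each primer is aligned end-gap-free against
  every window of a target; mismatches and gaps are weighted by their
  position relative to the primer's 3′ end (non-3′ mismatch 0.40, 3′ mismatch
  1.00, non-3′ gap 1.00, 3′ gap 3.00, plus 3.00 if the final 3′ base is
  mismatched). Low mean scores across a target set indicate broad
  amplification potential. A virtual PCR predicts amplicons per primer pair.
- **qPCR efficiency** — standard curves (Ct vs log10 dilution) fitted by
  ordinary least squares; efficiency `E = (10^(−1/slope) − 1) × 100`.
- **Read pipeline** — 454-style demultiplexing by MID + primer at both read
  ends (≤1 MID substitution, ≤2 primer substitutions), sliding-window
  quality truncation (mean Phred < 35 over 50 bases), ambiguity /
  homopolymer (>8) / length (200–600) filters, dereplication, a two-parent
  crossover chimera detector, greedy 97% OTU clustering, and
  global-singleton removal.
- **Diversity** — rarefaction (exact hypergeometric subsampling), Good's
  coverage, inverse Simpson (plugin and unbiased), Bray–Curtis, and
  chi-squared comparison of community frequency distributions.
- **Simulator** — mock rRNA operons carrying the real primer binding sites
  (optionally perturbed with known mismatches), multiplexed fusion-primer
  reads with substitution/homopolymer/ambiguity errors, chimeras and
  primer-dimer artifacts, and qPCR dilution series — all deterministic in
  the seed, with truth tables for every read and taxon.

The primer catalog covers ITS1F, ITS2, ITS3, ITS4 and ITS86F, including the
correction of the published ITS86R sequence (its terminal base should be C,
the reverse complement of ITS86F, not G).

## Worked example

```python
from itseval.insilico import best_hit, summarize_primer
from itseval.primers import ITS86F, ITS4
from itseval.qpcr import fit_efficiency
from itseval.simulate import CtSimConfig, simulate_ct

hit = best_hit(ITS86F, "TGGTGTTAACCTTACTATACTCCCG"
                        "GTGAATCATCGAATCTTTGAA"
                        "CTCCGGGGTTTGGCTCATATGAACA")
print(hit.score)          # 0.0 — perfect site
res = fit_efficiency(simulate_ct(CtSimConfig(true_efficiency=97.0,
                                             noise_sd=0.0)))
print(res.efficiency)     # 97.0 — noiseless series recovered exactly
```

Command line (same operations as the library):

```bash
itseval simulate --n-taxa 20 --n-samples 8 --reads-per-sample 120 --outdir sim
itseval run-all sim/reads.fastq sim/sample_table.tsv --outdir out
itseval qpcr-eff ct_table.csv
```

## Layout

- `src/itseval/` — the library (`insilico`, `qpcr`, `readpipe`, `otu`,
  `diversity`, `simulate`, `pipeline`, `cli`, plus `core`/`seqio`/`primers`).
- `analysis/` — numbered drivers reproducing the evaluation.
- `tests/` — unit, property and acceptance tests, including independent
  brute-force oracles (`tests/oracles.py`).
- `docs/methods.md` — model details, parameter choices and numerical notes.
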