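#!/usr/bin/env python
"""Step 1 — generate the mock community and the multiplexed 454-style run.

Writes reference operons, fusion-primer sample table, reads (FASTQ) and the
read/community truth tables under results/sim/.  Everything downstream reads
only these files, so the whole analysis replays from one seed.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from itseval.primers import PRIMER_PAIRS
from itseval.seqio import write_fastq
from itseval.simulate import (CommunityConfig, ReadSimConfig,
                              make_fusion_samples, make_reference_set,
                              simulate_reads)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-taxa", type=int, default=20)
    ap.add_argument("--n-samples", type=int, default=28)
    ap.add_argument("--reads-per-sample", type=int, default=500)
    ap.add_argument("--pair", default="ITS86F/ITS4",
                    choices=sorted(PRIMER_PAIRS))
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "sim")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    refs = make_reference_set(CommunityConfig(n_taxa=args.n_taxa,
                                              seed=args.seed))
    fwd, rev = PRIMER_PAIRS[args.pair]
    samples = make_fusion_samples(args.n_samples, fwd, rev,
                                  seed=args.seed + 1)
    cfg = ReadSimConfig(reads_per_sample=args.reads_per_sample,
                        n_samples=args.n_samples, seed=args.seed + 2)
    reads, truth = simulate_reads(refs, samples, cfg)

    with open(args.outdir / "references.fasta", "w") as fh:
        for t in refs.taxa:
            fh.write(f">{t}\n{refs.sequences[t]}\n")
    write_fastq(reads, args.outdir / "reads.fastq")
    truth.to_csv(args.outdir / "read_truth.tsv", sep="\t", index=False)
    refs.truth.to_csv(args.outdir / "community_truth.tsv", sep="\t",
                      index=False)
    with open(args.outdir / "sample_table.tsv", "w") as fh:
        for sid, f, r in samples:
            fh.write(f"{sid}\t{f.adaptor}\t{f.mid}\t{f.primer.name}\t"
                     f"{r.adaptor}\t{r.mid}\t{r.primer.name}\n")
    print(f"wrote {len(reads)} reads for {args.n_samples} samples "
          f"to {args.outdir}")


if __name__ == "__main__":
    main()
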