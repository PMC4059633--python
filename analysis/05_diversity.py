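#!/usr/bin/env python
"""Step 5 — diversity report from the OTU table of step 4.

Per-sample observed richness, Good's coverage, inverse Simpson and rarefied
richness; between-sample Bray-Curtis matrix; and a chi-squared comparison of
pooled OTU abundance distributions between the first and second half of the
samples (a stand-in for comparing two primer pools on the same community).
Writes diversity.tsv, bray_curtis.tsv and chisq.txt under results/diversity/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from itseval.diversity import bray_curtis, chisq_community, summarize_diversity
from itseval.otu import OTUTable

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--depth", type=int, default=200)
    ap.add_argument("--iters", type=int, default=10000)
    ap.add_argument("--otu-table", type=Path,
                    default=ROOT / "results" / "pipeline" / "otu_table.tsv")
    ap.add_argument("--outdir", type=Path,
                    default=ROOT / "results" / "diversity")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.otu_table, sep="\t", index_col="sample")
    reps = {c: "" for c in counts.columns}
    rep_fasta = args.otu_table.parent / "representatives.fasta"
    if rep_fasta.exists():
        from itseval.seqio import read_sequences
        reps.update({r.id: r.bases
                     for r in read_sequences(rep_fasta, "fasta")})
    table = OTUTable(counts=counts, representatives=reps)

    div = summarize_diversity(table, depth=args.depth, iters=args.iters,
                              seed=args.seed)
    div.to_csv(args.outdir / "diversity.tsv", sep="\t")
    print(div.round(3).to_string())
    if div.attrs["excluded"]:
        print(f"excluded from rarefaction (too shallow): "
              f"{div.attrs['excluded']}")

    bc = bray_curtis(table)
    bc.to_csv(args.outdir / "bray_curtis.tsv", sep="\t")

    half = len(counts) // 2
    pool_a = counts.iloc[:half].sum(axis=0).to_numpy()
    pool_b = counts.iloc[half:].sum(axis=0).to_numpy()
    stat, dof, p = chisq_community(pool_a, pool_b)
    msg = (f"chi-squared (first vs second half of samples): "
           f"stat={stat:.2f}, dof={dof}, p={p:.4f}")
    (args.outdir / "chisq.txt").write_text(msg + "\n")
    print(msg)


if __name__ == "__main__":
    main()
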