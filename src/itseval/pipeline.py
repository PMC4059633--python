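"""End-to-end pipeline: demultiplex -> trim -> dereplicate -> chimera ->
cluster -> singleton removal -> diversity, with per-stage read accounting."""

from __future__ import annotations

import dataclasses
import datetime
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .core import FusionPrimer, PipelineConfig, Read
from .diversity import bray_curtis, summarize_diversity
from .otu import OTUTable, build_otu_table, cluster_otus, remove_global_singletons
from .readpipe import (DemuxResult, DemuxRule, UniqueSeq, demultiplex,
                       dereplicate, flag_chimeras, quality_trim)

__all__ = ["PipelineResult", "RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """Provenance record written for every run."""

    command: str
    config: dict
    inputs: list[str]
    outputs: list[str]
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


@dataclass
class PipelineResult:
    stage_counts: pd.DataFrame  # stage, reads_in, reads_out
    demux: DemuxResult
    trimmed: list[Read]
    uniques: list[UniqueSeq]
    chimeras: list[UniqueSeq]
    otu_table: OTUTable          # after global-singleton removal
    otu_table_raw: OTUTable      # before singleton removal
    diversity: pd.DataFrame
    bray_curtis: Optional[pd.DataFrame]


def run_pipeline(reads: Sequence[Read],
                 samples: Sequence[tuple[str, FusionPrimer, FusionPrimer]],
                 cfg: PipelineConfig | None = None,
                 keep_chimeras: bool = False) -> PipelineResult:
    """Run every stage in order and account for reads at each step.

    ``samples`` is the demultiplexing table of (sample_id, forward fusion
    primer, reverse fusion primer).  Chimera-flagged uniques are removed
    unless ``keep_chimeras`` is set.
    """
    cfg = cfg or PipelineConfig()
    rule = DemuxRule(mid_max_err=cfg.mid_max_err, primer_max_err=cfg.primer_max_err)
    counts: list[dict] = []

    reads = list(reads)
    dm = demultiplex(reads, samples, rule)
    counts.append({"stage": "demultiplex", "reads_in": len(reads),
                   "reads_out": len(dm.assigned)})

    trimmed = quality_trim(dm.assigned, cfg)
    counts.append({"stage": "quality_trim", "reads_in": len(dm.assigned),
                   "reads_out": len(trimmed)})

    uniques = dereplicate(trimmed)
    counts.append({"stage": "dereplicate", "reads_in": len(trimmed),
                   "reads_out": sum(u.abundance for u in uniques)})

    clean, flagged = flag_chimeras(uniques)
    kept = uniques if keep_chimeras else clean
    counts.append({"stage": "chimera_removal",
                   "reads_in": sum(u.abundance for u in uniques),
                   "reads_out": sum(u.abundance for u in kept)})

    otus = cluster_otus(kept, similarity=cfg.otu_similarity)
    sample_ids = [s[0] for s in samples]
    table_raw = build_otu_table(otus, samples=sample_ids)
    counts.append({"stage": "cluster_otus",
                   "reads_in": sum(u.abundance for u in kept),
                   "reads_out": int(table_raw.counts.to_numpy().sum())})

    table = remove_global_singletons(table_raw)
    counts.append({"stage": "singleton_removal",
                   "reads_in": int(table_raw.counts.to_numpy().sum()),
                   "reads_out": int(table.counts.to_numpy().sum())})

    diversity = summarize_diversity(table, depth=cfg.rarefy_depth,
                                    iters=cfg.rarefy_iters, seed=cfg.seed)
    bc = bray_curtis(table) if table.counts.shape[0] >= 2 and \
        table.counts.shape[1] > 0 else None

    return PipelineResult(
        stage_counts=pd.DataFrame(counts), demux=dm, trimmed=trimmed,
        uniques=uniques, chimeras=flagged, otu_table=table,
        otu_table_raw=table_raw, diversity=diversity, bray_curtis=bc)
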