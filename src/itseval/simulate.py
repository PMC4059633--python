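"""Synthetic-data generator: mock rRNA operons, multiplexed 454-style reads,
and qPCR dilution series with known truth.

The generator provides every input the evaluation needs.  Each mock taxon is
an SSU-ITS1-5.8S-ITS2-LSU operon carrying the real primer binding sites
(ITS1F at the SSU 3' end; the ITS2/ITS3 site and the ITS86F site in 5.8S;
ITS4 at the LSU 5' start), optionally perturbed with controlled per-primer
substitutions so that expected in-silico scores are known in advance.  Reads
follow the fusion-primer layout adaptor + MID + primer + insert +
reverse-complemented reverse decorations, with per-base substitution errors,
homopolymer indels, ambiguous bases, two-parent single-crossover chimeras,
short primer-dimer artifacts (~116 bp, the empirical mean length of
unassignable reads), and linearly declining Phred quality.  Everything is a
deterministic function of (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import FusionPrimer, Primer, Read, reverse_complement, IUPAC_COMPLEMENT
from .insilico import ScoringWeights
from .primers import ITS1F, ITS2, ITS3, ITS4, ITS86F, PRIMER_PAIRS
from .qpcr import DilutionSeries

__all__ = [
    "ADAPTOR_A", "ADAPTOR_B",
    "CommunityConfig", "ReadSimConfig", "CtSimConfig", "ReferenceSet",
    "make_reference_set", "make_mids", "make_fusion_samples",
    "simulate_reads", "simulate_ct",
]

#: Roche 454 Titanium Lib-L adaptors (primer A / primer B).
ADAPTOR_A = "CGTATCGCCTCCCTCGCGCCATCAG"
ADAPTOR_B = "CTATGCGCCTTGCCAGCCCGCTCAG"

_SITE_PRIMERS = (ITS1F, ITS2, ITS3, ITS86F, ITS4)


@dataclass
class CommunityConfig:
    """Composition of the mock community.

    ``abundance_model`` is ``"log-series"`` (geometric rank-abundance with a
    dominant taxon near 25%, the shape observed in pioneer-forest soils),
    ``"uniform"``, or an explicit vector summing to 1.
    ``primer_site_mismatches`` maps taxon index -> primer name -> list of
    (position in primer, plus-strand-equivalent substitution base), position
    counted from the primer's 5' end.
    """

    n_taxa: int = 20
    abundance_model: object = "log-series"
    its1_len: tuple[int, int] = (250, 450)
    its2_len: tuple[int, int] = (250, 450)
    primer_site_mismatches: dict = field(default_factory=dict)
    seed: int = 0

    def abundances(self) -> np.ndarray:
        if isinstance(self.abundance_model, str):
            if self.abundance_model == "uniform":
                a = np.ones(self.n_taxa)
            elif self.abundance_model == "log-series":
                a = 0.75 ** np.arange(self.n_taxa)
            else:
                raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        else:
            a = np.asarray(self.abundance_model, dtype=float)
            if len(a) != self.n_taxa:
                raise ValueError("explicit abundances must match n_taxa")
        a = a / a.sum()
        return a


@dataclass
class ReadSimConfig:
    """Error model and layout of the simulated 454 run.

    Defaults mirror the study design: 28 samples (4 replicate extractions of
    7 pooled soil samples), ~500 reads per sample, a dimer-artifact fraction
    near the observed unassignable share, and dimer lengths around 116 bases.
    """

    reads_per_sample: int = 500
    n_samples: int = 28
    sub_rate: float = 0.005
    homopolymer_err_rate: float = 0.002
    ambig_rate: float = 0.001
    chimera_rate: float = 0.03
    dimer_rate: float = 0.5
    dimer_len_mean: float = 116.0
    dimer_len_sd: float = 10.0
    qual_start: float = 38.0
    qual_slope: float = 0.008  # mean Phred decline per base
    qual_jitter: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "homopolymer_err_rate", "ambig_rate",
                     "chimera_rate", "dimer_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class CtSimConfig:
    """Ground truth for a simulated qPCR dilution series."""

    true_efficiency: float = 97.0  # percent
    ct0: float = 20.0
    dilutions: tuple[float, ...] = (1, 1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32, 1 / 64)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.true_efficiency <= 120):
            raise ValueError("true_efficiency must be in (0, 120]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ReferenceSet:
    """Mock operons with known primer-site coordinates and truth table."""

    taxa: list[str]
    sequences: dict[str, str]
    sites: dict[str, dict[str, tuple[int, int]]]  # taxon -> primer -> [start, end)
    abundances: np.ndarray
    truth: pd.DataFrame  # taxon, abundance, expected_score_<primer> columns

    def insert(self, taxon: str, fwd: Primer, rev: Primer) -> str:
        """The amplified insert between a primer pair's sites (primers excluded)."""
        seq = self.sequences[taxon]
        f = self.sites[taxon][fwd.name]
        r = self.sites[taxon][rev.name]
        return seq[f[1]:r[0]]


def _random_seq(rng: np.random.Generator, length: int, max_run: int = 4) -> str:
    """Uniform random DNA without homopolymers longer than ``max_run``
    (so clean reads survive the homopolymer filter by construction)."""
    bases = "ACGT"
    out: list[str] = []
    run = 0
    for _ in range(length):
        choices = bases if run < max_run else bases.replace(out[-1], "")
        b = choices[rng.integers(len(choices))]
        if out and b == out[-1]:
            run += 1
        else:
            run = 1
        out.append(b)
    return "".join(out)


def _expected_score(primer: Primer, mismatches, w: ScoringWeights) -> float:
    """Score the formula predicts for a site carrying the given substitutions."""
    score = 0.0
    P = len(primer)
    for pos, _base in mismatches:
        if pos >= P - w.three_region_len:
            score += w.three_mismatch
        else:
            score += w.non3_mismatch
        if pos == P - 1:
            score += w.terminal_penalty
    return score


def _perturbed_site(primer: Primer, mismatches) -> str:
    """Plus-strand binding site for a primer, with substitutions applied.

    Forward primers appear verbatim on the plus strand, reverse primers as
    their reverse complement; mismatch positions are counted along the primer
    (5'->3') and mapped accordingly.
    """
    site = list(primer.sequence)
    seen: dict[int, str] = {}
    for pos, base in mismatches:
        if not (0 <= pos < len(site)):
            raise ValueError(f"{primer.name}: mismatch position {pos} outside primer")
        base = base.upper()
        if base == primer.sequence[pos]:
            raise ValueError(
                f"{primer.name}: substitution at {pos} equals the primer base")
        if seen.get(pos, base) != base:
            raise ValueError(f"{primer.name}: conflicting substitutions at {pos}")
        seen[pos] = base
        site[pos] = base
    plus = "".join(site)
    return plus if primer.direction == "forward" else reverse_complement(plus)


def make_reference_set(cfg: CommunityConfig) -> ReferenceSet:
    """Build one mock operon per taxon and the matching truth table."""
    rng = np.random.default_rng(cfg.seed)
    weights = ScoringWeights()
    taxa = [f"taxon{str(i + 1).zfill(2)}" for i in range(cfg.n_taxa)]
    abundances = cfg.abundances()
    sequences: dict[str, str] = {}
    sites: dict[str, dict[str, tuple[int, int]]] = {}
    rows = []
    for t_idx, taxon in enumerate(taxa):
        mm = cfg.primer_site_mismatches.get(t_idx, {})
        its1 = _random_seq(rng, int(rng.integers(*cfg.its1_len)))
        its2 = _random_seq(rng, int(rng.integers(*cfg.its2_len)))
        ssu = _random_seq(rng, 80)
        mid58 = _random_seq(rng, 60)
        lsu = _random_seq(rng, 80)

        site_seqs = {p.name: _perturbed_site(p, mm.get(p.name, []))
                     for p in _SITE_PRIMERS}
        # ITS2 (reverse) and ITS3 (forward) share one 5.8S locus: the plus
        # strand there reads as the ITS3 sequence.  When both carry mismatch
        # specs the ITS3 spec wins for the embedded sequence.
        locus_58s = site_seqs["ITS3"] if "ITS3" in mm or "ITS2" not in mm \
            else site_seqs["ITS2"]

        parts = [ssu, site_seqs["ITS1F"], its1, locus_58s, mid58,
                 site_seqs["ITS86F"], its2, site_seqs["ITS4"], lsu]
        seq = "".join(parts)
        pos = 0
        coords: dict[str, tuple[int, int]] = {}
        for part, label in zip(parts, [None, "ITS1F", None, "ITS2/ITS3", None,
                                       "ITS86F", None, "ITS4", None]):
            if label == "ITS2/ITS3":
                coords["ITS2"] = coords["ITS3"] = (pos, pos + len(part))
            elif label:
                coords[label] = (pos, pos + len(part))
            pos += len(part)
        sequences[taxon] = seq
        sites[taxon] = coords
        row = {"taxon": taxon, "abundance": abundances[t_idx]}
        for p in _SITE_PRIMERS:
            row[f"expected_score_{p.name}"] = _expected_score(
                p, mm.get(p.name, []), weights)
        rows.append(row)
    return ReferenceSet(taxa=taxa, sequences=sequences, sites=sites,
                        abundances=abundances, truth=pd.DataFrame(rows))


def make_mids(n: int, seed: int = 0, min_dist: int = 3) -> list[str]:
    """Random 10-base MIDs with pairwise Hamming distance >= ``min_dist``."""
    rng = np.random.default_rng(seed)
    mids: list[str] = []
    while len(mids) < n:
        cand = _random_seq(rng, 10)
        if all(sum(a != b for a, b in zip(cand, m)) >= min_dist for m in mids):
            mids.append(cand)
    return mids


def make_fusion_samples(n_samples: int, fwd: Primer, rev: Primer,
                        seed: int = 0) -> list[tuple[str, FusionPrimer, FusionPrimer]]:
    """One (sample_id, forward fusion, reverse fusion) triple per sample."""
    mids = make_mids(n_samples, seed=seed)
    out = []
    for i, mid in enumerate(mids):
        sid = f"S{str(i + 1).zfill(2)}"
        out.append((sid,
                    FusionPrimer(ADAPTOR_A, mid, fwd),
                    FusionPrimer(ADAPTOR_B, mid, rev)))
    return out


def _apply_errors(seq: str, rng: np.random.Generator, cfg: ReadSimConfig) -> str:
    bases = "ACGT"
    out: list[str] = []
    for i, b in enumerate(seq):
        if cfg.sub_rate and rng.random() < cfg.sub_rate:
            b = bases.replace(b, "")[rng.integers(3)] if b in bases else b
        if cfg.ambig_rate and rng.random() < cfg.ambig_rate:
            b = "N"
        out.append(b)
        # homopolymer miscalls: over/under-call at a run boundary
        if (cfg.homopolymer_err_rate and out and i + 1 < len(seq)
                and seq[i + 1] != b and rng.random() < cfg.homopolymer_err_rate):
            if rng.random() < 0.5:
                out.append(b)  # over-call
            elif len(out) > 1 and out[-2] == b:
                out.pop()  # under-call
    return "".join(out)


def _quals(n: int, rng: np.random.Generator, cfg: ReadSimConfig) -> list[int]:
    means = cfg.qual_start - cfg.qual_slope * np.arange(n)
    q = means + (rng.normal(0, cfg.qual_jitter, n) if cfg.qual_jitter else 0.0)
    return list(np.clip(np.rint(q), 2, 40).astype(int))


def simulate_reads(refs: ReferenceSet,
                   samples: Sequence[tuple[str, FusionPrimer, FusionPrimer]],
                   cfg: ReadSimConfig,
                   ) -> tuple[list[Read], pd.DataFrame]:
    """Simulate a multiplexed run for one primer pair.

    Returns the reads (as-sequenced, with qualities) and a truth table with
    one row per read: read_id, sample, taxon (empty for artifacts),
    is_chimera, is_dimer.
    """
    rng = np.random.default_rng(cfg.seed)
    if len(samples) != cfg.n_samples:
        raise ValueError(f"{len(samples)} fusion-primer triples for "
                         f"{cfg.n_samples} samples")
    reads: list[Read] = []
    truth_rows = []
    n_taxa = len(refs.taxa)
    for sid, fwd_fp, rev_fp in samples:
        fwd, rev = fwd_fp.primer, rev_fp.primer
        inserts = {t: refs.insert(t, fwd, rev) for t in refs.taxa}
        front = fwd_fp.full_sequence
        back = reverse_complement(rev_fp.full_sequence)
        for r in range(cfg.reads_per_sample):
            rid = f"{sid}_r{r + 1}"
            u = rng.random()
            is_dimer = u < cfg.dimer_rate
            is_chimera = (not is_dimer) and u < cfg.dimer_rate + cfg.chimera_rate
            if is_dimer:
                # two annealed fusion primers, no genuine insert and no
                # reverse-end decorations: unassignable by design
                length = max(60, int(rng.normal(cfg.dimer_len_mean, cfg.dimer_len_sd)))
                core = front + reverse_complement(rev.sequence)
                seq = (core + _random_seq(rng, max(0, length - len(core))))[:length]
                taxon = ""
            elif is_chimera:
                ta, tb = rng.choice(n_taxa, size=2, replace=False,
                                    p=refs.abundances)
                ia, ib = inserts[refs.taxa[ta]], inserts[refs.taxa[tb]]
                frac = rng.uniform(0.3, 0.7)
                insert = ia[:int(len(ia) * frac)] + ib[int(len(ib) * frac):]
                seq = front + _apply_errors(insert, rng, cfg) + back
                taxon = f"{refs.taxa[ta]}|{refs.taxa[tb]}"
            else:
                t = int(rng.choice(n_taxa, p=refs.abundances))
                taxon = refs.taxa[t]
                seq = front + _apply_errors(inserts[taxon], rng, cfg) + back
            reads.append(Read(id=rid, bases=seq, quals=_quals(len(seq), rng, cfg)))
            truth_rows.append({"read_id": rid, "sample": sid, "taxon": taxon,
                               "is_chimera": is_chimera, "is_dimer": is_dimer})
    return reads, pd.DataFrame(truth_rows)


def simulate_ct(cfg: CtSimConfig, sample_id: str = "sim",
                primer_pair: str = "sim") -> DilutionSeries:
    """Ct series from the standard-curve model with Gaussian noise.

    ct(d) = ct0 - log10(d) / log10(1 + E/100) + N(0, noise_sd); fitting the
    series recovers the true efficiency exactly when noise_sd = 0.
    """
    rng = np.random.default_rng(cfg.seed)
    base = 1.0 + cfg.true_efficiency / 100.0
    points = []
    for d in cfg.dilutions:
        ct = cfg.ct0 - np.log10(d) / np.log10(base)
        if cfg.noise_sd:
            ct += rng.normal(0, cfg.noise_sd)
        points.append((float(d), float(ct)))
    return DilutionSeries(sample_id=sample_id, primer_pair=primer_pair,
                          points=points)
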