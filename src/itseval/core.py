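"""Domain types and IUPAC nucleotide utilities.

The package models a 454-era multiplexed amplicon experiment: template-specific
PCR primers (optionally decorated with a sequencing adaptor and a 10-base
multiplex identifier, MID), the reads they produce, and the configuration of
the downstream read-processing pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "Primer",
    "FusionPrimer",
    "Read",
    "PipelineConfig",
    "reverse_complement",
    "iupac_match",
    "hamming",
]

#: Base sets encoded by each IUPAC nucleotide code.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def _validate_iupac(seq: str, *, what: str = "sequence") -> str:
    """Return ``seq`` upper-cased, raising on any non-IUPAC character."""
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in IUPAC_SETS:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {i} in {what}"
            )
    return up


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC nucleotide string.

    Degenerate codes map onto their complementary degenerate codes
    (e.g. R = {A,G} -> Y = {C,T}); an unknown character raises ``ValueError``
    naming the offending symbol and its 0-based position.
    """
    up = _validate_iupac(seq)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(up))


def iupac_match(primer_base: str, target_base: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect.

    This is the standard in-silico PCR convention: a degenerate primer base
    matches a target base whenever the target could pair with at least one of
    the bases the primer position encodes.
    """
    try:
        p = IUPAC_SETS[primer_base.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {primer_base!r}") from None
    try:
        t = IUPAC_SETS[target_base.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {target_base!r}") from None
    return not p.isdisjoint(t)


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings (IUPAC-aware)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(not iupac_match(x, y) for x, y in zip(a, b))


@dataclass(frozen=True)
class Primer:
    """A named 5'->3' oligonucleotide with a direction and binding-site label."""

    name: str
    sequence: str
    direction: str  # "forward" | "reverse"
    binding_site: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"primer {self.name!r}: empty sequence")
        object.__setattr__(
            self, "sequence", _validate_iupac(self.sequence, what=f"primer {self.name!r}")
        )
        if self.direction not in ("forward", "reverse"):
            raise ValueError(
                f"primer {self.name!r}: direction must be 'forward' or 'reverse', "
                f"got {self.direction!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FusionPrimer:
    """Adaptor + 10-base MID + template-specific primer, as synthesized for
    multiplexed 454 amplicon sequencing."""

    adaptor: str
    mid: str
    primer: Primer

    def __post_init__(self) -> None:
        object.__setattr__(self, "adaptor", _validate_iupac(self.adaptor, what="adaptor"))
        object.__setattr__(self, "mid", _validate_iupac(self.mid, what="MID"))
        if len(self.mid) != 10:
            raise ValueError(f"MID must be 10 bases, got {len(self.mid)}")

    @property
    def full_sequence(self) -> str:
        return self.adaptor + self.mid + self.primer.sequence


@dataclass
class Read:
    """A sequencing read, as-sequenced, with optional per-base Phred scores."""

    id: str
    bases: str
    quals: Optional[list[int]] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.quals is not None:
            if len(self.quals) != len(self.bases):
                raise ValueError(
                    f"read {self.id!r}: {len(self.quals)} quality values for "
                    f"{len(self.bases)} bases"
                )
            if any(q < 0 for q in self.quals):
                raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> "Read":
        """Sub-read over [start, end), keeping qualities in register."""
        return Read(
            id=self.id,
            bases=self.bases[start:end],
            quals=None if self.quals is None else self.quals[start:end],
            sample_id=self.sample_id,
        )


@dataclass
class PipelineConfig:
    """Thresholds of the read-processing pipeline.

    Defaults are the study's values: reads kept between 200 and 600 bases,
    homopolymers at most 8 bases, truncation at the first 50-base window whose
    mean Phred drops below 35, at most 1 erroneous MID base and 2 erroneous
    primer bases during demultiplexing, 97% OTUs, and rarefaction to 200 reads
    with 10,000 iterations.
    """

    min_len: int = 200
    max_len: int = 600
    max_homopolymer: int = 8
    qual_window: int = 50
    qual_threshold: float = 35.0
    mid_max_err: int = 1
    primer_max_err: int = 2
    otu_similarity: float = 0.97
    rarefy_depth: int = 200
    rarefy_iters: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.otu_similarity <= 1):
            raise ValueError("otu_similarity must be in (0, 1]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        for f in fields(self):
            if f.name in ("otu_similarity", "qual_threshold"):
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key=value`` config file mirroring the field names."""
        kwargs: dict[str, object] = {}
        valid = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = float(value) if key in ("otu_similarity", "qual_threshold") else int(value)
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
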