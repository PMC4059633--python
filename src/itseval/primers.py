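"""Catalog of the classic fungal ITS primers evaluated by this package.

ITS1F targets the 3' end of the small ribosomal subunit (SSU); ITS2, ITS3 and
ITS86F sit in the conserved 5.8S gene (ITS2 and ITS3 are exact reverse
complements of one another); ITS4 binds the 5' end of the large subunit (LSU).
The pairs ITS1F/ITS2, ITS3/ITS4 and ITS86F/ITS4 amplify the ITS1 region, the
ITS2 region and the ITS2 region respectively.

``ITS86R_PUBLISHED`` carries the literature sequence whose final 3' base (G)
is wrong — the correct reverse complement of ITS86F ends in C.  Both versions
are kept: the published one for reproducing historical primer sets, the
corrected one (``ITS86R``) for actual use.
"""

from __future__ import annotations

from .core import Primer

__all__ = [
    "ITS1F", "ITS2", "ITS3", "ITS4", "ITS86F", "ITS86R", "ITS86R_PUBLISHED",
    "PRIMERS", "PRIMER_PAIRS",
]

ITS1F = Primer("ITS1F", "CTTGGTCATTTAGAGGAAGTAA", "forward", "Small subunit")
ITS2 = Primer("ITS2", "GCTGCGTTCTTCATCGATGC", "reverse", "5.8S")
ITS3 = Primer("ITS3", "GCATCGATGAAGAACGCAGC", "forward", "5.8S")
ITS4 = Primer("ITS4", "TCCTCCGCTTATTGATATGC", "reverse", "Large subunit")
ITS86F = Primer("ITS86F", "GTGAATCATCGAATCTTTGAA", "forward", "5.8S")

#: Corrected ITS86R: the exact reverse complement of ITS86F.
ITS86R = Primer("ITS86R", "TTCAAAGATTCGATGATTCAC", "reverse", "5.8S")
#: ITS86R as originally published, with the erroneous terminal G.
ITS86R_PUBLISHED = Primer("ITS86R_published", "TTCAAAGATTCGATGATTCAG", "reverse", "5.8S")

PRIMERS: dict[str, Primer] = {
    p.name: p for p in (ITS1F, ITS2, ITS3, ITS4, ITS86F, ITS86R, ITS86R_PUBLISHED)
}

#: The three primer pairs compared in the evaluation, keyed by pair label.
PRIMER_PAIRS: dict[str, tuple[Primer, Primer]] = {
    "ITS1F/ITS2": (ITS1F, ITS2),
    "ITS3/ITS4": (ITS3, ITS4),
    "ITS86F/ITS4": (ITS86F, ITS4),
}
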