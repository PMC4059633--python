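"""Amplification-efficiency estimation from qPCR dilution series.

The threshold cycle Ct is linear in log10 of template amount, so an ordinary
least-squares fit of Ct against log10(dilution factor) gives the standard
curve.  Efficiency in percent follows from the slope:

    E = (10 ** (-1 / slope) - 1) * 100

A perfect doubling per cycle gives slope -3.3219 (= -1/log10(2)) and E = 100%.
A non-negative slope means no exponential amplification was observed; such
series are flagged rather than reported with a bogus efficiency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "EfficiencyResult",
    "fit_efficiency",
    "summarize_efficiencies",
    "read_ct_table",
    "slope_to_efficiency",
]


@dataclass
class DilutionSeries:
    """Ct measurements across a dilution series for one sample/primer pair.

    ``points`` are (dilution_factor, ct) pairs with dilution factors as
    fractions of the stock, strictly decreasing (e.g. 1, 1/2, ..., 1/64 for
    the 2-fold series used here).  ``ntc_ct`` is the no-template control.
    """

    sample_id: str
    primer_pair: str
    points: list[tuple[float, float]]
    ntc_ct: Optional[float] = None

    def __post_init__(self) -> None:
        facs = [d for d, _ in self.points]
        if any(not (0 < d <= 1) for d in facs):
            raise ValueError("dilution factors must be in (0, 1]")
        if any(b >= a for a, b in zip(facs, facs[1:])):
            raise ValueError("dilution factors must be strictly decreasing")
        if any(ct <= 0 for _, ct in self.points):
            raise ValueError("Ct values must be > 0")


@dataclass(frozen=True)
class EfficiencyResult:
    sample_id: str
    primer_pair: str
    slope: float
    efficiency: Optional[float]  # percent; None when amplification failed
    r2: float
    n_points: int

    @property
    def amplified(self) -> bool:
        return self.efficiency is not None


def slope_to_efficiency(slope: float) -> float:
    """E (%) from a standard-curve slope (requires slope < 0)."""
    if slope >= 0:
        raise ValueError("efficiency is defined only for negative slopes")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_efficiency(series: DilutionSeries) -> EfficiencyResult:
    """OLS standard curve Ct ~ log10(dilution factor) and the efficiency.

    Needs at least 3 dilution points.  The NTC never enters the fit; it is
    only sanity-checked (should be absent or well above every sample Ct).
    A slope >= 0 yields ``efficiency=None`` — no exponential amplification,
    mirroring how failed series are reported rather than dropped.
    """
    if len(series.points) < 3:
        raise ValueError(
            f"{series.sample_id}/{series.primer_pair}: need >= 3 dilution "
            f"points, got {len(series.points)}")
    x = np.log10([d for d, _ in series.points])
    y = np.array([ct for _, ct in series.points])
    if series.ntc_ct is not None and series.ntc_ct <= y.max() + 5:
        warnings.warn(
            f"{series.sample_id}/{series.primer_pair}: NTC Ct "
            f"{series.ntc_ct:.1f} within 5 cycles of sample Cts",
            stacklevel=2)
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    eff = slope_to_efficiency(slope) if slope < 0 else None
    return EfficiencyResult(
        sample_id=series.sample_id, primer_pair=series.primer_pair,
        slope=slope, efficiency=eff, r2=float(fit.rvalue) ** 2,
        n_points=len(series.points))


def summarize_efficiencies(results: Sequence[EfficiencyResult],
                           group_labels: Sequence[str] | None = None,
                           ) -> pd.DataFrame:
    """Per-group mean, SE, min and max efficiency (percent).

    Groups default to each result's primer pair.  Results without an
    efficiency (failed amplification) are excluded but counted in
    ``n_failed``.  SE is sample SD over sqrt(n) (0 for n = 1).
    """
    if group_labels is None:
        group_labels = [r.primer_pair for r in results]
    if len(group_labels) != len(results):
        raise ValueError("one group label per result required")
    df = pd.DataFrame({
        "group": list(group_labels),
        "efficiency": [r.efficiency for r in results],
    })
    rows = []
    for group, sub in df.groupby("group", sort=True):
        eff = sub["efficiency"].dropna()
        if len(sub) == 0:
            raise ValueError(f"empty group {group!r}")
        n = len(eff)
        rows.append({
            "group": group,
            "n": n,
            "n_failed": int(sub["efficiency"].isna().sum()),
            "mean": eff.mean() if n else math.nan,
            "se": (eff.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
            "min": eff.min() if n else math.nan,
            "max": eff.max() if n else math.nan,
        })
    return pd.DataFrame(rows).set_index("group")


def read_ct_table(path: str | Path) -> list[DilutionSeries]:
    """Load dilution series from CSV with columns
    sample_id, primer_pair, dilution_factor, ct, is_ntc."""
    df = pd.read_csv(path)
    required = {"sample_id", "primer_pair", "dilution_factor", "ct", "is_ntc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (sid, pair), sub in df.groupby(["sample_id", "primer_pair"], sort=True):
        ntc = sub[sub["is_ntc"].astype(bool)]
        pts = sub[~sub["is_ntc"].astype(bool)].sort_values(
            "dilution_factor", ascending=False)
        out.append(DilutionSeries(
            sample_id=str(sid), primer_pair=str(pair),
            points=list(zip(pts["dilution_factor"], pts["ct"])),
            ntc_ct=float(ntc["ct"].iloc[0]) if len(ntc) else None))
    return out
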