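"""Within- and between-sample diversity: rarefaction, Good's coverage,
inverse Simpson, Bray-Curtis dissimilarity, and chi-squared comparison of
community frequency distributions.

Rarefaction subsamples exactly (without replacement, hypergeometric) so that
samples sequenced to different depths are comparable; samples shallower than
the target depth are excluded with an explicit signal rather than silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .otu import OTUTable

__all__ = [
    "SampleTooShallow",
    "DiversitySummary",
    "rarefy",
    "goods_coverage",
    "inverse_simpson",
    "bray_curtis",
    "chisq_community",
    "summarize_diversity",
]


class SampleTooShallow(ValueError):
    """Raised when a sample has fewer reads than the rarefaction depth."""


@dataclass(frozen=True)
class DiversitySummary:
    sample_id: str
    n_reads: int
    observed_otus: int
    goods_coverage: float
    inv_simpson: Optional[float]
    rarefied_otus_mean: Optional[float]
    rarefied_otus_sd: Optional[float]


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D abundance vector")
    if (arr < 0).any():
        raise ValueError("negative counts")
    return arr.astype(np.int64)


def rarefy(counts, depth: int, iters: int = 10000, seed: int = 0,
           return_sample: bool = False):
    """Mean and SD of OTU richness under repeated exact subsampling.

    Draws ``iters`` independent subsamples of ``depth`` reads without
    replacement and reports the mean and population SD of the number of OTUs
    observed.  With ``return_sample`` the last resampled vector is returned
    as a third element (its sum equals ``depth``).  Raises
    :class:`SampleTooShallow` when the sample holds fewer than ``depth``
    reads.
    """
    arr = _as_counts(counts)
    total = int(arr.sum())
    if depth > total:
        raise SampleTooShallow(
            f"sample has {total} reads, fewer than rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    # multivariate hypergeometric: exact subsampling without replacement
    draws = rng.multivariate_hypergeometric(arr, depth, size=iters)
    richness = (draws > 0).sum(axis=1)
    mean = float(richness.mean())
    sd = float(richness.std())
    if return_sample:
        return mean, sd, draws[-1]
    return mean, sd


def goods_coverage(counts) -> float:
    """Good's coverage: 1 - singletons / reads."""
    arr = _as_counts(counts)
    total = int(arr.sum())
    if total == 0:
        raise ValueError("empty sample")
    return 1.0 - int((arr == 1).sum()) / total


def inverse_simpson(counts, estimator: str = "unbiased") -> float:
    """Inverse Simpson diversity (effective number of equally common OTUs).

    ``plugin``:   1 / sum(p_i^2)
    ``unbiased``: 1 / [sum n_i (n_i - 1) / (N (N - 1))]  (finite-sample form)

    The unbiased form is undefined when every OTU is a singleton
    (sum n_i(n_i-1) = 0); that case raises.
    """
    arr = _as_counts(counts)
    arr = arr[arr > 0]
    total = int(arr.sum())
    if total == 0:
        raise ValueError("empty sample")
    if estimator == "plugin":
        p = arr / total
        return float(1.0 / np.sum(p ** 2))
    if estimator == "unbiased":
        if total < 2:
            raise ValueError("unbiased estimator needs at least 2 reads")
        num = float(np.sum(arr * (arr - 1)))
        if num == 0:
            raise ValueError(
                "all OTUs are singletons; unbiased inverse Simpson undefined")
        return float(total * (total - 1) / num)
    raise ValueError(f"unknown estimator {estimator!r}")


def bray_curtis(table) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix between samples.

    BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum x + sum y); 0 for identical
    samples, 1 for samples sharing no OTU.  An all-zero sample makes its
    pairs undefined (NaN) with a warning.
    """
    if isinstance(table, OTUTable):
        counts = table.counts
    else:
        counts = pd.DataFrame(table)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = counts.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        empty = list(counts.index[totals == 0])
        warnings.warn(f"all-zero samples {empty}: dissimilarity undefined",
                      stacklevel=2)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = totals[i] + totals[j]
            if totals[i] == 0 or totals[j] == 0:
                d = np.nan
            else:
                d = 1.0 - 2.0 * np.minimum(X[i], X[j]).sum() / denom
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=counts.index, columns=counts.index)


def chisq_community(freq_a, freq_b) -> tuple[float, int, float]:
    """Pearson chi-squared comparing two abundance distributions.

    ``freq_a`` and ``freq_b`` are count vectors over the same categories
    (e.g. OTU or phylum abundances under two primer pairs).  Categories with
    zero total in both groups are dropped with a warning.  Returns
    (statistic, degrees of freedom, p-value); identical distributions give
    statistic 0 and p = 1.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors must share their category set")
    keep = (a + b) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} empty categories",
                      stacklevel=2)
        a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least 2 non-empty categories")
    obs = np.vstack([a, b])
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def summarize_diversity(table: OTUTable, depth: int = 200, iters: int = 10000,
                        seed: int = 0) -> pd.DataFrame:
    """Per-sample diversity report (one row per sample).

    Samples shallower than ``depth`` get NaN rarefied richness and are listed
    in the ``excluded`` attribute of the returned frame (``df.attrs``).
    """
    rows = []
    excluded = []
    for k, sid in enumerate(table.samples):
        counts = table.counts.loc[sid].to_numpy()
        total = int(counts.sum())
        row = {
            "sample_id": sid,
            "n_reads": total,
            "observed_otus": int((counts > 0).sum()),
            "goods_coverage": goods_coverage(counts) if total else np.nan,
        }
        try:
            row["inv_simpson"] = inverse_simpson(counts) if total else np.nan
        except ValueError:
            row["inv_simpson"] = np.nan
        try:
            mean, sd = rarefy(counts, depth, iters=iters, seed=seed + k)
            row["rarefied_otus_mean"], row["rarefied_otus_sd"] = mean, sd
        except SampleTooShallow:
            excluded.append(sid)
            row["rarefied_otus_mean"] = row["rarefied_otus_sd"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    df.attrs["excluded"] = excluded
    return df
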