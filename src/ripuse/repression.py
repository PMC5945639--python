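"""Cumulative-distribution validation of site-mediated repression.

After miRNA overexpression, transcripts whose 3'UTR carries a seed site
should be shifted toward repression relative to site-free transcripts, and
more strongly so for stronger site classes (8mer >= 7mer-m8 >= 7mer-1A >=
6mer).  Each transcript is assigned to exactly one class by its *best* site
(a transcript with both an 8mer and a 6mer counts as 8mer), and each class's
log2 fold-change distribution is compared against the site-free background
with a two-sided two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .sites import MicroRNA, SiteType, best_site_type, SITE_CLASSES

MIN_BACKGROUND = 8
MIN_RELIABLE_SAMPLE = 8


@dataclass
class SiteClassPartition:
    """Transcript ids grouped by best site class, with their log2 fold change.

    Groups are disjoint and cover the universe; the NONE group is the
    site-free background.
    """

    groups: dict[SiteType, list[str]]
    log2fc: pd.Series

    def values(self, site_type: SiteType) -> np.ndarray:
        return self.log2fc.loc[self.groups.get(site_type, [])].to_numpy(dtype=float)

    def sizes(self) -> dict[SiteType, int]:
        return {st: len(ids) for st, ids in self.groups.items()}


def partition_by_site(
    universe: Iterable[str],
    utrs: Mapping[str, str],
    mirna: MicroRNA,
    log2fc: Mapping[str, float] | pd.Series,
) -> SiteClassPartition:
    """Assign every transcript to exactly one site class by its best site."""
    ids = list(universe)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids in the universe")
    fc = pd.Series(log2fc, dtype=float)
    missing_fc = [t for t in ids if t not in fc.index]
    if missing_fc:
        raise ValueError(f"log2 fold change missing for {missing_fc[:5]}")
    groups: dict[SiteType, list[str]] = {st: [] for st in SiteType}
    for tid in ids:
        try:
            utr = utrs[tid]
        except KeyError:
            raise KeyError(f"no UTR sequence for transcript {tid!r}") from None
        groups[best_site_type(utr, mirna)].append(tid)
    return SiteClassPartition(groups, fc.loc[ids])


@dataclass
class KsResult:
    """Two-sided two-sample KS comparison of one class against background."""

    statistic: float        # D = sup |ECDF_group - ECDF_background|
    pvalue: float
    n_group: int
    n_background: int
    mean_shift: float       # mean(group) - mean(background), log2 units


def ks_two_sided(
    group: np.ndarray | list[float],
    background: np.ndarray | list[float],
    method: str = "auto",
) -> KsResult:
    """Two-sided two-sample KS test with the asymptotic p by default.

    ``method``: "asymp", "exact", or "auto" (exact when both samples are
    below 30, asymptotic otherwise).  p-values are unreliable for samples
    smaller than 8; a warning is emitted in that case.
    """
    g = np.asarray(group, dtype=float)
    b = np.asarray(background, dtype=float)
    if g.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if min(g.size, b.size) < MIN_RELIABLE_SAMPLE:
        warnings.warn(
            f"KS p-value unreliable for sample size < {MIN_RELIABLE_SAMPLE}",
            stacklevel=2,
        )
    if method == "auto":
        method = "exact" if max(g.size, b.size) < 30 else "asymp"
    res = ks_2samp(g, b, alternative="two-sided", method=method)
    return KsResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_group=g.size,
        n_background=b.size,
        mean_shift=float(g.mean() - b.mean()),
    )


@dataclass
class RepressionReport:
    """Per-class KS results plus the class-strength ordering check.

    ``ordering_ok`` is True when the mean log2 fold-change shifts of the
    classes present satisfy 8mer <= 7mer-m8 <= 7mer-1A <= 6mer <= 0
    (more negative = more repressed).
    """

    table: pd.DataFrame
    ordering_ok: bool


def repression_report(
    partition: SiteClassPartition,
    method: str = "auto",
    include_pooled: bool = True,
    min_background: int = MIN_BACKGROUND,
) -> RepressionReport:
    """One KS test per non-empty site class against the site-free background."""
    bg = partition.values(SiteType.NONE)
    if bg.size < min_background:
        raise ValueError(
            f"site-free background has {bg.size} transcripts; "
            f"at least {min_background} required"
        )
    rows = []
    shifts = []
    for st in SITE_CLASSES:
        vals = partition.values(st)
        if vals.size == 0:
            shifts.append(None)
            continue
        r = ks_two_sided(vals, bg, method=method)
        shifts.append(r.mean_shift)
        rows.append(
            {
                "site_class": st.label,
                "n": r.n_group,
                "mean_shift": r.mean_shift,
                "D": r.statistic,
                "p": r.pvalue,
            }
        )
    if include_pooled:
        pooled = np.concatenate(
            [partition.values(st) for st in SITE_CLASSES]
        ) if rows else np.empty(0)
        if pooled.size:
            r = ks_two_sided(pooled, bg, method=method)
            rows.append(
                {
                    "site_class": "any_site",
                    "n": r.n_group,
                    "mean_shift": r.mean_shift,
                    "D": r.statistic,
                    "p": r.pvalue,
                }
            )
    present = [s for s in shifts if s is not None]
    ordering_ok = bool(
        all(a <= b for a, b in zip(present, present[1:]))
        and (not present or present[-1] <= 0.0)
    )
    return RepressionReport(pd.DataFrame(rows), ordering_ok)


def plot_cdf(partition: SiteClassPartition, ax=None):
    """Empirical CDF of log2 fold change per site class (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for st in (*SITE_CLASSES, SiteType.NONE):
        vals = np.sort(partition.values(st))
        if vals.size == 0:
            continue
        ax.step(vals, np.arange(1, vals.size + 1) / vals.size, label=st.label)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("cumulative fraction")
    ax.legend(fontsize="small")
    return ax
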