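"""Ranked transcript lists from abundance tables.

The method consumes two orderings of one transcript universe:

* AGO2-RIP enrichment — transcripts sorted from most to least enriched in
  the AGO2 immunoprecipitate relative to input (``rip_enrichment_desc``);
* post-overexpression regulation — transcripts sorted most down-regulated
  first after transfecting the miRNA mimic, relative to a negative-control
  mimic (``downregulation_first``).

Both statistics are pseudocount-stabilised log2 ratios of replicate-averaged
abundances (RPKM or any ratio-preserving unit).  Differential-expression
modelling is deliberately out of scope: rankings, not significance calls,
are what the downstream word-enrichment stage needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class AbundanceTable:
    """Transcript x sample abundance matrix for one condition.

    ``values``: DataFrame indexed by transcript id, one column per replicate,
    non-negative.  ``lengths``: optional per-transcript length in nt (needed
    only for RPKM conversion).
    """

    values: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[1] < 1:
            raise ValueError("abundance table needs at least one sample column")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate transcript ids: {dups}")
        if not all(np.issubdtype(dt, np.number) for dt in v.dtypes):
            raise ValueError("abundance columns must be numeric")
        if v.isna().any().any():
            bad = v.index[v.isna().any(axis=1)][:5].tolist()
            raise ValueError(f"missing abundance values for transcripts {bad}")
        if (v.to_numpy() < 0).any():
            raise ValueError("negative abundance values are not allowed")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(v.index)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    def mean_abundance(self) -> pd.Series:
        """Arithmetic mean across replicate columns."""
        return self.values.mean(axis=1)


@dataclass
class RankedList:
    """Ordered transcript ids with the ranking statistic.

    ``direction`` documents the convention: ``rip_enrichment_desc`` (most
    AGO2-enriched first) or ``downregulation_first`` (most repressed first).
    """

    ids: list[str]
    statistic: pd.Series  # aligned with ids, in list order
    direction: str

    def __post_init__(self) -> None:
        if list(self.statistic.index) != list(self.ids):
            self.statistic = self.statistic.reindex(self.ids)
        if not np.isfinite(self.statistic.to_numpy()).all():
            raise ValueError("ranking statistic must be finite everywhere")

    def __len__(self) -> int:
        return len(self.ids)

    def top(self, n: int) -> list[str]:
        return self.ids[:n]

    def reversed(self) -> "RankedList":
        return RankedList(
            self.ids[::-1], self.statistic.iloc[::-1], self.direction + "_reversed"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ids) + 1),
                "transcript_id": self.ids,
                "statistic": self.statistic.to_numpy(),
            }
        )


def log2_ratio(treated, control, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2((treated + c) / (control + c)); finite for all abundances >= 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if (t < 0).any() or (c < 0).any():
        raise ValueError("abundances must be non-negative")
    out = np.log2((t + pseudocount) / (c + pseudocount))
    return out if out.ndim else float(out)


def _shared_ids(a: AbundanceTable, b: AbundanceTable) -> list[str]:
    ids = a.transcript_ids.intersection(b.transcript_ids)
    if len(ids) == 0:
        raise ValueError("the two abundance tables share no transcript ids")
    return sorted(ids)


def _rank(
    num: AbundanceTable,
    den: AbundanceTable,
    pseudocount: float,
    ascending: bool,
    direction: str,
) -> RankedList:
    ids = _shared_ids(num, den)
    stat = pd.Series(
        log2_ratio(
            num.mean_abundance().loc[ids].to_numpy(),
            den.mean_abundance().loc[ids].to_numpy(),
            pseudocount,
        ),
        index=ids,
        name="log2_ratio",
    )
    # ids are pre-sorted lexicographically; a stable sort on the statistic
    # therefore breaks ties by transcript id.
    stat = stat.sort_values(ascending=ascending, kind="stable")
    return RankedList(list(stat.index), stat, direction)


def rank_by_rip_enrichment(
    rip: AbundanceTable,
    reference: AbundanceTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RankedList:
    """Rank transcripts from most to least AGO2-RIP-enriched.

    Statistic: log2((mean RIP + c)/(mean input + c)), sorted descending.
    """
    return _rank(rip, reference, pseudocount, False, "rip_enrichment_desc")


def rank_by_regulation(
    overexpr: AbundanceTable,
    negctrl: AbundanceTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    most_downregulated_first: bool = True,
) -> RankedList:
    """Rank transcripts by response to miRNA overexpression.

    By default the most down-regulated transcripts lead the list, so that
    repressed-target motif enrichment appears at the list head, mirroring
    the RIP list head.  Set ``most_downregulated_first=False`` for the
    opposite convention.
    """
    if most_downregulated_first:
        return _rank(overexpr, negctrl, pseudocount, True, "downregulation_first")
    return _rank(overexpr, negctrl, pseudocount, False, "upregulation_first")


def counts_to_rpkm(table: AbundanceTable) -> AbundanceTable:
    """Reads-per-kilobase-per-million from raw counts and transcript lengths.

    rpkm = count * 1e9 / (column library size * transcript length).
    """
    if table.lengths is None:
        raise ValueError("counts_to_rpkm requires transcript lengths")
    lengths = table.lengths
    if lengths.isna().any():
        bad = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing transcript length for {bad}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    lib = table.values.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library size must be positive in every column")
    rpkm = table.values * 1e9
    rpkm = rpkm.div(lib, axis=1).div(lengths, axis=0)
    return AbundanceTable(rpkm, lengths=lengths)


def shared_universe(
    tables: Sequence[AbundanceTable], utr_ids: Iterable[str] | None = None
) -> list[str]:
    """Transcripts present in every table (and, if given, having a UTR).

    The downstream statistics all condition on this universe; transcripts
    dropped here are logged with a count.
    """
    if not tables:
        raise ValueError("at least one abundance table is required")
    ids = tables[0].transcript_ids
    union = set(tables[0].transcript_ids)
    for t in tables[1:]:
        ids = ids.intersection(t.transcript_ids)
        union |= set(t.transcript_ids)
    ids = set(ids)
    if utr_ids is not None:
        utr_ids = set(utr_ids)
        union |= utr_ids
        ids &= utr_ids
    if not ids:
        raise ValueError("empty transcript universe after intersection")
    dropped = len(union) - len(ids)
    if dropped:
        logger.info("universe: kept %d transcripts, dropped %d", len(ids), dropped)
    return sorted(ids)
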