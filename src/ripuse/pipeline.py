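"""End-to-end orchestration of the computational pipeline.

Given UTR sequences, the two paired abundance contrasts (RIP/input and
mimic/negative-control) and a miRNA, this runs the analysis stages in
order: build the shared transcript universe, rank by AGO2 enrichment and by
regulation, compute the word-enrichment landscapes, profile the canonical
seed words, validate repression by site class with KS cumulative
distributions, locate the site-density peaks, and call direct targets by
prefix overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ranking, repression, targetcall, wordscan
from .ranking import AbundanceTable, RankedList
from .sites import MicroRNA, SiteType


def _subset(table: AbundanceTable, ids: list[str]) -> AbundanceTable:
    lengths = table.lengths.loc[ids] if table.lengths is not None else None
    return AbundanceTable(table.values.loc[ids], lengths=lengths)


@dataclass
class PipelineResult:
    universe: list[str]
    rip_ranked: RankedList
    dw_ranked: RankedList
    rip_landscape: wordscan.EnrichmentLandscape
    dw_landscape: wordscan.EnrichmentLandscape
    rip_seed_profile: wordscan.SeedProfile
    dw_seed_profile: wordscan.SeedProfile
    repression: repression.RepressionReport
    rip_density: targetcall.DensityProfile
    dw_density: targetcall.DensityProfile
    call: targetcall.TargetCallResult

    def summary(self) -> dict:
        prof = {
            f"dw_peak_{r['site_class']}": r["peak_score"]
            for r in self.dw_seed_profile.table.to_dict("records")
        }
        return {
            "n_universe": len(self.universe),
            "overlap": self.call.summary(),
            "repression_ordering_ok": self.repression.ordering_ok,
            "rip_density_argmax": self.rip_density.argmax_rank,
            "dw_density_argmax": self.dw_density.argmax_rank,
            **prof,
        }


def run_pipeline(
    utrs: dict[str, str],
    rip: AbundanceTable,
    input_: AbundanceTable,
    mimic: AbundanceTable,
    control: AbundanceTable,
    mirna: MicroRNA,
    pseudocount: float = ranking.DEFAULT_PSEUDOCOUNT,
    k_set: tuple[int, ...] = wordscan.DEFAULT_K_SET,
    cutoffs: np.ndarray | None = None,
    n_rip: int | None = None,
    n_dw: int | None = None,
    density_site_type: SiteType = SiteType.SEVENMER_M8,
) -> PipelineResult:
    """Run all analysis stages; see the module docstring for the order.

    ``n_rip``/``n_dw`` default to the site-density argmax of each ranking
    (the data-driven prefix choice); pass explicit values to override.
    """
    universe = ranking.shared_universe([rip, input_, mimic, control], utrs)
    rip_ranked = ranking.rank_by_rip_enrichment(
        _subset(rip, universe), _subset(input_, universe), pseudocount
    )
    dw_ranked = ranking.rank_by_regulation(
        _subset(mimic, universe), _subset(control, universe), pseudocount
    )
    rip_ls = wordscan.landscape(rip_ranked, utrs, k_set=k_set, cutoffs=cutoffs)
    dw_ls = wordscan.landscape(dw_ranked, utrs, k_set=k_set, cutoffs=cutoffs)

    fc = dw_ranked.statistic
    part = repression.partition_by_site(universe, utrs, mirna, fc)
    rep = repression.repression_report(part)

    rip_density = targetcall.density_profile(rip_ranked, utrs, mirna,
                                             density_site_type)
    dw_density = targetcall.density_profile(dw_ranked, utrs, mirna,
                                            density_site_type)
    call = targetcall.call_direct_targets(
        rip_ranked,
        dw_ranked,
        n_rip=n_rip if n_rip is not None else rip_density.argmax_rank,
        n_dw=n_dw if n_dw is not None else dw_density.argmax_rank,
    )
    return PipelineResult(
        universe, rip_ranked, dw_ranked, rip_ls, dw_ls,
        wordscan.seed_profile(rip_ls, mirna), wordscan.seed_profile(dw_ls, mirna),
        rep, rip_density, dw_density, call,
    )
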