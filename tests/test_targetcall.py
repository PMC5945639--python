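"""Overlap-based direct-target calling and density profiling."""

import math

import numpy as np
import pandas as pd
import pytest

from ripuse.ranking import RankedList
from ripuse.sites import SiteType
from ripuse.targetcall import (
    call_direct_targets,
    density_profile,
    hypergeom_overlap,
    mirna_set_overlap,
)


def enum_upper(x, N, K, n):
    hi = min(K, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(x, hi + 1)) \
        / math.comb(N, n)


def make_ranked(ids, direction="rip_enrichment_desc"):
    stat = pd.Series(np.linspace(1, -1, len(ids)), index=ids)
    return RankedList(list(ids), stat, direction)


class TestHypergeomOverlap:
    def test_worked_example(self):
        expected, fold, p = hypergeom_overlap(100, 20, 10, 5)
        assert expected == pytest.approx(2.0)
        assert fold == pytest.approx(2.5)
        assert p == pytest.approx(enum_upper(5, 100, 20, 10), rel=1e-10)

    def test_zero_overlap_p_is_one(self):
        _, fold, p = hypergeom_overlap(50, 10, 5, 0)
        assert fold == 0.0
        assert p == pytest.approx(1.0)

    def test_maximal_overlap_single_term(self):
        N, K, n = 40, 12, 9
        x = min(K, n)
        _, _, p = hypergeom_overlap(N, K, n, x)
        single = math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        assert p == pytest.approx(single, rel=1e-10)

    def test_small_grid_matches_enumeration(self):
        for N in range(2, 13):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for x in range(max(0, n - (N - K)), min(K, n) + 1):
                        _, fold, p = hypergeom_overlap(N, K, n, x)
                        assert p == pytest.approx(
                            enum_upper(x, N, K, n), abs=1e-12)
                        assert fold * (K * n / N) == pytest.approx(x)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 5, 5, 6)
        with pytest.raises(ValueError):
            hypergeom_overlap(10, 0, 5, 0)


class TestCallDirectTargets:
    def test_identical_lists_perfect_concordance(self):
        ids = [f"t{i:03d}" for i in range(100)]
        a = make_ranked(ids)
        b = make_ranked(ids, "downregulation_first")
        m = 20
        res = call_direct_targets(a, b, n_rip=m, n_dw=m)
        assert res.overlap == m
        assert res.fold == pytest.approx(len(ids) / m)
        assert res.members == sorted(ids[:m])

    def test_mismatched_universe_reports_size(self):
        a = make_ranked([f"t{i}" for i in range(10)])
        b = make_ranked([f"u{i}" for i in range(10)])
        with pytest.raises(ValueError, match="20"):
            call_direct_targets(a, b, n_rip=2, n_dw=2)

    def test_relabeling_invariance(self, rng):
        ids = [f"t{i:03d}" for i in range(200)]
        perm_a = [ids[i] for i in rng.permutation(200)]
        perm_b = [ids[i] for i in rng.permutation(200)]
        res = call_direct_targets(make_ranked(perm_a), make_ranked(perm_b),
                                  n_rip=40, n_dw=30)
        relabel = {t: f"x{t}" for t in ids}
        res2 = call_direct_targets(
            make_ranked([relabel[t] for t in perm_a]),
            make_ranked([relabel[t] for t in perm_b]),
            n_rip=40, n_dw=30)
        assert res2.overlap == res.overlap
        assert res2.members == sorted(relabel[t] for t in res.members)

    def test_prefix_monotonicity(self, rng):
        ids = [f"t{i:03d}" for i in range(100)]
        a = make_ranked([ids[i] for i in rng.permutation(100)])
        b = make_ranked([ids[i] for i in rng.permutation(100)])
        x_small = call_direct_targets(a, b, n_rip=20, n_dw=20).overlap
        assert call_direct_targets(a, b, n_rip=40, n_dw=20).overlap >= x_small
        assert call_direct_targets(a, b, n_rip=20, n_dw=40).overlap >= x_small

    def test_independent_lists_near_null(self):
        rng = np.random.default_rng(3)
        ids = [f"t{i:05d}" for i in range(10_000)]
        a = make_ranked([ids[i] for i in rng.permutation(len(ids))])
        b = make_ranked([ids[i] for i in rng.permutation(len(ids))])
        res = call_direct_targets(a, b, n_rip=2000, n_dw=650)
        assert 0.6 <= res.fold <= 1.6
        assert res.pvalue > 1e-3

    def test_planted_dataset_recovers_targets(self):
        from ripuse.ranking import rank_by_regulation, rank_by_rip_enrichment
        from ripuse.sites import SiteType
        from ripuse.synthdata import SyntheticConfig, generate

        cfg = SyntheticConfig(
            seed=11, n_transcripts=600, utr_length=(300, 500),
            planting_fractions={SiteType.SEVENMER_M8: 0.12},
        )
        ds = generate(cfg)
        a = rank_by_rip_enrichment(ds.rip, ds.input_)
        b = rank_by_regulation(ds.mimic, ds.control)
        n_true = len(ds.true_targets())
        res = call_direct_targets(a, b, n_rip=n_true, n_dw=n_true)
        assert res.fold > 2.0
        assert res.pvalue < 1e-6
        # called set strongly enriched for truth; precision is the sharper check
        precision = len(set(res.members) & set(ds.true_targets())) / res.overlap
        assert precision > 0.6


class TestDensityProfile:
    def test_walk_peaks_where_hits_end(self, mir100):
        ids = [f"t{i:02d}" for i in range(20)]
        utrs = {t: ("AAATACGGGTAAA" if i < 6 else "CCCCCCCCCCCC")
                for i, t in enumerate(ids)}
        prof = density_profile(make_ranked(ids), utrs, mir100,
                               SiteType.SEVENMER_M8)
        assert prof.n_hits == 6
        assert prof.argmax_rank == 6
        assert prof.peak_value == pytest.approx(1.0)
        assert prof.walk[-1] == pytest.approx(0.0, abs=1e-12)

    def test_eightmer_counts_as_sevenmer_m8_hit(self, mir100):
        utrs = {"a": "AAATACGGGTAAA", "b": "CCCC"}
        prof = density_profile(make_ranked(["a", "b"]), utrs, mir100,
                               SiteType.SEVENMER_M8)
        assert prof.n_hits == 1

    def test_uniform_hits_stay_flat(self, mir100, rng):
        N = 2000
        ids = [f"t{i:04d}" for i in range(N)]
        hits = rng.permutation(N) < 400
        utrs = {t: ("CCTACGGGTCC" if h else "CCCCCCCCCCC")
                for t, h in zip(ids, hits)}
        prof = density_profile(make_ranked(ids), utrs, mir100)
        assert np.abs(prof.walk).max() <= 0.15

    def test_zero_hits_error(self, mir100):
        utrs = {"a": "CCCC", "b": "CCCC"}
        with pytest.raises(ValueError, match="no site-bearing"):
            density_profile(make_ranked(["a", "b"]), utrs, mir100)


class TestMirnaSetOverlap:
    def test_disjoint_sets(self):
        res = mirna_set_overlap({"a", "b"}, {"c", "d"}, 100)
        assert res.fold == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_equal_sets(self):
        res = mirna_set_overlap({"a", "b", "c", "d"}, {"a", "b", "c", "d"}, 100)
        assert res.fold == pytest.approx(100 / 4)

    def test_half_shared_planted_sets(self, rng):
        N = 2000
        universe = [f"t{i}" for i in range(N)]
        shared = set(universe[:100])
        a = shared | set(universe[100:200])
        b = shared | set(universe[200:300])
        res = mirna_set_overlap(a, b, N)
        assert res.fold > 1.0
        assert res.pvalue < 0.01

    def test_set_larger_than_universe(self):
        with pytest.raises(ValueError):
            mirna_set_overlap({"a", "b"}, {"c"}, 1)
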