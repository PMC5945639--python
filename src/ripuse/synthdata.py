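"""Synthetic experiment generator: UTR FASTA plus paired RIP/input and
mimic/negative-control abundance tables with planted, class-stratified
repression and AGO2-loading effects.

The generator emulates the measurement endpoint of the experimental design
— isoform-level RPKM tables for two paired contrasts — without simulating
reads.  Random UTRs are drawn per-base from a GC model; seed-site words are
planted into configured fractions of transcripts with rejection sampling so
that an intended site never scans as a higher class at its position.
Repression acts through realized site content: every transcript whose final
UTR carries a seed site (planted or arising by chance) is a candidate true
target; true targets receive the repression effect of their *best* realized
site class in the mimic/control contrast and the AGO2-loading effect in the
RIP/input contrast.  Noise is log-normal on the abundance scale (additive
Gaussian in log2).  ``true_target_fraction`` subsamples the carriers, for
experiments where site presence should not guarantee function; a pure-noise
null is obtained by setting both the planting fractions and
``true_target_fraction`` to zero.

Everything is deterministic given the seed (a mandatory field).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ranking import AbundanceTable
from .sites import (
    MicroRNA,
    MIR100_5P,
    SiteType,
    SITE_CLASSES,
    scan_sites,
)

_PLANT_MAX_RETRIES = 200


def _default_planting() -> dict[SiteType, float]:
    return {
        SiteType.EIGHTMER: 0.10,
        SiteType.SEVENMER_M8: 0.15,
        SiteType.SEVENMER_1A: 0.10,
        SiteType.SIXMER: 0.10,
    }


def _default_effects() -> dict[SiteType, float]:
    return {
        SiteType.EIGHTMER: -0.8,
        SiteType.SEVENMER_M8: -0.6,
        SiteType.SEVENMER_1A: -0.4,
        SiteType.SIXMER: -0.2,
    }


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    Defaults: 2,000 transcripts with 500-1,000 nt UTRs at 40% GC (3'UTRs are
    AT-rich); planted site fractions 10/15/10/10% for 8mer/7mer-m8/7mer-1A/
    6mer; repression effects -0.8/-0.6/-0.4/-0.2 log2 units by class; +1.0
    log2 AGO2 loading for true targets; log2 noise sd 0.4; two replicates
    per condition.  ``seed`` has no default: reproducibility is mandatory.
    """

    seed: int
    n_transcripts: int = 2000
    utr_length: tuple[int, int] = (500, 1000)
    gc_fraction: float = 0.4
    planting_fractions: dict[SiteType, float] = field(default_factory=_default_planting)
    true_target_fraction: float = 1.0
    effect_sizes: dict[SiteType, float] = field(default_factory=_default_effects)
    rip_loading: float = 1.0
    noise_sd: float = 0.4
    n_replicates: int = 2
    base_log2_rpkm_mean: float = 5.0
    base_log2_rpkm_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a random seed is mandatory")
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        lo, hi = self.utr_length
        if not (0 < lo <= hi):
            raise ValueError("utr_length must be a (lo, hi) range with 0 < lo <= hi")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        fr = self.planting_fractions
        if any(not 0.0 <= f <= 1.0 for f in fr.values()) or sum(fr.values()) > 1.0:
            raise ValueError("planting fractions must be in [0,1] and sum to <= 1")
        if not 0.0 <= self.true_target_fraction <= 1.0:
            raise ValueError("true_target_fraction must be in [0, 1]")
        if any(e > 0 for e in self.effect_sizes.values()):
            raise ValueError("repression effects are log2 units <= 0")
        if self.rip_loading < 0:
            raise ValueError("rip_loading is a log2 unit >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def null(self) -> "SyntheticConfig":
        """A no-signal variant: nothing planted, no transcript functional."""
        return replace(
            self,
            planting_fractions={st: 0.0 for st in SITE_CLASSES},
            true_target_fraction=0.0,
        )


@dataclass
class SyntheticDataset:
    """Generated inputs plus the truth manifest."""

    utrs: dict[str, str]
    rip: AbundanceTable
    input_: AbundanceTable
    mimic: AbundanceTable
    control: AbundanceTable
    manifest: pd.DataFrame
    config: SyntheticConfig
    mirna: MicroRNA

    def true_targets(self) -> list[str]:
        m = self.manifest
        return m.loc[m["is_true_target"], "transcript_id"].tolist()

    def planted_ids(self, site_type: SiteType | None = None) -> list[str]:
        m = self.manifest
        sel = m["planted_class"] != "none"
        if site_type is not None:
            sel = m["planted_class"] == site_type.label
        return m.loc[sel, "transcript_id"].tolist()


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_utr(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return bytearray(_BASE_BYTES[codes].tobytes())


def _plant_ok(seq: bytearray, start: int, word: str, site_type: SiteType,
              m8_base: str) -> bool:
    """Would the planted occurrence scan as exactly the intended class?"""
    end = start + len(word)
    left = chr(seq[start - 1]) if start >= 1 else ""
    right = chr(seq[end]) if end < len(seq) else ""
    if site_type == SiteType.EIGHTMER:
        return True
    if site_type == SiteType.SEVENMER_M8:
        return right != "A"
    if site_type == SiteType.SEVENMER_1A:
        return left != m8_base
    # SIXMER: neither an m8 extension on the left nor a 1A on the right
    return left != m8_base and right != "A"


def _plant_word(
    rng: np.random.Generator,
    seq: bytearray,
    word: str,
    site_type: SiteType,
    m8_base: str,
    occupied: list[tuple[int, int]],
) -> int:
    if len(word) > len(seq):
        raise ValueError(
            f"cannot plant {len(word)}-nt word into a {len(seq)}-nt UTR"
        )
    wbytes = word.encode("ascii")
    for _ in range(_PLANT_MAX_RETRIES):
        start = int(rng.integers(0, len(seq) - len(word) + 1))
        end = start + len(word)
        # keep 1 nt clearance so neighbouring plants cannot reclassify a site
        if any(start < e + 1 and end + 1 > s for s, e in occupied):
            continue
        saved = seq[start:end]
        seq[start:end] = wbytes
        if _plant_ok(seq, start, word, site_type, m8_base):
            occupied.append((start, end))
            return start
        seq[start:end] = saved
    raise RuntimeError(
        f"failed to plant a {site_type.label} site after "
        f"{_PLANT_MAX_RETRIES} attempts"
    )


def generate(config: SyntheticConfig, mirna: MicroRNA = MIR100_5P) -> SyntheticDataset:
    """Generate UTRs, four abundance tables and the truth manifest.

    Deterministic: two calls with the same config produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    ids = [f"TX{i:05d}" for i in range(1, n + 1)]
    words = mirna.site_words()
    m8_base = words[SiteType.SEVENMER_M8][0]

    lo, hi = config.utr_length
    lengths = rng.integers(lo, hi + 1, size=n)
    seqs = [_random_utr(rng, int(L), config.gc_fraction) for L in lengths]

    # class assignment for planting: a shuffled block per class
    plant_class = np.full(n, SiteType.NONE.value, dtype=int)
    order = rng.permutation(n)
    pos = 0
    for st in SITE_CLASSES:
        cnt = int(round(config.planting_fractions.get(st, 0.0) * n))
        plant_class[order[pos:pos + cnt]] = st.value
        pos += cnt

    planted_start = np.full(n, -1, dtype=int)
    planted_word = [""] * n
    for i in range(n):
        st = SiteType(plant_class[i])
        if st == SiteType.NONE:
            continue
        w = words[st]
        planted_start[i] = _plant_word(rng, seqs[i], w, st, m8_base, [])
        planted_word[i] = w

    utrs = {tid: seq.decode("ascii") for tid, seq in zip(ids, seqs)}

    # realized best class after planting and chance occurrences
    realized = np.array(
        [max((a.site_type for a in scan_sites(utrs[t], mirna)),
             default=SiteType.NONE).value for t in ids]
    )

    carriers = np.flatnonzero(realized != SiteType.NONE.value)
    n_true = int(round(config.true_target_fraction * carriers.size))
    true_idx = rng.choice(carriers, size=n_true, replace=False) if n_true else \
        np.empty(0, dtype=int)
    is_true = np.zeros(n, dtype=bool)
    is_true[true_idx] = True

    effects = np.zeros(n)
    for st in SITE_CLASSES:
        effects[(realized == st.value) & is_true] = config.effect_sizes[st]
    loading = np.where(is_true, config.rip_loading, 0.0)

    base = 2.0 ** rng.normal(
        config.base_log2_rpkm_mean, config.base_log2_rpkm_sd, size=n
    )

    def noisy(shift: np.ndarray | float) -> np.ndarray:
        eps = rng.normal(0.0, config.noise_sd, size=(n, config.n_replicates))
        return base[:, None] * 2.0 ** (np.asarray(shift).reshape(-1, 1) + eps)

    def table(mat: np.ndarray, prefix: str) -> AbundanceTable:
        cols = [f"{prefix}_rep{r + 1}" for r in range(config.n_replicates)]
        return AbundanceTable(
            pd.DataFrame(mat, index=pd.Index(ids, name="transcript_id"),
                         columns=cols),
            lengths=pd.Series(lengths, index=ids, name="length"),
        )

    control = table(noisy(0.0), "control")
    mimic = table(noisy(effects), "mimic")
    input_ = table(noisy(0.0), "input")
    rip = table(noisy(loading), "rip")

    manifest = pd.DataFrame(
        {
            "transcript_id": ids,
            "planted_class": [SiteType(v).label for v in plant_class],
            "planted_start": planted_start,
            "planted_word": planted_word,
            "realized_class": [SiteType(v).label for v in realized],
            "is_true_target": is_true,
            "log2_effect": effects,
            "log2_loading": loading,
        }
    )
    return SyntheticDataset(utrs, rip, input_, mimic, control, manifest,
                            config, mirna)


@dataclass
class VerificationReport:
    ok: bool
    mismatches: list[tuple[str, str]]


def verify_manifest(
    utrs: Mapping[str, str], manifest: pd.DataFrame, mirna: MicroRNA
) -> VerificationReport:
    """Re-scan every planted site and check position, class and word.

    Returns an all-pass report for a fresh :func:`generate` output; any
    mutated base inside a planted site is flagged with the transcript id.
    """
    mismatches: list[tuple[str, str]] = []
    for row in manifest.itertuples(index=False):
        if row.planted_class == "none":
            continue
        tid = row.transcript_id
        if tid not in utrs:
            mismatches.append((tid, "missing UTR"))
            continue
        anns = scan_sites(utrs[tid], mirna, tid)
        hit = [a for a in anns if a.start == row.planted_start]
        if not hit:
            mismatches.append((tid, f"no site found at {row.planted_start}"))
        elif hit[0].site_type.label != row.planted_class:
            mismatches.append(
                (tid, f"class {hit[0].site_type.label} != {row.planted_class}")
            )
        elif hit[0].word != row.planted_word:
            mismatches.append((tid, f"word {hit[0].word} != {row.planted_word}"))
    return VerificationReport(not mismatches, mismatches)
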