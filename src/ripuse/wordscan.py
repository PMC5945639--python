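"""Unbiased k-mer word-enrichment landscape over a ranked transcript list.

For every word of length k (k in {6,7,8}) and every cutoff n along a ranked
transcript list, the landscape holds a signed score

    score(word, n) = -log10 p_upper   if the word's presence rate in the
                                      top-n exceeds its universe rate,
                     +log10 p_lower   otherwise (a negative number),

where p_upper/p_lower are one-sided hypergeometric tail probabilities of the
word's per-transcript presence count in the top-n against the whole universe
(population = all ranked transcripts, successes = transcripts containing the
word, draws = n).  A word concentrated at the head of the list produces a
positive peak; a depleted word a negative trough; reversing the list flips
the sign.  This is the Sylamer-style landscape: with the list ranked by AGO2
enrichment or by post-overexpression repression, the miRNA's seed words (and
any other word mediating the loading) surface without being told the miRNA.

Presence/absence per transcript is the default counting unit, which makes
the hypergeometric model exact; an occurrence-count binomial mode is
available behind ``mode="occurrence"``.  No background composition
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln
from scipy.stats import binom

from .ranking import RankedList
from .sites import MicroRNA, normalize_utr, SITE_CLASSES

_LN10 = np.log(10.0)
_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i

DEFAULT_K_SET = (6, 7, 8)
DEFAULT_N_CUTOFFS = 20


def encode_word(word: str) -> int:
    """Base-4 integer code of a DNA word (A=0, C=1, G=2, T=3)."""
    code = 0
    for ch in word:
        v = _CODE[ord(ch)]
        if v < 0:
            raise ValueError(f"non-ACGT character in word {word!r}")
        code = code * 4 + v
    return code


def decode_word(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Codes of every length-k window; windows containing non-ACGT skipped."""
    u = normalize_utr(seq)
    if len(u) < k:
        return np.empty(0, dtype=np.int64)
    codes = _CODE[np.frombuffer(u.encode("ascii"), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[valid] @ powers


def distinct_kmer_codes(seq: str, k: int) -> np.ndarray:
    return np.unique(kmer_codes(seq, k))


def presence_matrix(
    ranked_ids: list[str] | RankedList, utrs: dict[str, str], k: int
) -> sparse.csr_matrix:
    """Sparse indicator matrix: row = rank position, column = word code.

    Entry (i, w) is 1 iff word w occurs at least once in the UTR of the
    transcript at rank i.
    """
    if isinstance(ranked_ids, RankedList):
        ranked_ids = ranked_ids.ids
    rows, cols = [], []
    for i, tid in enumerate(ranked_ids):
        try:
            utr = utrs[tid]
        except KeyError:
            raise KeyError(f"no UTR sequence for ranked transcript {tid!r}") from None
        codes = distinct_kmer_codes(utr, k)
        rows.append(np.full(codes.size, i, dtype=np.int64))
        cols.append(codes)
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    data = np.ones(rows.size, dtype=np.int8)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(ranked_ids), 4**k)
    )


def occurrence_matrix(
    ranked_ids: list[str] | RankedList, utrs: dict[str, str], k: int
) -> sparse.csr_matrix:
    """Like :func:`presence_matrix` but entries are occurrence counts."""
    if isinstance(ranked_ids, RankedList):
        ranked_ids = ranked_ids.ids
    rows, cols, data = [], [], []
    for i, tid in enumerate(ranked_ids):
        try:
            utr = utrs[tid]
        except KeyError:
            raise KeyError(f"no UTR sequence for ranked transcript {tid!r}") from None
        codes, counts = np.unique(kmer_codes(utr, k), return_counts=True)
        rows.append(np.full(codes.size, i, dtype=np.int64))
        cols.append(codes)
        data.append(counts)
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    data = np.concatenate(data) if data else np.empty(0, dtype=np.int64)
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(ranked_ids), 4**k)
    )


def default_cutoffs(n_universe: int, n_cutoffs: int = DEFAULT_N_CUTOFFS) -> np.ndarray:
    """Evenly spaced rank cutoffs from N/20 to N*19/20 (20 by default)."""
    lo = max(1, n_universe // (n_cutoffs))
    hi = n_universe * (n_cutoffs - 1) // n_cutoffs
    grid = np.unique(np.linspace(lo, hi, n_cutoffs).round().astype(int))
    return grid[(grid >= 1) & (grid < n_universe)]


@dataclass
class KLandscape:
    """Per-k slab of the landscape (arrays indexed by word code)."""

    k: int
    cutoffs: np.ndarray              # (C,)
    scores: np.ndarray               # (4**k, C) signed -log10 p
    raw_p: np.ndarray                # (4**k, C) tail p backing the score
    leading_counts: np.ndarray       # (4**k, C) presence/occurrence in top-n
    universe_counts: np.ndarray      # (4**k,) presence/occurrence in universe


@dataclass
class EnrichmentLandscape:
    """Word x cutoff matrix of signed -log10 hypergeometric p-values."""

    n_universe: int
    cutoffs: np.ndarray
    tables: dict[int, KLandscape]
    mode: str = "presence"

    @property
    def k_set(self) -> tuple[int, ...]:
        return tuple(sorted(self.tables))

    def score(self, word: str, cutoff: int) -> float:
        t = self.tables[len(word)]
        j = int(np.searchsorted(t.cutoffs, cutoff))
        if j >= t.cutoffs.size or t.cutoffs[j] != cutoff:
            raise KeyError(f"cutoff {cutoff} not in the landscape grid")
        return float(t.scores[encode_word(word), j])

    def profile(self, word: str) -> pd.Series:
        """Score-vs-cutoff curve for one word."""
        t = self.tables[len(word)]
        return pd.Series(t.scores[encode_word(word)], index=t.cutoffs, name=word)

    def to_long_frame(self, k: int, words: list[str] | None = None) -> pd.DataFrame:
        """Long-format table (k, word, cutoff, counts, signed_score, raw_p)."""
        t = self.tables[k]
        if words is None:
            codes = np.flatnonzero(t.universe_counts > 0)
        else:
            codes = np.array([encode_word(w) for w in words], dtype=np.int64)
        recs = []
        for c in codes:
            w = decode_word(int(c), k)
            for j, n in enumerate(t.cutoffs):
                recs.append(
                    (k, w, int(n), int(t.leading_counts[c, j]),
                     int(t.universe_counts[c]), float(t.scores[c, j]),
                     float(t.raw_p[c, j]))
                )
        return pd.DataFrame(
            recs,
            columns=["k", "word", "cutoff", "leading_count", "universe_count",
                     "signed_score", "raw_p"],
        )


def hypergeom_log_tail(x, N: int, K, n: int, upper: bool) -> np.ndarray:
    """Exact log hypergeometric tail, vectorised over (x, K).

    Returns log P(X >= x) when ``upper`` else log P(X <= x), for X
    hypergeometric with population N, K successes and n draws.  Computed in
    log space as log pmf(x) plus the log of a term-ratio series, so very
    small tails keep full log-scale accuracy instead of underflowing.  x
    must lie in the support.  Terms are accumulated until they fall below
    1e-18 of the running sum past the distribution mean, giving absolute
    accuracy far beyond 1e-12.
    """
    x = np.asarray(x, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    x, K = np.broadcast_arrays(x, K)
    x = x.copy()
    log_pmf_x = (
        gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
        + gammaln(N - K + 1) - gammaln(n - x + 1) - gammaln(N - K - n + x + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    mean = n * K / N
    total = np.ones_like(x)
    term = np.ones_like(x)
    i = x.copy()
    if upper:
        hi = np.minimum(K, n)
        active = i < hi
        while active.any():
            ratio = np.where(
                active, (K - i) * (n - i) / ((i + 1) * (N - K - n + i + 1)), 0.0
            )
            term = term * ratio
            total += term
            i += 1.0
            active = (i < hi) & ((term > total * 1e-18) | (i <= mean))
    else:
        lo = np.maximum(0.0, n - (N - K))
        active = i > lo
        while active.any():
            ratio = np.where(
                active, i * (N - K - n + i) / ((K - i + 1) * (n - i + 1)), 0.0
            )
            term = term * ratio
            total += term
            i -= 1.0
            active = (i > lo) & ((term > total * 1e-18) | (i >= mean))
    return log_pmf_x + np.log(total)


def _signed_scores_hypergeom(x, N, K, n):
    """Signed score + backing tail p for presence counts (vectorised)."""
    x = np.asarray(x, dtype=float)
    K = np.asarray(K, dtype=float)
    over = x / n > K / N
    log_p = np.empty_like(x)
    if over.any():
        log_p[over] = hypergeom_log_tail(x[over], N, K[over], n, upper=True)
    if (~over).any():
        log_p[~over] = hypergeom_log_tail(x[~over], N, K[~over], n, upper=False)
    scores = np.where(over, -log_p, log_p) / _LN10
    return scores, np.exp(log_p)


def _signed_scores_binom(x, W_top, K_occ, W_all):
    """Occurrence-count mode: binomial tails at the universe occurrence rate."""
    x = np.asarray(x, dtype=float)
    rate = np.asarray(K_occ, dtype=float) / W_all
    with np.errstate(divide="ignore", invalid="ignore"):
        log_upper = binom.logsf(x - 1, W_top, rate)
        log_lower = binom.logcdf(x, W_top, rate)
    over = x / W_top > rate
    log_p = np.where(over, log_upper, log_lower)
    scores = np.where(over, -log_p, log_p) / _LN10
    return scores, np.exp(log_p)


def landscape(
    ranked: RankedList,
    utrs: dict[str, str],
    k_set: tuple[int, ...] = DEFAULT_K_SET,
    cutoffs: np.ndarray | None = None,
    mode: str = "presence",
) -> EnrichmentLandscape:
    """Compute the full word-enrichment landscape for a ranked list.

    ``mode="presence"`` (default) tests per-transcript word presence with the
    exact hypergeometric distribution; ``mode="occurrence"`` tests total
    occurrence counts with a binomial at the universe occurrence rate.
    """
    N = len(ranked)
    if cutoffs is None:
        cutoffs = default_cutoffs(N)
    cutoffs = np.asarray(cutoffs, dtype=int)
    if cutoffs.size == 0:
        raise ValueError("empty cutoff grid")
    if not (np.diff(cutoffs) > 0).all():
        raise ValueError("cutoffs must be strictly increasing")
    if cutoffs[0] < 1 or cutoffs[-1] >= N:
        raise ValueError("cutoffs must lie in [1, universe size)")
    bad_k = [k for k in k_set if k not in (6, 7, 8)]
    if bad_k:
        raise ValueError(f"unsupported word lengths {bad_k}; k must be 6, 7 or 8")

    tables: dict[int, KLandscape] = {}
    for k in sorted(set(k_set)):
        if mode == "presence":
            M = presence_matrix(ranked, utrs, k)
        elif mode == "occurrence":
            M = occurrence_matrix(ranked, utrs, k)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        K_tot = np.asarray(M.sum(axis=0)).ravel()
        n_words = 4**k
        scores = np.empty((n_words, cutoffs.size))
        raw_p = np.empty_like(scores)
        leading = np.empty((n_words, cutoffs.size), dtype=np.int64)
        if mode == "occurrence":
            # window totals per transcript, cumulated along the ranking
            per_tx = np.asarray(M.sum(axis=1)).ravel()
            cum_windows = np.concatenate([[0], np.cumsum(per_tx)])
            W_all = cum_windows[-1]
        for j, n in enumerate(cutoffs):
            x = np.asarray(M[:n].sum(axis=0)).ravel()
            leading[:, j] = x
            if mode == "presence":
                scores[:, j], raw_p[:, j] = _signed_scores_hypergeom(x, N, K_tot, int(n))
            else:
                scores[:, j], raw_p[:, j] = _signed_scores_binom(
                    x, cum_windows[n], K_tot, W_all
                )
        tables[k] = KLandscape(k, cutoffs, scores, raw_p, leading, K_tot)
    return EnrichmentLandscape(N, cutoffs, tables, mode)


def top_words(
    ls: EnrichmentLandscape, m: int = 20, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Words ranked by Bonferroni-corrected peak significance.

    The correction factor for a word of length k is (number of length-k
    words) x (number of cutoffs) — every cell the unbiased scan looked at.
    Ties are broken lexicographically by word.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}")
    frames = []
    for k, t in ls.tables.items():
        factor = (4**k) * t.cutoffs.size
        peak_j = np.abs(t.scores).argmax(axis=1)
        codes = np.arange(4**k)
        peak_scores = t.scores[codes, peak_j]
        peak_p = t.raw_p[codes, peak_j]
        corrected = np.minimum(1.0, peak_p * factor)
        frames.append(
            pd.DataFrame(
                {
                    "k": k,
                    "word": [decode_word(int(c), k) for c in codes],
                    "peak_cutoff": t.cutoffs[peak_j],
                    "peak_score": peak_scores,
                    "raw_p": peak_p,
                    "corrected_p": corrected,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["corrected_p", "raw_p", "word"], kind="stable", ignore_index=True
    )
    return out.head(m)


@dataclass
class SeedProfile:
    """Score-vs-cutoff curves for one miRNA's four canonical site words."""

    table: pd.DataFrame          # site_class, word, peak_score, peak_cutoff
    curves: dict[str, pd.Series]  # word -> score vs cutoff


def seed_profile(ls: EnrichmentLandscape, mirna: MicroRNA) -> SeedProfile:
    """Extract the landscape rows of the miRNA's canonical site words.

    Words whose length is not in the landscape's k-set are skipped.
    """
    rows, curves = [], {}
    for st in SITE_CLASSES:
        word = mirna.site_words()[st]
        if len(word) not in ls.tables:
            continue
        curve = ls.profile(word)
        j = int(np.abs(curve.to_numpy()).argmax())
        rows.append(
            {
                "site_class": st.label,
                "word": word,
                "peak_score": float(curve.iloc[j]),
                "peak_cutoff": int(curve.index[j]),
            }
        )
        curves[word] = curve
    return SeedProfile(pd.DataFrame(rows), curves)


def plot_landscape(ls: EnrichmentLandscape, words: list[str], ax=None):
    """Score-vs-cutoff curves for selected words (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for w in words:
        curve = ls.profile(w)
        ax.plot(curve.index, curve.to_numpy(), label=w)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("rank cutoff")
    ax.set_ylabel("signed -log10 p")
    ax.legend(fontsize="small")
    return ax
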