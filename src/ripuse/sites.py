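"""Seed-match grammar: derive canonical site words from a mature miRNA and
scan 3'UTRs for their occurrences.

A miRNA represses targets mainly through Watson-Crick pairing of its *seed*
(nucleotides 2-8 counted from the 5' end) with sites in the target 3'UTR.
The four canonical site classes, in decreasing order of expected efficacy:

====================  =======================================================
class                 match on the mRNA (read 5'->3')
====================  =======================================================
8mer                  reverse complement of miRNA nt 2-8, followed by an A
7mer-m8               reverse complement of miRNA nt 2-8
7mer-1A               reverse complement of miRNA nt 2-7, followed by an A
6mer                  reverse complement of miRNA nt 2-7
====================  =======================================================

The trailing "A" of the 7mer-1A/8mer classes is required to be a literal A in
the UTR (it is recognised by Argonaute, not by base pairing with nt 1).

The internal alphabet is DNA: RNA input (U) is normalised to T at ingestion,
because UTR FASTA files are DNA.  Coordinates are 0-based, half-open, on the
given UTR strand (only that strand is searched).  N or any other non-ACGT
character never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum


class AlphabetError(ValueError):
    """A sequence contains characters outside the allowed alphabet."""


class InvalidMicroRNAError(ValueError):
    """A mature miRNA sequence is unusable (too short to derive the seed)."""


_RNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")

#: Minimum mature length required to derive all four site words (nt 1-8).
MIN_MATURE_LENGTH = 8

#: Typical minimum length of a real mature miRNA; shorter input is accepted
#: down to MIN_MATURE_LENGTH but is unusual.
TYPICAL_MATURE_LENGTH = 19


class SiteType(IntEnum):
    """Canonical seed-site classes, totally ordered by expected efficacy."""

    NONE = 0
    SIXMER = 1
    SEVENMER_1A = 2
    SEVENMER_M8 = 3
    EIGHTMER = 4

    @property
    def label(self) -> str:
        return _SITE_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "SiteType":
        try:
            return _LABEL_TO_SITE[label.lower()]
        except KeyError:
            raise ValueError(f"unknown site class label: {label!r}") from None


_SITE_LABELS = {
    SiteType.NONE: "none",
    SiteType.SIXMER: "6mer",
    SiteType.SEVENMER_1A: "7mer-1A",
    SiteType.SEVENMER_M8: "7mer-m8",
    SiteType.EIGHTMER: "8mer",
}
_LABEL_TO_SITE = {v.lower(): k for k, v in _SITE_LABELS.items()}

#: Site classes that correspond to an actual match, strongest first.
SITE_CLASSES = (
    SiteType.EIGHTMER,
    SiteType.SEVENMER_M8,
    SiteType.SEVENMER_1A,
    SiteType.SIXMER,
)


@dataclass(frozen=True)
class MicroRNA:
    """A named mature miRNA sequence, 5'->3'.

    ``mature_seq`` is stored in RNA alphabet (T normalised to U on input).
    At least 8 nt are required so that all four seed-site words can be
    derived.
    """

    name: str
    mature_seq: str

    def __post_init__(self) -> None:
        seq = self.mature_seq.upper().replace("T", "U")
        bad = set(seq) - set("ACGU")
        if bad:
            raise AlphabetError(
                f"miRNA {self.name!r}: non-ACGU characters {sorted(bad)!r}"
            )
        if len(seq) < MIN_MATURE_LENGTH:
            raise InvalidMicroRNAError(
                f"miRNA {self.name!r}: mature sequence has {len(seq)} nt; "
                f"at least {MIN_MATURE_LENGTH} are required to derive seed sites"
            )
        object.__setattr__(self, "mature_seq", seq)

    def site_words(self) -> dict[SiteType, str]:
        """All four site words, keyed by class."""
        return {st: seed_site_word(self, st) for st in SITE_CLASSES}


def _reverse_complement_rna_to_dna(rna: str) -> str:
    return rna.translate(_RNA_COMPLEMENT)[::-1]


def seed_site_word(mirna: MicroRNA, site_type: SiteType) -> str:
    """The mRNA-strand (5'->3', DNA alphabet) match word for one site class.

    6mer = reverse complement of miRNA nt 2-7; 7mer-m8 = reverse complement
    of nt 2-8; 7mer-1A = 6mer + "A"; 8mer = 7mer-m8 + "A".
    """
    if site_type == SiteType.NONE:
        raise ValueError("NONE has no site word")
    core6 = _reverse_complement_rna_to_dna(mirna.mature_seq[1:7])
    if site_type == SiteType.SIXMER:
        return core6
    if site_type == SiteType.SEVENMER_1A:
        return core6 + "A"
    m8 = _reverse_complement_rna_to_dna(mirna.mature_seq[1:8])
    if site_type == SiteType.SEVENMER_M8:
        return m8
    return m8 + "A"  # EIGHTMER


@dataclass(frozen=True)
class SiteAnnotation:
    """One seed-match occurrence in a 3'UTR.

    ``start`` is a 0-based offset; the site occupies the half-open interval
    ``[start, start + len(word))`` and the UTR substring there equals
    ``word`` exactly.  Overlapping occurrences at one seed-core position are
    collapsed to the highest-ranking class (an 8mer is not additionally
    reported as its embedded 7mers/6mer).
    """

    transcript_id: str
    start: int
    site_type: SiteType
    word: str

    @property
    def end(self) -> int:
        return self.start + len(self.word)


def normalize_utr(utr: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    return utr.upper().replace("U", "T")


def scan_sites(
    utr: str, mirna: MicroRNA, transcript_id: str = ""
) -> list[SiteAnnotation]:
    """All seed-site occurrences of ``mirna`` in ``utr``, strongest class per
    seed-core position, sorted by start.

    Every occurrence of the 6mer core is examined once; the flanking bases
    decide its class (m8 match upstream, literal A downstream).  Distinct
    core positions are reported independently even when their words overlap.
    """
    u = normalize_utr(utr)
    words = mirna.site_words()
    core = words[SiteType.SIXMER]
    m8_base = words[SiteType.SEVENMER_M8][0]
    out: list[SiteAnnotation] = []
    p = u.find(core)
    while p != -1:
        has_m8 = p >= 1 and u[p - 1] == m8_base
        has_a = p + 6 < len(u) and u[p + 6] == "A"
        if has_m8 and has_a:
            st, start = SiteType.EIGHTMER, p - 1
        elif has_m8:
            st, start = SiteType.SEVENMER_M8, p - 1
        elif has_a:
            st, start = SiteType.SEVENMER_1A, p
        else:
            st, start = SiteType.SIXMER, p
        out.append(SiteAnnotation(transcript_id, start, st, words[st]))
        p = u.find(core, p + 1)
    return out


def best_site_type(utr: str, mirna: MicroRNA) -> SiteType:
    """The strongest site class present in ``utr`` (NONE if no site)."""
    anns = scan_sites(utr, mirna)
    if not anns:
        return SiteType.NONE
    return max(a.site_type for a in anns)


def count_word_occurrences(utr: str, word: str) -> int:
    """Number of (possibly overlapping) exact occurrences of ``word``.

    Overlap counting is the convention throughout: "AAAA" contains "AA"
    three times.
    """
    if len(word) < 1:
        raise ValueError("word must be non-empty")
    u = normalize_utr(utr)
    w = normalize_utr(word)
    n = 0
    p = u.find(w)
    while p != -1:
        n += 1
        p = u.find(w, p + 1)
    return n


# Reference mature sequences (miRBase) for the two miRNAs this method was
# developed around; consistent with their full-length LNA detection probes.
MIR100_5P = MicroRNA("miR-100-5p", "AACCCGUAGAUCCGAACUUGUG")
MIR125B_5P = MicroRNA("miR-125b-5p", "UCCCUGAGACCCUAACUUGUGA")
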