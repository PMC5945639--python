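"""File formats: FASTA UTRs, TSV tables, JSON summaries, TOML configs.

Writers are deterministic (sorted JSON keys, 6 significant digits for
floats) so that identical inputs, config and seed regenerate every artifact
bit-identically.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .ranking import AbundanceTable, RankedList
from .sites import SiteAnnotation

FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Malformed input file (duplicate ids, ragged rows, bad values)."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an ordered {id: sequence} mapping.

    The record id is the first whitespace-delimited token of the header;
    wrapped and CRLF line endings are accepted; duplicate ids are an error.
    """
    out: dict[str, str] = {}
    with open(path, encoding="ascii", errors="strict", newline=None) as fh:
        for header, seq in SimpleFastaParser(fh):
            tid = header.split()[0] if header.split() else ""
            if not tid:
                raise FormatError(f"{path}: FASTA record with empty id")
            if tid in out:
                raise FormatError(f"{path}: duplicate FASTA id {tid!r}")
            out[tid] = seq.upper()
    return out


def write_fasta(utrs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for tid, seq in utrs.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_abundance_table(
    path: str | Path, length_column: str | None = None
) -> AbundanceTable:
    """Tab-delimited abundance table: header row, first column = transcript id."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{path}: duplicate transcript ids {dup}")
    lengths = None
    if length_column is not None:
        if length_column not in df.columns:
            raise FormatError(f"{path}: no column {length_column!r}")
        lengths = df.pop(length_column).astype(float)
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric abundance value ({exc})") from exc
    na_rows = values.isna().any(axis=1)
    if na_rows.any():
        first = values.index[na_rows][0]
        row_no = int(na_rows.to_numpy().argmax()) + 2  # header is line 1
        raise FormatError(f"{path}: missing value in row {row_no} ({first!r})")
    try:
        return AbundanceTable(values, lengths=lengths)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.values.copy()
    df.index.name = df.index.name or "transcript_id"
    write_table(df, path, index=True)


def write_ranked_list(ranked: RankedList, path: str | Path) -> None:
    write_table(ranked.to_frame(), path)


def read_ranked_list(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t")
    need = {"rank", "transcript_id", "statistic"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    df = df.sort_values("rank", kind="stable")
    ids = df["transcript_id"].astype(str).tolist()
    stat = pd.Series(df["statistic"].to_numpy(float), index=ids)
    direction = "downregulation_first" if stat.is_monotonic_increasing else \
        "rip_enrichment_desc"
    return RankedList(ids, stat, direction)


def annotations_to_frame(
    annotations: Iterable[SiteAnnotation], mirna_name: str
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": a.transcript_id,
                "start": a.start,
                "end": a.end,
                "site_type": a.site_type.label,
                "word": a.word,
                "mirna_name": mirna_name,
            }
            for a in annotations
        ],
        columns=["transcript_id", "start", "end", "site_type", "word", "mirna_name"],
    )


def annotations_to_bed(
    annotations: Iterable[SiteAnnotation], mirna_name: str
) -> pd.DataFrame:
    """BED intervals with the UTR itself as the coordinate system."""
    return pd.DataFrame(
        [
            {
                "chrom": a.transcript_id,
                "chromStart": a.start,
                "chromEnd": a.end,
                "name": f"{mirna_name}|{a.site_type.label}",
                "score": int(a.site_type),
                "strand": "+",
            }
            for a in annotations
        ],
        columns=["chrom", "chromStart", "chromEnd", "name", "score", "strand"],
    )


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return str(obj)
        if obj == 0:
            return 0.0
        return float(f"{obj:.{sig}g}")
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_toml(obj: Mapping, path: str | Path) -> None:
    """Flat key-value TOML echo of a configuration mapping."""
    lines = []
    for key, val in obj.items():
        if isinstance(val, bool):
            rep = "true" if val else "false"
        elif isinstance(val, (int, float)):
            rep = repr(val)
        elif isinstance(val, str):
            rep = json.dumps(val)
        elif isinstance(val, (list, tuple)):
            rep = "[" + ", ".join(repr(v) for v in val) + "]"
        elif isinstance(val, Mapping):
            rep = ("{" + ", ".join(f"{json.dumps(str(k))} = {repr(v)}"
                                   for k, v in val.items()) + "}")
        else:
            rep = json.dumps(str(val))
        lines.append(f"{key} = {rep}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")


def read_toml(path: str | Path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
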