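"""Readers and writers for the tab-separated formats the framework touches.

BED (3+ columns), BEDPE (6+ columns), chrom.sizes (2 columns), a 10-column
PET table, and verified-contact BEDPE with a source tag.  All readers accept
plain or gzip-compressed files (by ``.gz`` suffix) and report parse failures
with the offending line number.  Coordinates are 0-based half-open and
round-trip losslessly through the paired writer.
"""

from __future__ import annotations

import gzip
import io as _io
from typing import Callable, Iterable, Mapping

from .core import (
    ChromSizes,
    GenomicInterval,
    Loop,
    LoopSet,
    PeakSet,
    PETRecord,
)
from .goldstandard import VerifiedContact

__all__ = [
    "read_bedpe",
    "write_bedpe",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_pets",
    "write_pets",
    "read_contacts",
    "write_contacts",
    "DEFAULT_BEDPE_COLUMNS",
]

#: Default mapping of optional BEDPE columns (1-based indices).  Loop
#: callers disagree on output layout; pass a custom map to override.
DEFAULT_BEDPE_COLUMNS: dict[str, int] = {"pet_count": 7, "p_value": 8, "fdr": 9}

_MISSING = {"", ".", "NA", "nan"}


def _open_read(path) -> _io.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_write(path) -> _io.TextIOBase:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "wt")


def _data_lines(handle):
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line.split("\t")


def _parse(value: str, lineno: int, what: str, conv: Callable):
    try:
        return conv(value)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: cannot parse {what} from {value!r}") from exc


def _interval(chrom: str, start: str, end: str, lineno: int) -> GenomicInterval:
    s = _parse(start, lineno, "start", int)
    e = _parse(end, lineno, "end", int)
    try:
        return GenomicInterval(chrom, s, e)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


def read_bedpe(
    path,
    columns: Mapping[str, int] | None = None,
    label: str = "",
) -> LoopSet:
    """Read a BEDPE file into a :class:`LoopSet`.

    ``columns`` maps optional field names (``pet_count``, ``p_value``,
    ``fdr``) to 1-based column indices; missing columns or ``.`` entries
    leave the field absent.  Anchors are normalised into genome order; the
    row count is preserved.
    """
    colmap = dict(DEFAULT_BEDPE_COLUMNS if columns is None else columns)
    loops: list[Loop] = []
    with _open_read(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 6:
                raise ValueError(
                    f"line {lineno}: expected >=6 tab-separated columns, got {len(fields)}"
                )
            a1 = _interval(fields[0], fields[1], fields[2], lineno)
            a2 = _interval(fields[3], fields[4], fields[5], lineno)
            extras: dict[str, float | int | None] = {}
            for name, col in colmap.items():
                if col is None or len(fields) < col:
                    continue
                raw = fields[col - 1]
                if raw in _MISSING:
                    continue
                conv = int if name == "pet_count" else float
                extras[name] = _parse(raw, lineno, name, conv)
            try:
                loops.append(Loop(a1, a2, **extras))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return LoopSet(loops, label=label)


def write_bedpe(loopset: LoopSet, path) -> None:
    """Write a :class:`LoopSet` as BEDPE (optional columns 7-9 when present)."""
    has_pet = any(lp.pet_count is not None for lp in loopset)
    has_p = any(lp.p_value is not None for lp in loopset)
    has_fdr = any(lp.fdr is not None for lp in loopset)
    # trailing optional columns are only emitted up to the last populated one
    n_extra = 3 if has_fdr else (2 if has_p else (1 if has_pet else 0))
    with _open_write(path) as fh:
        for lp in loopset:
            cols = [
                lp.anchor1.chrom,
                str(lp.anchor1.start),
                str(lp.anchor1.end),
                lp.anchor2.chrom,
                str(lp.anchor2.start),
                str(lp.anchor2.end),
            ]
            extras = [
                "." if lp.pet_count is None else str(lp.pet_count),
                "." if lp.p_value is None else repr(lp.p_value),
                "." if lp.fdr is None else repr(lp.fdr),
            ]
            cols.extend(extras[:n_extra])
            fh.write("\t".join(cols) + "\n")


def read_bed(path, label: str = "") -> PeakSet:
    """Read a BED file (3+ columns, optional score in column 5)."""
    intervals: list[GenomicInterval] = []
    scores: list[float | None] = []
    any_score = False
    with _open_read(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            intervals.append(_interval(fields[0], fields[1], fields[2], lineno))
            if len(fields) >= 5 and fields[4] not in _MISSING:
                scores.append(_parse(fields[4], lineno, "score", float))
                any_score = True
            else:
                scores.append(None)
    return PeakSet(intervals, scores=scores if any_score else None, label=label)


def write_bed(peaks: PeakSet, path) -> None:
    scores = peaks.scores
    with _open_write(path) as fh:
        for i, iv in enumerate(peaks):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if scores is not None:
                score = scores[i]
                cols.extend([".", "." if score is None else repr(score)])
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path) -> ChromSizes:
    sizes: dict[str, int] = {}
    with _open_read(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 columns (chrom, length)")
            length = _parse(fields[1], lineno, "chromosome length", int)
            if length <= 0:
                raise ValueError(f"line {lineno}: non-positive length {length}")
            sizes[fields[0]] = length
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with _open_write(path) as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# PET tables
#
# PET records arrive as a 10-column tab-separated file exported upstream of
# this framework (alignment and duplicate marking are out of scope here):
# chrom1 start1 end1 chrom2 start2 end2 mapq1 mapq2 duplicate ligation_class


def read_pets(path) -> list[PETRecord]:
    records: list[PETRecord] = []
    with _open_read(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 10:
                raise ValueError(
                    f"line {lineno}: expected 10 columns "
                    "(chrom1 start1 end1 chrom2 start2 end2 mapq1 mapq2 "
                    f"duplicate ligation_class), got {len(fields)}"
                )
            end1 = _interval(fields[0], fields[1], fields[2], lineno)
            end2 = _interval(fields[3], fields[4], fields[5], lineno)
            mapq1 = _parse(fields[6], lineno, "mapq1", int)
            mapq2 = _parse(fields[7], lineno, "mapq2", int)
            dup = _parse(fields[8], lineno, "duplicate flag", int)
            try:
                records.append(
                    PETRecord(end1, end2, mapq1, mapq2, bool(dup), fields[9])
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return records


def write_pets(pets: Iterable[PETRecord], path) -> None:
    with _open_write(path) as fh:
        for r in pets:
            fh.write(
                "\t".join(
                    [
                        r.end1.chrom,
                        str(r.end1.start),
                        str(r.end1.end),
                        r.end2.chrom,
                        str(r.end2.start),
                        str(r.end2.end),
                        str(r.mapq1),
                        str(r.mapq2),
                        str(int(r.duplicate)),
                        r.ligation_class,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# verified contacts (BEDPE + source tag in column 7)


def read_contacts(path) -> list[VerifiedContact]:
    contacts: list[VerifiedContact] = []
    with _open_read(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) < 6:
                raise ValueError(
                    f"line {lineno}: expected >=6 tab-separated columns, got {len(fields)}"
                )
            region_a = _interval(fields[0], fields[1], fields[2], lineno)
            region_b = _interval(fields[3], fields[4], fields[5], lineno)
            source = fields[6] if len(fields) >= 7 and fields[6] not in _MISSING else "eqtl"
            try:
                contacts.append(VerifiedContact(region_a, region_b, source))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return contacts


def write_contacts(contacts: Iterable[VerifiedContact], path) -> None:
    with _open_write(path) as fh:
        for c in contacts:
            fh.write(
                "\t".join(
                    [
                        c.region_a.chrom,
                        str(c.region_a.start),
                        str(c.region_a.end),
                        c.region_b.chrom,
                        str(c.region_b.start),
                        str(c.region_b.end),
                        c.source,
                    ]
                )
                + "\n"
            )
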