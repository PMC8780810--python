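"""Core genomic data model for chromatin-loop evaluation.

All coordinates are 0-based, half-open ``[start, end)``, following the
BED/BEDPE convention.  The central objects are:

``GenomicInterval``
    one genomic region (a loop anchor, a ChIP-seq peak, an annotation
    element).

``Loop``
    a chromatin contact: an ordered pair of anchors plus a paired-end-tag
    (PET) count and optional significance fields, as emitted by ChIA-PET
    and HiChIP loop callers.

``PETRecord``
    a single paired-end tag with per-end mapping quality, a duplicate flag
    and its ligation class (inter-ligation PETs are the informative ones;
    self-ligation products arise from a fragment circularising on itself
    and are removed by a genomic-span cutoff).

``PETTrack``
    sorted per-chromosome PET end positions supporting fast range counts,
    the primitive behind enrichment-score flanking windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Loop",
    "LoopSet",
    "LoopIndex",
    "PETRecord",
    "PETTrack",
    "PeakSet",
    "ChromSizes",
    "classify_ligation",
    "merge_intervals",
    "union_merge",
    "overlap_length",
    "DEFAULT_SELF_LIGATION_CUTOFF",
    "LIGATION_CLASSES",
]

LIGATION_CLASSES = frozenset({"inter_ligation", "self_ligation", "invalid"})

#: Default genomic-span cutoff (bp) below which a same-chromosome PET is
#: treated as a self-ligation product.  Published pipelines use values
#: between 5 and 12 kb; 8 kb sits in the middle of that range.
DEFAULT_SELF_LIGATION_CUTOFF = 8000


def overlap_length(start1: int, end1: int, start2: int, end2: int) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(end1, end2) - max(start1, start2))


@dataclass(frozen=True)
class GenomicInterval:
    """A non-empty 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"negative start in interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return overlap_length(self.start, self.end, other.start, other.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Loop:
    """A chromatin contact between two anchors.

    Anchors are normalised into genome order (chromosome name, then start,
    then end) on construction, so ``anchor1`` always precedes ``anchor2``.
    ``pet_count`` is the number of supporting PETs; ``p_value`` and ``fdr``
    are caller-reported significances and may be absent.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int | None = None
    p_value: float | None = None
    fdr: float | None = None

    def __post_init__(self) -> None:
        if self.anchor2.key() < self.anchor1.key():
            a1, a2 = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)
        if self.pet_count is not None and self.pet_count < 0:
            raise ValueError(f"negative pet_count {self.pet_count}")
        for name in ("p_value", "fdr"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def is_intra(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def distance(self) -> float | None:
        """Inter-anchor distance: midpoint-to-midpoint, bp.

        ``None`` for inter-chromosomal loops, which carry no distance.
        """
        if not self.is_intra:
            return None
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)

    def key(self) -> tuple:
        return (*self.anchor1.key(), *self.anchor2.key())


@dataclass
class LoopSet:
    """An ordered collection of loops from one method/dataset."""

    loops: list[Loop] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self) -> Iterator[Loop]:
        return iter(self.loops)

    def __getitem__(self, i):
        return self.loops[i]

    def dedup(self) -> "LoopSet":
        """Drop exact duplicate (anchor1, anchor2) pairs, keeping first occurrence."""
        seen: set[tuple] = set()
        out = []
        for lp in self.loops:
            k = lp.key()
            if k not in seen:
                seen.add(k)
                out.append(lp)
        return LoopSet(out, label=self.label)

    def anchors(self) -> list[GenomicInterval]:
        out = []
        for lp in self.loops:
            out.append(lp.anchor1)
            out.append(lp.anchor2)
        return out

    def intra(self) -> "LoopSet":
        return LoopSet([lp for lp in self.loops if lp.is_intra], label=self.label)


@dataclass(frozen=True)
class PETRecord:
    """One paired-end tag: two mapped ends plus quality/validity flags."""

    end1: GenomicInterval
    end2: GenomicInterval
    mapq1: int
    mapq2: int
    duplicate: bool = False
    ligation_class: str = "inter_ligation"

    def __post_init__(self) -> None:
        if self.mapq1 < 0 or self.mapq2 < 0:
            raise ValueError("MAPQ must be non-negative")
        if self.ligation_class not in LIGATION_CLASSES:
            raise ValueError(
                f"unknown ligation class {self.ligation_class!r}; "
                f"expected one of {sorted(LIGATION_CLASSES)}"
            )

    @property
    def span(self) -> int | None:
        """Genomic span between the two ends (same chromosome only)."""
        if self.end1.chrom != self.end2.chrom:
            return None
        lo = min(self.end1.start, self.end2.start)
        hi = max(self.end1.end, self.end2.end)
        return hi - lo


def classify_ligation(
    end1: GenomicInterval,
    end2: GenomicInterval,
    cutoff: int = DEFAULT_SELF_LIGATION_CUTOFF,
) -> str:
    """Classify a PET by its span: self-ligation below ``cutoff``, else inter-ligation.

    Ends on different chromosomes are always inter-ligation.  Mapping
    failures ("invalid") cannot be inferred from coordinates and must be
    flagged upstream.
    """
    if end1.chrom != end2.chrom:
        return "inter_ligation"
    span = max(end1.end, end2.end) - min(end1.start, end2.start)
    return "self_ligation" if span < cutoff else "inter_ligation"


class PETTrack:
    """Sorted PET end positions per chromosome, supporting range counts.

    ``count(chrom, start, end)`` returns the number of recorded positions in
    ``[start, end)`` via binary search and equals a linear scan over the raw
    positions.
    """

    def __init__(
        self,
        positions: Mapping[str, Sequence[float]],
        sizes: "ChromSizes | None" = None,
    ) -> None:
        self._pos: dict[str, np.ndarray] = {
            chrom: np.sort(np.asarray(p, dtype=float))
            for chrom, p in positions.items()
        }
        self.sizes = sizes

    @classmethod
    def from_pet_records(
        cls, pets: Iterable[PETRecord], sizes: "ChromSizes | None" = None
    ) -> "PETTrack":
        """Build a track from both end midpoints of each PET."""
        acc: dict[str, list[float]] = {}
        for r in pets:
            for e in (r.end1, r.end2):
                acc.setdefault(e.chrom, []).append(e.midpoint)
        return cls(acc, sizes=sizes)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], sizes: "ChromSizes | None" = None
    ) -> "PETTrack":
        """Build a track from interval midpoints (e.g. 1-D ChIP-seq reads)."""
        acc: dict[str, list[float]] = {}
        for iv in intervals:
            acc.setdefault(iv.chrom, []).append(iv.midpoint)
        return cls(acc, sizes=sizes)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def count(self, chrom: str, start: float, end: float) -> int:
        if end <= start:
            return 0
        pos = self._pos.get(chrom)
        if pos is None or pos.size == 0:
            return 0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(hi - lo)

    def n_on(self, chrom: str) -> int:
        pos = self._pos.get(chrom)
        return 0 if pos is None else int(pos.size)

    @property
    def total(self) -> int:
        return sum(p.size for p in self._pos.values())

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0))


@dataclass
class PeakSet:
    """A 1-D interval collection (ChIP-seq peaks, annotation elements)."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    scores: list[float | None] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.scores is not None and len(self.scores) != len(self.intervals):
            raise ValueError("scores length does not match intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per chromosome: (starts, ends, original indices), sorted by (start, index)."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[tuple[int, int, int]]] = {}
        for idx, iv in enumerate(self.intervals):
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
        for chrom, rows in grouped.items():
            rows.sort(key=lambda r: (r[0], r[2]))
            arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
            out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return out


@dataclass
class ChromSizes:
    """Chromosome name -> length (bp).  Genome length G is the sum."""

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"non-positive length {length} for {chrom}")

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __len__(self) -> int:
        return len(self.sizes)

    def items(self):
        return self.sizes.items()

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    @property
    def genome_length(self) -> int:
        return sum(self.sizes.values())


# ---------------------------------------------------------------------------
# interval merging


def _qualifies(
    s1: int, e1: int, s2: int, e2: int, frac: float, reciprocal: bool
) -> bool:
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return False
    c1 = ov >= frac * (e1 - s1)
    c2 = ov >= frac * (e2 - s2)
    return (c1 and c2) if reciprocal else (c1 or c2)


def merge_intervals(
    intervals: Iterable[GenomicInterval],
    min_reciprocal_overlap: float = 0.9,
    reciprocal: bool = True,
) -> list[GenomicInterval]:
    """Merge intervals whose mutual overlap reaches a length fraction.

    Two intervals qualify for merging when their overlap is at least
    ``min_reciprocal_overlap`` times the length of *each* of them
    (``reciprocal=True``, the default, reading "overlapped with each other"
    as symmetric) or of *either* of them (``reciprocal=False``).  Merging
    replaces every connected component of the qualifying-pair graph by the
    union (span) of its members, and the closure is iterated until no pair
    qualifies, so the result is idempotent and independent of input order.

    With ``min_reciprocal_overlap=0`` any 1-bp overlap qualifies and the
    result is the plain interval union.
    """
    frac = float(min_reciprocal_overlap)
    if not 0 <= frac <= 1:
        raise ValueError(f"overlap fraction {frac} outside [0, 1]")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        while True:
            merged = _merge_pass(items, frac, reciprocal)
            if merged == items:
                break
            items = merged
        out.extend(GenomicInterval(chrom, s, e) for s, e in items)
    return out


def _merge_pass(
    items: list[tuple[int, int]], frac: float, reciprocal: bool
) -> list[tuple[int, int]]:
    """One closure step: union each connected component of qualifying pairs."""
    n = len(items)
    if n < 2:
        return list(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # items sorted by start: a sweep bounded by the running max end finds
    # every overlapping pair without the full O(n^2) comparison
    for i in range(n):
        si, ei = items[i]
        for j in range(i + 1, n):
            sj, ej = items[j]
            if sj >= ei:
                break
            if _qualifies(si, ei, sj, ej, frac, reciprocal):
                parent[find(i)] = find(j)
        # note: pairs (i, j) with sj >= ei cannot overlap, so breaking is safe
    comp: dict[int, tuple[int, int]] = {}
    for i in range(n):
        r = find(i)
        s, e = items[i]
        if r in comp:
            cs, ce = comp[r]
            comp[r] = (min(cs, s), max(ce, e))
        else:
            comp[r] = (s, e)
    return sorted(comp.values())


def union_merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Plain interval union: merge any overlapping or touching intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        cur_s: int | None = None
        cur_e = 0
        for s, e in sorted(by_chrom[chrom]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


class LoopIndex:
    """Both-anchor overlap queries against a fixed loop set.

    A query loop "intersects" an indexed loop when anchor1 overlaps anchor1
    and anchor2 overlaps anchor2 (anchors are already genome-ordered on
    construction, so a single orientation suffices).  With
    ``min_overlap_fraction > 0`` each anchor pair must additionally overlap
    reciprocally by that fraction of both anchor lengths.
    """

    def __init__(self, loops: LoopSet | Iterable[Loop]) -> None:
        self._groups: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        grouped: dict[tuple[str, str], list[tuple[int, int, int, int]]] = {}
        for lp in loops:
            key = (lp.anchor1.chrom, lp.anchor2.chrom)
            grouped.setdefault(key, []).append(
                (lp.anchor1.start, lp.anchor1.end, lp.anchor2.start, lp.anchor2.end)
            )
        for key, rows in grouped.items():
            arr = np.asarray(rows, dtype=np.int64).reshape(-1, 4)
            self._groups[key] = {
                "s1": arr[:, 0],
                "e1": arr[:, 1],
                "s2": arr[:, 2],
                "e2": arr[:, 3],
            }

    def match_count(self, loop: Loop, min_overlap_fraction: float = 0.0) -> int:
        g = self._groups.get((loop.anchor1.chrom, loop.anchor2.chrom))
        if g is None:
            return 0
        ov1 = np.minimum(g["e1"], loop.anchor1.end) - np.maximum(
            g["s1"], loop.anchor1.start
        )
        ov2 = np.minimum(g["e2"], loop.anchor2.end) - np.maximum(
            g["s2"], loop.anchor2.start
        )
        if min_overlap_fraction <= 0:
            hit = (ov1 > 0) & (ov2 > 0)
        else:
            f = min_overlap_fraction
            hit = (
                (ov1 >= f * (g["e1"] - g["s1"]))
                & (ov1 >= f * loop.anchor1.length)
                & (ov2 >= f * (g["e2"] - g["s2"]))
                & (ov2 >= f * loop.anchor2.length)
                & (ov1 > 0)
                & (ov2 > 0)
            )
        return int(hit.sum())

    def intersects(self, loop: Loop, min_overlap_fraction: float = 0.0) -> bool:
        return self.match_count(loop, min_overlap_fraction) > 0
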