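"""Evaluation metrics for ChIA-PET / HiChIP loop calls.

The suite covers the whole benchmarking flow:

* ``uv_rate`` — pre-processing quality: fraction of PETs that are uniquely
  mapped (both ends MAPQ-passing), non-duplicate and valid (inter-ligation).
* ``peak_co_occupancy`` — anchor reliability of peak-based callers against
  ChIP-seq peaks.
* ``enrichment_score`` / ``global_es`` — anchor reliability of cluster-based
  callers: a loop's PET count against the PET count of its flanking windows,
  with a chromosome-coverage correction for the genome-wide aggregate.
* ``accuracy`` — loop accuracy against a gold-standard true set and matched
  sampled false sets (FP/TN averaged over the false-set replicates).
* ``filter_significant`` / ``activation_rate`` — functional evaluation of
  significant loops via enhancer/promoter annotation and active versus
  repressive histone-mark overlap.
* ``resolution_levels`` — distribution of inter-anchor distances over the
  <=10 kb, 10-100 kb and 100 kb-1 Mb bins.
* ``scale_scores`` — min-max rescaling of per-method scores to [0, 1] for
  cross-method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    ChromSizes,
    GenomicInterval,
    Loop,
    LoopIndex,
    LoopSet,
    PeakSet,
    PETRecord,
    PETTrack,
    union_merge,
)

__all__ = [
    "ConfusionCounts",
    "ESReport",
    "ARReport",
    "PCResult",
    "ResolutionLevels",
    "uv_rate",
    "peak_co_occupancy",
    "enrichment_score",
    "es_table",
    "global_es",
    "accuracy",
    "scale_scores",
    "filter_significant",
    "activation_rate",
    "resolution_levels",
    "PET_COUNT_MIN",
]

#: Minimum supporting PET count for a significant loop, per protocol.
PET_COUNT_MIN = {"chiapet": 3, "hichip": 8}


# ---------------------------------------------------------------------------
# UV Rate


def uv_rate(pets: Sequence[PETRecord] | Iterable[PETRecord], mapq_min: int = 30) -> float:
    """Fraction of PETs that are uniquely mapped, non-duplicate and valid.

    A PET counts as Uniquely mapped Valid (UV) when both end MAPQs reach
    ``mapq_min`` (default 30), it is not a duplicate, and its ligation class
    is inter-ligation.  The rate is the number of UV PETs divided by the
    number of all PETs; an empty collection leaves the ratio undefined and
    raises ``ValueError``.
    """
    pets = list(pets)
    if not pets:
        raise ValueError("UV Rate is undefined for an empty PET collection")
    n_uv = sum(
        1
        for r in pets
        if r.mapq1 >= mapq_min
        and r.mapq2 >= mapq_min
        and not r.duplicate
        and r.ligation_class == "inter_ligation"
    )
    return n_uv / len(pets)


# ---------------------------------------------------------------------------
# Peak co-occupancy


class PCResult(NamedTuple):
    value: float
    mode: str
    table: pd.DataFrame


def peak_co_occupancy(
    anchors: Sequence[GenomicInterval],
    peaks: PeakSet,
    mode: str = "normalized",
) -> PCResult:
    """Peak co-occupancy (PC) between loop anchors and ChIP-seq peaks.

    Every anchor with at least 1 bp of ChIP-seq peak overlap enters the
    candidate set A (|A| = N_A out of N anchors).  For anchor i the peak
    with the longest overlap is selected (ties broken by leftmost peak
    start, then input order) and contributes

        term_i = max( L(o_i)/L(p_i), L(o_i)/L(a_i) )

    where L(o_i), L(p_i), L(a_i) are the overlap, peak and anchor lengths;
    anchors outside A contribute 0.

    ``mode="literal"`` returns ``N_A * sum(term_i) / N`` — the printed
    formula, which can exceed 1.  ``mode="normalized"`` (default) returns
    ``sum(term_i) / N``, a bounded co-occupancy fraction.

    Anchors are expected to be pre-merged (90% reciprocal overlap) by the
    caller; the CLI pipeline does this before calling in here.
    """
    if mode not in ("literal", "normalized"):
        raise ValueError(f"unknown PC mode {mode!r}")
    anchors = list(anchors)
    if not anchors:
        raise ValueError("PC is undefined for an empty anchor set")

    peak_index = peaks.by_chrom() if len(peaks) else {}
    rows = []
    for a in anchors:
        best_ov = 0
        best_peak: tuple[int, int] | None = None
        grp = peak_index.get(a.chrom)
        if grp is not None:
            starts, ends, _idx = grp
            ov = np.minimum(ends, a.end) - np.maximum(starts, a.start)
            ov = np.clip(ov, 0, None)
            k = int(np.argmax(ov))  # first max => leftmost start wins ties
            if ov[k] > 0:
                best_ov = int(ov[k])
                best_peak = (int(starts[k]), int(ends[k]))
        if best_peak is None:
            rows.append((a.chrom, a.start, a.end, -1, -1, 0, 0.0))
        else:
            term = max(best_ov / (best_peak[1] - best_peak[0]), best_ov / a.length)
            rows.append((a.chrom, a.start, a.end, *best_peak, best_ov, term))
    table = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "peak_start",
            "peak_end",
            "overlap",
            "term",
        ],
    )
    n = len(anchors)
    n_a = int((table["overlap"] > 0).sum())
    total = float(table["term"].sum())
    value = (n_a * total / n) if mode == "literal" else (total / n)
    return PCResult(value=value, mode=mode, table=table)


# ---------------------------------------------------------------------------
# Enrichment score


def _clip_window(start: float, end: float, chrom: str, sizes: ChromSizes | None):
    lo = max(0.0, start)
    hi = end
    if sizes is not None and chrom in sizes:
        hi = min(hi, sizes[chrom])
    return lo, hi


def _neighbor_count(loop: Loop, track: PETTrack) -> int:
    """PET count of the flanking windows, the denominator of the ES.

    The four windows are the flanks of mean anchor length l_m on each side
    of each anchor: [s1-l_m, s1), [e1, e1+l_m), [s2-l_m, s2), [e2, e2+l_m),
    clipped at chromosome bounds.  The neighbour count is the smaller of
    the two per-anchor flank sums.
    """
    a1, a2 = loop.anchor1, loop.anchor2
    l_m = 0.5 * (a1.length + a2.length)
    sizes = track.sizes

    def wcount(chrom: str, start: float, end: float) -> int:
        lo, hi = _clip_window(start, end, chrom, sizes)
        return track.count(chrom, lo, hi)

    left = wcount(a1.chrom, a1.start - l_m, a1.start) + wcount(
        a1.chrom, a1.end, a1.end + l_m
    )
    right = wcount(a2.chrom, a2.start - l_m, a2.start) + wcount(
        a2.chrom, a2.end, a2.end + l_m
    )
    return min(left, right)


def enrichment_score(loop: Loop, track: PETTrack) -> float:
    """Per-loop enrichment score ES_i = C_i / P_n_i.

    C_i is the loop's PET count and P_n_i the flanking-window neighbour
    count (see :func:`_neighbor_count`); a zero neighbour count is replaced
    by 1 to keep the ratio defined.  ES_i < 1 means the flanks are more
    enriched than the anchors themselves, flagging an invalid loop.
    """
    if loop.pet_count is None:
        raise ValueError("enrichment score requires a PET count on the loop")
    p_n = _neighbor_count(loop, track)
    return loop.pet_count / max(p_n, 1)


def es_table(loops: LoopSet | Iterable[Loop], track: PETTrack) -> pd.DataFrame:
    """Per-loop ES components: chrom, pet_count, neighbour count, ES."""
    rows = []
    for lp in loops:
        if lp.pet_count is None:
            raise ValueError("enrichment score requires a PET count on every loop")
        p_n = _neighbor_count(lp, track)
        rows.append(
            (
                lp.anchor1.chrom,
                lp.pet_count,
                p_n,
                lp.pet_count / max(p_n, 1),
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "pet_count", "p_n", "es"])


@dataclass
class ESReport:
    """Per-loop, per-chromosome and genome-aggregate enrichment scores."""

    per_loop: pd.DataFrame
    per_chrom: pd.DataFrame
    es_global: float
    genome_coverage: float


def global_es(
    loops: LoopSet,
    track: PETTrack,
    sizes: ChromSizes,
    pet_length: float,
    n_pets: int | None = None,
) -> ESReport:
    """Genome-wide enrichment score with chromosome-coverage correction.

    Uneven sequencing depth across chromosomes would otherwise distort the
    aggregate, so each chromosome's ratio sum(C_i)/sum(P_n_i) is multiplied
    by alpha_j = C / C_j, where C = L*N/G is the genome-wide PET coverage
    (PET length L, N PETs, genome length G) and C_j the same quantity on
    chromosome j.  Chromosome scores are combined into the genome aggregate
    with PET-count weights w_j = sum_j(C_i) / sum_all(C_i).

    ``n_pets`` defaults to the number of positions in ``track`` (one per
    recorded PET end); pass the PET count explicitly when the track holds
    both ends of each PET.
    """
    per_loop = es_table(loops, track)
    if n_pets is None:
        n_pets = track.total
    g = sizes.genome_length
    cov_genome = pet_length * n_pets / g

    rows = []
    for chrom, sub in per_loop.groupby("chrom", sort=True):
        n_j = track.n_on(chrom)
        if n_j == 0:
            raise ValueError(
                f"chromosome {chrom} carries loops but has zero PET coverage"
            )
        if chrom not in sizes:
            raise ValueError(f"chromosome {chrom} missing from chrom sizes")
        # track positions are on the same footing as n_pets (see docstring)
        cov_j = pet_length * n_j * (n_pets / track.total) / sizes[chrom]
        alpha = cov_genome / cov_j
        sum_c = int(sub["pet_count"].sum())
        sum_pn = int(np.maximum(sub["p_n"], 1).sum())
        rows.append((chrom, sum_c, sum_pn, cov_j, alpha, sum_c / sum_pn * alpha))
    per_chrom = pd.DataFrame(
        rows, columns=["chrom", "sum_c", "sum_pn", "coverage", "alpha", "es"]
    )
    total_c = per_chrom["sum_c"].sum()
    if total_c > 0:
        per_chrom["weight"] = per_chrom["sum_c"] / total_c
        es_g = float((per_chrom["weight"] * per_chrom["es"]).sum())
    else:
        per_chrom["weight"] = 0.0
        es_g = 0.0
    return ESReport(
        per_loop=per_loop,
        per_chrom=per_chrom,
        es_global=es_g,
        genome_coverage=cov_genome,
    )


# ---------------------------------------------------------------------------
# Accuracy


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN counts; FP and TN may be means over false-set replicates."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name}")

    @property
    def acc(self) -> float:
        denom = self.tp + self.tn + self.fp + self.fn
        if denom <= 0:
            raise ValueError("accuracy undefined: TP+TN+FP+FN is zero")
        return (self.tp + self.tn) / denom

    def to_dict(self) -> dict[str, float]:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn, "acc": self.acc}


def accuracy(
    detected: LoopSet,
    truth: LoopSet,
    false_sets: Sequence[LoopSet],
    min_overlap_fraction: float = 0.0,
) -> ConfusionCounts:
    """Loop accuracy against a gold-standard set and sampled false sets.

    A detected loop intersects a reference loop when both anchor pairs
    overlap by at least 1 bp (anchors genome-ordered; raise
    ``min_overlap_fraction`` to require reciprocal-fraction overlap
    instead).  TP counts detected loops intersecting the truth, FN truth
    loops missed by every detected loop; for each false-set replicate k,
    FP_k counts detected loops intersecting it and TN_k its loops missed by
    every detected loop.  FP and TN are the means over replicates and

        ACC = (TP + TN) / (TP + TN + FP + FN).
    """
    if len(truth) == 0:
        raise ValueError("gold-standard (truth) loop set is empty")
    if not false_sets:
        raise ValueError("at least one false loop set is required")

    truth_idx = LoopIndex(truth)
    det_idx = LoopIndex(detected)
    f = min_overlap_fraction
    tp = sum(1 for lp in detected if truth_idx.intersects(lp, f))
    fn = sum(1 for t in truth if not det_idx.intersects(t, f))
    fps, tns = [], []
    for fs in false_sets:
        fs_idx = LoopIndex(fs)
        fps.append(sum(1 for lp in detected if fs_idx.intersects(lp, f)))
        tns.append(sum(1 for fl in fs if not det_idx.intersects(fl, f)))
    return ConfusionCounts(
        tp=float(tp),
        fp=float(np.mean(fps)),
        tn=float(np.mean(tns)),
        fn=float(fn),
    )


# ---------------------------------------------------------------------------
# Score rescaling


def scale_scores(values):
    """Min-max rescale per-method scores to [0, 1].

    Accepts a mapping (method -> score) or a sequence and returns the same
    shape.  All-equal input rescales to all 1.0 (every method equally
    best).  Fewer than two values, or any non-finite value, is an error.
    """
    keys = None
    if isinstance(values, Mapping):
        keys = list(values)
        arr = np.asarray([values[k] for k in keys], dtype=float)
    else:
        arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("rescaling needs at least two scores")
    if not np.all(np.isfinite(arr)):
        raise ValueError("rescaling requires finite scores")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        scaled = np.ones_like(arr)
    else:
        scaled = (arr - lo) / (hi - lo)
    if keys is not None:
        return {k: float(s) for k, s in zip(keys, scaled)}
    return scaled


# ---------------------------------------------------------------------------
# Significant-loop pre-filter


def filter_significant(
    loops: LoopSet,
    protocol: str,
    p_max: float = 0.05,
    fdr_max: float = 0.05,
    pet_min: int | None = None,
) -> LoopSet:
    """Keep statistically significant loops per the protocol thresholds.

    ChIA-PET loops need at least 3 supporting PETs, HiChIP loops at least 8
    (override with ``pet_min``).  When a loop carries a p-value or FDR the
    corresponding threshold (default 0.05 each) applies as well; absent
    fields pass, since not every caller reports them.
    """
    if pet_min is None:
        try:
            pet_min = PET_COUNT_MIN[protocol]
        except KeyError:
            raise ValueError(
                f"unknown protocol {protocol!r}; expected one of {sorted(PET_COUNT_MIN)}"
            ) from None
    kept = []
    for lp in loops:
        if lp.pet_count is None:
            raise ValueError("significance filtering requires a PET count on every loop")
        if lp.pet_count < pet_min:
            continue
        if lp.p_value is not None and lp.p_value > p_max:
            continue
        if lp.fdr is not None and lp.fdr > fdr_max:
            continue
        kept.append(lp)
    return LoopSet(kept, label=loopset_label(loops, "significant"))


def loopset_label(loops: LoopSet, suffix: str) -> str:
    return f"{loops.label}|{suffix}" if loops.label else suffix


# ---------------------------------------------------------------------------
# Activation rate


@dataclass
class ARReport:
    """Activation-rate summary over enhancer/promoter-annotated loops."""

    n_active: int = 0
    n_inactive: int = 0
    n_other: int = 0
    n_ee: int = 0
    n_ep: int = 0
    n_pp: int = 0
    n_partial: int = 0  # exactly one anchor annotated
    n_unannotated: int = 0  # excluded from classification
    loop_classes: list[str] = field(default_factory=list)
    loop_states: list[str] = field(default_factory=list)

    @property
    def n_classified(self) -> int:
        return self.n_active + self.n_inactive + self.n_other

    @property
    def activation_rate(self) -> float:
        if self.n_classified == 0:
            raise ValueError("no annotated loops to classify")
        return self.n_active / self.n_classified


def _merged_arrays(peaksets: Iterable[PeakSet]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = union_merge(iv for ps in peaksets for iv in ps)
    out: dict[str, list[list[int]]] = {}
    for iv in merged:
        out.setdefault(iv.chrom, [[], []])
        out[iv.chrom][0].append(iv.start)
        out[iv.chrom][1].append(iv.end)
    return {
        chrom: (np.asarray(se[0], dtype=np.int64), np.asarray(se[1], dtype=np.int64))
        for chrom, se in out.items()
    }


def _overlap_total(
    iv: GenomicInterval, arrays: dict[str, tuple[np.ndarray, np.ndarray]]
) -> int:
    grp = arrays.get(iv.chrom)
    if grp is None:
        return 0
    starts, ends = grp
    ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
    return int(np.clip(ov, 0, None).sum())


def activation_rate(
    loops: LoopSet,
    enhancers: PeakSet,
    promoters: PeakSet,
    active_marks: Sequence[PeakSet],
    repressive_marks: Sequence[PeakSet],
    combine: str = "union",
) -> ARReport:
    """Classify significant loops as active / inactive / other.

    Each anchor is labelled E when it overlaps an enhancer-like element by
    at least 1 bp and P when it overlaps a promoter-like element (when both
    apply the promoter label wins, promoter-like signatures being the more
    specific annotation); loops with neither anchor labelled are excluded
    from classification.  For every retained loop the total overlap of both
    anchors with the active-mark peaks (H3K27ac/H3K4me1/H3K4me3-type) is
    compared with the repressive-mark overlap (H3K27me3-type): larger
    active overlap means active, larger repressive overlap inactive, and a
    tie — including no overlap with either — means other.  The activation
    rate AR is the fraction of retained loops classified active.

    ``combine="union"`` (default) measures overlap against the union of the
    mark peak sets; ``combine="sum"`` totals each mark set separately.
    """
    if combine not in ("union", "sum"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if combine == "union":
        active_arrays = [_merged_arrays(active_marks)]
        repressive_arrays = [_merged_arrays(repressive_marks)]
    else:
        active_arrays = [_merged_arrays([ps]) for ps in active_marks]
        repressive_arrays = [_merged_arrays([ps]) for ps in repressive_marks]
    enh = _merged_arrays([enhancers])
    prom = _merged_arrays([promoters])

    def anchor_label(a: GenomicInterval) -> str | None:
        if _overlap_total(a, prom) > 0:
            return "P"
        if _overlap_total(a, enh) > 0:
            return "E"
        return None

    report = ARReport()
    for lp in loops:
        l1 = anchor_label(lp.anchor1)
        l2 = anchor_label(lp.anchor2)
        if l1 is None and l2 is None:
            report.n_unannotated += 1
            continue
        if l1 is not None and l2 is not None:
            cls = "-".join(sorted((l1, l2)))  # E-E, E-P, P-P
            if cls == "E-E":
                report.n_ee += 1
            elif cls == "E-P":
                report.n_ep += 1
            else:
                report.n_pp += 1
        else:
            cls = "partial"
            report.n_partial += 1
        active_len = sum(
            _overlap_total(lp.anchor1, arr) + _overlap_total(lp.anchor2, arr)
            for arr in active_arrays
        )
        repressive_len = sum(
            _overlap_total(lp.anchor1, arr) + _overlap_total(lp.anchor2, arr)
            for arr in repressive_arrays
        )
        if active_len > repressive_len:
            state = "active"
            report.n_active += 1
        elif repressive_len > active_len:
            state = "inactive"
            report.n_inactive += 1
        else:
            state = "other"
            report.n_other += 1
        report.loop_classes.append(cls)
        report.loop_states.append(state)
    if report.n_classified == 0:
        raise ValueError("no loops with enhancer/promoter-annotated anchors")
    return report


# ---------------------------------------------------------------------------
# Resolution levels


class ResolutionLevels(NamedTuple):
    le_10kb: float
    from_10kb_to_100kb: float
    from_100kb_to_1mb: float


def resolution_levels(loops: LoopSet) -> ResolutionLevels:
    """Fractions of loops across the three inter-anchor distance bins.

    Distances are midpoint-to-midpoint; the bins are d <= 10 kb,
    10 kb < d <= 100 kb and 100 kb < d <= 1 Mb (boundaries inclusive on the
    right).  Inter-chromosomal loops and loops beyond 1 Mb fall in no bin;
    the fractions are over binned loops and sum to 1.
    """
    counts = [0, 0, 0]
    for lp in loops:
        d = lp.distance
        if d is None or d > 1_000_000:
            continue
        if d <= 10_000:
            counts[0] += 1
        elif d <= 100_000:
            counts[1] += 1
        else:
            counts[2] += 1
    total = sum(counts)
    if total == 0:
        raise ValueError("no loops within the 1 Mb resolution range")
    return ResolutionLevels(*(c / total for c in counts))
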