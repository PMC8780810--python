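"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — O(n^2) pairwise scans, per-basepair
set arithmetic, linear recounts — and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

from loopbench.core import GenomicInterval, Loop


# ---------------------------------------------------------------------------
# interval merging: pairwise fixpoint of the qualifying-pair closure


def _pair_qualifies(a, b, frac, reciprocal):
    if a[0] != b[0]:
        return False
    ov = min(a[2], b[2]) - max(a[1], b[1])
    if ov <= 0:
        return False
    c1 = ov >= frac * (a[2] - a[1])
    c2 = ov >= frac * (b[2] - b[1])
    return (c1 and c2) if reciprocal else (c1 or c2)


def oracle_merge(intervals, frac, reciprocal=True):
    """Closure semantics: union connected components of qualifying pairs, repeat."""
    items = sorted((iv.chrom, iv.start, iv.end) for iv in intervals)
    while True:
        # connected components via repeated pairwise absorption
        changed = False
        merged = []
        used = [False] * len(items)
        for i in range(len(items)):
            if used[i]:
                continue
            comp = [items[i]]
            used[i] = True
            grew = True
            while grew:
                grew = False
                for j in range(len(items)):
                    if used[j]:
                        continue
                    if any(_pair_qualifies(c, items[j], frac, reciprocal) for c in comp):
                        comp.append(items[j])
                        used[j] = True
                        grew = True
            chrom = comp[0][0]
            merged.append(
                (chrom, min(c[1] for c in comp), max(c[2] for c in comp))
            )
            if len(comp) > 1:
                changed = True
        items = sorted(merged)
        if not changed:
            break
    return [GenomicInterval(*t) for t in items]


# ---------------------------------------------------------------------------
# UV Rate


def oracle_uv_rate(pets, mapq_min=30):
    total = 0
    uv = 0
    for r in pets:
        total += 1
        ok = (
            min(r.mapq1, r.mapq2) >= mapq_min
            and r.duplicate is False
            and r.ligation_class == "inter_ligation"
        )
        if ok:
            uv += 1
    return uv / total


# ---------------------------------------------------------------------------
# peak co-occupancy


def oracle_pc(anchors, peaks, mode):
    terms = []
    n_a = 0
    peak_list = list(peaks)
    for a in anchors:
        best = None  # (sort key, peak, overlap)
        for idx, p in enumerate(peak_list):
            if p.chrom != a.chrom:
                continue
            ov = min(a.end, p.end) - max(a.start, p.start)
            if ov <= 0:
                continue
            key = (-ov, p.start, idx)
            if best is None or key < best[0]:
                best = (key, p, ov)
        if best is None:
            terms.append(0.0)
        else:
            n_a += 1
            _, p, ov = best
            terms.append(max(ov / p.length, ov / a.length))
    n = len(anchors)
    total = sum(terms)
    return (n_a * total / n) if mode == "literal" else (total / n)


# ---------------------------------------------------------------------------
# enrichment score


def _window_count(positions_by_chrom, sizes, chrom, lo, hi):
    lo = max(0.0, lo)
    if sizes is not None and chrom in sizes:
        hi = min(hi, sizes[chrom])
    return sum(1 for x in positions_by_chrom.get(chrom, []) if lo <= x < hi)


def oracle_es(loop, positions_by_chrom, sizes=None):
    a1, a2 = loop.anchor1, loop.anchor2
    lm = (a1.length + a2.length) / 2
    left = _window_count(
        positions_by_chrom, sizes, a1.chrom, a1.start - lm, a1.start
    ) + _window_count(positions_by_chrom, sizes, a1.chrom, a1.end, a1.end + lm)
    right = _window_count(
        positions_by_chrom, sizes, a2.chrom, a2.start - lm, a2.start
    ) + _window_count(positions_by_chrom, sizes, a2.chrom, a2.end, a2.end + lm)
    p_n = min(left, right)
    return loop.pet_count / max(p_n, 1), p_n


def oracle_global_es(loops, positions_by_chrom, sizes, pet_length, n_pets):
    """Hand recomputation of per-chromosome coverages, alphas and the aggregate."""
    total_pos = sum(len(v) for v in positions_by_chrom.values())
    g = sum(length for _, length in sizes.items())
    cov = pet_length * n_pets / g
    per_chrom = {}
    for lp in loops:
        chrom = lp.anchor1.chrom
        es, p_n = oracle_es(lp, positions_by_chrom, sizes)
        c, pn_sum = per_chrom.get(chrom, (0, 0))
        per_chrom[chrom] = (c + lp.pet_count, pn_sum + max(p_n, 1))
    total_c = sum(c for c, _ in per_chrom.values())
    if total_c == 0:
        return 0.0
    agg = 0.0
    for chrom, (c, pn_sum) in per_chrom.items():
        n_j = len(positions_by_chrom.get(chrom, [])) * (n_pets / total_pos)
        cov_j = pet_length * n_j / sizes[chrom]
        alpha = cov / cov_j
        agg += (c / total_c) * (c / pn_sum) * alpha
    return agg


# ---------------------------------------------------------------------------
# accuracy


def _loops_intersect(x: Loop, y: Loop) -> bool:
    return (
        x.anchor1.chrom == y.anchor1.chrom
        and x.anchor2.chrom == y.anchor2.chrom
        and min(x.anchor1.end, y.anchor1.end) > max(x.anchor1.start, y.anchor1.start)
        and min(x.anchor2.end, y.anchor2.end) > max(x.anchor2.start, y.anchor2.start)
    )


def oracle_accuracy(detected, truth, false_sets):
    tp = sum(1 for d in detected if any(_loops_intersect(d, t) for t in truth))
    fn = sum(1 for t in truth if not any(_loops_intersect(d, t) for d in detected))
    fps, tns = [], []
    for fs in false_sets:
        fps.append(sum(1 for d in detected if any(_loops_intersect(d, f) for f in fs)))
        tns.append(sum(1 for f in fs if not any(_loops_intersect(d, f) for d in detected)))
    fp = sum(fps) / len(fps)
    tn = sum(tns) / len(tns)
    return tp, fp, tn, fn, (tp + tn) / (tp + tn + fp + fn)


# ---------------------------------------------------------------------------
# activation rate (per-basepair set arithmetic)


def _bp_overlap(anchor, intervals):
    covered = set()
    for iv in intervals:
        if iv.chrom != anchor.chrom:
            continue
        covered.update(range(max(iv.start, anchor.start), min(iv.end, anchor.end)))
    return len(covered)


def oracle_ar(loops, enhancers, promoters, active_sets, repressive_sets):
    active_all = [iv for ps in active_sets for iv in ps]
    repressive_all = [iv for ps in repressive_sets for iv in ps]
    n_active = n_inactive = n_other = 0
    states = []
    for lp in loops:
        labels = []
        for a in (lp.anchor1, lp.anchor2):
            if _bp_overlap(a, promoters) > 0:
                labels.append("P")
            elif _bp_overlap(a, enhancers) > 0:
                labels.append("E")
            else:
                labels.append(None)
        if labels[0] is None and labels[1] is None:
            states.append("unannotated")
            continue
        alen = _bp_overlap(lp.anchor1, active_all) + _bp_overlap(lp.anchor2, active_all)
        rlen = _bp_overlap(lp.anchor1, repressive_all) + _bp_overlap(
            lp.anchor2, repressive_all
        )
        if alen > rlen:
            n_active += 1
            states.append("active")
        elif rlen > alen:
            n_inactive += 1
            states.append("inactive")
        else:
            n_other += 1
            states.append("other")
    classified = n_active + n_inactive + n_other
    return n_active / classified, states


# ---------------------------------------------------------------------------
# resolution levels


def oracle_resolution(loops):
    bins = [0, 0, 0]
    for lp in loops:
        if lp.anchor1.chrom != lp.anchor2.chrom:
            continue
        d = abs(
            (lp.anchor2.start + lp.anchor2.end) / 2
            - (lp.anchor1.start + lp.anchor1.end) / 2
        )
        if d <= 10_000:
            bins[0] += 1
        elif d <= 100_000:
            bins[1] += 1
        elif d <= 1_000_000:
            bins[2] += 1
    total = sum(bins)
    return tuple(b / total for b in bins)


# ---------------------------------------------------------------------------
# threshold filters


def oracle_filter_significant(loops, pet_min, p_max, fdr_max):
    kept = []
    for lp in loops:
        if lp.pet_count < pet_min:
            continue
        if lp.p_value is not None and lp.p_value > p_max:
            continue
        if lp.fdr is not None and lp.fdr > fdr_max:
            continue
        kept.append(lp)
    return kept


def oracle_filter_strong(loops, fdr_max=0.01, min_count=5):
    kept = []
    for lp in loops:
        ok = True
        if lp.fdr is not None and lp.fdr > fdr_max:
            ok = False
        if lp.pet_count is not None and lp.pet_count < min_count:
            ok = False
        if ok:
            kept.append(lp)
    return kept
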