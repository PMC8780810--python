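"""Run configuration, metric orchestration and cross-method comparison.

``evaluate`` runs every metric the supplied inputs allow for one loop-call
set and writes a one-row TSV plus a JSON report; metrics whose inputs are
missing are reported as NA, never as 0 (a method that cannot be scored is
not a method that scored zero).  ``compare`` assembles per-method reports
over shared datasets into a ranked matrix with min-max-scaled columns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import io as lio
from .core import LoopSet, PETTrack, merge_intervals
from .goldstandard import ExclusionMask, build_false_sets
from .metrics import (
    accuracy,
    activation_rate,
    filter_significant,
    global_es,
    peak_co_occupancy,
    resolution_levels,
    scale_scores,
    uv_rate,
)

__all__ = ["RunConfig", "evaluate", "compare", "REPORT_COLUMNS", "METRIC_COLUMNS"]

log = logging.getLogger("loopbench")

REPORT_COLUMNS = [
    "label",
    "dataset",
    "protocol",
    "method_class",
    "n_loops",
    "n_significant",
    "uv_rate",
    "pc_literal",
    "pc_normalized",
    "es_global",
    "acc",
    "ar",
    "res_le10k",
    "res_10k_100k",
    "res_100k_1m",
]

#: Columns that are scores comparable across methods.
METRIC_COLUMNS = ["uv_rate", "pc_normalized", "es_global", "acc", "ar"]


@dataclass
class RunConfig:
    """Inputs and thresholds for one evaluation run.

    File paths may be omitted (None); each metric is computed only when its
    inputs are present.  Threshold defaults follow the published settings:
    MAPQ 30, PET count >= 3 (ChIA-PET) / >= 8 (HiChIP), p and FDR 0.05,
    90% reciprocal anchor merging, 8 kb self-ligation cutoff.
    """

    loops: str
    protocol: str = "chiapet"
    method_class: str = "peak"  # peak | cluster
    label: str = ""
    dataset: str = ""
    sizes: str | None = None
    peaks: str | None = None
    pets: str | None = None
    enhancers: str | None = None
    promoters: str | None = None
    active_marks: list[str] = field(default_factory=list)
    repressive_marks: list[str] = field(default_factory=list)
    truth: str | None = None
    false_sets: list[str] = field(default_factory=list)
    mask_beds: list[str] = field(default_factory=list)
    n_false_sets: int = 3
    mapq_min: int = 30
    pet_min: int | None = None
    p_max: float = 0.05
    fdr_max: float = 0.05
    merge_fraction: float = 0.9
    self_ligation_cutoff: int = 8000
    anchor_overlap_fraction: float = 0.0
    pet_length: float = 100.0
    seed: int = 0
    outdir: str = "loopbench-out"

    def __post_init__(self) -> None:
        if self.protocol not in ("chiapet", "hichip"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.method_class not in ("peak", "cluster"):
            raise ValueError(f"unknown method class {self.method_class!r}")
        if not 0 <= self.merge_fraction <= 1:
            raise ValueError("merge_fraction outside [0, 1]")
        if not 5000 <= self.self_ligation_cutoff <= 12000:
            raise ValueError("self_ligation_cutoff outside the documented 5-12 kb range")
        if not self.label:
            self.label = Path(self.loops).stem

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        missing = []
        for name in ("loops", "sizes", "peaks", "pets", "enhancers", "promoters", "truth"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                missing.append(f"{name}: {p}")
        for name in ("active_marks", "repressive_marks", "false_sets", "mask_beds"):
            for p in getattr(self, name):
                if not Path(p).exists():
                    missing.append(f"{name}: {p}")
        if missing:
            raise ValueError("missing input files: " + "; ".join(missing))


def evaluate(config: RunConfig) -> dict:
    """Run every metric the config's inputs allow and write the report.

    Pipeline: UV Rate (PETs supplied) -> anchor merging -> PC (peak-based,
    needs ChIP peaks) or global ES (cluster-based, needs PETs + sizes) ->
    significance pre-filter -> ACC (needs truth + false sets, the latter
    sampled from mask BEDs when not supplied) -> AR (needs annotations) ->
    resolution levels.  Returns the report dict; TSV and JSON land in
    ``config.outdir``.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {c: None for c in REPORT_COLUMNS}
    report.update(
        label=config.label,
        dataset=config.dataset or config.label,
        protocol=config.protocol,
        method_class=config.method_class,
    )

    loops = lio.read_bedpe(config.loops, label=config.label).dedup()
    report["n_loops"] = len(loops)
    log.info("loaded %d loops from %s", len(loops), config.loops)

    sizes = lio.read_chrom_sizes(config.sizes) if config.sizes else None

    pets = None
    if config.pets:
        pets = lio.read_pets(config.pets)
        report["uv_rate"] = uv_rate(pets, mapq_min=config.mapq_min)
        log.info("UV Rate %.4f over %d PETs", report["uv_rate"], len(pets))

    anchors = merge_intervals(loops.anchors(), config.merge_fraction)
    log.info("merged %d anchors into %d at %.0f%% reciprocal overlap",
             2 * len(loops), len(anchors), 100 * config.merge_fraction)

    if config.method_class == "peak" and config.peaks:
        peaks = lio.read_bed(config.peaks)
        report["pc_literal"] = peak_co_occupancy(anchors, peaks, mode="literal").value
        report["pc_normalized"] = peak_co_occupancy(
            anchors, peaks, mode="normalized"
        ).value
        log.info("PC literal %.4f, normalized %.4f",
                 report["pc_literal"], report["pc_normalized"])
    elif config.method_class == "cluster" and pets is not None and sizes is not None:
        track = PETTrack.from_pet_records(pets, sizes=sizes)
        es = global_es(loops, track, sizes, config.pet_length, n_pets=len(pets))
        report["es_global"] = es.es_global
        log.info("global ES %.4f", es.es_global)

    significant = filter_significant(
        loops,
        config.protocol,
        p_max=config.p_max,
        fdr_max=config.fdr_max,
        pet_min=config.pet_min,
    )
    report["n_significant"] = len(significant)
    log.info("%d of %d loops pass the significance pre-filter",
             len(significant), len(loops))

    if config.truth:
        truth = lio.read_bedpe(config.truth, label="truth")
        if config.false_sets:
            false_sets = [lio.read_bedpe(p) for p in config.false_sets]
        elif sizes is not None:
            mask = ExclusionMask.build(
                interval_sets=[lio.read_bed(p) for p in config.mask_beds],
                loop_sets=[truth],
            )
            false_sets = build_false_sets(
                truth, mask, sizes, n_sets=config.n_false_sets, seed=config.seed
            )
            for k, fs in enumerate(false_sets):
                lio.write_bedpe(fs, outdir / f"false_set_{k}.bedpe")
        else:
            raise ValueError(
                "accuracy requested (truth supplied) but neither false_sets nor "
                "sizes (for sampling them) are available"
            )
        counts = accuracy(
            loops, truth, false_sets, min_overlap_fraction=config.anchor_overlap_fraction
        )
        report["acc"] = counts.acc
        report.update({f"acc_{k}": v for k, v in counts.to_dict().items() if k != "acc"})
        log.info("ACC %.4f (TP %.1f FP %.1f TN %.1f FN %.1f)",
                 counts.acc, counts.tp, counts.fp, counts.tn, counts.fn)

    if config.enhancers and config.promoters and (
        config.active_marks or config.repressive_marks
    ):
        ar = activation_rate(
            significant,
            lio.read_bed(config.enhancers),
            lio.read_bed(config.promoters),
            [lio.read_bed(p) for p in config.active_marks],
            [lio.read_bed(p) for p in config.repressive_marks],
        )
        report["ar"] = ar.activation_rate
        report.update(
            ar_active=ar.n_active,
            ar_inactive=ar.n_inactive,
            ar_other=ar.n_other,
            ar_ee=ar.n_ee,
            ar_ep=ar.n_ep,
            ar_pp=ar.n_pp,
        )
        log.info("AR %.4f (%d active / %d classified)",
                 ar.activation_rate, ar.n_active, ar.n_classified)

    try:
        res = resolution_levels(significant)
        report["res_le10k"] = res.le_10kb
        report["res_10k_100k"] = res.from_10kb_to_100kb
        report["res_100k_1m"] = res.from_100kb_to_1mb
    except ValueError:
        log.info("no loops within the 1 Mb range; resolution levels are NA")

    _write_report(report, outdir)
    return report


def _write_report(report: Mapping, outdir: Path) -> None:
    row = {c: report.get(c) for c in REPORT_COLUMNS}
    frame = pd.DataFrame([row], columns=REPORT_COLUMNS)
    frame.to_csv(outdir / "report.tsv", sep="\t", index=False, na_rep="NA")
    with open(outdir / "report.json", "w") as fh:
        json.dump(dict(report), fh, indent=1, sort_keys=True)


def compare(reports: Sequence[Mapping]) -> pd.DataFrame:
    """Cross-method comparison matrix: per-metric dataset means plus scaled columns.

    Every report must carry ``label`` (the method) and ``dataset``; all
    methods must cover the same dataset set (mismatches are an error
    listing the symmetric difference).  For each metric the mean over
    datasets is taken per method (NA entries are skipped) and min-max
    rescaled across methods into a ``*_scaled`` column.
    """
    if not reports:
        raise ValueError("no reports supplied")
    frame = pd.DataFrame([dict(r) for r in reports])
    if "label" not in frame or "dataset" not in frame:
        raise ValueError("reports must carry 'label' and 'dataset' fields")
    methods = sorted(frame["label"].unique())
    if len(methods) < 2:
        raise ValueError("comparison needs at least two methods")
    by_method = {m: set(frame.loc[frame["label"] == m, "dataset"]) for m in methods}
    reference = by_method[methods[0]]
    for m in methods[1:]:
        if by_method[m] != reference:
            diff = sorted(by_method[m] ^ reference)
            raise ValueError(
                f"methods {methods[0]!r} and {m!r} cover different datasets: "
                f"symmetric difference {diff}"
            )

    metrics = [c for c in METRIC_COLUMNS if c in frame.columns]
    for col in metrics:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    means = (
        frame.groupby("label")[metrics].mean().loc[methods]
        if metrics
        else pd.DataFrame(index=methods)
    )
    out = means.copy()
    for col in metrics:
        vals = means[col]
        if vals.notna().sum() >= 2:
            scaled = scale_scores({m: float(v) for m, v in vals.items() if pd.notna(v)})
            out[f"{col}_scaled"] = pd.Series(scaled)
        else:
            out[f"{col}_scaled"] = pd.NA
    out.index.name = "method"
    return out
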