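"""Self-consistent synthetic input bundles with known ground truth.

``make_fixture`` writes every file the evaluation pipeline consumes —
chrom.sizes, candidate loops (BEDPE), ChIP-seq peaks, PET records,
enhancer/promoter/TSS annotations, active and repressive histone-mark
peaks, and verified contacts planted on chosen loops — plus a ground-truth
JSON stating which loops are true, which PETs are UV, the expected UV Rate
and the expected per-loop activity labels.  Every metric and the
gold-standard constructor can then be tested end-to-end without any
external data.

Geometry is deliberately clean: candidate loops occupy disjoint genomic
blocks, so a planted contact covers exactly its own loop, annotations
label exactly the anchors they are placed on, and all planted quantities
are reproduced exactly rather than approximately.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as lio
from .core import ChromSizes, GenomicInterval, Loop, LoopSet, PeakSet, PETRecord
from .goldstandard import VerifiedContact

__all__ = ["FixtureSpec", "make_fixture", "default_fixture_sizes"]


@dataclass
class FixtureSpec:
    """Declared composition of a synthetic input bundle.

    Defaults encode the standard study conditions: 1000 PETs at a planted
    UV Rate of 0.4, 100 candidate loops of which 20 carry verified
    contacts, and an active/inactive/other split of 0.5/0.3/0.2 over the
    candidates.
    """

    n_pets: int = 1000
    uv_fraction: float = 0.4
    n_candidates: int = 100
    n_true: int = 20
    contacts_per_true: int = 8
    anchor_length: int = 2000
    min_span: int = 20000
    max_span: int = 200000
    pet_count_min: int = 3
    pet_count_max: int = 30
    active_fraction: float = 0.5
    inactive_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.uv_fraction <= 1:
            raise ValueError("uv_fraction must be in [0, 1]")
        if self.n_true > self.n_candidates:
            raise ValueError("n_true cannot exceed n_candidates")
        if self.min_span > self.max_span:
            raise ValueError("min_span exceeds max_span")
        if self.anchor_length <= 0 or self.n_pets <= 0 or self.n_candidates <= 0:
            raise ValueError("counts and lengths must be positive")
        if self.active_fraction + self.inactive_fraction > 1:
            raise ValueError("active_fraction + inactive_fraction exceeds 1")
        if self.min_span < self.anchor_length:
            raise ValueError("min_span must be at least anchor_length (anchors overlap)")


def default_fixture_sizes() -> ChromSizes:
    """A two-chromosome synthetic genome large enough for the default spec."""
    return ChromSizes({"chrS1": 12_000_000, "chrS2": 12_000_000})


def make_fixture(
    sizes: ChromSizes,
    spec: FixtureSpec,
    out_dir,
    seed: int = 0,
) -> dict:
    """Write a synthetic input bundle and return its paths and ground truth.

    Candidate loops are laid out in disjoint blocks cycling over the
    chromosomes; verified contacts are planted inside the anchors of
    ``n_true`` randomly chosen candidates; annotation files label anchor1
    of every candidate enhancer-like and anchor2 promoter-like, and
    histone-mark peaks implement the planted active/inactive/other labels.
    Raises ``ValueError`` when the genome cannot host the requested layout
    (a planted element would fall off a chromosome).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1D0]))

    # --- candidate layout: disjoint blocks, cycling over chromosomes
    margin = 10_000
    stride = spec.max_span + 2 * spec.anchor_length + 2 * margin
    capacity: list[tuple[str, int]] = []  # (chrom, block base)
    for chrom in sizes.chroms:
        n_blocks = max(0, (sizes[chrom] - margin) // stride)
        capacity.extend((chrom, margin + b * stride) for b in range(n_blocks))
    if len(capacity) < spec.n_candidates:
        raise ValueError(
            f"fixture genome too small: {len(capacity)} candidate blocks available, "
            f"{spec.n_candidates} requested"
        )

    candidates: list[Loop] = []
    for idx in range(spec.n_candidates):
        chrom, base = capacity[idx]
        span = int(rng.integers(spec.min_span, spec.max_span + 1))
        a1 = GenomicInterval(chrom, base, base + spec.anchor_length)
        mid2 = a1.midpoint + span
        s2 = int(round(mid2 - 0.5 * spec.anchor_length))
        a2 = GenomicInterval(chrom, s2, s2 + spec.anchor_length)
        if a2.end > sizes[chrom]:
            raise ValueError(f"planted loop {idx} extends beyond {chrom}")
        pet = int(rng.integers(spec.pet_count_min, spec.pet_count_max + 1))
        candidates.append(Loop(a1, a2, pet_count=pet, p_value=0.001))
    candidate_set = LoopSet(candidates, label="fixture-candidates")

    # --- planted verified contacts on n_true random candidates
    true_idx = np.sort(rng.choice(spec.n_candidates, size=spec.n_true, replace=False))
    contacts: list[VerifiedContact] = []
    sources = ["eqtl", "crispr"]
    for rank, idx in enumerate(true_idx):
        lp = candidates[int(idx)]
        for c in range(spec.contacts_per_true):
            contacts.append(
                VerifiedContact(
                    _sub_region(rng, lp.anchor1),
                    _sub_region(rng, lp.anchor2),
                    source=sources[(rank + c) % len(sources)],
                )
            )

    # --- annotations: anchor1 enhancer-like, anchor2 promoter-like
    enhancers = PeakSet([lp.anchor1 for lp in candidates], label="enhancer-like")
    promoters = PeakSet([lp.anchor2 for lp in candidates], label="promoter-like")
    tss = PeakSet(
        [
            GenomicInterval(lp.anchor2.chrom, lp.anchor2.start, lp.anchor2.start + 200)
            for lp in candidates
        ],
        label="tss",
    )
    chip_peaks = PeakSet(candidate_set.anchors(), label="chip-peaks")

    # --- activity labels and histone-mark peaks implementing them
    n_active = int(round(spec.active_fraction * spec.n_candidates))
    n_inactive = int(round(spec.inactive_fraction * spec.n_candidates))
    labels = np.array(
        ["active"] * n_active
        + ["inactive"] * n_inactive
        + ["other"] * (spec.n_candidates - n_active - n_inactive)
    )
    rng.shuffle(labels)
    active_1: list[GenomicInterval] = []  # H3K27ac-like
    active_2: list[GenomicInterval] = []  # H3K4me1/3-like
    repressive: list[GenomicInterval] = []  # H3K27me3-like
    for lp, lab in zip(candidates, labels):
        if lab == "active":
            # split across the two active-mark files to exercise the union
            active_1.append(lp.anchor1)
            active_2.append(lp.anchor2)
        elif lab == "inactive":
            repressive.append(lp.anchor1)
            repressive.append(lp.anchor2)

    # --- PET records with an exact planted UV fraction
    n_uv = int(round(spec.uv_fraction * spec.n_pets))
    pets: list[PETRecord] = []
    uv_flags: list[bool] = []
    for i in range(spec.n_pets):
        lp = candidates[i % spec.n_candidates]
        end1 = _sub_region(rng, lp.anchor1, length=50)
        end2 = _sub_region(rng, lp.anchor2, length=50)
        if i < n_uv:
            pets.append(PETRecord(end1, end2, 40, 40, False, "inter_ligation"))
            uv_flags.append(True)
        else:
            mode = i % 4
            if mode == 0:  # one end below MAPQ 30
                pets.append(PETRecord(end1, end2, 5, 40, False, "inter_ligation"))
            elif mode == 1:  # PCR duplicate
                pets.append(PETRecord(end1, end2, 40, 40, True, "inter_ligation"))
            elif mode == 2:  # self-ligation: both ends on one anchor
                near = _sub_region(rng, lp.anchor1, length=50)
                pets.append(PETRecord(end1, near, 40, 40, False, "self_ligation"))
            else:  # unmappable / chimeric
                pets.append(PETRecord(end1, end2, 40, 40, False, "invalid"))
            uv_flags.append(False)

    # --- write everything
    paths = {
        "sizes": out / "genome.chrom.sizes",
        "candidates": out / "candidates.bedpe",
        "contacts": out / "contacts.bedpe",
        "pets": out / "pets.tsv",
        "chip_peaks": out / "chip_peaks.bed",
        "enhancers": out / "enhancers.bed",
        "promoters": out / "promoters.bed",
        "tss": out / "tss.bed",
        "active_marks": [out / "h3k27ac.bed", out / "h3k4me.bed"],
        "repressive_marks": [out / "h3k27me3.bed"],
        "ground_truth": out / "ground_truth.json",
    }
    lio.write_chrom_sizes(sizes, paths["sizes"])
    lio.write_bedpe(candidate_set, paths["candidates"])
    lio.write_contacts(contacts, paths["contacts"])
    lio.write_pets(pets, paths["pets"])
    lio.write_bed(chip_peaks, paths["chip_peaks"])
    lio.write_bed(enhancers, paths["enhancers"])
    lio.write_bed(promoters, paths["promoters"])
    lio.write_bed(tss, paths["tss"])
    lio.write_bed(PeakSet(active_1, label="h3k27ac"), paths["active_marks"][0])
    lio.write_bed(PeakSet(active_2, label="h3k4me"), paths["active_marks"][1])
    lio.write_bed(PeakSet(repressive, label="h3k27me3"), paths["repressive_marks"][0])

    ground_truth = {
        "spec": asdict(spec),
        "seed": int(seed),
        "uv_rate": n_uv / spec.n_pets,
        "pet_is_uv": uv_flags,
        "true_loop_indices": [int(i) for i in true_idx],
        "loop_labels": [str(l) for l in labels],
        "expected_ar": float(np.mean(labels == "active")),
        "expected_classes": {"E-P": spec.n_candidates},
        "expected_pc_normalized": 1.0,
        "n_candidates": spec.n_candidates,
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=True)

    return {
        "paths": {
            k: ([str(p) for p in v] if isinstance(v, list) else str(v))
            for k, v in paths.items()
        },
        "ground_truth": ground_truth,
        "candidates": candidate_set,
        "contacts": contacts,
        "pets": pets,
    }


def _sub_region(
    rng: np.random.Generator, anchor: GenomicInterval, length: int | None = None
) -> GenomicInterval:
    """A random sub-interval strictly inside an anchor."""
    if length is None:
        length = int(rng.integers(200, min(1000, anchor.length) + 1))
    length = min(length, anchor.length)
    off = int(rng.integers(0, anchor.length - length + 1))
    return GenomicInterval(anchor.chrom, anchor.start + off, anchor.start + off + length)
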