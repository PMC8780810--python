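"""Synthetic ChIA-PET and HiChIP contact generators.

ChIA-PET contacts follow a Poisson distance-decay law: the genome is
segmented into fixed-size bins (default 5000 bp) and the interaction count
between bins i and j is drawn as n_ij ~ Pois(a / (1 + delta)) with
delta = |i - j| in bin units, so contact frequency falls off with genomic
distance as real ligation data does.  ``a`` sets the overall interaction
intensity.

HiChIP pairs start from Hi-C anchor pairs at the same bin size; ChIP-seq
read coverage over each anchor pair imitates the immunoprecipitation
enrichment, and pairs below the coverage threshold quantile (default the
median, i.e. the 50% threshold) are dropped to leave the final valid pairs.

``estimate_a`` closes the loop: a maximum-likelihood recovery of the
intensity from a simulated table, used to validate the generator.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ChromSizes, GenomicInterval, Loop, LoopSet, PETTrack

__all__ = [
    "SimulationParams",
    "simulate_chiapet",
    "simulate_hichip",
    "estimate_a",
]


@dataclass
class SimulationParams:
    """Knobs of the contact simulators.

    bin_size
        genomic bin width in bp (default 5000).
    a
        Poisson intensity scale: the expected count at zero bin distance.
    max_delta
        largest bin distance simulated; clipped per chromosome with a
        warning when it exceeds the chromosome's bin count.
    coverage_threshold
        HiChIP filter: quantile of ChIP coverage below which anchor pairs
        are dropped (0.5 keeps the top half).
    seed
        master seed; each chromosome derives an independent substream from
        it, so chromosome order never changes results.
    """

    bin_size: int = 5000
    a: float = 10.0
    max_delta: int = 200
    coverage_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.a <= 0:
            raise ValueError("intensity a must be positive")
        if self.max_delta < 1:
            raise ValueError("max_delta must be >= 1")
        if not 0 < self.coverage_threshold < 1:
            raise ValueError("coverage_threshold must be in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def _chrom_rng(seed: int, chrom: str) -> np.random.Generator:
    # keyed on the chromosome name, not its position in the dict
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(chrom.encode())])
    )


def simulate_chiapet(
    sizes: ChromSizes,
    params: SimulationParams,
    include_self: bool = False,
    label: str = "chiapet-sim",
) -> tuple[LoopSet, pd.DataFrame]:
    """Simulate ChIA-PET bin-pair contacts under the Poisson distance-decay law.

    Every intra-chromosomal bin pair (i, j) with 1 <= delta <= max_delta
    gets a count n_ij ~ Pois(a / (1 + delta)).  Pairs with n_ij > 0 are
    emitted as loops (anchors are the two bins, pet_count = n_ij); the
    companion table records (chrom, i, j, delta, lam, count) for every
    simulated pair, zeros included, for oracle checks and intensity
    recovery.  ``include_self=True`` additionally logs self pairs
    (delta = 0, lam = a) in the table; they never become loops, a loop
    needing two distinct anchors.
    """
    b = params.bin_size
    frames = []
    loops: list[Loop] = []
    for chrom in sorted(sizes.chroms):
        nbins = sizes[chrom] // b
        if nbins < 2:
            continue
        dmax = params.max_delta
        if dmax > nbins - 1:
            warnings.warn(
                f"max_delta {dmax} exceeds bin count on {chrom}; clipped to {nbins - 1}",
                stacklevel=2,
            )
            dmax = nbins - 1
        rng = _chrom_rng(params.seed, chrom)
        first_delta = 0 if include_self else 1
        for delta in range(first_delta, dmax + 1):
            i = np.arange(nbins - delta, dtype=np.int64)
            lam = params.a / (1 + delta)
            n = rng.poisson(lam, size=i.size)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "i": i,
                        "j": i + delta,
                        "delta": delta,
                        "lam": lam,
                        "count": n,
                    }
                )
            )
            if delta >= 1:
                for k in np.nonzero(n)[0]:
                    ii = int(i[k])
                    jj = ii + delta
                    loops.append(
                        Loop(
                            GenomicInterval(chrom, ii * b, (ii + 1) * b),
                            GenomicInterval(chrom, jj * b, (jj + 1) * b),
                            pet_count=int(n[k]),
                        )
                    )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "i", "j", "delta", "lam", "count"])
    )
    return LoopSet(loops, label=label), table


def simulate_hichip(
    hic_pairs: LoopSet,
    chip_reads: PETTrack | Mapping[str, Sequence[float]] | Iterable[GenomicInterval],
    params: SimulationParams,
    label: str = "hichip-sim",
) -> LoopSet:
    """Filter Hi-C anchor pairs by ChIP-seq coverage into simulated HiChIP pairs.

    The coverage score of a pair is the ChIP read count over anchor1 plus
    anchor2.  Pairs scoring at least the ``coverage_threshold`` quantile of
    all scores are retained; with all-equal scores every pair survives.
    """
    if len(hic_pairs) == 0:
        raise ValueError("no Hi-C anchor pairs supplied")
    if isinstance(chip_reads, PETTrack):
        track = chip_reads
    elif isinstance(chip_reads, Mapping):
        track = PETTrack(chip_reads)
    else:
        track = PETTrack.from_intervals(chip_reads)
    scores = np.array(
        [
            track.count(lp.anchor1.chrom, lp.anchor1.start, lp.anchor1.end)
            + track.count(lp.anchor2.chrom, lp.anchor2.start, lp.anchor2.end)
            for lp in hic_pairs
        ],
        dtype=float,
    )
    cut = float(np.quantile(scores, params.coverage_threshold))
    kept = [lp for lp, s in zip(hic_pairs, scores) if s >= cut]
    return LoopSet(kept, label=label)


def estimate_a(table: pd.DataFrame | Iterable[tuple[int, int]]) -> float:
    """Closed-form MLE of the Poisson intensity a from a (delta, count) table.

    Under n_ij ~ Pois(a / (1 + delta)) the log-likelihood is maximised at

        a_hat = sum(n_ij) / sum(1 / (1 + delta_ij)).

    Accepts the companion table of :func:`simulate_chiapet` or any iterable
    of (delta, count) pairs.
    """
    if isinstance(table, pd.DataFrame):
        deltas = table["delta"].to_numpy(dtype=float)
        counts = table["count"].to_numpy(dtype=float)
    else:
        rows = list(table)
        if rows:
            arr = np.asarray(rows, dtype=float)
            deltas, counts = arr[:, 0], arr[:, 1]
        else:
            deltas = counts = np.empty(0)
    if deltas.size == 0:
        raise ValueError("cannot estimate intensity from an empty table")
    return float(counts.sum() / (1.0 / (1.0 + deltas)).sum())
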