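from __future__ import annotations

import numpy as np
import pytest

from loopbench import ChromSizes, FixtureSpec, GenomicInterval, Loop, LoopSet, make_fixture


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def loop(chrom, s1, e1, s2, e2, **kw):
    return Loop(GenomicInterval(chrom, s1, e1), GenomicInterval(chrom, s2, e2), **kw)


@pytest.fixture
def sizes():
    return ChromSizes({"chrA": 1_000_000, "chrB": 600_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_intervals(rng, n, sizes, min_len=50, max_len=300):
    chroms = sizes.chroms
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, sizes[chrom] - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_loops(rng, n, sizes, anchor_len=(80, 250), span=(1_000, 400_000), pets=(0, 20)):
    chroms = sizes.chroms
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        la = int(rng.integers(*anchor_len))
        lb = int(rng.integers(*anchor_len))
        d = int(rng.integers(*span))
        limit = sizes[chrom] - (d + la + lb)
        s1 = int(rng.integers(0, max(1, limit)))
        s2 = s1 + la + d
        out.append(
            Loop(
                GenomicInterval(chrom, s1, s1 + la),
                GenomicInterval(chrom, s2, s2 + lb),
                pet_count=int(rng.integers(*pets)),
            )
        )
    return out


SMALL_FIXTURE_SPEC = FixtureSpec(
    n_pets=200,
    n_candidates=30,
    n_true=8,
    contacts_per_true=6,
    max_span=150_000,
)

SMALL_FIXTURE_SIZES = ChromSizes({"chrS1": 4_000_000, "chrS2": 4_000_000})


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic input bundle shared across tests (read-only)."""
    out = tmp_path_factory.mktemp("bundle")
    return make_fixture(SMALL_FIXTURE_SIZES, SMALL_FIXTURE_SPEC, out, seed=5)
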