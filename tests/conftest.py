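"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

from threedfunc.core import GenomicRegion
from threedfunc.hic import ContactStore
from threedfunc.simulate import SimulationConfig, write_fixture


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def bin_intersects(bin_idx: int, resolution: int, region: GenomicRegion) -> bool:
    return bin_idx * resolution < region.end and (bin_idx + 1) * resolution > region.start


def brute_force_if(entries, resolution, regionA, regionB, chromsizes):
    """Double loop over COO entries with explicit rectangle membership.

    ``entries`` lists each unordered bin pair once, as in the native file
    format; the symmetric mirror is enumerated explicitly here.
    """
    a = GenomicRegion(regionA.chrom, max(0, regionA.start), min(chromsizes[regionA.chrom], regionA.end))
    b = GenomicRegion(regionB.chrom, max(0, regionB.start), min(chromsizes[regionB.chrom], regionB.end))
    total = 0.0
    for ca, ia, cb, ib, v in entries:
        oriented = [(ca, ia, cb, ib)]
        if (ca, ia) != (cb, ib):
            oriented.append((cb, ib, ca, ia))
        for c1, i1, c2, i2 in oriented:
            if (
                c1 == a.chrom
                and bin_intersects(i1, resolution, a)
                and c2 == b.chrom
                and bin_intersects(i2, resolution, b)
            ):
                total += v
    return total


def nearest_resolution(length, available):
    best = None
    for r in sorted(available):
        if best is None or abs(length - r) < abs(length - best):
            best = r
    return best


def random_store(rng, n_resolutions=2):
    """A small random multi-resolution store plus its raw entry lists."""
    chromsizes = {"c1": int(rng.integers(30_000, 80_000)), "c2": int(rng.integers(30_000, 80_000))}
    resolutions = sorted(rng.choice([1_000, 2_000, 5_000, 10_000], size=n_resolutions, replace=False).tolist())
    entries = {}
    for res in resolutions:
        rows = []
        for ca in chromsizes:
            for cb in chromsizes:
                if list(chromsizes).index(ca) > list(chromsizes).index(cb):
                    continue
                na = math.ceil(chromsizes[ca] / res)
                nb = math.ceil(chromsizes[cb] / res)
                n_entries = int(rng.integers(5, 30))
                for _ in range(n_entries):
                    i = int(rng.integers(0, na))
                    j = int(rng.integers(0, nb))
                    if ca == cb and i > j:
                        i, j = j, i
                    rows.append((ca, i, cb, j, float(rng.uniform(0.1, 5.0))))
        # collapse duplicate coordinates: the store sums them, the brute-force
        # oracle iterates entries, so make coordinates unique for a clean diff
        uniq = {}
        for ca, i, cb, j, v in rows:
            uniq[(ca, i, cb, j)] = v
        entries[res] = [(k[0], k[1], k[2], k[3], v) for k, v in uniq.items()]
    store = ContactStore.from_entries(chromsizes, {r: list(e) for r, e in entries.items()})
    return store, entries, chromsizes, resolutions


def random_region(rng, chrom, size):
    start = int(rng.integers(0, size - 2_000))
    length = int(rng.integers(1_000, max(2_000, size // 3)))
    return GenomicRegion(chrom, start, min(start + length, size))


# ---------------------------------------------------------------------------
# Session fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory, sim_config):
    """One fully written synthetic input tree, shared across tests."""
    out = tmp_path_factory.mktemp("fixture")
    write_fixture(sim_config, out)
    return out
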