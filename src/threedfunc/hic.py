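"""Multi-resolution Hi-C contact store with rectangle queries and virtual 4C.

The native on-disk format is a documented text layout, one COO file per
resolution plus a JSON manifest:

``manifest.json``::

    {"chromsizes": {"chr1": 2000000, ...},
     "resolutions": [5000, 25000, 100000],
     "files": {"5000": "res_5000.coo.tsv", ...}}

``res_<R>.coo.tsv`` — tab-separated, no header, one record per stored
bin pair::

    chromA  binA  chromB  binB  value

Bin indices are 0-based at resolution ``R``.  Each unordered bin pair
appears once; the loader mirrors intra-chromosomal entries so the
in-memory map is symmetric.  Duplicate coordinates are summed (standard
COO semantics).  Values are normalized, non-negative contact counts —
matrix balancing is assumed to have been applied upstream.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from threedfunc.core import GenomicRegion

__all__ = ["ContactStore", "write_bedgraph"]


class ContactStore:
    """Normalized contact values at several resolutions, queryable by region.

    Parameters
    ----------
    chromsizes
        Mapping chromosome name -> length in bp.  Its order defines the
        canonical chromosome order used for inter-chromosomal matrix keys.
    matrices
        ``{resolution: {(chromA, chromB): csr_matrix}}`` with chromosome
        pairs in canonical order; intra-chromosomal matrices must be
        symmetric (the constructors below take care of this).
    """

    def __init__(self, chromsizes: Mapping[str, int], matrices: dict):
        self.chromsizes = dict(chromsizes)
        self._order = {c: i for i, c in enumerate(self.chromsizes)}
        self.resolutions = sorted(matrices)
        self._mats = matrices
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_entries(cls, chromsizes: Mapping[str, int], entries_by_resolution: Mapping[int, Iterable]):
        """Build from iterables of ``(chromA, binA, chromB, binB, value)``."""
        order = {c: i for i, c in enumerate(chromsizes)}
        matrices: dict[int, dict] = {}
        for res, entries in entries_by_resolution.items():
            buckets: dict[tuple, list] = {}
            for ca, ia, cb, ib, v in entries:
                if ca not in order or cb not in order:
                    raise ValueError(f"unknown chromosome {ca!r}/{cb!r} in contact entries")
                if v < 0:
                    raise ValueError(f"negative contact value {v} at ({ca},{ia})x({cb},{ib})")
                if order[ca] > order[cb] or (ca == cb and ia > ib):
                    ca, ia, cb, ib = cb, ib, ca, ia
                buckets.setdefault((ca, cb), []).append((ia, ib, v))
            mats = {}
            for (ca, cb), items in buckets.items():
                na = _n_bins(chromsizes[ca], res)
                nb = _n_bins(chromsizes[cb], res)
                rows = np.array([i for i, _, _ in items])
                cols = np.array([j for _, j, _ in items])
                vals = np.array([v for _, _, v in items], dtype=float)
                if rows.max(initial=-1) >= na or cols.max(initial=-1) >= nb:
                    raise ValueError(
                        f"bin index out of range for {ca}x{cb} at resolution {res}"
                    )
                m = sparse.coo_matrix((vals, (rows, cols)), shape=(na, nb))
                if ca == cb:
                    diag = sparse.diags(m.diagonal())
                    m = m + m.T - diag
                mats[(ca, cb)] = m.tocsr()
            matrices[res] = mats
        return cls(chromsizes, matrices)

    @classmethod
    def from_dense(cls, chromsizes: Mapping[str, int], dense_by_resolution: Mapping[int, Mapping[tuple, np.ndarray]]):
        """Build from dense arrays keyed by canonical chromosome pair."""
        matrices = {}
        for res, blocks in dense_by_resolution.items():
            mats = {}
            for key, arr in blocks.items():
                arr = np.asarray(arr, dtype=float)
                if key[0] == key[1] and not np.allclose(arr, arr.T):
                    raise ValueError(f"intra-chromosomal block {key} is not symmetric")
                mats[key] = sparse.csr_matrix(arr)
            matrices[res] = mats
        return cls(chromsizes, matrices)

    @classmethod
    def load(cls, manifest_path) -> "ContactStore":
        manifest_path = Path(manifest_path)
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        chromsizes = {str(c): int(n) for c, n in manifest["chromsizes"].items()}
        entries = {}
        for res in manifest["resolutions"]:
            fname = manifest["files"][str(res)]
            df = pd.read_csv(
                manifest_path.parent / fname,
                sep="\t",
                header=None,
                names=["chromA", "binA", "chromB", "binB", "value"],
                dtype={"chromA": str, "chromB": str},
            )
            entries[int(res)] = df.itertuples(index=False, name=None)
        return cls.from_entries(chromsizes, entries)

    def save(self, out_dir) -> Path:
        """Write the native COO tree; returns the manifest path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = {}
        for res in self.resolutions:
            fname = f"res_{res}.coo.tsv"
            with open(out_dir / fname, "wt") as fh:
                for (ca, cb), m in sorted(self._mats[res].items(), key=lambda kv: (self._order[kv[0][0]], self._order[kv[0][1]])):
                    coo = m.tocoo()
                    for i, j, v in zip(coo.row, coo.col, coo.data):
                        if ca == cb and i > j:
                            continue  # store each unordered pair once
                        fh.write(f"{ca}\t{i}\t{cb}\t{j}\t{float(v)!r}\n")
            files[str(res)] = fname
        manifest = {
            "chromsizes": self.chromsizes,
            "resolutions": self.resolutions,
            "files": files,
        }
        mpath = out_dir / "manifest.json"
        with open(mpath, "wt") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return mpath

    # -- queries -----------------------------------------------------------

    def n_bins(self, chrom: str, resolution: int) -> int:
        return _n_bins(self._chrom_length(chrom), resolution)

    def clamp(self, region: GenomicRegion) -> GenomicRegion:
        """Clamp a region to ``[0, chrom_length)``."""
        n = self._chrom_length(region.chrom)
        return GenomicRegion(region.chrom, max(0, region.start), min(n, region.end))

    def query_if(
        self,
        regionA: GenomicRegion,
        regionB: GenomicRegion,
        window: int,
        agg: str = "sum",
    ) -> float:
        """Aggregate interaction frequency over the query rectangle.

        Sums (default) the normalized contact values over every bin pair
        ``(i, j)`` at resolution ``window`` where bin ``i`` intersects
        ``regionA`` and bin ``j`` intersects ``regionB``.  Bins that merely
        touch a region boundary count fully.  Symmetric in its two region
        arguments; regions are clamped to the chromosome.  ``agg="mean"``
        divides by the number of bin pairs in the rectangle.
        """
        self._check_window(window)
        a, b = self.clamp(regionA), self.clamp(regionB)
        (ca, a0, a1), (cb, b0, b1) = _bin_span(a, window), _bin_span(b, window)
        if self._order[ca] > self._order[cb]:
            (ca, a0, a1), (cb, b0, b1) = (cb, b0, b1), (ca, a0, a1)
        m = self._mats[window].get((ca, cb))
        total = 0.0 if m is None else float(m[a0:a1, b0:b1].sum())
        if agg == "mean":
            npairs = (a1 - a0) * (b1 - b0)
            return total / npairs if npairs else 0.0
        if agg != "sum":
            raise ValueError(f"agg must be 'sum' or 'mean', got {agg!r}")
        return total

    def virtual_4c(self, viewpoint: GenomicRegion, resolution: int) -> np.ndarray:
        """One-vs-all contact profile along the viewpoint chromosome.

        ``profile[b]`` is the summed contact between the bins intersecting
        the viewpoint and bin ``b``, for every bin of ``viewpoint.chrom``
        at ``resolution`` (the viewpoint's own bins included).
        """
        self._check_window(resolution)
        n = self._chrom_length(viewpoint.chrom)
        if viewpoint.start >= n:
            raise ValueError(f"viewpoint {viewpoint} beyond chromosome end {n}")
        vp = self.clamp(viewpoint)
        chrom, v0, v1 = _bin_span(vp, resolution)
        nb = self.n_bins(chrom, resolution)
        m = self._mats[resolution].get((chrom, chrom))
        if m is None:
            return np.zeros(nb)
        return np.asarray(m[v0:v1, :].sum(axis=0)).ravel()

    # -- internals ---------------------------------------------------------

    def _chrom_length(self, chrom: str) -> int:
        try:
            return self.chromsizes[chrom]
        except KeyError:
            raise ValueError(
                f"unknown chromosome {chrom!r}; store has {list(self.chromsizes)}"
            ) from None

    def _check_window(self, window: int):
        if window not in self._mats:
            raise ValueError(
                f"resolution {window} not in store; available: {self.resolutions}"
            )

    def _validate(self):
        for res, mats in self._mats.items():
            for (ca, cb), m in mats.items():
                if ca not in self.chromsizes or cb not in self.chromsizes:
                    raise ValueError(f"matrix chromosome {ca}/{cb} missing from chromsizes")
                if self._order[ca] > self._order[cb]:
                    raise ValueError(f"matrix key {(ca, cb)} not in canonical order")
                exp = (_n_bins(self.chromsizes[ca], res), _n_bins(self.chromsizes[cb], res))
                if m.shape != exp:
                    raise ValueError(
                        f"matrix {ca}x{cb}@{res} has shape {m.shape}, expected {exp}"
                    )
                if m.nnz and m.data.min() < 0:
                    raise ValueError(f"negative contact values in {ca}x{cb}@{res}")


def _n_bins(length: int, resolution: int) -> int:
    return math.ceil(length / resolution)


def _bin_span(region: GenomicRegion, resolution: int) -> tuple[str, int, int]:
    """Indices of bins intersecting the (already clamped) region."""
    b0 = region.start // resolution
    b1 = math.ceil(region.end / resolution)
    return region.chrom, b0, b1


def write_bedgraph(profile: np.ndarray, chrom: str, resolution: int, path, chrom_length: int | None = None):
    """Write a virtual-4C profile as BEDGraph (zero bins skipped)."""
    with open(path, "wt") as fh:
        for b, v in enumerate(profile):
            if v == 0:
                continue
            end = (b + 1) * resolution
            if chrom_length is not None:
                end = min(end, chrom_length)
            fh.write(f"{chrom}\t{b * resolution}\t{end}\t{float(v)!r}\n")
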