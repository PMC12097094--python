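"""Mapping curated variants onto the four layers of 3D genome organization.

Four layers, four families of rules:

* **territory** — interchromosomal translocations (ICTs) joining genes on
  different chromosomes; recurrent fusion gene pairs are deduplicated,
  counted, and flagged when they recur more than 10 times.
* **compartment** — a structural variant's two breakpoints are looked up in
  an A/B compartment track; the ordered pair of labels gives the category
  (stable: A–A, B–B; switching: A–B, B–A).
* **TAD** — breakpoints are assigned to insulation domains or boundary
  intervals, giving intra-TAD, inter-TAD1 (domain + boundary), inter-TAD2
  (boundary + boundary) or inter-TAD3 (two different domains); variants
  longer than half the local domain size are excluded so that very large
  events do not skew the within-domain statistics.
* **loop** — a SNP is extended 1 kb on both sides and paired with a gene
  whenever a chromatin loop has one anchor over the extended SNP locus and
  the other over the gene body.  Loops are further classified by cancer-SNP
  content across tissues (CSL / OL / NSL) and by anchor annotation
  (enhancer–promoter first, then CTCF, else other).
"""

from __future__ import annotations

from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from threedfunc.core import GenomicRegion, GeneModel, ICTRecord, SNPRecord, SVRecord

__all__ = [
    "CompartmentTrack",
    "TADSet",
    "Loop",
    "DisruptionCall",
    "CompartmentCall",
    "TADCall",
    "RegionIndex",
    "filter_svs",
    "classify_compartment_disruption",
    "classify_tad_disruption",
    "merge_fusion_pairs",
    "categorize_fusion_if",
    "count_dosage_sensitive",
    "snp_locus",
    "map_snp_to_loops",
    "classify_loop_cancer_status",
    "classify_loop_type",
    "annotate_snp_coding",
]

SV_MIN_LENGTH = 10_000
SV_MAX_LENGTH = 10_000_000
SV_MIN_FREQUENCY = 0.01
FUSION_HIGH_FREQUENCY = 10  # strict: a pair is recurrent when count > 10
TAD_EXCLUSION_FRACTION = 0.5
SNP_LOOP_FLANK = 1_000
SPLICE_SITE_WINDOW = 10  # bp, inclusive

STABLE_CATEGORIES = frozenset({"A-A", "B-B"})
SWITCHING_CATEGORIES = frozenset({"A-B", "B-A"})


# ---------------------------------------------------------------------------
# Annotation containers
# ---------------------------------------------------------------------------

class RegionIndex:
    """Interval index over a set of regions, per chromosome."""

    def __init__(self, regions: Iterable[GenomicRegion]):
        self._trees: dict[str, IntervalTree] = {}
        for r in regions:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    def overlapping(self, region: GenomicRegion) -> list[GenomicRegion]:
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree.overlap(region.start, region.end))]

    def any_overlap(self, region: GenomicRegion) -> bool:
        tree = self._trees.get(region.chrom)
        return tree is not None and bool(tree.overlap(region.start, region.end))


class CompartmentTrack:
    """Binned A/B compartment intervals, with point lookup and transition
    distances.

    Intervals must be non-overlapping within a chromosome; gaps are allowed
    and look up as ``None``.  A *transition* is an edge between two
    consecutive covered intervals whose labels differ.
    """

    def __init__(self, intervals: Iterable[tuple[GenomicRegion, str]] | Iterable[tuple[GenomicRegion, str, float]]):
        per_chrom: dict[str, list] = {}
        for item in intervals:
            region, label = item[0], item[1]
            eigen = item[2] if len(item) > 2 else None
            if label not in ("A", "B"):
                raise ValueError(f"compartment label must be A or B, got {label!r}")
            if eigen is not None and eigen != 0 and (eigen > 0) != (label == "A"):
                raise ValueError(
                    f"eigen-value sign {eigen} inconsistent with label {label} at {region}"
                )
            per_chrom.setdefault(region.chrom, []).append((region, label, eigen))
        self._per_chrom = {}
        self._transitions = {}
        for chrom, items in per_chrom.items():
            items.sort(key=lambda t: t[0].start)
            for (a, _, _), (b, _, _) in zip(items, items[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping compartment intervals {a} and {b}")
            self._per_chrom[chrom] = items
            trans = []
            for (a, la, _), (b, lb, _) in zip(items, items[1:]):
                if la != lb:
                    trans.extend({a.end, b.start})
            self._transitions[chrom] = sorted(trans)

    @classmethod
    def from_bed(cls, path) -> "CompartmentTrack":
        """Read ``chrom start end label [eigen]`` BED rows."""
        from threedfunc.core import _lines

        items = []
        for lineno, line in _lines(path):
            f = line.split("\t")
            region = GenomicRegion(f[0], int(f[1]), int(f[2]))
            eigen = float(f[4]) if len(f) > 4 else None
            items.append((region, f[3], eigen))
        return cls(items)

    def label_at(self, chrom: str, pos: int) -> str | None:
        items = self._per_chrom.get(chrom)
        if not items:
            return None
        starts = [r.start for r, _, _ in items]
        i = bisect_right(starts, pos) - 1
        if i >= 0 and items[i][0].contains(pos):
            return items[i][1]
        return None

    def nearest_transition_distance(self, chrom: str, pos: int) -> int | None:
        trans = self._transitions.get(chrom)
        if not trans:
            return None
        return min(abs(pos - t) for t in trans)


class TADSet:
    """Insulation domains plus boundary intervals for one or more chromosomes."""

    def __init__(self, domains: Iterable[GenomicRegion], boundaries: Iterable[GenomicRegion] = ()):
        self.domains = sorted(domains)
        self.boundaries = sorted(boundaries)
        self._dom_by_chrom: dict[str, list[GenomicRegion]] = {}
        for d in self.domains:
            self._dom_by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, doms in self._dom_by_chrom.items():
            for a, b in zip(doms, doms[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping domains {a} and {b}")
        self._bnd_by_chrom: dict[str, list[GenomicRegion]] = {}
        for b in self.boundaries:
            self._bnd_by_chrom.setdefault(b.chrom, []).append(b)

    def locate(self, chrom: str, pos: int):
        """Return ``("domain", region)``, ``("boundary", region)`` or ``None``.

        Boundary intervals win over domains if the two ever overlap.
        """
        for b in self._bnd_by_chrom.get(chrom, ()):
            if b.contains(pos):
                return ("boundary", b)
        doms = self._dom_by_chrom.get(chrom, ())
        starts = [d.start for d in doms]
        i = bisect_right(starts, pos) - 1
        if i >= 0 and doms[i].contains(pos):
            return ("domain", doms[i])
        return None


@dataclass
class Loop:
    """A point-to-point chromatin contact between two anchors."""

    anchorA: GenomicRegion
    anchorB: GenomicRegion
    tissues: frozenset = frozenset()
    cancer_class: str = "unset"  # CSL / OL / NSL, set by classify_loop_cancer_status
    loop_type: str = "unset"  # EP / CTCF / other, set by classify_loop_type
    loop_id: str = ""


@dataclass(frozen=True)
class DisruptionCall:
    """One variant mapped onto one 3D layer in one cell type."""

    variant_id: str
    layer: str  # territory / compartment / TAD / loop
    category: str
    cell_type: str = ""


@dataclass(frozen=True)
class CompartmentCall:
    category: str  # A-A, A-B, B-A, B-B or unmapped
    left_label: str | None
    right_label: str | None
    left_transition_distance: int | None
    right_transition_distance: int | None


@dataclass(frozen=True)
class TADCall:
    category: str  # intra-TAD, inter-TAD1, inter-TAD2, inter-TAD3, unmapped, excluded
    raw_category: str  # category before the 50%-of-domain-size exclusion
    local_tad_size: float | None


# ---------------------------------------------------------------------------
# SV curation and compartment / TAD classification
# ---------------------------------------------------------------------------

def filter_svs(svs: Sequence[SVRecord]) -> tuple[list[SVRecord], dict[str, int]]:
    """Apply the curation filters: length 10 kb–10 Mb (inclusive) AND
    population frequency > 1%.

    Returns the retained records in input order plus per-rule drop counts
    (a record failing both rules increments both counters).
    """
    retained = []
    drops = {"length": 0, "frequency": 0}
    for sv in svs:
        ok_len = SV_MIN_LENGTH <= sv.length <= SV_MAX_LENGTH
        ok_freq = sv.frequency > SV_MIN_FREQUENCY
        if not ok_len:
            drops["length"] += 1
        if not ok_freq:
            drops["frequency"] += 1
        if ok_len and ok_freq:
            retained.append(sv)
    return retained, drops


def _breakpoints(sv: SVRecord) -> tuple[int, int]:
    # Right breakpoint at end-1: under half-open coordinates an SV ending
    # exactly at a transition belongs to the interval on its left.
    return sv.region.start, sv.region.end - 1


def classify_compartment_disruption(sv: SVRecord, track: CompartmentTrack) -> CompartmentCall:
    """Label an SV by the compartments of its two breakpoints.

    The left breakpoint is ``region.start``, the right is ``region.end - 1``;
    the ordered label pair gives A-A / A-B / B-A / B-B, or ``unmapped`` when
    either breakpoint falls in a track gap.  Distances from each breakpoint
    to the nearest compartment transition are reported alongside.
    """
    left, right = _breakpoints(sv)
    chrom = sv.region.chrom
    ll = track.label_at(chrom, left)
    rl = track.label_at(chrom, right)
    category = f"{ll}-{rl}" if ll is not None and rl is not None else "unmapped"
    return CompartmentCall(
        category=category,
        left_label=ll,
        right_label=rl,
        left_transition_distance=track.nearest_transition_distance(chrom, left),
        right_transition_distance=track.nearest_transition_distance(chrom, right),
    )


def classify_tad_disruption(sv: SVRecord, tads: TADSet) -> TADCall:
    """Classify an SV against a TAD set.

    Categories: ``intra-TAD`` (both breakpoints in the same domain),
    ``inter-TAD1`` (one in a boundary, one in a domain), ``inter-TAD2``
    (both in boundary intervals — possibly different boundaries),
    ``inter-TAD3`` (two different domains).  ``unmapped`` when a breakpoint
    is outside all domains and boundaries.

    An SV longer than half the *local* domain size is reported as
    ``excluded`` (the raw category is kept alongside).  The local domain is
    the one containing the left breakpoint; for inter-TAD3 the mean of the
    two containing domains; for inter-TAD1 the single domain involved; no
    exclusion is applied to inter-TAD2 (no containing domain exists).
    """
    left, right = _breakpoints(sv)
    chrom = sv.region.chrom
    la = tads.locate(chrom, left)
    ra = tads.locate(chrom, right)
    if la is None or ra is None:
        return TADCall("unmapped", "unmapped", None)
    (lk, lr), (rk, rr) = la, ra
    local: float | None = None
    if lk == "domain" and rk == "domain":
        if lr == rr:
            raw = "intra-TAD"
            local = float(lr.length)
        else:
            raw = "inter-TAD3"
            local = (lr.length + rr.length) / 2.0
    elif lk == "boundary" and rk == "boundary":
        raw = "inter-TAD2"
    else:
        raw = "inter-TAD1"
        local = float(lr.length if lk == "domain" else rr.length)
    category = raw
    if local is not None and sv.length > TAD_EXCLUSION_FRACTION * local:
        category = "excluded"
    return TADCall(category, raw, local)


# ---------------------------------------------------------------------------
# Territory layer: fusion gene pairs
# ---------------------------------------------------------------------------

def merge_fusion_pairs(icts: Sequence[ICTRecord]) -> tuple[pd.DataFrame, int]:
    """Deduplicate ICTs and tabulate recurrent fusion gene pairs.

    Exact duplicates (same breakpoints and gene symbols) are removed before
    counting; gene pairs are unordered, compared after uppercasing.  A pair
    is ``high_frequency`` when its count is strictly greater than 10.
    Records missing a gene symbol are skipped; the skip count is returned.

    Returns a DataFrame with columns ``gene_a, gene_b, count,
    high_frequency`` sorted by descending count then pair name.
    """
    seen = set()
    counts: Counter = Counter()
    skipped = 0
    for ict in icts:
        if not ict.geneA or not ict.geneB:
            skipped += 1
            continue
        key = (
            ict.breakA.chrom, ict.breakA.start, ict.breakA.end,
            ict.breakB.chrom, ict.breakB.start, ict.breakB.end,
            ict.geneA.upper(), ict.geneB.upper(),
        )
        if key in seen:
            continue
        seen.add(key)
        pair = tuple(sorted((ict.geneA.upper(), ict.geneB.upper())))
        counts[pair] += 1
    rows = [
        {"gene_a": a, "gene_b": b, "count": c, "high_frequency": c > FUSION_HIGH_FREQUENCY}
        for (a, b), c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "count", "high_frequency"])
    if len(df):
        df = df.sort_values(["count", "gene_a", "gene_b"], ascending=[False, True, True]).reset_index(drop=True)
    return df, skipped


def categorize_fusion_if(values: Sequence[float], t_strong: float = 0.5) -> str:
    """Bucket a fusion pair's per-cell-line flexible IF values.

    ``none`` when the mean flexible IF is exactly zero, ``weak`` below the
    strong threshold, ``strong`` at or above it.  The threshold is a
    configuration parameter on the flexible-IF scale.
    """
    if not values:
        raise ValueError("need at least one flexible-IF value")
    if any(v < 0 for v in values):
        raise ValueError("flexible IF values must be non-negative")
    if not 0 < t_strong:
        raise ValueError("t_strong must be positive")
    mean = sum(values) / len(values)
    if mean == 0:
        return "none"
    return "strong" if mean >= t_strong else "weak"


# ---------------------------------------------------------------------------
# Dosage-sensitive gene counting
# ---------------------------------------------------------------------------

def count_dosage_sensitive(
    calls: Sequence[tuple[str, str]],
    svs: Mapping[str, SVRecord],
    genes: Sequence[GeneModel],
) -> dict:
    """Count dosage-sensitive genes inside compartment-disrupting SVs.

    ``calls`` is ``(variant_id, compartment_category)``; ``genes`` is the
    dosage-sensitive gene set (an input list, e.g. ClinVar-derived).  The
    counting unit is the (SV, gene) overlap pair: a gene overlapping two
    SVs of the same class counts twice.  Returns per-category counts plus
    ``stable`` (A-A ∪ B-B) and ``switching`` (A-B ∪ B-A) totals.
    """
    index = RegionIndex(g.region for g in genes)
    per_category: Counter = Counter()
    for variant_id, category in calls:
        if category not in STABLE_CATEGORIES | SWITCHING_CATEGORIES:
            continue
        sv = svs[variant_id]
        n = len(index.overlapping(sv.region))
        per_category[category] += n
    stable = sum(per_category[c] for c in STABLE_CATEGORIES)
    switching = sum(per_category[c] for c in SWITCHING_CATEGORIES)
    return {
        "per_category": dict(per_category),
        "stable": stable,
        "switching": switching,
    }


# ---------------------------------------------------------------------------
# Loop layer
# ---------------------------------------------------------------------------

def snp_locus(snp: SNPRecord, flank: int = SNP_LOOP_FLANK) -> GenomicRegion:
    """The SNP's extended locus: ±1 kb around the variant base, clamped at 0."""
    return GenomicRegion(snp.chrom, max(0, snp.pos - flank), snp.pos + flank + 1)


def map_snp_to_loops(
    snp: SNPRecord,
    genes: Sequence[GeneModel],
    loops: Sequence[Loop],
) -> list[tuple[SNPRecord, GeneModel, Loop]]:
    """Pair a SNP with target genes through chromatin loops.

    The SNP is extended 1 kb on both sides; a (SNP, gene) pair is emitted
    whenever some loop has one anchor intersecting the extended SNP locus
    and the other anchor intersecting the gene body (either orientation).
    Each emitted pair records its supporting loop.
    """
    locus = snp_locus(snp)
    out = []
    for loop in loops:
        matched: set[str] = set()  # gene ids already emitted for this loop
        for snp_anchor, gene_anchor in ((loop.anchorA, loop.anchorB), (loop.anchorB, loop.anchorA)):
            if not snp_anchor.intersects(locus):
                continue
            for gene in genes:
                if gene.gene_id not in matched and gene_anchor.intersects(gene.region):
                    matched.add(gene.gene_id)
                    out.append((snp, gene, loop))
    return out


def classify_loop_cancer_status(
    loop: Loop,
    cancer_snps_by_tissue: Mapping[str, Iterable[SNPRecord]],
    tissues: Sequence[str],
) -> str:
    """CSL / OL / NSL classification by cancer-SNP content across tissues.

    A loop is a cancer-specific loop (CSL) when *every* tissue contributes
    at least one cancer-related SNP inside either anchor; a normal-specific
    loop (NSL) when *no* tissue does; otherwise an overlap loop (OL).
    """
    if not tissues:
        raise ValueError("tissue list must be nonempty")
    hit = []
    for tissue in tissues:
        snps = cancer_snps_by_tissue.get(tissue, ())
        hit.append(
            any(
                snp.chrom == anchor.chrom and anchor.contains(snp.pos)
                for snp in snps
                for anchor in (loop.anchorA, loop.anchorB)
            )
        )
    if all(hit):
        return "CSL"
    if not any(hit):
        return "NSL"
    return "OL"


def classify_loop_type(
    loop: Loop,
    ctcf_peaks: Sequence[GenomicRegion] | RegionIndex,
    enhancers: Sequence[GenomicRegion] | RegionIndex,
    promoters: Sequence[GenomicRegion] | RegionIndex,
) -> str:
    """EP / CTCF / other classification by anchor annotation overlap.

    Enhancer–promoter loops are identified first (one anchor on an
    enhancer, the other on a promoter, either orientation); remaining
    loops with at least one anchor on a CTCF peak are CTCF loops; the rest
    are ``other``.
    """
    ctcf = ctcf_peaks if isinstance(ctcf_peaks, RegionIndex) else RegionIndex(ctcf_peaks)
    enh = enhancers if isinstance(enhancers, RegionIndex) else RegionIndex(enhancers)
    prom = promoters if isinstance(promoters, RegionIndex) else RegionIndex(promoters)
    a, b = loop.anchorA, loop.anchorB
    if (enh.any_overlap(a) and prom.any_overlap(b)) or (enh.any_overlap(b) and prom.any_overlap(a)):
        return "EP"
    if ctcf.any_overlap(a) or ctcf.any_overlap(b):
        return "CTCF"
    return "other"


def annotate_snp_coding(snp: SNPRecord, genes: Sequence[GeneModel]) -> str:
    """Coding/noncoding annotation.

    A SNP is *coding* when it lies inside any CDS interval or within 10 bp
    (inclusive) of any annotated splice-site coordinate; otherwise
    *noncoding*.
    """
    for gene in genes:
        if gene.region.chrom != snp.chrom:
            continue
        for cds in gene.cds_intervals:
            if cds.contains(snp.pos):
                return "coding"
        for ss in gene.splice_sites:
            if abs(snp.pos - ss) <= SPLICE_SITE_WINDOW:
                return "coding"
    return "noncoding"


def read_loops_bedpe(path) -> list[Loop]:
    """Read loops from BEDPE; column 7 onward holds semicolon-separated
    tissue tags (first extra column) and an optional loop id (second)."""
    from threedfunc.core import read_regions

    loops = []
    for i, (a, b, extra) in enumerate(read_regions(path, "BEDPE")):
        tissues = frozenset(t for t in extra[0].split(";") if t) if extra else frozenset()
        loop_id = extra[1] if len(extra) > 1 else f"loop_{i + 1}"
        loops.append(Loop(anchorA=a, anchorB=b, tissues=tissues, loop_id=loop_id))
    return loops
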