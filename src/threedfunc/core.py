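"""Coordinate conventions, domain record types, and readers/writers.

Every coordinate held in memory is **0-based, half-open** ``[start, end)``,
regardless of the source format.  BED and BEDPE already use that convention;
VCF and 1-based TSV positions are shifted on read and shifted back on write.
Chromosome names are passed through verbatim — no implicit ``chr`` prefix
munging — so stores, tracks and variant files must agree on naming.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

__all__ = [
    "GenomicRegion",
    "ICTRecord",
    "SVRecord",
    "SNPRecord",
    "GeneModel",
    "ParseError",
    "read_regions",
    "write_bed",
    "write_bedpe",
    "read_sv_table",
    "read_ict_table",
    "read_snp_table",
    "read_snp_vcf",
    "read_gene_models_bed12",
    "overlap_fraction",
]

SV_TYPES = frozenset(
    {"copy_number_gain", "copy_number_loss", "deletion", "duplication", "insertion", "other"}
)


class ParseError(ValueError):
    """A malformed line in an input file; carries file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _open_text(path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A chromosome interval, 0-based half-open.

    The universal coordinate currency of the package: contact-store query
    rectangles, variant breakpoint spans, gene bodies, loop anchors and
    annotation intervals are all ``GenomicRegion`` instances.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True if the 0-based position lies inside the half-open interval."""
        return self.start <= pos < self.end

    def intersects(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_region(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @classmethod
    def from_string(cls, text: str) -> "GenomicRegion":
        """Parse ``chrom:start-end`` (0-based half-open, commas allowed)."""
        try:
            chrom, span = text.rsplit(":", 1)
            s, e = span.replace(",", "").split("-")
            return cls(chrom, int(s), int(e))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end") from exc

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class ICTRecord:
    """An interchromosomal translocation joining two loci.

    ``breakA``/``breakB`` are breakpoint regions (point-like or gene-sized);
    the two loci are on different chromosomes by definition.
    """

    breakA: GenomicRegion
    breakB: GenomicRegion
    geneA: str
    geneB: str
    source: str = ""

    def __post_init__(self):
        if self.breakA.chrom == self.breakB.chrom:
            raise ValueError(
                "ICT breakpoints must be on different chromosomes, "
                f"both on {self.breakA.chrom}"
            )


@dataclass(frozen=True)
class SVRecord:
    """A structural variant; breakpoints are ``region.start`` and ``region.end``."""

    region: GenomicRegion
    sv_type: str
    frequency: float
    variant_id: str = ""

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}; expected one of {sorted(SV_TYPES)}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency must be in [0,1], got {self.frequency}")

    @property
    def length(self) -> int:
        return self.region.length


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide variant; ``pos`` is stored 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tissues: frozenset = frozenset()
    is_cancer_related: bool = False
    variant_id: str = ""

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if not self.ref or not self.alt:
            raise ValueError("ref/alt alleles must be nonempty")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its body, CDS intervals and splice-site coordinates.

    Splice sites are exon–intron junction coordinates: for a multi-exon
    gene they are every internal exon end and internal exon start (the
    transcript termini are not splice sites).
    """

    gene_id: str
    region: GenomicRegion
    strand: str = "+"
    cds_intervals: tuple = ()
    splice_sites: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for cds in self.cds_intervals:
            if not self.region.contains_region(cds):
                raise ValueError(f"CDS {cds} outside gene body {self.region}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _lines(path) -> Iterator[tuple[int, str]]:
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_regions(path, format: str = "BED"):
    """Read genomic intervals from BED, BEDPE or a generic TSV.

    Returns, in input order:

    * ``BED``   — ``list[GenomicRegion]`` (columns beyond 3 ignored);
    * ``BEDPE`` — ``list[(GenomicRegion, GenomicRegion, extra_fields)]``;
    * ``TSV``   — ``list[list[str]]`` of raw fields (header line allowed,
      detected by a non-integer second column).

    Coordinates come back 0-based half-open; an unparseable line raises
    :class:`ParseError` naming the line.
    """
    fmt = format.upper()
    if fmt not in ("BED", "BEDPE", "TSV"):
        raise ValueError(f"unknown format {format!r}")
    out = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if fmt == "TSV":
            out.append(fields)
            continue
        try:
            if fmt == "BED":
                out.append(GenomicRegion(fields[0], int(fields[1]), int(fields[2])))
            else:  # BEDPE
                a = GenomicRegion(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicRegion(fields[3], int(fields[4]), int(fields[5]))
                out.append((a, b, tuple(fields[6:])))
        except (IndexError, ValueError) as exc:
            raise ParseError(path, lineno, f"malformed {fmt} line: {exc}") from exc
    return out


def write_bed(regions: Iterable[GenomicRegion], path, extra: Sequence[Sequence] | None = None):
    """Write BED3 (+ optional extra columns); round-trips coordinates exactly."""
    regions = list(regions)
    with open(path, "wt") as fh:
        for i, r in enumerate(regions):
            cols = [r.chrom, str(r.start), str(r.end)]
            if extra is not None:
                cols += [str(x) for x in extra[i]]
            fh.write("\t".join(cols) + "\n")


def write_bedpe(pairs, path):
    """Write BEDPE rows; each item is ``(regionA, regionB, extra_fields)``."""
    with open(path, "wt") as fh:
        for a, b, extra in pairs:
            cols = [a.chrom, str(a.start), str(a.end), b.chrom, str(b.start), str(b.end)]
            cols += [str(x) for x in extra]
            fh.write("\t".join(cols) + "\n")


def _maybe_header(fields: list[str], int_cols: Sequence[int]) -> bool:
    try:
        for c in int_cols:
            int(fields[c])
        return False
    except (ValueError, IndexError):
        return True


def read_sv_table(path) -> list[SVRecord]:
    """Read SVs from a TSV: ``chrom  start  end  type  frequency`` (0-based)."""
    out = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if not out and _maybe_header(f, (1, 2)):
            continue
        try:
            out.append(
                SVRecord(
                    region=GenomicRegion(f[0], int(f[1]), int(f[2])),
                    sv_type=f[3],
                    frequency=float(f[4]),
                    variant_id=f[5] if len(f) > 5 else f"sv_{lineno}",
                )
            )
        except (IndexError, ValueError) as exc:
            raise ParseError(path, lineno, f"malformed SV line: {exc}") from exc
    return out


def read_ict_table(path) -> list[ICTRecord]:
    """Read ICTs from a TSV: ``chromA posA chromB posB geneA geneB source``.

    Positions are 1-based single-base breakpoints in the file; stored as
    1-bp half-open regions.
    """
    out = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if not out and _maybe_header(f, (1, 3)):
            continue
        try:
            pa, pb = int(f[1]) - 1, int(f[3]) - 1
            out.append(
                ICTRecord(
                    breakA=GenomicRegion(f[0], pa, pa + 1),
                    breakB=GenomicRegion(f[2], pb, pb + 1),
                    geneA=f[4],
                    geneB=f[5],
                    source=f[6] if len(f) > 6 else "",
                )
            )
        except (IndexError, ValueError) as exc:
            raise ParseError(path, lineno, f"malformed ICT line: {exc}") from exc
    return out


def read_snp_table(path) -> list[SNPRecord]:
    """Read SNPs from a TSV: ``chrom pos ref alt tissues cancer_related``.

    ``pos`` is 1-based in the file (VCF-style) and stored 0-based;
    ``tissues`` is a semicolon-separated tag list (may be empty).
    """
    out = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        if not out and _maybe_header(f, (1,)):
            continue
        try:
            tissues = frozenset(t for t in f[4].split(";") if t) if len(f) > 4 else frozenset()
            out.append(
                SNPRecord(
                    chrom=f[0],
                    pos=int(f[1]) - 1,
                    ref=f[2],
                    alt=f[3],
                    tissues=tissues,
                    is_cancer_related=(len(f) > 5 and f[5].lower() in ("1", "true", "yes")),
                    variant_id=f[6] if len(f) > 6 else f"snp_{lineno}",
                )
            )
        except (IndexError, ValueError) as exc:
            raise ParseError(path, lineno, f"malformed SNP line: {exc}") from exc
    return out


def read_snp_vcf(path) -> list[SNPRecord]:
    """Read sites from a VCF (plain or gzipped) into SNP records.

    Uses pysam; only CHROM/POS/ID/REF/ALT are consumed.  POS is 1-based in
    VCF and stored 0-based.  Multi-allelic sites yield one record per ALT.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            for alt in rec.alts or ():
                out.append(
                    SNPRecord(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alt=alt,
                        variant_id=rec.id or f"{rec.chrom}_{rec.pos}",
                    )
                )
    return out


def read_gene_models_bed12(path) -> list[GeneModel]:
    """Read gene models from BED12.

    Exons come from the block columns; CDS intervals are exons intersected
    with ``[thickStart, thickEnd)``; splice sites are internal exon junction
    coordinates.
    """
    out = []
    for lineno, line in _lines(path):
        f = line.split("\t")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            nblocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != nblocks or len(offsets) != nblocks:
                raise ValueError("block count mismatch")
        except (IndexError, ValueError) as exc:
            raise ParseError(path, lineno, f"malformed BED12 line: {exc}") from exc
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        cds = []
        for es, ee in exons:
            cs, ce = max(es, thick_s), min(ee, thick_e)
            if cs < ce:
                cds.append(GenomicRegion(chrom, cs, ce))
        splice = []
        for i, (es, ee) in enumerate(exons):
            if i > 0:
                splice.append(es)
            if i < len(exons) - 1:
                splice.append(ee)
        out.append(
            GeneModel(
                gene_id=name,
                region=GenomicRegion(chrom, start, end),
                strand=strand,
                cds_intervals=tuple(cds),
                splice_sites=tuple(sorted(splice)),
            )
        )
    return out


def write_gene_models_bed12(genes: Iterable[GeneModel], path):
    """Write gene models as BED12, reconstructing blocks from CDS or the body."""
    with open(path, "wt") as fh:
        for g in genes:
            exons = _exons_from_model(g)
            thick_s = min((c.start for c in g.cds_intervals), default=g.region.start)
            thick_e = max((c.end for c in g.cds_intervals), default=g.region.start)
            sizes = ",".join(str(e - s) for s, e in exons)
            offs = ",".join(str(s - g.region.start) for s, _ in exons)
            fh.write(
                "\t".join(
                    [
                        g.region.chrom,
                        str(g.region.start),
                        str(g.region.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(thick_s),
                        str(thick_e),
                        "0",
                        str(len(exons)),
                        sizes,
                        offs,
                    ]
                )
                + "\n"
            )


def _exons_from_model(g: GeneModel) -> list[tuple[int, int]]:
    # Reconstruct an exon chain whose internal junctions are the splice sites.
    cuts = sorted(set(g.splice_sites))
    edges = [g.region.start] + cuts + [g.region.end]
    exons = [(edges[i], edges[i + 1]) for i in range(0, len(edges) - 1, 2)]
    return exons or [(g.region.start, g.region.end)]


def overlap_fraction(query: Iterable[str], reference: Iterable[str]) -> float:
    """Fraction of query gene symbols present in the reference set.

    Symbols are compared case-insensitively (uppercased); the result is
    ``|query ∩ reference| / |query|`` in ``[0, 1]``.  An empty query is an
    error — the fraction is undefined.
    """
    q = {s.upper() for s in query}
    r = {s.upper() for s in reference}
    if not q:
        raise ValueError("overlap_fraction: query set is empty")
    if not r:
        raise ValueError("overlap_fraction: reference set is empty")
    return len(q & r) / len(q)
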