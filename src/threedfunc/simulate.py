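"""Deterministic synthetic fixtures for every input class.

The generators emulate the statistical structure the analysis assumes, at
toy scale (three ~2 Mb chromosomes, 60 insulation domains), with planted
ground truth so classifier and scorer output can be checked exactly:

* ``gen_hic`` — contact maps with power-law distance decay, a checkerboard
  A/B compartment factor, elevated within-domain (TAD) contact, planted
  loop peaks, a sparse inter-chromosomal background, and elevated blocks
  between designated fusion gene pairs;
* ``gen_expression`` — log-normal baseline expression for cancer and
  normal sample groups with planted differential genes;
* ``gen_variant_truth`` — ICT / SV / SNP tables placed at known positions
  relative to the planted compartments, domains and loop anchors, plus a
  variant–gene pair table whose EC values follow the exponential-decay
  curve with a small displaced (causal) fraction.

Every generator is a pure function of the configuration (including its
seed): the same config yields byte-identical fixture files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from threedfunc.core import (
    GenomicRegion,
    GeneModel,
    ICTRecord,
    SNPRecord,
    SVRecord,
    write_bed,
    write_bedpe,
    write_gene_models_bed12,
)
from threedfunc.hic import ContactStore
from threedfunc.layers import CompartmentTrack, Loop, TADSet

__all__ = [
    "SimulationConfig",
    "SimulationLayout",
    "build_layout",
    "gen_hic",
    "gen_expression",
    "gen_variant_truth",
    "write_fixture",
]

TISSUES = ("blood", "liver", "skin")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic genome, with study-scale defaults."""

    seed: int = 0
    chrom_sizes: tuple = (("chr1", 2_000_000), ("chr2", 2_000_000), ("chr3", 2_000_000))
    resolutions: tuple = (5_000, 25_000, 100_000)  # finest first; multiples of the finest
    decay_exponent: float = -1.0  # canonical interphase contact scaling
    compartment_block: int = 250_000
    compartment_strength: float = 2.0
    domain_size: int = 95_000
    boundary_width: int = 5_000
    tad_strength: float = 3.0
    loop_strength: float = 30.0
    noise_level: float = 0.05
    interchrom_level: float = 0.2
    interchrom_density: float = 0.05
    fusion_block_value: float = 5.0
    # expression
    n_genes: int = 300
    n_cancer: int = 20
    n_normal: int = 15
    log_mu_range: tuple = (1.0, 4.0)
    log_sigma: float = 0.25
    effect_size: float = 2.0  # planted log-scale shift
    frac_diff: float = 0.1
    # variant-gene pair curve
    n_pairs: int = 200
    curve_A: float = 0.9
    curve_tau: float = 0.5
    ic_max: float = 2.0
    ec_noise_sd: float = 0.02
    causal_fraction: float = 0.05
    displacement: float = 0.4

    def __post_init__(self):
        if any(n <= 0 for _, n in self.chrom_sizes):
            raise ValueError("chromosome sizes must be positive")
        f = self.resolutions[0]
        if any(r % f for r in self.resolutions):
            raise ValueError("coarser resolutions must be multiples of the finest")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in [0,1]")
        if not 0 <= self.frac_diff <= 1:
            raise ValueError("frac_diff must be in [0,1]")

    @property
    def chromsizes(self) -> dict:
        return dict(self.chrom_sizes)


# ---------------------------------------------------------------------------
# Layout: deterministic geometry shared by the Hi-C and variant generators
# ---------------------------------------------------------------------------

@dataclass
class SimulationLayout:
    compartments: list  # (GenomicRegion, label, eigen)
    domains: list
    boundaries: list
    loops: list  # Loop, 3 per chromosome
    loop_genes: dict  # loop_id -> GeneModel on anchorB
    fusion_genes: dict  # symbol -> GeneModel
    strong_fusion: tuple  # (symbolA, symbolB)
    weak_fusion: tuple

    def compartment_track(self) -> CompartmentTrack:
        return CompartmentTrack(self.compartments)

    def tad_set(self) -> TADSet:
        return TADSet(self.domains, self.boundaries)


def _make_gene(gene_id: str, chrom: str, start: int, length: int = 10_000) -> GeneModel:
    # Two-exon model: exon1 [s, s+2k), exon2 [s+6k, s+len); CDS trimmed inside.
    s, e = start, start + length
    cds = (GenomicRegion(chrom, s + 500, s + 2_000), GenomicRegion(chrom, s + 6_000, e - 1_000))
    return GeneModel(
        gene_id=gene_id,
        region=GenomicRegion(chrom, s, e),
        strand="+",
        cds_intervals=cds,
        splice_sites=(s + 2_000, s + 6_000),
    )


LOOP_DOMAIN_PAIRS = ((2, 6), (9, 13), (15, 19))


def build_layout(config: SimulationConfig) -> SimulationLayout:
    """Deterministic geometry: compartments, domains, loops, marker genes."""
    comps, domains, boundaries, loops = [], [], [], []
    loop_genes: dict[str, GeneModel] = {}
    f = config.resolutions[0]
    for chrom, size in config.chrom_sizes:
        # checkerboard compartments, A first
        pos = 0
        k = 0
        while pos < size:
            end = min(pos + config.compartment_block, size)
            label = "A" if k % 2 == 0 else "B"
            eigen = 1.0 if label == "A" else -1.0
            comps.append((GenomicRegion(chrom, pos, end), label, eigen))
            pos, k = end, k + 1
        # alternating domain / boundary tiling
        pos = 0
        chrom_domains = []
        while pos + config.domain_size <= size:
            chrom_domains.append(GenomicRegion(chrom, pos, pos + config.domain_size))
            pos += config.domain_size
            if pos + config.boundary_width <= size:
                boundaries.append(GenomicRegion(chrom, pos, pos + config.boundary_width))
                pos += config.boundary_width
            else:
                break
        domains.extend(chrom_domains)
        # three loops per chromosome between domain-center bins
        for li, (da, db) in enumerate(LOOP_DOMAIN_PAIRS):
            ca = (chrom_domains[da].start + chrom_domains[da].end) // 2 // f * f
            cb = (chrom_domains[db].start + chrom_domains[db].end) // 2 // f * f
            loop_id = f"{chrom}_loop{li}"
            loop = Loop(
                anchorA=GenomicRegion(chrom, ca, ca + f),
                anchorB=GenomicRegion(chrom, cb, cb + f),
                loop_id=loop_id,
            )
            loops.append(loop)
            loop_genes[loop_id] = _make_gene(f"GENE_{loop_id}", chrom, cb)
    fusion_genes = {
        "FUSA": _make_gene("FUSA", "chr1", 250_000, 15_000),
        "FUSB": _make_gene("FUSB", "chr2", 500_000, 15_000),
        "FUSC": _make_gene("FUSC", "chr2", 1_200_000, 15_000),
        "FUSD": _make_gene("FUSD", "chr3", 800_000, 15_000),
    }
    return SimulationLayout(
        compartments=comps,
        domains=domains,
        boundaries=boundaries,
        loops=loops,
        loop_genes=loop_genes,
        fusion_genes=fusion_genes,
        strong_fusion=("FUSA", "FUSB"),
        weak_fusion=("FUSC", "FUSD"),
    )


# ---------------------------------------------------------------------------
# Hi-C generator
# ---------------------------------------------------------------------------

def _aggregate(block: np.ndarray, fa: int, fb: int) -> np.ndarray:
    """Sum-pool a dense block by integer factors, padding the ragged edge."""
    na, nb = block.shape
    pa, pb = math.ceil(na / fa) * fa, math.ceil(nb / fb) * fb
    if (pa, pb) != (na, nb):
        padded = np.zeros((pa, pb))
        padded[:na, :nb] = block
        block = padded
    return block.reshape(pa // fa, fa, pb // fb, fb).sum(axis=(1, 3))


def gen_hic(config: SimulationConfig, layout: SimulationLayout | None = None) -> ContactStore:
    """Generate the multi-resolution contact store.

    At the finest resolution the intra-chromosomal contact between bins
    i and j is ``(|i-j|+1)^decay_exponent`` scaled up by the compartment
    factor when the bins share a checkerboard phase and by the TAD factor
    when they share a domain, plus symmetric non-negative noise; planted
    loop peaks are added on top.  Inter-chromosomal contact is a sparse
    uniform background plus elevated blocks between the strong fusion
    gene pair.  Coarser resolutions are sum-pooled from the finest.
    """
    layout = layout or build_layout(config)
    rng = np.random.default_rng([config.seed, 1])
    f = config.resolutions[0]
    chroms = [c for c, _ in config.chrom_sizes]
    sizes = config.chromsizes
    dense_f: dict[tuple, np.ndarray] = {}

    dom_by_chrom: dict[str, list[GenomicRegion]] = {}
    for d in layout.domains:
        dom_by_chrom.setdefault(d.chrom, []).append(d)

    for chrom in chroms:
        n = math.ceil(sizes[chrom] / f)
        starts = np.arange(n) * f
        phase = (starts // config.compartment_block) % 2
        dom_id = np.full(n, -1)
        for di, d in enumerate(dom_by_chrom.get(chrom, [])):
            dom_id[(starts >= d.start) & (starts < d.end)] = di
        dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) + 1
        m = dist.astype(float) ** config.decay_exponent
        m *= np.where(phase[:, None] == phase[None, :], config.compartment_strength, 1.0)
        same_dom = (dom_id[:, None] == dom_id[None, :]) & (dom_id[:, None] >= 0)
        m *= np.where(same_dom, config.tad_strength, 1.0)
        noise = rng.uniform(0, config.noise_level, (n, n))
        m += (noise + noise.T) / 2
        for loop in layout.loops:
            if loop.anchorA.chrom != chrom:
                continue
            a, b = loop.anchorA.start // f, loop.anchorB.start // f
            m[a, b] += config.loop_strength
            m[b, a] += config.loop_strength
        dense_f[(chrom, chrom)] = m

    for i, ca in enumerate(chroms):
        for cb in chroms[i + 1:]:
            na, nb = math.ceil(sizes[ca] / f), math.ceil(sizes[cb] / f)
            mask = rng.random((na, nb)) < config.interchrom_density
            vals = config.interchrom_level * rng.uniform(0.5, 1.5, (na, nb))
            m = np.where(mask, vals, 0.0)
            ga = layout.fusion_genes[layout.strong_fusion[0]]
            gb = layout.fusion_genes[layout.strong_fusion[1]]
            if (ga.region.chrom, gb.region.chrom) == (ca, cb):
                a0, a1 = ga.region.start // f, math.ceil(ga.region.end / f)
                b0, b1 = gb.region.start // f, math.ceil(gb.region.end / f)
                m[a0:a1, b0:b1] += config.fusion_block_value
            dense_f[(ca, cb)] = m

    dense_all = {f: dense_f}
    for res in config.resolutions[1:]:
        factor = res // f
        dense_all[res] = {k: _aggregate(v, factor, factor) for k, v in dense_f.items()}
    return ContactStore.from_dense(sizes, dense_all)


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

def gen_expression(config: SimulationConfig, gene_ids=None):
    """Log-normal expression matrix plus the planted-differential truth table.

    Each gene draws a log-scale baseline mean; cancer samples of planted
    genes are shifted by ±``effect_size`` on the log scale.  Returns
    ``(ExpressionMatrix, truth)`` where ``truth`` has columns
    ``gene, direction, effect`` (direction ``up``/``down``/``none``).
    """
    from threedfunc.expression import ExpressionMatrix

    rng = np.random.default_rng([config.seed, 2])
    if gene_ids is None:
        gene_ids = [f"BG{i:04d}" for i in range(config.n_genes)]
    n_genes = len(gene_ids)
    mu = rng.uniform(*config.log_mu_range, n_genes)
    n_diff = int(round(config.frac_diff * n_genes))
    diff_idx = rng.choice(n_genes, size=n_diff, replace=False)
    direction = np.zeros(n_genes)
    direction[diff_idx] = rng.choice([-1.0, 1.0], size=n_diff)

    cancer_cols = [f"cancer_{i:02d}" for i in range(config.n_cancer)]
    normal_cols = [f"normal_{i:02d}" for i in range(config.n_normal)]
    mu_cancer = mu + direction * config.effect_size
    C = rng.lognormal(mu_cancer[:, None], config.log_sigma, (n_genes, config.n_cancer))
    N = rng.lognormal(mu[:, None], config.log_sigma, (n_genes, config.n_normal))
    values = pd.DataFrame(
        np.hstack([C, N]), index=pd.Index(gene_ids, name="gene"), columns=cancer_cols + normal_cols
    )
    meta = pd.DataFrame(
        {
            "condition": ["cancer"] * config.n_cancer + ["normal"] * config.n_normal,
            "aliquot": [f"aliquot_{i:02d}" for i in range(config.n_cancer + config.n_normal)],
        },
        index=pd.Index(cancer_cols + normal_cols, name="sample"),
    )
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "direction": np.select([direction > 0, direction < 0], ["up", "down"], "none"),
            "effect": direction * config.effect_size,
        }
    )
    expr = ExpressionMatrix(values=values, meta=meta, value_kind="FPKM")
    return expr, truth


# ---------------------------------------------------------------------------
# Variant + truth generator
# ---------------------------------------------------------------------------

@dataclass
class VariantFixture:
    svs: list  # SVRecord, including records designed to fail the curation filters
    icts: list  # ICTRecord
    snps: list  # SNPRecord
    genes: list  # GeneModel: loop targets, fusion genes, dosage genes, decoys
    dosage_genes: list  # subset of genes: the dosage-sensitive input list
    sv_filter_truth: pd.DataFrame  # variant_id, retained
    compartment_truth: pd.DataFrame  # variant_id, category
    tad_truth: pd.DataFrame  # variant_id, category
    loop_pair_truth: pd.DataFrame  # snp_id, gene_id, loop_id
    loop_class_truth: pd.DataFrame  # loop_id, cancer_class, loop_type
    pairs: pd.DataFrame  # variant, gene, cell_line, EC, Ci, Ni
    causal_truth: pd.DataFrame  # pair_id, causal
    annotations: dict  # ctcf / enhancers / promoters region lists


def _comp_svs() -> list[tuple[str, GenomicRegion, str]]:
    # (variant_id, region, planted category) on the chr1 250-kb checkerboard.
    spans = {
        "sv_AA_1": (60_000, 560_001, "A-A"),
        "sv_AB_1": (100_000, 300_001, "A-B"),
        "sv_BA_1": (300_000, 510_001, "B-A"),
        "sv_BB_1": (260_000, 760_001, "B-B"),
        "sv_AA_2": (1_060_000, 1_560_001, "A-A"),
        "sv_AB_2": (1_100_000, 1_300_001, "A-B"),
        "sv_BA_2": (1_300_000, 1_510_001, "B-A"),
        "sv_BB_2": (1_260_000, 1_760_001, "B-B"),
    }
    return [(vid, GenomicRegion("chr1", s, e), cat) for vid, (s, e, cat) in spans.items()]


def _tad_svs() -> list[tuple[str, GenomicRegion, str]]:
    # chr2 tiling: domain k = [100k*k, 100k*k + 95k), boundary k follows it.
    spans = {
        "sv_intra": (310_000, 350_001, "intra-TAD"),
        "sv_intra_excl": (305_000, 385_001, "excluded"),
        "sv_inter1": (296_000, 330_001, "inter-TAD1"),
        "sv_inter2": (496_000, 597_001, "inter-TAD2"),
        "sv_inter3": (680_000, 710_001, "inter-TAD3"),
        "sv_inter3_excl": (610_000, 740_001, "excluded"),
    }
    return [(vid, GenomicRegion("chr2", s, e), cat) for vid, (s, e, cat) in spans.items()]


def gen_variant_truth(
    config: SimulationConfig,
    layout: SimulationLayout | None = None,
) -> VariantFixture:
    """Plant ICTs, SVs and SNPs with exact classifier truth, and build the
    variant–gene pair table for the scoring phase."""
    layout = layout or build_layout(config)
    rng = np.random.default_rng([config.seed, 3])
    f = config.resolutions[0]

    # --- SVs: compartment truth, TAD truth, and filter-failing records ----
    svs, comp_rows, tad_rows, filter_rows = [], [], [], []
    sv_types = ["deletion", "duplication", "copy_number_gain", "copy_number_loss"]
    for i, (vid, region, cat) in enumerate(_comp_svs()):
        svs.append(SVRecord(region, sv_types[i % 4], 0.05, vid))
        comp_rows.append({"variant_id": vid, "category": cat})
        filter_rows.append({"variant_id": vid, "retained": True})
    for i, (vid, region, cat) in enumerate(_tad_svs()):
        svs.append(SVRecord(region, sv_types[i % 4], 0.05, vid))
        tad_rows.append({"variant_id": vid, "category": cat})
        filter_rows.append({"variant_id": vid, "retained": True})
    for vid, region, freq in (
        ("sv_short", GenomicRegion("chr3", 100_000, 105_000), 0.05),
        ("sv_long", GenomicRegion("chr1", 0, 20_000_000), 0.05),
        ("sv_rare", GenomicRegion("chr3", 200_000, 250_000), 0.001),
    ):
        svs.append(SVRecord(region, "other", freq, vid))
        filter_rows.append({"variant_id": vid, "retained": False})

    # --- ICTs: recurrent fusion pairs ------------------------------------
    ga = layout.fusion_genes[layout.strong_fusion[0]]
    gb = layout.fusion_genes[layout.strong_fusion[1]]
    gc = layout.fusion_genes[layout.weak_fusion[0]]
    gd = layout.fusion_genes[layout.weak_fusion[1]]
    icts = []

    def _ict(gx: GeneModel, gy: GeneModel, offset: int, source: str) -> ICTRecord:
        pa = gx.region.start + offset
        pb = gy.region.start + offset
        return ICTRecord(
            breakA=GenomicRegion(gx.region.chrom, pa, pa + 1),
            breakB=GenomicRegion(gy.region.chrom, pb, pb + 1),
            geneA=gx.gene_id,
            geneB=gy.gene_id,
            source=source,
        )

    for k in range(11):  # 11 unique records -> count 11 (> 10: recurrent)
        icts.append(_ict(ga, gb, 100 * k, "srcA"))
    icts.append(_ict(ga, gb, 0, "srcA"))  # exact duplicate, removed by dedup
    for k in range(10):  # exactly 10: below the strict recurrence cut
        icts.append(_ict(gc, gd, 100 * k, "srcB"))
    singles = [("S1", "chr1", 1_800_000, "S2", "chr3", 50_000),
               ("S3", "chr2", 1_900_000, "S4", "chr3", 1_500_000)]
    single_genes = []
    for sa, ca, pa, sb, cb, pb in singles:
        gsa, gsb = _make_gene(sa, ca, pa), _make_gene(sb, cb, pb)
        single_genes += [gsa, gsb]
        icts.append(_ict(gsa, gsb, 0, "srcC"))

    # --- SNPs, loop annotations, loop truth -------------------------------
    snps, loop_pair_rows, loop_class_rows = [], [], []
    ctcf, enhancers, promoters = [], [], []
    alleles = ("A", "C", "G", "T")
    for chrom, _ in config.chrom_sizes:
        chrom_loops = [l for l in layout.loops if l.anchorA.chrom == chrom]
        for li, loop in enumerate(chrom_loops):
            gene = layout.loop_genes[loop.loop_id]
            center = (loop.anchorA.start + loop.anchorA.end) // 2
            if li == 0:
                # cancer SNPs from every tissue in the anchor: CSL; annotate E-P
                # (plus a CTCF peak on the same anchor: E-P must win).
                for ti, tissue in enumerate(TISSUES):
                    snp = SNPRecord(
                        chrom, center + ti, alleles[ti], alleles[(ti + 1) % 4],
                        tissues=frozenset({tissue}), is_cancer_related=True,
                        variant_id=f"snp_{loop.loop_id}_{tissue}",
                    )
                    snps.append(snp)
                    loop_pair_rows.append(
                        {"snp_id": snp.variant_id, "gene_id": gene.gene_id, "loop_id": loop.loop_id}
                    )
                enhancers.append(loop.anchorA)
                promoters.append(loop.anchorB)
                ctcf.append(loop.anchorA)
                loop_class_rows.append(
                    {"loop_id": loop.loop_id, "cancer_class": "CSL", "loop_type": "EP"}
                )
            elif li == 1:
                snp = SNPRecord(
                    chrom, center, "A", "G",
                    tissues=frozenset({TISSUES[0]}), is_cancer_related=True,
                    variant_id=f"snp_{loop.loop_id}_{TISSUES[0]}",
                )
                snps.append(snp)
                loop_pair_rows.append(
                    {"snp_id": snp.variant_id, "gene_id": gene.gene_id, "loop_id": loop.loop_id}
                )
                ctcf.append(loop.anchorB)
                loop_class_rows.append(
                    {"loop_id": loop.loop_id, "cancer_class": "OL", "loop_type": "CTCF"}
                )
            else:
                loop_class_rows.append(
                    {"loop_id": loop.loop_id, "cancer_class": "NSL", "loop_type": "other"}
                )
        # decoy SNP far from every planted anchor (domain 0 center)
        snps.append(
            SNPRecord(chrom, 45_000, "T", "C", variant_id=f"snp_decoy_{chrom}")
        )

    # --- dosage-sensitive genes inside compartment SVs --------------------
    dosage = [
        _make_gene("DOSE1", "chr1", 150_000),  # inside sv_AB_1 (switching)
        _make_gene("DOSE2", "chr1", 200_000),  # inside sv_AB_1 (switching)
        _make_gene("DOSE3", "chr1", 520_000),  # inside sv_AA_1 / sv_BB_1 (stable)
    ]

    genes = (
        list(layout.loop_genes.values())
        + list(layout.fusion_genes.values())
        + single_genes
        + dosage
    )

    # --- variant-gene pairs on the decay curve ----------------------------
    n = config.n_pairs
    ic = rng.uniform(0.0, config.ic_max, n)
    ec = config.curve_A * np.exp(-ic / config.curve_tau)
    ec = ec + rng.normal(0.0, config.ec_noise_sd, n)
    n_causal = int(round(config.causal_fraction * n))
    causal_idx = rng.choice(n, size=n_causal, replace=False)
    causal = np.zeros(n, dtype=bool)
    causal[causal_idx] = True
    for i in causal_idx:
        # displace toward whichever side has room, keeping EC inside (0, 1)
        ec[i] = ec[i] + config.displacement if ec[i] + config.displacement < 0.995 else ec[i] - config.displacement
    ec = np.clip(ec, 1e-4, 1 - 1e-4)
    gene_cycle = [g.gene_id for g in genes]
    pairs = pd.DataFrame(
        {
            "variant": [f"pair_{i:04d}" for i in range(n)],
            "gene": [gene_cycle[i % len(gene_cycle)] for i in range(n)],
            "cell_line": "CL1",
            "EC": ec,
            "Ci": ic,
            "Ni": 0.0,
        }
    )
    causal_truth = pd.DataFrame({"pair_id": pairs["variant"], "causal": causal})

    return VariantFixture(
        svs=svs,
        icts=icts,
        snps=snps,
        genes=genes,
        dosage_genes=dosage,
        sv_filter_truth=pd.DataFrame(filter_rows),
        compartment_truth=pd.DataFrame(comp_rows),
        tad_truth=pd.DataFrame(tad_rows),
        loop_pair_truth=pd.DataFrame(loop_pair_rows),
        loop_class_truth=pd.DataFrame(loop_class_rows),
        pairs=pairs,
        causal_truth=causal_truth,
        annotations={"ctcf": ctcf, "enhancers": enhancers, "promoters": promoters},
    )


# ---------------------------------------------------------------------------
# Fixture tree writer
# ---------------------------------------------------------------------------

def write_fixture(config: SimulationConfig, out_dir) -> dict:
    """Generate everything and write the on-disk fixture tree.

    Returns a dict of the paths written.  Same config -> byte-identical
    tree.
    """
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    layout = build_layout(config)
    store = gen_hic(config, layout)
    fixture = gen_variant_truth(config, layout)
    gene_ids = [g.gene_id for g in fixture.genes]
    filler = [f"BG{i:04d}" for i in range(max(0, config.n_genes - len(gene_ids)))]
    expr, expr_truth = gen_expression(config, gene_ids + filler)

    paths = {}
    paths["manifest"] = str(store.save(out / "hic"))

    write_bed(
        [r for r, _, _ in layout.compartments],
        out / "compartments.bed",
        extra=[(lab, eig) for _, lab, eig in layout.compartments],
    )
    write_bed(layout.domains, out / "tads.bed")
    write_bed(layout.boundaries, out / "boundaries.bed")
    write_bedpe(
        [
            (l.anchorA, l.anchorB, (";".join(sorted(l.tissues)), l.loop_id))
            for l in layout.loops
        ],
        out / "loops.bedpe",
    )
    for name in ("ctcf", "enhancers", "promoters"):
        write_bed(fixture.annotations[name], out / f"{name}.bed")
    write_gene_models_bed12(fixture.genes, out / "genes.bed12")
    write_bed([g.region for g in fixture.dosage_genes], out / "dosage_genes.bed",
              extra=[(g.gene_id,) for g in fixture.dosage_genes])

    with open(out / "svs.tsv", "wt") as fh:
        fh.write("chrom\tstart\tend\ttype\tfrequency\tvariant_id\n")
        for sv in fixture.svs:
            r = sv.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{sv.sv_type}\t{sv.frequency}\t{sv.variant_id}\n")
    with open(out / "icts.tsv", "wt") as fh:
        fh.write("chromA\tposA\tchromB\tposB\tgeneA\tgeneB\tsource\n")
        for ict in fixture.icts:
            fh.write(
                f"{ict.breakA.chrom}\t{ict.breakA.start + 1}\t{ict.breakB.chrom}\t"
                f"{ict.breakB.start + 1}\t{ict.geneA}\t{ict.geneB}\t{ict.source}\n"
            )
    with open(out / "snps.tsv", "wt") as fh:
        fh.write("chrom\tpos\tref\talt\ttissues\tcancer_related\tvariant_id\n")
        for s in fixture.snps:
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t{s.ref}\t{s.alt}\t{';'.join(sorted(s.tissues))}\t"
                f"{int(s.is_cancer_related)}\t{s.variant_id}\n"
            )

    expr.values.to_csv(out / "expression.tsv", sep="\t")
    expr.meta.to_csv(out / "samples.tsv", sep="\t")
    lengths = pd.Series({g.gene_id: g.region.length for g in fixture.genes}, name="length")
    lengths = lengths.reindex(expr.values.index).fillna(10_000).astype(int)
    lengths.rename_axis("gene").to_csv(out / "gene_lengths.tsv", sep="\t")
    fixture.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)

    fixture.sv_filter_truth.to_csv(out / "truth" / "sv_filter.tsv", sep="\t", index=False)
    fixture.compartment_truth.to_csv(out / "truth" / "compartment.tsv", sep="\t", index=False)
    fixture.tad_truth.to_csv(out / "truth" / "tad.tsv", sep="\t", index=False)
    fixture.loop_pair_truth.to_csv(out / "truth" / "loop_pairs.tsv", sep="\t", index=False)
    fixture.loop_class_truth.to_csv(out / "truth" / "loop_classes.tsv", sep="\t", index=False)
    fixture.causal_truth.to_csv(out / "truth" / "causal_pairs.tsv", sep="\t", index=False)
    expr_truth.to_csv(out / "truth" / "diff_genes.tsv", sep="\t", index=False)

    with open(out / "config.json", "wt") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True, default=list)
    paths["root"] = str(out)
    return paths
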