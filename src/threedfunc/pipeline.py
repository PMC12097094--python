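"""Staged analysis pipeline over a fixture/input tree.

Stages (each runnable standalone, each emitting a TSV or JSON):

``flexif``     fusion-pair flexible IF + strong/weak/none categories
``layers``     SV curation filters, compartment & TAD classification,
               SNP-to-loop mapping, loop type and cancer-status classes
``ec``         per-gene expression change
``fit``        per-cell-line exponential-decay fit of EC against IC
``score``      3DFunc scores, significance, ranks
``evaluate``   ranking quality against causal-pair truth

Every output file starts with a header comment carrying the tool version
and the hash of the run configuration, and a ``run_log.json`` records
parameters and input checksums.  Outputs are byte-deterministic for a
given input tree and configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

import threedfunc
from threedfunc.core import (
    GenomicRegion,
    read_gene_models_bed12,
    read_ict_table,
    read_snp_table,
    read_sv_table,
    read_regions,
)
from threedfunc.expression import ec_table, read_expression_tsv
from threedfunc.flexif import compute_flexible_if
from threedfunc.hic import ContactStore
from threedfunc.layers import (
    CompartmentTrack,
    TADSet,
    categorize_fusion_if,
    classify_compartment_disruption,
    classify_loop_cancer_status,
    classify_loop_type,
    classify_tad_disruption,
    count_dosage_sensitive,
    filter_svs,
    map_snp_to_loops,
    merge_fusion_pairs,
    read_loops_bedpe,
)
from threedfunc.scoring import (
    VariantGenePair,
    evaluate_ranking,
    fit_ec_ic,
    score_pairs,
    score_significance,
)

__all__ = ["RunConfig", "run_pipeline"]


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    t_strong: float = Field(0.5, gt=0, description="strong-interaction threshold on the flexible-IF scale")
    high_score: float = Field(0.9, gt=0, description="high-confidence score cut")
    filter_score: float = Field(0.5, gt=0, description="network-filter score cut")
    p_cutoff: float = Field(0.05, gt=0, lt=1)
    strict_asymmetric_extension: bool = False
    if_agg: str = Field("sum", pattern="^(sum|mean)$")
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"# threedfunc v{threedfunc.__version__} config={cfg.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig):
    with open(path, "wt") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def _write_json(obj, path: Path, cfg: RunConfig):
    payload = {"_tool": f"threedfunc v{threedfunc.__version__}", "_config": cfg.config_hash()}
    payload.update(obj)
    with open(path, "wt") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_flexif(fixture: Path, out: Path, cfg: RunConfig) -> Path:
    """Flexible IF and interaction category for each unique fusion pair."""
    store = ContactStore.load(_require(fixture / "hic" / "manifest.json"))
    icts = read_ict_table(_require(fixture / "icts.tsv"))
    genes = {g.gene_id.upper(): g for g in read_gene_models_bed12(_require(fixture / "genes.bed12"))}
    table, _ = merge_fusion_pairs(icts)
    rows = []
    for rec in table.itertuples(index=False):
        ga, gb = genes.get(rec.gene_a), genes.get(rec.gene_b)
        if ga is None or gb is None:
            continue
        res = compute_flexible_if(
            store, ga.region, gb.region,
            strict_asymmetric_extension=cfg.strict_asymmetric_extension,
            agg=cfg.if_agg,
        )
        rows.append(
            {
                "gene_a": rec.gene_a,
                "gene_b": rec.gene_b,
                "count": rec.count,
                "high_frequency": rec.high_frequency,
                "flexible_if": res.flexible_if,
                "category": categorize_fusion_if([res.flexible_if], t_strong=cfg.t_strong),
                **{k: v for k, v in res.as_row().items() if k not in ("region_a", "region_b")},
            }
        )
    out_path = out / "fusion_if.tsv"
    _write_tsv(pd.DataFrame(rows), out_path, cfg)
    return out_path


def stage_layers(fixture: Path, out: Path, cfg: RunConfig) -> dict:
    """SV filters + compartment/TAD classification + loop annotation."""
    svs = read_sv_table(_require(fixture / "svs.tsv"))
    track = CompartmentTrack.from_bed(_require(fixture / "compartments.bed"))
    tads = TADSet(
        read_regions(_require(fixture / "tads.bed"), "BED"),
        read_regions(_require(fixture / "boundaries.bed"), "BED"),
    )
    retained, drops = filter_svs(svs)
    rows = []
    comp_calls = []
    for sv in retained:
        comp = classify_compartment_disruption(sv, track)
        tad = classify_tad_disruption(sv, tads)
        comp_calls.append((sv.variant_id, comp.category))
        rows.append(
            {
                "variant_id": sv.variant_id,
                "chrom": sv.region.chrom,
                "start": sv.region.start,
                "end": sv.region.end,
                "compartment": comp.category,
                "left_transition_distance": comp.left_transition_distance,
                "right_transition_distance": comp.right_transition_distance,
                "tad": tad.category,
                "tad_raw": tad.raw_category,
            }
        )
    layers_path = out / "layers.tsv"
    _write_tsv(pd.DataFrame(rows), layers_path, cfg)

    genes = read_gene_models_bed12(fixture / "genes.bed12")
    dosage_rows = read_regions(fixture / "dosage_genes.bed", "TSV")
    dosage_ids = {r[3].upper() for r in dosage_rows}
    dosage_genes = [g for g in genes if g.gene_id.upper() in dosage_ids]
    dosage = count_dosage_sensitive(
        comp_calls, {sv.variant_id: sv for sv in retained}, dosage_genes
    )

    snps = read_snp_table(fixture / "snps.tsv")
    loops = read_loops_bedpe(fixture / "loops.bedpe")
    pair_rows = []
    for snp in snps:
        for s, g, loop in map_snp_to_loops(snp, genes, loops):
            pair_rows.append(
                {"snp_id": s.variant_id, "gene_id": g.gene_id, "loop_id": loop.loop_id}
            )
    pairs_path = out / "snp_gene_pairs.tsv"
    _write_tsv(pd.DataFrame(pair_rows, columns=["snp_id", "gene_id", "loop_id"]), pairs_path, cfg)

    cancer_by_tissue: dict[str, list] = {}
    tissues = set()
    for snp in snps:
        tissues |= snp.tissues
        if snp.is_cancer_related:
            for t in snp.tissues:
                cancer_by_tissue.setdefault(t, []).append(snp)
    tissues = sorted(tissues)
    ctcf = read_regions(fixture / "ctcf.bed", "BED")
    enh = read_regions(fixture / "enhancers.bed", "BED")
    prom = read_regions(fixture / "promoters.bed", "BED")
    loop_rows = []
    for loop in loops:
        loop_rows.append(
            {
                "loop_id": loop.loop_id,
                "cancer_class": classify_loop_cancer_status(loop, cancer_by_tissue, tissues),
                "loop_type": classify_loop_type(loop, ctcf, enh, prom),
            }
        )
    loops_path = out / "loops_annotated.tsv"
    _write_tsv(pd.DataFrame(loop_rows), loops_path, cfg)
    _write_json(
        {"sv_drops": drops, "n_retained": len(retained), "dosage_counts": dosage},
        out / "layers_summary.json",
        cfg,
    )
    return {
        "layers": layers_path,
        "snp_gene_pairs": pairs_path,
        "loops_annotated": loops_path,
    }


def stage_ec(fixture: Path, out: Path, cfg: RunConfig) -> Path:
    expr = read_expression_tsv(
        _require(fixture / "expression.tsv"), _require(fixture / "samples.tsv"), value_kind="FPKM"
    )
    ec = ec_table(expr)
    out_path = out / "ec.tsv"
    _write_tsv(ec.reset_index(), out_path, cfg)
    return out_path


def _read_pairs(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def stage_fit(fixture: Path, out: Path, cfg: RunConfig) -> Path:
    """Fit the decay model separately for each cell line."""
    df = _read_pairs(_require(fixture / "pairs.tsv"))
    models = {}
    for cell_line, grp in df.groupby("cell_line", sort=True):
        pairs = [
            VariantGenePair(r.variant, r.gene, r.EC, r.Ci, r.Ni, cell_line)
            for r in grp.itertuples(index=False)
        ]
        m = fit_ec_ic(pairs)
        models[cell_line] = {
            "A": m.A,
            "tau": m.tau,
            "rss": m.rss,
            "n_points": m.n_points,
            "converged": m.converged,
            "residual_sd": m.residual_sd,
        }
    out_path = out / "model.json"
    _write_json({"models": models}, out_path, cfg)
    return out_path


def stage_score(fixture: Path, out: Path, cfg: RunConfig) -> Path:
    from threedfunc.scoring import FitModel

    df = _read_pairs(_require(fixture / "pairs.tsv"))
    with open(_require(out / "model.json")) as fh:
        models = json.load(fh)["models"]
    all_rows = []
    for cell_line, grp in df.groupby("cell_line", sort=True):
        m = FitModel(**models[cell_line])
        pairs = [
            VariantGenePair(r.variant, r.gene, r.EC, r.Ci, r.Ni, cell_line)
            for r in grp.itertuples(index=False)
        ]
        scored = score_significance(score_pairs(m, pairs, force=True), m)
        for s in scored:
            p = s.pair
            all_rows.append(
                {
                    "variant": p.variant_id,
                    "gene": p.gene_id,
                    "cell_line": cell_line,
                    "EC": p.EC,
                    "Ci": p.Ci,
                    "Ni": p.Ni,
                    "IC": p.IC,
                    "expected_EC": s.expected_EC,
                    "score": s.score,
                    "signed_residual": s.signed_residual,
                    "p_value": s.p_value,
                    "rank": s.rank,
                    "top_decile": s.top_decile,
                    "high_score": s.score >= cfg.high_score and s.p_value < cfg.p_cutoff,
                }
            )
    out_path = out / "scored.tsv"
    _write_tsv(pd.DataFrame(all_rows), out_path, cfg)
    return out_path


def stage_evaluate(fixture: Path, out: Path, cfg: RunConfig) -> Path:
    from threedfunc.scoring import ScoredPair, VariantGenePair as VGP

    scored_df = pd.read_csv(out / "scored.tsv", sep="\t", comment="#")
    truth = pd.read_csv(_require(fixture / "truth" / "causal_pairs.tsv"), sep="\t")
    merged = scored_df.merge(truth, left_on="variant", right_on="pair_id", how="inner")
    scored = [
        ScoredPair(
            pair=VGP(r.variant, r.gene, r.EC, r.Ci, r.Ni, r.cell_line),
            expected_EC=r.expected_EC,
            score=r.score,
            signed_residual=r.signed_residual,
            p_value=r.p_value,
            rank=r.rank,
            top_decile=bool(r.top_decile),
        )
        for r in merged.itertuples(index=False)
    ]
    metrics = evaluate_ranking(scored, merged["causal"].tolist())
    out_path = out / "evaluate.json"
    _write_json(metrics, out_path, cfg)
    return out_path


STAGES = {
    "flexif": stage_flexif,
    "layers": stage_layers,
    "ec": stage_ec,
    "fit": stage_fit,
    "score": stage_score,
    "evaluate": stage_evaluate,
}
STAGE_ORDER = ("flexif", "layers", "ec", "fit", "score", "evaluate")


def run_pipeline(fixture_dir, out_dir, cfg: RunConfig | None = None, stages=STAGE_ORDER) -> dict:
    """Run the staged pipeline; returns a dict of output paths.

    A failing stage halts the run but leaves the outputs of completed
    stages in place.  ``run_log.json`` records the tool version, the
    configuration, and sha256 checksums of every input file consumed.
    """
    cfg = cfg or RunConfig()
    fixture, out = Path(fixture_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    for name in stages:
        results[name] = STAGES[name](fixture, out, cfg)
    inputs = {
        str(p.relative_to(fixture)): _sha256(p)
        for p in sorted(fixture.rglob("*"))
        if p.is_file()
    }
    _write_json(
        {
            "config": cfg.model_dump(),
            "stages": list(stages),
            "inputs": inputs,
        },
        out / "run_log.json",
        cfg,
    )
    return results
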