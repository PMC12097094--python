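"""Layer classifiers: SV filters, compartments, TADs, fusions, loops, SNPs."""

import numpy as np
import pytest

from threedfunc.core import GenomicRegion, GeneModel, ICTRecord, SNPRecord, SVRecord
from threedfunc.layers import (
    CompartmentTrack,
    Loop,
    TADSet,
    annotate_snp_coding,
    categorize_fusion_if,
    classify_compartment_disruption,
    classify_loop_cancer_status,
    classify_loop_type,
    classify_tad_disruption,
    count_dosage_sensitive,
    filter_svs,
    map_snp_to_loops,
    merge_fusion_pairs,
    snp_locus,
)
from threedfunc.simulate import SimulationConfig, build_layout, gen_variant_truth


def _sv(chrom, start, end, freq=0.05, vid="sv"):
    return SVRecord(GenomicRegion(chrom, start, end), "deletion", freq, vid)


class TestFilterSVs:
    def test_length_and_frequency_rules_combined(self):
        svs = [
            _sv("chr1", 0, 5_000),  # too short
            _sv("chr1", 0, 50_000),  # passes both
            _sv("chr1", 0, 20_000_000),  # too long
            _sv("chr1", 0, 50_000, freq=0.001),  # too rare
        ]
        retained, drops = filter_svs(svs)
        assert [sv.region.end for sv in retained] == [50_000]
        assert drops == {"length": 2, "frequency": 1}

    def test_length_bounds_inclusive(self):
        lo = _sv("chr1", 0, 10_000, freq=0.02)
        hi = _sv("chr1", 0, 10_000_000, freq=0.02)
        retained, _ = filter_svs([lo, hi])
        assert retained == [lo, hi]

    def test_frequency_bound_strict(self):
        at_cut = _sv("chr1", 0, 50_000, freq=0.01)
        retained, drops = filter_svs([at_cut])
        assert retained == [] and drops["frequency"] == 1

    def test_empty_input(self):
        assert filter_svs([]) == ([], {"length": 0, "frequency": 0})


@pytest.fixture
def checkerboard():
    # A [0,1000) B [1000,2000) A [2000,3000) with a gap [3000,4000) then B
    items = [
        (GenomicRegion("chr1", 0, 1_000), "A", 1.0),
        (GenomicRegion("chr1", 1_000, 2_000), "B", -1.0),
        (GenomicRegion("chr1", 2_000, 3_000), "A", 0.5),
        (GenomicRegion("chr1", 4_000, 5_000), "B", -0.5),
    ]
    return CompartmentTrack(items)


class TestCompartmentDisruption:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (100, 900, "A-A"),
            (100, 1_500, "A-B"),
            (1_100, 2_500, "B-A"),
            (1_100, 1_900, "B-B"),
        ],
    )
    def test_ordered_breakpoint_labels(self, checkerboard, start, end, expected):
        call = classify_compartment_disruption(_sv("chr1", start, end), checkerboard)
        assert call.category == expected

    def test_right_breakpoint_is_end_minus_one(self, checkerboard):
        # end exactly at the A->B transition: right breakpoint 999 is still A
        call = classify_compartment_disruption(_sv("chr1", 100, 1_000), checkerboard)
        assert call.category == "A-A"

    def test_gap_maps_to_unmapped(self, checkerboard):
        call = classify_compartment_disruption(_sv("chr1", 100, 3_500), checkerboard)
        assert call.category == "unmapped"
        assert call.left_label == "A" and call.right_label is None

    def test_transition_distances_reported(self, checkerboard):
        call = classify_compartment_disruption(_sv("chr1", 100, 1_500), checkerboard)
        assert call.left_transition_distance == 900  # |100 - 1000|
        assert call.right_transition_distance == 499  # |1499 - 1000|

    def test_invariant_to_interval_order(self, checkerboard):
        items = [
            (GenomicRegion("chr1", 2_000, 3_000), "A"),
            (GenomicRegion("chr1", 0, 1_000), "A"),
            (GenomicRegion("chr1", 1_000, 2_000), "B"),
        ]
        shuffled = CompartmentTrack(items)
        sv = _sv("chr1", 100, 1_500)
        assert classify_compartment_disruption(sv, shuffled).category == "A-B"

    def test_label_eigen_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CompartmentTrack([(GenomicRegion("chr1", 0, 1_000), "A", -2.0)])

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            CompartmentTrack(
                [
                    (GenomicRegion("chr1", 0, 1_000), "A"),
                    (GenomicRegion("chr1", 500, 1_500), "B"),
                ]
            )


@pytest.fixture
def tadset():
    # domains [0,1M) and [1.2M,2M); boundary [1M,1.2M)
    return TADSet(
        domains=[GenomicRegion("chr1", 0, 1_000_000), GenomicRegion("chr1", 1_200_000, 2_000_000)],
        boundaries=[GenomicRegion("chr1", 1_000_000, 1_200_000)],
    )


class TestTADDisruption:
    def test_intra_tad(self, tadset):
        call = classify_tad_disruption(_sv("chr1", 100_000, 300_000), tadset)
        assert call.category == "intra-TAD"
        assert call.local_tad_size == 1_000_000

    def test_inter_tad1_boundary_plus_domain(self, tadset):
        call = classify_tad_disruption(_sv("chr1", 1_050_000, 1_300_000), tadset)
        assert call.category == "inter-TAD1"

    def test_inter_tad2_both_in_boundaries(self, tadset):
        call = classify_tad_disruption(_sv("chr1", 1_010_000, 1_150_000), tadset)
        assert call.category == "inter-TAD2"

    def test_inter_tad3_two_domains_with_mean_size_exclusion(self, tadset):
        # mean domain size (1.0 Mb, 0.8 Mb) = 0.9 Mb; 50% = 450 kb
        ok = classify_tad_disruption(_sv("chr1", 900_000, 1_300_000), tadset)
        assert ok.category == "inter-TAD3" and ok.local_tad_size == 900_000
        too_big = classify_tad_disruption(_sv("chr1", 800_000, 1_300_000), tadset)
        assert too_big.category == "excluded" and too_big.raw_category == "inter-TAD3"

    def test_intra_tad_exclusion_uses_containing_domain(self, tadset):
        call = classify_tad_disruption(_sv("chr1", 100_000, 700_000), tadset)
        assert call.category == "excluded" and call.raw_category == "intra-TAD"

    def test_breakpoint_outside_layout_is_unmapped(self):
        tads = TADSet(domains=[GenomicRegion("chr1", 0, 1_000_000)])
        call = classify_tad_disruption(_sv("chr1", 500_000, 1_600_000), tads)
        assert call.category == "unmapped"


@pytest.fixture(scope="module")
def planted():
    config = SimulationConfig(seed=5)
    layout = build_layout(config)
    fixture = gen_variant_truth(config, layout)
    return layout, fixture


class TestPlantedTruthRecovery:
    """Classifier output must match the generator's planted labels exactly."""

    def test_compartment_checkerboard_recovery(self, planted):
        layout, fixture = planted
        track = layout.compartment_track()
        truth = dict(zip(fixture.compartment_truth.variant_id, fixture.compartment_truth.category))
        svs = {sv.variant_id: sv for sv in fixture.svs}
        for vid, expected in truth.items():
            assert classify_compartment_disruption(svs[vid], track).category == expected

    def test_tad_truth_recovery(self, planted):
        layout, fixture = planted
        tads = layout.tad_set()
        truth = dict(zip(fixture.tad_truth.variant_id, fixture.tad_truth.category))
        svs = {sv.variant_id: sv for sv in fixture.svs}
        for vid, expected in truth.items():
            assert classify_tad_disruption(svs[vid], tads).category == expected

    def test_categories_partition_classified_inputs(self, planted):
        layout, fixture = planted
        track, tads = layout.compartment_track(), layout.tad_set()
        retained, _ = filter_svs(fixture.svs)
        comp = [classify_compartment_disruption(sv, track).category for sv in retained]
        tad = [classify_tad_disruption(sv, tads).category for sv in retained]
        comp_classified = [c for c in comp if c != "unmapped"]
        assert all(c in {"A-A", "A-B", "B-A", "B-B"} for c in comp_classified)
        tad_classified = [t for t in tad if t not in ("unmapped", "excluded")]
        assert all(t in {"intra-TAD", "inter-TAD1", "inter-TAD2", "inter-TAD3"} for t in tad_classified)
        assert len(tad_classified) + tad.count("unmapped") + tad.count("excluded") == len(retained)


class TestFusionPairs:
    def _ict(self, ga, gb, off=0):
        return ICTRecord(
            breakA=GenomicRegion("chr1", 100 + off, 101 + off),
            breakB=GenomicRegion("chr2", 500 + off, 501 + off),
            geneA=ga,
            geneB=gb,
        )

    def test_dedup_then_count_with_strict_recurrence_cut(self):
        records = [self._ict("X", "Y", off=i) for i in range(11)]
        records.append(self._ict("X", "Y", off=0))  # exact duplicate
        table, skipped = merge_fusion_pairs(records)
        assert skipped == 0
        row = table.iloc[0]
        assert (row["gene_a"], row["gene_b"], row["count"]) == ("X", "Y", 11)
        assert bool(row["high_frequency"])

    def test_count_of_exactly_ten_is_not_high_frequency(self):
        records = [self._ict("X", "Y", off=i) for i in range(10)]
        table, _ = merge_fusion_pairs(records)
        assert table.iloc[0]["count"] == 10
        assert not bool(table.iloc[0].high_frequency)

    def test_pair_key_is_unordered_and_case_normalized(self):
        records = [self._ict("x", "Y"), self._ict("Y", "x", off=7)]
        table, _ = merge_fusion_pairs(records)
        assert len(table) == 1 and table.iloc[0]["count"] == 2

    def test_records_without_symbols_are_skipped(self):
        records = [self._ict("X", "Y"), self._ict("", "Y", off=3)]
        table, skipped = merge_fusion_pairs(records)
        assert skipped == 1 and table.iloc[0]["count"] == 1

    @pytest.mark.parametrize(
        "values,expected",
        [([0.0, 0.0], "none"), ([0.1, 0.3], "weak"), ([0.7, 0.7], "strong"), ([0.5], "strong")],
    )
    def test_interaction_categories(self, values, expected):
        assert categorize_fusion_if(values, t_strong=0.5) == expected

    def test_negative_if_rejected(self):
        with pytest.raises(ValueError):
            categorize_fusion_if([-0.1])


class TestDosageSensitive:
    def test_pairwise_counting(self):
        svs = {
            "switch": _sv("chr1", 100_000, 300_000, vid="switch"),
            "stable": _sv("chr1", 500_000, 700_000, vid="stable"),
        }
        genes = [
            GeneModel("G1", GenomicRegion("chr1", 150_000, 160_000)),
            GeneModel("G2", GenomicRegion("chr1", 200_000, 210_000)),
        ]
        calls = [("switch", "A-B"), ("stable", "A-A")]
        counts = count_dosage_sensitive(calls, svs, genes)
        assert counts["switching"] == 2 and counts["stable"] == 0
        assert counts["per_category"] == {"A-B": 2, "A-A": 0}

    def test_gene_overlapping_two_svs_counts_twice(self):
        svs = {
            "s1": _sv("chr1", 0, 200_000, vid="s1"),
            "s2": _sv("chr1", 100_000, 300_000, vid="s2"),
        }
        genes = [GeneModel("G", GenomicRegion("chr1", 150_000, 160_000))]
        counts = count_dosage_sensitive([("s1", "A-B"), ("s2", "B-A")], svs, genes)
        assert counts["switching"] == 2

    def test_empty_gene_set_gives_zeros(self):
        svs = {"s": _sv("chr1", 0, 200_000, vid="s")}
        counts = count_dosage_sensitive([("s", "A-A")], svs, [])
        assert counts["stable"] == 0 and counts["switching"] == 0


class TestSnpLoopMapping:
    def test_pair_emitted_through_loop(self):
        snp = SNPRecord("chr1", 10_500, "A", "G", variant_id="rs1")
        gene = GeneModel("G", GenomicRegion("chr1", 50_000, 60_000))
        loop = Loop(
            anchorA=GenomicRegion("chr1", 10_000, 11_000),
            anchorB=GenomicRegion("chr1", 55_000, 56_000),
        )
        pairs = map_snp_to_loops(snp, [gene], [loop])
        assert [(s.variant_id, g.gene_id, l) for s, g, l in pairs] == [("rs1", "G", loop)]

    def test_gene_side_required(self):
        snp = SNPRecord("chr1", 10_500, "A", "G")
        gene = GeneModel("G", GenomicRegion("chr1", 900_000, 910_000))
        loop = Loop(  # both anchors over the SNP locus, neither over the gene
            anchorA=GenomicRegion("chr1", 10_000, 10_400),
            anchorB=GenomicRegion("chr1", 10_600, 11_000),
        )
        assert map_snp_to_loops(snp, [gene], [loop]) == []

    def test_locus_clamps_at_chromosome_start(self):
        snp = SNPRecord("chr1", 300, "A", "G")
        assert snp_locus(snp) == GenomicRegion("chr1", 0, 1_301)

    def test_planted_loop_pairs_recovered_exactly(self):
        config = SimulationConfig(seed=5)
        layout = build_layout(config)
        fixture = gen_variant_truth(config, layout)
        loops = layout.loops
        observed = set()
        for snp in fixture.snps:
            for s, g, l in map_snp_to_loops(snp, fixture.genes, loops):
                observed.add((s.variant_id, g.gene_id, l.loop_id))
        expected = {
            (r.snp_id, r.gene_id, r.loop_id)
            for r in fixture.loop_pair_truth.itertuples(index=False)
        }
        assert observed == expected


class TestLoopClassification:
    def _loop(self):
        return Loop(
            anchorA=GenomicRegion("chr1", 1_000, 2_000),
            anchorB=GenomicRegion("chr1", 9_000, 10_000),
        )

    def test_cancer_status_three_ways(self):
        loop = self._loop()
        tissues = ["t1", "t2", "t3"]
        inside = lambda tissue: SNPRecord("chr1", 1_500, "A", "G", tissues=frozenset({tissue}))
        all_hit = {t: [inside(t)] for t in tissues}
        assert classify_loop_cancer_status(loop, all_hit, tissues) == "CSL"
        one_hit = {"t1": [inside("t1")]}
        assert classify_loop_cancer_status(loop, one_hit, tissues) == "OL"
        assert classify_loop_cancer_status(loop, {}, tissues) == "NSL"

    def test_cancer_status_classes_are_exclusive_and_exhaustive(self):
        rng = np.random.default_rng(9)
        tissues = ["t1", "t2"]
        for _ in range(50):
            loop = Loop(
                anchorA=GenomicRegion("chr1", int(rng.integers(0, 5_000)), int(rng.integers(5_000, 6_000))),
                anchorB=GenomicRegion("chr1", 8_000, 9_000),
            )
            snps = {
                t: [SNPRecord("chr1", int(rng.integers(0, 10_000)), "A", "G")]
                for t in tissues
                if rng.random() < 0.7
            }
            assert classify_loop_cancer_status(loop, snps, tissues) in {"CSL", "OL", "NSL"}

    def test_ep_priority_over_ctcf_on_triple_overlap(self):
        loop = self._loop()
        enhancers = [GenomicRegion("chr1", 1_200, 1_400)]
        promoters = [GenomicRegion("chr1", 9_200, 9_400)]
        ctcf = [GenomicRegion("chr1", 1_100, 1_900)]  # also under anchorA
        assert classify_loop_type(loop, ctcf, enhancers, promoters) == "EP"

    def test_ctcf_when_single_anchor_overlap(self):
        loop = self._loop()
        ctcf = [GenomicRegion("chr1", 9_100, 9_200)]
        assert classify_loop_type(loop, ctcf, [], []) == "CTCF"

    def test_other_when_no_overlap(self):
        assert classify_loop_type(self._loop(), [], [], []) == "other"

    def test_enhancer_and_promoter_on_same_anchor_is_not_ep(self):
        loop = self._loop()
        enhancers = [GenomicRegion("chr1", 1_200, 1_300)]
        promoters = [GenomicRegion("chr1", 1_400, 1_500)]  # both on anchorA
        assert classify_loop_type(loop, [], enhancers, promoters) == "other"


class TestSnpCodingAnnotation:
    @pytest.fixture
    def gene(self):
        return GeneModel(
            "G",
            GenomicRegion("chr1", 1_000, 5_000),
            cds_intervals=(GenomicRegion("chr1", 1_200, 2_000),),
            splice_sites=(2_000, 3_000),
        )

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (1_500, "coding"),  # inside CDS
            (2_010, "coding"),  # exactly 10 bp from splice site: inclusive
            (3_011, "noncoding"),  # 11 bp away, outside CDS
            (4_500, "noncoding"),
            (10_000, "noncoding"),
        ],
    )
    def test_cds_or_near_splice_site(self, gene, pos, expected):
        snp = SNPRecord("chr1", pos, "A", "G")
        assert annotate_snp_coding(snp, [gene]) == expected

    def test_other_chromosome_ignored(self, gene):
        snp = SNPRecord("chr2", 1_500, "A", "G")
        assert annotate_snp_coding(snp, [gene]) == "noncoding"
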