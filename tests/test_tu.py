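"""Three-stage transcription-unit assembly."""

import numpy as np
import pytest

from tucast import InputError, InvariantError
from tucast.annotation import detect_overlap_links
from tucast.boundaries import detect_boundaries
from tucast.lmb import LMB_FINAL_TUS
from tucast.models import BoundaryCall, GeneModel, JunctionEvidence, OverlapLink
from tucast.quant import fpkm_from_coverage
from tucast.simulate import SimulationConfig, generate_annotation, generate_coverage
from tucast.tu import (
    assert_partition,
    label_units,
    partition_similarity,
    stage1_coupling_partition,
    stage2_boundary_fpkm_merge,
    stage2_decisions,
    stage3_junction_refine,
)

LMB_COUPLED_GROUPS = [
    ["lmbB1", "lmbB2"],
    ["lmbG", "lmbF"],
    ["lmbJ", "lmbIH"],
    ["lmbO", "lmbP", "lmbZ", "lmbN", "lmbM", "lmbL"],
    ["lmbR", "lmbS"],
    ["lmbV", "lmbT", "lmbQ"],
    ["lmbY", "lmbX"],
]


def _genes_run(n, strand="+", gap=100, length=300, contig="c"):
    genes, pos = [], 1
    for i in range(n):
        genes.append(GeneModel(f"g{i + 1}", contig, pos, pos + length - 1, strand))
        pos += length + gap
    return genes


class TestStage1:
    def test_cluster_fixture_groups(self, lmb, lmb_stages):
        s1 = lmb_stages[0]
        assert len(s1) == 17
        multi = [u for u in s1 if len(u) > 1]
        assert sorted(map(tuple, multi)) == sorted(map(tuple, LMB_COUPLED_GROUPS))
        singles = {u[0] for u in s1 if len(u) == 1}
        assert singles == {
            "lmrA", "lmbA", "lmbC", "lmbD", "lmbE", "lmbK", "lmbW", "lmbU",
            "lmrB", "lmrC",
        }

    def test_no_links_all_singletons(self):
        genes = _genes_run(5)
        assert stage1_coupling_partition(genes, []) == [[g.gene_id] for g in genes]

    def test_chain_transitivity(self):
        genes = _genes_run(4, gap=-4, length=300)  # consecutive 4-bp overlaps
        links = [
            OverlapLink(f"g{i}", f"g{i + 1}", 4, "ATGA", True) for i in (1, 2, 3)
        ]
        assert stage1_coupling_partition(genes, links) == [
            ["g1", "g2", "g3", "g4"]
        ]

    def test_unknown_gene_in_link_rejected(self):
        genes = _genes_run(2)
        with pytest.raises(InputError, match="unknown"):
            stage1_coupling_partition(
                genes, [OverlapLink("g1", "nope", 4, "ATGA", True)]
            )


class TestStage2:
    def test_cluster_fixture_seventeen_units(self, lmb_stages):
        s2 = lmb_stages[1]
        assert len(s2) == 17
        as_sets = [tuple(u) for u in s2]
        # the boundary/FPKM merge relocates the unit border inside the
        # lmbL..lmbO overlap chain and joins lmbS-R to lmbO-P-Z
        assert ("lmbN", "lmbM", "lmbL") in as_sets
        assert ("lmbR", "lmbS", "lmbO", "lmbP", "lmbZ") in as_sets
        # stage 2 keeps these apart; RT-PCR merges them only in stage 3
        assert ("lmbE",) in as_sets and ("lmbG", "lmbF") in as_sets
        assert ("lmbU",) in as_sets and ("lmbY", "lmbX") in as_sets

    def test_cluster_fixture_junction_reasons(self, lmb, lmb_stages):
        decisions = {
            (d.upstream_gene, d.downstream_gene): d
            for d in stage2_decisions(
                lmb_stages[0], lmb.genes, lmb.boundaries, lmb.fpkm
            )
        }
        assert decisions[("lmbA", "lmbB1")].split  # FPKM jump (also a TSS)
        assert decisions[("lmbA", "lmbB1")].reason == "fpkm_jump"
        d = decisions[("lmbF", "lmbE")]
        assert d.split and d.reason == "start_boundary"
        d = decisions[("lmbZ", "lmbN")]
        assert d.split and d.reason == "fpkm_jump_breaks_coupling"
        d = decisions[("lmbS", "lmbO")]
        assert not d.split and d.reason == "degressive_boundary_reassigned"
        d = decisions[("lmbU", "lmbY")]
        assert d.split and d.reason == "start_boundary"

    def test_nothing_forces_a_split(self):
        """Co-directional genes, no boundaries, uniform FPKM: one unit."""
        genes = _genes_run(4)
        s1 = stage1_coupling_partition(genes, [])
        fpkm = {g.gene_id: 50.0 for g in genes}
        assert stage2_boundary_fpkm_merge(s1, genes, [], fpkm) == [
            ["g1", "g2", "g3", "g4"]
        ]

    def test_strand_change_always_splits(self):
        genes = _genes_run(2) + [GeneModel("g3", "c", 900, 1199, "-")]
        fpkm = {"g1": 10.0, "g2": 10.0, "g3": 10.0}
        s2 = stage2_boundary_fpkm_merge(
            stage1_coupling_partition(genes, []), genes, [], fpkm
        )
        assert [len(u) for u in s2] == [2, 1]

    def test_exact_threshold_ratio_splits(self):
        genes = _genes_run(2)
        fpkm = {"g1": 10.0, "g2": 40.0}  # ratio exactly jump_factor
        s2 = stage2_boundary_fpkm_merge(
            stage1_coupling_partition(genes, []), genes, [], fpkm
        )
        assert s2 == [["g1"], ["g2"]]

    def test_missing_fpkm_rejected(self):
        genes = _genes_run(2)
        with pytest.raises(InputError, match="FPKM"):
            stage2_boundary_fpkm_merge(
                stage1_coupling_partition(genes, []), genes, [], {"g1": 1.0}
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_junction_evaluator(self, seed):
        """For small uncoupled gene sets, the staged merge equals a
        junction-by-junction evaluator written from the rules directly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        genes, pos = [], 1
        for i in range(n):
            strand = "+" if rng.random() < 0.7 else "-"
            genes.append(GeneModel(f"g{i + 1}", "c", pos, pos + 299, strand))
            pos += 400
        fpkm = {g.gene_id: float(rng.uniform(1, 100)) for g in genes}
        boundaries = []
        for g in genes:
            if rng.random() < 0.4:
                p = g.start - 50 if g.strand == "+" else g.end + 50
                boundaries.append(BoundaryCall(p, g.strand, "TSS"))

        # independent oracle over adjacent pairs
        def expect_split(left, right):
            if left.strand != right.strand:
                return True
            up, down = (left, right) if left.strand == "+" else (right, left)
            if fpkm[down.gene_id] >= 4.0 * fpkm[up.gene_id]:
                return True
            for b in boundaries:
                if b.strand != down.strand:
                    continue
                in_gap = (
                    up.end < b.position <= down.start + 25
                    if down.strand == "+"
                    else down.end - 25 <= b.position < up.start
                )
                if in_gap:
                    return True
            return False

        expected, unit = [], [genes[0].gene_id]
        for left, right in zip(genes, genes[1:]):
            if expect_split(left, right):
                expected.append(unit)
                unit = [right.gene_id]
            else:
                unit.append(right.gene_id)
        expected.append(unit)
        # transcription-order the expected units
        by_id = {g.gene_id: g for g in genes}
        expected = [
            u[::-1] if by_id[u[0]].strand == "-" else u for u in expected
        ]

        s2 = stage2_boundary_fpkm_merge(
            stage1_coupling_partition(genes, []), genes, boundaries, fpkm
        )
        assert s2 == expected


class TestStage3:
    def test_cluster_fixture_final_fifteen(self, lmb, lmb_stages):
        s3 = lmb_stages[2]
        assert len(s3) == 15
        assert sorted(map(tuple, s3)) == sorted(LMB_FINAL_TUS)

    def test_labeled_composition(self, lmb, lmb_stages):
        labeled = label_units(lmb_stages[2], lmb.genes)
        comp = {}
        for u in labeled:
            comp[u.cistron_class] = comp.get(u.cistron_class, 0) + 1
        assert comp == {"mono": 8, "bi": 2, "tri": 4, "penta": 1}
        assert [u.tu_id for u in labeled] == [f"TU{i}" for i in range(1, 16)]

    def test_empty_evidence_is_identity(self, lmb, lmb_stages):
        assert stage3_junction_refine(lmb_stages[1], lmb.genes, []) == lmb_stages[1]

    def test_idempotent_on_merged_junction(self, lmb, lmb_stages):
        s3 = lmb_stages[2]
        again = stage3_junction_refine(s3, lmb.genes, lmb.evidence)
        assert again == s3

    def test_undetected_evidence_never_splits(self, lmb, lmb_stages):
        undetected = [ev for ev in lmb.evidence if not ev.detected]
        assert stage3_junction_refine(lmb_stages[1], lmb.genes, undetected) == (
            lmb_stages[1]
        )

    def test_non_adjacent_pair_rejected(self, lmb, lmb_stages):
        with pytest.raises(InputError, match="adjacent"):
            stage3_junction_refine(
                lmb_stages[1], lmb.genes, [JunctionEvidence("lmbU", "lmbX", True)]
            )


class TestPartitionProperties:
    def test_every_stage_is_a_partition(self, lmb, lmb_stages):
        for stage in lmb_stages:
            assert_partition(lmb.genes, stage)  # raises on violation

    def test_mixed_strand_unit_rejected(self, lmb):
        bad = [[g.gene_id for g in lmb.genes]]
        with pytest.raises(InvariantError):
            assert_partition(lmb.genes, bad)

    @pytest.mark.parametrize("seed", range(6))
    def test_synthetic_recovery_is_exact(self, seed):
        """Planted units with clean boundaries are recovered exactly, and
        coupled links survive stages 2 and 3 untouched."""
        cfg = SimulationConfig(
            seed=seed,
            n_genes=20,
            tu_plan=(("+", 2), ("-", 3), ("+", 1), ("-", 2), ("+", 4), ("-", 1)),
            coverage_noise=False,
            n_up_noncluster=0,
            n_down_noncluster=0,
        )
        genome, genes, truth = generate_annotation(cfg)
        cov = generate_coverage(truth, cfg)
        links = detect_overlap_links(genes, genome)
        fpkm = fpkm_from_coverage(cov, genes)
        s1 = stage1_coupling_partition(genes, links)
        s2 = stage2_boundary_fpkm_merge(s1, genes, detect_boundaries(cov), fpkm)
        s3 = stage3_junction_refine(s2, genes, [])
        assert partition_similarity(genes, truth.true_tus, s3) == 1.0
        unit_of = {g: i for i, u in enumerate(s3) for g in u}
        for link in links:
            if link.coupled:
                assert unit_of[link.upstream_gene] == unit_of[link.downstream_gene]

    def test_boundary_dropout_degrades_similarity_monotonically(self):
        cfg = SimulationConfig(
            seed=5,
            n_genes=29,
            coverage_noise=False,
            n_up_noncluster=0,
            n_down_noncluster=0,
        )
        genome, genes, truth = generate_annotation(cfg)
        cov = generate_coverage(truth, cfg)
        links = detect_overlap_links(genes, genome)
        fpkm = fpkm_from_coverage(cov, genes)
        s1 = stage1_coupling_partition(genes, links)
        calls = detect_boundaries(cov)["cluster"]
        tss = [c for c in calls if c.kind == "TSS"]
        rng = np.random.default_rng(0)
        order = rng.permutation(len(tss))
        sims = []
        for n_drop in range(0, len(tss) + 1, 2):  # nested dropout sets
            dropped = set(order[:n_drop])
            kept = [c for i, c in enumerate(tss) if i not in dropped]
            s2 = stage2_boundary_fpkm_merge(s1, genes, kept, fpkm)
            sims.append(partition_similarity(genes, truth.true_tus, s2))
        assert sims[0] == 1.0
        assert all(a >= b for a, b in zip(sims, sims[1:]))
        assert sims[-1] < 1.0
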