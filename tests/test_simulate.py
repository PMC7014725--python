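"""Synthetic-data generator: layouts, determinism, planted effect sizes."""

import numpy as np
import pytest

from tucast.annotation import detect_overlap_links, read_annotation
from tucast.errors import ConfigError
from tucast.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_counts,
    generate_coverage,
    simulate_dataset,
    write_fixture_files,
)
from tucast.trackio import read_bedgraph_pair, read_boundaries_tsv


def _small(seed=0, **kw):
    defaults = dict(
        seed=seed,
        n_genes=10,
        tu_plan=(("+", 2), ("-", 3), ("+", 1)),
        n_up_noncluster=0,
        n_down_noncluster=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAnnotationLayout:
    def test_coupled_junctions_carry_stop_start_motifs(self):
        cfg = _small(seed=1, coupled_fraction=1.0)
        genome, genes, truth = generate_annotation(cfg)
        assert all(g.length % 3 == 0 for g in genes)
        cluster = [g for g in genes if g.contig == "cluster"]
        links = detect_overlap_links(cluster, genome)
        # every intra-unit junction is coupled; check the planted junctions
        n_expected = sum(k - 1 for _, k in cfg.tu_plan)
        assert len(links) == n_expected
        for link in links:
            assert link.overlap_bp in (4, 8)
            if link.overlap_bp == 4:
                assert link.junction_seq in ("ATGA", "GTGA")
            else:
                assert link.junction_seq.startswith(("ATG", "GTG"))
                assert link.junction_seq.endswith(("TGA", "TAA", "TAG"))

    def test_singleton_plan_has_no_links(self):
        cfg = _small(seed=2, n_genes=1, tu_plan=(("+", 1),))
        genome, genes, _ = generate_annotation(cfg)
        assert len(genes) == 1
        assert detect_overlap_links(genes, genome) == []

    def test_partition_property(self):
        _, genes, truth = generate_annotation(_small(seed=3, n_genes=16))
        flat = [g for unit in truth.true_tus for g in unit]
        assert sorted(flat) == sorted(g.gene_id for g in genes)
        assert len(flat) == len(set(flat))

    def test_determinism_byte_identical_files(self, tmp_path):
        cfg = _small(seed=4, n_genes=14)
        paths = []
        for run in ("a", "b"):
            ds = simulate_dataset(cfg)
            paths.append(write_fixture_files(ds, tmp_path / run))
        for key in ("fasta", "gff3", "counts", "bedgraph_plus", "bedgraph_minus"):
            a = open(paths[0][key], "rb").read()
            b = open(paths[1][key], "rb").read()
            assert a == b, f"{key} differs between identical runs"

    def test_infeasible_layout_rejected(self):
        with pytest.raises(ConfigError):
            _small(gene_len_bp=(6, 9))  # overlap would span a whole CDS
        with pytest.raises(ConfigError):
            _small(knockdown_range=(0.0, 50.0))
        with pytest.raises(ConfigError):
            _small(degression_factor=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(n_genes=5)  # fewer genes than the unit plan

    def test_files_roundtrip_through_readers(self, tmp_path):
        cfg = _small(seed=6, n_genes=12)
        ds = simulate_dataset(cfg)
        paths = write_fixture_files(ds, tmp_path)
        genes, genome = read_annotation(paths["gff3"], paths["fasta"])
        assert [g.gene_id for g in genes if g.contig == "cluster"] == [
            g.gene_id for g in ds.genes if g.contig == "cluster"
        ]
        cov = read_bedgraph_pair(
            paths["bedgraph_plus"],
            paths["bedgraph_minus"],
            {c: len(s) for c, s in genome.items()},
        )
        for contig in cov.contigs():
            np.testing.assert_allclose(
                cov.get(contig, "+"), ds.coverage.get(contig, "+"), rtol=1e-9
            )
        assert read_boundaries_tsv(paths["boundaries"]) == sorted(
            ds.boundaries, key=lambda b: (b.position, b.strand, b.kind)
        )


class TestCoverage:
    def test_noise_free_single_unit_is_exact_step(self):
        cfg = _small(seed=7, n_genes=1, tu_plan=(("+", 1),), expression_sigma=0.0)
        _, genes, truth = generate_annotation(cfg)
        cov = generate_coverage(truth, cfg)
        arr = cov.get("cluster", "+")
        g = genes[0]
        level = truth.true_fpkm[g.gene_id]
        assert (arr[g.start - 1 : g.end] == level).all()
        assert arr[: g.start - 1].sum() == 0 and arr[g.end :].sum() == 0

    def test_degression_halves_mean_coverage_gene_to_gene(self):
        from tucast.quant import per_gene_mean_coverage

        cfg = _small(
            seed=8,
            n_genes=3,
            tu_plan=(("+", 3),),
            degression_factor=0.5,
            expression_sigma=0.0,
            coupled_fraction=0.0,  # abutting genes, no overlap smearing
        )
        _, genes, truth = generate_annotation(cfg)
        cov = generate_coverage(truth, cfg)
        means = [per_gene_mean_coverage(cov, g) for g in genes]
        base = cfg.base_expression
        # geometric sequence: each downstream gene at half the level
        expected = [base, base / 2, base / 4]
        for m, e in zip(means, expected):
            assert m == pytest.approx(e, rel=1e-3)

    def test_empty_plan_all_zero(self):
        cfg = SimulationConfig(
            n_genes=0, tu_plan=(), n_up_noncluster=0, n_down_noncluster=0
        )
        _, genes, truth = generate_annotation(cfg)
        assert genes == []
        cov = generate_coverage(truth, cfg)
        assert cov.contigs() == []


class TestCounts:
    def test_knockdown_arithmetic_exact(self):
        """d = 93.71% on mean mu leaves mu * 0.0629 (629 for mu = 10000)."""
        assert round(10000 * (1 - 0.9371)) == 629
        cfg = _small(
            seed=9, noise=False, knockdown_range=(93.71, 93.71), expression_sigma=0.0
        )
        _, genes, truth = generate_annotation(cfg)
        orig = generate_counts(truth, cfg, "original")
        mut = generate_counts(truth, cfg, "deletion")
        by_id = {g.gene_id: g for g in genes}
        for gid in truth.cluster_genes:
            mu = truth.true_fpkm[gid] * by_id[gid].length * cfg.library_size / 1e9
            if gid == truth.deleted_gene:
                continue
            assert mut[gid] == round(mu * (1 - 0.9371))
            assert orig[gid] == round(mu)

    def test_deleted_gene_has_zero_reads(self):
        cfg = _small(seed=10)
        _, _, truth = generate_annotation(cfg)
        mut = generate_counts(truth, cfg, "deletion")
        assert mut[truth.deleted_gene] == 0
        assert generate_counts(truth, cfg, "original")[truth.deleted_gene] > 0

    def test_zero_dispersion_noise_off_rounds_means(self):
        cfg = _small(seed=12, dispersion=0.0, noise=False)
        _, genes, truth = generate_annotation(cfg)
        counts = generate_counts(truth, cfg, "original")
        by_id = {g.gene_id: g for g in genes}
        for gid, c in counts.items():
            mu = truth.true_fpkm[gid] * by_id[gid].length * cfg.library_size / 1e9
            assert c == round(mu)

    def test_effect_size_recovery_converges_to_midpoint(self):
        """Mean knockdown over genes and replicate seeds approaches the
        knockdown-range midpoint (96.845%)."""
        declines = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_up_noncluster=0, n_down_noncluster=0)
            _, _, truth = generate_annotation(cfg)
            orig = generate_counts(truth, cfg, "original")
            mut = generate_counts(truth, cfg, "deletion")
            for gid in truth.cluster_genes:
                if gid == truth.deleted_gene or orig[gid] == 0:
                    continue
                declines.append(100 * (1 - mut[gid] / orig[gid]))
        midpoint = (93.71 + 99.98) / 2
        assert np.mean(declines) == pytest.approx(midpoint, abs=0.5)
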