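import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from restcobind.cobinding import CobindClass
from restcobind.intervals import intervals_overlap, point_distance
from restcobind.simulate import (
    SiteSpec,
    SyntheticConfig,
    generate_annotation,
    generate_fixture,
    load_fixture,
    plant_sites,
    simulate_tags,
)

from conftest import small_synth_config


def tiny_config(seed=3, **overrides):
    spec = [
        SiteSpec("R+/S+/L+", "both", 20.0, True, 4.0),
        SiteSpec("R+/S+/L-", "ES-only", 20.0, True, 4.0),
        SiteSpec("R+/S-/L+", "EpiS-only", 20.0, False, 4.0),
        SiteSpec("R+/S-/L-", "both", 20.0, False, 4.0),
    ]
    base = dict(
        seed=seed,
        genome=[("chr1", 400_000)],
        n_coding_genes=20,
        n_noncoding_genes=0,
        n_intergenic_promoters=2,
        site_spec=spec,
        chip_depth=40_000,
        input_depth=40_000,
        tss_depth=40_000,
        mrna_depth=40_000,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def dir_digest(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(Path(path).rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


class TestAnnotation:
    def test_zero_genes_is_valid(self):
        layout, genes = generate_annotation(
            tiny_config(n_coding_genes=0, n_noncoding_genes=0)
        )
        assert genes == [] and layout.total_length == 400_000

    def test_gene_bodies_do_not_overlap(self):
        _, genes = generate_annotation(small_synth_config())
        ordered = sorted(genes, key=lambda g: (g.chrom, g.tx_start))
        for a, b in zip(ordered, ordered[1:]):
            if a.chrom == b.chrom:
                assert a.tx_end <= b.tx_start

    def test_deterministic(self):
        cfg = tiny_config()
        assert generate_annotation(cfg)[1] == generate_annotation(cfg)[1]

    def test_lengths_within_range(self):
        cfg = small_synth_config()
        _, genes = generate_annotation(cfg)
        lo, hi = cfg.gene_length_range
        assert all(lo <= g.length <= hi for g in genes)

    def test_impossible_placement_raises(self):
        with pytest.raises(ValueError):
            generate_annotation(
                tiny_config(genome=[("chr1", 30_000)], n_coding_genes=20)
            )


class TestPlanting:
    def test_truth_matches_blueprint(self):
        cfg = tiny_config()
        layout, genes = generate_annotation(cfg)
        truth = plant_sites(cfg, layout, genes)
        assert [(s.cobind.value, s.occupancy) for s in truth.sites] == [
            (sp.cobind, sp.occupancy) for sp in cfg.site_spec
        ]

    def test_sites_within_flank_of_host_gene(self):
        cfg = small_synth_config()
        layout, genes = generate_annotation(cfg)
        truth = plant_sites(cfg, layout, genes)
        by_id = {g.gene_id: g for g in genes}
        for s in truth.sites:
            host = by_id[s.gene_id]
            assert point_distance(s.interval, host.five_prime) <= 50_000

    def test_sites_disjoint(self):
        cfg = small_synth_config()
        layout, genes = generate_annotation(cfg)
        truth = plant_sites(cfg, layout, genes)
        ivs = [s.interval for s in truth.sites]
        for i, a in enumerate(ivs):
            for b in ivs[i + 1 :]:
                assert not intervals_overlap(a, b)

    def test_induced_sites_mark_host_genes(self):
        cfg = tiny_config()
        layout, genes = generate_annotation(cfg)
        truth = plant_sites(cfg, layout, genes)
        folds = truth.gene_expression.set_index("gene_id")["kd_fold"]
        for s in truth.sites:
            expected = s.induction_fold if s.induced else 1.0
            assert folds[s.gene_id] == pytest.approx(expected)


class TestTags:
    def test_depths_match_configuration(self):
        cfg = tiny_config()
        layout, genes = generate_annotation(cfg)
        truth = plant_sites(cfg, layout, genes)
        samples = simulate_tags(truth, cfg)
        assert len(samples["Rest_ES"]) == cfg.chip_depth
        assert len(samples["Input_EpiS"]) == cfg.input_depth
        assert len(samples["TSS_ES"]) == cfg.tss_depth
        assert len(samples["mRNA_ES_ctrl"]) == cfg.mrna_depth
        # knock-down library grows with the induced mass
        assert len(samples["mRNA_ES_restKD"]) > cfg.mrna_depth

    def test_factor_enrichment_respects_occupancy(self):
        cfg = tiny_config()
        layout, genes = generate_annotation(cfg)
        truth = plant_sites(cfg, layout, genes)
        samples = simulate_tags(truth, cfg)
        es_only = next(s for s in truth.sites if s.occupancy == "ES-only")
        iv = es_only.interval
        in_site = lambda frame: (
            (frame["chrom"] == iv.chrom)
            & (frame["pos5"] >= iv.start)
            & (frame["pos5"] < iv.end)
        ).sum()
        background = cfg.chip_depth * iv.length / 400_000
        assert in_site(samples["Rest_ES"]) > 5 * background
        assert in_site(samples["Rest_EpiS"]) < 5 * background

    def test_kd_count_ratio_concentrates_near_induction_fold(self):
        cfg = small_synth_config()
        layout, genes = generate_annotation(cfg)
        truth = plant_sites(cfg, layout, genes)
        samples = simulate_tags(truth, cfg)
        induced = {s.gene_id for s in truth.sites if s.induced}
        by_id = {g.gene_id: g for g in genes}
        checked = 0
        for gene_id in sorted(induced):
            g = by_id[gene_id]
            count = lambda frame: (
                (frame["pos5"] >= g.tx_start) & (frame["pos5"] < g.tx_end)
            ).sum()
            n_ctrl = count(samples["mRNA_ES_ctrl"])
            if n_ctrl < 200:  # ratio concentration needs adequate counts
                continue
            n_kd = count(samples["mRNA_ES_restKD"])
            assert 3.0 <= n_kd / n_ctrl <= 5.3
            checked += 1
        assert checked >= 3

    def test_flat_enrichment_is_null(self):
        spec = [SiteSpec("R+/S+/L+", "both", 1.0, False, 4.0)]
        cfg = tiny_config(site_spec=spec)
        layout, genes = generate_annotation(cfg)
        truth = plant_sites(cfg, layout, genes)
        samples = simulate_tags(truth, cfg)
        p = stats.ks_2samp(
            samples["Rest_ES"]["pos5"], samples["Input_ES"]["pos5"]
        ).pvalue
        assert p > 0.01


class TestFixtureIO:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = tiny_config(seed=9)
        generate_fixture(cfg, tmp_path / "a")
        generate_fixture(cfg, tmp_path / "b")
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_roundtrip_and_manifest(self, tmp_path):
        cfg = tiny_config(seed=4)
        truth, _ = generate_fixture(cfg, tmp_path / "fix")
        fix = load_fixture(tmp_path / "fix")
        assert fix.genes == truth.genes
        assert [s.site_id for s in fix.truth_sites] == [
            s.site_id for s in truth.sites
        ]
        assert [s.cobind for s in fix.truth_sites] == [
            s.cobind for s in truth.sites
        ]
        import json

        manifest = json.loads((tmp_path / "fix" / "manifest.json").read_text())
        assert manifest["seed"] == 4
        assert manifest["config_hash"] == cfg.config_hash()
        # hash changes iff config changes
        assert tiny_config(seed=5).config_hash() != cfg.config_hash()
        assert tiny_config(seed=4).config_hash() == cfg.config_hash()

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = tiny_config(seed=6)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
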