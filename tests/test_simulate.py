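"""Synthetic-data generator: determinism, truth-table structure, read sampling."""

import math
from pathlib import Path

import numpy as np
import pytest

from poolsnv import SimConfig, load_gene_models, make_genome, plant_variants
from poolsnv.simulate import (GenerationError, simulate_pool_reads, write_fasta,
                              write_fastq, write_gff3, write_sam,
                              write_truth_tsv, write_truth_vcf)


def _no_variants(cfg):
    return cfg.replace(n_variants_per_class={k: 0 for k in cfg.n_variants_per_class})


class TestGenome:
    def test_same_seed_byte_identical_outputs(self, tiny_config, tmp_path):
        for d in ("a", "b"):
            genome, models = make_genome(tiny_config)
            truth = plant_variants(genome, models, tiny_config)
            (tmp_path / d).mkdir()
            write_fasta(genome, tmp_path / d / "g.fa")
            write_gff3(models, genome, tmp_path / d / "g.gff3")
            write_truth_tsv(truth, tiny_config, tmp_path / d / "t.tsv")
            write_truth_vcf(truth, genome, tiny_config, tmp_path / d / "t.vcf")
        for name in ("g.fa", "g.gff3", "t.tsv", "t.vcf"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_no_genes_still_yields_genome(self, tiny_config):
        cfg = tiny_config.replace(genes_per_scaffold=0)
        genome, models = make_genome(cfg)
        assert models == []
        assert len(genome) == 1 and len(next(iter(genome.values()))) == cfg.scaffold_len

    def test_gene_count_matches_construction(self, tmp_path):
        cfg = SimConfig(seed=2, n_scaffolds=2, scaffold_len=11_000, genes_per_scaffold=3)
        genome, models = make_genome(cfg)
        assert len(models) == 6
        write_gff3(models, genome, tmp_path / "g.gff3")
        assert len(load_gene_models(tmp_path / "g.gff3")) == 6

    def test_oversized_gene_structure_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(scaffold_len=1000, genes_per_scaffold=2)


class TestPlanting:
    def test_empty_request_empty_truth(self, tiny_config):
        genome, models = make_genome(tiny_config)
        assert plant_variants(genome, models, _no_variants(tiny_config)) == []

    def test_class_counts_exact(self, tiny_config):
        genome, models = make_genome(tiny_config)
        truth = plant_variants(genome, models, tiny_config)
        want = dict(tiny_config.n_variants_per_class)
        want["clustered"] *= 2  # planted as pairs
        got = {}
        for t in truth:
            got[t.vclass] = got.get(t.vclass, 0) + 1
        assert got == {k: v for k, v in want.items() if v > 0}

    def test_fixed_differential_frequencies(self, tiny_config):
        cfg = tiny_config.replace(n_variants_per_class={"fixed_differential": 10})
        genome, models = make_genome(cfg)
        truth = plant_variants(genome, models, cfg)
        a, b = cfg.differential_pairs[0]
        assert len(truth) == 10
        for t in truth:
            assert t.per_pool_freq[a] == 1.0 and t.per_pool_freq[b] == 0.0
            assert set(t.per_pool_freq) == set(cfg.pools())
            assert t.ref_allele != t.alt_allele

    def test_clustered_pairs_within_window(self, tiny_config):
        cfg = tiny_config.replace(n_variants_per_class={"clustered": 5})
        genome, models = make_genome(cfg)
        truth = sorted(plant_variants(genome, models, cfg), key=lambda t: t.pos)
        assert len(truth) == 10
        gaps = [truth[i + 1].pos - truth[i].pos for i in range(0, 10, 2)]
        assert all(g <= 60 for g in gaps)

    def test_spacing_and_exonic_confinement(self, tiny_config):
        genome, models = make_genome(tiny_config)
        truth = plant_variants(genome, models, tiny_config)
        exonic = {(m.scaffold, p) for m in models for s, e in m.exons
                  for p in range(s, e + 1)}
        clustered = {(t.scaffold, t.pos) for t in truth if t.vclass == "clustered"}
        positions = sorted((t.scaffold, t.pos) for t in truth)
        for key in positions:
            assert key in exonic
        for (s1, p1), (s2, p2) in zip(positions, positions[1:]):
            if s1 == s2 and (s1, p1) not in clustered:
                assert p2 - p1 >= tiny_config.min_spacing

    def test_near_intron_class_is_junction_proximal(self, tiny_config):
        genome, models = make_genome(tiny_config)
        truth = plant_variants(genome, models, tiny_config)
        junctions = {m.scaffold: [j for j in m.junctions] for m in models}
        for t in truth:
            if t.vclass != "near_intron":
                continue
            d = min(abs(t.pos - j) for m in models if m.scaffold == t.scaffold
                    for j in m.junctions)
            assert d < 60

    def test_insufficient_space_raises(self):
        cfg = SimConfig(seed=3, n_scaffolds=1, scaffold_len=3000,
                        genes_per_scaffold=1,
                        n_variants_per_class={"shared_all": 500})
        genome, models = make_genome(cfg)
        with pytest.raises(GenerationError):
            plant_variants(genome, models, cfg)


class TestReads:
    def test_zero_depth_gives_empty_sam_body(self, tiny_config, tmp_path):
        cfg = _no_variants(tiny_config).replace(per_pool_depth=0.0)
        genome, models = make_genome(cfg)
        reads = simulate_pool_reads(genome, models, [], 1, cfg)
        assert reads == []
        write_sam(reads, genome, tmp_path / "empty.sam")
        lines = Path(tmp_path / "empty.sam").read_text().splitlines()
        assert all(l.startswith("@") for l in lines) and len(lines) >= 2

    def test_unknown_pool_rejected(self, tiny_config):
        genome, models = make_genome(tiny_config)
        with pytest.raises(ValueError):
            simulate_pool_reads(genome, models, [], 99, tiny_config)

    def test_fixed_site_all_reads_carry_alt(self, tiny_config):
        cfg = tiny_config.replace(
            error_rate=0.0, missing_rate=0.0,
            n_variants_per_class={"fixed_differential": 3})
        genome, models = make_genome(cfg)
        truth = plant_variants(genome, models, cfg)
        pool_fixed = cfg.differential_pairs[0][0]
        reads = simulate_pool_reads(genome, models, truth, pool_fixed, cfg)
        for t in truth:
            covering = [r for r in reads
                        if r.scaffold == t.scaffold
                        and r.pos <= t.pos < r.pos + cfg.read_len]
            assert covering
            for r in covering:
                assert r.seq[t.pos - r.pos] == t.alt_allele

    def test_het_site_alt_fraction_binomial(self, tiny_config):
        cfg = tiny_config.replace(
            per_pool_depth=100.0, error_rate=0.0, missing_rate=0.0,
            n_variants_per_class={"shared_all": 6})
        genome, models = make_genome(cfg)
        truth = plant_variants(genome, models, cfg)
        reads = simulate_pool_reads(genome, models, truth, 1, cfg)
        for t in truth:
            covering = [r.seq[t.pos - r.pos] for r in reads
                        if r.scaffold == t.scaffold
                        and r.pos <= t.pos < r.pos + cfg.read_len]
            n = len(covering)
            alt = sum(1 for b in covering if b == t.alt_allele)
            sd = math.sqrt(0.25 / n)
            assert abs(alt / n - 0.5) <= 3 * sd

    def test_mean_exon_coverage_near_target(self, tiny_config):
        cfg = _no_variants(tiny_config).replace(per_pool_depth=25.0)
        genome, models = make_genome(cfg)
        reads = simulate_pool_reads(genome, models, [], 1, cfg)
        exon_bp = sum(e - s + 1 for m in models for s, e in m.exons)
        mean_cov = len(reads) * cfg.read_len / exon_bp
        assert abs(mean_cov - 25.0) / 25.0 < 0.15

    def test_reads_confined_to_single_exons(self, tiny_config):
        genome, models = make_genome(tiny_config)
        truth = plant_variants(genome, models, tiny_config)
        reads = simulate_pool_reads(genome, models, truth, 2, tiny_config)
        exons = [(m.scaffold, s, e) for m in models for s, e in m.exons]
        for r in reads[::17]:
            ref_span = sum(ln for ln, op in _cigar_ops(r.cigar) if op in "MD")
            assert any(sc == r.scaffold and s <= r.pos and r.pos + ref_span - 1 <= e + 2
                       for sc, s, e in exons)

    def test_same_pool_seed_reproducible_different_seed_not(self, tiny_config):
        genome, models = make_genome(tiny_config)
        truth = plant_variants(genome, models, tiny_config)
        a = simulate_pool_reads(genome, models, truth, 1, tiny_config)
        b = simulate_pool_reads(genome, models, truth, 1, tiny_config)
        assert [(r.pos, r.seq) for r in a] == [(r.pos, r.seq) for r in b]
        cfg2 = tiny_config.replace(seed=tiny_config.seed + 1)
        genome2, models2 = make_genome(cfg2)
        c = simulate_pool_reads(genome2, models2, truth, 1, cfg2)
        assert [r.pos for r in a] != [r.pos for r in c]


def _cigar_ops(cigar):
    import re
    return [(int(n), op) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)]
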