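"""End-to-end synthetic pipeline: simulate → clean → call → annotate →
diversity → select-panel, with all intermediate files written to an output
directory.  Deterministic for a fixed configuration seed."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import calling, diversity, genemodels, markers, readqc, simulate


@dataclass
class PipelineResult:
    config: simulate.SimConfig
    outdir: Path
    genome: dict[str, str]
    models: list[genemodels.GeneModel]
    truth: list[simulate.TruthRecord]
    qc_reports: dict[int, readqc.QcReport]
    profiles: list[calling.PoolProfile]
    records: list[calling.VariantRecord]
    gene_index: genemodels.GeneIndex
    coverage_mask: genemodels.CoverageMask
    feature_report: genemodels.FeatureDensityReport
    summary: diversity.DiversitySummary
    pair_matrix: pd.DataFrame
    filter_counts: pd.DataFrame
    panel: list[calling.VariantRecord]


def default_panel_criteria(config: simulate.SimConfig) -> markers.PanelCriteria:
    """Fixed-difference panel between the first configured differential pool
    pair, monomorphic within one unrelated pool."""
    a, b = config.differential_pairs[0]
    others = [p for p in config.pools() if p not in (a, b)]
    return markers.PanelCriteria(
        monomorphic_within=(others[0],) if others else (),
        polymorphic_between=((a, b),),
        cs60_maf_t=None,
        n_select=24,
        seed=config.seed,
    )


def run_pipeline(config: simulate.SimConfig, outdir: str | Path,
                 call_params: calling.CallParams = calling.CallParams(),
                 clean_params: readqc.CleanParams = readqc.CleanParams(),
                 panel_criteria: markers.PanelCriteria | None = None,
                 cs60_thresholds: Sequence[float | None] = (None, 0.99, 0.95, 0.7),
                 ) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # simulate
    genome, models = simulate.make_genome(config)
    simulate.write_fasta(genome, outdir / "genome.fa")
    simulate.write_gff3(models, genome, outdir / "genes.gff3")
    truth = simulate.plant_variants(genome, models, config)
    simulate.write_truth_tsv(truth, config, outdir / "truth.tsv")
    simulate.write_truth_vcf(truth, genome, config, outdir / "truth.vcf")

    qc_reports: dict[int, readqc.QcReport] = {}
    profiles: list[calling.PoolProfile] = []
    for pool in config.pools():
        reads = simulate.simulate_pool_reads(genome, models, truth, pool, config)
        sam = outdir / f"pool{pool}.sam"
        fq = outdir / f"pool{pool}.fastq"
        simulate.write_sam(reads, genome, sam)
        simulate.write_fastq(reads, fq)

        # clean (the FASTQ mirror of the aligned reads)
        qc_reports[pool] = readqc.clean_fastq(
            fq, outdir / f"pool{pool}.clean.fastq", clean_params,
            outdir / f"pool{pool}.qc.tsv")

        # call
        profiles.append(calling.pool_profile(pool, sam, genome, call_params))

    records = calling.merge_pool_calls(profiles)
    calling.write_vcf(records, genome, config.pools(), outdir / "variants.vcf")
    calling.records_to_table(records, config.pools()).to_csv(
        outdir / "variants.tsv", sep="\t", index=False)

    # annotate
    index = genemodels.GeneIndex(models)
    mask = calling.build_coverage_mask(profiles, {k: len(v) for k, v in genome.items()})
    feature_report = genemodels.gene_summary(
        [r.key for r in records], models, mask)

    # diversity
    summary = diversity.summarize_pools(records, profiles)
    summary.table.to_csv(outdir / "pool_summary.tsv", sep="\t", index=False)
    summary.histograms.to_csv(outdir / "maf_histograms.tsv", sep="\t", index=False)
    pair = diversity.pairwise_matrix(records, config.pools())
    pair.to_csv(outdir / "pairwise_matrix.tsv", sep="\t")

    # marker filters and panel
    filter_counts = markers.filter_table(records, index, cs60_thresholds,
                                         pools=config.pools())
    filter_counts.to_csv(outdir / "filter_counts.tsv", sep="\t", index=False)
    criteria = panel_criteria or default_panel_criteria(config)
    panel = markers.select_panel(records, index, criteria)
    markers.panel_table(panel, config.pools()).to_csv(
        outdir / "panel.tsv", sep="\t", index=False)

    return PipelineResult(config, outdir, genome, models, truth, qc_reports,
                          profiles, records, index, mask, feature_report,
                          summary, pair, filter_counts, panel)
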