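"""End-to-end orchestration: preprocess -> profiling -> site tests -> DMRs ->
methylation-expression correlation, with all result tables written as TSV."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import correlation, diffmeth, dmr, io, preprocess, profiling
from .config import CorrelationConfig, DmrConfig, SimConfig
from .synthetic import StudyBundle, simulate_study

log = logging.getLogger("endomethyl")


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    max_gap: int = 500
    min_cpgs: int = 3
    delta_beta_threshold: float = 0.1
    n_permutations: int = 10_000
    m_offset: float = 1.0
    max_fail_frac: float = 0.05
    adjust_age: bool = True
    seed: int = 0

    def dmr_config(self) -> DmrConfig:
        return DmrConfig(min_cpgs=self.min_cpgs, max_gap=self.max_gap,
                         alpha=self.alpha).validate()

    def correlation_config(self) -> CorrelationConfig:
        return CorrelationConfig(delta_beta_threshold=self.delta_beta_threshold,
                                 alpha=self.alpha,
                                 n_permutations=self.n_permutations,
                                 seed=self.seed).validate()


@dataclass
class PipelineResult:
    beta: pd.DataFrame
    m_values: pd.DataFrame
    filter_report: preprocess.FilterReport
    state_fractions: pd.Series
    state_table: pd.DataFrame
    consensus: diffmeth.ConsensusSet
    site_table: pd.DataFrame
    moderation: diffmeth.ModerationParams
    diffs: diffmeth.PairedDiffs
    dmrs: pd.DataFrame
    enrichment: dict = field(default_factory=dict)
    clustering: profiling.ClusteringResult | None = None
    correlation_records: pd.DataFrame | None = None
    region_medians: pd.DataFrame | None = None
    table1: pd.DataFrame | None = None
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(bundle: StudyBundle, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run every stage on an in-memory study bundle."""
    config = config or PipelineConfig()
    counts = {}

    log.info("preprocess: scaling normalization and beta/M computation")
    m_scaled, u_scaled, _ = preprocess.scale_normalize(
        bundle.m_intensity, bundle.u_intensity)
    beta = preprocess.compute_beta(m_scaled, u_scaled)
    m_values = preprocess.compute_m(m_scaled, u_scaled, offset=config.m_offset)
    beta, m_values, report = preprocess.filter_probes(
        beta, m_values, bundle.manifest,
        detection_fail=bundle.detection_fail,
        max_fail_frac=config.max_fail_frac)
    for line in report.log_lines():
        log.info(line)
    counts["probes_initial"] = report.n_initial
    counts["probes_tested"] = report.n_remaining

    log.info("profiling: methylation states and category distributions")
    state_table, state_fractions = profiling.classify_states(beta, bundle.sheet)

    log.info("diffmeth: paired differences and three site-level tests")
    diffs = diffmeth.paired_differences(m_values, beta, bundle.sheet)
    consensus, site_table, params = diffmeth.run_site_tests(
        diffs, bundle.manifest, alpha=config.alpha, max_gap=config.max_gap,
        adjust_age=config.adjust_age)
    counts["consensus_sites"] = len(consensus)
    log.info("diffmeth: %d consensus sites (%d up, %d down)",
             len(consensus), consensus.n_increased, consensus.n_decreased)

    enrichment = {}
    if len(consensus) and counts["probes_tested"]:
        for axis in ("cgi", "subregion"):
            enrichment[axis] = profiling.chisq_category_enrichment(
                consensus.probes, bundle.manifest.loc[beta.index], axis)

    clustering = None
    if len(consensus) >= 2:
        clustering = profiling.cluster_samples(beta, consensus.probes, bundle.sheet)
        log.info("profiling: two-branch cut phase agreement %.2f",
                 clustering.phase_agreement)

    log.info("dmr: window scan over consensus sites")
    dmrs = dmr.call_dmrs(site_table, bundle.manifest, diffs=diffs,
                         config=config.dmr_config(),
                         adjust_age=config.adjust_age)
    counts["dmrs"] = len(dmrs)

    correlation_records = region_medians = table1 = None
    if bundle.expression is not None and len(bundle.expression):
        log.info("correlate: cis methylation-expression pairs")
        cc = config.correlation_config()
        cpm_mat = correlation.cpm(bundle.expression)
        pairs = correlation.select_pairs(site_table, bundle.manifest,
                                         cpm_mat.index, cc)
        counts["correlation_pairs"] = len(pairs)
        if len(pairs):
            correlation_records = correlation.correlate_pairs(
                pairs, beta, cpm_mat, bundle.sheet, cc)
            region_medians = correlation.aggregate_region_median(correlation_records)
            table1 = correlation.summarize_table1(correlation_records)
            counts["correlated_pairs"] = int(correlation_records["significant"].sum())

    return PipelineResult(
        beta=beta, m_values=m_values, filter_report=report,
        state_fractions=state_fractions, state_table=state_table,
        consensus=consensus, site_table=site_table, moderation=params,
        diffs=diffs, dmrs=dmrs, enrichment=enrichment, clustering=clustering,
        correlation_records=correlation_records, region_medians=region_medians,
        table1=table1, stage_counts=counts)


def load_bundle(indir, sim_config: SimConfig | None = None) -> StudyBundle:
    """Read a study bundle from a directory of TSV/CSV files."""
    indir = Path(indir)
    manifest = io.read_manifest(indir / "manifest.tsv")
    sheet = io.read_sample_sheet(indir / "samples.csv")
    m_int = io.read_matrix(indir / "m_intensity.tsv", sheet)
    u_int = io.read_matrix(indir / "u_intensity.tsv", sheet)
    det_path = indir / "detection_fail.tsv"
    detection = io.read_matrix(det_path, sheet).astype(bool) \
        if det_path.exists() else None
    expr_path = indir / "expression_counts.tsv"
    expression = io.read_matrix(expr_path, index_label="gene_id") \
        if expr_path.exists() else pd.DataFrame()
    truth_path = indir / "truth.tsv"
    truth = io.read_matrix(truth_path) if truth_path.exists() else None
    return StudyBundle(config=sim_config or SimConfig(), manifest=manifest,
                       sheet=sheet, m_intensity=m_int, u_intensity=u_int,
                       detection_fail=detection, expression=expression,
                       truth=truth, latent_m=None)


def write_results(result: PipelineResult, outdir, *,
                  config: PipelineConfig, seed: int) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_matrix(result.beta, out / "beta.tsv")
    io.write_matrix(result.m_values, out / "m_values.tsv")
    result.filter_report.to_frame().to_csv(out / "filter_report.tsv",
                                           sep="\t", index=False)
    result.state_fractions.rename("fraction").to_csv(
        out / "state_fractions.tsv", sep="\t", index_label="state",
        float_format="%.6g")
    io.write_matrix(result.site_table, out / "site_results.tsv")
    result.dmrs.to_csv(out / "dmrs.tsv", sep="\t", index=False,
                       float_format="%.6g")
    dmr.dmrs_to_bed(result.dmrs, out / "dmrs.bed")
    for axis, (test, table) in result.enrichment.items():
        table.to_csv(out / f"enrichment_{axis}.tsv", sep="\t",
                     index_label="category", float_format="%.6g")
    if result.correlation_records is not None:
        result.correlation_records.to_csv(out / "correlation_records.tsv",
                                          sep="\t", index=False,
                                          float_format="%.6g")
        result.region_medians.to_csv(out / "region_medians.tsv", sep="\t",
                                     index=False, float_format="%.6g")
        result.table1.to_csv(out / "regional_summary.tsv", sep="\t", index=False)
    io.write_run_manifest(out / "run_manifest.json",
                          params=vars(config), seed=seed,
                          stage_counts=result.stage_counts)


def run_synthetic(sim_config: SimConfig, pipe_config: PipelineConfig | None = None,
                  outdir=None) -> tuple[StudyBundle, PipelineResult]:
    """Simulate a study and run the full pipeline on it."""
    pipe_config = pipe_config or PipelineConfig(seed=sim_config.seed)
    bundle = simulate_study(sim_config)
    result = run_pipeline(bundle, pipe_config)
    if outdir is not None:
        write_results(result, outdir, config=pipe_config, seed=pipe_config.seed)
    return bundle, result
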