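"""Three-method site-level differential methylation and the consensus set.

Runs the moderated paired t-test, the Wilcoxon signed-rank test and the
segment-level test on the M-value paired differences, intersects the
FDR < 0.05 calls, summarizes delta-beta by direction, tests the genomic
distribution of the consensus against the array background (chi-square),
clusters samples on the consensus CpGs, and scores recovery against the
planted truth.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPE_CONFIG, SCRATCH, results_dir  # noqa: E402

from endomethyl import diffmeth, io, profiling  # noqa: E402
from endomethyl.pipeline import load_bundle  # noqa: E402


def main():
    bundle = load_bundle(SCRATCH)
    beta = io.read_matrix(SCRATCH / "beta_filtered.tsv", bundle.sheet)
    mv = io.read_matrix(SCRATCH / "m_filtered.tsv", bundle.sheet)

    diffs = diffmeth.paired_differences(mv, beta, bundle.sheet)
    consensus, table, params = diffmeth.run_site_tests(
        diffs, bundle.manifest, alpha=PIPE_CONFIG.alpha,
        max_gap=PIPE_CONFIG.max_gap)
    io.write_matrix(table, SCRATCH / "site_results.tsv")

    out = results_dir()
    n = len(table)
    sig = table[table["consensus"]]
    inc = sig[sig["direction"] == "increased"]
    dec = sig[sig["direction"] == "decreased"]
    per_method = {m: int(table[f"{m}_significant"].sum())
                  for m in ("moderated", "wilcoxon", "segment")}
    truth = bundle.truth.loc[table.index]
    tp = int((table["consensus"] & truth["is_dmc"]).sum())
    fp = int((table["consensus"] & ~truth["is_dmc"]).sum())
    clustering = profiling.cluster_samples(beta, consensus.probes, bundle.sheet)

    rows = [
        ("probes_tested", n),
        ("moderated_significant", per_method["moderated"]),
        ("wilcoxon_significant", per_method["wilcoxon"]),
        ("segment_significant", per_method["segment"]),
        ("consensus_sites", len(consensus)),
        ("consensus_pct", f"{100 * len(consensus) / n:.2f}"),
        ("consensus_increased", consensus.n_increased),
        ("consensus_increased_pct",
         f"{100 * consensus.n_increased / max(len(consensus), 1):.1f}"),
        ("delta_beta_mean_increased", f"{inc['delta_beta'].mean():.4f}"),
        ("delta_beta_median_increased", f"{inc['delta_beta'].median():.4f}"),
        ("delta_beta_mean_decreased", f"{dec['delta_beta'].mean():.4f}"),
        ("delta_beta_median_decreased", f"{dec['delta_beta'].median():.4f}"),
        ("abs_delta_beta_gt_0.1", int((sig["delta_beta"].abs() > 0.1).sum())),
        ("moderation_prior_df", f"{params.d0:.2f}"),
        ("moderation_prior_var", f"{params.s0sq:.4f}"),
        ("empirical_fdr", f"{fp / max(len(sig), 1):.4f}"),
        ("sensitivity", f"{tp / int(truth['is_dmc'].sum()):.4f}"),
        ("clustering_phase_agreement",
         f"{clustering.phase_agreement:.3f}"),
    ]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
        out / "04_consensus_summary.tsv", sep="\t", index=False)

    for axis in ("cgi", "subregion"):
        res, enrich = profiling.chisq_category_enrichment(
            consensus.probes, bundle.manifest.loc[table.index], axis)
        enrich.to_csv(out / f"04_enrichment_{axis}.tsv", sep="\t",
                      index_label="category", float_format="%.4g")
        print(f"chi-square ({axis}): X2={res.statistic:.1f}, df={res.df}, "
              f"p={res.pvalue:.3g}")

    for metric, value in rows:
        print(f"{metric}\t{value}")


if __name__ == "__main__":
    main()
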