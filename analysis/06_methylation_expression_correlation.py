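"""Cis methylation-expression correlation over the expression sub-cohort.

Selects consensus CpGs with |delta-beta| > 0.1 that carry a gene annotation,
correlates their beta values with the annotated gene's CPM across the 14
expression samples (Spearman, permutation p), aggregates significant
correlations to region medians, and writes the regional summary table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPE_CONFIG, SCRATCH, results_dir  # noqa: E402

from endomethyl import correlation, io  # noqa: E402
from endomethyl.pipeline import load_bundle  # noqa: E402


def main():
    bundle = load_bundle(SCRATCH)
    beta = io.read_matrix(SCRATCH / "beta_filtered.tsv", bundle.sheet)
    table = io.read_matrix(SCRATCH / "site_results.tsv")
    table["consensus"] = table["consensus"].astype(bool)

    cfg = PIPE_CONFIG.correlation_config()
    cpm_mat = correlation.cpm(bundle.expression)
    pairs = correlation.select_pairs(table, bundle.manifest, cpm_mat.index, cfg)
    records = correlation.correlate_pairs(pairs, beta, cpm_mat,
                                          bundle.sheet, cfg)
    medians = correlation.aggregate_region_median(records)
    table1 = correlation.summarize_table1(records)

    out = results_dir()
    records.sort_values("p").head(50).to_csv(
        out / "06_top_correlations.tsv", sep="\t", index=False,
        float_format="%.4g")
    medians.to_csv(out / "06_region_medians.tsv", sep="\t", index=False,
                   float_format="%.4g")
    table1.to_csv(out / "06_regional_summary.tsv", sep="\t", index=False)

    n_sig = int(records["significant"].sum())
    n_pos = int((records.loc[records["significant"], "sign"]
                 == "positive").sum())
    print(f"pairs tested: {len(records)} "
          f"({records['probe_id'].nunique()} CpGs, "
          f"{records['gene'].nunique()} genes)")
    print(f"significant: {n_sig} ({100 * n_sig / max(len(records), 1):.1f}%), "
          f"{n_pos} positive / {n_sig - n_pos} negative")
    print(table1.to_string(index=False))


if __name__ == "__main__":
    main()
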