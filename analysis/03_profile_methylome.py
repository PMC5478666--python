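"""Descriptive profiling of the methylome.

Classifies CpGs as consistently hyper-/hypomethylated, summarizes beta
distributions per CpG-island-relation and gene-subregion category, and runs
pairwise Kolmogorov-Smirnov comparisons between key categories.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SCRATCH, results_dir  # noqa: E402

from endomethyl import io, profiling  # noqa: E402
from endomethyl.pipeline import load_bundle  # noqa: E402


def main():
    bundle = load_bundle(SCRATCH)
    beta = io.read_matrix(SCRATCH / "beta_filtered.tsv", bundle.sheet)

    table, fractions = profiling.classify_states(beta, bundle.sheet)
    out = results_dir()
    fractions.rename("fraction").to_csv(out / "03_state_fractions.tsv",
                                        sep="\t", index_label="state",
                                        float_format="%.4f")
    print("state fractions:")
    print(fractions.to_string(float_format="%.3f"))

    rows = []
    for axis in ("cgi", "subregion"):
        dist = profiling.distribution_by_category(beta, bundle.manifest,
                                                  bundle.sheet, axis)
        summary = dist.groupby(["category", "phase"])["mean_beta"] \
            .describe().reset_index()
        summary.insert(0, "axis", axis)
        rows.append(summary)
    pd.concat(rows).to_csv(out / "03_category_distributions.tsv", sep="\t",
                           index=False, float_format="%.4g")

    # KS comparisons between island-relation categories (receptive phase)
    dist = profiling.distribution_by_category(beta, bundle.manifest,
                                              bundle.sheet, "cgi")
    rec = dist[dist["phase"] == "LH+8"]
    ks_rows = []
    cats = ["island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            va = rec.loc[rec["category"] == a, "mean_beta"]
            vb = rec.loc[rec["category"] == b, "mean_beta"]
            if len(va) and len(vb):
                res = profiling.ks_compare(va, vb)
                ks_rows.append((a, b, res.statistic, res.pvalue))
    ks = pd.DataFrame(ks_rows, columns=["category_a", "category_b", "D", "p"])
    ks.to_csv(out / "03_ks_island_relation.tsv", sep="\t", index=False,
              float_format="%.4g")
    print(f"\nKS comparisons (receptive phase), strongest contrast: "
          f"{ks.loc[ks['D'].idxmax(), 'category_a']} vs "
          f"{ks.loc[ks['D'].idxmax(), 'category_b']} "
          f"(D={ks['D'].max():.3f})")


if __name__ == "__main__":
    main()
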