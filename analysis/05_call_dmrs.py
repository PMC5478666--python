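"""Region-level analysis: call DMRs and score planted-block recovery.

Scans the position-ordered consensus CpGs into maximal same-direction runs
(>= 3 CpGs, adjacent gaps <= 500 bp), writes the DMR table and its BED6
export, and checks the planted contiguous blocks against the calls.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPE_CONFIG, SCRATCH, results_dir  # noqa: E402

from endomethyl import diffmeth, dmr, io  # noqa: E402
from endomethyl.pipeline import load_bundle  # noqa: E402


def main():
    bundle = load_bundle(SCRATCH)
    beta = io.read_matrix(SCRATCH / "beta_filtered.tsv", bundle.sheet)
    mv = io.read_matrix(SCRATCH / "m_filtered.tsv", bundle.sheet)
    table = io.read_matrix(SCRATCH / "site_results.tsv")
    table["consensus"] = table["consensus"].astype(bool)

    diffs = diffmeth.paired_differences(mv, beta, bundle.sheet)
    dmrs = dmr.call_dmrs(table, bundle.manifest, diffs=diffs,
                         config=PIPE_CONFIG.dmr_config())

    out = results_dir()
    dmrs.to_csv(out / "05_dmrs.tsv", sep="\t", index=False,
                float_format="%.4g")
    dmr.dmrs_to_bed(dmrs, out / "05_dmrs.bed")

    blocks = bundle.truth[bundle.truth["dmr_block_id"] >= 0] \
        .groupby("dmr_block_id")
    dmr_sets = [set(p.split(";")) for p in dmrs["probes"]]
    recovered = sum(any(len(set(g.index) & s) >= 3 for s in dmr_sets)
                    for _, g in blocks)
    n_inc = int((dmrs["direction"] == "increased").sum())
    print(f"DMRs called: {len(dmrs)} ({n_inc} increased, "
          f"{len(dmrs) - n_inc} decreased)")
    print(f"planted blocks recovered: {recovered}/{blocks.ngroups}")
    genes_inc = {g for gg in dmrs.loc[dmrs['direction'] == 'increased', 'genes']
                 if gg for g in gg.split(';')}
    genes_dec = {g for gg in dmrs.loc[dmrs['direction'] == 'decreased', 'genes']
                 if gg for g in gg.split(';')}
    print(f"genes with increased-methylation DMRs: {len(genes_inc)}, "
          f"decreased: {len(genes_dec)}, in both: {len(genes_inc & genes_dec)}")


if __name__ == "__main__":
    main()
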