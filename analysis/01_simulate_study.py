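"""Generate the synthetic paired methylation + expression study.

Writes the full data bundle (manifest, intensities, sample sheet, expression
counts, ground truth) under scratch/ and a small design summary under
results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SCRATCH, SIM_CONFIG, results_dir  # noqa: E402

from endomethyl.synthetic import simulate_study, write_bundle  # noqa: E402


def main():
    bundle = simulate_study(SIM_CONFIG)
    write_bundle(bundle, SCRATCH)

    truth = bundle.truth
    n_dmc = int(truth["is_dmc"].sum())
    n_blocks = truth.loc[truth["dmr_block_id"] >= 0, "dmr_block_id"].nunique()
    n_coupled = int((truth["coupled_gene"] != "").sum())
    lines = [
        f"probes\t{len(bundle.manifest)}",
        f"subjects\t{bundle.sheet['subject_id'].nunique()}",
        f"samples\t{len(bundle.sheet)}",
        f"expression_samples\t{bundle.expression.shape[1]}",
        f"genes\t{bundle.expression.shape[0]}",
        f"planted_dmcs\t{n_dmc}",
        f"planted_dmc_pct\t{100 * n_dmc / len(bundle.manifest):.2f}",
        f"planted_increase_pct\t"
        f"{100 * (truth['true_delta_beta'] > 0).sum() / n_dmc:.1f}",
        f"planted_dmr_blocks\t{n_blocks}",
        f"planted_coupled_pairs\t{n_coupled}",
    ]
    out = results_dir() / "01_study_design.tsv"
    out.write_text("metric\tvalue\n" + "\n".join(lines) + "\n")
    print(f"simulated study written to {SCRATCH}")
    print("\n".join(lines))


if __name__ == "__main__":
    main()
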