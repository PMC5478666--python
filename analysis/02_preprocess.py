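"""Normalize intensities, compute beta/M, filter probes.

Reports the per-rule removal counts (SNP overlap, cross-reactivity,
unreliable measurement, sex chromosomes, non-CpG context) and writes the
filtered beta/M matrices back to scratch/ for the downstream drivers.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SCRATCH, results_dir  # noqa: E402

from endomethyl import io, preprocess  # noqa: E402
from endomethyl.pipeline import load_bundle  # noqa: E402


def main():
    bundle = load_bundle(SCRATCH)
    m, u, scalars = preprocess.scale_normalize(bundle.m_intensity,
                                               bundle.u_intensity)
    beta = preprocess.compute_beta(m, u)
    mv = preprocess.compute_m(m, u)
    beta, mv, report = preprocess.filter_probes(
        beta, mv, bundle.manifest, bundle.detection_fail)

    io.write_matrix(beta, SCRATCH / "beta_filtered.tsv")
    io.write_matrix(mv, SCRATCH / "m_filtered.tsv")
    report.to_frame().to_csv(results_dir() / "02_filter_report.tsv",
                             sep="\t", index=False)
    print(f"scaling factors span {scalars.min():.3f}-{scalars.max():.3f}")
    for line in report.log_lines():
        print(line)


if __name__ == "__main__":
    main()
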