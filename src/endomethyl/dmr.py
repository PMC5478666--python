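"""Differentially methylated region (DMR) calling.

A DMR is a maximal run of at least ``min_cpgs`` consecutive significant CpGs
(FDR < alpha) on one chromosome, sharing a direction of change, with every
adjacent pair at most ``max_gap`` bp apart (the default "gap" reading of a
500 bp window; a total-span reading is available via ``window_rule='span'``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import DmrConfig
from .diffmeth import PairedDiffs, _fit_intercept, _intercept_design, bh_fdr
from .errors import ValidationError
from .io import parse_gene_tokens
from scipy import stats

DMR_COLUMNS = ["dmr_id", "chrom", "start", "end", "n_cpgs", "direction",
               "probes", "p", "q", "genes"]


def _significant_frame(site_results: pd.DataFrame, manifest: pd.DataFrame,
                       config: DmrConfig, q_column: str) -> pd.DataFrame:
    missing = site_results.index.difference(manifest.index)
    if len(missing):
        raise ValidationError(
            f"site results not covered by manifest: {missing.tolist()[:5]}")
    if q_column == "consensus":
        sig_mask = site_results["consensus"].to_numpy(bool)
    else:
        sig_mask = (site_results[q_column] < config.alpha).to_numpy()
    sig = site_results.loc[sig_mask, ["direction"]].copy()
    ann = manifest.loc[manifest.index.isin(sig.index)]
    sig = sig.loc[ann.index]
    sig["chrom"] = ann["chrom"].to_numpy()
    sig["pos"] = ann["pos"].to_numpy()
    sig["genes"] = ann["genes"].to_numpy()
    return sig


def call_dmrs(site_results: pd.DataFrame, manifest: pd.DataFrame,
              diffs: PairedDiffs | None = None,
              config: DmrConfig | None = None,
              q_column: str = "consensus", adjust_age: bool = True
              ) -> pd.DataFrame:
    """Scan position-ordered significant CpGs into maximal same-direction runs.

    ``q_column`` selects the significance source: the default ``"consensus"``
    uses the consensus flag of the site table; any per-method q column (e.g.
    ``"segment_q"``) thresholds that method at ``config.alpha`` instead.
    Region p-values come from the unmoderated intercept test on per-subject
    region-mean differences when ``diffs`` is given; region q is BH across
    the emitted DMRs.
    """
    config = (config or DmrConfig()).validate()
    sig = _significant_frame(site_results, manifest, config, q_column)

    runs: list[list] = []
    current: list = []

    def flush():
        if len(current) >= config.min_cpgs:
            runs.append(list(current))

    prev = None
    for probe, row in sig.iterrows():
        if current:
            same = (row["chrom"] == prev["chrom"]
                    and row["direction"] == prev["direction"])
            if config.window_rule == "gap":
                within = same and row["pos"] - prev["pos"] <= config.max_gap
            else:
                within = same and row["pos"] - sig.at[current[0], "pos"] <= config.max_gap
            if not within:
                flush()
                current = []
        current.append(probe)
        prev = row
    flush()

    records = []
    for i, members in enumerate(runs):
        sub = sig.loc[members]
        genes = sorted({g for toks in sub["genes"] if toks
                        for g, _ in parse_gene_tokens(toks)})
        records.append({
            "dmr_id": f"DMR{i + 1:05d}",
            "chrom": sub["chrom"].iloc[0],
            "start": int(sub["pos"].min()),
            "end": int(sub["pos"].max()),
            "n_cpgs": len(members),
            "direction": sub["direction"].iloc[0],
            "probes": ";".join(members),
            "genes": ";".join(genes),
        })
    dmrs = pd.DataFrame(records, columns=[c for c in DMR_COLUMNS if c not in ("p", "q")])
    if len(dmrs) == 0:
        dmrs["p"] = pd.Series(dtype=float)
        dmrs["q"] = pd.Series(dtype=float)
        return dmrs[DMR_COLUMNS]

    if diffs is not None:
        X = _intercept_design(diffs, adjust_age)
        means = np.vstack([
            diffs.d.loc[members.split(";")].mean(axis=0).to_numpy()
            for members in dmrs["probes"]
        ])
        b0, s2, df, c00 = _fit_intercept(means, X)
        se = np.sqrt(s2 * c00)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, b0 / se, 0.0)
        dmrs["p"] = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        dmrs["p"] = np.nan
    dmrs["q"] = bh_fdr(dmrs["p"].fillna(1.0)) if dmrs["p"].notna().all() else np.nan
    return dmrs[DMR_COLUMNS]


def dmrs_to_bed(dmrs: pd.DataFrame, path=None) -> list[str]:
    """Export DMRs as BED6 (0-based half-open; score = -10 log10 region q)."""
    lines = ["#chrom\tstart\tend\tname\tscore\tstrand"]
    for row in dmrs.itertuples(index=False):
        q = row.q
        if q is None or (isinstance(q, float) and (np.isnan(q) or q <= 0)):
            score = 1000
        else:
            score = int(min(round(-10.0 * np.log10(q)), 1000))
        lines.append(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.dmr_id}"
                     f"\t{max(score, 0)}\t.")
    if path is not None:
        Path(path).write_text("\n".join(lines) + "\n")
    return lines
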