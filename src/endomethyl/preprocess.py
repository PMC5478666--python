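"""Intensity-to-methylation conversion, probe filtering, scaling normalization.

Beta values use the Illumina formula beta = m / (m + u + 100); M values are
computed from intensities as log2((m + 1) / (u + 1)) so the large beta offset
does not contaminate the log-ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

BETA_OFFSET = 100.0

#: filtering rules in application order; a probe is charged to the first rule
#: that removes it
FILTER_RULES = ("snp", "crossreactive", "unreliable", "sex_chromosome", "non_cpg")
_STAGE1 = ("snp", "crossreactive", "unreliable")


def _check_intensities(m: pd.DataFrame, u: pd.DataFrame) -> None:
    if not m.index.equals(u.index) or list(m.columns) != list(u.columns):
        raise ValidationError("methylated/unmethylated matrices are misaligned")
    if (m.to_numpy() < 0).any() or (u.to_numpy() < 0).any():
        raise ValidationError("negative intensities")


def compute_beta(m: pd.DataFrame, u: pd.DataFrame) -> pd.DataFrame:
    """beta = m / (m + u + 100), elementwise; in [0, 1)."""
    _check_intensities(m, u)
    return m / (m + u + BETA_OFFSET)


def compute_m(m: pd.DataFrame, u: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """M = log2((m + offset) / (u + offset)); finite for non-negative input."""
    if offset <= 0:
        raise ConfigError(f"M-value offset must be positive, got {offset}")
    _check_intensities(m, u)
    return np.log2((m + offset) / (u + offset))


@dataclass
class FilterReport:
    """Per-rule removal accounting; rules charged on a first-hit basis."""

    n_initial: int
    removed: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_remaining(self) -> int:
        return self.n_initial - self.n_removed

    @property
    def n_stage1(self) -> int:
        return sum(self.removed.get(r, 0) for r in _STAGE1)

    def to_frame(self) -> pd.DataFrame:
        rows = [(rule, self.removed.get(rule, 0)) for rule in FILTER_RULES]
        rows.append(("remaining", self.n_remaining))
        return pd.DataFrame(rows, columns=["rule", "n_probes"])

    def log_lines(self) -> list[str]:
        lines = [f"filter: {self.n_initial} probes in"]
        for rule in FILTER_RULES:
            lines.append(f"filter: removed {self.removed.get(rule, 0)} ({rule})")
        lines.append(f"filter: stage 1 removed {self.n_stage1} in total")
        lines.append(f"filter: {self.n_remaining} probes remain")
        return lines


def filter_probes(beta: pd.DataFrame, m_matrix: pd.DataFrame,
                  manifest: pd.DataFrame,
                  detection_fail: pd.DataFrame | None = None,
                  max_fail_frac: float = 0.05,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Apply the staged probe-filtering protocol.

    Stage 1 removes SNP-overlapping, cross-reactive and unreliable probes
    (detection failure in more than ``max_fail_frac`` of samples); stage 2
    removes sex-chromosome and non-CpG-context probes.  Returns the filtered
    beta and M matrices plus an exactly-balancing :class:`FilterReport`.
    """
    if not beta.index.equals(m_matrix.index):
        raise ValidationError("beta and M matrices are misaligned")
    unknown = beta.index.difference(manifest.index)
    if len(unknown):
        raise ValidationError(
            f"probes absent from manifest: {unknown.tolist()[:10]}")
    ann = manifest.loc[beta.index]

    rules = {
        "snp": ann["snp_flag"].to_numpy(bool),
        "crossreactive": ann["crossreactive_flag"].to_numpy(bool),
        "unreliable": np.zeros(len(beta), dtype=bool),
        "sex_chromosome": ann["chrom"].isin(["chrX", "chrY"]).to_numpy(),
        "non_cpg": ~np.asarray(beta.index.str.startswith("cg")),
    }
    if detection_fail is not None:
        frac = detection_fail.loc[beta.index].mean(axis=1).to_numpy()
        rules["unreliable"] = frac > max_fail_frac

    report = FilterReport(n_initial=len(beta))
    hit = np.zeros(len(beta), dtype=bool)
    for rule in FILTER_RULES:
        newly = rules[rule] & ~hit
        report.removed[rule] = int(newly.sum())
        hit |= newly
    keep = ~hit
    return beta.loc[keep], m_matrix.loc[keep], report


def scale_normalize(m: pd.DataFrame, u: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-sample total-intensity scaling.

    Each sample's intensities are multiplied by a scalar so its mean total
    intensity (m + u over retained probes) equals the across-sample grand
    mean.  Within-sample m:u ratios are untouched, so M values are unchanged
    up to the small offset and beta only moves through the +100 offset.
    Returns the scaled matrices and the per-sample scalars.
    """
    _check_intensities(m, u)
    if m.shape[1] < 2:
        raise ValidationError("scaling normalization needs >= 2 samples")
    totals = (m + u).mean(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"all-zero intensity sample(s): {zero.index.tolist()}")
    scalars = totals.mean() / totals
    return m * scalars, u * scalars, scalars
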