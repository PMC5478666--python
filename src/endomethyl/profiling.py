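"""Descriptive methylome statistics.

Hyper/hypomethylation classification, per-category methylation value
distributions (CpG-island relation or gene subregion), Kolmogorov-Smirnov
comparisons between categories, chi-square enrichment of a significant CpG
set against the array background, and hierarchical clustering of samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .config import PHASE_PRE, PHASE_REC
from .errors import ConfigError, ValidationError
from .io import parse_gene_tokens

HYPER_THRESHOLD = 0.8
HYPO_THRESHOLD = 0.2


@dataclass
class StatTestResult:
    statistic: float
    pvalue: float
    df: int | None = None


def _phase_means(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    by_subject = sheet.groupby("subject_id")["phase"].nunique()
    incomplete = by_subject[by_subject < 2]
    if len(incomplete):
        raise ValidationError(
            f"subject(s) missing a phase: {incomplete.index.tolist()}")
    cols = {}
    for phase in (PHASE_PRE, PHASE_REC):
        samples = sheet.loc[sheet["phase"] == phase, "sample_id"]
        cols[phase] = beta[samples].mean(axis=1)
    return pd.DataFrame(cols)


def classify_states(beta: pd.DataFrame, sheet: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Classify probes as consistently hyper-/hypomethylated or intermediate.

    A probe is hypermethylated when its phase-mean beta exceeds 0.8 in both
    phases, hypomethylated when below 0.2 in both, intermediate otherwise.
    Returns the per-probe table and the summary state fractions.
    """
    means = _phase_means(beta, sheet)
    hyper = (means > HYPER_THRESHOLD).all(axis=1)
    hypo = (means < HYPO_THRESHOLD).all(axis=1)
    state = pd.Series("intermediate", index=beta.index, name="state")
    state[hyper] = "hypermethylated"
    state[hypo] = "hypomethylated"
    table = means.rename(columns={PHASE_PRE: "beta_pre", PHASE_REC: "beta_rec"})
    table["state"] = state
    fractions = state.value_counts(normalize=True).reindex(
        ["hypermethylated", "hypomethylated", "intermediate"], fill_value=0.0)
    return table, fractions


def annotate_category(manifest: pd.DataFrame, category_axis: str) -> pd.Series:
    """Per-probe category along the requested axis.

    ``subregion`` pools probes with multiple distinct subregion annotations
    into 'Others' and unannotated probes into 'Unknown'; ``cgi`` passes the
    island-relation label through.
    """
    if category_axis == "cgi":
        return manifest["cgi_relation"].astype(str)
    if category_axis != "subregion":
        raise ConfigError(f"unknown category axis: {category_axis!r}")

    def label(tokens: str) -> str:
        regions = {r for _, r in parse_gene_tokens(tokens)}
        if not regions:
            return "Unknown"
        if len(regions) > 1:
            return "Others"
        return regions.pop()

    return manifest["genes"].map(label)


def distribution_by_category(beta: pd.DataFrame, manifest: pd.DataFrame,
                             sheet: pd.DataFrame, category_axis: str
                             ) -> pd.DataFrame:
    """Tidy table of per-probe phase-mean beta by category and phase."""
    means = _phase_means(beta, sheet)
    cats = annotate_category(manifest.loc[beta.index], category_axis)
    rows = []
    for phase in (PHASE_PRE, PHASE_REC):
        rows.append(pd.DataFrame({
            "probe_id": beta.index,
            "category": cats.to_numpy(),
            "phase": phase,
            "mean_beta": means[phase].to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def ks_compare(values_a, values_b) -> StatTestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("KS comparison needs non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return StatTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def chisq_category_enrichment(significant_probes, manifest: pd.DataFrame,
                              category_axis: str,
                              all_probes=None
                              ) -> tuple[StatTestResult, pd.DataFrame]:
    """Goodness-of-fit of the significant set's category counts against the
    category proportions of the full analysed set."""
    all_idx = manifest.index if all_probes is None else pd.Index(all_probes)
    sig_idx = pd.Index(significant_probes)
    stray = sig_idx.difference(all_idx)
    if len(stray):
        raise ValidationError(f"significant probes outside the all-set: "
                              f"{stray.tolist()[:5]}")
    cats = annotate_category(manifest.loc[all_idx], category_axis)
    all_counts = cats.value_counts()
    sig_counts = cats.loc[sig_idx].value_counts().reindex(
        all_counts.index, fill_value=0)
    if len(all_counts) < 2:
        raise ValidationError("chi-square needs >= 2 categories")
    expected = all_counts / all_counts.sum() * sig_counts.sum()
    collapse = expected[(expected == 0) & (sig_counts > 0)]
    if len(collapse):
        raise ValidationError(
            f"zero expected count for non-empty categories {collapse.index.tolist()}"
            " -- collapse categories first")
    chi2, p = stats.chisquare(sig_counts.to_numpy(), expected.to_numpy())
    table = pd.DataFrame({
        "n_significant": sig_counts,
        "frac_significant": sig_counts / max(sig_counts.sum(), 1),
        "n_all": all_counts,
        "frac_all": all_counts / all_counts.sum(),
    })
    return StatTestResult(statistic=float(chi2), pvalue=float(p),
                          df=len(all_counts) - 1), table


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    sample_ids: list
    cut_labels: pd.Series
    #: fraction of samples on the branch where their phase is the majority
    phase_agreement: float
    table: pd.DataFrame


def cluster_samples(beta: pd.DataFrame, probe_subset, sheet: pd.DataFrame,
                    metric: str = "euclidean", method: str = "average"
                    ) -> ClusteringResult:
    """Hierarchical clustering of samples on a probe subset, two-branch cut."""
    subset = pd.Index(probe_subset)
    if len(subset) < 2:
        raise ValidationError("clustering needs >= 2 probes")
    if beta.shape[1] < 3:
        raise ValidationError("clustering needs >= 3 samples")
    data = beta.loc[subset].T.to_numpy()
    Z = hierarchy.linkage(pdist(data, metric=metric), method=method)
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    cut = pd.Series(labels, index=beta.columns, name="branch")
    phase = sheet.set_index("sample_id")["phase"].loc[beta.columns]
    table = pd.crosstab(cut, phase)
    agreement = float(table.max(axis=0).sum() / len(cut))
    return ClusteringResult(linkage=Z, sample_ids=list(beta.columns),
                            cut_labels=cut, phase_agreement=agreement,
                            table=table)
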