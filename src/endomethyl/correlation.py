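"""Cis methylation-expression correlation with permutation p-values.

Candidate pairs are consensus-significant CpGs with |delta-beta| above a
threshold (default 0.1) and at least one gene annotation (which excludes
open-sea CpGs), each paired with every annotated gene present in the
expression matrix.  Correlation is Spearman's rho between the CpG's beta
values and the gene's CPM over the samples carrying both data types; its
significance comes from a permutation null on the expression vector.
Significant correlations are aggregated to region medians per gene and
summarized per subregion and 5'-region / gene-body super-group.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .config import (CorrelationConfig, FIVE_PRIME_GROUP, GENE_BODY_GROUP,
                     super_group)
from .errors import ValidationError
from .io import parse_gene_tokens

REGION_ORDER = ["1stExon", "TSS200", "TSS1500", "5'UTR", "Body", "3'UTR"]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million with library size = per-sample total counts."""
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative counts")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero-total sample(s): {zero.index.tolist()}")
    return counts / totals * 1e6


def select_pairs(site_results: pd.DataFrame, manifest: pd.DataFrame,
                 expression_genes, config: CorrelationConfig | None = None
                 ) -> pd.DataFrame:
    """Candidate (CpG, gene) pairs for cis correlation.

    A CpG annotated to k genes yields k pairs; CpGs without gene annotation
    (open sea) are excluded by construction.
    """
    config = (config or CorrelationConfig()).validate()
    genes_available = set(expression_genes)
    eligible = site_results.index[
        site_results["consensus"]
        & (site_results["delta_beta"].abs() > config.delta_beta_threshold)
    ]
    rows = []
    for probe in eligible:
        tokens = manifest.at[probe, "genes"]
        seen = set()
        for gene, region in parse_gene_tokens(tokens):
            if gene not in genes_available or gene in seen:
                continue
            seen.add(gene)
            rows.append((probe, gene, region, super_group(region),
                         float(site_results.at[probe, "delta_beta"])))
    return pd.DataFrame(rows, columns=["probe_id", "gene", "region",
                                       "super_group", "delta_beta"])


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman_permutation(x, y, config: CorrelationConfig | None = None,
                         rng: np.random.Generator | None = None,
                         pairs=None) -> tuple[float, float]:
    """Spearman rho with a permutation p-value.

    Two-sided p over |rho|: exhaustive over all n! orderings of y when
    n! <= n_permutations, else Monte Carlo over B seeded permutations with
    the add-one correction p = (1 + #{|rho_b| >= |rho|}) / (B + 1).  The
    "paired" scheme restricts to within-subject swaps (2^k arrangements).
    A constant input yields rho = nan, p = 1.
    """
    config = (config or CorrelationConfig()).validate()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("vectors must be 1-D and aligned")
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if math.isnan(rho):
        return rho, 1.0

    tol = 1e-12
    if config.scheme == "paired" and pairs is not None:
        perms = _paired_permutations(ry, pairs, config, rng)
        exhaustive = perms.shape[0] <= config.n_permutations
    elif math.factorial(n) <= config.n_permutations:
        perms = np.array(list(permutations(range(n))))
        perms = ry[perms]
        exhaustive = True
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        perms = rng.permuted(np.tile(ry, (config.n_permutations, 1)), axis=1)
        exhaustive = False

    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc ** 2).sum() * (pc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rho_b = (pc @ rxc) / denom
    hits = int((np.abs(rho_b) >= abs(rho) - tol).sum())
    if exhaustive:
        p = hits / perms.shape[0]
    else:
        p = (1 + hits) / (config.n_permutations + 1)
    return rho, float(p)


def _paired_permutations(ry, pairs, config, rng):
    """Within-subject swap arrangements of y (phase-label permutation)."""
    pairs = np.asarray(pairs)
    groups = [np.flatnonzero(pairs == g) for g in np.unique(pairs)]
    k = len(groups)
    if 2 ** k <= config.n_permutations:
        out = []
        for mask in range(2 ** k):
            perm = ry.copy()
            for gi, idx in enumerate(groups):
                if mask >> gi & 1 and idx.size == 2:
                    perm[idx] = perm[idx[::-1]]
            out.append(perm)
        return np.array(out)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = np.tile(ry, (config.n_permutations, 1))
    for idx in groups:
        if idx.size == 2:
            swap = rng.random(config.n_permutations) < 0.5
            out[np.ix_(swap, idx)] = out[np.ix_(swap, idx[::-1])]
    return out


def correlate_pairs(pairs: pd.DataFrame, beta: pd.DataFrame,
                    cpm_matrix: pd.DataFrame, sheet: pd.DataFrame,
                    config: CorrelationConfig | None = None) -> pd.DataFrame:
    """Run the permutation-Spearman test for every candidate pair.

    Samples used are those present in both the methylation and expression
    matrices (both phases pooled).  Each pair gets an independent child RNG
    derived from the config seed, so results do not depend on pair order.
    """
    config = (config or CorrelationConfig()).validate()
    samples = [s for s in cpm_matrix.columns if s in beta.columns]
    if len(samples) < 3:
        raise ValidationError("need >= 3 shared samples for correlation")
    subj = sheet.set_index("sample_id")["subject_id"].loc[samples].to_numpy()
    seeds = np.random.SeedSequence(config.seed).spawn(len(pairs))
    records = []
    for (row, seed) in zip(pairs.itertuples(index=False), seeds):
        x = beta.loc[row.probe_id, samples].to_numpy(dtype=float)
        y = cpm_matrix.loc[row.gene, samples].to_numpy(dtype=float)
        rng = np.random.default_rng(seed)
        rho, p = spearman_permutation(
            x, y, config, rng=rng,
            pairs=subj if config.scheme == "paired" else None)
        records.append({
            "probe_id": row.probe_id, "gene": row.gene, "region": row.region,
            "super_group": row.super_group, "delta_beta": row.delta_beta,
            "rho": rho, "p": p,
            "significant": bool(p < config.alpha and not math.isnan(rho)),
            "sign": "positive" if (rho if not math.isnan(rho) else 0) > 0
                    else "negative",
        })
    return pd.DataFrame(records, columns=[
        "probe_id", "gene", "region", "super_group", "delta_beta",
        "rho", "p", "significant", "sign"])


def aggregate_region_median(records: pd.DataFrame) -> pd.DataFrame:
    """Median rho per (gene, region) over significant CpGs (singletons pass)."""
    sig = records.loc[records["significant"].astype(bool)]
    grouped = sig.groupby(["gene", "region"], sort=True)["rho"] \
        .agg(["median", "size"]).reset_index()
    return grouped.rename(columns={"median": "median_rho", "size": "n_cpgs"})


def _fmt_pct(num: int, den: int) -> str:
    return f"{100.0 * num / den:.1f}%" if den else ""


def summarize_table1(records: pd.DataFrame) -> pd.DataFrame:
    """Regional correlation summary.

    One row per subregion plus super-group rows ("5' region", "Body") that
    sum their member regions: CpGs tested, n (%) correlated, n (%) positive
    and negative among the correlated.
    """
    def row(name, sub):
        n = len(sub)
        sig = sub.loc[sub["significant"].astype(bool)]
        n_sig = len(sig)
        n_pos = int((sig["sign"] == "positive").sum())
        n_neg = n_sig - n_pos
        return {
            "region": name, "n_tested": n,
            "n_correlated": n_sig, "pct_correlated": _fmt_pct(n_sig, n),
            "n_positive": n_pos, "pct_positive": _fmt_pct(n_pos, n_sig),
            "n_negative": n_neg, "pct_negative": _fmt_pct(n_neg, n_sig),
        }

    rows = [row("5' region", records[records["region"].isin(FIVE_PRIME_GROUP)])]
    for region in REGION_ORDER:
        if region in FIVE_PRIME_GROUP:
            rows.append(row(f"  {region}", records[records["region"] == region]))
    rows.append(row("Body", records[records["region"].isin(GENE_BODY_GROUP)]))
    for region in REGION_ORDER:
        if region in GENE_BODY_GROUP:
            rows.append(row(f"  {region}", records[records["region"] == region]))
    return pd.DataFrame(rows)
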