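"""Site-level paired differential methylation: three tests and their consensus.

The paired design (one pre-receptive and one receptive sample per subject)
reduces to one M-value difference per probe and subject,
``d = M(LH+8) - M(LH+2)``.  Age is subject-constant, so it cannot enter a
model that already absorbs subject effects through pairing; instead every
parametric test here regresses the paired differences on centered age and
tests the intercept — the age-adjusted mean phase effect.

Three tests are run per probe:

1. an empirical-Bayes moderated t-test — per-probe residual variances are
   shrunk toward a pooled prior (d0, s0^2) estimated by moment matching on
   log s^2, and the intercept t-statistic is referenced to d0 + d degrees of
   freedom;
2. the Wilcoxon signed-rank test on the paired differences (exact null
   distribution when there are no ties or zeros and n <= 25, normal
   approximation with tie and continuity corrections otherwise; the rank
   test admits no covariate, so this arm is unadjusted);
3. a segment-level t-test: consecutive CpGs within ``max_gap`` bp are pooled,
   per-subject segment-mean differences are tested with the same intercept
   model (unmoderated), and the segment p-value is assigned to every member
   probe.

Each arm is Benjamini-Hochberg adjusted (sites for 1-2, segments for 3), and
the consensus set is the intersection of the three FDR < alpha calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .config import PHASE_PRE, PHASE_REC
from .errors import ConfigError, ValidationError


# --------------------------------------------------------------------------
# paired differences
# --------------------------------------------------------------------------

@dataclass
class PairedDiffs:
    """Per-(probe, subject) paired differences, receptive minus pre-receptive."""

    d: pd.DataFrame        # M-scale differences, probes x subjects
    dbeta: pd.DataFrame    # beta-scale differences, probes x subjects
    ages: pd.Series        # one age per subject
    age_centered: pd.Series

    @property
    def n_subjects(self) -> int:
        return self.d.shape[1]


def paired_differences(m_matrix: pd.DataFrame, beta: pd.DataFrame,
                       sheet: pd.DataFrame) -> PairedDiffs:
    counts = sheet.groupby(["subject_id", "phase"]).size().unstack(fill_value=0)
    bad = counts.index[(counts.get(PHASE_PRE, 0) != 1) | (counts.get(PHASE_REC, 0) != 1)]
    if len(bad):
        raise ValidationError(f"unpaired subject(s): {bad.tolist()}")
    idx = sheet.set_index(["subject_id", "phase"])["sample_id"]
    subjects = sorted(counts.index)
    pre = [idx.loc[(s, PHASE_PRE)] for s in subjects]
    rec = [idx.loc[(s, PHASE_REC)] for s in subjects]
    d = pd.DataFrame(m_matrix[rec].to_numpy() - m_matrix[pre].to_numpy(),
                     index=m_matrix.index, columns=subjects)
    dbeta = pd.DataFrame(beta[rec].to_numpy() - beta[pre].to_numpy(),
                         index=beta.index, columns=subjects)
    ages = sheet.drop_duplicates("subject_id").set_index("subject_id")["age"]
    ages = ages.loc[subjects].astype(float)
    return PairedDiffs(d=d, dbeta=dbeta, ages=ages,
                       age_centered=ages - ages.mean())


# --------------------------------------------------------------------------
# moderated paired t-test
# --------------------------------------------------------------------------

@dataclass
class ModerationParams:
    d0: float     # prior degrees of freedom (may be inf)
    s0sq: float   # prior variance on the M scale squared


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: int) -> ModerationParams:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Works on z = log(s^2): E[z] and Var[z] have closed forms in terms of
    digamma/trigamma of the residual and prior degrees of freedom, which are
    inverted for (d0, s0^2).  Var[z] at or below its sampling floor implies
    no excess spread, i.e. d0 = inf with a common variance.
    """
    s2 = np.maximum(np.asarray(s2, float), 1e-300)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    excess = evar - float(polygamma(1, df / 2.0))
    if excess <= 0:
        return ModerationParams(d0=np.inf, s0sq=float(np.exp(emean)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationParams(d0=d0, s0sq=s0sq)


def _intercept_design(diffs: PairedDiffs, adjust_age: bool) -> np.ndarray:
    n = diffs.n_subjects
    age = diffs.age_centered.to_numpy()
    # a constant-age cohort carries no information for the covariate
    if adjust_age and np.ptp(age) > 0:
        return np.column_stack([np.ones(n), age])
    return np.ones((n, 1))


def _fit_intercept(D: np.ndarray, X: np.ndarray):
    """OLS of every row of D on X; returns (b0, s2, df, c00)."""
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValidationError(f"zero residual degrees of freedom (n={n}, k={k})")
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = D @ (X @ xtx_inv)           # probes x k
    resid = D - coefs @ X.T
    s2 = (resid ** 2).sum(axis=1) / df
    return coefs[:, 0], s2, df, xtx_inv[0, 0]


def moderated_paired_test(diffs: PairedDiffs, adjust_age: bool = True,
                          prior: ModerationParams | None = None
                          ) -> tuple[pd.DataFrame, ModerationParams]:
    """Empirical-Bayes moderated t-test of the age-adjusted mean difference.

    ``prior`` overrides the pooled (d0, s0^2) estimate; d0 = 0 recovers the
    ordinary per-probe t-test, d0 = inf fully pools the variances.
    """
    if diffs.n_subjects < 3:
        raise ValidationError("moderated test needs >= 3 subjects")
    D = diffs.d.to_numpy(dtype=float)
    X = _intercept_design(diffs, adjust_age)
    b0, s2, df, c00 = _fit_intercept(D, X)
    params = prior if prior is not None else fit_variance_prior(s2, df)
    if np.isinf(params.d0):
        s2_tilde = np.full_like(s2, params.s0sq)
        df_total = np.inf
    else:
        s2_tilde = (params.d0 * params.s0sq + df * s2) / (params.d0 + df)
        df_total = params.d0 + df
    se = np.sqrt(s2_tilde * c00)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b0 / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame({"statistic": t, "p": p}, index=diffs.d.index)
    return out, params


# --------------------------------------------------------------------------
# Wilcoxon signed-rank test
# --------------------------------------------------------------------------

def signed_rank_cdf(n: int) -> np.ndarray:
    """CDF of the signed-rank statistic W under H0 for sample size n.

    Built from the generating polynomial prod_r (1 + x^r): entry w is
    P(W <= w), w = 0 .. n(n+1)/2.
    """
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return np.cumsum(counts) / 2.0 ** n


def _exact_two_sided_p(w: np.ndarray, cdf: np.ndarray) -> np.ndarray:
    w = w.astype(int)
    lower = cdf[w]
    upper = 1.0 - np.where(w > 0, cdf[w - 1], 0.0)
    return np.minimum(2.0 * np.minimum(lower, upper), 1.0)


def wilcoxon_paired_test(diffs: PairedDiffs, max_exact_n: int = 25
                         ) -> pd.DataFrame:
    """Per-probe Wilcoxon signed-rank test on the paired M differences.

    Zeros are dropped (the original convention); ties in |d| get midranks.
    Exact enumeration-based p-values when the probe has no zeros/ties and
    n <= ``max_exact_n``; otherwise the normal approximation with tie and
    continuity corrections.  All-zero probes get W = 0, p = 1.
    """
    D = diffs.d.to_numpy(dtype=float)
    n_probes, n = D.shape
    W = np.zeros(n_probes)
    P = np.ones(n_probes)
    zero_flag = np.zeros(n_probes, dtype=bool)

    absD = np.abs(D)
    has_zero = (D == 0).any(axis=1)
    sorted_abs = np.sort(absD, axis=1)
    has_tie = (np.diff(sorted_abs, axis=1) == 0).any(axis=1)

    fast = ~has_zero & ~has_tie & (n <= max_exact_n)
    if fast.any():
        ranks = stats.rankdata(absD[fast], axis=1)
        w = np.where(D[fast] > 0, ranks, 0.0).sum(axis=1)
        cdf = signed_rank_cdf(n)
        W[fast] = w
        P[fast] = _exact_two_sided_p(w, cdf)

    slow = np.flatnonzero(~fast)
    for i in slow:
        d = D[i]
        d = d[d != 0]
        m = d.size
        if m == 0:
            zero_flag[i] = True
            continue
        r = stats.rankdata(np.abs(d))
        w = float(r[d > 0].sum())
        W[i] = w
        if m <= max_exact_n and np.unique(np.abs(d)).size == m:
            P[i] = float(_exact_two_sided_p(np.array([w]), signed_rank_cdf(m))[0])
        else:
            mu = m * (m + 1) / 4.0
            _, tie_counts = np.unique(r, return_counts=True)
            tie_term = (tie_counts ** 3 - tie_counts).sum() / 48.0
            sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0 - tie_term)
            if sigma == 0:
                P[i] = 1.0
                continue
            diff = w - mu
            z = (diff - 0.5 * np.sign(diff)) / sigma
            P[i] = float(2.0 * stats.norm.sf(abs(z)))
    out = pd.DataFrame({"statistic": W, "p": P, "all_zero": zero_flag},
                       index=diffs.d.index)
    return out


# --------------------------------------------------------------------------
# segment-level test
# --------------------------------------------------------------------------

def assign_segments(diffs: PairedDiffs, manifest: pd.DataFrame,
                    max_gap: int = 500, split_on_sign: bool = False
                    ) -> pd.Series:
    """Partition tested probes into positional segments.

    A new segment starts at a chromosome change or when the gap to the
    previous tested probe exceeds ``max_gap`` bp.  ``split_on_sign``
    additionally breaks segments where the sign of the probe-mean difference
    flips; the default keeps segmentation data-independent.
    """
    ann = manifest.loc[manifest.index.isin(diffs.d.index)]
    if len(ann) != len(diffs.d):
        missing = diffs.d.index.difference(manifest.index)
        raise ValidationError(f"probes absent from manifest: {missing.tolist()[:5]}")
    pos = ann["pos"].to_numpy()
    chrom = ann["chrom"].to_numpy()
    for c in pd.unique(chrom):
        pc = pos[chrom == c]
        if (np.diff(pc) <= 0).any():
            raise ValidationError(f"manifest not position-sorted on {c}")
    new_seg = np.ones(len(ann), dtype=bool)
    if len(ann) > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) <= max_gap
        new_seg[1:] = ~(same_chrom & close)
        if split_on_sign:
            mean_sign = np.sign(diffs.d.loc[ann.index].mean(axis=1).to_numpy())
            new_seg[1:] |= mean_sign[1:] != mean_sign[:-1]
    seg_ids = np.cumsum(new_seg) - 1
    return pd.Series(seg_ids, index=ann.index, name="segment_id")


def segment_test(diffs: PairedDiffs, manifest: pd.DataFrame,
                 max_gap: int = 500, adjust_age: bool = True,
                 split_on_sign: bool = False
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment-level paired test; member probes inherit their segment's p.

    Returns (per-probe table with statistic/p/segment_id, per-segment table).
    """
    segments = assign_segments(diffs, manifest, max_gap, split_on_sign)
    order = segments.index
    D = diffs.d.loc[order].to_numpy(dtype=float)
    seg_ids = segments.to_numpy()
    n_seg = seg_ids[-1] + 1 if len(seg_ids) else 0
    # per-subject segment means
    sums = np.zeros((n_seg, D.shape[1]))
    np.add.at(sums, seg_ids, D)
    sizes = np.bincount(seg_ids, minlength=n_seg).astype(float)
    seg_means = sums / sizes[:, None]

    X = _intercept_design(diffs, adjust_age)
    b0, s2, df, c00 = _fit_intercept(seg_means, X)
    se = np.sqrt(s2 * c00)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b0 / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)

    ann = manifest.loc[order]
    seg_table = pd.DataFrame({
        "segment_id": np.arange(n_seg),
        "chrom": ann["chrom"].groupby(seg_ids).first().to_numpy(),
        "start": ann["pos"].groupby(seg_ids).min().to_numpy(),
        "end": ann["pos"].groupby(seg_ids).max().to_numpy(),
        "n_cpgs": sizes.astype(int),
        "statistic": t,
        "p": p,
    })
    site = pd.DataFrame({
        "statistic": t[seg_ids],
        "p": p[seg_ids],
        "segment_id": seg_ids,
    }, index=order).loc[diffs.d.index]
    return site, seg_table


# --------------------------------------------------------------------------
# multiple testing and consensus
# --------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ConsensusSet:
    probes: pd.Index
    n_increased: int
    n_decreased: int

    def __len__(self) -> int:
        return len(self.probes)


def consensus_sites(method_results: dict[str, pd.DataFrame],
                    diffs: PairedDiffs, alpha: float = 0.05
                    ) -> tuple[ConsensusSet, pd.DataFrame]:
    """Intersect the per-method FDR < alpha calls into the consensus set.

    ``method_results`` maps method name -> DataFrame with at least a ``q``
    column (and optionally statistic/p), all indexed identically by probe.
    The returned site table carries delta-beta, per-method columns, the
    consensus flag and the direction (sign of delta-beta).
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigError("alpha must be in (0, 1]")
    names = list(method_results)
    base = method_results[names[0]].index
    for name in names[1:]:
        if not method_results[name].index.equals(base):
            raise ValidationError(f"probe ids of method {name!r} are misaligned")
    if not diffs.d.index.equals(base):
        raise ValidationError("paired differences are misaligned with test results")

    table = pd.DataFrame(index=base)
    table["delta_beta"] = diffs.dbeta.mean(axis=1)
    consensus = np.ones(len(base), dtype=bool)
    for name in names:
        res = method_results[name]
        for col in res.columns:
            table[f"{name}_{col}"] = res[col].to_numpy()
        sig = (res["q"] < alpha).to_numpy()
        table[f"{name}_significant"] = sig
        consensus &= sig
    table["consensus"] = consensus
    table["direction"] = np.where(table["delta_beta"] >= 0, "increased", "decreased")

    cons_idx = base[consensus]
    n_inc = int((table.loc[cons_idx, "direction"] == "increased").sum())
    return ConsensusSet(probes=cons_idx, n_increased=n_inc,
                        n_decreased=len(cons_idx) - n_inc), table


def run_site_tests(diffs: PairedDiffs, manifest: pd.DataFrame,
                   alpha: float = 0.05, max_gap: int = 500,
                   adjust_age: bool = True
                   ) -> tuple[ConsensusSet, pd.DataFrame, ModerationParams]:
    """The full three-method site analysis with per-method BH adjustment.

    BH runs across sites for the moderated and Wilcoxon arms and across
    segments for the segment arm (segment q propagated to member probes).
    """
    mod, params = moderated_paired_test(diffs, adjust_age=adjust_age)
    mod = mod.assign(q=bh_fdr(mod["p"]))
    wil = wilcoxon_paired_test(diffs)[["statistic", "p"]]
    wil = wil.assign(q=bh_fdr(wil["p"]))
    seg_site, seg_table = segment_test(diffs, manifest, max_gap=max_gap,
                                       adjust_age=adjust_age)
    seg_q = bh_fdr(seg_table["p"])
    seg_site = seg_site.assign(q=seg_q[seg_site["segment_id"].to_numpy()])
    consensus, table = consensus_sites(
        {"moderated": mod, "wilcoxon": wil,
         "segment": seg_site[["statistic", "p", "q"]]},
        diffs, alpha=alpha)
    return consensus, table, params
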