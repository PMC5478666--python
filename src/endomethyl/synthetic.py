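"""Synthetic study generator.

Emulates a paired 450K-style methylation study of the endometrial
pre-receptive (LH+2) to receptive (LH+8) transition, plus a matched RNA-seq
count matrix, so that every downstream stage (filtering, site tests, region
calling, methylation-expression correlation) can be exercised and scored
against known ground truth.

Generative model
----------------
* CpGs are laid out in clusters along chromosomes (within-cluster spacing of
  tens to hundreds of bp, large gaps between clusters), mirroring the spatial
  clumping of array probes around islands and promoters.
* Baseline methylation is drawn on the M scale from a tri-modal landscape
  (hypomethylated / intermediate / hypermethylated); beta values arise by
  inverse logit2, so the emitted beta distribution is the familiar U shape.
* A minority of CpGs (``frac_dmc``) receives a phase effect: the receptive
  sample of every subject is shifted by a delta chosen on the M scale so the
  induced beta-difference equals a planted ``true_delta_beta`` (mostly
  positive, small).  Some effects are planted as contiguous same-sign blocks
  of >= 3 CpGs within 500 bp — ground-truth DMRs.
* Per-sample M values add a subject random effect and Gaussian noise, and are
  emitted as methylated/unmethylated intensity pairs by drawing a log-normal
  total intensity T and splitting it, so downstream beta/M recomputation
  (including the +100 offset bias of the beta formula) is exercised.
* Expression counts are Poisson around library-size-scaled rates; designated
  CpG-gene pairs couple log-expression to the CpG's M value with a planted
  sign and a noise level tuned to a target Spearman magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .config import PHASE_PRE, PHASE_REC, SimConfig, super_group
from .errors import GenerationError, ValidationError
from . import io

_LN2 = np.log(2.0)

# distinct child-stream ids so each generator is individually reproducible
_STREAM_MANIFEST = 1
_STREAM_COHORT = 2
_STREAM_METH = 3
_STREAM_EXPR = 4


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def expit2(m: np.ndarray) -> np.ndarray:
    """Inverse logit2: M-value -> offset-free beta."""
    return expit(np.asarray(m, dtype=float) * _LN2)


def logit2(beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    return np.log2(beta / (1.0 - beta))


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Inverse-CDF sampling of a truncated normal (vectorized, deterministic)."""
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size)
    return mean + sd * ndtri(u)


# --------------------------------------------------------------------------
# manifest and cohort
# --------------------------------------------------------------------------

def generate_manifest(config: SimConfig) -> pd.DataFrame:
    """Generate a probe manifest with clustered coordinates and annotations.

    Returns a DataFrame indexed by ``probe_id`` with columns chrom, pos,
    genes (semicolon-delimited ``gene:subregion`` tokens, possibly empty),
    cgi_relation, snp_flag, crossreactive_flag; sorted by (chrom, pos) with
    strictly increasing positions within a chromosome.
    """
    config.validate()
    cols = ["chrom", "pos", "genes", "cgi_relation", "snp_flag", "crossreactive_flag"]
    if config.n_probes == 0:
        empty = pd.DataFrame(columns=cols)
        empty.index.name = "probe_id"
        return empty
    rng = _rng(config, _STREAM_MANIFEST)

    # cluster sizes until we cover n_probes
    sizes = []
    total = 0
    while total < config.n_probes:
        s = 1 + int(rng.poisson(max(config.mean_cluster_size - 1.0, 0.0)))
        s = min(s, config.n_probes - total)
        sizes.append(s)
        total += s
    n_clusters = len(sizes)

    autosomes = [f"chr{i}" for i in range(1, config.n_chromosomes + 1)]
    sex = rng.random(n_clusters) < config.frac_sex_clusters
    chroms = np.array(
        [rng.choice(["chrX", "chrY"]) if s else rng.choice(autosomes) for s in sex]
    )
    # island-centered / open-sea / flank cluster themes
    theme = rng.choice(["island", "opensea", "flank"], n_clusters, p=[0.50, 0.35, 0.15])

    cursors = {c: 10_000 for c in autosomes + ["chrX", "chrY"]}
    rows_chrom, rows_pos, rows_cgi, rows_genes = [], [], [], []
    gene_counter = 0
    for ci in range(n_clusters):
        size, chrom, th = sizes[ci], chroms[ci], theme[ci]
        start = cursors[chrom] + int(rng.integers(*config.intercluster_gap))
        gaps = rng.integers(config.cluster_gap[0], config.cluster_gap[1] + 1, size)
        pos = start + np.cumsum(gaps)
        cursors[chrom] = int(pos[-1])

        if th == "island":
            cgi = []
            half = max((size - 1) / 2.0, 1.0)
            for i in range(size):
                rel = i - (size - 1) / 2.0
                frac = abs(rel) / half if size > 1 else 0.0
                if frac <= 0.6:
                    cgi.append("island")
                elif frac <= 0.85:
                    cgi.append("N_Shore" if rel < 0 else "S_Shore")
                else:
                    cgi.append("N_Shelf" if rel < 0 else "S_Shelf")
        elif th == "opensea":
            cgi = ["OpenSea"] * size
        else:
            cgi = list(rng.choice(["N_Shore", "S_Shore", "N_Shelf", "S_Shelf"], size))

        gene_prob = config.frac_gene_cluster * (0.4 if th == "opensea" else 1.0)
        if rng.random() < gene_prob:
            gene_counter += 1
            gene = f"GENE{gene_counter:05d}"
            if th == "island":
                regions = rng.choice(["TSS1500", "TSS200", "5'UTR", "1stExon"],
                                     size, p=[0.35, 0.25, 0.25, 0.15])
            else:
                regions = rng.choice(["Body", "3'UTR"], size, p=[0.8, 0.2])
            tokens = [f"{gene}:{r}" for r in regions]
            # occasional overlap with a second gene -> multi-annotated probes
            for i in range(size):
                if rng.random() < config.frac_second_gene:
                    tokens[i] += f";GENE{gene_counter + 1:05d}:Body"
        else:
            tokens = [""] * size

        rows_chrom.extend([chrom] * size)
        rows_pos.extend(pos.tolist())
        rows_cgi.extend(cgi)
        rows_genes.extend(tokens)

    n = len(rows_pos)
    noncpg = rng.random(n) < config.frac_noncpg
    snp = rng.random(n) < config.frac_snp
    xr = rng.random(n) < config.frac_crossreactive
    manifest = pd.DataFrame({
        "chrom": rows_chrom,
        "pos": np.asarray(rows_pos, dtype=np.int64),
        "genes": rows_genes,
        "cgi_relation": rows_cgi,
        "snp_flag": snp,
        "crossreactive_flag": xr,
        "_noncpg": noncpg,
    })
    manifest = io.sort_manifest(manifest).reset_index(drop=True)
    prefix = np.where(manifest.pop("_noncpg").to_numpy(), "ch", "cg")
    # ids assigned after the genomic sort, so lexical id order == genomic order
    manifest.index = pd.Index(
        [f"{p}{i + 1:08d}" for i, p in enumerate(prefix)], name="probe_id")
    validate_manifest(manifest)
    return manifest


def validate_manifest(manifest: pd.DataFrame) -> None:
    if manifest.index.has_duplicates:
        raise ValidationError("duplicate probe ids in manifest")
    dup = manifest.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise ValidationError(
            f"duplicate (chrom, pos) coordinates: {manifest.index[dup].tolist()[:5]}")


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: two samples (LH+2, LH+8) per subject, one age each."""
    config.validate()
    rng = _rng(config, _STREAM_COHORT)
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    ages = rng.integers(config.age_range[0], config.age_range[1] + 1,
                        config.n_subjects)
    rows = []
    for subj, age in zip(subjects, ages):
        rows.append((f"{subj}_LH2", subj, PHASE_PRE, int(age)))
        rows.append((f"{subj}_LH8", subj, PHASE_REC, int(age)))
    return pd.DataFrame(rows, columns=io.SHEET_COLUMNS)


# --------------------------------------------------------------------------
# methylation
# --------------------------------------------------------------------------

@dataclass
class SimulatedMethylation:
    m_intensity: pd.DataFrame
    u_intensity: pd.DataFrame
    detection_fail: pd.DataFrame
    truth: pd.DataFrame
    #: latent per-sample M values (generative scale, before intensity emission)
    latent_m: pd.DataFrame = field(repr=False, default=None)


#: ordering scores tilting the landscape by island relation: CpG islands are
#: preferentially hypomethylated, open sea hypermethylated, as on real arrays
_CGI_SCORE = {"island": -1.2, "N_Shore": -0.4, "S_Shore": -0.4,
              "N_Shelf": 0.4, "S_Shelf": 0.4, "OpenSea": 0.7}


def _assign_modes(rng, manifest: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Assign (hypo, intermediate, hyper) modes with exact marginal weights.

    Probes are ranked by a noisy CGI-relation score and the configured mode
    counts are dealt out along that ranking, so category-conditional
    methylation is realistic while the overall landscape fractions equal
    ``landscape_weights``.
    """
    n_p = len(manifest)
    score = manifest["cgi_relation"].map(_CGI_SCORE).to_numpy(dtype=float)
    score = score + rng.normal(0.0, 1.0, n_p)
    order = np.argsort(score, kind="stable")
    w = config.landscape_weights
    n_hypo, n_hyper = int(round(w[0] * n_p)), int(round(w[2] * n_p))
    modes = np.ones(n_p, dtype=np.int64)
    modes[order[:n_hypo]] = 0
    if n_hyper:
        modes[order[n_p - n_hyper:]] = 2
    return modes


def _draw_baseline_m(rng, modes: np.ndarray) -> np.ndarray:
    mu = np.empty(modes.shape[0])
    hypo, mid, hyper = modes == 0, modes == 1, modes == 2
    mu[hypo] = _truncnorm(rng, -3.5, 0.7, -6.0, -2.2, int(hypo.sum()))
    mu[mid] = rng.uniform(-1.8, 1.8, int(mid.sum()))
    mu[hyper] = _truncnorm(rng, 3.5, 0.7, 2.2, 6.0, int(hyper.sum()))
    return mu


def _candidate_runs(manifest: pd.DataFrame, eligible: np.ndarray,
                    max_gap: int = 500) -> list[np.ndarray]:
    """Maximal runs of eligible probes with same-chromosome gaps <= max_gap."""
    idx = np.flatnonzero(eligible)
    runs, current = [], []
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    for k in idx:
        if current and chrom[k] == chrom[current[-1]] and \
                pos[k] - pos[current[-1]] <= max_gap:
            current.append(k)
        else:
            if len(current) >= 3:
                runs.append(np.array(current))
            current = [k]
    if len(current) >= 3:
        runs.append(np.array(current))
    return runs


def simulate_methylation(manifest: pd.DataFrame, sheet: pd.DataFrame,
                         config: SimConfig) -> SimulatedMethylation:
    """Simulate intensities for every probe x sample plus the truth table."""
    config.validate()
    rng = _rng(config, _STREAM_METH)
    n_p = len(manifest)
    probes = manifest.index

    is_cg = probes.str.startswith("cg")
    autosomal = ~manifest["chrom"].isin(["chrX", "chrY"]).to_numpy()
    unreliable = rng.random(n_p) < config.frac_unreliable
    clean = (is_cg & autosomal & ~manifest["snp_flag"].to_numpy()
             & ~manifest["crossreactive_flag"].to_numpy() & ~unreliable)

    modes = _assign_modes(rng, manifest, config)
    mu = _draw_baseline_m(rng, modes)

    # --- plant differential CpGs -------------------------------------------
    is_dmc = clean & (rng.random(n_p) < config.frac_dmc)
    block_id = np.full(n_p, -1, dtype=np.int64)
    if config.n_dmr_blocks > 0 and n_p > 0:
        runs = _candidate_runs(manifest, clean)
        if len(runs) < config.n_dmr_blocks:
            raise GenerationError(
                f"cannot place DMR block {len(runs) + 1}: only {len(runs)} "
                f"candidate runs of >=3 clustered eligible probes")
        chosen = rng.choice(len(runs), config.n_dmr_blocks, replace=False)
        for b, ri in enumerate(chosen):
            run = runs[ri]
            k = int(min(len(run), rng.integers(3, 6)))
            off = int(rng.integers(0, len(run) - k + 1))
            members = run[off:off + k]
            is_dmc[members] = True
            block_id[members] = b

    sign = np.where(rng.random(n_p) < config.frac_increase, 1.0, -1.0)
    for b in np.unique(block_id[block_id >= 0]):
        members = block_id == b
        sign[members] = sign[np.flatnonzero(members)[0]]
    mag = rng.uniform(*config.effect_delta_beta, n_p)

    beta1 = expit2(mu)
    target = beta1 + sign * mag
    bad = is_dmc & ((target <= 0.02) | (target >= 0.98) |
                    (beta1 <= 0.02) | (beta1 >= 0.98))
    if bad.any():
        # re-draw baseline so the planted shift fits inside (0, 1)
        nb = int(bad.sum())
        lo = np.where(sign[bad] > 0, 0.05, 0.03 + mag[bad])
        hi = np.where(sign[bad] > 0, 0.97 - mag[bad], 0.95)
        beta1_new = rng.uniform(lo, hi, nb)
        beta1[bad] = beta1_new
        mu[bad] = logit2(beta1_new)

    true_delta_beta = np.where(is_dmc, sign * mag, 0.0)
    beta2 = beta1 + true_delta_beta
    delta_m = np.where(is_dmc, logit2(beta2) - logit2(beta1), 0.0)

    # --- per-sample M values -----------------------------------------------
    subjects = sheet["subject_id"].unique()
    subj_index = {s: i for i, s in enumerate(subjects)}
    b_subj = rng.normal(0.0, config.subject_sd, (n_p, len(subjects))) \
        if config.subject_sd > 0 else np.zeros((n_p, len(subjects)))

    n_s = len(sheet)
    M = np.empty((n_p, n_s))
    for j, row in enumerate(sheet.itertuples(index=False)):
        eps = rng.normal(0.0, config.sigma_m, n_p) if config.sigma_m > 0 else 0.0
        M[:, j] = (mu + b_subj[:, subj_index[row.subject_id]]
                   + (row.phase == PHASE_REC) * delta_m + eps)

    total = rng.lognormal(config.intensity_lognorm[0],
                          config.intensity_lognorm[1], (n_p, n_s))
    frac = expit2(M)
    m_int = frac * total
    u_int = total - m_int

    fail = np.zeros((n_p, n_s), dtype=bool)
    fail[unreliable] = rng.random((int(unreliable.sum()), n_s)) < 0.2
    fail |= rng.random((n_p, n_s)) < 0.0005

    samples = sheet["sample_id"].tolist()
    truth = pd.DataFrame({
        "is_dmc": is_dmc,
        "true_delta_beta": true_delta_beta,
        "dmr_block_id": block_id,
        "coupled_gene": "",
        "coupling_sign": np.zeros(n_p, dtype=np.int64),
        "coupling_strength": np.zeros(n_p),
    }, index=probes)
    return SimulatedMethylation(
        m_intensity=pd.DataFrame(m_int, index=probes, columns=samples),
        u_intensity=pd.DataFrame(u_int, index=probes, columns=samples),
        detection_fail=pd.DataFrame(fail, index=probes, columns=samples),
        truth=truth,
        latent_m=pd.DataFrame(M, index=probes, columns=samples),
    )


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def simulate_expression(manifest: pd.DataFrame, sheet: pd.DataFrame,
                        truth: pd.DataFrame, config: SimConfig,
                        m_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate RNA-seq counts for the expression sub-cohort.

    Returns (counts, truth) where counts is genes x samples (integer) for the
    ``n_expr_subjects`` subjects with expression data, and truth has the
    coupling columns (coupled_gene, coupling_sign, coupling_strength) filled
    for the planted CpG-gene pairs.
    """
    config.validate()
    rng = _rng(config, _STREAM_EXPR)
    truth = truth.copy()

    genes = sorted({g for toks in manifest["genes"] if toks
                    for g, _ in io.parse_gene_tokens(toks)})
    subjects = sorted(sheet["subject_id"].unique())
    expr_subjects = sorted(rng.choice(subjects, config.effective_expr_subjects,
                                      replace=False))
    expr_sheet = sheet[sheet["subject_id"].isin(expr_subjects)]
    samples = expr_sheet["sample_id"].tolist()
    n_g, n_s = len(genes), len(samples)
    if n_g == 0:
        return pd.DataFrame(columns=samples), truth

    gene_pos = {g: i for i, g in enumerate(genes)}
    baseline = rng.uniform(4.0, 9.0, n_g)
    log_expr = baseline[:, None] + rng.normal(
        0.0, config.expression_noise_sd, (n_g, n_s))

    # target Pearson r of the latent Gaussian giving the requested Spearman rho
    strength = config.coupling_strength
    r_target = 2.0 * np.sin(np.pi * strength / 6.0)

    eligible = truth.index[
        truth["is_dmc"]
        & (truth["true_delta_beta"].abs() > 0.1)
        & (manifest.loc[truth.index, "genes"] != "")
    ]
    taken_genes: set[str] = set()
    for probe in eligible:
        gene, region = io.parse_gene_tokens(manifest.at[probe, "genes"])[0]
        if gene not in gene_pos or gene in taken_genes:
            continue
        if rng.random() >= config.frac_corr_pairs:
            continue
        p_pos = config.corr_sign_by_region[super_group(region)]
        sgn = 1 if rng.random() < p_pos else -1
        x = m_matrix.loc[probe, samples].to_numpy(dtype=float)
        sd_sig = float(np.std(x))
        if sd_sig == 0.0:
            continue
        tau = sd_sig * np.sqrt(max(1.0 / r_target**2 - 1.0, 0.0))
        noise = rng.normal(0.0, tau, n_s) if tau > 0 else 0.0
        gi = gene_pos[gene]
        log_expr[gi] = baseline[gi] + sgn * (x - x.mean()) + noise
        taken_genes.add(gene)
        truth.at[probe, "coupled_gene"] = gene
        truth.at[probe, "coupling_sign"] = sgn
        truth.at[probe, "coupling_strength"] = strength

    rates = np.exp2(log_expr)
    libs = rng.integers(config.libsize_range[0], config.libsize_range[1] + 1, n_s)
    if config.count_noise:
        props = rates / rates.sum(axis=0, keepdims=True)
        counts = rng.poisson(props * libs[None, :])
    else:
        # deterministic mode: fixed library and denominator keep counts
        # exactly monotone in the latent expression rate
        lam = rates * (float(np.mean(config.libsize_range)) / rates.sum(axis=0).mean())
        counts = np.rint(lam).astype(np.int64)
    counts = pd.DataFrame(counts.astype(np.int64), index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    return counts, truth


# --------------------------------------------------------------------------
# full bundle
# --------------------------------------------------------------------------

@dataclass
class StudyBundle:
    config: SimConfig
    manifest: pd.DataFrame
    sheet: pd.DataFrame
    m_intensity: pd.DataFrame
    u_intensity: pd.DataFrame
    detection_fail: pd.DataFrame
    expression: pd.DataFrame
    truth: pd.DataFrame
    latent_m: pd.DataFrame


def simulate_study(config: SimConfig) -> StudyBundle:
    """Generate the full synthetic study (manifest, cohort, arrays, RNA-seq)."""
    manifest = generate_manifest(config)
    sheet = generate_cohort(config)
    meth = simulate_methylation(manifest, sheet, config)
    expression, truth = simulate_expression(
        manifest, sheet, meth.truth, config, meth.latent_m)
    return StudyBundle(config=config, manifest=manifest, sheet=sheet,
                       m_intensity=meth.m_intensity, u_intensity=meth.u_intensity,
                       detection_fail=meth.detection_fail, expression=expression,
                       truth=truth, latent_m=meth.latent_m)


def write_bundle(bundle: StudyBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_manifest(bundle.manifest, out / "manifest.tsv")
    io.write_sample_sheet(bundle.sheet, out / "samples.csv")
    io.write_matrix(bundle.m_intensity, out / "m_intensity.tsv")
    io.write_matrix(bundle.u_intensity, out / "u_intensity.tsv")
    io.write_matrix(bundle.detection_fail.astype(int), out / "detection_fail.tsv")
    io.write_matrix(bundle.expression, out / "expression_counts.tsv",
                    index_label="gene_id")
    io.write_matrix(bundle.truth, out / "truth.tsv")
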