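"""Configuration objects for the simulation and analysis stages.

All tunables of the pipeline live here so that every stage is reproducible
from a single config + seed.  Defaults encode the study design the pipeline
emulates: 17 subjects sampled in the pre-receptive (LH+2) and receptive
(LH+8) endometrial phases, a 450K-style probe landscape, a ~5% minority of
truly differential CpGs with small, mostly positive beta-shifts, and a
7-subject (14-sample) methylation-expression correlation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Tuple

from .errors import ConfigError

PHASE_PRE = "LH+2"
PHASE_REC = "LH+8"

GENE_SUBREGIONS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR")
CGI_CATEGORIES = ("island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: promoter-proximal subregions pooled as the 5' region; the rest is gene body
FIVE_PRIME_GROUP = ("TSS1500", "TSS200", "5'UTR", "1stExon")
GENE_BODY_GROUP = ("Body", "3'UTR")


def super_group(region: str) -> str:
    """Map a gene subregion to its 5'-region / gene-body super-group."""
    if region in FIVE_PRIME_GROUP:
        return "5' region"
    if region in GENE_BODY_GROUP:
        return "gene body"
    raise ConfigError(f"unknown gene subregion: {region!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    The generative scale for methylation is the M scale (log2 methylated /
    unmethylated intensity) with Gaussian noise; beta values arise by inverse
    logit2 so the emitted intensities reproduce the familiar tri-modal beta
    landscape.
    """

    n_subjects: int = 17
    age_range: Tuple[int, int] = (24, 35)
    n_probes: int = 20_000
    n_chromosomes: int = 22
    #: within-cluster inter-CpG spacing (uniform, bp)
    cluster_gap: Tuple[int, int] = (20, 400)
    #: between-cluster spacing (uniform, bp)
    intercluster_gap: Tuple[int, int] = (2_000, 50_000)
    #: cluster size is 1 + Poisson(mean_cluster_size - 1)
    mean_cluster_size: float = 4.0
    #: baseline weights of the (hypo, intermediate, hyper) methylation modes
    landscape_weights: Tuple[float, float, float] = (0.33, 0.48, 0.19)
    frac_dmc: float = 0.05
    #: fraction of true DMCs gaining methylation in the receptive phase
    frac_increase: float = 0.845
    #: range of |delta-beta| for planted differential CpGs
    effect_delta_beta: Tuple[float, float] = (0.05, 0.25)
    #: within-subject noise SD on the M scale
    sigma_m: float = 0.3
    #: between-subject random-effect SD on the M scale
    subject_sd: float = 0.3
    n_dmr_blocks: int = 30
    #: probability that an eligible CpG-gene pair gets planted expression coupling
    frac_corr_pairs: float = 0.5
    coupling_strength: float = 0.9
    #: probability of a positive methylation-expression coupling by super-group
    corr_sign_by_region: Mapping[str, float] = field(
        default_factory=lambda: {"gene body": 0.565, "5' region": 0.444}
    )
    libsize_range: Tuple[int, int] = (800_000, 1_200_000)
    #: subjects with expression data (both phases); the study had 7 of 17
    n_expr_subjects: int = 7
    # manifest nuisance fractions (450K-like proportions)
    frac_snp: float = 0.010
    frac_crossreactive: float = 0.063
    frac_sex_clusters: float = 0.022
    frac_noncpg: float = 0.003
    frac_unreliable: float = 0.0035
    frac_gene_cluster: float = 0.70
    frac_second_gene: float = 0.02
    #: total-intensity log-normal parameters (log-mean, log-sd)
    intensity_lognorm: Tuple[float, float] = (8.0, 0.3)
    #: draw Poisson counts for expression; False emits rounded expected counts
    count_noise: bool = True
    expression_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.n_probes < 0:
            raise ConfigError("n_probes must be non-negative")
        if self.n_chromosomes <= 0:
            raise ConfigError("n_chromosomes must be positive")
        if abs(sum(self.landscape_weights) - 1.0) > 1e-9:
            raise ConfigError("landscape_weights must sum to 1")
        for name in ("frac_dmc", "frac_increase", "frac_corr_pairs", "frac_snp",
                     "frac_crossreactive", "frac_sex_clusters", "frac_noncpg",
                     "frac_unreliable", "frac_gene_cluster", "frac_second_gene"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.coupling_strength <= 1.0:
            raise ConfigError("coupling_strength must be in (0, 1]")
        lo, hi = self.effect_delta_beta
        if not 0.0 < lo <= hi < 1.0:
            raise ConfigError("effect_delta_beta must satisfy 0 < lo <= hi < 1")
        if self.n_probes and self.n_probes < 3 * self.n_dmr_blocks:
            raise ConfigError("n_probes must be >= 3 * n_dmr_blocks")
        if self.sigma_m < 0 or self.subject_sd < 0:
            raise ConfigError("noise SDs must be non-negative")
        if self.n_expr_subjects < 2:
            raise ConfigError("n_expr_subjects must be >= 2")
        return self

    @property
    def effective_expr_subjects(self) -> int:
        """Expression sub-cohort size, capped by the cohort itself."""
        return min(self.n_expr_subjects, self.n_subjects)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corr_sign_by_region"] = dict(self.corr_sign_by_region)
        return d


@dataclass
class DmrConfig:
    """Windowing rule for region calling: >= min_cpgs consecutive significant
    CpGs whose adjacent gaps stay within max_gap bp and share a direction."""

    min_cpgs: int = 3
    max_gap: int = 500
    alpha: float = 0.05
    #: "gap" = adjacent-pair gaps <= max_gap; "span" = total span <= max_gap
    window_rule: str = "gap"

    def validate(self) -> "DmrConfig":
        if self.min_cpgs < 2:
            raise ConfigError("min_cpgs must be >= 2")
        if self.max_gap <= 0:
            raise ConfigError("max_gap must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError("alpha must be in (0, 1]")
        if self.window_rule not in ("gap", "span"):
            raise ConfigError("window_rule must be 'gap' or 'span'")
        return self


@dataclass
class CorrelationConfig:
    delta_beta_threshold: float = 0.1
    alpha: float = 0.05
    n_permutations: int = 10_000
    #: permute expression across all samples; "paired" swaps within subjects
    scheme: str = "free"
    seed: int = 0

    def validate(self) -> "CorrelationConfig":
        if self.delta_beta_threshold <= 0:
            raise ConfigError("delta_beta_threshold must be positive")
        if self.n_permutations < 99:
            raise ConfigError("n_permutations must be >= 99")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError("alpha must be in (0, 1]")
        if self.scheme not in ("free", "paired"):
            raise ConfigError("scheme must be 'free' or 'paired'")
        return self
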