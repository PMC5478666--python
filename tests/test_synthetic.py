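"""Generator contracts: determinism, planted structure, landscape shape."""

import numpy as np
import pandas as pd
import pytest

from endomethyl import preprocess
from endomethyl.config import PHASE_PRE, PHASE_REC, SimConfig
from endomethyl.errors import ConfigError, ValidationError
from endomethyl.synthetic import (generate_cohort, generate_manifest,
                                  simulate_methylation, simulate_study,
                                  validate_manifest)


class TestManifest:
    def test_empty_config_gives_empty_table(self):
        man = generate_manifest(SimConfig(n_probes=0, n_dmr_blocks=0))
        assert len(man) == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError):
            generate_manifest(SimConfig(n_probes=-5))

    def test_duplicate_coordinates_rejected(self):
        man = generate_manifest(SimConfig(n_probes=10, n_dmr_blocks=0, seed=1))
        man.iloc[1, man.columns.get_loc("pos")] = man["pos"].iloc[0]
        with pytest.raises(ValidationError):
            validate_manifest(man)

    def test_determinism(self):
        cfg = SimConfig(n_probes=1000, n_dmr_blocks=0, seed=1)
        pd.testing.assert_frame_equal(generate_manifest(cfg),
                                      generate_manifest(cfg))

    def test_sorted_and_annotated(self, small_bundle):
        man = small_bundle.manifest
        for _, grp in man.groupby("chrom", sort=False):
            assert (np.diff(grp["pos"]) > 0).all()
        assert man["cgi_relation"].isin(
            ["island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]).all()


class TestCohort:
    def test_paired_design(self):
        sheet = generate_cohort(SimConfig(n_subjects=17))
        assert len(sheet) == 34
        per_subject = sheet.groupby("subject_id")["phase"].apply(set)
        assert all(p == {PHASE_PRE, PHASE_REC} for p in per_subject)
        ages = sheet.groupby("subject_id")["age"].nunique()
        assert (ages == 1).all()

    def test_two_subjects(self):
        sheet = generate_cohort(SimConfig(n_subjects=2))
        assert len(sheet) == 4 and sheet["age"].between(24, 35).all()

    def test_age_determinism(self):
        cfg = SimConfig(n_subjects=5, seed=3)
        a = generate_cohort(cfg)["age"]
        b = generate_cohort(cfg)["age"]
        assert (a == b).all()


class TestMethylation:
    def test_noise_free_null_is_phase_constant(self):
        cfg = SimConfig(n_probes=200, n_subjects=4, sigma_m=0.0,
                        subject_sd=0.0, frac_dmc=0.0, n_dmr_blocks=0, seed=2)
        man, sheet = generate_manifest(cfg), generate_cohort(cfg)
        sim = simulate_methylation(man, sheet, cfg)
        # latent M identical across all samples per probe
        assert np.allclose(sim.latent_m.to_numpy().std(axis=1), 0.0)
        # recomputed M is phase-constant (the +1 offset is negligible here)
        mv = preprocess.compute_m(sim.m_intensity, sim.u_intensity)
        assert mv.to_numpy().std(axis=1).max() < 0.01
        # recomputed beta varies only through the +100 offset bias, bounded
        # by beta * 100 * spread(1/total)
        beta = preprocess.compute_beta(sim.m_intensity, sim.u_intensity)
        total = (sim.m_intensity + sim.u_intensity).to_numpy()
        bound = 100.0 * (1.0 / total.min(axis=1) - 1.0 / total.max(axis=1))
        assert (beta.to_numpy().std(axis=1) <= bound).all()

    def test_planted_block_shifts_beta(self):
        cfg = SimConfig(n_probes=500, n_subjects=6, sigma_m=0.05,
                        subject_sd=0.05, frac_dmc=0.0, n_dmr_blocks=1,
                        frac_increase=1.0, effect_delta_beta=(0.2, 0.2), seed=4)
        man, sheet = generate_manifest(cfg), generate_cohort(cfg)
        sim = simulate_methylation(man, sheet, cfg)
        block = sim.truth.index[sim.truth["dmr_block_id"] == 0]
        assert len(block) >= 3
        beta = preprocess.compute_beta(sim.m_intensity, sim.u_intensity)
        pre = sheet.loc[sheet["phase"] == PHASE_PRE, "sample_id"]
        rec = sheet.loc[sheet["phase"] == PHASE_REC, "sample_id"]
        dbeta = beta[rec].to_numpy().mean(1) - beta[pre].to_numpy().mean(1)
        assert (dbeta[sim.truth.index.get_indexer(block)] > 0.1).all()

    def test_dmc_count_binomial(self, small_bundle):
        """~frac_dmc of eligible probes are planted, within binomial 3 SD."""
        cfg = SimConfig(n_probes=20_000, frac_dmc=0.05, n_dmr_blocks=0, seed=9)
        man, sheet = generate_manifest(cfg), generate_cohort(cfg)
        sim = simulate_methylation(man, sheet, cfg)
        eligible = (man.index.str.startswith("cg")
                    & ~man["chrom"].isin(["chrX", "chrY"])
                    & ~man["snp_flag"] & ~man["crossreactive_flag"])
        n_elig = int(eligible.sum())
        n_dmc = int(sim.truth["is_dmc"].sum())
        sd = np.sqrt(n_elig * 0.05 * 0.95)
        assert abs(n_dmc - 0.05 * n_elig) < 3 * sd + 30  # +30: unreliable overlap

    def test_truth_invariant_null_probes_have_zero_delta(self, small_bundle):
        truth = small_bundle.truth
        assert (truth.loc[~truth["is_dmc"], "true_delta_beta"] == 0).all()
        assert (truth.loc[truth["is_dmc"], "true_delta_beta"] != 0).all()

    def test_planted_effect_fidelity(self, small_bundle):
        """Recomputed paired mean delta-beta tracks the planted values."""
        b = small_bundle
        beta = preprocess.compute_beta(b.m_intensity, b.u_intensity)
        pre = b.sheet.loc[b.sheet["phase"] == PHASE_PRE, "sample_id"]
        rec = b.sheet.loc[b.sheet["phase"] == PHASE_REC, "sample_id"]
        dbeta = beta[rec].to_numpy().mean(1) - beta[pre].to_numpy().mean(1)
        dmc = b.truth["is_dmc"].to_numpy()
        r = np.corrcoef(dbeta[dmc], b.truth["true_delta_beta"].to_numpy()[dmc])[0, 1]
        assert r > 0.95

    def test_landscape_fractions_match_weights(self):
        cfg = SimConfig(n_probes=20_000, frac_dmc=0.0, n_dmr_blocks=0, seed=13)
        man, sheet = generate_manifest(cfg), generate_cohort(cfg)
        sim = simulate_methylation(man, sheet, cfg)
        beta = preprocess.compute_beta(sim.m_intensity, sim.u_intensity)
        mean_beta = beta.to_numpy().mean(axis=1)
        n = len(mean_beta)
        for frac, weight in [((mean_beta > 0.8).mean(), 0.19),
                             ((mean_beta < 0.2).mean(), 0.33)]:
            sd = np.sqrt(weight * (1 - weight) / n)
            assert abs(frac - weight) < 3 * sd + 0.01


class TestExpression:
    def test_noise_free_coupling_is_exactly_monotone(self):
        cfg = SimConfig(n_probes=2000, n_subjects=8, n_expr_subjects=7,
                        coupling_strength=1.0, frac_corr_pairs=1.0,
                        effect_delta_beta=(0.15, 0.25), count_noise=False,
                        libsize_range=(50_000_000, 50_000_000),
                        n_dmr_blocks=0, seed=6)
        bundle = simulate_study(cfg)
        from scipy.stats import spearmanr
        coupled = bundle.truth[bundle.truth["coupled_gene"] != ""]
        assert len(coupled) >= 5
        samples = bundle.expression.columns
        for probe, row in coupled.head(10).iterrows():
            x = bundle.latent_m.loc[probe, samples]
            y = bundle.expression.loc[row["coupled_gene"], samples]
            rho = spearmanr(x, y).statistic
            assert rho == pytest.approx(row["coupling_sign"], abs=1e-12)

    def test_null_coupling_centred_on_zero(self):
        cfg = SimConfig(n_probes=2000, frac_corr_pairs=0.0, n_dmr_blocks=0,
                        seed=8)
        bundle = simulate_study(cfg)
        assert (bundle.truth["coupled_gene"] == "").all()
        from scipy.stats import spearmanr
        rng = np.random.default_rng(0)
        genes = rng.choice(bundle.expression.index, 50)
        probes = rng.choice(bundle.truth.index, 50)
        rhos = [spearmanr(bundle.latent_m.loc[p, bundle.expression.columns],
                          bundle.expression.loc[g]).statistic
                for p, g in zip(probes, genes)]
        assert abs(np.mean(rhos)) < 0.1

    def test_negative_coupling_sign_recovered(self):
        """Planted rho=-0.9 at n=14 estimates negative in >= 95% of seeds."""
        from scipy.stats import spearmanr
        hits = total = 0
        for seed in range(40):
            cfg = SimConfig(n_probes=600, n_subjects=7, n_expr_subjects=7,
                            coupling_strength=0.9, frac_corr_pairs=1.0,
                            effect_delta_beta=(0.15, 0.25), n_dmr_blocks=0,
                            corr_sign_by_region={"gene body": 0.0,
                                                 "5' region": 0.0},
                            seed=100 + seed)
            bundle = simulate_study(cfg)
            coupled = bundle.truth[bundle.truth["coupled_gene"] != ""]
            for probe, row in coupled.iterrows():
                x = bundle.latent_m.loc[probe, bundle.expression.columns]
                y = bundle.expression.loc[row["coupled_gene"]]
                total += 1
                hits += spearmanr(x, y).statistic < 0
        assert total >= 100 and hits / total >= 0.95

    def test_coupling_strength_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(coupling_strength=1.5).validate()


def test_full_bundle_determinism(tmp_path):
    from endomethyl.synthetic import write_bundle
    cfg = SimConfig(n_probes=800, n_dmr_blocks=3, seed=21)
    for sub in ("a", "b"):
        write_bundle(simulate_study(cfg), tmp_path / sub)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name
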