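"""Paired differences, the three site tests, BH and the consensus."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from endomethyl import diffmeth
from endomethyl.config import PHASE_PRE, PHASE_REC
from endomethyl.diffmeth import (ModerationParams, PairedDiffs, bh_fdr,
                                 consensus_sites, moderated_paired_test,
                                 paired_differences, segment_test,
                                 wilcoxon_paired_test)
from endomethyl.errors import ValidationError


def make_diffs(d, ages=None):
    d = np.atleast_2d(np.asarray(d, dtype=float))
    subjects = [f"S{i}" for i in range(d.shape[1])]
    ages = pd.Series(np.asarray(ages, float) if ages is not None
                     else np.full(d.shape[1], 30.0), index=subjects)
    dd = pd.DataFrame(d, columns=subjects,
                      index=[f"cg{i:03d}" for i in range(d.shape[0])])
    return PairedDiffs(d=dd, dbeta=dd / 10.0, ages=ages,
                       age_centered=ages - ages.mean())


def sheet_for(n, ages=None):
    rows = []
    for i in range(n):
        age = 30 if ages is None else ages[i]
        rows.append((f"S{i}_a", f"S{i}", PHASE_PRE, age))
        rows.append((f"S{i}_b", f"S{i}", PHASE_REC, age))
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "phase", "age"])


class TestPairedDifferences:
    def test_sign_convention_and_values(self):
        sheet = sheet_for(2)
        m = pd.DataFrame([[1.0, 1.5, 2.0, 2.25]], index=["cg000"],
                         columns=["S0_a", "S0_b", "S1_a", "S1_b"])
        beta = pd.DataFrame([[0.30, 0.42, 0.5, 0.55]], index=["cg000"],
                            columns=m.columns)
        diffs = paired_differences(m, beta, sheet)
        assert diffs.d.loc["cg000", "S0"] == pytest.approx(0.5)
        assert diffs.dbeta.loc["cg000", "S0"] == pytest.approx(0.12)

    def test_swapped_phases_flip_signs(self):
        sheet = sheet_for(3)
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(4, 6)), columns=sheet["sample_id"])
        d1 = paired_differences(m, m.copy(), sheet).d
        swapped = sheet.copy()
        swapped["phase"] = swapped["phase"].map({PHASE_PRE: PHASE_REC,
                                                 PHASE_REC: PHASE_PRE})
        d2 = paired_differences(m, m.copy(), swapped).d
        np.testing.assert_allclose(d1.to_numpy(), -d2.to_numpy())

    def test_unpaired_subject_rejected(self):
        sheet = sheet_for(2).iloc[:-1]
        m = pd.DataFrame(np.zeros((1, 3)), columns=sheet["sample_id"])
        with pytest.raises(ValidationError, match="S1"):
            paired_differences(m, m.copy(), sheet)


class TestModeratedTest:
    def test_d0_zero_equals_ordinary_t(self):
        """With a null prior the moderated t is the ordinary intercept t."""
        rng = np.random.default_rng(1)
        diffs = make_diffs(rng.normal(size=(20, 8)))
        res, _ = moderated_paired_test(diffs, adjust_age=False,
                                       prior=ModerationParams(0.0, 1.0))
        expected = stats.ttest_1samp(diffs.d.to_numpy(), 0.0, axis=1)
        np.testing.assert_allclose(res["statistic"], expected.statistic, rtol=1e-12)
        np.testing.assert_allclose(res["p"], expected.pvalue, rtol=1e-12)

    def test_hand_computed_single_probe(self):
        # d = [1,2,3]: mean 2, sd 1, t = 2 / (1/sqrt(3)) = 3.4641
        diffs = make_diffs([[1.0, 2.0, 3.0]])
        res, _ = moderated_paired_test(diffs, adjust_age=False,
                                       prior=ModerationParams(0.0, 1.0))
        assert res["statistic"].iloc[0] == pytest.approx(2 * np.sqrt(3), rel=1e-6)

    def test_d0_inf_pools_variance(self):
        rng = np.random.default_rng(2)
        diffs = make_diffs(rng.normal(size=(30, 6)))
        res, _ = moderated_paired_test(diffs, adjust_age=False,
                                       prior=ModerationParams(np.inf, 2.0))
        # all probes share SE sqrt(2/6)
        se = diffs.d.mean(axis=1) / res["statistic"]
        np.testing.assert_allclose(se, np.sqrt(2.0 / 6.0), rtol=1e-9)

    def test_age_adjustment_removes_age_effect(self):
        """Differences linear in age: intercept test stays null-calibrated."""
        rng = np.random.default_rng(3)
        ages = np.arange(10, dtype=float) + 25
        d = np.outer(np.ones(200), ages - ages.mean()) * 0.5 \
            + rng.normal(0, 0.3, (200, 10))
        res_adj, _ = moderated_paired_test(make_diffs(d, ages), adjust_age=True)
        assert (res_adj["p"] < 0.05).mean() < 0.1

    def test_moment_matching_agrees_with_limma(self):
        """Pooled (d0, s0^2) match Bioconductor limma::squeezeVar."""
        rng = np.random.default_rng(4)
        true_var = 0.04 * 4 / rng.chisquare(4, 300)
        s2 = true_var * rng.chisquare(10, 300) / 10
        params = diffmeth.fit_variance_prior(s2, 10)
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            s2 <- c({','.join(f'{v:.12g}' for v in s2)})
            fit <- squeezeVar(s2, df=10)
            cat(fit$df.prior, fit$var.prior, sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        d0_r, s0_r = map(float, out.stdout.split())
        assert params.d0 == pytest.approx(d0_r, rel=1e-4)
        assert params.s0sq == pytest.approx(s0_r, rel=1e-4)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValidationError):
            moderated_paired_test(make_diffs([[1.0, 2.0]]))


def enumeration_wilcoxon(d):
    """2^n sign-flip oracle for the exact two-sided signed-rank p-value."""
    d = np.asarray(d, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [np.sum(ranks[list(signs)]) for signs in
          (np.array(bits, bool) for bits in itertools.product([0, 1], repeat=n))]
    ws = np.array(ws)
    p_low = (ws <= w_obs).mean()
    p_high = (ws >= w_obs).mean()
    return w_obs, min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    @pytest.mark.parametrize("d,w,p", [
        ([1, 2, 3, 4, 5], 15, 0.0625),   # 2/32
        ([2, -1, 3], 5, 0.5),            # 4/8
    ])
    def test_known_exact_values(self, d, w, p):
        res = wilcoxon_paired_test(make_diffs([d]))
        assert res["statistic"].iloc[0] == w
        assert res["p"].iloc[0] == pytest.approx(p)

    def test_symmetry_all_negative(self):
        pos = wilcoxon_paired_test(make_diffs([[1, 2, 3, 4, 5]]))
        neg = wilcoxon_paired_test(make_diffs([[-1, -2, -3, -4, -5]]))
        assert neg["statistic"].iloc[0] == 0
        assert neg["p"].iloc[0] == pytest.approx(pos["p"].iloc[0])

    def test_all_zero_flagged(self):
        res = wilcoxon_paired_test(make_diffs([[0.0, 0.0, 0.0]]))
        assert res["p"].iloc[0] == 1.0 and bool(res["all_zero"].iloc[0])

    def test_zeros_dropped(self):
        with_zero = wilcoxon_paired_test(make_diffs([[0.0, 1.0, 2.0, 3.0]]))
        without = wilcoxon_paired_test(make_diffs([[1.0, 2.0, 3.0]]))
        assert with_zero["p"].iloc[0] == pytest.approx(without["p"].iloc[0])

    def test_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(50, 12))
        res = wilcoxon_paired_test(make_diffs(d))
        for i in range(50):
            ref = stats.wilcoxon(d[i], alternative="two-sided", mode="exact")
            assert res["p"].iloc[i] == pytest.approx(ref.pvalue, rel=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-10, 10).filter(lambda v: abs(v) > 1e-6),
                    min_size=3, max_size=10, unique_by=abs))
    def test_matches_enumeration_oracle(self, d):
        w, p = enumeration_wilcoxon(d)
        res = wilcoxon_paired_test(make_diffs([d]))
        assert res["statistic"].iloc[0] == pytest.approx(w)
        assert res["p"].iloc[0] == pytest.approx(p, rel=1e-12)


class TestSegmentTest:
    def manifest_for(self, positions, chrom="chr1"):
        idx = [f"cg{i:03d}" for i in range(len(positions))]
        return pd.DataFrame({"chrom": chrom, "pos": positions, "genes": "",
                             "cgi_relation": "OpenSea", "snp_flag": False,
                             "crossreactive_flag": False},
                            index=pd.Index(idx, name="probe_id"))

    def test_identical_probes_form_one_segment_with_single_probe_p(self):
        d = np.tile([0.5, 0.8, 0.3, 0.9, 0.4], (3, 1))
        diffs = make_diffs(d)
        man = self.manifest_for([100, 300, 550])
        site, seg = segment_test(diffs, man, adjust_age=False)
        assert site["segment_id"].nunique() == 1
        single = moderated_paired_test(make_diffs([d[0]]), adjust_age=False,
                                       prior=ModerationParams(0.0, 1.0))[0]
        assert site["p"].iloc[0] == pytest.approx(single["p"].iloc[0])

    def test_gap_breaks_segment(self):
        diffs = make_diffs(np.random.default_rng(0).normal(size=(3, 5)))
        man = self.manifest_for([100, 300, 901])  # 601 bp gap
        site, seg = segment_test(diffs, man)
        assert len(seg) == 2 and site["segment_id"].tolist() == [0, 0, 1]

    def test_variance_shrinks_with_segment_size(self):
        """Segment-mean variance scales ~1/k for independent probes."""
        rng = np.random.default_rng(6)
        k, reps, n = 5, 400, 10
        singles, segs = [], []
        for _ in range(reps):
            d = rng.normal(0, 1, (k, n))
            singles.append(d[0].mean())
            segs.append(d.mean())
        ratio = np.var(segs) / np.var(singles)
        assert ratio == pytest.approx(1.0 / k, rel=0.3)

    def test_unsorted_manifest_rejected(self):
        diffs = make_diffs(np.zeros((2, 4)))
        man = self.manifest_for([500, 100])
        with pytest.raises(ValidationError, match="sorted"):
            segment_test(diffs, man)


class TestBH:
    @pytest.mark.parametrize("p,q", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.01, 0.04, 0.03, 0.002], [0.02, 0.04, 0.04, 0.008]),
        ([0.5], [0.5]),
    ])
    def test_hand_computed_step_up(self, p, q):
        np.testing.assert_allclose(bh_fdr(p), q, rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_monotone_capped_order_preserving(self, p):
        q = bh_fdr(p)
        assert (q <= 1.0).all() and (q >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])


class TestConsensus:
    def build(self, qs):
        idx = pd.Index([f"cg{i}" for i in range(len(qs[0]))])
        diffs = make_diffs(np.ones((len(idx), 4)))
        diffs.d.index = diffs.dbeta.index = idx
        methods = {f"m{k}": pd.DataFrame({"q": q}, index=idx)
                   for k, q in enumerate(qs)}
        return methods, diffs

    def test_set_intersection(self):
        # sig sets {a,b,c}, {b,c,d}, {c,b} -> consensus {b,c}
        qs = [[0.01, 0.01, 0.01, 0.9, 0.9],
              [0.9, 0.01, 0.01, 0.01, 0.9],
              [0.9, 0.01, 0.01, 0.9, 0.9]]
        methods, diffs = self.build(qs)
        cons, table = consensus_sites(methods, diffs)
        assert set(cons.probes) == {"cg1", "cg2"}
        assert table["consensus"].sum() == 2

    def test_two_of_three_excluded(self):
        qs = [[0.01], [0.01], [0.9]]
        methods, diffs = self.build(qs)
        cons, _ = consensus_sites(methods, diffs)
        assert len(cons) == 0

    def test_order_invariant(self):
        rng = np.random.default_rng(7)
        qs = [rng.uniform(0, 0.1, 20) for _ in range(3)]
        methods, diffs = self.build(qs)
        a, _ = consensus_sites(methods, diffs)
        reordered = {k: methods[k] for k in reversed(list(methods))}
        b, _ = consensus_sites(reordered, diffs)
        assert list(a.probes) == list(b.probes)

    def test_direction_counts_sum(self, small_run):
        _, result = small_run
        cons = result.consensus
        assert cons.n_increased + cons.n_decreased == len(cons)
        sig = result.site_table[result.site_table["consensus"]]
        assert ((sig["direction"] == "increased")
                == (sig["delta_beta"] >= 0)).all()

    def test_misaligned_ids_rejected(self):
        methods, diffs = self.build([[0.1, 0.1], [0.1, 0.1], [0.1, 0.1]])
        methods["m1"] = methods["m1"].iloc[::-1]
        with pytest.raises(ValidationError):
            consensus_sites(methods, diffs)
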