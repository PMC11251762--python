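import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cismr.meta import assign_cis_trans, clump, dl_meta, meta_analyse
from cismr.sumstats import ConfigError, GeneRegion, LDMatrix, SummaryStats, VariantKey


class TestDLMeta:
    def test_identical_studies_pool_without_heterogeneity(self):
        r = dl_meta([0.2, 0.2], [0.1, 0.1])
        assert r.pooled_beta == pytest.approx(0.2)
        assert r.Q_het == pytest.approx(0.0, abs=1e-12)
        assert r.tau2 == pytest.approx(0.0, abs=1e-12)
        assert r.pooled_se == pytest.approx(np.sqrt(1 / 200))

    def test_heterogeneous_pair_hand_computed(self):
        # w = 100 each; beta_FE = 0.2; Q = 2; tau2 = (2-1)/(200-100) = 0.01;
        # w* = 1/(0.01+0.01) = 50 each; pooled = 0.2; se = sqrt(1/100) = 0.1
        r = dl_meta([0.10, 0.30], [0.10, 0.10])
        assert r.pooled_beta == pytest.approx(0.20)
        assert r.Q_het == pytest.approx(2.0)
        assert r.tau2 == pytest.approx(0.01)
        assert r.pooled_se == pytest.approx(0.10)

    def test_single_study_passthrough(self):
        r = dl_meta([0.15], [0.05])
        assert (r.pooled_beta, r.pooled_se) == (pytest.approx(0.15), pytest.approx(0.05))
        assert r.Q_het == 0.0 and r.tau2 == 0.0 and r.k_studies == 1

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ConfigError):
            dl_meta([0.1, 0.2], [0.1, 0.0])

    @given(
        betas=st.lists(st.floats(-1, 1), min_size=2, max_size=6),
        ses=st.lists(st.floats(0.01, 0.5), min_size=6, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_random_effects_se_never_below_fixed_effects(self, betas, ses):
        k = len(betas)
        ses = ses[:k]
        r = dl_meta(betas, ses)
        fe_se = np.sqrt(1 / np.sum(1 / np.asarray(ses) ** 2))
        assert r.pooled_se >= fe_se - 1e-12
        if r.tau2 == 0:
            assert r.pooled_se == pytest.approx(fe_se)

    @given(
        data=st.lists(
            st.tuples(st.floats(-1, 1), st.floats(0.01, 0.5)), min_size=2, max_size=6
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_order_invariance_and_sign_equivariance(self, data):
        betas = [d[0] for d in data]
        ses = [d[1] for d in data]
        a = dl_meta(betas, ses)
        b = dl_meta(betas[::-1], ses[::-1])
        assert a.pooled_beta == pytest.approx(b.pooled_beta, abs=1e-12)
        assert a.pooled_se == pytest.approx(b.pooled_se, abs=1e-12)
        c = dl_meta([-x for x in betas], ses)
        assert c.pooled_beta == pytest.approx(-a.pooled_beta, abs=1e-12)
        assert c.pooled_se == pytest.approx(a.pooled_se, abs=1e-12)


class TestMetaAnalyse:
    def test_single_study_identity(self, scenario):
        study = scenario.exposure_studies[0][0]
        out = meta_analyse([study])
        merged = study.df.merge(out.df, on=["chrom", "pos", "a1", "a2"], suffixes=("_in", "_out"))
        assert np.allclose(merged["beta_in"], merged["beta_out"])
        assert np.allclose(merged["se_in"], merged["se_out"])
        assert (out.df["k_studies"] == 1).all()

    def test_pooling_reduces_error_vs_any_single_study(self, panel):
        from cismr.simulate import OutcomeModel, ScenarioConfig, generate_scenario
        from cismr.simulate import default_architectures

        arch = default_architectures(panel)[0]
        truth = panel.ld.r @ arch.joint_vector(panel.n_variants)
        scale = 1 / np.sqrt(2 * panel.eaf * (1 - panel.eaf))
        rmse_meta, rmse_single = [], []
        for s in range(15):
            b = generate_scenario(ScenarioConfig(seed=5000 + s, study_noise_sd=0.0), panel=panel)
            studies = b.exposure_studies[0]
            pooled = meta_analyse(studies)
            # align pooled output to panel orientation via per-allele truth
            m = pooled.df.sort_values("pos")
            sign = np.where([e == v.ea for e, v in zip(m["ea"], panel.variants)], 1.0, -1.0)
            std_beta = sign * m["beta"].to_numpy() / scale
            rmse_meta.append(np.sqrt(np.mean((std_beta - truth) ** 2)))
            for stud in studies:
                ms = stud.df.sort_values("pos")
                sg = np.where([e == v.ea for e, v in zip(ms["ea"], panel.variants)], 1.0, -1.0)
                sb = sg * ms["beta"].to_numpy() / scale
                rmse_single.append(np.sqrt(np.mean((sb - truth) ** 2)))
        assert np.mean(rmse_meta) < min(np.mean(rmse_single), np.median(rmse_single))

    def test_study_order_irrelevant(self, scenario):
        studies = scenario.exposure_studies[0]
        a = meta_analyse(studies)
        b = meta_analyse(studies[::-1])
        ka = a.df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        kb = b.df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        sign = np.where(ka["ea"] == kb["ea"], 1.0, -1.0)
        assert np.allclose(ka["beta"], sign * kb["beta"], atol=1e-10)
        assert np.allclose(ka["se"], kb["se"], atol=1e-10)
        assert np.allclose(ka["Q_het"], kb["Q_het"], atol=1e-8)

    def test_heterogeneity_detected_when_present(self, panel):
        from cismr.simulate import ScenarioConfig, generate_scenario

        b = generate_scenario(ScenarioConfig(seed=8, study_noise_sd=0.1), panel=panel)
        out = meta_analyse(b.exposure_studies[0])
        causal = b.truth["causal_variants"]["GENE1"]
        pos = [panel.variants[i].pos for i in causal]
        tau2_causal = out.df[out.df["pos"].isin(pos)]["tau2"]
        assert (tau2_causal > 0).all()


def _table(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pvalue", "n"])
    return SummaryStats("t", df)


class TestClump:
    @pytest.fixture()
    def trio(self):
        keys = [VariantKey("1", p, "A", "G") for p in (100, 200, 300)]
        r = np.array([[1.0, np.sqrt(0.5), 0.0], [np.sqrt(0.5), 1.0, 0.0], [0.0, 0.0, 1.0]])
        ld = LDMatrix(keys, r, n_ref=1000)
        stats = _table(
            [
                ("1", 100, "A", "G", 0.3, 0.5, 0.05, 1e-10, 1000),
                ("1", 200, "A", "G", 0.3, 0.5, 0.05, 1e-9, 1000),
                ("1", 300, "A", "G", 0.3, 0.5, 0.05, 1e-8, 1000),
            ]
        )
        return stats, ld

    def test_greedy_rule_traced(self, trio):
        stats, ld = trio
        leads = clump(stats, ld, p_threshold=5.8e-8, r2_threshold=0.40)
        assert [v.pos for v in leads] == [100, 300]

    def test_no_significant_candidates_gives_empty_list(self, trio):
        stats, ld = trio
        assert clump(stats, ld, p_threshold=1e-20, r2_threshold=0.4) == []

    def test_threshold_one_keeps_every_candidate(self, trio):
        stats, ld = trio
        leads = clump(stats, ld, p_threshold=5.8e-8, r2_threshold=1.0000001)
        assert len(leads) == 3

    def test_variant_missing_from_ld_is_named(self, trio):
        stats, _ = trio
        keys = [VariantKey("1", p, "A", "G") for p in (100, 200)]
        ld = LDMatrix(keys, np.eye(2), n_ref=10)
        with pytest.raises(ConfigError, match="1:300"):
            clump(stats, ld, p_threshold=5.8e-8, r2_threshold=0.4)

    def test_leads_mutually_below_threshold_on_real_data(self, scenario, panel):
        meta = meta_analyse(scenario.exposure_studies[0])
        leads = clump(meta, panel.ld, 5.8e-8, 0.01)
        assert len(leads) >= 1
        sub = panel.ld.aligned_submatrix(leads)
        off = (sub.r**2)[~np.eye(len(leads), dtype=bool)]
        assert (off < 0.01).all()


class TestAssignCisTrans:
    REGION = GeneRegion("APCS_LIKE", "1", 10_000_000, 10_050_000)

    def _leads(self, chrom, pos):
        return [VariantKey(chrom, pos, "A", "G")]

    def _stats(self):
        return _table([("1", 10_000_000, "A", "G", 0.3, 0.5, 0.05, 1e-10, 1000)])

    def test_inside_flank_is_cis(self):
        t = assign_cis_trans(self._leads("1", 10_000_000 - 1_999_999), self._stats(), self.REGION, 2_000_000)
        assert t.loc[0, "locus_label"] == "cis"

    def test_outside_flank_is_trans(self):
        t = assign_cis_trans(self._leads("1", 10_000_000 - 2_000_001), self._stats(), self.REGION, 2_000_000)
        assert t.loc[0, "locus_label"] == "trans"

    def test_other_chromosome_is_trans(self):
        t = assign_cis_trans(self._leads("7", 10_000_000), self._stats(), self.REGION, 2_000_000)
        assert t.loc[0, "locus_label"] == "trans"
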