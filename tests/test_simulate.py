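"""Synthetic-data generator: determinism, planted truth, marginal behavior,
and fixture round-trips."""

import numpy as np
import pandas as pd
import pytest

from editscape import io as eio
from editscape.calling import resolve_missing
from editscape.core import GenomicSite
from editscape.simulate import (
    SimConfig,
    SurvSimConfig,
    gen_dna_variants,
    gen_editing_counts,
    gen_ic50,
    gen_repeat_annotation,
    gen_survival,
    matrix_to_observations,
    write_fixtures,
)


SMALL = SimConfig(n_sites=120, n_group1=6, n_group2=5, seed=3)


class TestConfigValidation:
    def test_fraction_ranges(self):
        with pytest.raises(ValueError):
            SimConfig(frac_des=1.5)
        with pytest.raises(ValueError):
            SimConfig(dropout_rate=-0.1)
        with pytest.raises(ValueError):
            SimConfig(n_group1=1)

    def test_infeasible_fold_change_rejected_not_clipped(self):
        # 0.3 * 2**2.5 > 1: the raised mean leaves (0,1)
        with pytest.raises(ValueError, match="infeasible"):
            gen_editing_counts(SimConfig(n_sites=50, null_mean=0.3, des_log2fc=2.5))

    def test_survival_config_ranges(self):
        with pytest.raises(ValueError):
            SurvSimConfig(n_patients=2)
        with pytest.raises(ValueError):
            SurvSimConfig(censor_rate=1.0)


class TestEditingCounts:
    def test_deterministic_under_seed(self):
        m1, t1 = gen_editing_counts(SMALL)
        m2, t2 = gen_editing_counts(SMALL)
        assert m1.equals(m2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_config_has_no_des(self):
        _, truth = gen_editing_counts(SimConfig(n_sites=60, frac_des=0.0, seed=1))
        assert truth["is_des"].sum() == 0
        assert (truth["true_mean_g1"] == truth["true_mean_g2"]).all()

    def test_planted_fold_change_closed_form(self):
        cfg = SimConfig(n_sites=200, null_mean=0.1, des_log2fc=2.5, seed=2)
        _, truth = gen_editing_counts(cfg)
        des = truth[truth["is_des"]]
        raised = 0.1 * 2**2.5  # ~0.566
        up_g1 = des[des["true_mean_g1"] > des["true_mean_g2"]]
        up_g2 = des[des["true_mean_g2"] > des["true_mean_g1"]]
        assert np.allclose(up_g1["true_mean_g1"], raised)
        assert np.allclose(up_g2["true_mean_g2"], raised)
        assert np.allclose(des["true_log2fc"].abs(), 2.5)
        # directions split evenly
        assert abs(len(up_g1) - len(up_g2)) <= 1

    def test_truth_counts(self):
        cfg = SimConfig(n_sites=100, frac_des=0.1, frac_dna_variant=0.1, seed=4)
        _, truth = gen_editing_counts(cfg)
        assert truth["is_des"].sum() == 10
        assert truth["is_dna_variant"].sum() == 10
        # contaminants are never differential
        assert not (truth["is_des"] & truth["is_dna_variant"]).any()

    def test_marginal_mean_converges_to_null_mean(self):
        cfg = SimConfig(
            n_sites=2500, frac_des=0.0, frac_dna_variant=0.0, dropout_rate=0.0,
            n_group1=20, n_group2=20, null_mean=0.1, seed=5,
        )
        m, _ = gen_editing_counts(cfg)  # 1e5 cells
        lev = m.editing_levels().to_numpy()
        assert np.nanmean(lev) == pytest.approx(0.1, abs=0.01)

    def test_overdispersion_exceeds_binomial(self):
        base = dict(
            n_sites=400, frac_des=0.0, frac_dna_variant=0.0, dropout_rate=0.0,
            n_group1=15, n_group2=15, null_mean=0.2, seed=6,
        )
        m_od, _ = gen_editing_counts(SimConfig(**base, null_overdispersion=0.15))
        m_bin, _ = gen_editing_counts(SimConfig(**base, null_overdispersion=0.0))

        def mean_excess_var(m):
            lev = m.editing_levels().to_numpy()
            tot = m.total.to_numpy()
            excess = []
            for i in range(lev.shape[0]):
                ok = np.isfinite(lev[i]) & (tot[i] > 0)
                if ok.sum() < 3:
                    continue
                l, t = lev[i, ok], tot[i, ok]
                # variance across samples minus the mean binomial component
                excess.append(np.var(l, ddof=1) - np.mean(l.mean() * (1 - l.mean()) / t))
            return float(np.mean(excess))

        assert mean_excess_var(m_od) > 0
        assert mean_excess_var(m_od) > mean_excess_var(m_bin) + 0.001

    def test_dropout_produces_missing_cells(self):
        cfg = SimConfig(n_sites=200, dropout_rate=0.3, seed=7)
        m, _ = gen_editing_counts(cfg)
        missing_frac = 1 - m.observed().to_numpy().mean()
        assert missing_frac == pytest.approx(0.3, abs=0.05)


class TestVariantsIc50Survival:
    def test_variant_record_count_and_alleles(self):
        cfg = SimConfig(n_sites=100, frac_dna_variant=0.1, seed=8)
        _, truth = gen_editing_counts(cfg)
        records = gen_dna_variants(truth)
        assert len(records) == 10
        for chrom, pos, ref, alt in records:
            assert (ref, alt) in {("A", "G"), ("T", "C")}

    def test_no_variants_empty_list(self):
        _, truth = gen_editing_counts(SimConfig(n_sites=50, frac_dna_variant=0.0, seed=9))
        assert gen_dna_variants(truth) == []

    def test_ic50_deterministic_and_separable(self):
        t1 = gen_ic50(16, separation=3.0, seed=10)
        t2 = gen_ic50(16, separation=3.0, seed=10)
        pd.testing.assert_frame_equal(t1, t2)
        one = t1[t1["drug"] == "drug1"]
        shifted = one.iloc[:8]["ic50"].mean()
        rest = one.iloc[8:]["ic50"].mean()
        assert shifted > rest + 1.0

    def test_ic50_unseparated_still_varies(self):
        t = gen_ic50(8, separation=0.0, seed=11)
        assert t[t["drug"] == "drug1"]["ic50"].nunique() == 8

    def test_survival_censor_rate_zero_all_events(self):
        rng = np.random.default_rng(12)
        surv = gen_survival(rng.random(20), SurvSimConfig(n_patients=20, censor_rate=0.0, seed=1))
        assert (surv["event"] == 1).all()

    def test_high_editing_shortens_survival(self):
        cfg = SurvSimConfig(n_patients=400, effect_beta=3.0, censor_rate=0.0, seed=13)
        levels = np.concatenate([np.full(200, 0.05), np.full(200, 0.9)])
        surv = gen_survival(levels, cfg)
        low = surv[surv["editing_level"] < 0.5]["pfs_months"].median()
        high = surv[surv["editing_level"] >= 0.5]["pfs_months"].median()
        assert high < low / 3  # hazard ratio exp(3*0.85) ~ 12.8

    def test_null_effect_balanced(self):
        cfg = SurvSimConfig(n_patients=400, effect_beta=0.0, censor_rate=0.0, seed=14)
        levels = np.concatenate([np.full(200, 0.05), np.full(200, 0.9)])
        surv = gen_survival(levels, cfg)
        low = surv[surv["editing_level"] < 0.5]["pfs_months"].median()
        high = surv[surv["editing_level"] >= 0.5]["pfs_months"].median()
        assert 0.6 < high / low < 1.6

    def test_level_validation(self):
        with pytest.raises(ValueError):
            gen_survival([0.5, 1.2], SurvSimConfig(n_patients=2))


class TestFixtures:
    def test_round_trip_through_readers(self, tmp_path):
        matrix, truth = gen_editing_counts(SMALL)
        repeats = gen_repeat_annotation(matrix.sites, seed=3)
        ic50 = gen_ic50(11, seed=3, sample_ids=matrix.sample_ids)
        paths = write_fixtures(tmp_path, matrix, truth, ic50=ic50, repeats=repeats)

        obs = pd.concat(
            [eio.read_site_counts(p, s) for s, p in paths.counts.items()], ignore_index=True
        )
        sites = [GenomicSite.from_id(sid) for sid in matrix.site_ids]
        back = resolve_missing(sites, obs, matrix.sample_ids)
        # resolve_missing orders sites canonically; realign before comparing
        assert back.subset_sites(matrix.site_ids).equals(matrix)

        variants = eio.read_vcf_variants(paths.vcf)
        assert len(variants) == truth["is_dna_variant"].sum()
        assert eio.read_bed_repeats(paths.bed) == repeats
        pd.testing.assert_frame_equal(eio.read_table(paths.ic50), ic50)

    def test_bed_intervals_cover_their_sites(self):
        matrix, _ = gen_editing_counts(SMALL)
        repeats = gen_repeat_annotation(matrix.sites, frac_alu=1.0, frac_non_alu=0.0, seed=0)
        # every site must overlap its interval under the half-open convention
        for iv, (_, row) in zip(repeats, matrix.sites.iterrows()):
            assert iv.start <= row["pos"] - 1 < iv.end

    def test_empty_matrix_valid_files(self, tmp_path):
        cfg = SimConfig(n_sites=0, frac_des=0.0, frac_dna_variant=0.0, seed=1)
        matrix, truth = gen_editing_counts(cfg)
        paths = write_fixtures(tmp_path, matrix, truth)
        assert eio.read_vcf_variants(paths.vcf) == set()
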