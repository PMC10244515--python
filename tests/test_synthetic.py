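"""Synthetic-cohort generator: planted structure, sampling accuracy,
determinism."""

import numpy as np
import pandas as pd
import pytest

from connricci import (SimulationConfig, build_group_covariance,
                       generate_cohort, generate_phenotypes,
                       generate_term_table, sample_fc_matrix)
from connricci.simulate import generate_annotations


def small_config(**kw):
    base = dict(n_rois=4, n_blocks=2, n_young=2, n_old=2, n_timepoints=10,
                base_within_corr=0.6, base_between_corr=0.1,
                effect_rois=frozenset(), effect_size=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestGroupCovariance:
    def test_block_structure_young(self):
        cov = build_group_covariance(small_config(), "young")
        expected = np.array([[1.0, 0.6, 0.1, 0.1],
                             [0.6, 1.0, 0.1, 0.1],
                             [0.1, 0.1, 1.0, 0.6],
                             [0.1, 0.1, 0.6, 1.0]])
        np.testing.assert_allclose(cov, expected)

    def test_old_group_shift_localized(self):
        cfg = small_config(effect_rois=frozenset({0, 1}), effect_size=-0.3)
        young = build_group_covariance(cfg, "young")
        old = build_group_covariance(cfg, "old")
        assert old[0, 1] == pytest.approx(0.3)
        diff = old - young
        diff[0, 1] = diff[1, 0] = 0
        np.testing.assert_allclose(diff, 0, atol=1e-12)

    def test_pd_repair_by_eigenvalue_clipping(self):
        # breaking one correlation inside a tight block makes the raw matrix
        # indefinite (eigen-solver oracle); the repair must restore PD with a
        # unit diagonal
        cfg = SimulationConfig(n_rois=3, n_blocks=1, n_young=2, n_old=2,
                               n_timepoints=10, base_within_corr=0.9,
                               base_between_corr=0.0,
                               effect_rois=frozenset({0, 1}),
                               effect_size=-0.9)
        raw = np.array([[1.0, 0.0, 0.9],
                        [0.0, 1.0, 0.9],
                        [0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(raw).min() < 0  # oracle: needs repair
        cov = build_group_covariance(cfg, "old")
        assert np.linalg.eigvalsh(cov).min() > 0
        np.testing.assert_allclose(np.diag(cov), 1.0, atol=1e-12)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            build_group_covariance(small_config(), "middle")


class TestSampleFCMatrix:
    def test_sampling_error_bound_identity(self):
        # independent ROIs: sample correlation within ~3/sqrt(T) of zero
        fc = sample_fc_matrix(np.eye(3), 10000, seed=7)
        off = fc.values[np.triu_indices(3, 1)]
        assert np.abs(off).max() < 0.05

    def test_recovers_planted_correlation(self):
        cov = np.eye(3)
        cov[0, 1] = cov[1, 0] = 0.6
        fc = sample_fc_matrix(cov, 10000, seed=3)
        assert fc.values[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_deterministic_given_seed(self):
        cov = build_group_covariance(small_config(), "young")
        a = sample_fc_matrix(cov, 50, seed=11)
        b = sample_fc_matrix(cov, 50, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_singular_covariance_rejected(self):
        cov = np.ones((3, 3))
        with pytest.raises(ValueError):
            sample_fc_matrix(cov, 100, seed=0)

    def test_group_mean_recovery(self):
        # averaging many subjects recovers the group covariance entrywise
        cfg = SimulationConfig(n_rois=8, n_blocks=2, n_young=2, n_old=2,
                               n_timepoints=80, effect_rois=frozenset(),
                               effect_size=0.0)
        cov = build_group_covariance(cfg, "young")
        acc = np.zeros_like(cov)
        n_subj = 200
        for s in range(n_subj):
            acc += sample_fc_matrix(cov, cfg.n_timepoints, seed=s).values
        mean = acc / n_subj
        # Fisher-z standard error of a mean of n_subj sample correlations
        se = (1 - cov ** 2) / np.sqrt(cfg.n_timepoints) / np.sqrt(n_subj)
        off = ~np.eye(cfg.n_rois, dtype=bool)
        assert np.all(np.abs(mean - cov)[off] < 4 * se[off] + 1e-3)


class TestTermTable:
    def test_enriched_terms_planted_on_effect_rois(self):
        cfg = small_config(n_rois=6, effect_rois=frozenset({3, 4}),
                           effect_size=0.1, n_terms=10, terms_per_roi=2,
                           enriched_terms=("movement",))
        annot = generate_annotations(cfg)
        table = generate_term_table(annot, cfg.effect_rois, cfg)
        for roi_idx in (3, 4):
            roi = cfg.roi_ids[roi_idx]
            assert "movement" in set(table.loc[table.roi_id == roi, "term"])

    def test_degenerate_empty_table(self):
        cfg = small_config(terms_per_roi=0, enriched_terms=())
        table = generate_term_table(generate_annotations(cfg),
                                    frozenset(), cfg)
        assert len(table) == 0

    def test_base_rate_binomial(self):
        # non-effect ROIs carry each term at rate terms_per_roi/n_terms
        cfg = SimulationConfig(n_rois=500, n_blocks=1, n_young=2, n_old=2,
                               n_timepoints=600, n_terms=20, terms_per_roi=4,
                               effect_rois=frozenset(), effect_size=0.0,
                               enriched_terms=())
        table = generate_term_table(generate_annotations(cfg), frozenset(),
                                    cfg)
        p = cfg.terms_per_roi / cfg.n_terms
        sd = np.sqrt(p * (1 - p) / cfg.n_rois)
        rates = table.groupby("term").size() / cfg.n_rois
        assert np.all(np.abs(rates - p) < 3 * sd)

    def test_enriched_term_outside_universe_rejected(self):
        cfg = small_config(n_terms=5, terms_per_roi=2,
                           enriched_terms=("movement",))
        annot = generate_annotations(cfg)
        with pytest.raises(ValueError):
            generate_term_table(annot, frozenset(), cfg,
                                universe=("other_a", "other_b"))


class TestPhenotypes:
    def test_zero_slope_gives_null_correlation(self):
        from scipy.stats import spearmanr
        cfg = small_config(pheno_slope=0.0, pheno_noise_sd=1.0, n_subscores=1)
        n = 400
        u = pd.Series(np.linspace(0, 1.5, n),
                      index=[f"s{i}" for i in range(n)])
        ph = generate_phenotypes(u, cfg, seed=5)
        rho = spearmanr(ph["value"].to_numpy(), u.to_numpy())[0]
        assert abs(rho) < 3 / np.sqrt(n)

    def test_noiseless_scores_preserve_ranks(self):
        cfg = small_config(pheno_slope=1.0, pheno_noise_sd=0.0, n_subscores=1)
        u = pd.Series([0.3, 1.2, 0.7, 0.1], index=list("abcd"))
        ph = generate_phenotypes(u, cfg, seed=1).set_index("subject_id")
        assert (ph.loc[u.index, "value"].rank() == u.rank()).all()

    def test_attenuation_lower_bound(self):
        # rho >= attenuated Pearson: r = slope*sd_u/sqrt(slope^2 sd_u^2+sd_e^2)
        from scipy.stats import spearmanr
        cfg = small_config(pheno_slope=1.0, pheno_noise_sd=0.5, n_subscores=1)
        n = 200
        rng = np.random.default_rng(0)
        u = pd.Series(rng.uniform(0.5, 1.5, n),
                      index=[f"s{i}" for i in range(n)])
        ph = generate_phenotypes(u, cfg, seed=9)
        rho = spearmanr(ph["value"].to_numpy(), u.to_numpy())[0]
        sd_u = u.std()
        r_expect = sd_u / np.sqrt(sd_u ** 2 + 0.5 ** 2)
        assert rho > 0
        assert rho > r_expect - 3 / np.sqrt(n)


class TestCohortBundle:
    def test_full_determinism(self):
        cfg = small_config(n_rois=6, n_blocks=2, n_timepoints=20,
                           effect_rois=frozenset({0}), effect_size=0.2)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ma, mb in zip(a.fc_matrices, b.fc_matrices):
            np.testing.assert_array_equal(ma.values, mb.values)
        pd.testing.assert_frame_equal(a.term_table, b.term_table)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert a.ground_truth["subject_factors"] == \
            b.ground_truth["subject_factors"]

    def test_planted_difference_localized_empirically(self):
        # with many timepoints the young-old mean FC difference concentrates
        # on effect-ROI pairs
        cfg = SimulationConfig(n_rois=6, n_blocks=2, n_young=30, n_old=30,
                               n_timepoints=2000,
                               effect_rois=frozenset({0, 1}), effect_size=0.3)
        cohort = generate_cohort(cfg)
        young = np.mean([m.values for m in cohort.fc_matrices
                         if m.group == "young"], axis=0)
        old = np.mean([m.values for m in cohort.fc_matrices
                       if m.group == "old"], axis=0)
        diff = np.abs(old - young)
        assert diff[0, 1] > 0.2
        diff[0, 1] = diff[1, 0] = 0
        assert diff.max() < 0.08

    def test_young_factors_zero_old_in_range(self):
        cohort = generate_cohort(small_config(n_rois=6, n_blocks=2,
                                              n_timepoints=20))
        fac = cohort.ground_truth["subject_factors"]
        for sid, u in fac.items():
            if sid.startswith("young"):
                assert u == 0.0
            else:
                assert 0.5 <= u <= 1.5
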