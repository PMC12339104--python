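"""Ground-truth generators: block BOLD, GM covariates, phenotypes, trials."""

import numpy as np
import pandas as pd
import pytest

from segnav.connectivity import ConnectivityExtractor, correlation_matrix
from segnav.parcellation import make_parcellation
from segnav.segregation import network_summary, parcel_fc_profile
from segnav.simulate import (
    GM_PROFILES,
    SimConfig,
    TrialGenConfig,
    block_correlation,
    contaminate_fc,
    simulate_bold,
    simulate_gm_covariates,
    simulate_phenotypes,
    simulate_trials,
)


class TestSimConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(network_sizes=(1, 5)),                       # singleton network
            dict(r_within=0.3, r_between=0.5),                # order violated
            dict(r_within=0.3, r_between=0.3),                # no gap
            dict(ar1=1.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(n_subjects=2, network_sizes=(3, 3))
        with pytest.raises(ValueError):
            SimConfig(**{**base, **kwargs})

    def test_non_psd_block_matrix_named(self):
        with pytest.raises(ValueError, match="not PSD"):
            block_correlation((2, 2, 2), r_within=0.05, r_between=0.9)


class TestSimulateBold:
    def test_deterministic_from_seed(self):
        cfg = SimConfig(n_subjects=3, network_sizes=(4, 4), seed=5)
        a, _ = simulate_bold(cfg)
        b, _ = simulate_bold(cfg)
        np.testing.assert_array_equal(a, b)

    def test_empirical_block_correlations_converge(self):
        cfg = SimConfig(
            n_subjects=1, network_sizes=(10, 10), n_timepoints=5000,
            r_within=0.5, r_between=0.0, seed=6,
        )
        series, corr = simulate_bold(cfg)
        emp = correlation_matrix(series[0])
        within = emp[:10, :10][~np.eye(10, dtype=bool)]
        between = emp[:10, 10:]
        assert within.mean() == pytest.approx(0.5, abs=0.02)
        assert between.mean() == pytest.approx(0.0, abs=0.02)

    def test_ar1_preserves_spatial_correlation_and_adds_memory(self):
        cfg = SimConfig(
            n_subjects=1, network_sizes=(6, 6), n_timepoints=5000,
            r_within=0.5, r_between=0.1, ar1=0.4, seed=7,
        )
        series, _ = simulate_bold(cfg)
        emp = correlation_matrix(series[0])
        assert emp[0, 1] == pytest.approx(0.5, abs=0.05)
        x = series[0, 0]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 == pytest.approx(0.4, abs=0.05)

    def test_equal_within_between_gives_zero_segregation(self):
        # uniform correlation: no within/between distinction by construction
        corr = block_correlation((5, 5), 0.3, 0.3 - 1e-12)
        rng = np.random.default_rng(8)
        L = np.linalg.cholesky(corr + 1e-10 * np.eye(10))
        series = (rng.standard_normal((5000, 10)) @ L.T).T
        parc = make_parcellation([5, 5], ["A", "B"])
        z = ConnectivityExtractor(parc).fit([series]).transform([series])[0]
        seg = network_summary(parcel_fc_profile(z, parc))["segregation"]
        assert np.allclose(seg, 0.0, atol=0.05)


class TestGmCovariates:
    def test_positive_with_between_parcel_variance(self):
        parc = make_parcellation([5, 5], ["A", "B"])
        gm = simulate_gm_covariates(parc, n_subjects=1, seed=9)
        assert set(gm) == set(GM_PROFILES)
        for mat in gm.values():
            assert mat.shape == (1, 10)
            assert (mat > 0).all()
            assert mat[0].std() > 0

    def test_reproducible(self):
        parc = make_parcellation([4, 4], ["A", "B"])
        a = simulate_gm_covariates(parc, 3, seed=10)
        b = simulate_gm_covariates(parc, 3, seed=10)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])


class TestContaminateFc:
    def _z(self, rng, n=8):
        from conftest import random_z_connectivity

        return random_z_connectivity(rng, n, neg_fraction=0.1)

    def test_zero_slope_and_constant_gm_are_identity(self):
        rng = np.random.default_rng(11)
        z = self._z(rng)
        for args in [(np.linspace(2, 3, 8), 0.0), (np.full(8, 2.5), 0.7)]:
            out = contaminate_fc(z, *args)
            np.testing.assert_allclose(out.z, z.z, atol=1e-12)
            np.testing.assert_array_equal(out.valid_mask, z.valid_mask)

    def test_parcel_mean_z_increases_with_gm(self):
        rng = np.random.default_rng(12)
        z = self._z(rng)
        gm = np.linspace(2.0, 3.0, 8)
        out = contaminate_fc(z, gm, slope=0.5)
        g = gm - gm.mean()
        off = ~np.eye(8, dtype=bool)
        row_delta = np.array(
            [(out.z - z.z)[i, off[i]].mean() for i in range(8)]
        )
        assert np.all(np.diff(row_delta) > 0)
        # direct recomputation: mean over j != i of slope*(g_i + g_j)/2
        # with centred g is slope/2 * g_i * (n/(n-1))... i.e. g_i*(1 - 1/(n-1))
        np.testing.assert_allclose(row_delta, 0.25 * g * (1 - 1 / 7), atol=1e-12)

    def test_mean_perturbation_zero_and_mask_rederived(self):
        rng = np.random.default_rng(13)
        z = self._z(rng)
        gm = rng.normal(2.5, 0.5, size=8)
        out = contaminate_fc(z, gm, slope=0.8)
        off = ~np.eye(8, dtype=bool)
        assert (out.z - z.z)[off].mean() == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(out.valid_mask, off & (out.z >= 0))

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="parcels"):
            contaminate_fc(self._z(rng), np.ones(5), 0.5)


class TestPhenotypes:
    def test_carrier_fraction_zero_and_positivity(self):
        df = simulate_phenotypes(50, carrier_fraction=0.0, seed=15)
        assert not df["apoe_carrier"].any()
        for col in ("insulin", "glucose", "homa_ir", "mtbs"):
            assert (df[col] > 0).all() or col == "mtbs"
        assert (df["homa_ir"] > 0).all()

    def test_reproducible(self):
        a = simulate_phenotypes(20, seed=16)
        b = simulate_phenotypes(20, seed=16)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotypes(5, carrier_fraction=1.5)


class TestSimulateTrials:
    def _inputs(self, n=30, seed=17):
        ph = simulate_phenotypes(n, seed=seed)
        seg = pd.DataFrame(
            {
                "subject_id": ph["subject_id"],
                "segregation": np.random.default_rng(seed + 1).normal(0.8, 0.05, n),
            }
        )
        return ph, seg

    def test_deterministic_intercept_only(self):
        ph, seg = self._inputs()
        cfg = TrialGenConfig(
            subtask_offsets={}, beta_distance=0.0,
            sd_subject_intercept=0.0, sd_residual=0.0, seed=18,
        )
        trials, truth = simulate_trials(ph, seg, cfg)
        np.testing.assert_allclose(
            trials["drop_error"], np.exp(cfg.intercept), rtol=1e-12
        )

    def test_trial_count_per_subject(self):
        ph, seg = self._inputs(n=10)
        trials, _ = simulate_trials(ph, seg, TrialGenConfig(seed=19))
        counts = trials.groupby("subject_id").size()
        assert (counts == 24).all()  # two subtasks x 12 trials
        per_subtask = trials.groupby(["subject_id", "subtask"]).size()
        assert (per_subtask == 12).all()

    def test_planted_interaction_shows_in_sample_covariance(self):
        ph, seg = self._inputs(n=400, seed=20)
        cfg = TrialGenConfig(beta_homa_x_seg=0.3, sd_residual=0.2, seed=21)
        trials, _ = simulate_trials(ph, seg, cfg)
        prod = trials["homa_z"] * trials["seg_z"]
        cov = np.cov(prod, np.log(trials["drop_error"]))[0, 1]
        assert cov > 0

    def test_drop_errors_strictly_positive(self):
        ph, seg = self._inputs()
        trials, _ = simulate_trials(ph, seg, TrialGenConfig(seed=22, lam=0.2))
        assert (trials["drop_error"] > 0).all()

    def test_missing_subjects_rejected(self):
        ph, seg = self._inputs()
        with pytest.raises(ValueError, match="both tables"):
            simulate_trials(ph.iloc[:-1], seg, TrialGenConfig(seed=23))

    def test_truth_reports_all_planted_terms(self):
        ph, seg = self._inputs()
        cfg = TrialGenConfig(
            subtasks=("PPI", "BPI", "LPI"), beta_apoe=0.1,
            apoe_x_subtask={"LPI": -0.12}, seed=24,
        )
        _, truth = simulate_trials(ph, seg, cfg)
        assert truth["apoe:subtask_LPI"] == -0.12
        assert truth["apoe:subtask_BPI"] == 0.0
        assert truth["homa_z:apoe:subtask_LPI"] == 0.0
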