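import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mapcorr as mc
from mapcorr.datagen import _correlation_matrix


def unit_spec(rho_within, rcs, rcd, R=6, **kw):
    defaults = dict(region_specific_mean=False, region_specific_variance=False)
    defaults.update(kw)
    return mc.GenerativeSpec(
        region_labels=tuple(f"r{i}" for i in range(R)),
        mu=np.zeros((2, R)), sigma=np.ones((2, R)),
        rho_within=rho_within, rho_cross_same=rcs, rho_cross_diff=rcd,
        **defaults,
    )


# pairs (rho_within, marginal, conditional) that give a PD 2Rx2R matrix
valid_params = st.tuples(
    st.floats(0.05, 0.7), st.floats(0.05, 0.7),
    st.floats(-0.3, 0.3), st.floats(-0.4, 0.4),
)


class TestSolveCrossCorrelations:
    def test_zero_targets_give_zero_parameters(self):
        assert mc.solve_cross_correlations(0.0, 0.0, (0.3, 0.6)) == (0.0, 0.0)

    def test_closed_form(self):
        rcs, rcd = mc.solve_cross_correlations(0.250, 0.500, (0.6, 0.6))
        assert rcs == pytest.approx(0.250, abs=1e-15)
        assert rcd == pytest.approx(0.250 - 0.500 * 0.4, abs=1e-12)
        # matrix round-trip: rebuilt spec reproduces both targets
        spec = unit_spec((0.6, 0.6), rcs, rcd)
        assert spec.marginal_correlation == pytest.approx(0.250, abs=1e-12)
        assert spec.conditional_correlation == pytest.approx(0.500, abs=1e-12)

    def test_scenario_e_round_trip(self, spec_e):
        rcs, rcd = mc.solve_cross_correlations(0.135, 0.057, spec_e.rho_within)
        spec = unit_spec(spec_e.rho_within, rcs, rcd)
        assert spec.marginal_correlation == pytest.approx(0.135, abs=1e-10)
        assert spec.conditional_correlation == pytest.approx(0.057, abs=1e-10)

    def test_incompatible_targets_rejected(self):
        # zero marginal with a huge conditional correlation forces
        # rho_cross_diff = -0.9; the exchangeable cross block then has an
        # eigenvalue below -1 at R=18 and the matrix loses positive
        # definiteness
        with pytest.raises(ValueError):
            mc.solve_cross_correlations(0.0, 0.9, (0.0, 0.0))


class TestBuildCovariance:
    def test_identity_when_uncorrelated_unit_variance(self):
        spec = unit_spec((0.0, 0.0), 0.0, 0.0, R=18,
                         cross_modality_correlation=False)
        np.testing.assert_allclose(mc.build_covariance(spec), np.eye(36))

    def test_four_distinct_offdiagonal_values(self, spec_a):
        cov = mc.build_covariance(spec_a)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        distinct = np.unique(np.round(off, 12))
        # rho_within (x2, equal here), rho_cross_same, rho_cross_diff
        assert set(np.round(distinct, 6)) == {0.0, 0.25, 0.5}

    def test_entry_pattern(self):
        spec = unit_spec((0.4, 0.2), 0.25, 0.1, R=3)
        cov = mc.build_covariance(spec)
        R = 3
        assert cov[0, 1] == pytest.approx(0.4)     # within modality 0
        assert cov[R, R + 1] == pytest.approx(0.2)  # within modality 1
        assert cov[0, R] == pytest.approx(0.25)    # same region, cross modality
        assert cov[0, R + 1] == pytest.approx(0.1)  # different region, cross

    def test_sampling_moments_match(self):
        spec = unit_spec((0.45, 0.3), 0.2, 0.05, R=4)
        cov = mc.build_covariance(spec)
        data = mc.simulate_dataset(spec, 200_000, 7)
        emp = np.cov(data.values.reshape(200_000, 8), rowvar=False)
        np.testing.assert_allclose(emp, cov, atol=0.012)

    def test_nonpositive_definite_raises_with_parameters_named(self):
        with pytest.raises(ValueError, match="rho_cross_diff"):
            unit_spec((0.0, 0.0), 0.0, -0.5, R=18,
                      cross_modality_correlation=True)


class TestScenarioSpec:
    def test_flags_match_scenario_grid(self, fixture_dict):
        grid = {
            "A": (False, False, True), "B": (True, False, False),
            "C": (True, False, True), "D": (False, True, False),
            "E": (True, True, True),
        }
        for label, (m, v, x) in grid.items():
            s = mc.scenario_spec(label, fixture_dict)
            assert (s.region_specific_mean, s.region_specific_variance,
                    s.cross_modality_correlation) == (m, v, x)

    def test_scenario_b_zero_cross_with_region_means(self, spec_b):
        assert spec_b.rho_cross_same == 0.0 and spec_b.rho_cross_diff == 0.0
        assert np.std(spec_b.mu[0]) > 0 and np.std(spec_b.mu[1]) > 0

    def test_scenario_a_constant_means(self, spec_a):
        assert np.allclose(spec_a.mu[0], spec_a.mu[0, 0])
        assert np.allclose(spec_a.mu[1], spec_a.mu[1, 0])

    def test_scenario_e_implied_correlations(self, spec_e):
        assert spec_e.marginal_correlation == pytest.approx(0.135, abs=1e-12)
        assert spec_e.conditional_correlation == pytest.approx(0.057, abs=1e-12)

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            mc.scenario_spec("Z")

    def test_mean_profiles_calibrated(self, fixture_dict):
        bp = np.array(fixture_dict["mean_profile"]["BPND"])
        cbf = np.array(fixture_dict["mean_profile"]["CBF"])
        r = np.corrcoef(bp, cbf)[0, 1]
        assert r == pytest.approx(0.672, abs=1e-5)
        # mean-profile spread dominates the sampling noise of a regional mean
        # at n=24, so the region confound drives the across-regions estimate
        for m, prof in (("BPND", bp), ("CBF", cbf)):
            sd = fixture_dict["baseline"][m]["sd"]
            rho_w = fixture_dict["rho_within"][m]
            se = sd * np.sqrt((1 - rho_w) / 24)
            assert prof.std(ddof=1) >= 5 * se


class TestSimulateDataset:
    def test_shape_and_labels(self, spec_a):
        t = mc.simulate_dataset(spec_a, 2, 1)
        assert len(t) == 72 and t.n_participants == 2
        assert t.regions == spec_a.region_labels
        assert t.modalities == ("BPND", "CBF")

    def test_seed_determinism_byte_identical(self, spec_e):
        a = mc.simulate_dataset(spec_e, 10, 42)
        b = mc.simulate_dataset(spec_e, 10, 42)
        assert a.values.tobytes() == b.values.tobytes()
        c = mc.simulate_dataset(spec_e, 10, 43)
        assert not np.array_equal(a.values, c.values)

    def test_degenerate_noise_returns_means(self, fixture_dict):
        spec = mc.GenerativeSpec(
            region_labels=fixture_dict["regions"],
            mu=np.array([fixture_dict["mean_profile"]["BPND"],
                         fixture_dict["mean_profile"]["CBF"]]),
            sigma=np.full((2, 18), 1e-8),
            rho_within=(0.5, 0.5), rho_cross_same=0.25, rho_cross_diff=0.0,
            region_specific_variance=False,
        )
        t = mc.simulate_dataset(spec, 5, 3)
        np.testing.assert_allclose(t.values, np.broadcast_to(spec.mu, (5, 2, 18)),
                                   atol=1e-6)

    def test_large_n_regional_correlations(self, spec_a):
        t = mc.simulate_dataset(spec_a, 100_000, 11)
        for j in range(0, 18, 5):
            r = np.corrcoef(t.values[:, 0, j], t.values[:, 1, j])[0, 1]
            assert r == pytest.approx(0.250, abs=0.01)

    def test_n_zero_rejected(self, spec_a):
        with pytest.raises(ValueError):
            mc.simulate_dataset(spec_a, 0, 1)


class TestSpecProperties:
    @settings(max_examples=25, deadline=None)
    @given(valid_params)
    def test_conditional_equals_partial_given_subject_effects(self, params):
        """Brute-force oracle: conditional correlation == partial correlation of
        the two same-region variables given the participant's latent modality
        means, via a Schur complement on the joint covariance."""
        rw0, rw1, marg, cond = params
        try:
            rcs, rcd = mc.solve_cross_correlations(marg, cond, (rw0, rw1), n_regions=6)
            spec = unit_spec((rw0, rw1), rcs, rcd)
        except ValueError:
            return  # incompatible targets: nothing to check
        # joint covariance of (X_0r, X_1r, a_0, a_1) where a_m is the latent
        # participant-level modality mean with var(a_m)=rho_within[m]
        S = np.array([
            [1.0, rcs, rw0, rcd],
            [rcs, 1.0, rcd, rw1],
            [rw0, rcd, rw0, rcd],
            [rcd, rw1, rcd, rw1],
        ])
        if np.linalg.eigvalsh(S).min() < -1e-10:
            return  # latent representation infeasible (rcd^2 > rw0*rw1)
        cond_cov = S[:2, :2] - S[:2, 2:] @ np.linalg.pinv(S[2:, 2:]) @ S[2:, :2]
        oracle = cond_cov[0, 1] / np.sqrt(cond_cov[0, 0] * cond_cov[1, 1])
        assert spec.conditional_correlation == pytest.approx(oracle, abs=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(valid_params, st.floats(0.1, 50), st.floats(-100, 100))
    def test_affine_equivariance_of_correlations(self, params, scale, shift):
        rw0, rw1, marg, cond = params
        try:
            rcs, rcd = mc.solve_cross_correlations(marg, cond, (rw0, rw1), n_regions=6)
            spec = unit_spec((rw0, rw1), rcs, rcd)
        except ValueError:
            return
        R = spec.n_regions
        mu2 = spec.mu.copy(); mu2[0] += shift
        sg2 = spec.sigma.copy(); sg2[0] *= scale
        spec2 = mc.GenerativeSpec(
            region_labels=spec.region_labels, mu=mu2, sigma=sg2,
            rho_within=spec.rho_within, rho_cross_same=rcs, rho_cross_diff=rcd,
            region_specific_mean=False, region_specific_variance=False,
        )
        for s in (spec, spec2):
            cov = mc.build_covariance(s)
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            np.testing.assert_allclose(corr, _correlation_matrix(spec), atol=1e-12)

    def test_round_trip_correlation_parameters(self, spec_e):
        cov = mc.build_covariance(spec_e)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        R = spec_e.n_regions
        off = ~np.eye(R, dtype=bool)
        assert corr[:R, :R][off].mean() == pytest.approx(spec_e.rho_within[0], abs=1e-12)
        assert np.diag(corr[:R, R:]).mean() == pytest.approx(spec_e.rho_cross_same, abs=1e-12)
        assert corr[:R, R:][off].mean() == pytest.approx(spec_e.rho_cross_diff, abs=1e-12)

    def test_flag_consistency_enforced(self, spec_c):
        with pytest.raises(ValueError, match="region_specific_mean"):
            mc.GenerativeSpec(
                region_labels=spec_c.region_labels, mu=spec_c.mu,
                sigma=spec_c.sigma, rho_within=spec_c.rho_within,
                rho_cross_same=spec_c.rho_cross_same,
                rho_cross_diff=spec_c.rho_cross_diff,
                region_specific_mean=False, region_specific_variance=False,
            )


class TestRegionalTable:
    def test_frame_round_trip(self, spec_e):
        t = mc.simulate_dataset(spec_e, 4, 9)
        df = t.to_frame()
        assert list(df.columns) == list(mc.RegionalTable.COLUMNS)
        back = mc.RegionalTable.from_frame(df)
        assert back == t

    def test_unbalanced_frame_rejected(self, spec_a):
        df = mc.simulate_dataset(spec_a, 3, 1).to_frame().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            mc.RegionalTable.from_frame(df)
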