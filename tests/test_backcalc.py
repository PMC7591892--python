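"""Modified Fry kernels, proportionality fit and posterior propagation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from otogrow import (
    MCMCSettings,
    ProportionalityPosterior,
    SimulationConfig,
    simulate_dataset,
)
from otogrow.backcalc import (
    DataError,
    backcalculate_group,
    biological_intercept_a,
    estimates_frame,
    fit_proportionality,
    modified_fry,
    predict_capture_length,
    run_backcalculation,
)
from otogrow.data_model import select_backcalc_groups

from conftest import FAST_MCMC


class TestPredictCaptureLength:
    def test_equal_radii_return_hatch_length(self):
        assert predict_capture_length(2.0, 0.05, 0.05, 150.0, 1.2) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "l0p,b,c,r0p,rcpt,expected",
        [(2.0, 200.0, 1.0, 0.01, 1.0, 200.0), (2.0, 100.0, 2.0, 0.1, 1.0, 101.0)],
    )
    def test_direct_evaluations(self, l0p, b, c, r0p, rcpt, expected):
        assert predict_capture_length(l0p, r0p, rcpt, b, c) == pytest.approx(expected)

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            predict_capture_length(2.0, -0.01, 1.0, 200.0, 1.0)


class TestBiologicalIntercept:
    @pytest.mark.parametrize(
        "l0p,b,c,r0p,expected",
        [(2.0, 200.0, 1.0, 0.01, 0.0), (2.0, 100.0, 2.0, 0.1, 1.0),
         (2.0, 0.0, 1.0, 0.05, 2.0)],
    )
    def test_values(self, l0p, b, c, r0p, expected):
        assert biological_intercept_a(l0p, r0p, b, c) == pytest.approx(expected)

    def test_below_hatch_length_for_positive_slope(self):
        assert biological_intercept_a(2.0, 0.05, 150.0, 1.2) < 2.0


class TestModifiedFry:
    def test_hand_evaluated_interpolation(self):
        # a=0: log-linear interpolation gives exp(ln 2 + 0.5 ln 100) = 20
        val = modified_fry(200.0, 2.0, 1.0, 0.01, 0.1, 0.0)
        assert val == pytest.approx(20.0, rel=1e-12)

    def test_capture_radius_returns_capture_length(self):
        val = modified_fry(180.0, 2.5, 0.9, 0.05, 0.9, -3.0)
        assert val == pytest.approx(180.0, rel=1e-12)

    def test_hatch_radius_returns_hatch_length(self):
        val = modified_fry(180.0, 2.5, 0.9, 0.05, 0.05, -3.0)
        assert val == pytest.approx(2.5, rel=1e-12)

    def test_log_domain_violation_yields_nan_not_crash(self):
        val = modified_fry(180.0, 2.5, 0.9, 0.05, 0.4, 200.0)  # a > L_cpt
        assert np.isnan(val)

    def test_equal_anchors_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            modified_fry(180.0, 2.5, 0.05, 0.05, 0.05, 0.0)

    @given(
        l0p=st.floats(1.0, 5.0),
        lcpt=st.floats(20.0, 900.0),
        r0p=st.floats(0.01, 0.13),
        rcpt=st.floats(0.2, 3.8),
        a=st.floats(-50.0, 0.9),
        frac=st.floats(0.0, 1.0),
    )
    @hyp_settings(max_examples=200, derandomize=True)
    def test_endpoint_identities_and_bounds(self, l0p, lcpt, r0p, rcpt, a, frac):
        """Endpoints are exact; interior radii interpolate between them."""
        assert modified_fry(lcpt, l0p, rcpt, r0p, r0p, a) == pytest.approx(
            l0p, rel=1e-9
        )
        assert modified_fry(lcpt, l0p, rcpt, r0p, rcpt, a) == pytest.approx(
            lcpt, rel=1e-9
        )
        ri = np.exp(np.log(r0p) + frac * (np.log(rcpt) - np.log(r0p)))
        li = modified_fry(lcpt, l0p, rcpt, r0p, ri, a)
        assert min(l0p, lcpt) - 1e-9 <= li <= max(l0p, lcpt) + 1e-9

    @given(
        lcpt=st.floats(50.0, 900.0),
        a=st.floats(-50.0, 0.9),
        data=st.data(),
    )
    @hyp_settings(max_examples=100, derandomize=True)
    def test_strictly_increasing_in_radius(self, lcpt, a, data):
        from hypothesis import assume

        l0p, r0p, rcpt = 2.5, 0.05, 2.0
        radii = np.sort(
            np.array(
                data.draw(
                    st.lists(st.floats(0.06, 1.9), min_size=3, max_size=8,
                             unique=True)
                )
            )
        )
        # strictness is only meaningful for separated radii: adjacent-ulp
        # inputs collapse to equal lengths in floating point
        assume(np.all(np.diff(radii) / radii[:-1] > 1e-9))
        lengths = modified_fry(lcpt, l0p, rcpt, r0p, radii, a)
        assert np.all(np.diff(lengths) > 0)


class TestBackcalculateGroup:
    def test_point_mass_posterior_reproduces_truth(self, noise_free_synthetic):
        ds, truth = noise_free_synthetic
        groups = select_backcalc_groups(ds, "species")
        post = ProportionalityPosterior.point_mass(truth.true_b, truth.true_c)
        est = backcalculate_group(groups[0].members, post, ds.increments)
        for e in est:
            tr = truth.individuals[e.individual_id]
            assert e.length_mean == pytest.approx(
                tr.true_lengths[e.age_i], abs=1e-6
            )
            assert e.length_sd == 0.0

    def test_age_zero_estimate_is_hatch_length_with_zero_sd(
        self, noise_free_synthetic
    ):
        ds, truth = noise_free_synthetic
        groups = select_backcalc_groups(ds, "species")
        post = ProportionalityPosterior.point_mass(truth.true_b, truth.true_c)
        frame = estimates_frame(
            backcalculate_group(groups[0].members, post, ds.increments)
        )
        at0 = frame[frame["Age_i"] == 0]
        assert not at0.empty
        assert np.allclose(at0["length_mean"], 2.5)
        assert np.allclose(at0["length_sd"], 0.0)

    def test_estimates_bounded_by_anchors_under_posterior_draws(
        self, small_synthetic
    ):
        ds, _ = small_synthetic
        grp = select_backcalc_groups(ds, "species")[0]
        rng = np.random.default_rng(3)
        n = 200
        post = ProportionalityPosterior(
            group_label="rand",
            b=rng.uniform(50, 300, n), c=rng.uniform(0.8, 1.4, n),
            sigma=np.zeros(n), mu_r=np.full(n, 0.05), sigma_r=np.full(n, 0.01),
            r0p_imputed={
                m.individual_id: rng.uniform(0.02, 0.08, n)
                for m in grp.members if m.radius_0p is None
            },
        )
        for e in backcalculate_group(grp.members, post, ds.increments):
            fish = ds.individual(e.individual_id)
            lo = min(fish.length_0p, fish.length_cpt)
            hi = max(fish.length_0p, fish.length_cpt)
            assert lo - 1e-9 <= e.length_mean <= hi + 1e-9


class TestFitProportionality:
    def test_requires_two_known_hatch_radii(self, small_synthetic):
        ds, _ = small_synthetic
        grp = select_backcalc_groups(ds, "species")[0]
        known = [m for m in grp.members if m.radius_0p is not None]
        missing = [m for m in grp.members if m.radius_0p is None]
        with pytest.raises(DataError, match="known hatch radii"):
            fit_proportionality(known[:1] + missing, settings=FAST_MCMC)

    def test_recovers_generative_parameters_and_matches_least_squares(self):
        """Posterior means near truth and near an independent NLS fit."""
        from scipy.optimize import curve_fit

        cfg = SimulationConfig(
            n_species=1, n_individuals_per_species=40, true_b=150.0, true_c=1.2,
            sigma_length=2.0, missing_r0p_rate=0.0, seed=21,
        )
        ds, truth = simulate_dataset(cfg)
        grp = select_backcalc_groups(ds, "species")[0]
        post = fit_proportionality(
            grp.members, settings=FAST_MCMC, group_label="recovery",
            check_convergence=False,
        )
        assert post.b.mean() == pytest.approx(150.0, rel=0.05)
        assert post.c.mean() == pytest.approx(1.2, rel=0.05)
        assert post.n_draws == FAST_MCMC.n_draws

        # independent point-estimate route: NLS on the same capture data
        l_cpt = np.array([m.length_cpt for m in grp.members])
        r_cpt = np.array([m.radius_cpt for m in grp.members])
        r0p = np.array([m.radius_0p for m in grp.members])
        popt, _ = curve_fit(
            lambda X, b, c: 2.5 - b * X[0] ** c + b * X[1] ** c,
            (r0p, r_cpt), l_cpt, p0=(100.0, 1.0),
        )
        assert post.b.mean() == pytest.approx(popt[0], rel=0.1)
        assert post.c.mean() == pytest.approx(popt[1], rel=0.05)

    def test_linear_limit_credible_interval_covers_one(self):
        cfg = SimulationConfig(
            n_species=1, n_individuals_per_species=30, true_b=200.0, true_c=1.0,
            sigma_length=3.0, missing_r0p_rate=0.0, seed=8,
        )
        ds, _ = simulate_dataset(cfg)
        grp = select_backcalc_groups(ds, "species")[0]
        post = fit_proportionality(
            grp.members, settings=FAST_MCMC, group_label="linear",
            check_convergence=False,
        )
        lo, hi = np.percentile(post.c, [2.5, 97.5])
        assert lo <= 1.0 <= hi

    def test_imputed_draws_are_positive_and_aligned(self, small_synthetic):
        ds, _ = small_synthetic
        grp = select_backcalc_groups(ds, "species")[0]
        post = fit_proportionality(
            grp.members, settings=FAST_MCMC, group_label=grp.label,
            check_convergence=False,
        )
        assert post.r0p_imputed  # the fixture masks some hatch radii
        for draws in post.r0p_imputed.values():
            assert draws.shape == post.b.shape
            assert (draws > 0).all()


class TestRunBackcalculation:
    def test_species_with_single_known_r0p_left_missing(self):
        cfg = SimulationConfig(
            n_species=2, n_individuals_per_species=6, sigma_length=1.0,
            missing_r0p_rate=0.0, seed=4,
        )
        ds, _ = simulate_dataset(cfg)
        # mask all but one hatch radius of the first species
        first = ds.individuals.index[ds.individuals["Species"] == "simulatus1"]
        for iid in first[1:]:
            ds.individuals.loc[iid, "R_0p"] = np.nan
            sel = (ds.increments["ID"] == iid) & (ds.increments["Age_i"] == 0)
            ds.increments.loc[sel, "R_i"] = np.nan
        out, report, _ = run_backcalculation(
            ds, "species", settings=FAST_MCMC
        )
        sp1 = out.increments[out.increments["ID"].isin(first)]
        assert sp1["Li_sp_m"].isna().all()
        assert any("insufficient_r0p" in v for v in report.dropped_groups.values())
        sp2 = out.increments[~out.increments["ID"].isin(first)]
        assert sp2["Li_sp_m"].notna().sum() > 0

    def test_empty_columns_for_unfitted_rows_and_report_accounts_all(self):
        cfg = SimulationConfig(
            n_species=1, n_individuals_per_species=8, sigma_length=1.0,
            missing_r0p_rate=0.0, seed=6,
        )
        ds, _ = simulate_dataset(cfg)
        out, report, posts = run_backcalculation(ds, "species", settings=FAST_MCMC)
        assert report.fitted_groups and not report.dropped_groups
        fitted = out.increments["Li_sp_m"].notna()
        known_radius = out.increments["R_i"].notna()
        assert (fitted <= known_radius).all()
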