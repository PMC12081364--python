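"""Likelihood core, dataset contract, fit behavior and residuals."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from mtxppk.covariate_model import ErrorModel, RandomEffects
from mtxppk.estimation import (
    DatasetError,
    EventDataset,
    ParamSpec,
    base_model_spec,
    cwres,
    final_model_spec,
    fit,
    information_criteria,
    laplace_neg2ll,
    ofv,
    predict,
    read_dataset,
    write_dataset,
)
from mtxppk.synthetic_cohort import StudyDesign, simulate_cohort

from conftest import TRUTH


class TestDatasetIO:
    def test_csv_roundtrip(self, small_cohort, tmp_path):
        path = tmp_path / "events.csv"
        write_dataset(small_cohort.events, path)
        ds = read_dataset(path)
        assert ds.n_subjects == 60
        np.testing.assert_allclose(
            ds.obs_y,
            EventDataset.from_dataframe(small_cohort.events).obs_y,
            rtol=1e-10)

    def test_header_is_the_documented_dialect(self, small_cohort, tmp_path):
        path = tmp_path / "events.csv"
        write_dataset(small_cohort.events, path)
        header = path.read_text().splitlines()[0]
        assert header == "ID,TIME,EVID,AMT,DUR,DV,BQL,EGFR,BW,TBIL,ALB,BLM"

    def test_missing_column_rejected(self, small_cohort):
        with pytest.raises(DatasetError, match="missing"):
            EventDataset.from_dataframe(small_cohort.events.drop(columns=["DV"]))

    def test_row_numbered_validation_errors(self, small_cohort):
        df = small_cohort.events.copy()
        obs_idx = df.index[df["EVID"] == 0][0]
        df.loc[obs_idx, "DV"] = np.nan
        with pytest.raises(DatasetError, match=r"row \d+"):
            EventDataset.from_dataframe(df)

    def test_dose_row_with_dv_rejected(self, small_cohort):
        df = small_cohort.events.copy()
        dose_idx = df.index[df["EVID"] == 1][0]
        df.loc[dose_idx, "DV"] = 1.0
        with pytest.raises(DatasetError, match="must not carry DV"):
            EventDataset.from_dataframe(df)

    def test_negative_time_rejected(self, small_cohort):
        df = small_cohort.events.copy()
        df.loc[df.index[0], "TIME"] = -1.0
        with pytest.raises(DatasetError, match="TIME"):
            EventDataset.from_dataframe(df)


class TestInformationCriteria:
    def test_published_aic(self):
        aic, _ = information_criteria(10421.315, 11, 5470)
        assert aic == pytest.approx(10443.315, abs=1e-9)

    def test_published_bic(self):
        _, bic = information_criteria(10421.315, 11, 5470)
        assert bic == pytest.approx(10515.99, abs=0.01)

    def test_degenerate_case(self):
        aic, bic = information_criteria(0.0, 1, 1)
        assert aic == 2.0 and bic == 0.0

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            information_criteria(10.0, 0, 5)


class TestLikelihoodCore:
    def test_no_iiv_matches_gaussian_closed_form(self):
        """ω = 0 with additive error is an exact independent-Gaussian -2LL."""
        rng = np.random.default_rng(0)
        y = rng.normal(5.0, 1.0, size=12)
        f_const = np.full(12, 5.2)
        sigma = 0.8
        err = ErrorModel(kind="additive", sigma_add=sigma)
        value = laplace_neg2ll(y, np.zeros(12, dtype=int), 1,
                               lambda eta: f_const.copy(), np.empty(0), err)
        expected = np.sum(np.log(2 * np.pi * sigma**2)
                          + (y - f_const) ** 2 / sigma**2)
        assert value == pytest.approx(expected, abs=1e-8)

    def test_linear_random_effect_matches_marginal_gaussian(self):
        """One observation per subject, f = μ + η: the Laplace value equals
        the closed-form one-way random-effects marginal likelihood."""
        rng = np.random.default_rng(1)
        s_count = 40
        mu, omega, sigma = 3.0, 0.7, 0.5
        y = mu + rng.normal(0, omega, s_count) + rng.normal(0, sigma, s_count)
        sidx = np.arange(s_count)

        def pred(eta):
            flat = np.atleast_2d(eta[..., 0]) if eta.ndim == 3 else eta[:, 0][None]
            out = mu + flat
            return out[0] if eta.ndim == 2 else out

        err = ErrorModel(kind="additive", sigma_add=sigma)
        value = laplace_neg2ll(y, sidx, s_count, pred,
                               np.array([omega**2]), err)
        v_tot = sigma**2 + omega**2
        expected = np.sum(np.log(2 * np.pi * v_tot) + (y - mu) ** 2 / v_tot)
        assert value == pytest.approx(expected, abs=1e-6)

    def test_quadrature_refinement_is_exact_for_linear_model(self):
        """For a model linear in η the Laplace value is already exact, so
        Gauss-Hermite refinement must not change it."""
        rng = np.random.default_rng(2)
        s_count = 25
        mu, omega, sigma = 1.0, 0.4, 0.3
        y = mu + rng.normal(0, omega, s_count) + rng.normal(0, sigma, s_count)
        sidx = np.arange(s_count)

        def pred(eta):
            flat = np.atleast_2d(eta[..., 0]) if eta.ndim == 3 else eta[:, 0][None]
            out = mu + flat
            return out[0] if eta.ndim == 2 else out

        err = ErrorModel(kind="additive", sigma_add=sigma)
        v1 = laplace_neg2ll(y, sidx, s_count, pred, np.array([omega**2]), err)
        v5 = laplace_neg2ll(y, sidx, s_count, pred, np.array([omega**2]), err,
                            n_quad=5)
        assert v5 == pytest.approx(v1, abs=1e-6)

    def test_ofv_invariant_to_subject_relabeling(self, small_cohort):
        spec = final_model_spec()
        ds = EventDataset.from_dataframe(small_cohort.events)
        df = small_cohort.events.copy()
        # relabel subjects in reverse order
        ids = sorted(df["ID"].unique())
        df["ID"] = df["ID"].map({old: new for old, new
                                 in zip(ids, reversed(ids))})
        ds2 = EventDataset.from_dataframe(df)
        v1 = ofv(spec, TRUTH, ds)
        v2 = ofv(spec, TRUTH, ds2)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_ofv_invariant_to_row_shuffle(self, small_cohort):
        spec = final_model_spec()
        ds = EventDataset.from_dataframe(small_cohort.events)
        shuffled = small_cohort.events.sample(frac=1.0, random_state=0)
        ds2 = EventDataset.from_dataframe(shuffled, validate=False)
        assert ofv(spec, TRUTH, ds2) == pytest.approx(ofv(spec, TRUTH, ds),
                                                      rel=1e-9)


class TestPredict:
    def test_pred_equals_noise_free_data(self, noise_free_dataset):
        spec = final_model_spec()
        est = dict(TRUTH, omega_cl=0.0, omega_vc=0.0, sigma_prop=0.0)
        pred, ipred = predict(spec, est, noise_free_dataset)
        np.testing.assert_allclose(pred, noise_free_dataset.obs_y, rtol=1e-9)
        np.testing.assert_allclose(ipred, pred, rtol=1e-12)

    def test_eta_modes_vanish_on_noise_free_data(self, noise_free_dataset):
        """With data generated at η = 0, conditional modes sit near 0.

        (Not exactly 0: under proportional error with interaction the
        conditional objective's variance term pulls the mode slightly
        off the residual-free point; the shift is O(σ²).)
        """
        spec = final_model_spec()
        est = dict(TRUTH, sigma_prop=0.05)
        _, details_ipred = predict(spec, est, noise_free_dataset)
        np.testing.assert_allclose(details_ipred, noise_free_dataset.obs_y,
                                   rtol=1e-2)


class TestFit:
    def test_zero_noise_identifiability(self, noise_free_dataset):
        """Started at truth on noise-free data, the optimizer stays there."""
        spec = final_model_spec(
            cl_init=12.88, vc_init=72.04, omega_init=0.0, sigma_init=1e-6)
        spec = replace(
            spec,
            covariates=tuple(replace(e, init=TRUTH[e.name])
                             for e in spec.covariates),
            iiv=tuple((p, ParamSpec(0.0, fixed=True)) for p, _ in spec.iiv),
            sigma=(("prop", ParamSpec(1e-6, fixed=True)),),
        )
        res = fit(spec, noise_free_dataset, seed=0)
        for name in ("cl", "vc", "beta_egfr_cl", "beta_bw_cl", "beta_bw_vc"):
            assert res.estimates[name] == pytest.approx(TRUTH[name], rel=1e-4)

    def test_aic_bic_identities(self, small_dataset):
        spec = base_model_spec()
        res = fit(spec, small_dataset, seed=0)
        assert res.aic == pytest.approx(res.ofv + 2 * res.n_params, abs=1e-9)
        assert res.bic == pytest.approx(
            res.ofv + res.n_params * np.log(res.n_obs), abs=1e-9)
        assert res.n_obs == small_dataset.n_obs

    def test_fit_deterministic(self, small_dataset):
        spec = base_model_spec()
        r1 = fit(spec, small_dataset, seed=0)
        r2 = fit(spec, small_dataset, seed=0)
        for k in r1.estimates:
            assert r1.estimates[k] == pytest.approx(r2.estimates[k], rel=1e-12)
        assert r1.ofv == pytest.approx(r2.ofv, rel=1e-12)

    def test_profile_optimality(self, small_dataset):
        """±20% perturbations of any estimated parameter never lower the OFV."""
        spec = base_model_spec()
        res = fit(spec, small_dataset, seed=0)
        for name in ("cl", "vc", "omega_cl", "sigma_prop"):
            for factor in (0.8, 1.2):
                perturbed = dict(res.estimates)
                perturbed[name] = res.estimates[name] * factor
                assert ofv(spec, perturbed, small_dataset) >= res.ofv - 1e-6

    def test_two_compartment_beats_one_on_two_compartment_data(
            self, small_dataset):
        two = fit(base_model_spec(n_compartments=2), small_dataset, seed=0)
        one = fit(base_model_spec(n_compartments=1), small_dataset, seed=0)
        assert two.ofv < one.ofv

    def test_self_consistency_on_resimulated_data(self):
        """Refitting data re-simulated from a fit's own estimates gives
        estimates scattered around those values."""
        from mtxppk.estimation import simulate_observations
        sim = simulate_cohort(n=100, seed=41, design=StudyDesign(n_courses=1))
        ds = EventDataset.from_dataframe(sim.events)
        spec = base_model_spec()
        first = fit(spec, ds, seed=0)
        rng = np.random.default_rng(5)
        devs = []
        for rep in range(3):
            new_y = simulate_observations(spec, first.estimates, ds, 1,
                                          int(rng.integers(2**31)))[0]
            df = ds.df.copy()
            df.loc[df["EVID"] == 0, "DV"] = new_y
            df.loc[df["EVID"] == 0, "BQL"] = (new_y < 0.3).astype(int)
            refit = fit(spec, EventDataset.from_dataframe(df, validate=False),
                        seed=0, compute_se=False)
            devs.append(refit.estimates["cl"] - first.estimates["cl"])
        # centered on the generating value within a few standard errors
        assert abs(np.mean(devs)) < 4 * first.se["cl"]

    def test_confidence_intervals_contain_estimates(self, small_dataset):
        res = fit(base_model_spec(), small_dataset, seed=0)
        for name in res.se:
            if np.isfinite(res.se[name]):
                assert res.ci_lower[name] <= res.estimates[name] <= res.ci_upper[name]

    def test_report_serialization(self, small_dataset, tmp_path):
        res = fit(base_model_spec(), small_dataset, seed=0)
        res.to_json(tmp_path / "fit.json")
        import json
        loaded = json.loads((tmp_path / "fit.json").read_text())
        assert loaded["ofv"] == pytest.approx(res.ofv)
        assert "estimates" in loaded and "cl" in loaded["estimates"]
        text = res.report_text()
        assert "OFV" in text and "cl" in text


class TestCwres:
    def test_reduces_to_scaled_residual_without_iiv(self):
        sim = simulate_cohort(n=15, seed=21, design=StudyDesign(n_courses=1),
                              omega=RandomEffects(omega_cl=0.0, omega_vc=0.0),
                              error=ErrorModel(kind="additive", sigma_add=0.2,
                                               sigma_prop=0.0))
        ds = EventDataset.from_dataframe(sim.events)
        spec = base_model_spec(error_kind="additive",
                               cl_init=12.88, vc_init=72.04)
        spec = replace(spec,
                       iiv=tuple((p, ParamSpec(0.0, fixed=True))
                                 for p, _ in spec.iiv))
        res = fit(spec, ds, seed=0)
        w = cwres(spec, res, ds)
        pred, _ = predict(spec, res.estimates, ds)
        expected = (ds.obs_y - pred) / res.estimates["sigma_add"]
        np.testing.assert_allclose(w, expected, rtol=1e-9)

    def test_deterministic(self, small_dataset):
        spec = base_model_spec()
        res = fit(spec, small_dataset, seed=0)
        np.testing.assert_array_equal(cwres(spec, res, small_dataset),
                                      cwres(spec, res, small_dataset))

    def test_calibration_on_self_simulated_data(self):
        """CWRES of a fitted model on data re-simulated from that same
        fit pools to ~N(0, 1)."""
        from mtxppk.estimation import simulate_observations
        sim = simulate_cohort(n=200, seed=17)
        ds = EventDataset.from_dataframe(sim.events)
        spec = base_model_spec()
        res = fit(spec, ds, seed=0, compute_se=False)
        rng = np.random.default_rng(99)
        new_y = simulate_observations(spec, res.estimates, ds, 1, rng)[0]
        df = ds.df.copy()
        df.loc[df["EVID"] == 0, "DV"] = new_y
        df.loc[df["EVID"] == 0, "BQL"] = (new_y < 0.3).astype(int)
        ds_new = EventDataset.from_dataframe(df, validate=False)
        w = cwres(spec, res, ds_new)
        assert ds_new.n_obs >= 2000
        assert abs(w.mean()) <= 0.05
        assert w.std(ddof=1) == pytest.approx(1.0, abs=0.1)
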