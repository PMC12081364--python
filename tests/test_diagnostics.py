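"""GOF table, bootstrap, VPC and NPDE diagnostics."""

import numpy as np
import pandas as pd
import pytest

from mtxppk.covariate_model import ErrorModel, RandomEffects
from mtxppk.diagnostics import (
    bootstrap,
    gof_table,
    npde,
    plot_gof,
    plot_npde,
    plot_vpc,
    time_after_dose,
    vpc,
)
from mtxppk.estimation import (
    EventDataset,
    base_model_spec,
    final_model_spec,
    fit,
)
from mtxppk.synthetic_cohort import StudyDesign, simulate_cohort

from conftest import TRUTH

pytestmark = pytest.mark.filterwarnings("ignore")


class TestTimeAfterDose:
    def test_first_course_counts_from_course_start(self, small_dataset):
        """The 1 h + 11 h chained infusions are one administration: an
        observation at 36 h has TAD 36, not 35."""
        tad = time_after_dose(small_dataset)
        first_course = small_dataset.obs_time < 500
        np.testing.assert_allclose(tad[first_course],
                                   small_dataset.obs_time[first_course])

    def test_second_course_resets_clock(self):
        sim = simulate_cohort(n=10, seed=44, design=StudyDesign(n_courses=2))
        ds = EventDataset.from_dataframe(sim.events)
        tad = time_after_dose(ds)
        late = ds.obs_time >= 504.0
        assert late.any()
        np.testing.assert_allclose(tad[late], ds.obs_time[late] - 504.0)

    def test_all_nonnegative(self, small_dataset):
        assert np.all(time_after_dose(small_dataset) >= 0)


class TestGofTable:
    def test_noise_free_dv_equals_ipred(self, noise_free_dataset):
        spec = final_model_spec()
        est = dict(TRUTH, omega_cl=0.0, omega_vc=0.0, sigma_prop=1e-6)
        from dataclasses import replace
        from mtxppk.estimation import ParamSpec
        spec2 = replace(
            spec,
            structural=tuple((n, ParamSpec(est[n], fixed=True))
                             for n, _ in spec.structural),
            covariates=tuple(replace(e, init=est[e.name], fixed=True)
                             for e in spec.covariates),
            iiv=tuple((p, ParamSpec(0.0, fixed=True)) for p, _ in spec.iiv),
            sigma=(("prop", ParamSpec(1e-6, fixed=False)),),
        )
        res = fit(spec2, noise_free_dataset, seed=0, compute_se=False)
        table = gof_table(res, noise_free_dataset).table
        np.testing.assert_allclose(table["DV"], table["IPRED"], rtol=1e-5)
        assert {"ID", "TIME", "TAD", "DV", "PRED", "IPRED", "CWRES"} <= set(
            table.columns)
        assert len(table) == noise_free_dataset.n_obs


class TestBootstrap:
    def test_single_subject_degenerate(self):
        sim = simulate_cohort(n=1, seed=50, design=StudyDesign(n_courses=2))
        ds = EventDataset.from_dataframe(sim.events)
        spec = base_model_spec(cl_init=12.0, vc_init=70.0)
        res = bootstrap(spec, ds, n_runs=3, seed=1)
        # every resample draws the same subject: zero-width intervals
        for _, row in res.summary.iterrows():
            assert row["p97.5"] - row["p2.5"] == pytest.approx(0.0, abs=1e-6)

    def test_seed_reproducibility(self, small_dataset):
        spec = base_model_spec()
        a = bootstrap(spec, small_dataset, n_runs=3, seed=7)
        b = bootstrap(spec, small_dataset, n_runs=3, seed=7)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_percentiles_bracket_median(self, small_dataset):
        spec = base_model_spec()
        res = bootstrap(spec, small_dataset, n_runs=5, seed=3)
        assert res.n_success <= res.n_requested
        for _, row in res.summary.iterrows():
            assert row["p2.5"] <= row["median"] <= row["p97.5"]

    def test_invalid_runs_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            bootstrap(base_model_spec(), small_dataset, n_runs=0)

    def test_bootstrap_median_consistent_with_fit(self):
        """At reduced replicate count, the bootstrap median clearance
        stays inside the original fit's 95% CI."""
        sim = simulate_cohort(n=40, seed=77, design=StudyDesign(n_courses=1))
        ds = EventDataset.from_dataframe(sim.events)
        spec = base_model_spec()
        res = fit(spec, ds, seed=0)
        boot = bootstrap(spec, ds, n_runs=6, seed=1, init=res.estimates)
        med = float(boot.summary.set_index("parameter").loc["cl", "median"])
        assert res.ci_lower["cl"] <= med <= res.ci_upper["cl"]


class TestVpc:
    def test_deterministic_given_seed(self, small_dataset):
        spec = final_model_spec()
        a = vpc(spec, TRUTH, small_dataset, n_sim=100, seed=5)
        b = vpc(spec, TRUTH, small_dataset, n_sim=100, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_bands_collapse_without_variability(self, noise_free_dataset):
        est = dict(TRUTH, omega_cl=0.0, omega_vc=0.0, sigma_prop=0.0)
        spec = final_model_spec()
        res = vpc(spec, est, noise_free_dataset, n_sim=100, seed=0)
        for p in ("5", "50", "95"):
            np.testing.assert_allclose(res.table[f"sim_p{p}_lo"],
                                       res.table[f"sim_p{p}_hi"], rtol=1e-9)

    def test_percentiles_ordered(self, small_dataset):
        res = vpc(final_model_spec(), TRUTH, small_dataset, n_sim=150, seed=2)
        t = res.table
        assert (t["obs_p5"] <= t["obs_p50"]).all()
        assert (t["obs_p50"] <= t["obs_p95"]).all()
        assert (t["sim_p5_med"] <= t["sim_p50_med"]).all()

    def test_observed_median_inside_band_under_correct_model(self):
        """Self-consistency: simulating from the generating model, the
        observed medians fall inside the simulated confidence bands in
        most bins."""
        # full retention at every nominal time so the check spans 7 bins
        design = StudyDesign(n_courses=1, retention=(1.0,) * 7)
        sim = simulate_cohort(n=250, seed=60, design=design)
        ds = EventDataset.from_dataframe(sim.events)
        res = vpc(final_model_spec(), TRUTH, ds, n_sim=400, seed=1)
        t = res.table
        inside = ((t["obs_p50"] >= t["sim_p50_lo"])
                  & (t["obs_p50"] <= t["sim_p50_hi"]))
        assert inside.mean() >= 0.8

    def test_minimum_simulations_enforced(self, small_dataset):
        with pytest.raises(ValueError):
            vpc(final_model_spec(), TRUTH, small_dataset, n_sim=10, seed=0)


class TestNpde:
    def test_deterministic_given_seed(self, small_dataset):
        spec = final_model_spec()
        a = npde(spec, TRUTH, small_dataset, n_sim=200, seed=4)
        b = npde(spec, TRUTH, small_dataset, n_sim=200, seed=4)
        np.testing.assert_array_equal(a.npde, b.npde)

    def test_invariant_to_row_order_and_subsetting(self, small_cohort):
        """NPDE values follow the subject, not the processing order:
        permuting dataset rows leaves them unchanged, and a subject's
        values in a sub-cohort equal its values in the full cohort
        (each subject consumes its own seeded simulation stream)."""
        spec = final_model_spec()
        ds = EventDataset.from_dataframe(small_cohort.events)
        shuffled = small_cohort.events.sample(frac=1.0, random_state=1)
        ds2 = EventDataset.from_dataframe(shuffled, validate=False)
        a = npde(spec, TRUTH, ds, n_sim=150, seed=8)
        b = npde(spec, TRUTH, ds2, n_sim=150, seed=8)
        np.testing.assert_allclose(a.npde, b.npde, atol=1e-12)
        keep = list(ds.subject_ids[:10])
        sub = ds.subset_subjects(keep, relabel=False)
        c = npde(spec, TRUTH, sub, n_sim=150, seed=8)
        mask = np.isin(ds.df[ds.df["EVID"] == 0]["ID"].to_numpy(), keep)
        np.testing.assert_allclose(c.npde, a.npde[mask], atol=1e-12)

    def test_null_calibration(self):
        """NPDE from the generating model is ~standard normal."""
        sim = simulate_cohort(n=200, seed=70, design=StudyDesign(n_courses=2))
        ds = EventDataset.from_dataframe(sim.events)
        res = npde(final_model_spec(), TRUTH, ds, n_sim=500, seed=2)
        assert abs(res.mean) <= 0.1
        assert 0.85 <= res.variance <= 1.15
        assert np.all(np.isfinite(res.npde))

    def test_misspecified_clearance_detected(self):
        """Doubling CL in the evaluated model shifts the NPDE mean."""
        sim = simulate_cohort(n=80, seed=71, design=StudyDesign(n_courses=2))
        ds = EventDataset.from_dataframe(sim.events)
        wrong = dict(TRUTH, cl=2 * TRUTH["cl"])
        res = npde(final_model_spec(), wrong, ds, n_sim=300, seed=3)
        assert res.p_wilcoxon < 0.05

    def test_pvalues_in_unit_interval(self, small_dataset):
        res = npde(final_model_spec(), TRUTH, small_dataset, n_sim=150, seed=9)
        for p in res.tests().values():
            assert 0.0 <= p <= 1.0


class TestPlots:
    def test_plot_files_created(self, small_dataset, tmp_path):
        spec = base_model_spec()
        res = fit(spec, small_dataset, seed=0, compute_se=False)
        gof = gof_table(res, small_dataset)
        plot_gof(gof, tmp_path / "gof.svg")
        v = vpc(spec, res.estimates, small_dataset, n_sim=100, seed=0)
        plot_vpc(v, small_dataset, tmp_path / "vpc.svg")
        n = npde(spec, res.estimates, small_dataset, n_sim=100, seed=0)
        plot_npde(n, small_dataset, tmp_path / "npde.svg")
        for name in ("gof.svg", "vpc.svg", "npde.svg"):
            assert (tmp_path / name).stat().st_size > 0
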