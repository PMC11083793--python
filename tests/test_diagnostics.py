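"""Residual deviance/leverage, inconsistency check, prior sensitivity."""

import numpy as np
import pytest

import armnma as am
from armnma.diagnostics import (
    design_by_treatment_check,
    prior_sensitivity,
    residual_deviance,
)
from armnma.nma_model import HeterogeneityPrior, ModelSpec
from armnma.sampler import PosteriorDraws, SamplerConfig

from conftest import make_binary_ds, make_continuous_ds


def _perfect_fit_draws(ds):
    """Continuous draws whose fitted means equal the data exactly."""
    lo = am.ParamLayout(ds)
    n = 50
    mu = np.array([a.mean for a in ds.arms])[lo.baseline_arm]
    delta = np.array([
        ds.arms[j].mean - mu[lo.arm_study[j]] for j in lo.nonbase_arms
    ])
    return PosteriorDraws(
        ds=ds, spec=ModelSpec.for_dataset(ds),
        config=SamplerConfig(iterations=n, burn_in=0, thin=1, chains=1, seed=0),
        d=np.zeros((1, n, lo.n_treat - 1)),
        mu=np.tile(mu, (1, n, 1)).reshape(1, n, -1),
        delta=np.tile(delta, (1, n, 1)).reshape(1, n, -1),
        tau=np.full((1, n), 0.1),
    )


class TestResidualDeviance:
    def test_exactly_fitted_arms_have_zero_deviance(self):
        ds = make_continuous_ds([
            ("s1", "A", 30, 10.0, 2.0), ("s1", "B", 30, 12.0, 2.0),
            ("s2", "A", 30, 9.0, 2.0), ("s2", "B", 30, 11.0, 2.0),
        ])
        dev = residual_deviance(_perfect_fit_draws(ds))
        assert np.allclose(dev.per_arm.dev_mean, 0.0, atol=1e-20)
        assert np.allclose(dev.per_arm.leverage, 0.0, atol=1e-20)

    def test_total_deviance_near_data_count(self, sim_draws, sim_ds):
        # chi-square heuristic for a well-specified model: total posterior-mean
        # residual deviance ~ number of data points, within 2 * sqrt(2N)
        dev = residual_deviance(sim_draws)
        N = len(sim_ds.arms)
        assert abs(dev.total_deviance - N) < 2 * np.sqrt(2 * N)

    def test_leverage_sums_to_pd(self, sim_draws):
        dev = residual_deviance(sim_draws)
        assert abs(dev.per_arm.leverage.sum() - dev.pD) < 1e-8
        assert dev.dic == pytest.approx(dev.total_deviance + dev.pD)
        assert dev.pD > 0

    def test_leverages_bounded_for_well_fitting_model(self, sim_draws):
        dev = residual_deviance(sim_draws)
        assert dev.per_arm.leverage.min() > -0.05
        assert dev.per_arm.leverage.max() <= 1.5
        flagged = dev.influential(leverage_limit=1.0)
        assert (flagged.leverage > 1.0).all()

    def test_plot_table_columns(self, sim_draws):
        tab = residual_deviance(sim_draws).plot_table()
        assert list(tab.columns) == ["study", "treatment", "sqrt_dev", "leverage"]
        assert (tab.sqrt_dev >= 0).all()

    def test_refit_on_self_generated_data_fits_well(self, sim_draws, sim_ds):
        # simulate from the fitted model's posterior means and refit: the
        # refit must not show lack of fit (deviance near the data count)
        dfull = sim_draws.d_full_pooled().mean(axis=0)
        mu = sim_draws.pooled("mu").mean(axis=0)
        lo = am.ParamLayout(sim_ds)
        rng = np.random.default_rng(31)
        rows = []
        for j, a in enumerate(sim_ds.arms):
            s = lo.arm_study[j]
            eta = mu[s] + (dfull[lo.arm_treat[j]]
                           - dfull[lo.arm_treat[lo.baseline_arm[s]]])
            rows.append((a.study_id, a.treatment,
                         int(rng.binomial(a.total, np.exp(eta))), a.total))
        ds2 = make_binary_ds(rows, reference="OpDG")
        draws2 = am.run_mcmc(ds2, cfg=SamplerConfig(3000, 1200, 2, 2, seed=32))
        dev2 = residual_deviance(draws2)
        N = len(ds2.arms)
        assert dev2.total_deviance < N + 2 * np.sqrt(2 * N)


class TestDesignByTreatment:
    def test_star_plus_one_edge_returns_structural_note(self, sim_ds):
        # the packaged geometry: hub reference + one extra edge, every
        # comparison informed by a single design -> no identifiable loop
        res = design_by_treatment_check(sim_ds)
        assert not res.identifiable
        assert "not statistically identifiable" in res.structural_note
        assert "consistent" in res.verdict
        assert res.omegas == [] and res.delta_dic is None

    @pytest.mark.parametrize("n_spokes", [2, 3])
    def test_any_single_design_per_comparison_network_is_structural(self, n_spokes):
        rows = []
        for i, t in enumerate("BCD"[:n_spokes]):
            rows += [(f"s{i}", "A", 3, 60), (f"s{i}", t, 4, 60)]
        res = design_by_treatment_check(make_binary_ds(rows))
        assert not res.identifiable

    def test_consistent_triangle_passes(self):
        truth = am.SimulationTruth(
            treatments=["A", "B", "C"], d_true=[0.3, -0.2], tau_true=0.08,
            designs=[(("A", "B"), (300, 300)), (("A", "C"), (300, 300)),
                     (("B", "C"), (300, 300))] * 2,
            baseline_beta=(25, 100), seed=17,
        )
        ds = am.simulate_network(truth)
        res = design_by_treatment_check(
            ds, cfg=SamplerConfig(3000, 1200, 2, 2, seed=18)
        )
        assert res.identifiable and len(res.omegas) == 1
        assert all(o["cri_contains_zero"] for o in res.omegas)
        assert res.verdict == "no significant inconsistency"

    def test_inconsistent_triangle_detected(self):
        # generate a consistent triangle, then shift the direct A-B design's
        # events far off the consistency value
        truth = am.SimulationTruth(
            treatments=["A", "B", "C"], d_true=[0.0, 0.0], tau_true=0.05,
            designs=[(("A", "B"), (800, 800)), (("A", "C"), (800, 800)),
                     (("B", "C"), (800, 800))] * 4,
            baseline_beta=(40, 160), seed=19,
        )
        ds = am.simulate_network(truth)
        shifted = {f"study{i:02d}" for i in (1, 4, 7, 10)}
        rows = []
        for a in ds.arms:
            ev = a.events
            if a.study_id in shifted and a.treatment == "B":
                ev = int(round(ev * 3))  # direct A-B effect pushed off
            rows.append((a.study_id, a.treatment, ev, a.total))
        ds_shift = make_binary_ds(rows)
        res = design_by_treatment_check(
            ds_shift, cfg=SamplerConfig(3000, 1200, 2, 2, seed=20)
        )
        assert res.identifiable
        assert any(not o["cri_contains_zero"] for o in res.omegas)
        assert res.verdict == "potential inconsistency"


class TestPriorSensitivity:
    def test_base_prior_alone_shifts_nothing(self, sim_ds):
        spec = ModelSpec.for_dataset(sim_ds)
        res = prior_sensitivity(
            sim_ds, spec, alt_priors=[spec.priors.heterogeneity],
            cfg=SamplerConfig(1500, 600, 2, 2, seed=23),
        )
        assert np.all(res.table.max_abs_shift == 0.0)
        assert res.table.is_base.all()

    def test_sparse_data_tau_tracks_prior(self):
        # two tiny trials: the tau posterior is prior-driven, so widening the
        # heterogeneity prior visibly moves the fit
        ds = make_binary_ds([
            ("s1", "A", 2, 25), ("s1", "B", 4, 25),
            ("s2", "A", 3, 25), ("s2", "B", 1, 25),
        ])
        res = prior_sensitivity(
            ds, alt_priors=[HeterogeneityPrior("half-normal", 2.0)],
            cfg=SamplerConfig(4000, 1500, 2, 2, seed=24),
        )
        base, wide = res.table.iloc[0], res.table.iloc[1]
        assert wide.tau_median > base.tau_median
        assert wide.max_abs_shift > 0.0

    def test_default_alternatives_cover_stated_set(self):
        labels = [p.label() for p in am.diagnostics.DEFAULT_ALT_PRIORS]
        assert labels == ["half-normal(0.25)", "half-normal(1.0)", "uniform(2.0)"]
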