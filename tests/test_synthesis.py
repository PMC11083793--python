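"""League tables, ranking probabilities, SUCRA and I-squared."""

import numpy as np
import pytest

import armnma as am
from armnma.nma_model import ModelSpec
from armnma.sampler import PosteriorDraws, SamplerConfig
from armnma.synthesis import (
    categorize_i2,
    compute_I2,
    league_table,
    rank_probabilities,
    typical_sampling_variance,
)

from conftest import make_binary_ds


def _draws_with(ds, d_draws, tau_draws=None):
    """Wrap hand-made pooled draws (1 chain) in a PosteriorDraws."""
    d = np.asarray(d_draws, float)[None, :, :]
    n = d.shape[1]
    tau = (np.asarray(tau_draws, float) if tau_draws is not None
           else np.full(n, 0.1))[None, :]
    lo = am.ParamLayout(ds)
    return PosteriorDraws(
        ds=ds, spec=ModelSpec.for_dataset(ds),
        config=SamplerConfig(iterations=n, burn_in=0, thin=1, chains=1, seed=0),
        d=d, mu=np.zeros((1, n, lo.n_study)) - 2.0,
        delta=np.zeros((1, n, lo.n_delta)), tau=tau,
    )


class TestLeagueTable:
    def test_diagonal_is_identity(self, sim_draws):
        lt = league_table(sim_draws)
        for t in lt.treatments:
            c = lt.cell(t, t)
            assert (c.mean, c.cri_low, c.cri_high) == (1.0, 1.0, 1.0)
            assert not c.significant

    def test_rr_quantile_reciprocity_exact(self, sim_draws):
        lt = league_table(sim_draws)
        for a in lt.treatments:
            for b in lt.treatments:
                if a == b:
                    continue
                assert lt.cell(a, b).cri_low == pytest.approx(
                    1.0 / lt.cell(b, a).cri_high, rel=1e-12
                )

    def test_wmd_antisymmetry_exact(self, cont_draws):
        lt = league_table(cont_draws)
        assert lt.scale == "WMD"
        for a in lt.treatments:
            for b in lt.treatments:
                ab, ba = lt.cell(a, b), lt.cell(b, a)
                assert ab.mean == -ba.mean
                # percentile interpolation is symmetric to the last ulp only
                assert ab.cri_low == pytest.approx(-ba.cri_high, rel=1e-12)
                assert ab.cri_high == pytest.approx(-ba.cri_low, rel=1e-12)

    def test_indirect_cell_is_difference_of_basic_contrasts(self, sim_draws):
        # the (LapDG, LapAsDG) cell must summarize the per-draw composition of
        # (LapAsDG vs ref) and (LapDG vs ref), i.e. indirect evidence only
        lt = league_table(sim_draws)
        dfull = sim_draws.d_full_pooled()
        i = lt.treatments.index("LapDG")
        j = lt.treatments.index("LapAsDG")
        contrast = dfull[:, j] - dfull[:, i]
        cell = lt.cell("LapDG", "LapAsDG")
        assert cell.mean == pytest.approx(np.mean(np.exp(contrast)), rel=1e-12)
        lo, hi = np.exp(np.percentile(contrast, [2.5, 97.5]))
        assert (cell.cri_low, cell.cri_high) == pytest.approx((lo, hi), rel=1e-12)

    def test_significance_rule_is_cri_excluding_null(self, toy2x2):
        d_draws = np.full((200, 1), 0.5) + np.linspace(-0.1, 0.1, 200)[:, None]
        lt = league_table(_draws_with(toy2x2, d_draws))
        assert lt.cell("A", "B").significant  # CrI entirely above RR = 1
        d_draws = np.linspace(-0.5, 0.5, 200)[:, None]
        lt = league_table(_draws_with(toy2x2, d_draws))
        assert not lt.cell("A", "B").significant


class TestRanking:
    def test_probabilities_normalized_both_ways(self, sim_draws):
        rk = rank_probabilities(sim_draws)
        assert np.allclose(rk.prob.sum(axis=1), 1.0)  # per treatment
        assert np.allclose(rk.prob.sum(axis=0), 1.0)  # per rank

    def test_sucra_mean_is_half_exactly(self, sim_draws):
        rk = rank_probabilities(sim_draws)
        assert rk.sucra.mean() == 0.5

    def test_exchangeable_treatments_split_first_place(self):
        ds = make_binary_ds([("s1", "A", 10, 100), ("s1", "B", 10, 100)])
        draws = am.run_mcmc(ds, cfg=SamplerConfig(6000, 2000, 2, 2, seed=4))
        rk = rank_probabilities(draws)
        assert np.all(np.abs(rk.p_first - 0.5) < 0.08)

    def test_direction_harm_ranks_lowest_contrast_first(self, toy2x2):
        rng = np.random.default_rng(0)
        # B's contrast concentrated at -1: under "harm", B is safest
        d_draws = rng.normal(-1.0, 0.05, (500, 1))
        rk = rank_probabilities(_draws_with(toy2x2, d_draws), direction="harm")
        assert rk.p_first[rk.treatments.index("B")] > 0.99
        rk = rank_probabilities(_draws_with(toy2x2, d_draws), direction="benefit")
        assert rk.p_first[rk.treatments.index("A")] > 0.99

    def test_known_truth_ordering(self):
        truth = am.SimulationTruth(
            treatments=["A", "B", "C"], d_true=[-1.0, 1.0], tau_true=0.05,
            designs=[(("A", "B"), (400, 400)), (("A", "C"), (400, 400)),
                     (("B", "C"), (400, 400))] * 2,
            baseline_beta=(30, 170), seed=8,
        )
        ds = am.simulate_network(truth)
        draws = am.run_mcmc(ds, cfg=SamplerConfig(3000, 1000, 2, 2, seed=9))
        rk = rank_probabilities(draws, direction="harm")
        assert rk.p_first[rk.treatments.index("B")] == max(rk.p_first)
        assert rk.sucra[rk.treatments.index("C")] == min(rk.sucra)


class TestHeterogeneity:
    def test_no_heterogeneity_is_low(self, toy2x2):
        draws = _draws_with(toy2x2, np.zeros((100, 1)), tau_draws=np.zeros(100))
        het = compute_I2(draws)
        assert het.i2 == 0.0 and het.category == "low"

    def test_formula_midpoint(self, toy2x2):
        s2 = typical_sampling_variance(toy2x2)
        draws = _draws_with(toy2x2, np.zeros((100, 1)),
                            tau_draws=np.full(100, np.sqrt(s2)))
        het = compute_I2(draws)
        assert het.i2 == pytest.approx(50.0)
        assert het.category == "moderate"

    @pytest.mark.parametrize("i2,cat", [
        (10.0, "low"), (25.0, "low"), (30.0, "intermediate"),
        (49.9, "intermediate"), (50.0, "moderate"), (74.9, "moderate"),
        (75.0, "high"), (95.0, "high"),
    ])
    def test_category_bands(self, i2, cat):
        assert categorize_i2(i2) == cat

    def test_single_study_warns_and_omits(self):
        ds = make_binary_ds([("s1", "A", 5, 50), ("s1", "B", 8, 50)])
        draws = _draws_with(ds, np.zeros((50, 1)))
        with pytest.warns(UserWarning, match="not estimable"):
            assert compute_I2(draws) is None

    def test_i2_recovery_on_simulated_network(self):
        # 20-study network generated at known tau: the posterior median I^2
        # should sit near the generating 100 tau^2 / (tau^2 + s^2)
        truth = am.SimulationTruth(
            treatments=["A", "B"], d_true=[0.0], tau_true=0.25,
            designs=[(("A", "B"), (250, 250))] * 20,
            baseline_beta=(30, 170), seed=12,
        )
        ds = am.simulate_network(truth)
        draws = am.run_mcmc(ds, cfg=SamplerConfig(5000, 2000, 2, 2, seed=13))
        het = compute_I2(draws)
        s2 = typical_sampling_variance(ds)
        target = 100 * truth.tau_true**2 / (truth.tau_true**2 + s2)
        assert abs(het.i2 - target) < 10.0

    def test_league_table_carries_i2(self, sim_draws):
        lt = league_table(sim_draws)
        assert lt.i2 is not None and 0.0 <= lt.i2.i2 < 100.0


class TestExports:
    def test_grid_and_frame_round_out(self, sim_draws, tmp_path):
        lt = league_table(sim_draws)
        grid = lt.to_grid()
        assert len(grid["grid"]) == 4 and len(grid["grid"][0]) == 4
        lt.save(tmp_path / "league.csv")
        lt.save(tmp_path / "league.json")
        assert (tmp_path / "league.csv").exists()
        assert (tmp_path / "league.json").exists()
        rk = rank_probabilities(sim_draws)
        dd = rk.to_dict()
        assert set(dd["p_first"]) == set(lt.treatments)
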