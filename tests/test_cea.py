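"""Costs, ICER, CEAC, and coefficient uncertainty."""
import numpy as np
import pytest
from scipy.stats import norm

import precog as pg
from precog.errors import ConfigError, DominanceError

GBP = pg.CostSchedule({"s": 15896.0, "f": 6677.0, "st": 4843.0})


def econ(cost, effect, label=""):
    return pg.PlanEconomics(pg.DStudyPlan({}, label), cost, effect)


class TestCosts:
    def test_unit_example(self):
        sched = pg.CostSchedule({"a": 1.0, "b": 1.0, "c": 1.0})
        assert pg.total_cost(sched, pg.DStudyPlan({"a": 2, "b": 3, "c": 4})) == 9

    def test_multisite_schedule_exact_sum(self):
        plan = pg.DStudyPlan({"s": 6, "f": 4, "st": 18})
        assert pg.total_cost(GBP, plan) == pytest.approx(209258.0)

    def test_fixed_cost_only(self):
        sched = pg.CostSchedule({"a": 0.0}, fixed_cost=100.0)
        assert pg.total_cost(sched, pg.DStudyPlan({"a": 5})) == 100.0

    def test_missing_facet_rejected(self):
        with pytest.raises(ConfigError, match="lacks unit costs"):
            pg.total_cost(GBP, pg.DStudyPlan({"s": 6, "raters": 2}))

    def test_linearity_scale_invariance(self):
        plan = pg.DStudyPlan({"s": 6, "f": 4, "st": 18})
        doubled = pg.DStudyPlan({"s": 12, "f": 8, "st": 36})
        halved = pg.CostSchedule({k: v / 2 for k, v in GBP.unit_costs.items()})
        assert pg.total_cost(halved, doubled) == pytest.approx(
            pg.total_cost(GBP, plan)
        )

    def test_negative_unit_cost_rejected(self):
        with pytest.raises(ConfigError):
            pg.CostSchedule({"a": -1.0})


class TestICER:
    def test_cost_saving_less_effective_positive_by_sign_cancellation(self):
        value = pg.icer(econ(147491.0, 0.75), econ(209240.0, 0.81))
        assert value == pytest.approx(1_029_150.0, rel=1e-9)

    def test_simple_ratio(self):
        assert pg.icer(econ(10.0, 1.0), econ(0.0, 0.0)) == pytest.approx(10.0)

    def test_equal_effectiveness_is_dominance_error(self):
        with pytest.raises(DominanceError, match="compare"):
            pg.icer(econ(10.0, 0.8), econ(20.0, 0.8))

    def test_rescale_and_display(self):
        value = pg.icer(econ(147491.0, 0.75), econ(209240.0, 0.81))
        scaled = pg.rescale_icer(value, 0.01)
        assert scaled == pytest.approx(10291.5, rel=1e-9)
        assert pg.display_round(scaled) == 10292

    def test_rescale_identity_and_zero(self):
        assert pg.rescale_icer(123.4, 1.0) == 123.4
        assert pg.rescale_icer(0.0, 0.01) == 0.0
        with pytest.raises(ConfigError):
            pg.rescale_icer(1.0, 0.0)

    @pytest.mark.parametrize("x,want", [
        (10291.5, 10292), (-10291.5, -10292), (2.4, 2), (-2.4, -2), (0.5, 1),
    ])
    def test_display_round_half_away_from_zero(self, x, want):
        assert pg.display_round(x) == want


class TestCEAC:
    DC, DE = -61749.0, -0.06  # cost-saving, less-effective intervention

    def test_degenerate_distributions_step_at_icer(self):
        """With ΔC, ΔE both negative, net benefit > 0 iff λ < ΔC/ΔE: the
        curve steps from 1 to 0 exactly at the ICER."""
        icer_scaled = (self.DC / self.DE) * 0.01
        grid = np.linspace(0, 3 * icer_scaled, 97)
        res = pg.ceac(
            pg.DeltaDistribution("degenerate", self.DC),
            pg.DeltaDistribution("degenerate", self.DE),
            grid, n_draws=10, seed=0, rescale_unit=0.01,
        )
        for lam, prob in zip(res.wtp_grid, res.ceac):
            expected = 1.0 if (lam / 0.01) * self.DE - self.DC > 0 else 0.0
            assert prob == expected
        # brute-force location of the step equals the rescaled ICER
        drop = np.nonzero(np.diff(res.ceac) < 0)[0]
        assert len(drop) == 1
        assert grid[drop[0]] < icer_scaled <= grid[drop[0] + 1]

    def test_identical_seed_identical_curve(self):
        kw = dict(
            delta_cost_dist=pg.DeltaDistribution("normal", self.DC, sd=5000.0),
            delta_effect_dist=pg.DeltaDistribution("normal", self.DE, sd=0.01,
                                                   bounds=(-1, 1)),
            wtp_grid=np.linspace(0, 30000, 50), n_draws=2000,
        )
        a = pg.ceac(seed=42, **kw)
        b = pg.ceac(seed=42, **kw)
        c = pg.ceac(seed=43, **kw)
        assert np.array_equal(a.ceac, b.ceac)
        # difference of two independent binomial proportions: pooled
        # variance 2 p(1-p)/n plus a 2/n continuity floor near p ∈ {0, 1}
        pooled = (a.ceac + c.ceac) / 2
        band = 3 * np.sqrt(2 * pooled * (1 - pooled) / 2000) + 2 / 2000
        assert np.all(np.abs(a.ceac - c.ceac) <= band)

    def test_monotone_in_wtp_for_fixed_draws(self):
        res = pg.ceac(
            pg.DeltaDistribution("normal", self.DC, sd=20000.0),
            pg.DeltaDistribution("normal", self.DE, sd=0.02, bounds=(-1, 1)),
            np.linspace(0, 40000, 80), n_draws=5000, seed=1,
        )
        # ΔE < 0: higher willingness to pay favors the more effective base
        assert np.all(np.diff(res.ceac) <= 0)

    def test_converges_to_normal_theory(self):
        """Large-draw CEAC matches the closed-form normal probability."""
        sd_c, sd_e = 8000.0, 0.015
        grid = np.array([2000.0, 6000.0, 10291.5, 15000.0, 25000.0])
        res = pg.ceac(
            pg.DeltaDistribution("normal", self.DC, sd=sd_c),
            pg.DeltaDistribution("normal", self.DE, sd=sd_e),
            grid, n_draws=10**5, seed=2,
        )
        lam = grid / 0.01
        mean = lam * self.DE - self.DC
        sd = np.sqrt(lam**2 * sd_e**2 + sd_c**2)
        assert np.allclose(res.ceac, norm.sf(0.0, loc=mean, scale=sd), atol=0.01)

    def test_bad_config_rejected(self):
        d = pg.DeltaDistribution("degenerate", 1.0)
        with pytest.raises(ConfigError):
            pg.ceac(d, d, [], n_draws=10, seed=0)
        with pytest.raises(ConfigError):
            pg.ceac(d, d, [1.0], n_draws=0, seed=0)
        with pytest.raises(ConfigError):
            pg.DeltaDistribution("triangular", 0.0)
        with pytest.raises(ConfigError):
            pg.DeltaDistribution("normal", 1.0)  # no sd/cv

    def test_lognormal_cost_draws_keep_sign_and_moments(self):
        dist = pg.DeltaDistribution("lognormal", -20000.0, cv=0.2)
        draws = dist.sample(np.random.default_rng(0), 200_000)
        assert np.all(draws < 0)
        assert draws.mean() == pytest.approx(-20000.0, rel=0.01)
        assert draws.std() == pytest.approx(4000.0, rel=0.02)


class TestEffectivenessUncertainty:
    def _vc(self, seed=21, sizes=(30, 4, 3)):
        design = pg.parse_design("p x t x r")
        spec = pg.SimulationSpec(
            design=design,
            sizes=dict(zip(("p", "t", "r"), sizes)),
            true_components={"p": 4.0, "pt": 1.0, "pr": 1.0, "ptr": 2.0},
            seed=seed,
        )
        return design, spec

    def test_user_supplied_passthrough(self, crossed_design):
        vc = pg.VarianceComponents.assumed(crossed_design, {"p": 1.0})
        se = pg.effectiveness_uncertainty(
            vc, pg.DStudyPlan({"t": 2, "r": 2}), method="user-supplied", value=0.02
        )
        assert se == 0.02

    def test_assumed_components_cannot_bootstrap(self, crossed_design):
        vc = pg.VarianceComponents.assumed(crossed_design, {"p": 1.0})
        with pytest.raises(ConfigError, match="mean squares"):
            pg.effectiveness_uncertainty(vc, pg.DStudyPlan({"t": 2, "r": 2}))

    def test_zero_variance_data_gives_zero_se(self, crossed_design):
        import pandas as pd
        from conftest import random_balanced_table
        table = random_balanced_table(crossed_design, {"p": 5, "t": 3, "r": 2}, 0)
        table["score"] = 4.0
        vc = pg.estimate_components(table, crossed_design)
        se = pg.effectiveness_uncertainty(
            vc, pg.DStudyPlan({"t": 3, "r": 2}), seed=0, n_replicates=200
        )
        assert se == 0.0

    def test_parametric_bootstrap_tracks_sampling_sd(self):
        """Bootstrap SE agrees with the SD of the coefficient across 500
        independently simulated datasets (25% relative).  One dataset's
        bootstrap SE is itself a noisy statistic, so the check compares the
        mean bootstrap SE over ten datasets."""
        design, spec = self._vc(sizes=(100, 8, 4))
        plan = pg.DStudyPlan({"t": 8, "r": 4})

        coefs = []
        master = np.random.default_rng(2024)
        for s in master.integers(0, 2**31 - 1, size=500):
            rep = pg.SimulationSpec(
                design=design, sizes=spec.sizes,
                true_components=spec.true_components, seed=int(s),
            )
            vc = pg.estimate_components(pg.simulate_scores(rep), design)
            coefs.append(pg.g_coefficient(vc, plan, "relative").coefficient)
        empirical = float(np.std(coefs, ddof=1))

        boots = []
        for s in np.random.default_rng(4202).integers(0, 2**31 - 1, size=10):
            rep = pg.SimulationSpec(
                design=design, sizes=spec.sizes,
                true_components=spec.true_components, seed=int(s),
            )
            vc0 = pg.estimate_components(pg.simulate_scores(rep), design)
            boots.append(
                pg.effectiveness_uncertainty(
                    vc0, plan, method="parametric-bootstrap",
                    n_replicates=2000, seed=77,
                )
            )
        assert float(np.mean(boots)) == pytest.approx(empirical, rel=0.25)

    def test_jackknife_runs_and_is_comparable(self):
        design, spec = self._vc()
        plan = pg.DStudyPlan({"t": 4, "r": 3})
        scores = pg.simulate_scores(spec)
        vc = pg.estimate_components(scores, design)
        jk = pg.effectiveness_uncertainty(
            vc, plan, method="jackknife", scores=scores
        )
        boot = pg.effectiveness_uncertainty(
            vc, plan, method="parametric-bootstrap", n_replicates=2000, seed=5
        )
        assert jk > 0
        assert jk == pytest.approx(boot, rel=0.75)  # same order of magnitude

    def test_unknown_method_rejected(self, crossed_design):
        vc = pg.VarianceComponents.assumed(crossed_design, {"p": 1.0})
        with pytest.raises(ConfigError, match="unknown"):
            pg.effectiveness_uncertainty(
                vc, pg.DStudyPlan({"t": 1, "r": 1}), method="delta"
            )
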