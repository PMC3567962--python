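"""Value-of-information estimators: EVPI, effective population, nested EVPPI."""

import numpy as np
import pytest

from htncea import (
    EffectivePopulationSpec,
    degenerate_config,
    effective_population,
    evpi,
    evppi,
    population_evpi,
    run_psa,
)
from htncea.psa import PSAResults
from htncea.synthetic import closed_form_case
from htncea.voi import standard_parameter_groups


def make_psa(strategies, qaly, cost):
    qaly = np.asarray(qaly, dtype=float)
    cost = np.asarray(cost, dtype=float)
    return PSAResults(
        strategies=list(strategies), qaly=qaly, cost=cost, seed=0, n_iter=qaly.shape[1]
    )


class TestEffectivePopulation:
    def test_undiscounted_is_cohort_times_horizon(self):
        assert effective_population(EffectivePopulationSpec(1000, 30, 0.0)) == 30000

    def test_single_cohort_is_its_own_population(self):
        assert effective_population(EffectivePopulationSpec(1, 1, 0.04)) == 1

    def test_matches_geometric_series_closed_form(self):
        got = effective_population(EffectivePopulationSpec(1000, 30, 0.03))
        closed = 1000 * (1 - 1.03**-30) / (1 - 1.03**-1)
        assert got == pytest.approx(closed, abs=1e-6)
        assert got == pytest.approx(20188.45, abs=0.01)


class TestEVPI:
    def test_zero_when_one_strategy_always_wins(self):
        psa = make_psa(["a", "b"], [[2, 2], [1, 1]], [[0, 0], [0, 0]])
        assert evpi(psa, 1000) == 0.0

    def test_hand_enumerated_two_by_two(self):
        # NMB iterations a:(1,0), b:(0,1) at wtp=1 with zero costs
        psa = make_psa(["a", "b"], [[1, 0], [0, 1]], [[0, 0], [0, 0]])
        assert evpi(psa, 1.0) == pytest.approx(0.5)

    def test_invariant_to_common_nmb_shift(self, psa_by_stratum):
        psa = psa_by_stratum["medium"]
        shifted = make_psa(psa.strategies, psa.qaly, psa.cost - 1234.5)
        assert evpi(psa, 8000) == pytest.approx(evpi(shifted, 8000), abs=1e-9)

    def test_degenerate_psa_has_zero_evpi(self, medium_config):
        psa = run_psa(degenerate_config(medium_config), n_iter=4, seed=0)
        assert evpi(psa, 15000) == 0.0

    def test_nonnegative_across_grid(self, psa_by_stratum):
        for psa in psa_by_stratum.values():
            for wtp in (0, 2700, 15000):
                assert evpi(psa, wtp) >= 0.0

    def test_population_scaling_is_linear(self, psa_by_stratum):
        psa = psa_by_stratum["low"]
        one = population_evpi(psa, 2700, EffectivePopulationSpec(1000, 30, 0.03))
        five = population_evpi(psa, 2700, EffectivePopulationSpec(5000, 30, 0.03))
        assert five.population == pytest.approx(5 * one.population, rel=1e-12)
        assert one.population == pytest.approx(one.per_patient * 20188.4546, rel=1e-6)


@pytest.fixture(scope="module")
def single_uncertainty_config():
    """Only one influential uncertain parameter: the drug's annual cost.

    A no-event, constant-mortality model where the treated arm lowers
    all-cause mortality (relative risk 0.8) at an uncertain triangular
    annual cost; at a willingness-to-pay of $3,400/QALY the break-even
    cost sits at the triangular mode, so the optimal choice genuinely
    depends on the cost draw.
    """
    from htncea.parameters import DrugEffect, NormalSpec, TriangularSpec

    cfg, _ = closed_form_case("mortality_only", mortality=0.02, discount_rate=0.03)
    cfg = degenerate_config(cfg)
    drug = DrugEffect(
        name="drug",
        rr_stroke=NormalSpec(mean=1.0, se=0.0),
        rr_chd=NormalSpec(mean=1.0, se=0.0),
        rr_death=NormalSpec(mean=0.8, se=0.0),
    )
    costs = cfg.costs.model_copy(
        update={
            "annual_drug_cost": {
                "null": TriangularSpec(minimum=0, mode=0, maximum=0),
                "drug": TriangularSpec(minimum=0.0, mode=150.0, maximum=600.0),
            }
        }
    )
    return cfg.model_copy(update={"strategies": cfg.strategies + [drug], "costs": costs})


class TestEVPPI:

    def test_relevant_parameter_captures_all_information(self, single_uncertainty_config):
        """With a single uncertain parameter, its EVPPI equals total EVPI."""
        cfg = single_uncertainty_config
        wtp = 3400.0
        psa = run_psa(cfg, n_iter=4000, seed=10)
        total = evpi(psa, wtp)
        assert total > 0
        res = evppi(cfg, ["drug_cost:drug"], wtp, outer=400, inner=1, seed=11)
        mc_tol = 4 * res.mc_se if res.mc_se else 1.0
        assert res.per_patient == pytest.approx(total, abs=max(mc_tol, 0.05 * total))

    def test_irrelevant_parameter_has_negligible_value(self, single_uncertainty_config):
        """A parameter that cannot influence any NMB yields zero EVPPI.

        Chronic management cost never accrues here (no one ever has an
        event); with the drug cost pinned to its mode the management
        cost is the only sampled quantity, so the estimate is exact.
        """
        from htncea.parameters import TriangularSpec

        cfg = single_uncertainty_config
        costs = cfg.costs.model_copy(
            update={
                "annual_drug_cost": {
                    **cfg.costs.annual_drug_cost,
                    "drug": TriangularSpec(minimum=150.0, mode=150.0, maximum=150.0),
                },
                "chronic_management": TriangularSpec(minimum=100.0, mode=400.0, maximum=800.0),
            }
        )
        cfg = cfg.model_copy(update={"costs": costs})
        res = evppi(cfg, ["cost:management"], 3400.0, outer=30, inner=4, seed=3)
        assert res.per_patient <= 1e-9

    def test_small_inner_loops_bias_upward_on_irrelevant_parameter(
        self, single_uncertainty_config
    ):
        """With another parameter still uncertain, a small inner loop
        inflates the EVPPI of even an irrelevant parameter — the known
        upward bias of the nested estimator."""
        res = evppi(
            single_uncertainty_config, ["cost:management"], 3400.0, outer=30, inner=4, seed=3
        )
        big = evppi(
            single_uncertainty_config, ["cost:management"], 3400.0, outer=30, inner=64, seed=3
        )
        assert res.per_patient >= 0.0
        assert big.per_patient <= res.per_patient

    def test_evppi_bounded_by_evpi_on_toy_model(self, single_uncertainty_config):
        cfg = single_uncertainty_config
        wtp = 3400.0
        psa = run_psa(cfg, n_iter=4000, seed=20)
        total = evpi(psa, wtp)
        res = evppi(cfg, ["drug_cost:drug"], wtp, outer=200, inner=2, seed=21)
        assert 0.0 <= res.per_patient <= total + 4 * (res.mc_se or 0.0) + 0.05 * total

    def test_unknown_parameter_name_lists_valid_names(self, medium_config):
        with pytest.raises(KeyError, match="valid names"):
            evppi(medium_config, ["not_a_parameter"], 15000, outer=1, inner=1, seed=0)

    def test_standard_groups_reference_real_parameters(self, medium_config):
        from htncea.psa import parameter_names

        valid = set(parameter_names(medium_config))
        groups = standard_parameter_groups(medium_config, drug="thiazide")
        assert len(groups) == 10
        for members in groups.values():
            assert set(members) <= valid
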