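"""Parameter model: validation, serialization, lookups and cost utilities."""

import math

import pytest

from htncea import (
    ConfigError,
    annualize_risk,
    inflate_cost,
    load_config,
    lookup_annual_risk,
    ppp_convert,
    reference_config,
    save_config,
)
from htncea.parameters import validate_config


class TestRoundTrip:
    @pytest.mark.parametrize("stratum", ["low", "medium", "high"])
    def test_reference_config_round_trips(self, stratum):
        cfg = reference_config(stratum)
        assert load_config(save_config(cfg)) == cfg

    def test_round_trip_through_file(self, tmp_path, medium_config):
        path = tmp_path / "cfg.yaml"
        save_config(medium_config, str(path))
        assert load_config(str(path)) == medium_config


class TestValidation:
    def test_out_of_range_probability_is_reported_with_location(self, medium_config):
        import yaml

        data = medium_config.model_dump()
        for e in data["risk_table"]["entries"]:
            if e["event"] == "stroke" and e["bp"] == "high_bp" and e["age"] == 40:
                e["probability"]["mean"] = 1.2
        with pytest.raises(ConfigError) as exc:
            load_config(yaml.safe_dump(data))
        assert any("1.2" in e and "stroke" in e for e in exc.value.errors)

    def test_missing_null_strategy_rejected(self, medium_config):
        data = medium_config.model_dump()
        data["strategies"] = [s for s in data["strategies"] if s["name"] != "null"]
        import yaml

        errors = validate_config(yaml.safe_dump(data))
        assert any("null strategy required" in e for e in errors)

    def test_non_monotone_risk_table_rejected(self, medium_config):
        data = medium_config.model_dump()
        for e in data["risk_table"]["entries"]:
            if e["event"] == "chd" and e["bp"] == "high_bp" and e["age"] == 70:
                e["probability"]["mean"] = 0.0001
        import yaml

        errors = validate_config(yaml.safe_dump(data))
        assert any("decreases" in e for e in errors)

    def test_valid_document_has_no_errors(self, medium_config):
        assert validate_config(save_config(medium_config)) == []


class TestReferenceValues:
    """Spot checks of the bundled study parameter set."""

    def test_risk_table_values(self):
        med = reference_config("medium")
        assert med.risk_table.value(40, "stroke", "high_bp") == 0.0105
        high = reference_config("high")
        assert high.risk_table.value(70, "chd", "high_bp") == 0.0530
        low = reference_config("low")
        assert low.risk_table.value(40, "chd", "high_bp") == 0.0010

    def test_life_table_values(self, medium_config):
        assert medium_config.life_table.rate(60) == 0.03287
        assert medium_config.life_table.rate(44) == 0.01372

    def test_life_table_strictly_increasing(self, medium_config):
        rates = [
            medium_config.life_table.rate(b) for b in medium_config.life_table.bands
        ]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_thiazide_specifications(self, medium_config):
        thi = medium_config.strategy("thiazide")
        assert (thi.rr_stroke.mean, thi.rr_stroke.se) == (0.63, 0.056)
        cost = medium_config.costs.annual_drug_cost["thiazide"]
        assert (cost.minimum, cost.mode, cost.maximum) == (71.75, 89.69, 107.63)

    def test_utility_and_case_fatality_means(self, medium_config):
        u = medium_config.utilities.well
        assert (u.alpha, u.beta) == (206.1, 155.1)
        assert medium_config.case_fatality.stroke.point() == pytest.approx(0.27)
        assert medium_config.case_fatality.chd.point() == pytest.approx(0.51)


class TestLookup:
    def test_step_function_within_band(self, medium_config):
        assert lookup_annual_risk(medium_config.risk_table, 43, "stroke") == 0.0105

    def test_band_boundary_belongs_to_new_band(self, medium_config):
        assert lookup_annual_risk(medium_config.risk_table, 45, "stroke") == 0.0150

    def test_carry_forward_beyond_last_band(self, medium_config):
        assert lookup_annual_risk(medium_config.risk_table, 85, "stroke") == 0.0922

    def test_age_below_first_band_errors(self, medium_config):
        with pytest.raises(ValueError, match="below first band"):
            lookup_annual_risk(medium_config.risk_table, 35, "stroke")


class TestCostUtilities:
    @pytest.mark.parametrize(
        "amount,rate,years,expected",
        [(100, 0.0, 5, 100.0), (0, 0.03, 5, 0.0), (100, 0.03, 5, 100 * 1.03**5)],
    )
    def test_inflate_cost(self, amount, rate, years, expected):
        assert inflate_cost(amount, rate, years) == pytest.approx(expected, abs=1e-9)

    def test_inflate_cost_composes(self):
        once = inflate_cost(inflate_cost(250.0, 0.03, 2), 0.03, 3)
        assert once == pytest.approx(inflate_cost(250.0, 0.03, 5), abs=1e-9)

    def test_inflate_cost_rejects_negative_amount(self):
        with pytest.raises(ValueError):
            inflate_cost(-1.0, 0.03, 1)

    @pytest.mark.parametrize(
        "price,ppp,fx,expected", [(10, 150, 150, 10.0), (10, 100, 150, 10 * 100 / 150), (0, 100, 150, 0.0)]
    )
    def test_ppp_convert(self, price, ppp, fx, expected):
        assert ppp_convert(price, ppp, fx) == pytest.approx(expected)

    def test_ppp_convert_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            ppp_convert(10, 0, 150)

    @pytest.mark.parametrize("p,h,expected", [(0.0, 10, 0.0), (1.0, 10, 1.0)])
    def test_annualize_risk_edges(self, p, h, expected):
        assert annualize_risk(p, h) == expected

    def test_annualize_risk_inverts_exactly(self):
        p = 0.15
        annual = annualize_risk(p, 10)
        assert annual == pytest.approx(1 - (1 - 0.15) ** 0.1)
        assert 1 - (1 - annual) ** 10 == pytest.approx(p, abs=1e-12)

    def test_annualize_risk_monotone_and_bounded(self):
        ps = [i / 20 for i in range(21)]
        vals = [annualize_risk(p, 10) for p in ps]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v <= p for v, p in zip(vals, ps))

    def test_annualize_risk_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            annualize_risk(1.5, 10)


def test_export_tables_writes_three_csvs(tmp_path, medium_config):
    from htncea.parameters import export_tables

    paths = export_tables(medium_config, str(tmp_path))
    names = {p.split("/")[-1] for p in paths}
    assert names == {"risk_table.csv", "life_table.csv", "distributions.csv"}
    import pandas as pd

    risk = pd.read_csv(tmp_path / "risk_table.csv")
    assert len(risk) == 7 * 2 * 2
    assert math.isclose(
        risk.query("age_band == 40 and event == 'stroke' and bp_status == 'high_bp'")[
            "annual_probability"
        ].iloc[0],
        0.0105,
    )
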