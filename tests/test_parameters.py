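"""Parameter schema: unit-cost arithmetic, file I/O, validation reporting."""

import math

import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from psilocea import (
    ParameterSet,
    load_parameters,
    save_parameters,
    therapist_unit_cost,
    validate,
)
from psilocea.parameters import ParameterFormatError, ParameterValidationError


@pytest.mark.parametrize(
    "base_rate, minutes, expected",
    [
        (58, 30, 87),  # Band 7 psychologist with half an hour non-direct time
        (58, 0, 58),
        (100, 15, 125),
    ],
)
def test_therapist_unit_cost(base_rate, minutes, expected):
    assert therapist_unit_cost(base_rate, minutes) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [(-1, 30), (58, -5)])
def test_therapist_unit_cost_rejects_negative(bad):
    with pytest.raises(ValueError):
        therapist_unit_cost(*bad)


@settings(derandomize=True, max_examples=50)
@given(
    r1=st.floats(0, 500),
    r2=st.floats(0, 500),
    m=st.floats(0, 120),
)
def test_therapist_unit_cost_linear_in_base_rate(r1, r2, m):
    combined = therapist_unit_cost(r1 + r2, m)
    assert combined == pytest.approx(
        therapist_unit_cost(r1, m) + therapist_unit_cost(r2, m), abs=1e-9
    )


@settings(derandomize=True, max_examples=50)
@given(r=st.floats(0, 500), m1=st.floats(0, 120), m2=st.floats(0, 120))
def test_therapist_unit_cost_linear_in_minutes(r, m1, m2):
    lhs = therapist_unit_cost(r, m1 + m2)
    rhs = therapist_unit_cost(r, m1) + therapist_unit_cost(r, m2) - therapist_unit_cost(r, 0)
    assert lhs == pytest.approx(rhs, abs=1e-6)


def _fixture_dict(base_params):
    return base_params.model_dump(mode="json", exclude_none=True)


def test_load_applies_fixed_defaults(base_params, tmp_path):
    """Omitting body-text-fixed fields fills them in (CBT course GBP 1050)."""
    data = _fixture_dict(base_params)
    del data["costs"]["cbt_course_cost"]
    del data["analysis"]
    del data["horizon"]
    path = tmp_path / "p.yaml"
    path.write_text(yaml.safe_dump(data))
    loaded = load_parameters(path)
    assert loaded.costs.cbt_course_cost == 1050
    assert loaded.analysis.societal_multiplier == 2
    assert loaded.horizon.acute_weeks == 6 and loaded.horizon.followup_weeks == 20
    assert loaded.analysis.price_grid[0] == 400 and loaded.analysis.price_grid[-1] == 2000


def test_load_rejects_out_of_range_probability(base_params, tmp_path):
    data = _fixture_dict(base_params)
    data["ssri"]["completer"] = {
        "p_remission": 1.2,
        "p_response": -0.2,
        "p_no_response": 0.0,
    }
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump(data))
    with pytest.raises(ParameterValidationError) as exc:
        load_parameters(path)
    assert "p_remission" in str(exc.value)


def test_load_rejects_unnormalised_distribution(base_params, tmp_path):
    data = _fixture_dict(base_params)
    data["pap"]["completer"] = {
        "p_remission": 0.5,
        "p_response": 0.3,
        "p_no_response": 0.1,
    }
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump(data))
    with pytest.raises(ParameterValidationError) as exc:
        load_parameters(path)
    assert "sum" in str(exc.value)


def test_load_reports_every_violation_at_once(base_params, tmp_path):
    data = _fixture_dict(base_params)
    data["pap"]["p_relapse"] = 1.5
    data["analysis"]["societal_multiplier"] = -1
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump(data))
    with pytest.raises(ParameterValidationError) as exc:
        load_parameters(path)
    failed = {c.name for c in exc.value.report.failures}
    assert "pap.p_relapse.range" in failed
    assert "analysis.societal_multiplier.nonneg" in failed


def test_format_error_names_offending_key(tmp_path):
    path = tmp_path / "garbled.yaml"
    path.write_text(yaml.safe_dump({"pap": {"p_complete": "many"}}))
    with pytest.raises(ParameterFormatError) as exc:
        load_parameters(path)
    assert "p_complete" in str(exc.value)


def test_round_trip(base_params, tmp_path):
    """write(load(x)) == load(write(x)) for a valid parameter set."""
    p1 = tmp_path / "a.yaml"
    save_parameters(base_params, p1)
    once = load_parameters(p1)
    p2 = tmp_path / "b.yaml"
    save_parameters(once, p2)
    twice = load_parameters(p2)
    assert once == twice == base_params
    assert p1.read_text() == p2.read_text()


def test_validate_resolves_derived_arms(params):
    """An RR that pushes a derived probability above 1 fails validation."""
    params.combo.rr.rr_remission = 4.0  # 4.0 * 0.28 = 1.12 > 1
    report = validate(params)
    assert not report.ok
    assert any("combo" in c.name for c in report.failures)


def test_validate_warns_on_utility_disorder(params):
    params.utilities.u_response = params.utilities.u_remission + 0.05
    with pytest.warns(UserWarning, match="u_remission"):
        report = validate(params)
    assert report.ok  # ordering is a warning, not an error
    assert report.warnings


def test_validated_distributions_sum_to_one(base_params):
    for arm in (base_params.pap, base_params.ssri):
        assert math.fsum(arm.completer.as_tuple()) == pytest.approx(1, abs=1e-9)
        assert math.fsum(arm.dropout.as_tuple()) == pytest.approx(1, abs=1e-9)


def test_fixture_body_text_values(base_params):
    """Fields fixed in the source's body text are present verbatim."""
    assert base_params.combo.rr.rr_dropout == 0.79
    assert base_params.combo.rr.rr_response == 0.86
    assert base_params.combo.rr.rr_remission == 1.27
    assert base_params.cbt.rr.rr_dropout == 0.62
    assert base_params.cbt.rr.rr_response == 0.97
    assert base_params.cbt.rr.rr_remission == 1.11
    assert base_params.pap.completer.p_remission == 0.57
    # 48% SSRI response = remission 0.28 + response-without-remission 0.20
    assert base_params.ssri.completer.p_remission + base_params.ssri.completer.p_response == pytest.approx(0.48)
    assert base_params.costs.therapist_hours * base_params.costs.therapist_unit_cost_value == pytest.approx(38 * 87)
    assert validate(base_params).ok
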