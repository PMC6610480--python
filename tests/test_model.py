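"""Service-model layer: rate derivations, funnel, resources, pathways."""

import numpy as np
import pytest

from ecr_des.engine import Engine, RngBank, arrival_times
from ecr_des.errors import ConfigurationError, ConfigValidationError
from ecr_des.model import (
    DEFAULT_ANNUAL_COUNTS,
    DEFAULT_PRIORITIES,
    DurationSpec,
    ECRModel,
    ModelParams,
    SUITE,
    SamplerBank,
    build_angio_pathway,
    build_stroke_pathway,
    default_resources,
    derive_branch_probs,
    derive_interarrival,
    execute_pathway,
    interarrival_report,
)


# ---------------------------------------------------------------------------
# Table-derived rates and probabilities
# ---------------------------------------------------------------------------

class TestInterarrival:
    @pytest.mark.parametrize(
        "annual,expected",
        [(3805, 138), (58, 9062), (525_600, 1), (468, 1123), (104, 5054), (750, 701)],
    )
    def test_reporting_view_matches_annual_counts(self, annual, expected):
        assert interarrival_report(annual) == expected

    def test_exact_real_used_internally(self):
        assert derive_interarrival(750) == pytest.approx(700.8)

    @pytest.mark.parametrize("bad", [0, -3, None])
    def test_nonpositive_count_rejected(self, bad):
        with pytest.raises(ConfigValidationError):
            derive_interarrival(bad)


class TestBranchProbs:
    def test_defaults_are_count_ratios(self):
        probs = derive_branch_probs(DEFAULT_ANNUAL_COUNTS)
        assert probs["suspected"] == pytest.approx(750 / 107_700)
        assert probs["ais"] == pytest.approx(0.600)
        assert probs["ecr"] == pytest.approx(58 / 450, abs=1e-4)
        assert probs["ecr"] == pytest.approx(0.1289, abs=1e-4)

    def test_degenerate_funnel(self):
        counts = dict(DEFAULT_ANNUAL_COUNTS, ecr=450)
        assert derive_branch_probs(counts)["ecr"] == 1.0

    def test_non_nested_counts_rejected(self):
        counts = dict(DEFAULT_ANNUAL_COUNTS, ais=900)  # AIS > suspected stroke
        with pytest.raises(ConfigValidationError):
            derive_branch_probs(counts)

    def test_funnel_expectation_is_ecr_count(self):
        # ED rate x P(suspected) x P(AIS|susp) x P(ECR|AIS) == ECR annual count
        assert ModelParams().expected_ecr_per_year() == pytest.approx(58.0)


# ---------------------------------------------------------------------------
# arrivals
# ---------------------------------------------------------------------------

class TestArrivals:
    def test_poisson_counts_match_rate(self):
        horizon = 525_600.0
        ia = derive_interarrival(3805)
        counts = [
            arrival_times(RngBank(s).rng("arr:elective_ir"), ia, horizon).size
            for s in range(10)
        ]
        se = np.sqrt(3805 / len(counts))
        assert abs(np.mean(counts) - 3805) < 3 * se

    def test_times_strictly_increasing_and_truncated(self):
        t = arrival_times(np.random.default_rng(0), 30.0, 10_000.0)
        assert (np.diff(t) > 0).all()
        assert t[-1] < 10_000.0

    def test_demand_multiplier_scales_all_streams_linearly(self):
        p2 = ModelParams(demand_multiplier=2.0, demand_mode="all")
        assert p2.interarrival("elective_ir") == pytest.approx(derive_interarrival(3805) / 2)
        assert p2.interarrival("ed") == pytest.approx(derive_interarrival(107_700) / 2)

    def test_funnel_mode_scales_branch_not_ed(self):
        p2 = ModelParams(demand_multiplier=2.0, demand_mode="funnel")
        base = ModelParams()
        assert p2.interarrival("ed") == base.interarrival("ed")
        assert p2.branch_probs()["suspected"] == pytest.approx(
            2 * base.branch_probs()["suspected"]
        )
        assert p2.expected_ecr_per_year() == pytest.approx(116.0)

    def test_overlarge_multiplier_rejected_when_prob_exceeds_one(self):
        with pytest.raises(ConfigValidationError):
            ModelParams(demand_multiplier=10.0, demand_mode="ecr")


class TestDurationSpec:
    @pytest.mark.parametrize("dist", ["fixed", "exponential", "lognormal"])
    def test_sample_mean_close(self, dist):
        spec = DurationSpec(dist, 60.0, 0.5)
        x = spec.sample(np.random.default_rng(1), 40_000)
        assert (x > 0).all()
        assert x.mean() == pytest.approx(60.0, rel=0.03)

    def test_lognormal_cv(self):
        x = DurationSpec("lognormal", 100.0, 0.5).sample(np.random.default_rng(2), 200_000)
        assert x.std() / x.mean() == pytest.approx(0.5, rel=0.03)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            DurationSpec("weibull", 10.0)
        with pytest.raises(ConfigurationError):
            DurationSpec("fixed", -1.0)


# ---------------------------------------------------------------------------
# resources
# ---------------------------------------------------------------------------

class TestDefaultResources:
    def test_shift_capacities(self):
        res = {r.name: r for r in default_resources()}
        assert res["ir"].schedule.capacity_at(9 * 60) == 2
        assert res["ir"].schedule.capacity_at(2 * 60) == 1
        assert res["angio_staff"].schedule.capacity_at(2 * 60) == 3
        assert res["angio_staff"].schedule.capacity_at(12 * 60) == 6
        for t in (0, 600, 1200):
            assert res["ct"].schedule.capacity_at(t) == 2
            assert res["inr"].schedule.capacity_at(t) == 1
        assert res["ed_team"].schedule.capacity_at(300) == 10
        assert res["stroke_team"].schedule.capacity_at(300) == 1

    def test_eligibility_baseline(self):
        res = {r.name: r for r in default_resources()}
        assert res["angio_inr"].eligible_classes == {
            "stroke", "elective_inr", "emergency_ir", "elective_ir"
        }
        assert res["angio_ir"].eligible_classes == {"emergency_ir", "elective_ir"}
        assert "stroke" not in res["angio_ir"].eligible_classes

    def test_priority_ordering(self):
        p = DEFAULT_PRIORITIES
        assert p["stroke"] < p["emergency_ir"] < p["elective_inr"]
        assert p["emergency_ir"] < p["elective_ir"]


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

class TestPathways:
    def test_stroke_pathway_structure(self):
        steps = build_stroke_pathway(ModelParams(), default_resources())
        kinds = [s.kind for s in steps]
        assert kinds[0] == "seize" and kinds[-1] == "exit"
        bundle = [s for s in steps if s.kind == "seize" and len(s.resources) == 3]
        assert len(bundle) == 1
        assert dict(bundle[0].resources) == {SUITE: 1, "inr": 1, "angio_staff": 1}
        assert not bundle[0].gated  # stroke is never gated to work hours
        assert kinds.count("branch") == 3

    def test_elective_inr_routes_only_to_angio_inr(self):
        steps = build_angio_pathway("elective_inr", default_resources())
        route = [s for s in steps if s.kind == "route"][0]
        assert route.candidates == ("angio_inr",)
        bundle = [s for s in steps if s.kind == "seize" and len(s.resources) == 3][0]
        assert bundle.gated
        assert ("inr", 1) in bundle.resources

    def test_emergency_ir_may_use_both_suites_ungated(self):
        steps = build_angio_pathway("emergency_ir", default_resources())
        route = [s for s in steps if s.kind == "route"][0]
        assert route.candidates == ("angio_inr", "angio_ir")
        bundle = [s for s in steps if s.kind == "seize" and len(s.resources) == 3][0]
        assert not bundle.gated
        assert ("ir", 1) in bundle.resources

    def test_missing_resource_is_configuration_error(self):
        res = [r for r in default_resources() if r.name != "ct"]
        with pytest.raises(ConfigurationError, match="ct"):
            build_stroke_pathway(ModelParams(), res)

    def test_uncontended_stroke_patient_total_time_is_sum_of_services(self):
        """With fixed durations, certain branches and an empty system, the
        patient's time in system is exactly the sum of service durations."""
        fixed = {
            k: DurationSpec("fixed", m)
            for k, m in [("ed_triage", 15), ("stroke_assessment", 20),
                         ("ct_scan", 20), ("ecr_procedure", 120)]
        }
        params = ModelParams(durations=fixed,
                             branch_overrides={"suspected": 1.0, "ais": 1.0, "ecr": 1.0})
        res = default_resources()
        steps = build_stroke_pathway(params, res)
        eng = Engine(res, horizon=10_000.0)
        ctx = SamplerBank(RngBank(0), fixed, params.branch_probs())

        def factory(entity):
            return execute_pathway(entity, steps, ctx, DEFAULT_PRIORITIES)

        eng.schedule_arrival(480.0, "ed_other", factory, "ed")  # during work hours
        eng.run_until()
        log = eng.finish()
        exit_t = [t for (t, _, _, _, a, _, _) in log.records if a == "exit"][0]
        assert exit_t == pytest.approx(480.0 + 15 + 20 + 20 + 120)
        # and the patient was relabelled stroke after triage
        classes = {cls for (_, _, cls, _, _, _, _) in log.records}
        assert {"ed_other", "stroke"} <= classes

    def test_funnel_exit_leaves_no_downstream_records(self):
        params = ModelParams(branch_overrides={"suspected": 0.0})
        res = default_resources()
        steps = build_stroke_pathway(params, res)
        eng = Engine(res, horizon=10_000.0)
        ctx = SamplerBank(RngBank(0), dict(params.durations), params.branch_probs())
        eng.schedule_arrival(0.0, "ed_other", lambda e: execute_pathway(
            e, steps, ctx, DEFAULT_PRIORITIES), "ed")
        eng.run_until()
        log = eng.finish()
        resources_touched = {r for (_, _, _, r, _, _, _) in log.records if r}
        assert resources_touched == {"ed_team"}


# ---------------------------------------------------------------------------
# end-to-end funnel expectation (small, fast configuration)
# ---------------------------------------------------------------------------

def test_ecr_cases_emerge_at_funnel_rate():
    """Without the heavy ED background, completed ECR cases per simulated year
    match the funnel expectation of 58 within Monte-Carlo error."""
    model = ECRModel(params=ModelParams(background_ed=False))
    counts = []
    for seed in range(8):
        log = model.simulate(525_600.0, seed)
        treated = {eid for (_, eid, cls, res, a, _, _) in log.records
                   if cls == "stroke" and res == "angio_inr" and a == "seize"}
        counts.append(len(treated - set(log.incomplete_ids)))
    se = np.sqrt(58 / len(counts))
    assert abs(np.mean(counts) - 58) < 3 * se


def test_baseline_stroke_and_elective_inr_never_use_angio_ir():
    model = ECRModel(params=ModelParams(background_ed=False))
    for seed in (0, 1):
        log = model.simulate(100_000.0, seed)
        for (_, _, cls, res, _, _, _) in log.records:
            if res == "angio_ir":
                assert cls in ("emergency_ir", "elective_ir")
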