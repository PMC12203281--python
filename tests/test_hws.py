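"""Decision engine: normalization, rule firing, plan invariants,
explanations."""

import dataclasses
import hashlib
import json
import logging

import pytest
from hypothesis import given, settings, strategies as st

from hichkit import emr_synth as es
from hichkit import hkg, hws


def mkstate(make_profile, **kw):
    return hws.profile_to_state(make_profile(**kw))


class TestRulesetLoading:
    def test_default_ruleset_validates(self, ruleset):
        assert ruleset.version == "R0"
        assert all(r.weight >= 0 for r in ruleset.rules)
        assert set(ruleset.branches.values()) <= set(hws.BRANCHES)

    def test_every_rule_consequent_is_traceable_in_seed_graph(self, ruleset,
                                                              seed_graph):
        """Each rule's asserted items are backed by `indicates` triples, so
        explanation traces are never empty for fired rules."""
        for rule in ruleset.rules:
            trace = hkg.basis_trace(seed_graph, rule.rule_id)
            indicated = {t.object for t, _ in trace if t.predicate == "indicates"}
            assert {i for i, _ in rule.consequents} <= indicated, rule.rule_id

    def test_unknown_field_rejected_at_load(self, tmp_path):
        bad = {"branches": {"repeat-head-ct": "diagnostic"},
               "rules": [{"id": "x", "when": [{"field": "no_field", "op": "=="}],
                          "consequents": ["repeat-head-ct"]}]}
        path = tmp_path / "r.yaml"
        import yaml
        path.write_text(yaml.safe_dump(bad))
        with pytest.raises(hws.RulesetError):
            hws.load_ruleset(path)

    def test_unknown_plan_item_rejected_at_load(self, tmp_path):
        bad = {"branches": {"repeat-head-ct": "diagnostic"},
               "rules": [{"id": "x", "when": [], "consequents": ["leeches"]}]}
        import yaml
        path = tmp_path / "r.yaml"
        path.write_text(yaml.safe_dump(bad))
        with pytest.raises(hws.RulesetError):
            hws.load_ruleset(path)


class TestApplyHws:
    def test_cerebellar_compression_indicates_surgery(self, make_profile,
                                                      ruleset, seed_graph):
        state = mkstate(make_profile, hematoma_location="cerebellar",
                        hematoma_volume=15.0, ventricular_compression=True)
        plan = hws.apply_hws(state, ruleset, seed_graph)
        assert plan.surgical
        rules = {b["rule"] for b in plan.bases["surgical-evacuation"]}
        assert "r-surg-cereb-10" in rules  # the cerebellar volume rule

    def test_mild_case_gets_conservative_plan(self, make_profile, ruleset):
        plan = hws.apply_hws(mkstate(make_profile), ruleset)
        assert not plan.surgical
        assert plan.rescue == {"vital-sign-monitoring", "venous-access"}
        assert plan.drugs == {"antihypertensive"}  # SBP 185 >= 180

    def test_all_missing_state_gets_minimal_safe_plan(self, ruleset, seed_graph):
        plan = hws.apply_hws(hws.PatientState(), ruleset, seed_graph)
        assert plan.diagnostic == {"repeat-head-ct"}
        assert plan.rescue == {"vital-sign-monitoring"}
        assert not plan.surgical and not plan.drugs
        for item in plan.selected_items():
            assert plan.bases[item]

    def test_identical_inputs_hash_identically(self, make_profile, ruleset,
                                               seed_graph):
        state = mkstate(make_profile, gcs_total=7, hematoma_volume=45.0)
        h = [hashlib.sha256(
            hws.apply_hws(state, ruleset, seed_graph).to_json().encode()
        ).hexdigest() for _ in range(3)]
        assert len(set(h)) == 1


class TestSurgicalIndication:
    def test_large_supratentorial_with_shift_indicated(self, make_profile, ruleset):
        state = mkstate(make_profile, hematoma_volume=40.0, gcs_total=9,
                        midline_shift=8.0)
        flag, bases = hws.surgical_indication(state, ruleset)
        assert flag and bases

    def test_brainstem_conservative_default_cites_location_rule(
            self, make_profile, ruleset):
        state = mkstate(make_profile, hematoma_location="brainstem",
                        hematoma_volume=50.0)
        flag, bases = hws.surgical_indication(state, ruleset)
        assert not flag
        assert [b["rule"] for b in bases] == ["r-surg-brainstem"]

    def test_zero_volume_never_indicated_by_volume_rules(self, make_profile,
                                                         ruleset):
        for loc in ("basal-ganglia", "cerebellar", "lobar"):
            state = mkstate(make_profile, hematoma_location=loc,
                            hematoma_volume=0.0)
            assert not hws.surgical_indication(state, ruleset)[0]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), bump=st.floats(0.1, 60.0))
    def test_monotone_in_volume_and_shift(self, seed, bump, ruleset):
        profile = es.sample_profile(seed=seed)
        base = hws.profile_to_state(profile)
        before = hws.surgical_indication(base, ruleset)[0]
        bigger = hws.profile_to_state(dataclasses.replace(
            profile,
            hematoma_volume=round(profile.hematoma_volume + bump, 1),
            midline_shift=round(profile.midline_shift + bump, 1)))
        after = hws.surgical_indication(bigger, ruleset)[0]
        assert after >= before  # raising volume/shift never switches surgery off


class TestRescueTriggers:
    def test_arrest_triggers_cpr_and_monitoring(self, make_profile, ruleset):
        items, _ = hws.rescue_triggers(mkstate(make_profile, airway="arrest"),
                                       ruleset)
        assert "cpr" in items and "vital-sign-monitoring" in items

    def test_coma_with_hypoxemia_full_airway_bundle(self, make_profile, ruleset):
        items, _ = hws.rescue_triggers(
            mkstate(make_profile, gcs_total=6, spo2=88), ruleset)
        assert {"airway-clearance", "tracheal-intubation", "ventilator"} <= items

    def test_hypoxemia_alone_below_ventilator_threshold(self, make_profile,
                                                        ruleset):
        items, _ = hws.rescue_triggers(mkstate(make_profile, spo2=88), ruleset)
        assert "ventilator" not in items  # 0.6 < activation threshold 1.0

    def test_stable_patient_gets_no_airway_items(self, make_profile, ruleset):
        items, _ = hws.rescue_triggers(
            mkstate(make_profile, gcs_total=15, airway="patent", spo2=99),
            ruleset)
        assert not items & {"airway-clearance", "tracheal-intubation",
                            "ventilator", "cpr"}


class TestDiagnosticTriggers:
    def test_anticoagulant_history_orders_coagulation_panel(self, make_profile,
                                                            ruleset):
        items, _ = hws.diagnostic_triggers(
            mkstate(make_profile, history=frozenset({"anticoagulant-use"})),
            ruleset)
        assert "coagulation-panel" in items

    def test_atypical_young_lobar_gets_vascular_workup(self, make_profile,
                                                       ruleset):
        items, _ = hws.diagnostic_triggers(
            mkstate(make_profile, age=25, hematoma_location="lobar",
                    history=frozenset()), ruleset)
        assert {"cta", "multimodal-mri"} <= items
        assert "mra" not in items  # weight 0.5 below the activation threshold

    def test_typical_hypertensive_bleed_only_repeat_ct(self, make_profile,
                                                       ruleset):
        items, _ = hws.diagnostic_triggers(mkstate(make_profile), ruleset)
        assert items == {"repeat-head-ct"}


class TestResolveConflicts:
    def test_intubation_implies_airway_clearance(self):
        plan = hws.TreatmentPlan(
            rescue=frozenset({"tracheal-intubation"}),
            bases={"tracheal-intubation": [{"rule": "x", "text": "", "trace": []}]})
        fixed = hws.resolve_conflicts(plan)
        assert "airway-clearance" in fixed.rescue
        assert fixed.bases["airway-clearance"]

    def test_cpr_implies_monitoring(self):
        plan = hws.TreatmentPlan(
            rescue=frozenset({"cpr"}),
            bases={"cpr": [{"rule": "x", "text": "", "trace": []}]})
        assert "vital-sign-monitoring" in hws.resolve_conflicts(plan).rescue

    def test_idempotent_on_consistent_plan(self, make_profile, ruleset):
        plan = hws.apply_hws(mkstate(make_profile, gcs_total=5), ruleset)
        assert hws.resolve_conflicts(plan) == plan


class TestNormalizeEntities:
    def test_full_mentions_give_fully_explicit_state(self, make_profile,
                                                     seed_graph):
        profile = make_profile(gcs_total=7, hematoma_volume=33.3,
                               midline_shift=6.0, ventricular_compression=True)
        doc = es.render_emr(profile)
        state = hws.normalize_entities(doc.gold_mentions(), seed_graph,
                                       demographics=doc.meta)
        for f in ("gcs_total", "sbp", "spo2", "hematoma_location",
                  "hematoma_volume", "midline_shift", "ventricular_compression",
                  "pupils", "airway", "age", "sex"):
            assert state.fields[f].confidence == "explicit", f
        assert state.get("gcs_total") == 7
        assert state.get("hematoma_volume") == 33.3
        assert state.get("hematoma_location") == "basal-ganglia"

    def test_empty_mentions_give_all_missing_state(self, seed_graph):
        state = hws.normalize_entities([], seed_graph)
        assert all(state.is_missing(f) for f in hws.STATE_FIELDS)

    def test_conflicting_volumes_later_mention_wins(self, seed_graph, caplog):
        mentions = [
            ((0, 4), "VOLUME", ("estimated", "volume", "25", "ml")),
            ((10, 14), "VOLUME", ("estimated", "volume", "30", "ml")),
        ]
        with caplog.at_level(logging.WARNING, logger="hichkit.hws"):
            state = hws.normalize_entities(mentions, seed_graph)
        assert state.get("hematoma_volume") == 30.0
        assert any("conflicting" in r.getMessage() for r in caplog.records)

    def test_unparseable_numeric_recorded_missing_not_crash(self, seed_graph,
                                                            caplog):
        mentions = [((0, 3), "VOLUME", ("volume", "large", "ml"))]
        with caplog.at_level(logging.WARNING, logger="hichkit.hws"):
            state = hws.normalize_entities(mentions, seed_graph)
        assert state.is_missing("hematoma_volume")
        assert any("unparseable" in r.getMessage() for r in caplog.records)

    def test_state_round_trips_profile(self, seed_graph, ruleset):
        """Normalizing a clean rendering reproduces the profile's decisions."""
        for seed in range(40):
            profile = es.sample_profile(seed=seed)
            doc = es.render_emr(profile)
            state = hws.normalize_entities(doc.gold_mentions(), seed_graph,
                                           demographics=doc.meta)
            assert hws.apply_hws(state, ruleset) == \
                hws.apply_hws(hws.profile_to_state(profile), ruleset)


class TestExplain:
    def test_report_names_fired_surgical_rule(self, make_profile, ruleset,
                                              seed_graph):
        state = mkstate(make_profile, hematoma_location="cerebellar",
                        hematoma_volume=15.0, ventricular_compression=True)
        plan = hws.apply_hws(state, ruleset, seed_graph)
        report = hws.explain(plan, ruleset)
        surg = [e for e in report["items"] if e["item"] == "surgical-evacuation"]
        assert surg and any(b["rule"] == "r-surg-cereb-10"
                            for b in surg[0]["bases"])
        md = hws.render_markdown(report)
        assert "r-surg-cereb-10" in md

    def test_empty_branches_render_not_indicated_with_strongest_rule(
            self, ruleset, seed_graph):
        plan = hws.apply_hws(hws.PatientState(), ruleset, seed_graph)
        report = hws.explain(plan, ruleset)
        branches = {ni["branch"] for ni in report["not_indicated"]}
        assert {"surgical", "drug"} <= branches
        assert all(ni["strongest_rule"] for ni in report["not_indicated"])

    def test_report_item_count_equals_selected_count(self, make_profile,
                                                     ruleset):
        plan = hws.apply_hws(mkstate(make_profile, gcs_total=5), ruleset)
        report = hws.explain(plan, ruleset)
        assert len(report["items"]) == len(plan.selected_items())
        md = hws.render_markdown(report)
        for e in report["items"]:
            assert f"## {e['item']}" in md


class TestPlanInvariants:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_explanations_replay_true_on_the_state(self, seed, ruleset):
        state = hws.profile_to_state(es.sample_profile(seed=seed))
        plan = hws.apply_hws(state, ruleset)
        rules = {r.rule_id: r for r in ruleset.rules}
        for item in plan.selected_items():
            assert plan.bases[item]
            for basis in plan.bases[item]:
                if basis["rule"] in rules:
                    assert rules[basis["rule"]].fires(state)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           dropped=st.sampled_from(hws.STATE_FIELDS))
    def test_dropping_any_field_keeps_vital_sign_monitoring(self, seed,
                                                            dropped, ruleset):
        state = hws.profile_to_state(es.sample_profile(seed=seed))
        state.fields[dropped] = hws.FieldValue.missing()
        plan = hws.apply_hws(state, ruleset)
        assert "vital-sign-monitoring" in plan.rescue

    def test_plan_json_round_trip(self, make_profile, ruleset, seed_graph):
        plan = hws.apply_hws(mkstate(make_profile, gcs_total=6), ruleset,
                             seed_graph)
        back = hws.TreatmentPlan.from_dict(json.loads(plan.to_json()))
        assert back == plan
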