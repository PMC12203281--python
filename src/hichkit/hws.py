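"""The HICH weight scoring system: normalization, rules, explainable plans.

Extracted entity mentions are normalized against the knowledge graph into a
canonical :class:`PatientState`; weighted guideline rules then fire over the
state, and a plan item activates when the summed weight of its fired rules
reaches the item's activation threshold.  Every selected item carries a
machine-readable basis — the fired rule, its filled explanation text, and
the knowledge-graph triples backing the rule — which is what makes the
output auditable.

The shipped default ruleset R0 (``data/ruleset_r0.yaml``) is a
reconstruction in the guideline tradition (supratentorial volume >= 30 mL,
cerebellar >= 10 mL or ventricular compression, midline shift >= 5 mm,
GCS <= 8 for airway protection, SBP >= 180 mmHg for antihypertensives);
the full weight table of the original scoring system is unpublished, so R0
is data, editable without code changes.  With its default unit weights the
system behaves as crisp rules; editing weights below 1 makes activation
genuinely cumulative (the ventilator item ships that way).

Missing-data semantics: positive conditions (>=, ==, in, has, present) are
false on a missing field; negated conditions (!=, not-in, not-has) are true
on a missing field, so absence of evidence escalates diagnostics but never
fabricates a positive finding.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field as dc_field, replace
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import yaml

from . import hkg
from .emr_synth import PatientProfile

log = logging.getLogger(__name__)

BRANCHES = ("diagnostic", "surgical", "rescue", "drug")

STATE_FIELDS = (
    "age", "sex", "gcs_total", "sbp", "dbp", "pupils", "airway", "spo2",
    "hematoma_location", "hematoma_volume", "midline_shift",
    "ventricular_compression", "intraventricular_extension",
    "history", "suspicion",
)

SURGICAL_ITEM = "surgical-evacuation"

_NUM_RE = re.compile(r"^\d+(\.\d+)?$")


class RulesetError(ValueError):
    """A rule references an unknown field, op, or plan item."""


# ---------------------------------------------------------------------------
# Patient state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldValue:
    """One normalized finding: value + provenance + confidence."""

    value: object = None
    source: str | None = None        # "structured input" or "tokens i-j: ..."
    entity: str | None = None        # canonical knowledge-graph identifier
    confidence: str = "missing"      # explicit | inferred | missing

    @classmethod
    def missing(cls) -> "FieldValue":
        return cls()


@dataclass
class PatientState:
    """Canonical, KG-aligned findings; the decision engine's input."""

    fields: dict = dc_field(default_factory=dict)
    extras: dict = dc_field(default_factory=dict)  # non-decisive mentions

    def __post_init__(self):
        for f in STATE_FIELDS:
            self.fields.setdefault(f, FieldValue.missing())
        unknown = set(self.fields) - set(STATE_FIELDS)
        if unknown:
            raise ValueError(f"unknown state fields {sorted(unknown)}")

    def get(self, name: str):
        return self.fields[name].value

    def is_missing(self, name: str) -> bool:
        return self.fields[name].confidence == "missing"

    def values(self) -> dict:
        return {f: self.fields[f].value for f in STATE_FIELDS}

    @classmethod
    def from_profile(cls, profile: PatientProfile) -> "PatientState":
        """Fully explicit state taken from structured ground truth."""
        entity_map = {
            "gcs_total": "glasgow-coma-score",
            "hematoma_volume": "hematoma-volume",
            "midline_shift": "midline-shift",
            "ventricular_compression": "ventricular-compression",
            "intraventricular_extension": "intraventricular-extension",
        }
        fields = {}
        for f in STATE_FIELDS:
            v = getattr(profile, f)
            ent = entity_map.get(f)
            if f in ("hematoma_location", "pupils", "airway"):
                ent = v
            fields[f] = FieldValue(v, "structured input", ent, "explicit")
        return cls(fields)


profile_to_state = PatientState.from_profile


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

_POSITIVE_OPS = {">=", "<=", ">", "<", "==", "in", "has", "present"}
_NEGATIVE_OPS = {"!=", "not-in", "not-has"}
_ALL_OPS = _POSITIVE_OPS | _NEGATIVE_OPS | {"missing"}


@dataclass(frozen=True)
class Condition:
    field: str
    op: str
    value: object = None

    def evaluate(self, state: PatientState) -> bool:
        if self.op == "missing":
            return state.is_missing(self.field)
        if state.is_missing(self.field):
            return self.op in _NEGATIVE_OPS
        v = state.get(self.field)
        if self.op == "present":
            return True
        if self.op == ">=":
            return v >= self.value
        if self.op == "<=":
            return v <= self.value
        if self.op == ">":
            return v > self.value
        if self.op == "<":
            return v < self.value
        if self.op == "==":
            return v == self.value
        if self.op == "!=":
            return v != self.value
        if self.op == "in":
            return v in self.value
        if self.op == "not-in":
            return v not in self.value
        if self.op == "has":
            return self.value in v
        if self.op == "not-has":
            return self.value not in v
        raise RulesetError(f"unknown op {self.op!r}")


@dataclass(frozen=True)
class Rule:
    """One weighted guideline rule with an explanation template."""

    rule_id: str
    when: tuple           # conjunction of Conditions; empty = always fires
    weight: float
    consequents: tuple    # of (item, weight) pairs
    tier: str = "subdomain-specific"
    source: str = ""
    basis: str = ""

    def fires(self, state: PatientState) -> bool:
        return all(c.evaluate(state) for c in self.when)

    def fill_basis(self, state: PatientState) -> str:
        vals = {f: ("unknown" if state.is_missing(f) else state.get(f))
                for f in STATE_FIELDS}
        try:
            return self.basis.format(**vals)
        except (KeyError, IndexError):
            return self.basis


@dataclass
class Ruleset:
    version: str
    rules: list
    branches: dict        # item -> branch
    activation: dict      # item -> threshold
    activation_default: float = 1.0

    def threshold(self, item: str) -> float:
        return float(self.activation.get(item, self.activation_default))

    def items_in(self, branch: str) -> list[str]:
        return sorted(i for i, b in self.branches.items() if b == branch)


def _parse_condition(raw: Mapping) -> Condition:
    if set(raw) - {"field", "op", "value"} or "field" not in raw or "op" not in raw:
        raise RulesetError(f"malformed condition {raw!r}")
    if raw["field"] not in STATE_FIELDS:
        raise RulesetError(f"condition references unknown field {raw['field']!r}")
    if raw["op"] not in _ALL_OPS:
        raise RulesetError(f"unknown condition op {raw['op']!r}")
    value = raw.get("value")
    if isinstance(value, list):
        value = tuple(value)
    return Condition(raw["field"], raw["op"], value)


def load_ruleset(path=None) -> Ruleset:
    """Load and validate a YAML ruleset; defaults to the shipped R0."""
    if path is None:
        text = resources.files("hichkit.data").joinpath("ruleset_r0.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    branches = dict(raw["branches"])
    for item, br in branches.items():
        if br not in BRANCHES:
            raise RulesetError(f"item {item!r} maps to unknown branch {br!r}")
    rules = []
    for rr in raw["rules"]:
        weight = float(rr.get("weight", 1.0))
        if weight < 0:
            raise RulesetError(f"rule {rr.get('id')!r} has negative weight")
        cons = []
        for c in rr["consequents"]:
            if isinstance(c, Mapping):
                item, w = c["item"], float(c.get("weight", weight))
            else:
                item, w = c, weight
            if item not in branches:
                raise RulesetError(
                    f"rule {rr.get('id')!r} asserts unknown plan item {item!r}")
            cons.append((item, w))
        rules.append(Rule(
            rule_id=rr["id"],
            when=tuple(_parse_condition(c) for c in rr.get("when", [])),
            weight=weight,
            consequents=tuple(cons),
            tier=rr.get("tier", "subdomain-specific"),
            source=rr.get("source", ""),
            basis=rr.get("basis", ""),
        ))
    if len({r.rule_id for r in rules}) != len(rules):
        raise RulesetError("duplicate rule ids")
    return Ruleset(
        version=str(raw.get("version", "custom")),
        rules=rules,
        branches=branches,
        activation=dict(raw.get("activation", {})),
        activation_default=float(raw.get("activation_default", 1.0)),
    )


# ---------------------------------------------------------------------------
# Treatment plan
# ---------------------------------------------------------------------------


@dataclass
class TreatmentPlan:
    """Four-branch plan; every selected item carries >= 1 basis entry."""

    diagnostic: frozenset = frozenset()
    surgical: bool = False
    rescue: frozenset = frozenset()
    drugs: frozenset = frozenset()
    bases: dict = dc_field(default_factory=dict)   # item -> [basis entries]
    scores: dict = dc_field(default_factory=dict)  # item -> summed fired weight

    def selected_items(self) -> set:
        out = set(self.diagnostic) | set(self.rescue) | set(self.drugs)
        if self.surgical:
            out.add(SURGICAL_ITEM)
        return out

    def to_dict(self) -> dict:
        return {
            "diagnostic": sorted(self.diagnostic),
            "surgical": self.surgical,
            "rescue": sorted(self.rescue),
            "drugs": sorted(self.drugs),
            "bases": {k: self.bases[k] for k in sorted(self.bases)},
            "scores": {k: self.scores[k] for k in sorted(self.scores)},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TreatmentPlan":
        return cls(frozenset(d["diagnostic"]), bool(d["surgical"]),
                   frozenset(d["rescue"]), frozenset(d["drugs"]),
                   dict(d.get("bases", {})), dict(d.get("scores", {})))

    def __eq__(self, other) -> bool:
        return isinstance(other, TreatmentPlan) and self.to_dict() == other.to_dict()

    def validate(self) -> "TreatmentPlan":
        for item in self.selected_items():
            if not self.bases.get(item):
                raise ValueError(f"selected item {item!r} has no basis")
        if "tracheal-intubation" in self.rescue and "airway-clearance" not in self.rescue:
            raise ValueError("tracheal intubation requires airway clearance")
        if "cpr" in self.rescue and "vital-sign-monitoring" not in self.rescue:
            raise ValueError("CPR requires vital-sign monitoring")
        return self


_IMPLICATIONS = (
    ("tracheal-intubation", "airway-clearance"),
    ("cpr", "vital-sign-monitoring"),
)


def resolve_conflicts(plan: TreatmentPlan) -> TreatmentPlan:
    """Apply implication closures (idempotent): intubation implies airway
    clearance; CPR implies vital-sign monitoring."""
    rescue = set(plan.rescue)
    bases = {k: list(v) for k, v in plan.bases.items()}
    for antecedent, implied in _IMPLICATIONS:
        if antecedent in rescue and implied not in rescue:
            rescue.add(implied)
            bases.setdefault(implied, []).append({
                "rule": f"implied-by:{antecedent}",
                "text": f"{implied} is implied whenever {antecedent} is selected",
                "trace": [],
            })
    return replace(plan, rescue=frozenset(rescue), bases=bases)


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------


def apply_hws(state: PatientState, ruleset: Ruleset | None = None,
              graph: hkg.KnowledgeGraph | None = None) -> TreatmentPlan:
    """Fire the ruleset over a state and emit the explainable plan.

    An item is selected iff the summed weight of its fired rules reaches the
    item's activation threshold; zero-weight rules still contribute their
    basis (used for conservative-default explanations).  Deterministic.
    """
    ruleset = ruleset or load_ruleset()
    scores: dict[str, float] = {}
    bases: dict[str, list] = {}
    for rule in ruleset.rules:
        if not rule.fires(state):
            continue
        entry = {
            "rule": rule.rule_id,
            "text": rule.fill_basis(state),
            "trace": _trace(graph, rule.rule_id),
        }
        for item, w in rule.consequents:
            scores[item] = scores.get(item, 0.0) + w
            bases.setdefault(item, []).append(entry)
    selected = {i for i, s in scores.items() if s >= ruleset.threshold(i)}
    by_branch: dict[str, set] = {b: set() for b in BRANCHES}
    for item in selected:
        by_branch[ruleset.branches[item]].add(item)
    plan = TreatmentPlan(
        diagnostic=frozenset(by_branch["diagnostic"]),
        surgical=SURGICAL_ITEM in by_branch["surgical"],
        rescue=frozenset(by_branch["rescue"]),
        drugs=frozenset(by_branch["drug"]),
        bases=bases,
        scores=scores,
    )
    return resolve_conflicts(plan).validate()


def _trace(graph: hkg.KnowledgeGraph | None, rule_id: str) -> list[dict]:
    if graph is None:
        return []
    try:
        pairs = hkg.basis_trace(graph, rule_id)
    except LookupError:
        return []
    return [{"subject": t.subject, "predicate": t.predicate, "object": t.object,
             "source": src} for t, src in pairs]


def surgical_indication(state: PatientState, ruleset: Ruleset | None = None,
                        graph: hkg.KnowledgeGraph | None = None
                        ) -> tuple[bool, list]:
    """The surgical branch of :func:`apply_hws`: (indicated?, bases).

    The bases include fired zero-weight rules, so a conservatively managed
    brainstem hemorrhage returns ``(False, [location-rule basis])``.
    """
    plan = apply_hws(state, ruleset, graph)
    return plan.surgical, plan.bases.get(SURGICAL_ITEM, [])


def rescue_triggers(state: PatientState, ruleset: Ruleset | None = None,
                    graph: hkg.KnowledgeGraph | None = None) -> tuple[set, dict]:
    plan = apply_hws(state, ruleset, graph)
    return set(plan.rescue), {i: plan.bases.get(i, []) for i in plan.rescue}


def diagnostic_triggers(state: PatientState, ruleset: Ruleset | None = None,
                        graph: hkg.KnowledgeGraph | None = None) -> tuple[set, dict]:
    plan = apply_hws(state, ruleset, graph)
    return set(plan.diagnostic), {i: plan.bases.get(i, []) for i in plan.diagnostic}


# ---------------------------------------------------------------------------
# Normalization of extracted mentions
# ---------------------------------------------------------------------------


def _numbers(tokens: Sequence[str]) -> list[float]:
    return [float(t) for t in tokens if _NUM_RE.match(t)]


def _span_source(span: tuple, tokens: Sequence[str]) -> str:
    return f"tokens {span[0]}-{span[1]}: {' '.join(tokens)}"


def normalize_entities(mentions: Iterable[tuple],
                       graph: hkg.KnowledgeGraph,
                       matcher: Callable[[str, str], float] = hkg.bigram_dice,
                       demographics: Mapping | None = None,
                       token_normalizer: Callable | None = None) -> PatientState:
    """Turn ``((start, end), entity_type, tokens)`` mentions into a state.

    Mentions are aligned via the knowledge graph's synonym table (falling
    back to the similarity matcher), numeric values are parsed with their
    units, duplicate conflicting values resolve to the later mention in
    document order (logged), and unmentioned fields stay missing.
    Structured demographics (age, sex) enter with source "structured input".
    """
    fields: dict[str, FieldValue] = {}
    extras: dict[str, list] = {}
    flags: dict[str, set] = {"history": set(), "suspicion": set()}
    flag_sources: dict[str, list] = {"history": [], "suspicion": []}

    def put(name: str, value, span, tokens, entity=None, confidence="explicit"):
        fv = FieldValue(value, _span_source(span, tokens), entity, confidence)
        if name in fields and fields[name].value != value:
            log.warning("conflicting %s: %r supersedes %r (later in document)",
                        name, value, fields[name].value)
        fields[name] = fv

    for span, etype, tokens in sorted(mentions, key=lambda m: m[0]):
        toks = [str(t) for t in tokens]
        if token_normalizer is not None:
            toks = list(token_normalizer(toks))
        low = [t.lower() for t in toks]
        surface = " ".join(low)
        nums = _numbers(low)
        if etype == "VOLUME":
            if nums:
                put("hematoma_volume", nums[0], span, toks, "hematoma-volume")
            else:
                log.warning("unparseable volume mention %r; field stays missing", surface)
        elif etype == "MIDLINE-SHIFT":
            if "no" in low:
                put("midline_shift", 0.0, span, toks, "midline-shift")
            elif nums:
                put("midline_shift", nums[0], span, toks, "midline-shift")
            else:
                log.warning("unparseable midline-shift mention %r", surface)
        elif etype == "GCS":
            vals = [int(n) for n in nums if 3 <= n <= 15]
            if vals:
                put("gcs_total", vals[0], span, toks, "glasgow-coma-score")
            else:
                log.warning("unparseable GCS mention %r", surface)
        elif etype == "VITAL-SIGN":
            if "pressure" in low or "bp" in low:
                if len(nums) >= 2:
                    put("sbp", int(nums[0]), span, toks)
                    put("dbp", int(nums[1]), span, toks)
                else:
                    log.warning("unparseable blood-pressure mention %r", surface)
            elif "saturation" in low or "spo2" in low:
                vals = [int(n) for n in nums if 0 <= n <= 100]
                if vals:
                    put("spo2", vals[0], span, toks)
                else:
                    log.warning("unparseable oxygen-saturation mention %r", surface)
            else:
                extras.setdefault("vital-sign", []).append(surface)
        elif etype == "LOCATION":
            core = " ".join(t for t in low if t not in ("left", "right", "the"))
            ent = hkg.align_entity(core, "location", graph, matcher)
            if ent:
                put("hematoma_location", ent, span, toks, ent)
            else:
                log.warning("unalignable location mention %r", surface)
        elif etype == "PUPIL":
            ent = hkg.align_entity(surface, "pupil-state", graph, matcher)
            if ent:
                put("pupils", ent, span, toks, ent)
        elif etype == "AIRWAY":
            ent = hkg.align_entity(surface, "airway-state", graph, matcher)
            if ent:
                put("airway", ent, span, toks, ent)
        elif etype == "VENTRICULAR-COMPRESSION":
            if "intraventricular" in low or "ivh" in low:
                fields["intraventricular_extension"] = FieldValue(
                    True, _span_source(span, toks), "intraventricular-extension",
                    "explicit")
            else:
                value = "no" not in low
                put("ventricular_compression", value, span, toks,
                    "ventricular-compression")
        elif etype == "HISTORY-ITEM":
            ent = hkg.align_entity(surface, "history-item", graph, matcher)
            if ent:
                flags["history"].add(ent)
                flag_sources["history"].append(_span_source(span, toks))
        elif etype == "SUSPICION-ITEM":
            ent = hkg.align_entity(surface, "suspicion-item", graph, matcher)
            if ent:
                flags["suspicion"].add(ent)
                flag_sources["suspicion"].append(_span_source(span, toks))
        else:  # CHIEF-COMPLAINT, NATURE and anything non-decisive
            extras.setdefault(etype.lower(), []).append(surface)

    for name in ("history", "suspicion"):
        if flags[name]:
            fields[name] = FieldValue(frozenset(flags[name]),
                                      "; ".join(flag_sources[name]), None, "explicit")
    if fields.get("intraventricular_extension") and "ventricular_compression" not in fields:
        pass  # compression stays missing unless asserted; extension alone is explicit
    if demographics:
        if "age" in demographics:
            fields["age"] = FieldValue(int(demographics["age"]), "structured input",
                                       None, "explicit")
        if "sex" in demographics:
            fields["sex"] = FieldValue(str(demographics["sex"]), "structured input",
                                       None, "explicit")
    return PatientState(fields, extras)


# ---------------------------------------------------------------------------
# Explanation reports
# ---------------------------------------------------------------------------


def explain(plan: TreatmentPlan, ruleset: Ruleset | None = None) -> dict:
    """Structured report: one entry per selected item, plus explicit
    "not indicated" sections for empty branches showing the strongest rule
    that did not fire there."""
    ruleset = ruleset or load_ruleset()
    items = []
    branch_of = ruleset.branches
    for item in sorted(plan.selected_items()):
        items.append({
            "item": item,
            "branch": branch_of[item],
            "score": plan.scores.get(item, 0.0),
            "bases": plan.bases.get(item, []),
        })
    not_indicated = []
    selected_branches = {e["branch"] for e in items}
    for branch in BRANCHES:
        if branch in selected_branches:
            continue
        cands = [r for r in ruleset.rules
                 if any(branch_of[i] == branch for i, _ in r.consequents)]
        strongest = max(cands, key=lambda r: (r.weight, r.rule_id), default=None)
        not_indicated.append({
            "branch": branch,
            "strongest_rule": strongest.rule_id if strongest else None,
            "note": "not indicated: no rule reached the activation threshold",
        })
    return {"items": items, "not_indicated": not_indicated}


def render_markdown(report: Mapping) -> str:
    """Human-readable rendering; agrees with the JSON report item-for-item."""
    lines = ["# Treatment plan", ""]
    for entry in report["items"]:
        lines.append(f"## {entry['item']} ({entry['branch']}, score {entry['score']:g})")
        for b in entry["bases"]:
            lines.append(f"- [{b['rule']}] {b['text']}")
            for t in b.get("trace", []):
                lines.append(f"  - {t['subject']} {t['predicate']} {t['object']}"
                             f" ({t['source']})")
        lines.append("")
    for ni in report.get("not_indicated", []):
        lines.append(f"## {ni['branch']}: not indicated")
        if ni["strongest_rule"]:
            lines.append(f"- strongest non-fired rule: {ni['strongest_rule']}")
        lines.append("")
    return "\n".join(lines)
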