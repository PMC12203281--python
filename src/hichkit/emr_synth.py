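"""Seeded synthetic HICH electronic medical records.

Every downstream stage (entity extraction, normalization, decision rules,
evaluation) is exercised against corpora produced here, so no clinical data
download is needed.  A :class:`PatientProfile` is sampled from a prevalence
configuration, rendered into an English EMR-like note with token-aligned BIO
entity tags, and optionally corrupted with misspellings and abbreviations
that the preprocessor is able to undo exactly.

The note language is English with whitespace/punctuation tokenization; the
12-type entity inventory covers the two annotation categories of the target
corpus: clinical and CT manifestations (chief complaint, vital signs, coma
score, pupils, airway, hematoma location and nature, history and suspicion
items) and quantitative hematoma parameters (volume, midline shift,
ventricular involvement).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ENTITY_TYPES",
    "PatientProfile",
    "AnnotatedDocument",
    "CorruptionConfig",
    "ConfigurationError",
    "TemplateError",
    "ParseError",
    "DEFAULT_PREVALENCE",
    "DEFAULT_TEMPLATE_BANK",
    "DEFAULT_LEXICON",
    "ABBREVIATIONS",
    "sample_profile",
    "render_emr",
    "preprocess",
    "tokenize",
    "write_conll",
    "read_conll",
    "generate_corpus",
]


class ConfigurationError(ValueError):
    """A prevalence distribution has invalid support."""


class TemplateError(ValueError):
    """A template references a field with no verbalizer."""


class ParseError(ValueError):
    """A corpus file is malformed; the message names the offending line."""


ENTITY_TYPES = (
    "CHIEF-COMPLAINT", "VITAL-SIGN", "GCS", "PUPIL", "AIRWAY", "LOCATION",
    "NATURE", "VOLUME", "MIDLINE-SHIFT", "VENTRICULAR-COMPRESSION",
    "HISTORY-ITEM", "SUSPICION-ITEM",
)

LOCATIONS = ("basal-ganglia", "thalamus", "lobar", "cerebellar", "brainstem")
PUPIL_STATES = ("bilateral-equal-reactive", "unilateral-dilated", "bilateral-dilated-fixed")
AIRWAY_STATES = ("patent", "obstructed", "arrest")
HISTORY_FLAGS = ("hypertension", "anticoagulant-use", "hemophilia", "hemodialysis")
SUSPICION_FLAGS = ("vascular-lesion", "tumor")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientProfile:
    """Structured ground-truth clinical state a synthetic note renders.

    Units: age in years, blood pressures in mmHg, SpO2 in percent, hematoma
    volume in mL, midline shift in mm.  GCS is the 3-15 Glasgow Coma Score.
    """

    age: int
    sex: str
    gcs_total: int
    sbp: int
    dbp: int
    pupils: str
    airway: str
    spo2: int
    hematoma_location: str
    hematoma_volume: float
    midline_shift: float
    ventricular_compression: bool
    intraventricular_extension: bool
    history: frozenset = frozenset()
    suspicion: frozenset = frozenset()

    def validate(self) -> "PatientProfile":
        if not (3 <= self.gcs_total <= 15):
            raise ValueError("gcs_total must lie in [3, 15]")
        if not (10 <= self.age <= 80):
            raise ValueError("age must lie in [10, 80] (study inclusion range)")
        if self.hematoma_volume < 0 or self.midline_shift < 0:
            raise ValueError("hematoma volume and midline shift must be >= 0")
        if not (0 <= self.spo2 <= 100):
            raise ValueError("spo2 must lie in [0, 100]")
        if self.hematoma_location not in LOCATIONS:
            raise ValueError(f"unknown hematoma location {self.hematoma_location!r}")
        if self.pupils not in PUPIL_STATES or self.airway not in AIRWAY_STATES:
            raise ValueError("unknown pupil or airway category")
        if not set(self.history) <= set(HISTORY_FLAGS):
            raise ValueError("unknown history flag")
        if not set(self.suspicion) <= set(SUSPICION_FLAGS):
            raise ValueError("unknown suspicion flag")
        return self


@dataclass
class AnnotatedDocument:
    """A tokenized note with BIO tags; the NER train/test unit."""

    doc_id: str
    text: str
    tokens: list
    tags: list
    profile_ref: str | None = None
    meta: dict = field(default_factory=dict)  # structured demographics (age, sex)

    def validate(self, tag_alphabet: Iterable[str] | None = None) -> "AnnotatedDocument":
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags must have equal length")
        alphabet = set(tag_alphabet) if tag_alphabet is not None else None
        prev = "O"
        for tag in self.tags:
            if alphabet is not None and tag not in alphabet:
                raise ValueError(f"tag {tag!r} outside the configured alphabet")
            if tag.startswith("I-"):
                if not (prev.startswith(("B-", "I-")) and prev[2:] == tag[2:]):
                    raise ValueError(f"dangling I- tag {tag!r}")
            prev = tag
        return self

    def gold_mentions(self) -> list[tuple[tuple[int, int], str, tuple]]:
        """((start, end), type, span tokens) for every tagged entity."""
        from .ner import spans_from_bio
        out = []
        for (s, e), etype in spans_from_bio(self.tags):
            out.append(((s, e), etype, tuple(self.tokens[s:e])))
        return out


@dataclass(frozen=True)
class CorruptionConfig:
    """Noise the synthesizer injects and the preprocessor must undo."""

    misspell_rate: float = 0.0
    abbreviation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.misspell_rate <= 1 and 0 <= self.abbreviation_rate <= 1):
            raise ValueError("corruption rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Profile sampling
# ---------------------------------------------------------------------------

# Distribution specs: {"point": v} | {"choice": {v: p}} | {"uniform_int": [lo, hi]}
# | {"normal_int": [mu, sd, lo, hi]} | {"lognormal": [mu, sd, lo, hi, decimals]}
# | {"mixture": [[w, spec], ...]} | {"flags": {flag: p}}
# | {"zero_inflated": [p_zero, spec]}

DEFAULT_PREVALENCE: dict = {
    "age": {"mixture": [[0.15, {"uniform_int": [10, 44]}],
                        [0.85, {"uniform_int": [45, 80]}]]},
    "sex": {"choice": {"male": 0.6, "female": 0.4}},
    "gcs_total": {"mixture": [[0.25, {"uniform_int": [3, 8]}],
                              [0.35, {"uniform_int": [9, 12]}],
                              [0.40, {"uniform_int": [13, 15]}]]},
    "sbp": {"normal_int": [175, 25, 100, 250]},
    "dbp": {"normal_int": [100, 15, 60, 150]},
    "pupils": {"choice": {"bilateral-equal-reactive": 0.85,
                          "unilateral-dilated": 0.12,
                          "bilateral-dilated-fixed": 0.03}},
    "airway": {"choice": {"patent": 0.85, "obstructed": 0.12, "arrest": 0.03}},
    "spo2": {"mixture": [[0.8, {"uniform_int": [94, 100]}],
                         [0.2, {"uniform_int": [80, 93]}]]},
    "hematoma_location": {"choice": {"basal-ganglia": 0.45, "thalamus": 0.20,
                                     "lobar": 0.15, "cerebellar": 0.12,
                                     "brainstem": 0.08}},
    "hematoma_volume": {"lognormal": [2.9, 0.55, 1.0, 90.0, 1]},
    "midline_shift": {"zero_inflated": [0.6, {"lognormal": [1.2, 0.6, 0.5, 15.0, 1]}]},
    "ventricular_compression": {"choice": {True: 0.25, False: 0.75}},
    "intraventricular_extension": {"choice": {True: 0.15, False: 0.85}},
    "history": {"flags": {"hypertension": 0.75, "anticoagulant-use": 0.10,
                          "hemophilia": 0.02, "hemodialysis": 0.03}},
    "suspicion": {"flags": {"vascular-lesion": 0.07, "tumor": 0.05}},
}


def _draw(spec: Mapping, rng: np.random.Generator):
    if not isinstance(spec, Mapping) or len(spec) != 1:
        raise ConfigurationError(f"malformed distribution spec {spec!r}")
    kind, arg = next(iter(spec.items()))
    if kind == "point":
        return arg
    if kind == "choice":
        vals = list(arg.keys())
        probs = np.array([arg[v] for v in vals], dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("choice probabilities must be >= 0 and sum to 1")
        return vals[int(rng.choice(len(vals), p=probs))]
    if kind == "uniform_int":
        lo, hi = arg
        if lo > hi:
            raise ConfigurationError("uniform_int needs lo <= hi")
        return int(rng.integers(lo, hi + 1))
    if kind == "normal_int":
        mu, sd, lo, hi = arg
        if sd < 0 or lo > hi:
            raise ConfigurationError("normal_int needs sd >= 0 and lo <= hi")
        return int(np.clip(round(rng.normal(mu, sd)), lo, hi))
    if kind == "lognormal":
        mu, sd, lo, hi, dec = arg
        if sd < 0 or lo > hi or lo < 0:
            raise ConfigurationError("lognormal needs sd >= 0 and 0 <= lo <= hi")
        return float(np.clip(round(rng.lognormal(mu, sd), int(dec)), lo, hi))
    if kind == "zero_inflated":
        p_zero, sub = arg
        if not (0 <= p_zero <= 1):
            raise ConfigurationError("zero-inflation probability must lie in [0, 1]")
        return 0.0 if rng.random() < p_zero else _draw(sub, rng)
    if kind == "mixture":
        ws = np.array([w for w, _ in arg], dtype=float)
        if (ws < 0).any() or abs(ws.sum() - 1.0) > 1e-9:
            raise ConfigurationError("mixture weights must be >= 0 and sum to 1")
        k = int(rng.choice(len(arg), p=ws))
        return _draw(arg[k][1], rng)
    if kind == "flags":
        out = set()
        for flag in sorted(arg):
            p = arg[flag]
            if not (0 <= p <= 1):
                raise ConfigurationError(f"flag probability for {flag!r} outside [0, 1]")
            if rng.random() < p:
                out.add(flag)
        return frozenset(out)
    raise ConfigurationError(f"unknown distribution kind {kind!r}")


def sample_profile(prevalence_config: Mapping | None = None,
                   seed: int = 0) -> PatientProfile:
    """Draw one profile; deterministic given the seed.

    Fields absent from the config fall back to the default prevalence, so a
    degenerate config like ``{"gcs_total": {"point": 3}}`` pins one field.
    """
    cfg = dict(DEFAULT_PREVALENCE)
    if prevalence_config:
        unknown = set(prevalence_config) - set(DEFAULT_PREVALENCE)
        if unknown:
            raise ConfigurationError(f"unknown profile fields {sorted(unknown)}")
        cfg.update(prevalence_config)
    rng = np.random.default_rng(seed)
    values = {f: _draw(cfg[f], rng) for f in DEFAULT_PREVALENCE}
    return PatientProfile(**values).validate()


# ---------------------------------------------------------------------------
# Tokenization and rendering
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\d+\.\d+|\w+|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Whitespace plus punctuation splitting; decimals stay single tokens."""
    return _TOKEN_RE.findall(text)


def _lit(text: str) -> list[tuple[str, str]]:
    return [(t, "O") for t in tokenize(text)]


def _span(text: str, etype: str) -> list[tuple[str, str]]:
    toks = tokenize(text)
    return [(t, f"B-{etype}" if i == 0 else f"I-{etype}") for i, t in enumerate(toks)]


_LOCATION_SURFACE = {
    "basal-ganglia": "basal ganglia",
    "thalamus": "thalamus",
    "lobar": "lobar white matter",
    "cerebellar": "cerebellar hemisphere",
    "brainstem": "brainstem",
}
_PUPIL_SURFACE = {
    "bilateral-equal-reactive": "pupils equal and reactive to light",
    "unilateral-dilated": "unilateral pupillary dilation",
    "bilateral-dilated-fixed": "bilateral fixed dilated pupils",
}
_AIRWAY_SURFACE = {
    "patent": "airway patent",
    "obstructed": "airway obstructed by secretions",
    "arrest": "respiratory arrest",
}
_HISTORY_SURFACE = {
    "hypertension": "hypertension",
    "anticoagulant-use": "anticoagulant therapy",
    "hemophilia": "hemophilia",
    "hemodialysis": "long term hemodialysis",
}
_SUSPICION_SURFACE = {
    "vascular-lesion": "underlying vascular lesion",
    "tumor": "tumor associated hemorrhage",
}


def _v_chief_complaint(p: PatientProfile, rng) -> list[tuple[str, str]]:
    if p.gcs_total <= 8:
        cc = "sudden loss of consciousness"
    elif p.hematoma_volume >= 30:
        cc = "severe headache with repeated vomiting"
    else:
        cc = "sudden headache and limb weakness"
    return _span(cc, "CHIEF-COMPLAINT")


def _v_vitals(p: PatientProfile, rng) -> list[tuple[str, str]]:
    out = _span(f"blood pressure {p.sbp} / {p.dbp} mmhg", "VITAL-SIGN")
    out += _lit(" and ")
    out += _span(f"oxygen saturation {p.spo2} %", "VITAL-SIGN")
    return out


def _v_gcs(p: PatientProfile, rng) -> list[tuple[str, str]]:
    return _span(f"glasgow coma score {p.gcs_total}", "GCS")


def _v_pupils(p: PatientProfile, rng) -> list[tuple[str, str]]:
    return _span(_PUPIL_SURFACE[p.pupils], "PUPIL")


def _v_airway(p: PatientProfile, rng) -> list[tuple[str, str]]:
    return _span(_AIRWAY_SURFACE[p.airway], "AIRWAY")


def _v_history(p: PatientProfile, rng) -> list[tuple[str, str]]:
    if not p.history:
        return _lit("no significant past medical history")
    out = _lit("known")
    for i, flag in enumerate(sorted(p.history)):
        if i:
            out += _lit("and")
        out += _span(_HISTORY_SURFACE[flag], "HISTORY-ITEM")
    return out


def _v_location(p: PatientProfile, rng) -> list[tuple[str, str]]:
    surface = _LOCATION_SURFACE[p.hematoma_location]
    if p.hematoma_location not in ("brainstem", "thalamus"):
        side = "left" if rng.random() < 0.5 else "right"
        surface = f"{side} {surface}"
    return _span(surface, "LOCATION")


def _v_nature(p: PatientProfile, rng) -> list[tuple[str, str]]:
    return _span("hypertensive hemorrhage", "NATURE")


def _v_volume(p: PatientProfile, rng) -> list[tuple[str, str]]:
    return _span(f"estimated volume {p.hematoma_volume:.1f} ml", "VOLUME")


def _v_midline(p: PatientProfile, rng) -> list[tuple[str, str]]:
    if p.midline_shift == 0:
        return _span("no midline shift", "MIDLINE-SHIFT")
    return _span(f"midline shift of {p.midline_shift:.1f} mm", "MIDLINE-SHIFT")


def _v_ventricles(p: PatientProfile, rng) -> list[tuple[str, str]]:
    if p.ventricular_compression:
        out = _span("compression of the lateral ventricle", "VENTRICULAR-COMPRESSION")
    else:
        out = _span("no ventricular compression", "VENTRICULAR-COMPRESSION")
    if p.intraventricular_extension:
        out += _lit("with")
        out += _span("intraventricular extension", "VENTRICULAR-COMPRESSION")
    return out


def _v_suspicion(p: PatientProfile, rng) -> list[tuple[str, str]]:
    if not p.suspicion:
        return _lit("no features suggesting a secondary cause")
    out = _lit("suspicion of")
    for i, flag in enumerate(sorted(p.suspicion)):
        if i:
            out += _lit("and")
        out += _span(_SUSPICION_SURFACE[flag], "SUSPICION-ITEM")
    return out


VERBALIZERS = {
    "chief_complaint": _v_chief_complaint,
    "vitals": _v_vitals,
    "gcs_total": _v_gcs,
    "pupils": _v_pupils,
    "airway": _v_airway,
    "history": _v_history,
    "hematoma_location": _v_location,
    "nature": _v_nature,
    "hematoma_volume": _v_volume,
    "midline_shift": _v_midline,
    "ventricles": _v_ventricles,
    "suspicion": _v_suspicion,
}

# A template is a list of strings; "{name}" items are verbalizer slots, the
# rest is literal O-tagged prose.  "{age}" and "{sex}" inline the structured
# demographics as plain text.
DEFAULT_TEMPLATE_BANK: list[list[str]] = [
    [
        "a {age} year old {sex} presented with", "{chief_complaint}", ".",
        "{history}", ".",
        "on examination", "{vitals}", ",", "{gcs_total}", ",",
        "{pupils}", ",", "{airway}", ".",
        "head ct shows a", "{nature}", "in the", "{hematoma_location}",
        "with", "{hematoma_volume}", ",", "{midline_shift}",
        "and", "{ventricles}", ".",
        "{suspicion}", ".",
    ],
    [
        "the patient is a {sex} aged {age} complaining of", "{chief_complaint}", ".",
        "vital signs :", "{vitals}", ".",
        "neurological assessment found", "{gcs_total}", "with",
        "{pupils}", "and", "{airway}", ".",
        "{history}", ".",
        "ct reading :", "{nature}", ",", "{hematoma_location}", ",",
        "{hematoma_volume}", ",", "{midline_shift}", ",", "{ventricles}", ".",
        "{suspicion}", ".",
    ],
]

_SLOT_RE = re.compile(r"^\{(\w+)\}$")


def _profile_render_seed(p: PatientProfile) -> int:
    """Stable per-profile seed so clean and corrupted renders share surfaces."""
    key = repr(sorted((k, str(v)) for k, v in p.__dict__.items()))
    h = 2166136261
    for ch in key.encode():
        h = ((h ^ ch) * 16777619) & 0x7FFFFFFF
    return h


def render_emr(profile: PatientProfile,
               template_bank: Sequence[Sequence[str]] | None = None,
               corruption: CorruptionConfig | None = None,
               doc_id: str = "doc-0") -> AnnotatedDocument:
    """Render a profile into an annotated note.

    Every verbalized finding appears as a tagged span; corruption alters only
    surface forms (and may contract registered multi-token phrases into their
    abbreviations) but never misaligns tags.  With zero corruption the output
    equals the clean template rendering.
    """
    bank = DEFAULT_TEMPLATE_BANK if template_bank is None else template_bank
    if not bank:
        raise TemplateError("template bank is empty")
    corruption = corruption or CorruptionConfig()
    rng = np.random.default_rng(_profile_render_seed(profile))
    template = bank[int(rng.integers(len(bank)))]
    pairs: list[tuple[str, str]] = []
    for item in template:
        m = _SLOT_RE.match(item)
        if m:
            name = m.group(1)
            if name not in VERBALIZERS:
                raise TemplateError(f"template references unknown field {name!r}")
            pairs += VERBALIZERS[name](profile, rng)
        else:
            text = item.replace("{age}", str(profile.age)).replace("{sex}", profile.sex)
            if "{" in text:
                bad = re.findall(r"\{(\w+)\}", text)
                raise TemplateError(f"template references unknown field {bad[0]!r}")
            pairs += _lit(text)
    pairs = _corrupt(pairs, corruption)
    tokens = [t for t, _ in pairs]
    tags = [g for _, g in pairs]
    doc = AnnotatedDocument(
        doc_id=doc_id, text=" ".join(tokens), tokens=tokens, tags=tags,
        profile_ref=doc_id, meta={"age": profile.age, "sex": profile.sex})
    return doc.validate()


# ---------------------------------------------------------------------------
# Corruption and its inverse (the preprocessor)
# ---------------------------------------------------------------------------

ABBREVIATIONS: dict[str, tuple[str, ...]] = {
    "BP": ("blood", "pressure"),
    "GCS": ("glasgow", "coma", "score"),
    "SpO2": ("oxygen", "saturation"),
    "HTN": ("hypertension",),
    "IVH": ("intraventricular", "extension"),
}


def _template_vocabulary() -> dict[str, int]:
    """Word frequencies over everything the default templates can emit."""
    freq: dict[str, int] = {}
    texts = [
        item for tpl in DEFAULT_TEMPLATE_BANK for item in tpl if not _SLOT_RE.match(item)
    ]
    texts += list(_LOCATION_SURFACE.values()) + list(_PUPIL_SURFACE.values())
    texts += list(_AIRWAY_SURFACE.values()) + list(_HISTORY_SURFACE.values())
    texts += list(_SUSPICION_SURFACE.values())
    texts += [
        "sudden loss of consciousness", "severe headache with repeated vomiting",
        "sudden headache and limb weakness", "no significant past medical history",
        "blood pressure mmhg and oxygen saturation", "glasgow coma score",
        "hypertensive hemorrhage", "estimated volume ml",
        "midline shift of mm", "no midline shift",
        "compression of the lateral ventricle", "no ventricular compression",
        "with intraventricular extension", "known and",
        "no features suggesting a secondary cause", "suspicion of",
        "left right male female",
    ]
    for text in texts:
        for tok in tokenize(text):
            if tok.isalpha():
                freq[tok] = freq.get(tok, 0) + 1
    return freq


DEFAULT_LEXICON: dict[str, int] = _template_vocabulary()

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def _ed1_variants(word: str) -> Iterable[str]:
    for i in range(len(word)):
        yield word[:i] + word[i + 1:]  # deletion
        for c in _ALPHABET:
            if c != word[i]:
                yield word[:i] + c + word[i + 1:]  # substitution
    for i in range(len(word) + 1):
        for c in _ALPHABET:
            yield word[:i] + c + word[i:]  # insertion


def correct_spelling(token: str, lexicon: Mapping[str, int]) -> str:
    """Edit-distance-1 nearest lexicon entry; ties broken by frequency then
    lexicographic order.  Unknown/uncorrectable tokens pass through."""
    if token in lexicon or not token.isalpha() or len(token) < 3:
        return token
    candidates = {v for v in _ed1_variants(token) if v in lexicon}
    if not candidates:
        return token
    return min(candidates, key=lambda w: (-lexicon[w], w))


@lru_cache(maxsize=4096)
def _safe_misspellings(word: str, lexicon: Mapping[str, int] | None = None) -> tuple[str, ...]:
    """Misspellings of ``word`` the spell checker resolves uniquely back."""
    lexicon = DEFAULT_LEXICON if lexicon is None else lexicon
    out = []
    for v in _ed1_variants(word):
        if v != word and v not in lexicon and correct_spelling(v, lexicon) == word:
            out.append(v)
    return tuple(sorted(set(out)))


def _corrupt(pairs: list[tuple[str, str]], cfg: CorruptionConfig) -> list[tuple[str, str]]:
    if cfg.misspell_rate == 0 and cfg.abbreviation_rate == 0:
        return pairs
    rng = np.random.default_rng(cfg.seed)
    # abbreviation contraction: replace a registered expansion phrase with its
    # short form; the single surviving token inherits the phrase-initial tag.
    out: list[tuple[str, str]] = []
    i = 0
    by_phrase = {v: k for k, v in ABBREVIATIONS.items()}
    max_len = max(len(v) for v in ABBREVIATIONS.values())
    while i < len(pairs):
        done = False
        for L in range(max_len, 0, -1):
            phrase = tuple(t for t, _ in pairs[i:i + L])
            if phrase in by_phrase and rng.random() < cfg.abbreviation_rate:
                tags = [g for _, g in pairs[i:i + L]]
                same_region = all(g == "O" for g in tags) or \
                    all(g != "O" and g[2:] == tags[0][2:] for g in tags)
                if same_region:
                    out.append((by_phrase[phrase], tags[0]))
                    i += L
                    done = True
                    break
        if not done:
            out.append(pairs[i])
            i += 1
    # misspelling: per-token, only where the spell checker can invert it.
    final = []
    for tok, tag in out:
        if tok in DEFAULT_LEXICON and rng.random() < cfg.misspell_rate:
            variants = _safe_misspellings(tok)
            if variants:
                tok = variants[int(rng.integers(len(variants)))]
        final.append((tok, tag))
    return final


def preprocess(text: str, lexicon: Mapping[str, int] | None = None,
               abbreviations: Mapping[str, tuple[str, ...]] | None = None) -> list[str]:
    """Tokenize, expand registered abbreviations, correct misspellings.

    The corrections are exactly the inverse of what :func:`render_emr`'s
    corruption can inject, so preprocessing a corrupted note recovers the
    clean token stream.  Unknown tokens pass through unchanged.
    """
    lexicon = DEFAULT_LEXICON if lexicon is None else lexicon
    abbreviations = ABBREVIATIONS if abbreviations is None else abbreviations
    out: list[str] = []
    for tok in tokenize(text):
        if tok in abbreviations:
            out.extend(abbreviations[tok])
        else:
            out.append(correct_spelling(tok, lexicon))
    return out


# ---------------------------------------------------------------------------
# CoNLL persistence
# ---------------------------------------------------------------------------


def write_conll(docs: Sequence[AnnotatedDocument], path) -> None:
    """Two-column (token TAB tag) files; blank line between documents;
    ``# key = value`` headers carry doc id and structured demographics."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, doc in enumerate(docs):
            if i:
                fh.write("\n")
            fh.write(f"# doc_id = {doc.doc_id}\n")
            if doc.profile_ref is not None:
                fh.write(f"# profile_ref = {doc.profile_ref}\n")
            for k, v in sorted(doc.meta.items()):
                fh.write(f"# {k} = {v}\n")
            for tok, tag in zip(doc.tokens, doc.tags):
                fh.write(f"{tok}\t{tag}\n")


def read_conll(path) -> list[AnnotatedDocument]:
    """Inverse of :func:`write_conll`; malformed lines raise :class:`ParseError`
    naming the line number, and BIO chain violations are rejected."""
    docs: list[AnnotatedDocument] = []
    cur_tokens: list[str] = []
    cur_tags: list[str] = []
    meta: dict = {}
    doc_id, profile_ref = None, None
    start_line = 1

    def flush(line_no: int) -> None:
        nonlocal cur_tokens, cur_tags, meta, doc_id, profile_ref, start_line
        if not cur_tokens and doc_id is None:
            return
        doc = AnnotatedDocument(
            doc_id=doc_id or f"doc-{len(docs)}",
            text=" ".join(cur_tokens), tokens=cur_tokens, tags=cur_tags,
            profile_ref=profile_ref, meta=meta)
        try:
            doc.validate()
        except ValueError as exc:
            raise ParseError(f"line {line_no}: {exc}") from exc
        docs.append(doc)
        cur_tokens, cur_tags, meta = [], [], {}
        doc_id, profile_ref = None, None

    n = 0
    with open(path, encoding="utf-8") as fh:
        for n, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush(n)
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(.*)", line)
                if m:
                    k, v = m.group(1), m.group(2).strip()
                    if k == "doc_id":
                        doc_id = v
                    elif k == "profile_ref":
                        profile_ref = v
                    elif k == "age":
                        meta["age"] = int(v)
                    else:
                        meta[k] = v
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ParseError(f"line {n}: expected 'token<TAB>tag', got {line!r}")
            prev = cur_tags[-1] if cur_tags else "O"
            tag = parts[1]
            if tag.startswith("I-") and not (prev.startswith(("B-", "I-"))
                                             and prev[2:] == tag[2:]):
                raise ParseError(f"line {n}: dangling I- tag {tag!r}")
            cur_tokens.append(parts[0])
            cur_tags.append(tag)
        flush(n + 1)
    return docs


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def generate_corpus(n: int, seed: int = 0,
                    corruption: CorruptionConfig | None = None,
                    prevalence_config: Mapping | None = None,
                    ) -> list[tuple[PatientProfile, AnnotatedDocument]]:
    """Sample ``n`` profiles and render each into an annotated document.

    Per-document corruption seeds derive from the corpus seed, so the whole
    corpus is reproducible from ``(n, seed, corruption)``.
    """
    root = np.random.default_rng(seed)
    out = []
    for i in range(n):
        p_seed = int(root.integers(0, 2 ** 31 - 1))
        profile = sample_profile(prevalence_config, seed=p_seed)
        corr = None
        if corruption is not None:
            corr = replace(corruption, seed=int(root.integers(0, 2 ** 31 - 1)))
        doc = render_emr(profile, corruption=corr, doc_id=f"doc-{i:05d}")
        out.append((profile, doc))
    return out
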