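"""End-to-end orchestration: EMR text -> NER -> KG alignment -> weighted
rules -> explanation -> evaluation.

A :class:`RunConfig` fixes every input (corpus, knowledge graph, ruleset,
model, seed); :func:`run_pipeline` executes the stages per document,
isolates per-document failures, and writes a manifest with configuration
snapshot, per-stage SHA-256 checksums and timings so a rerun with the same
config is byte-identical for the deterministic stages.

The synthetic gold plans are produced by the same ruleset the pipeline
applies — deliberate circularity that makes the closed-loop benchmark a
test of extraction and plumbing, not of clinical ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from . import emr_synth as es
from . import evaluation as ev
from . import hkg, hws, ner

log = logging.getLogger(__name__)


def load_default_graph() -> hkg.KnowledgeGraph:
    """The packaged seed knowledge graph."""
    with resources.as_file(resources.files("hichkit.data") / "seed_graph.tsv") as p:
        return hkg.load_graph(p)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; seeded end to end."""

    seed: int = 0
    out_dir: str = "run"
    corpus_path: str | None = None     # CoNLL corpus; None -> generate
    gold_path: str | None = None       # gold-plan JSON sidecar
    kg_path: str | None = None         # None -> packaged seed graph
    ruleset_path: str | None = None    # None -> packaged R0
    n_docs: int = 100
    misspell_rate: float = 0.02
    abbreviation_rate: float = 0.1
    mode: str = "gold"                 # "gold" (bypass NER) or "ner"
    model_path: str | None = None      # required for mode="ner" unless training
    variant: str = "bert-idcnn-bilstm-crf"
    epochs: int = 10
    train_frac: float = 0.7
    dev_frac: float = 0.1
    alignment_threshold: float = 0.5
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if self.mode not in ("gold", "ner"):
            raise ValueError("mode must be 'gold' or 'ner'")
        for p in (self.corpus_path, self.gold_path, self.kg_path,
                  self.ruleset_path, self.model_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return self


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _token_normalizer(tokens):
    return es.preprocess(" ".join(tokens))


def write_corpus(out_dir, n: int, seed: int, misspell: float = 0.02,
                 abbrev: float = 0.1, ruleset=None, graph=None) -> tuple[Path, Path]:
    """Generate a corpus + matched gold plans; returns (conll, gold) paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ruleset = ruleset or hws.load_ruleset()
    graph = graph if graph is not None else load_default_graph()
    corr = es.CorruptionConfig(misspell, abbrev, seed)
    corpus = es.generate_corpus(n, seed=seed, corruption=corr)
    conll = out / "corpus.conll"
    es.write_conll([d for _, d in corpus], conll)
    gold = {}
    for profile, doc in corpus:
        plan = hws.apply_hws(hws.profile_to_state(profile), ruleset, graph)
        gold[doc.doc_id] = {"plan": plan.to_dict(),
                            "profile": {k: sorted(v) if isinstance(v, frozenset) else v
                                        for k, v in profile.__dict__.items()}}
    gold_path = out / "gold.json"
    gold_path.write_text(json.dumps(gold, sort_keys=True, indent=1))
    return conll, gold_path


def document_mentions(doc: es.AnnotatedDocument,
                      model: ner.SequenceLabeler | None) -> list[tuple]:
    """Entity mentions of one document: gold tags, or the model's decode."""
    if model is None:
        return doc.gold_mentions()
    spans = ner.extract_entities(model, doc)
    return [((s, e), etype, tuple(doc.tokens[s:e])) for (s, e), etype in spans]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the workflow and persist plans, reports and a manifest.

    Each document runs in isolation: a failure is recorded as a per-document
    error without aborting the rest, and the manifest counts errors (the CLI
    maps a nonzero count to a nonzero exit code).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.time()
    out = Path(config.out_dir)
    plans_dir = out / "plans"
    plans_dir.mkdir(parents=True, exist_ok=True)
    graph = hkg.load_graph(config.kg_path) if config.kg_path else load_default_graph()
    ruleset = hws.load_ruleset(config.ruleset_path)
    timings = {}
    if config.corpus_path is None:
        conll, gold_path = write_corpus(out, config.n_docs, config.seed,
                                        config.misspell_rate, config.abbreviation_rate,
                                        ruleset, graph)
    else:
        conll, gold_path = Path(config.corpus_path), \
            Path(config.gold_path) if config.gold_path else None
    timings["setup"] = time.time() - t0
    docs = es.read_conll(conll)
    model = None
    if config.mode == "ner":
        if config.model_path is None:
            raise ValueError("mode='ner' requires model_path (train one first)")
        model = ner.SequenceLabeler.load(config.model_path)
    gold = json.loads(Path(gold_path).read_text()) if gold_path else None

    errors: list[dict] = []
    plan_files: dict[str, str] = {}
    t1 = time.time()
    predicted: dict[str, hws.TreatmentPlan] = {}
    for doc in docs:
        try:
            mentions = document_mentions(doc, model)
            state = hws.normalize_entities(
                mentions, graph, demographics=doc.meta,
                token_normalizer=_token_normalizer)
            plan = hws.apply_hws(state, ruleset, graph)
            path = plans_dir / f"{doc.doc_id}.json"
            path.write_text(plan.to_json())
            report = hws.explain(plan, ruleset)
            (plans_dir / f"{doc.doc_id}.md").write_text(hws.render_markdown(report))
            plan_files[doc.doc_id] = _sha256(path)
            predicted[doc.doc_id] = plan
        except Exception as exc:  # noqa: BLE001 - per-document isolation
            log.error("stage=decide doc=%s event=error %s", doc.doc_id, exc)
            errors.append({"stage": "decide", "doc_id": doc.doc_id, "error": str(exc)})
    timings["decide"] = time.time() - t1

    evaluation = None
    if gold:
        t2 = time.time()
        evaluation = evaluate_plans(predicted, gold)
        (out / "report.json").write_text(json.dumps(evaluation, sort_keys=True, indent=1))
        _write_report_csv(out / "report.csv", evaluation)
        timings["evaluate"] = time.time() - t2

    manifest = {
        "schema_version": 1,
        "config": asdict(config),
        "inputs": {"corpus": _sha256(Path(conll)),
                   "gold": _sha256(Path(gold_path)) if gold_path else None},
        "plans": {k: plan_files[k] for k in sorted(plan_files)},
        "errors": errors,
        "n_documents": len(docs),
        "timings": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    if evaluation:
        manifest["evaluation"] = evaluation
    return manifest


def evaluate_plans(predicted: Mapping[str, hws.TreatmentPlan], gold: Mapping,
                   rubric: ev.RubricConfig | None = None) -> dict:
    """Rubric scores plus per-positive-event classification metrics."""
    rubric = rubric or ev.RubricConfig()
    totals, per_category = [], {"diagnostic": [], "surgical": [], "rescue": [], "drug": []}
    event_rows: dict[str, dict] = {}
    scores_by_event: dict[str, list] = {e: [] for e in ev.POSITIVE_EVENTS}
    labels_by_event: dict[str, list] = {e: [] for e in ev.POSITIVE_EVENTS}
    pred_by_event: dict[str, list] = {e: [] for e in ev.POSITIVE_EVENTS}
    for doc_id, entry in sorted(gold.items()):
        if doc_id not in predicted:
            continue
        g = hws.TreatmentPlan.from_dict(entry["plan"])
        p = predicted[doc_id]
        sc = ev.rubric_score(p, g, rubric)
        totals.append(sc["total"])
        for c in per_category:
            per_category[c].append(sc[c])
        for event in ev.POSITIVE_EVENTS:
            in_gold = event in g.selected_items()
            in_pred = event in p.selected_items()
            labels_by_event[event].append(in_gold)
            pred_by_event[event].append(in_pred)
            scores_by_event[event].append(float(p.scores.get(event, 0.0)))
    for event in ev.POSITIVE_EVENTS:
        labels = labels_by_event[event]
        preds = pred_by_event[event]
        if not labels:
            continue
        counts = ev.ConfusionCounts(
            tp=sum(p and g for p, g in zip(preds, labels)),
            fp=sum(p and not g for p, g in zip(preds, labels)),
            tn=sum(not p and not g for p, g in zip(preds, labels)),
            fn=sum(not p and g for p, g in zip(preds, labels)))
        row = classification = ev.classification_metrics(counts)
        try:
            row["auc"] = 100.0 * ev.roc_auc(scores_by_event[event], labels)
        except ValueError:
            row["auc"] = None
        try:
            table = ev.RaterTable.from_categories(preds, labels, [False, True])
            row["kappa"] = ev.cohens_kappa(table.counts)
        except ValueError:
            row["kappa"] = None
        event_rows[event] = row
    dist = ev.score_distribution(totals, rubric) if totals else None
    return {
        "n_scored": len(totals),
        "rubric": {
            "mean_total": float(np.mean(totals)) if totals else None,
            "mean_by_category": {c: float(np.mean(v)) for c, v in per_category.items()
                                 if v},
            "distribution_pct": dist,
        },
        "events": event_rows,
    }


def _write_report_csv(path: Path, evaluation: Mapping) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["measure", "branch", "value"])
        rub = evaluation["rubric"]
        w.writerow(["rubric_mean_total", "all", rub["mean_total"]])
        for c, v in sorted(rub["mean_by_category"].items()):
            w.writerow(["rubric_mean", c, v])
        for event, row in sorted(evaluation["events"].items()):
            for k, v in sorted(row.items()):
                w.writerow([k, event, v])


# ---------------------------------------------------------------------------
# The synthetic benchmark
# ---------------------------------------------------------------------------


def end_to_end_benchmark(n_docs: int = 500, seed: int = 0, mode: str = "ner",
                         variant: str = "bert-idcnn-bilstm-crf",
                         epochs: int = 10, misspell_rate: float = 0.02,
                         abbreviation_rate: float = 0.1,
                         train_frac: float = 0.7, dev_frac: float = 0.1,
                         ruleset: hws.Ruleset | None = None,
                         graph: hkg.KnowledgeGraph | None = None) -> dict:
    """Generate a corpus, (optionally) train the labeler, run the pipeline
    on the held-out split and score the plans against the synthetic gold.

    ``mode="gold"`` bypasses extraction (gold entities straight into the
    rule engine) and closes the loop exactly; ``mode="ner"`` measures the
    cost of extraction errors.  Returns NER metrics, rubric scores and
    per-event classification metrics.
    """
    graph = graph if graph is not None else load_default_graph()
    ruleset = ruleset or hws.load_ruleset()
    corr = es.CorruptionConfig(misspell_rate, abbreviation_rate, seed)
    corpus = es.generate_corpus(n_docs, seed=seed, corruption=corr)
    n_train = int(n_docs * train_frac)
    n_dev = int(n_docs * dev_frac)
    train = [d for _, d in corpus[:n_train]]
    dev = [d for _, d in corpus[n_train:n_train + n_dev]]
    test = corpus[n_train + n_dev:]

    model, ner_metrics_out, trace = None, None, None
    if mode == "ner":
        cfg = ner.VariantConfig.from_name(variant, epochs=epochs, seed=seed)
        model, trace = ner.train_ner(train, dev, cfg)
        p, r, f1 = ner.evaluate_ner(model, [d for _, d in test])
        ner_metrics_out = {"precision": p, "recall": r, "f1": f1}

    predicted, gold = {}, {}
    for profile, doc in test:
        gold_plan = hws.apply_hws(hws.profile_to_state(profile), ruleset, graph)
        gold[doc.doc_id] = {"plan": gold_plan.to_dict()}
        mentions = document_mentions(doc, model)
        state = hws.normalize_entities(mentions, graph, demographics=doc.meta,
                                       token_normalizer=_token_normalizer)
        predicted[doc.doc_id] = hws.apply_hws(state, ruleset, graph)
    report = evaluate_plans(predicted, gold)
    exact = sum(predicted[d] == hws.TreatmentPlan.from_dict(gold[d]["plan"])
                for d in gold)
    report["exact_plan_match_rate"] = 100.0 * exact / len(gold)
    report["mode"] = mode
    report["n_test"] = len(test)
    if ner_metrics_out:
        report["ner"] = ner_metrics_out
        report["trace"] = trace
    return report
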