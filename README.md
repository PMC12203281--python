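# hichkit

Explainable decision support for hypertensive intracerebral hemorrhage
(HICH), end to end and desk-scale: a neural key-entity extractor for
EMR-like text, a provenance-tagged medical knowledge graph, a weighted
guideline rule engine that emits four-branch treatment plans where every
item carries its machine-readable basis, and the matching evaluation suite
(100-point plan rubric, sensitivity/specificity/accuracy, ROC-AUC, Cohen
kappa).  A built-in synthetic EMR generator makes the whole loop
reproducible on one CPU with no clinical data.

Who it is for: researchers studying explainable clinical NLP pipelines who
need a complete, testable reference loop — text to entities to canonical
state to auditable plan to score — rather than a black-box model.

## The core method

1. **Key named-entity recognition.** Seven composable sequence-labeling
   variants (IDCNN-CRF, BiLSTM-CRF, BiLSTM-IDCNN-CRF, and each with a small
   masked-LM-pretrained transformer encoder in front), all terminated by a
   linear-chain CRF:

   P(Y|X) = (1/R(X)) prod_t exp W_t(y_{t-1}, y_t | X),  with R(X) the
   partition function computed by the log-space forward recursion and
   decoding by Viterbi.  Attention is softmax(QK^T/sqrt(d_k))V; entity
   scores are exact-span precision/recall with F1 = 2PR/(P+R).

2. **Knowledge-graph normalization.** Mentions align to canonical entities
   through a synonym table plus character-bigram similarity over a triple
   store covering three knowledge tiers (general / subdomain /
   subdomain-specific), queried with conjunctive basic graph patterns.

3. **Weighted rule engine.** A plan item activates when the summed weight of
   its fired guideline rules reaches the item's threshold; each selected
   item reports the fired rules, their filled explanation text and their
   knowledge-graph provenance.  The shipped ruleset R0 follows the guideline
   tradition (supratentorial volume >= 30 mL, cerebellar >= 10 mL or
   ventricular compression, midline shift >= 5 mm, GCS <= 8 for airway
   protection, SBP >= 180 mmHg for antihypertensives).

4. **Assessment.** Plans score against gold on a 100-point rubric
   (diagnostic 15 + therapeutic 85 = surgical 40 + rescue 35 + drug 10;
   surgical all-or-nothing), with score-bin distributions, per-event
   confusion metrics, Mann-Whitney ROC-AUC and Cohen kappa.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from hichkit import emr_synth as es, hws, pipeline

profile = es.sample_profile(seed=7)
doc = es.render_emr(profile)                      # annotated synthetic note
graph = pipeline.load_default_graph()
ruleset = hws.load_ruleset()
state = hws.normalize_entities(doc.gold_mentions(), graph,
                               demographics=doc.meta)
plan = hws.apply_hws(state, ruleset, graph)
print(sorted(plan.rescue), sorted(plan.drugs), plan.surgical)
```

The seed-7 patient is a 69-year-old with GCS 8, blood pressure 164/85 mmHg
and a 22.1 mL basal-ganglia hematoma without midline shift.  The engine
prints

```
['airway-clearance', 'tracheal-intubation', 'venous-access', 'vital-sign-monitoring'] ['anti-gi-bleeding', 'icp-lowering'] False
```

— coma (GCS 8 <= 8) triggers airway protection, ICP lowering and
stress-ulcer prophylaxis; the 22 mL supratentorial hematoma without shift
stays below the surgical thresholds; SBP 164 stays below the
antihypertensive threshold.  `hws.explain(plan, ruleset)` renders the same
decisions with their rule ids and knowledge-graph citations, e.g.

```
## airway-clearance (rescue, score 1)
- [r-airway-gcs] coma (GCS 8 <= 8): airway protection with tracheal cannula
  - r-airway-gcs indicates airway-clearance (Airway protection convention for coma (GCS <= 8))
```

The same flow is scriptable from the shell:

```bash
hichkit synth --n 1000 --seed 7 --out corpus/ --misspell 0.02 --abbrev 0.1
hichkit train --variant bert-idcnn-bilstm-crf --train corpus/corpus.conll \
              --dev corpus/corpus.conll --seed 1 --out run/
hichkit benchmark --n 500 --seed 1 --mode ner
hichkit kg query '(?x indicates surgical-evacuation)'
```

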