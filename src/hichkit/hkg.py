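"""The HICH knowledge graph: a provenance-tagged triple store.

Triples carry one of three knowledge tiers — general medical knowledge,
neurosurgical subdomain knowledge, and subdomain-specific knowledge from the
weighted scoring rules — plus a free-text source citation.  The store
answers conjunctive basic-graph-pattern queries (variables written ``?x``)
and aligns surface mentions to canonical entities, which is how extracted
text lands on the vocabulary the decision engine reasons over.

Native persistence is a 5-column TSV (subject, predicate, object, tier,
source).  N-Triples import/export is supported for interchange but carries
only subject/predicate/object; tier defaults to "general" and the source is
empty on import.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

log = logging.getLogger(__name__)

TIERS = ("general", "subdomain", "subdomain-specific")

SYNONYM_PREDICATE = "synonym-of"
CATEGORY_PREDICATE = "category"


class GraphParseError(ValueError):
    """A graph file line could not be parsed; the message names the line."""


@dataclass(frozen=True)
class Triple:
    """One subject-predicate-object fact with provenance."""

    subject: str
    predicate: str
    object: str
    tier: str = "general"
    source: str = ""

    def __post_init__(self):
        if not self.subject or not self.predicate:
            raise ValueError("triple subject and predicate must be non-empty")
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}, got {self.tier!r}")


@dataclass
class QueryPattern:
    """A conjunction of triple patterns; ``?``-prefixed positions are
    variables, and shared variables across patterns denote joins."""

    patterns: list

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("a query needs at least one triple pattern")
        for p in self.patterns:
            if len(tuple(p)) != 3:
                raise ValueError(f"triple pattern must have 3 positions: {p!r}")

    @staticmethod
    def is_var(term: str) -> bool:
        return isinstance(term, str) and term.startswith("?")

    @classmethod
    def parse(cls, text: str) -> "QueryPattern":
        """Parse ``(?x indicates ?y) (?y category plan-item)`` style text."""
        import re
        groups = re.findall(r"\(([^()]*)\)", text)
        if not groups:
            groups = [text]
        pats = []
        for g in groups:
            terms = g.split()
            if len(terms) != 3:
                raise ValueError(f"pattern {g!r} must have exactly 3 terms")
            pats.append(tuple(terms))
        return cls(pats)


class KnowledgeGraph:
    """Set-semantics triple store with subject/predicate/object indexes and
    a synonym table (surface form -> canonical entity)."""

    def __init__(self, triples: Iterable[Triple] = ()):
        self._triples: set[Triple] = set()
        self._by_s: dict[str, set[Triple]] = {}
        self._by_p: dict[str, set[Triple]] = {}
        self._by_o: dict[str, set[Triple]] = {}
        for t in triples:
            self.add(t)

    # -- mutation ------------------------------------------------------------
    def add(self, triple: Triple) -> None:
        if triple in self._triples:
            return
        self._triples.add(triple)
        self._by_s.setdefault(triple.subject, set()).add(triple)
        self._by_p.setdefault(triple.predicate, set()).add(triple)
        self._by_o.setdefault(triple.object, set()).add(triple)

    # -- views ---------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self):
        return iter(sorted(self._triples, key=lambda t: (t.subject, t.predicate, t.object)))

    def __eq__(self, other) -> bool:
        return isinstance(other, KnowledgeGraph) and self._triples == other._triples

    def triples(self) -> set[Triple]:
        return set(self._triples)

    @property
    def synonym_table(self) -> dict[str, str]:
        """Surface form -> canonical entity, from ``synonym-of`` triples."""
        return {t.subject: t.object for t in self._by_p.get(SYNONYM_PREDICATE, ())}

    def entities_of_type(self, category: str) -> list[str]:
        return sorted(t.subject for t in self._by_p.get(CATEGORY_PREDICATE, ())
                      if t.object == category)

    def mentions_entity(self, name: str) -> bool:
        return name in self._by_s or name in self._by_o

    # -- queries -------------------------------------------------------------
    def _candidates(self, pat: tuple, binding: dict) -> Iterable[Triple]:
        s, p, o = (binding.get(t, None) if QueryPattern.is_var(t) else t for t in pat)
        pools = []
        if s is not None:
            pools.append(self._by_s.get(s, set()))
        if p is not None:
            pools.append(self._by_p.get(p, set()))
        if o is not None:
            pools.append(self._by_o.get(o, set()))
        if not pools:
            return self._triples
        out = min(pools, key=len)
        for pool in pools:
            if pool is not out:
                out = out & pool
        return out

    def query(self, pattern: QueryPattern | Sequence) -> list[dict]:
        """All variable bindings satisfying every pattern, sorted."""
        if not isinstance(pattern, QueryPattern):
            pattern = QueryPattern(list(pattern))
        results: list[dict] = []

        def walk(i: int, binding: dict) -> None:
            if i == len(pattern.patterns):
                results.append(dict(binding))
                return
            pat = tuple(pattern.patterns[i])
            for t in self._candidates(pat, binding):
                trial = dict(binding)
                ok = True
                for term, value in zip(pat, (t.subject, t.predicate, t.object)):
                    if QueryPattern.is_var(term):
                        if trial.get(term, value) != value:
                            ok = False
                            break
                        trial[term] = value
                    elif term != value:
                        ok = False
                        break
                if ok:
                    walk(i + 1, trial)

        walk(0, {})
        uniq = {tuple(sorted(b.items())): b for b in results}
        return [dict(k) for k in sorted(uniq)]


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_NT_BASE = "urn:hich:"


def save_graph(graph: KnowledgeGraph, path) -> None:
    """Write TSV (full fidelity) or N-Triples (s/p/o only) by extension."""
    path = str(path)
    if path.endswith(".nt"):
        import rdflib
        from urllib.parse import quote
        g = rdflib.Graph()
        for t in graph:
            g.add((rdflib.URIRef(_NT_BASE + quote(t.subject)),
                   rdflib.URIRef(_NT_BASE + quote(t.predicate)),
                   rdflib.URIRef(_NT_BASE + quote(t.object))))
        g.serialize(destination=path, format="nt", encoding="utf-8")
        return
    with open(path, "w", encoding="utf-8") as fh:
        for t in graph:
            fh.write(f"{t.subject}\t{t.predicate}\t{t.object}\t{t.tier}\t{t.source}\n")


def load_graph(path) -> KnowledgeGraph:
    """Load a TSV or N-Triples graph; duplicates collapse to one triple."""
    path = str(path)
    graph = KnowledgeGraph()
    if path.endswith(".nt"):
        import rdflib
        from urllib.parse import unquote
        g = rdflib.Graph()
        g.parse(path, format="nt")

        def strip(term) -> str:
            s = str(term)
            return unquote(s[len(_NT_BASE):]) if s.startswith(_NT_BASE) else s

        for s, p, o in g:
            graph.add(Triple(strip(s), strip(p), strip(o)))
        return graph
    with open(path, encoding="utf-8") as fh:
        for n, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                parts += ["general"]
            if len(parts) == 4:
                parts += [""]
            if len(parts) != 5:
                raise GraphParseError(
                    f"line {n}: expected 3-5 tab-separated fields, got {len(parts)}")
            try:
                graph.add(Triple(*parts))
            except ValueError as exc:
                raise GraphParseError(f"line {n}: {exc}") from exc
    return graph


# ---------------------------------------------------------------------------
# Entity alignment
# ---------------------------------------------------------------------------


def bigram_dice(a: str, b: str) -> float:
    """Character-bigram Dice coefficient; symmetric, self-similarity 1."""
    a, b = a.lower(), b.lower()
    if a == b:
        return 1.0
    A = {a[i:i + 2] for i in range(len(a) - 1)} or {a}
    B = {b[i:i + 2] for i in range(len(b) - 1)} or {b}
    return 2.0 * len(A & B) / (len(A) + len(B))


def align_entity(mention: str, entity_type: str | None, graph: KnowledgeGraph,
                 similarity: Callable[[str, str], float] = bigram_dice,
                 threshold: float = 0.5) -> str | None:
    """Map a surface mention to a canonical entity identifier, or ``None``.

    Exact synonym-table hits (and exact canonical names) return without any
    similarity computation.  Otherwise the argmax-similarity entity of the
    requested category wins if its best synonym scores at least the
    threshold; ties break lexicographically on the entity identifier.
    """
    mention = " ".join(mention.lower().split())
    table = graph.synonym_table
    if mention in table:
        return table[mention]
    candidates = graph.entities_of_type(entity_type) if entity_type else \
        sorted({t.object for t in graph.triples() if t.predicate == SYNONYM_PREDICATE})
    if mention in candidates:
        return mention
    surfaces: dict[str, list[str]] = {}
    for surface, entity in table.items():
        surfaces.setdefault(entity, []).append(surface)
    best: tuple[float, str] | None = None
    for entity in candidates:
        names = surfaces.get(entity, []) + [entity.replace("-", " ")]
        score = max(similarity(mention, s) for s in names)
        if best is None or score > best[0] + 1e-12 or \
                (abs(score - best[0]) <= 1e-12 and entity < best[1]):
            best = (score, entity)
    if best is not None and best[0] >= threshold:
        return best[1]
    return None


def basis_trace(graph: KnowledgeGraph, reference: str) -> list[tuple[Triple, str]]:
    """Supporting triples (with their source citations) for an entity or rule.

    Unknown references raise ``LookupError``; a known entity with no
    outgoing triples yields an empty list and a logged warning.
    """
    if not graph.mentions_entity(reference):
        raise LookupError(f"unknown entity or rule reference {reference!r}")
    out = sorted((t for t in graph.triples() if t.subject == reference),
                 key=lambda t: (t.predicate, t.object))
    if not out:
        log.warning("no supporting triples for %r", reference)
    return [(t, t.source) for t in out]
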