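"""Gene Ontology handling: OBO 1.2 flat-file parsing, depth and ancestry queries.

The ontology is a directed acyclic graph of GO terms connected by ``is_a``
and ``part_of`` edges, one rooted tree-ish DAG per namespace (biological
process, molecular function, cellular component).  Term *depth* is the length
of the shortest ``is_a`` path from the namespace root down to the term; the
root has depth 0.  ``part_of`` edges are parsed and available for ancestry
queries but never contribute to depth — the conservative convention shared by
most GO tooling, where ``is_a`` is the one relation guaranteed to be a true
subsumption hierarchy.

Obsolete terms are kept in the graph (so inputs referencing them can be
diagnosed) but are rejected by depth/ancestor queries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

log = logging.getLogger("goclust.ontology")

GO_ID_RE = re.compile(r"^GO:\d{7}$")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OboParseError(ValueError):
    """Malformed OBO input; message names the offending line."""


class OntologyValidationError(ValueError):
    """Structurally invalid ontology (e.g. a cyclic is_a relation)."""


class UnknownTermError(KeyError):
    """Accession not present in the ontology (neither canonical nor alt_id)."""

    def __init__(self, acc: str):
        super().__init__(acc)
        self.accession = acc

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unknown GO accession: {self.accession}"


@dataclass(frozen=True)
class OntologyTerm:
    """One GO term as parsed from a ``[Term]`` stanza."""

    id: str
    name: str = ""
    namespace: str = "biological_process"
    parents_is_a: frozenset = frozenset()
    parents_part_of: frozenset = frozenset()
    alt_ids: frozenset = frozenset()
    obsolete: bool = False


class OntologyGraph:
    """Validated GO DAG with alt-id resolution, depth and ancestor queries.

    Parameters
    ----------
    terms:
        Mapping of canonical accession to :class:`OntologyTerm`.
    data_version:
        The ``data-version:`` header of the source OBO file, echoed into all
        output-file provenance headers.
    """

    def __init__(self, terms: dict, data_version: str | None = None):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self.data_version = data_version
        self.alt_index: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                self.alt_index[alt] = term.id
        self._depth_cache: dict[str, int] = {}
        self._validate()

    # -- construction-time validation ------------------------------------

    def _validate(self) -> None:
        cycle = self._find_is_a_cycle()
        if cycle is not None:
            raise OntologyValidationError(
                "cyclic is_a relation: " + " -> ".join(cycle)
            )
        for term in self.terms.values():
            if term.obsolete and (term.parents_is_a or term.parents_part_of):
                raise OntologyValidationError(
                    f"obsolete term {term.id} declares parents"
                )
            for p in term.parents_is_a:
                parent = self.terms.get(p)
                if parent is not None and parent.namespace != term.namespace:
                    log.warning(
                        "cross-namespace is_a edge %s (%s) -> %s (%s); edge kept",
                        term.id, term.namespace, p, parent.namespace,
                    )

    def _find_is_a_cycle(self) -> list | None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.terms}
        for start in self.terms:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(self._is_a_parents(start)))]
            color[start] = GREY
            path = [start]
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if nxt not in self.terms:
                        continue
                    if color[nxt] == GREY:
                        i = path.index(nxt)
                        return path[i:] + [nxt]
                    if color[nxt] == WHITE:
                        color[nxt] = GREY
                        stack.append((nxt, iter(self._is_a_parents(nxt))))
                        path.append(nxt)
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()
                    path.pop()
        return None

    def _is_a_parents(self, acc: str) -> Iterable:
        term = self.terms[acc]
        if term.obsolete:
            return ()
        return term.parents_is_a

    # -- queries -----------------------------------------------------------

    def __contains__(self, acc: str) -> bool:
        return acc in self.terms or acc in self.alt_index

    def resolve(self, acc: str) -> str:
        """Return the canonical accession for ``acc`` (itself, or via alt_id)."""
        if acc in self.terms:
            return acc
        if acc in self.alt_index:
            return self.alt_index[acc]
        raise UnknownTermError(acc)

    def term(self, acc: str) -> OntologyTerm:
        return self.terms[self.resolve(acc)]

    def depth(self, acc: str) -> int:
        """Shortest is_a path length from the namespace root; root depth is 0."""
        acc = self.resolve(acc)
        term = self.terms[acc]
        if term.obsolete:
            raise OntologyValidationError(f"depth undefined for obsolete term {acc}")
        if acc in self._depth_cache:
            return self._depth_cache[acc]
        # iterative post-order over the (acyclic) is_a parent relation
        stack = [acc]
        while stack:
            node = stack[-1]
            if node in self._depth_cache:
                stack.pop()
                continue
            parents = [
                p for p in self.terms[node].parents_is_a
                if p in self.terms and not self.terms[p].obsolete
            ]
            pending = [p for p in parents if p not in self._depth_cache]
            if pending:
                stack.extend(pending)
                continue
            if parents:
                self._depth_cache[node] = 1 + min(
                    self._depth_cache[p] for p in parents
                )
            else:
                self._depth_cache[node] = 0
            stack.pop()
        return self._depth_cache[acc]

    def ancestors(self, acc: str, relations: Iterable = ("is_a",)) -> set:
        """Transitive closure of parents over the selected relations.

        Does not include ``acc`` itself.  ``relations`` is any subset of
        ``{"is_a", "part_of"}``.
        """
        acc = self.resolve(acc)
        relations = frozenset(relations)
        bad = relations - {"is_a", "part_of"}
        if bad:
            raise ValueError(f"unknown relations: {sorted(bad)}")
        seen: set = set()
        frontier = [acc]
        while frontier:
            node = frontier.pop()
            term = self.terms.get(node)
            if term is None:
                continue
            parents: set = set()
            if "is_a" in relations:
                parents |= term.parents_is_a
            if "part_of" in relations:
                parents |= term.parents_part_of
            for p in parents:
                if p not in seen:
                    seen.add(p)
                    frontier.append(p)
        return seen

    def roots(self, namespace: str) -> list:
        """Non-obsolete terms of ``namespace`` with no is_a parents."""
        return sorted(
            t.id for t in self.terms.values()
            if t.namespace == namespace and not t.obsolete and not t.parents_is_a
        )


# -- module-level operation aliases (functional surface) --------------------

def resolve_id(graph: OntologyGraph, acc: str) -> str:
    return graph.resolve(acc)


def term_depth(graph: OntologyGraph, acc: str) -> int:
    return graph.depth(acc)


def ancestors(graph: OntologyGraph, acc: str, relations: Iterable = ("is_a",)) -> set:
    return graph.ancestors(acc, relations)


# -- OBO 1.2 parsing ---------------------------------------------------------

_BOOL_TRUE = {"true", "True", "TRUE", "1"}


def _strip_comment(value: str) -> str:
    # OBO trailing comments: "GO:0000001 ! term name"
    return value.split("!", 1)[0].strip()


def parse_obo_text(text: str, source: str = "<string>") -> OntologyGraph:
    """Parse OBO 1.2 flat-file *text* into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are materialized; ``[Typedef]`` and other stanza
    kinds are skipped.  Recognized tags: ``id``, ``name``, ``namespace``,
    ``is_a``, ``relationship: part_of``, ``alt_id``, ``is_obsolete``.
    """
    data_version: str | None = None
    terms: dict[str, OntologyTerm] = {}

    in_term = False
    in_header = True
    stanza_line = 0
    cur: dict | None = None

    def _flush(end_line: int) -> None:
        nonlocal cur
        if cur is None:
            return
        if "id" not in cur:
            raise OboParseError(
                f"{source}: [Term] stanza starting at line {stanza_line} has no id"
            )
        tid = cur["id"]
        if not GO_ID_RE.match(tid):
            raise OboParseError(
                f"{source}: malformed GO accession {tid!r} in stanza at line "
                f"{stanza_line} (expected GO: followed by 7 digits)"
            )
        obsolete = cur.get("obsolete", False)
        terms[tid] = OntologyTerm(
            id=tid,
            name=cur.get("name", ""),
            namespace=cur.get("namespace", "biological_process"),
            parents_is_a=frozenset() if obsolete else frozenset(cur.get("is_a", ())),
            parents_part_of=frozenset() if obsolete else frozenset(cur.get("part_of", ())),
            alt_ids=frozenset(cur.get("alt_id", ())),
            obsolete=obsolete,
        )
        cur = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            _flush(lineno)
            in_header = False
            if line == "[Term]":
                in_term = True
                stanza_line = lineno
                cur = {}
            else:
                in_term = False
            continue
        if in_header:
            if line.startswith("data-version:"):
                data_version = line.split(":", 1)[1].strip()
            continue
        if not in_term or cur is None:
            continue
        if ":" not in line:
            raise OboParseError(f"{source}: line {lineno}: not a tag-value pair: {line!r}")
        tag, value = line.split(":", 1)
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            cur["id"] = _strip_comment(value)
        elif tag == "name":
            cur["name"] = value
        elif tag == "namespace":
            cur["namespace"] = value
        elif tag == "is_a":
            cur.setdefault("is_a", []).append(_strip_comment(value))
        elif tag == "alt_id":
            cur.setdefault("alt_id", []).append(_strip_comment(value))
        elif tag == "is_obsolete":
            cur["obsolete"] = _strip_comment(value) in _BOOL_TRUE
        elif tag == "relationship":
            parts = _strip_comment(value).split()
            if len(parts) >= 2 and parts[0] == "part_of":
                cur.setdefault("part_of", []).append(parts[1])
            # other relationship typedefs (regulates, ...) are ignored
        # unrecognized tags (def, synonym, xref, ...) are ignored

    _flush(-1)
    if not terms:
        raise OboParseError(f"{source}: no [Term] stanza found")
    return OntologyGraph(terms, data_version=data_version)


def parse_obo(path) -> OntologyGraph:
    """Read an OBO 1.2 flat file from ``path``."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_obo_text(fh.read(), source=str(path))


def write_obo(graph: OntologyGraph) -> str:
    """Serialize ``graph`` back to OBO 1.2 text (round-trip stable)."""
    lines = ["format-version: 1.2"]
    if graph.data_version:
        lines.append(f"data-version: {graph.data_version}")
    lines.append("")
    for tid in sorted(graph.terms):
        t = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        if t.name:
            lines.append(f"name: {t.name}")
        lines.append(f"namespace: {t.namespace}")
        for alt in sorted(t.alt_ids):
            lines.append(f"alt_id: {alt}")
        for p in sorted(t.parents_is_a):
            lines.append(f"is_a: {p}")
        for p in sorted(t.parents_part_of):
            lines.append(f"relationship: part_of {p}")
        if t.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    return "\n".join(lines)
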