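"""Readers for GO enrichment-tool output files.

Four tool dialects (BiNGO, g:Profiler GEM, agriGO, GOrilla) plus a documented
generic TSV layout are normalized into one record type, :class:`EnrichedTerm`:
a GO accession with its (corrected, where available) enrichment p-value, the
test-set gene members annotated to the term, and the term's size ``n`` in the
reference annotation.  Gene identifiers are upper-cased and deduplicated so
that overlaps between terms survive the mixed capitalization different tools
emit; ``x`` is always recomputed as the number of distinct gene members.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace

log = logging.getLogger("goclust.enrichment")

DIALECTS = ("bingo", "gprofiler", "agrigo", "gorilla", "generic")

GENERIC_REQUIRED = ("GO_ID", "Description", "P_value", "n", "Genes")
GENERIC_OPTIONAL = ("Namespace", "x")

_AGRIGO_NS = {"P": "biological_process", "F": "molecular_function",
              "C": "cellular_component"}


class EnrichmentFormatError(ValueError):
    """Unreadable or unrecognized enrichment file / row."""


@dataclass(frozen=True)
class EnrichedTerm:
    """One normalized enrichment-result row.

    ``x`` is the number of test-set genes annotated to the term (always equal
    to ``len(genes)``); ``n`` the total genes annotated to the term in the
    reference annotation (``None`` when the source dialect does not report it).
    """

    go_id: str
    description: str
    p_value: float
    genes: frozenset
    n: int | None = None
    namespace: str = "unknown"

    @property
    def x(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class EnrichmentList:
    terms: tuple
    source_dialect: str = "generic"
    source_path: str = "<memory>"

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def by_id(self) -> dict:
        return {t.go_id: t for t in self.terms}


# -- normalization helpers ---------------------------------------------------

def normalize_genes(raw) -> frozenset:
    """Trim, upper-case and deduplicate gene identifier strings."""
    return frozenset(g.strip().upper() for g in raw if g and g.strip())


def _pad_go_id(token: str, where: str) -> str:
    token = token.strip()
    if token.upper().startswith("GO:"):
        digits = token[3:]
    else:
        digits = token
    if not digits.isdigit():
        raise EnrichmentFormatError(f"{where}: malformed GO id {token!r}")
    return "GO:%07d" % int(digits)


def _parse_p(token: str, where: str) -> float:
    try:
        p = float(token)
    except ValueError:
        raise EnrichmentFormatError(f"{where}: unparsable p-value {token!r}") from None
    if not (0.0 < p <= 1.0) or math.isnan(p):
        raise EnrichmentFormatError(f"{where}: p-value {p!r} outside (0, 1]")
    return p


def _parse_n(token: str, where: str) -> int:
    try:
        n = int(float(token))
    except ValueError:
        raise EnrichmentFormatError(f"{where}: unparsable term size n {token!r}") from None
    if n <= 0:
        raise EnrichmentFormatError(f"{where}: term size n must be positive, got {n}")
    return n


# -- dialect detection -------------------------------------------------------

def detect_dialect(path) -> str:
    """Sniff the enrichment dialect from the file's header line."""
    with open(path, "r", encoding="utf-8") as fh:
        head = [fh.readline() for _ in range(60)]
    seen_headers = []
    for line in head:
        if not line:
            break
        cols = [c.strip() for c in line.rstrip("\n").split("\t")]
        colset = set(cols)
        if cols and cols[0] == "GO-ID" and "Genes in test set" in colset:
            return "bingo"
        if set(GENERIC_REQUIRED) <= colset:
            return "generic"
        if {"GO.ID", "Genes"} <= colset and ("FDR" in colset or "p.Val" in colset):
            return "gprofiler"
        if {"GO_acc", "entries"} <= colset:
            return "agrigo"
        if {"GO Term", "FDR q-value", "Genes"} <= colset:
            return "gorilla"
        if len(cols) > 1:
            seen_headers.append(cols)
    raise EnrichmentFormatError(
        f"{path}: unrecognized enrichment layout; headers seen: "
        f"{seen_headers[:3]!r}; expected one of BiNGO ('GO-ID' ... 'Genes in "
        f"test set'), g:Profiler GEM ('GO.ID', 'Genes'), agriGO ('GO_acc', "
        f"'entries'), GOrilla ('GO Term', 'FDR q-value', 'Genes') or the "
        f"generic columns {GENERIC_REQUIRED}"
    )


# -- per-dialect row parsing -------------------------------------------------

def _rows(path):
    """Yield (lineno, fields) for non-empty TAB-separated lines."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            yield lineno, line.split("\t")


def _col_index(header, required, path):
    idx = {}
    for name in required:
        if name not in header:
            raise EnrichmentFormatError(
                f"{path}: missing required column {name!r}; found {header!r}"
            )
        idx[name] = header.index(name)
    return idx


def _read_bingo(path):
    terms = []
    header_seen = False
    idx = None
    for lineno, fields in _rows(path):
        if not header_seen:
            if fields[0].strip() == "GO-ID":
                header = [c.strip() for c in fields]
                idx = _col_index(
                    header,
                    ["GO-ID", "corr p-value", "x", "n", "Description",
                     "Genes in test set"],
                    path,
                )
                header_seen = True
            continue
        where = f"{path}:{lineno}"
        go_id = _pad_go_id(fields[idx["GO-ID"]], where)
        p = _parse_p(fields[idx["corr p-value"]], where)
        n = _parse_n(fields[idx["n"]], where)
        genes = normalize_genes(fields[idx["Genes in test set"]].split("|"))
        terms.append((lineno, EnrichedTerm(
            go_id=go_id, description=fields[idx["Description"]].strip(),
            p_value=p, n=n, genes=genes)))
    if not header_seen:
        raise EnrichmentFormatError(f"{path}: BiNGO header line 'GO-ID ...' not found")
    return terms


def _read_gprofiler(path):
    terms = []
    idx = None
    for lineno, fields in _rows(path):
        if idx is None:
            header = [c.strip() for c in fields]
            idx = _col_index(header, ["GO.ID", "Description", "FDR", "Genes"], path)
            continue
        where = f"{path}:{lineno}"
        go_id = _pad_go_id(fields[idx["GO.ID"]], where)
        p = _parse_p(fields[idx["FDR"]], where)
        genes = normalize_genes(fields[idx["Genes"]].split(","))
        terms.append((lineno, EnrichedTerm(
            go_id=go_id, description=fields[idx["Description"]].strip(),
            p_value=p, n=None, genes=genes)))
    return terms


def _read_agrigo(path):
    terms = []
    idx = None
    for lineno, fields in _rows(path):
        if idx is None:
            header = [c.strip() for c in fields]
            idx = _col_index(
                header, ["GO_acc", "term_type", "Term", "bgitem", "FDR", "entries"],
                path)
            continue
        where = f"{path}:{lineno}"
        go_id = _pad_go_id(fields[idx["GO_acc"]], where)
        p = _parse_p(fields[idx["FDR"]], where)
        n = _parse_n(fields[idx["bgitem"]], where)
        raw = []
        for chunk in fields[idx["entries"]].split("//"):
            raw.extend(chunk.split(","))
        genes = normalize_genes(raw)
        ns = _AGRIGO_NS.get(fields[idx["term_type"]].strip(), "unknown")
        terms.append((lineno, EnrichedTerm(
            go_id=go_id, description=fields[idx["Term"]].strip(),
            p_value=p, n=n, genes=genes, namespace=ns)))
    return terms


def _read_gorilla(path):
    terms = []
    idx = None
    for lineno, fields in _rows(path):
        if idx is None:
            header = [c.strip() for c in fields]
            idx = _col_index(
                header, ["GO Term", "Description", "FDR q-value", "B", "Genes"],
                path)
            continue
        where = f"{path}:{lineno}"
        go_id = _pad_go_id(fields[idx["GO Term"]], where)
        p = _parse_p(fields[idx["FDR q-value"]], where)
        n = _parse_n(fields[idx["B"]], where)
        blob = fields[idx["Genes"]].strip()
        if blob.startswith("[") and blob.endswith("]"):
            blob = blob[1:-1]
        # entries look like "GENE1 - description"; the symbol ends at the
        # first space
        raw = [entry.strip().split(" ", 1)[0] for entry in blob.split(",")]
        genes = normalize_genes(raw)
        terms.append((lineno, EnrichedTerm(
            go_id=go_id, description=fields[idx["Description"]].strip(),
            p_value=p, n=n, genes=genes)))
    return terms


def _read_generic(path):
    terms = []
    idx = None
    opt = {}
    for lineno, fields in _rows(path):
        if fields[0].startswith("#"):
            continue
        if idx is None:
            header = [c.strip() for c in fields]
            idx = _col_index(header, list(GENERIC_REQUIRED), path)
            opt = {name: header.index(name) for name in GENERIC_OPTIONAL
                   if name in header}
            continue
        where = f"{path}:{lineno}"
        go_id = _pad_go_id(fields[idx["GO_ID"]], where)
        p = _parse_p(fields[idx["P_value"]], where)
        n_raw = fields[idx["n"]].strip()
        n = _parse_n(n_raw, where) if n_raw else None
        genes = normalize_genes(fields[idx["Genes"]].split(","))
        ns = "unknown"
        if "Namespace" in opt and len(fields) > opt["Namespace"]:
            val = fields[opt["Namespace"]].strip()
            if val:
                ns = val
        terms.append((lineno, EnrichedTerm(
            go_id=go_id, description=fields[idx["Description"]].strip(),
            p_value=p, n=n, genes=genes, namespace=ns)))
    return terms


_READERS = {
    "bingo": _read_bingo,
    "gprofiler": _read_gprofiler,
    "agrigo": _read_agrigo,
    "gorilla": _read_gorilla,
    "generic": _read_generic,
}


# -- public API --------------------------------------------------------------

def read_enrichment(path, dialect: str = "auto") -> EnrichmentList:
    """Read an enrichment file into a normalized :class:`EnrichmentList`.

    With ``dialect="auto"`` the layout is sniffed from the header line.
    Duplicate GO ids within one file are collapsed to the row with the
    smaller p-value.  Rows with an empty gene list are an error: similarity
    between terms is computed from gene members, so a memberless row cannot
    participate in clustering.
    """
    if dialect == "auto":
        dialect = detect_dialect(path)
    if dialect not in _READERS:
        raise EnrichmentFormatError(
            f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    rows = _READERS[dialect](path)
    if not rows:
        raise EnrichmentFormatError(f"{path}: no data rows found")
    collected: dict[str, EnrichedTerm] = {}
    order: list[str] = []
    for lineno, term in rows:
        if not term.genes:
            raise EnrichmentFormatError(
                f"{path}:{lineno}: row for {term.go_id} has an empty gene list")
        if term.n is not None and term.x > term.n:
            raise EnrichmentFormatError(
                f"{path}:{lineno}: {term.go_id} has x={term.x} > n={term.n}")
        prev = collected.get(term.go_id)
        if prev is None:
            collected[term.go_id] = term
            order.append(term.go_id)
        else:
            keep = term if term.p_value < prev.p_value else prev
            log.warning("%s: duplicate rows for %s collapsed (kept p=%g)",
                        path, term.go_id, keep.p_value)
            collected[term.go_id] = keep
    return EnrichmentList(
        terms=tuple(collected[g] for g in order),
        source_dialect=dialect,
        source_path=str(path),
    )


def filter_namespaces(elist: EnrichmentList, graph, keep) -> EnrichmentList:
    """Keep only terms whose *ontology* namespace is in ``keep``.

    The namespace always comes from the ontology graph (after alt-id
    resolution), overriding any namespace column in the source file.  Terms
    absent from the ontology are dropped with a warning.
    """
    keep = frozenset(keep)
    if not keep:
        raise ValueError("keep must name at least one namespace")
    out = []
    for term in elist:
        try:
            oterm = graph.term(term.go_id)
        except KeyError:
            log.warning("%s not in ontology; dropped by namespace filter",
                        term.go_id)
            continue
        if oterm.namespace in keep:
            out.append(replace(term, namespace=oterm.namespace))
    return EnrichmentList(terms=tuple(out), source_dialect=elist.source_dialect,
                          source_path=elist.source_path)


def format_generic(elist: EnrichmentList) -> str:
    """Render ``elist`` in the generic TSV dialect (bit-exact, re-readable)."""
    lines = ["\t".join(list(GENERIC_REQUIRED) + ["Namespace", "x"])]
    for t in elist:
        lines.append("\t".join([
            t.go_id, t.description, "%.10g" % t.p_value,
            str(t.n) if t.n is not None else "",
            ",".join(sorted(t.genes)),
            t.namespace, str(t.x),
        ]))
    return "\n".join(lines) + "\n"


def write_generic(elist: EnrichmentList, path) -> None:
    """Write ``elist`` in the generic TSV dialect."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(format_generic(elist))
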