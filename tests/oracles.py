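"""Independent reference implementations used only to check the package.

Everything here is deliberately naive and coded without reusing goclust
internals: pure-Python list-of-lists matrix algebra for the Markov-cluster
iteration, and networkx reachability for the hierarchy reduction.
"""

from __future__ import annotations

import networkx as nx


# -- naive dense MCL ----------------------------------------------------------

def _matmul(A, B):
    n = len(A)
    out = [[0.0] * n for _ in range(n)]
    for i in range(n):
        Ai = A[i]
        for k in range(n):
            a = Ai[k]
            if a == 0.0:
                continue
            Bk = B[k]
            row = out[i]
            for j in range(n):
                row[j] += a * Bk[j]
    return out


def _normalize_columns(M):
    n = len(M)
    sums = [sum(M[i][j] for i in range(n)) for j in range(n)]
    return [[(M[i][j] / sums[j]) if sums[j] else 0.0 for j in range(n)]
            for i in range(n)]


def _inflate(M, r, prune):
    n = len(M)
    out = [[M[i][j] ** r for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(n):
            if out[i][j] < prune:
                out[i][j] = 0.0
    return _normalize_columns(out)


def mcl_reference(nodes, weighted_edges, inflation, self_loop=1.0,
                  prune=1e-5, tol=1e-6, max_iter=100):
    """Naive MCL: returns a sorted list of frozensets partitioning ``nodes``.

    ``weighted_edges`` is an iterable of (u, v, weight).  Ties in attractor
    assignment break toward the lexicographically smallest attractor.
    """
    nodes = sorted(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = [[0.0] * n for _ in range(n)]
    for u, v, w in weighted_edges:
        M[idx[u]][idx[v]] = w
        M[idx[v]][idx[u]] = w
    for i in range(n):
        M[i][i] += self_loop
    M = _normalize_columns(M)

    for _ in range(max_iter):
        new = _inflate(_matmul(M, M), inflation, prune)
        change = max(abs(new[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = new
        if change < tol:
            break

    attractors = [i for i in range(n) if M[i][i] > 1e-8]
    assignment = {}
    for j in range(n):
        claims = [(M[i][j], i) for i in attractors if M[i][j] > 0.0]
        if not claims:
            assignment[j] = -(j + 1)
            continue
        best = max(w for w, _ in claims)
        tied = sorted(i for w, i in claims if w >= best * (1 - 1e-9))
        assignment[j] = tied[0]
    groups = {}
    for j, a in assignment.items():
        groups.setdefault(a, set()).add(nodes[j])
    return sorted((frozenset(g) for g in groups.values()),
                  key=lambda c: (-len(c), min(c)))


# -- brute-force cluster hierarchy --------------------------------------------

def hierarchy_reference(graph, members, relations=("is_a",)):
    """Reachability + O(n^3) reduction via networkx; returns {(p, c): tag}."""
    D = nx.DiGraph()
    for term in graph.terms.values():
        if term.obsolete:
            continue
        D.add_node(term.id)
        parents = set()
        if "is_a" in relations:
            parents |= term.parents_is_a
        if "part_of" in relations:
            parents |= term.parents_part_of
        for p in parents:
            D.add_edge(p, term.id)  # parent -> child

    members = sorted({graph.resolve(m) for m in members
                      if m in graph and not graph.term(m).obsolete})
    mset = set(members)
    reach = {m: (nx.ancestors(D, m) & mset) if m in D else set() for m in members}

    pairs = {(p, c) for c in members for p in reach[c]}
    reduced = set()
    for p, c in pairs:
        if any(m not in (p, c) and m in reach[c] and p in reach[m] for m in mset):
            continue
        reduced.add((p, c))
    out = {}
    for p, c in reduced:
        out[(p, c)] = "direct" if D.has_edge(p, c) else "transitive"
    return out


# -- brute-force similarity network -------------------------------------------

def edge_set_reference(terms, metric, cutoff):
    """Quadratic enumeration of all intersecting pairs at/above cutoff."""
    out = {}
    terms = list(terms)
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            A, B = set(terms[i].genes), set(terms[j].genes)
            inter = len(A & B)
            if inter == 0:
                continue
            if metric == "JC":
                w = inter / len(A | B)
            else:
                w = inter / min(len(A), len(B))
            if w >= cutoff:
                key = tuple(sorted((terms[i].go_id, terms[j].go_id)))
                out[key] = w
    return out
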