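"""Brute-force reference implementations used only to check the library.

These deliberately avoid the library's algorithms: ancestor sets are
enumerated by an explicit parent walk, Wang S-values by exhaustive path
enumeration, combines by nested loops, and AUC by pairwise concordance
counting.
"""

from __future__ import annotations

import math


def ancestors_by_walk(graph, term: str) -> set[str]:
    """Ancestor closure (incl. the term) via an explicit worklist walk."""
    seen = {term}
    frontier = [term]
    while frontier:
        node = frontier.pop()
        for parent in graph.parents(node):
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return seen


def ic_by_counting(corpus, graph) -> dict[str, float]:
    """Per-term IC by recounting propagated gene sets from direct terms."""
    closures = {}
    for gene in corpus.direct:
        closure = set()
        for term in corpus.direct_terms(gene):
            closure |= ancestors_by_walk(graph, term)
        closures[gene] = closure
    root = graph.roots[corpus.aspect]
    denom = sum(1 for c in closures.values() if root in c)
    table = {}
    for term in graph.terms:
        count = sum(1 for c in closures.values() if term in c)
        if count:
            table[term] = -math.log(count / denom)
    return table


def mica_brute(t1, t2, graph, ic):
    common = ancestors_by_walk(graph, t1) & ancestors_by_walk(graph, t2)
    scored = [t for t in common if t in ic]
    if not scored:
        return graph.roots[graph.namespace(t1)]
    return min(scored, key=lambda t: (-ic.ic[t], t))


def resnik_brute(t1, t2, graph, ic):
    if t1 not in ic or t2 not in ic:
        return None
    top = max(ic.ic.values())
    if top == 0:
        return 0.0
    return ic.ic[mica_brute(t1, t2, graph, ic)] / top


def rel_brute(t1, t2, graph, ic):
    if t1 not in ic or t2 not in ic:
        return None
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0:
        return 0.0
    m = mica_brute(t1, t2, graph, ic)
    return 2 * ic.ic[m] / denom * (1 - ic.p[m])


def _all_paths_up(graph, start, target):
    """Every simple child->parent path from start to target."""
    if start == target:
        yield [start]
        return
    for parent in graph.parents(start):
        for rest in _all_paths_up(graph, parent, target):
            yield [start] + rest


def wang_svalues_brute(term, graph, weights) -> dict[str, float]:
    """S-value of each ancestor = best product of edge weights over paths."""
    table = {}
    for anc in ancestors_by_walk(graph, term):
        best = 0.0
        for path in _all_paths_up(graph, term, anc):
            product = 1.0
            for child, parent in zip(path, path[1:]):
                product *= weights.of(graph.relation(child, parent))
            best = max(best, product)
        table[anc] = best
    return table


def wang_brute(t1, t2, graph, weights):
    s1 = wang_svalues_brute(t1, graph, weights)
    s2 = wang_svalues_brute(t2, graph, weights)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    return sum(s1[t] + s2[t] for t in common) / (
        sum(s1.values()) + sum(s2.values())
    )


def term_score_brute(ta, tb, graph, ic, weights, measure):
    if measure == "resnik":
        return resnik_brute(ta, tb, graph, ic)
    if measure == "rel":
        return rel_brute(ta, tb, graph, ic)
    return wang_brute(ta, tb, graph, weights)


def gene_sim_brute(terms1, terms2, graph, ic, weights, measure, combine):
    """Exhaustive all-pairs combine over two explicit term lists."""
    if not terms1 or not terms2:
        return None
    grid = [
        [term_score_brute(ta, tb, graph, ic, weights, measure) for tb in terms2]
        for ta in terms1
    ]
    if combine == "max":
        return max(max(row) for row in grid)
    row_best = sum(max(row) for row in grid)
    col_best = sum(
        max(grid[i][j] for i in range(len(terms1)))
        for j in range(len(terms2))
    )
    return (row_best + col_best) / (len(terms1) + len(terms2))


def auc_by_concordance(scores, labels) -> float:
    """AUC as the concordant fraction of all positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = concordant = 0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total
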