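"""Semantic similarity: term-level measures and the gene similarity matrix.

Three term-level measures are provided, all mapped to [0, 1]:

* **Resnik** — IC of the most informative common ancestor (MICA),
  normalized by the corpus-wide maximum IC (raw Resnik is unbounded).
* **Relevance (Rel)** — the Schlicker measure,
  ``2·IC(MICA) / (IC(t1) + IC(t2)) · (1 − p(MICA))``: a Lin-style IC ratio
  weighted by the rarity of the shared ancestor.
* **Wang** — a purely topological measure built from semantic-contribution
  S-values that decay along is_a (weight 0.8) and part_of (weight 0.6)
  edges toward the root.

Term scores are combined to gene level over the genes' direct (filtered)
annotation term lists by either **max** (best pair overall) or **bma**
(best-match average in both directions).  A gene with no usable terms has
no similarity: the result is the ``None`` sentinel, never silently zero —
a genuine similarity of 0 and an unknown similarity must stay distinct.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from gosimpred.annotations import AnnotationCorpus, ICTable
from gosimpred.ontology import OntologyError, OntologyGraph

logger = logging.getLogger(__name__)

MEASURES = ("resnik", "rel", "wang")
COMBINES = ("max", "bma")


@dataclass(frozen=True)
class WangWeights:
    """Edge semantic-contribution factors for the Wang measure."""

    is_a: float = 0.8
    part_of: float = 0.6

    def __post_init__(self) -> None:
        for name in ("is_a", "part_of"):
            w = getattr(self, name)
            if not 0.0 < w < 1.0:
                raise ValueError(f"Wang weight {name} must be in (0, 1), got {w}")

    def of(self, relation: str) -> float:
        return getattr(self, relation)


def mica(t1: str, t2: str, graph: OntologyGraph, ic: ICTable) -> str:
    """Most informative common ancestor of two terms.

    Ancestor sets include the terms themselves.  Ties on IC are broken by
    the lexicographically smallest term id so results are reproducible.
    If no common ancestor has a defined IC, the namespace root is returned
    (IC 0 by construction).
    """
    common = graph.ancestors(t1) & graph.ancestors(t2)
    candidates = [t for t in common if t in ic]
    if not candidates:
        return graph.roots[graph.namespace(t1)]
    best_ic = max(ic.ic[t] for t in candidates)
    return min(t for t in candidates if ic.ic[t] == best_ic)


def term_sim_resnik(
    t1: str, t2: str, graph: OntologyGraph, ic: ICTable
) -> float | None:
    """Normalized Resnik similarity: IC(MICA) / max IC over the table.

    Returns ``None`` (missing) when either term has no defined IC.
    A degenerate corpus where every term has IC 0 scores 0.
    """
    if t1 not in ic or t2 not in ic:
        return None
    ic_max = ic.ic_max
    if ic_max == 0.0:
        return 0.0
    return ic.ic[mica(t1, t2, graph, ic)] / ic_max


def term_sim_rel(
    t1: str, t2: str, graph: OntologyGraph, ic: ICTable
) -> float | None:
    """Relevance (Schlicker) similarity.

    ``2·IC(m)/(IC(t1)+IC(t2)) · (1 − p(m))`` with m the MICA.  Defined as
    0 when IC(t1)+IC(t2) = 0 (both terms are the root).  Returns ``None``
    when either term lacks an IC.
    """
    if t1 not in ic or t2 not in ic:
        return None
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0.0:
        return 0.0
    m = mica(t1, t2, graph, ic)
    return (2.0 * ic.ic[m] / denom) * (1.0 - ic.p[m])


def wang_svalues(
    term: str, graph: OntologyGraph, weights: WangWeights
) -> dict[str, float]:
    """Semantic contributions of ``term``'s ancestors to ``term``.

    S(term) = 1; walking rootward, each ancestor t gets the best
    weight-decayed contribution over its children on paths toward
    ``term``: S(t) = max over children c of w(c->t) · S(c).
    """
    anc = graph.ancestors(term)
    sub = graph.graph.subgraph(anc)
    s: dict[str, float] = {term: 1.0}
    # child->parent edges: topological order visits children before parents
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child in sub.predecessors(node):
            w = weights.of(graph.relation(child, node))
            contrib = w * s.get(child, 0.0)
            if contrib > best:
                best = contrib
        s[node] = best
    return s


def term_sim_wang(
    t1: str,
    t2: str,
    graph: OntologyGraph,
    weights: WangWeights = WangWeights(),
) -> float:
    """Wang similarity: overlap of S-value profiles of the two terms."""
    if graph.namespace(t1) != graph.namespace(t2):
        raise OntologyError(
            f"Wang similarity is undefined across namespaces: "
            f"{t1} ({graph.namespace(t1)}) vs {t2} ({graph.namespace(t2)})"
        )
    s1 = wang_svalues(t1, graph, weights)
    s2 = wang_svalues(t2, graph, weights)
    common = s1.keys() & s2.keys()
    if not common:
        return 0.0
    numerator = sum(s1[t] + s2[t] for t in common)
    return numerator / (sum(s1.values()) + sum(s2.values()))


class _TermPairCache:
    """Memoizes symmetric term-pair scores for one (measure, corpus) context."""

    def __init__(self, graph, measure, ic, weights):
        self.graph = graph
        self.measure = measure
        self.ic = ic
        self.weights = weights
        self._scores: dict[tuple[str, str], float | None] = {}

    def score(self, ta: str, tb: str) -> float | None:
        key = (ta, tb) if ta <= tb else (tb, ta)
        if key not in self._scores:
            if self.measure == "resnik":
                value = term_sim_resnik(ta, tb, self.graph, self.ic)
            elif self.measure == "rel":
                value = term_sim_rel(ta, tb, self.graph, self.ic)
            elif self.measure == "wang":
                value = term_sim_wang(ta, tb, self.graph, self.weights)
            else:
                raise ValueError(f"unknown measure: {self.measure!r}")
            self._scores[key] = value
        return self._scores[key]


def usable_terms(
    gene: str,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    measure: str,
    ic: ICTable | None,
) -> list[str]:
    """The gene's direct terms that the measure can actually score.

    IC-based measures require a defined IC (zero-frequency terms are
    unusable); Wang only needs graph membership.  Sorted for determinism.
    """
    terms = corpus.direct_terms(gene)
    if measure in ("resnik", "rel"):
        if ic is None:
            raise ValueError(f"measure {measure!r} requires an ICTable")
        return sorted(t for t in terms if t in ic)
    return sorted(t for t in terms if t in graph)


def gene_sim(
    g1: str,
    g2: str,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    measure: str = "resnik",
    combine: str = "max",
    ic: ICTable | None = None,
    weights: WangWeights = WangWeights(),
    _cache: _TermPairCache | None = None,
) -> float | None:
    """Gene-level functional similarity from all term pairs.

    * ``max``: the maximum term-pair score over the two term lists.
    * ``bma``: best-match average,
      ``(Σ_i max_j s_ij + Σ_j max_i s_ij) / (m + n)``.

    Returns ``None`` (missing similarity) when either gene has no usable
    annotation term.  Term lists are the direct, post-filter annotations;
    propagation serves only IC and MICA computation.
    """
    if combine not in COMBINES:
        raise ValueError(f"unknown combine: {combine!r}")
    terms1 = usable_terms(g1, corpus, graph, measure, ic)
    terms2 = usable_terms(g2, corpus, graph, measure, ic)
    if not terms1 or not terms2:
        return None
    cache = _cache or _TermPairCache(graph, measure, ic, weights)
    scores = np.empty((len(terms1), len(terms2)))
    for i, ta in enumerate(terms1):
        for j, tb in enumerate(terms2):
            scores[i, j] = cache.score(ta, tb)
    if combine == "max":
        return float(scores.max())
    m, n = scores.shape
    return float((scores.max(axis=1).sum() + scores.max(axis=0).sum()) / (m + n))


@dataclass
class GeneSimilarityMatrix:
    """Square symmetric matrix of gene functional similarities in [0, 1].

    ``excluded_genes`` lists input genes dropped before computation for
    lack of usable annotations — excluded, never imputed as similarity 0.
    """

    genes: list[str]
    values: np.ndarray
    measure: str
    combine: str
    excluded_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.genes)):
            raise ValueError("matrix shape does not match gene list length")

    def index_of(self, gene: str) -> int:
        return self.genes.index(gene)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)

    # -- persistence -------------------------------------------------------

    def to_tsv(self, path: str, sidecar: dict | None = None) -> None:
        """Write the matrix as TSV plus a JSON metadata sidecar."""
        with open(path, "w") as handle:
            handle.write("gene_id\t" + "\t".join(self.genes) + "\n")
            for gene, row in zip(self.genes, self.values):
                handle.write(
                    gene + "\t" + "\t".join(format(v, ".12g") for v in row) + "\n"
                )
        meta = {
            "measure": self.measure,
            "combine": self.combine,
            "excluded_genes": list(self.excluded_genes),
            "n_genes": len(self.genes),
        }
        if sidecar:
            meta.update(sidecar)
        with open(str(path) + ".json", "w") as handle:
            json.dump(meta, handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_tsv(cls, path: str) -> "GeneSimilarityMatrix":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t", index_col=0)
        meta: dict = {}
        try:
            with open(str(path) + ".json") as handle:
                meta = json.load(handle)
        except FileNotFoundError:
            logger.warning("no metadata sidecar next to %s", path)
        return cls(
            genes=list(frame.index),
            values=frame.to_numpy(),
            measure=meta.get("measure", "unknown"),
            combine=meta.get("combine", "unknown"),
            excluded_genes=meta.get("excluded_genes", []),
        )


def build_matrix(
    genes: Sequence[str],
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    measure: str = "resnik",
    combine: str = "max",
    ic: ICTable | None = None,
    weights: WangWeights = WangWeights(),
) -> GeneSimilarityMatrix:
    """Build the square gene functional-similarity matrix.

    Genes with no usable annotation terms (absent from the corpus, empty
    after filtering, or all terms unscorable under the measure) are moved
    to ``excluded_genes`` before any pairwise computation.  Each pair is
    computed once and mirrored, so the matrix is symmetric by
    construction.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure: {measure!r}")
    seen = set()
    ordered = [g for g in genes if not (g in seen or seen.add(g))]
    kept, excluded = [], []
    for gene in ordered:
        if gene in corpus and usable_terms(gene, corpus, graph, measure, ic):
            kept.append(gene)
        else:
            excluded.append(gene)
    if excluded:
        logger.warning(
            "excluding %d/%d genes with no usable annotations: %s",
            len(excluded), len(ordered), ", ".join(excluded[:10])
            + ("..." if len(excluded) > 10 else ""),
        )
    if len(kept) < 2:
        raise ValueError(
            f"need at least 2 genes with usable annotations, have {len(kept)}"
        )

    cache = _TermPairCache(graph, measure, ic, weights)
    n = len(kept)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            score = gene_sim(
                kept[i], kept[j], corpus, graph,
                measure=measure, combine=combine, ic=ic, weights=weights,
                _cache=cache,
            )
            assert score is not None  # kept genes all have usable terms
            values[i, j] = values[j, i] = score
    return GeneSimilarityMatrix(
        genes=kept, values=values, measure=measure, combine=combine,
        excluded_genes=excluded,
    )
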