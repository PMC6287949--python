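"""Annotation corpora: GAF/TSV loading, filtering, propagation, information content.

A corpus holds one aspect only (biological process by default).  Evidence
filtering drops electronically inferred annotations (IEA) by default, since
they are unreviewed.  Propagation applies the true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor of that term
along is_a and part_of edges.  Information content of a term is the
negative natural log of the fraction of corpus genes annotated (after
propagation) to it.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from gosimpred.ontology import ASPECTS, OntologyGraph

logger = logging.getLogger(__name__)

#: Evidence codes excluded by default ("inferred from electronic annotation").
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA"})

_GAF_ASPECT = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}
_ASPECT_ALIASES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
    **_GAF_ASPECT,
    **{a: a for a in ASPECTS},
}


class AnnotationError(ValueError):
    """Raised on malformed annotation input in strict mode."""


def normalize_aspect(label: str) -> str:
    try:
        return _ASPECT_ALIASES[label.strip()]
    except KeyError:
        raise AnnotationError(f"unknown aspect label: {label!r}") from None


@dataclass
class AnnotationCorpus:
    """Gene -> GO term annotation sets for a single aspect.

    ``direct`` stores the filtered annotations exactly as loaded, as
    ``(term, evidence_code)`` pairs.  ``propagated`` stores the ancestor
    closure of the direct terms and is empty until
    :func:`propagate_annotations` runs.  Genes whose rows were all filtered
    out remain present with an empty direct set so that downstream
    exclusion reporting can name them.
    """

    aspect: str
    direct: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    propagated: dict[str, set[str]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.direct)

    def __contains__(self, gene: str) -> bool:
        return gene in self.direct

    def direct_terms(self, gene: str) -> set[str]:
        """Terms directly annotated to ``gene`` (after filtering)."""
        return {term for term, _ in self.direct.get(gene, set())}

    def add(self, gene: str, term: str, evidence: str) -> None:
        self.direct.setdefault(gene, set()).add((term, evidence))

    def register(self, gene: str) -> None:
        """Ensure ``gene`` exists in the corpus, possibly with no terms."""
        self.direct.setdefault(gene, set())


def load_annotations(
    path: str,
    graph: OntologyGraph,
    exclude_evidence: Iterable[str] = DEFAULT_EXCLUDED_EVIDENCE,
    aspect: str = "biological_process",
    fmt: str | None = None,
    strict: bool = False,
) -> AnnotationCorpus:
    """Load gene->term annotations from a GAF 2.x or 4-column TSV file.

    Rows are dropped (never the whole file) when they carry an excluded
    evidence code, belong to a different aspect, or reference a term absent
    from the ontology (logged as a warning).  Alternate term ids are mapped
    to their primary id.  GAF rows whose qualifier contains ``NOT`` are
    negated annotations and are skipped.

    Parameters
    ----------
    fmt : {"gaf", "tsv", None}
        ``None`` auto-detects: a ``!gaf-version`` header or ``.gaf``
        extension selects GAF, anything else the TSV dialect with header
        ``gene_id  term_id  evidence_code  aspect``.
    strict : bool
        If True, malformed rows raise :class:`AnnotationError` instead of
        being skipped with a warning.
    """
    aspect = normalize_aspect(aspect)
    exclude = {code.upper() for code in exclude_evidence}
    if aspect not in set(graph.roots):
        raise AnnotationError(
            f"aspect {aspect!r} not present in ontology "
            f"(namespaces: {sorted(graph.roots)})"
        )

    with open(path) as handle:
        first = handle.readline()
        handle.seek(0)
        if fmt is None:
            if first.startswith("!gaf") or str(path).endswith(".gaf"):
                fmt = "gaf"
            else:
                fmt = "tsv"
        if fmt == "gaf":
            rows = _iter_gaf(handle, strict)
        elif fmt == "tsv":
            rows = _iter_tsv(handle, strict)
        else:
            raise AnnotationError(f"unknown annotation format: {fmt!r}")

        corpus = AnnotationCorpus(aspect=aspect)
        counts = Counter()
        for gene, term, evidence, row_aspect in rows:
            corpus.register(gene)
            counts["rows"] += 1
            if evidence.upper() in exclude:
                counts[f"evidence:{evidence.upper()}"] += 1
                continue
            if normalize_aspect(row_aspect) != aspect:
                counts["other_aspect"] += 1
                continue
            term = graph.resolve(term)
            if term not in graph:
                counts["unknown_term"] += 1
                logger.warning(
                    "dropping annotation %s -> %s: term not in ontology",
                    gene, term,
                )
                continue
            corpus.add(gene, term, evidence.upper())

    logger.info(
        "loaded %d genes from %s; %d rows read, %d dropped for evidence, "
        "%d other-aspect, %d unknown-term",
        len(corpus.direct), path, counts["rows"],
        sum(v for k, v in counts.items() if k.startswith("evidence:")),
        counts["other_aspect"], counts["unknown_term"],
    )
    return corpus


def _iter_gaf(handle, strict: bool):
    for lineno, line in enumerate(handle, 1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 15:
            _malformed(lineno, line, strict)
            continue
        qualifier = cols[3]
        if "NOT" in qualifier.split("|"):
            continue
        # GAF columns: 2 = DB object id, 5 = GO id, 7 = evidence, 9 = aspect
        yield cols[1], cols[4], cols[6], cols[8]


def _iter_tsv(handle, strict: bool):
    header = handle.readline().rstrip("\n").split("\t")
    expected = ["gene_id", "term_id", "evidence_code", "aspect"]
    if [h.strip() for h in header[:4]] != expected:
        raise AnnotationError(
            f"TSV annotation file must start with header {expected}, got {header}"
        )
    for lineno, line in enumerate(handle, 2):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 4 or not all(c.strip() for c in cols[:4]):
            _malformed(lineno, line, strict)
            continue
        yield cols[0], cols[1], cols[2], cols[3]


def _malformed(lineno: int, line: str, strict: bool) -> None:
    message = f"malformed annotation row at line {lineno}: {line.rstrip()!r}"
    if strict:
        raise AnnotationError(message)
    logger.warning("%s (skipped)", message)


def propagate_annotations(
    corpus: AnnotationCorpus, graph: OntologyGraph
) -> AnnotationCorpus:
    """Apply the true-path rule: fill ``propagated`` with ancestor closures.

    Idempotent; returns the corpus (mutated in place) for chaining.
    Raises ``KeyError`` if a direct term is absent from the graph — such
    rows should have been dropped at load time.
    """
    cache: dict[str, set[str]] = {}
    for gene, pairs in corpus.direct.items():
        closure: set[str] = set()
        for term, _ in pairs:
            if term not in graph:
                raise KeyError(
                    f"annotation term {term} for gene {gene} is not in the ontology"
                )
            if term not in cache:
                cache[term] = graph.ancestors(term, include_self=True)
            closure |= cache[term]
        corpus.propagated[gene] = closure
    return corpus


@dataclass
class ICTable:
    """Per-term information content over an annotation corpus.

    ``p`` maps each term to the fraction of corpus genes whose propagated
    annotation set contains it (denominator: genes annotated to the
    namespace root, i.e. all genes with at least one annotation).  ``ic``
    is ``-ln p`` in natural-log units.  Terms covering zero genes are
    absent from the table.
    """

    ic: dict[str, float]
    p: dict[str, float]
    corpus_size: int
    root: str

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __len__(self) -> int:
        return len(self.ic)

    @property
    def ic_max(self) -> float:
        return max(self.ic.values())


def compute_ic(
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    background: Iterable[str] | None = None,
) -> ICTable:
    """Information content IC(c) = -ln p(c) over the propagated corpus.

    p(c) is gene-based: the number of genes whose propagated set contains
    c, divided by the number of genes whose propagated set contains the
    namespace root.  By the true-path rule every gene with at least one
    annotation is annotated to the root, so IC(root) = 0 and p is
    monotonically non-increasing from root to leaves.

    Parameters
    ----------
    background : iterable of gene ids, optional
        Restrict the corpus to these genes (e.g. an external background
        population).  Default: every gene in the corpus.
    """
    if not corpus.propagated:
        raise ValueError("corpus has no propagated annotations; propagate first")
    genes = corpus.propagated.keys()
    if background is not None:
        background = set(background)
        genes = [g for g in genes if g in background]

    counts: Counter[str] = Counter()
    for gene in genes:
        counts.update(corpus.propagated[gene])
    root = graph.roots[corpus.aspect]
    denominator = counts.get(root, 0)
    if denominator == 0:
        raise ValueError(
            "no gene in the corpus has any propagated annotation; "
            "cannot define term usage probabilities"
        )
    p = {term: count / denominator for term, count in counts.items()}
    ic = {term: -math.log(prob) for term, prob in p.items()}
    logger.info(
        "information content over %d genes: %d terms, max IC %.4f",
        denominator, len(ic), max(ic.values()),
    )
    return ICTable(ic=ic, p=p, corpus_size=denominator, root=root)


# -- writers ---------------------------------------------------------------

def write_annotations_tsv(corpus: AnnotationCorpus, path: str) -> None:
    """Write direct annotations in the 4-column TSV dialect (round-trippable)."""
    short = {"biological_process": "BP", "molecular_function": "MF",
             "cellular_component": "CC"}[corpus.aspect]
    with open(path, "w") as handle:
        handle.write("gene_id\tterm_id\tevidence_code\taspect\n")
        for gene in sorted(corpus.direct):
            for term, evidence in sorted(corpus.direct[gene]):
                handle.write(f"{gene}\t{term}\t{evidence}\t{short}\n")


def write_propagated_tsv(corpus: AnnotationCorpus, path: str) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tterm_id\n")
        for gene in sorted(corpus.propagated):
            for term in sorted(corpus.propagated[gene]):
                handle.write(f"{gene}\t{term}\n")
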