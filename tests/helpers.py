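"""Random-DAG and random-corpus builders shared across test modules."""

from __future__ import annotations

import io

import numpy as np

from gosimpred.annotations import AnnotationCorpus, compute_ic, propagate_annotations
from gosimpred.ontology import load_obo


def random_dag(rng: np.random.Generator, n_terms: int = 20,
               part_of_fraction: float = 0.3):
    """A random single-rooted DAG, loaded through the OBO parser.

    Term i > 0 gets one or two parents drawn from earlier terms, so the
    graph is acyclic by construction and every term reaches the root.
    """
    lines = ["format-version: 1.2",
             "default-namespace: biological_process",
             "ontology: random", ""]
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    for i, term in enumerate(ids):
        lines += ["[Term]", f"id: {term}", f"name: t{i}"]
        if i > 0:
            n_parents = 1 + int(rng.random() < 0.4 and i > 1)
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in parents:
                if rng.random() < part_of_fraction:
                    lines.append(f"relationship: part_of {ids[p]}")
                else:
                    lines.append(f"is_a: {ids[p]}")
        lines.append("")
    return load_obo(io.StringIO("\n".join(lines)))


def random_corpus(rng: np.random.Generator, graph, n_genes: int = 20,
                  max_terms: int = 4):
    """Random direct annotations over a graph, propagated, with IC."""
    terms = sorted(graph.terms)
    corpus = AnnotationCorpus(aspect="biological_process")
    for i in range(n_genes):
        gene = f"g{i:03d}"
        n = int(rng.integers(1, max_terms + 1))
        for t in rng.choice(terms, size=n, replace=False):
            corpus.add(gene, str(t), "EXP")
    propagate_annotations(corpus, graph)
    ic = compute_ic(corpus, graph)
    return corpus, ic
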