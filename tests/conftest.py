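"""Shared fixtures: tiny hand-written ontologies and random DAG corpora."""

from __future__ import annotations

import io

import pytest

from gosimpred.annotations import compute_ic, propagate_annotations
from gosimpred.ontology import load_obo
from gosimpred.synthetic import SyntheticConfig, generate_dataset

CHAIN_OBO = """format-version: 1.2
default-namespace: biological_process
ontology: test

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: B
is_a: GO:0000001

[Term]
id: GO:0000003
name: A
alt_id: GO:0000099
is_a: GO:0000002

[Term]
id: GO:0000004
name: sibling of A
is_a: GO:0000002

[Term]
id: GO:0000005
name: part of B
relationship: part_of GO:0000002

[Term]
id: GO:0000006
name: gone
is_obsolete: true
"""


@pytest.fixture
def chain_graph():
    """Root <- B <- {A (alt GO:0000099), sibling, part-of child}."""
    return load_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free planted-signal dataset: the signal-recovery condition."""
    return generate_dataset(SyntheticConfig(noise=0.0, seed=20))


@pytest.fixture(scope="session")
def clean_matrix(clean_dataset):
    """Resnik/max similarity matrix over the noise-free dataset."""
    from gosimpred.semsim import build_matrix

    ds = clean_dataset
    propagate_annotations(ds.corpus, ds.ontology.graph)
    ic = compute_ic(ds.corpus, ds.ontology.graph)
    matrix = build_matrix(
        ds.labels.genes, ds.corpus, ds.ontology.graph,
        measure="resnik", combine="max", ic=ic,
    )
    return matrix, ds.labels
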