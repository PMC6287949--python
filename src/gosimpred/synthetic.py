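"""Synthetic ontologies and annotation corpora with planted functional signal.

The generator emulates the structure the pipeline exploits in real data:
an ontology DAG with several disjoint functional branches under one root,
disease genes preferentially annotated to one "signature" branch and
non-disease genes to the others.  The annotation-noise rate is the
probability that any single term is drawn from a non-signature branch, so
at noise 0 the two classes occupy disjoint parts of the DAG and at noise
near 1 the planted signal disappears.  A configurable fraction of genes is
emitted with no annotations at all, to exercise the missing-annotation
exclusion path, and a fraction of annotation rows can carry the IEA
evidence code to exercise evidence filtering.

Everything is generated to real OBO / GAF / TSV files so that the parsers
are exercised end to end, and every artifact is byte-deterministic given
the config seed.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gosimpred.annotations import AnnotationCorpus
from gosimpred.classify import LabeledGeneSet
from gosimpred.ontology import OntologyGraph, load_obo

logger = logging.getLogger(__name__)

_NAMESPACE = "biological_process"


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    The ontology is one root plus ``n_branches`` disjoint subtrees, each a
    complete ``branching_factor``-ary tree of ``depth`` levels, edges
    typed part_of with probability ``part_of_fraction`` (else is_a).
    Positives sign on branch 1; each negative gets a home branch among the
    others.  ``noise`` is the per-term probability of drawing from a
    non-home branch.  ``ld_fraction`` of the positives are labeled LD
    (low-confidence) and annotate at twice the noise rate, HD genes at
    half, mirroring the difference between strongly and weakly evidenced
    disease genes.
    """

    n_branches: int = 2
    depth: int = 3
    branching_factor: int = 2
    part_of_fraction: float = 0.2
    n_pos: int = 40
    n_neg: int = 120
    n_candidates: int = 20
    terms_per_gene: tuple[int, int] = (2, 5)
    noise: float = 0.1
    missing_fraction: float = 0.0
    iea_fraction: float = 0.0
    ld_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 2 or self.depth < 2 or self.branching_factor < 1:
            raise ValueError("need n_branches >= 2, depth >= 2, branching >= 1")
        if min(self.n_pos, self.n_neg) < 1:
            raise ValueError("gene counts must be positive")
        for name in ("part_of_fraction", "noise", "missing_fraction",
                     "iea_fraction", "ld_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.terms_per_gene
        if not 1 <= lo <= hi:
            raise ValueError(f"bad terms_per_gene range: {self.terms_per_gene}")


@dataclass
class SyntheticOntology:
    """A generated ontology plus its branch structure and OBO serialization."""

    graph: OntologyGraph
    root: str
    branch_terms: list[list[str]]
    obo_text: str


def generate_ontology(config: SyntheticConfig) -> SyntheticOntology:
    """Build the branched DAG, serialize it to OBO, and re-parse it.

    Parsing the serialized text (rather than wiring a graph directly)
    guarantees the on-disk and in-memory representations agree and runs
    the OBO reader in every end-to-end test.  Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    counter = 1
    root = f"GO:{counter:07d}"
    counter += 1
    stanzas = [_stanza(root, "synthetic root", [])]
    branch_terms: list[list[str]] = []
    for branch in range(config.n_branches):
        terms: list[str] = []
        previous = [root]
        for level in range(1, config.depth + 1):
            current = []
            for parent_idx in range(len(previous)):
                for _ in range(config.branching_factor):
                    term = f"GO:{counter:07d}"
                    counter += 1
                    relation = (
                        "part_of"
                        if rng.random() < config.part_of_fraction
                        else "is_a"
                    )
                    stanzas.append(_stanza(
                        term,
                        f"branch {branch + 1} level {level} term",
                        [(relation, previous[parent_idx])],
                    ))
                    current.append(term)
            terms.extend(current)
            previous = current
        branch_terms.append(terms)
    header = (
        "format-version: 1.2\n"
        f"default-namespace: {_NAMESPACE}\n"
        "ontology: synthetic\n"
    )
    obo_text = header + "\n" + "\n".join(stanzas)
    graph = load_obo(io.StringIO(obo_text))
    return SyntheticOntology(
        graph=graph, root=root, branch_terms=branch_terms, obo_text=obo_text
    )


def _stanza(term: str, name: str, parents: list[tuple[str, str]]) -> str:
    lines = ["[Term]", f"id: {term}", f"name: {name}", f"namespace: {_NAMESPACE}"]
    for relation, parent in parents:
        if relation == "is_a":
            lines.append(f"is_a: {parent}")
        else:
            lines.append(f"relationship: {relation} {parent}")
    return "\n".join(lines) + "\n"


@dataclass
class SyntheticDataset:
    """A full synthetic study: ontology, corpus, labels, candidates."""

    ontology: SyntheticOntology
    corpus: AnnotationCorpus
    labels: LabeledGeneSet
    candidates: list[str]
    candidate_branch: dict[str, int]
    gene_branch: dict[str, int]
    config: SyntheticConfig


def generate_gene_sets(
    ontology: SyntheticOntology, config: SyntheticConfig
) -> SyntheticDataset:
    """Plant class-specific annotation signal on labeled genes.

    Positive genes draw each term from branch 1 with probability
    1 - noise, otherwise uniformly from the other branches; negatives do
    the same around a home branch drawn from branches 2..n.  HD positives
    use an effective noise of ``noise/2`` and LD positives ``2*noise``
    (capped at 1).  ``missing_fraction`` of each class is emitted with an
    empty annotation set.  Candidates (unlabeled) are generated the same
    way, half signing on branch 1 and half elsewhere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    corpus = AnnotationCorpus(aspect=_NAMESPACE)
    classes: dict[str, str] = {}
    gene_branch: dict[str, int] = {}

    n_ld = round(config.ld_fraction * config.n_pos)
    pos_ids = [f"P{i:04d}" for i in range(1, config.n_pos + 1)]
    neg_ids = [f"N{i:04d}" for i in range(1, config.n_neg + 1)]
    for i, gene in enumerate(pos_ids):
        classes[gene] = "LD" if i >= config.n_pos - n_ld else "HD"
    for gene in neg_ids:
        classes[gene] = "negative"

    missing = set()
    for ids in (pos_ids, neg_ids):
        n_missing = round(config.missing_fraction * len(ids))
        if n_missing:
            missing.update(rng.choice(ids, size=n_missing, replace=False))

    def annotate(gene: str, home: int, eff_noise: float) -> None:
        corpus.register(gene)
        gene_branch[gene] = home
        if gene in missing:
            return
        lo, hi = config.terms_per_gene
        n_terms = int(rng.integers(lo, hi + 1))
        others = [b for b in range(config.n_branches) if b != home]
        for _ in range(n_terms):
            branch = (
                others[int(rng.integers(len(others)))]
                if rng.random() < eff_noise
                else home
            )
            pool = ontology.branch_terms[branch]
            term = pool[int(rng.integers(len(pool)))]
            evidence = "IEA" if rng.random() < config.iea_fraction else "EXP"
            corpus.add(gene, term, evidence)

    for gene in pos_ids:
        eff = (
            min(1.0, 2.0 * config.noise)
            if classes[gene] == "LD"
            else config.noise / 2.0
        )
        annotate(gene, home=0, eff_noise=eff)
    for gene in neg_ids:
        home = 1 + int(rng.integers(config.n_branches - 1))
        annotate(gene, home=home, eff_noise=config.noise)

    candidates: list[str] = []
    candidate_branch: dict[str, int] = {}
    n_signature = (config.n_candidates + 1) // 2
    for i in range(1, config.n_candidates + 1):
        cand = f"C{i:04d}"
        home = 0 if i <= n_signature else 1 + int(
            rng.integers(config.n_branches - 1)
        )
        candidates.append(cand)
        candidate_branch[cand] = home
        annotate(cand, home=home, eff_noise=config.noise)

    labels = LabeledGeneSet(classes)
    logger.info(
        "synthetic gene sets: %d positives (%d LD), %d negatives, "
        "%d candidates, %d genes without annotations",
        config.n_pos, n_ld, config.n_neg, config.n_candidates, len(missing),
    )
    return SyntheticDataset(
        ontology=ontology, corpus=corpus, labels=labels,
        candidates=candidates, candidate_branch=candidate_branch,
        gene_branch=gene_branch, config=config,
    )


def generate_dataset(
    config: SyntheticConfig | None = None, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a complete dataset; optionally write all files to ``outdir``."""
    config = config or SyntheticConfig()
    dataset = generate_gene_sets(generate_ontology(config), config)
    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write ontology.obo, annotations.gaf/.tsv, labels.tsv, candidates.tsv
    and a manifest.json recording the full config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
        "tsv": outdir / "annotations.tsv",
        "labels": outdir / "labels.tsv",
        "candidates": outdir / "candidates.tsv",
        "manifest": outdir / "manifest.json",
    }
    paths["ontology"].write_text(dataset.ontology.obo_text)
    _write_gaf(dataset.corpus, paths["gaf"])
    _write_tsv(dataset.corpus, paths["tsv"])
    dataset.labels.to_tsv(paths["labels"])
    with open(paths["candidates"], "w") as handle:
        handle.write("gene_id\n")
        for cand in dataset.candidates:
            handle.write(cand + "\n")
    manifest = {
        "config": dataclasses.asdict(dataset.config),
        "candidate_branch": dataset.candidate_branch,
        "n_terms": len(dataset.ontology.graph),
    }
    with open(paths["manifest"], "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return paths


def _write_gaf(corpus: AnnotationCorpus, path: Path) -> None:
    lines = ["!gaf-version: 2.2"]
    for gene in corpus.direct:  # genes with no rows are simply absent
        for term, evidence in sorted(corpus.direct[gene]):
            cols = [
                "SYNT", gene, gene, "", term, "SYNT_REF:0000001", evidence,
                "", "P", gene, "", "protein", "taxon:0", "20260101", "SYNT",
                "", "",
            ]
            lines.append("\t".join(cols))
    path.write_text("\n".join(lines) + "\n")


def _write_tsv(corpus: AnnotationCorpus, path: Path) -> None:
    lines = ["gene_id\tterm_id\tevidence_code\taspect"]
    for gene in corpus.direct:
        for term, evidence in sorted(corpus.direct[gene]):
            lines.append(f"{gene}\t{term}\t{evidence}\tBP")
    path.write_text("\n".join(lines) + "\n")


def permute_labels(labels: LabeledGeneSet, seed: int) -> LabeledGeneSet:
    """Shuffle class assignments among genes, preserving the class multiset.

    The null-model utility: any genuine annotation signal is destroyed
    while every marginal property of the label set is retained.
    """
    if not labels.classes:
        raise ValueError("cannot permute an empty label set")
    genes = labels.genes
    values = [labels.classes[g] for g in genes]
    rng = np.random.default_rng(seed)
    permuted = [values[i] for i in rng.permutation(len(values))]
    return LabeledGeneSet(dict(zip(genes, permuted)))
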