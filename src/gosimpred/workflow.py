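"""Pipeline orchestration: input -> similarity matrix -> classifier -> output.

Each runner chains the library stages, writes TSV outputs with headers,
and drops a ``manifest.json`` (full configuration, master seed, SHA-256 of
every input file, package version) sufficient to reproduce the run
bit-for-bit.  Filter counts — genes in, genes excluded for missing
annotations, rows dropped per evidence code or aspect — are logged at each
stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import gosimpred
from gosimpred.annotations import (
    compute_ic,
    load_annotations,
    propagate_annotations,
)
from gosimpred.classify import (
    ClassifierConfig,
    LabeledGeneSet,
    METHODS,
    evaluate_cv,
)
from gosimpred.model import DiseaseGeneModel
from gosimpred.ontology import load_obo
from gosimpred.semsim import (
    GeneSimilarityMatrix,
    MEASURES,
    WangWeights,
    build_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration shared by the pipeline runners.

    Values can come from a YAML/JSON file and be overridden field-by-field
    (command-line flags win over the file).
    """

    ontology: str | None = None
    annotations: str | None = None
    labels: str | None = None
    candidates: str | None = None
    matrix: str | None = None
    measure: str = "resnik"
    combine: str = "max"
    method: str = "rf"
    scheme: str = "stratified"
    k: int = 5
    repeats: int = 1
    undersample: bool = False
    undersample_perc: float = 30.0
    evidence_exclude: tuple[str, ...] = ("IEA",)
    aspect: str = "biological_process"
    background: str | None = None
    wang_w_is_a: float = 0.8
    wang_w_part_of: float = 0.6
    seed: int = 0
    outdir: str = "gosimpred_out"

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        if self.method != "all" and self.method not in METHODS:
            raise ValueError(f"method must be 'all' or one of {METHODS}")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "evidence_exclude" in data and not isinstance(
            data["evidence_exclude"], tuple
        ):
            data["evidence_exclude"] = tuple(data["evidence_exclude"])
        return cls(**data)

    def require(self, *fields_: str) -> None:
        missing = [f for f in fields_ if getattr(self, f) is None]
        if missing:
            raise ValueError(f"configuration is missing: {', '.join(missing)}")


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(outdir: Path, config: RunConfig, stage: str,
                   extra: dict | None = None) -> Path:
    inputs = {}
    for name in ("ontology", "annotations", "labels", "candidates", "matrix"):
        path = getattr(config, name)
        if path and Path(path).exists():
            inputs[name] = {"path": str(path), "sha256": _sha256(path)}
    manifest = {
        "stage": stage,
        "config": dataclasses.asdict(config),
        "inputs": inputs,
        "version": gosimpred.__version__,
    }
    if extra:
        manifest.update(extra)
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
    return path


def load_inputs(config: RunConfig):
    """Parse ontology + annotations, propagate, and (if needed) compute IC.

    The Wang measure is purely topological, so the IC table is computed
    only for the IC-based measures.  The IC corpus is every gene in the
    annotation file, optionally restricted to a background gene list.
    """
    config.require("ontology", "annotations")
    graph = load_obo(config.ontology)
    corpus = load_annotations(
        config.annotations, graph,
        exclude_evidence=config.evidence_exclude, aspect=config.aspect,
    )
    propagate_annotations(corpus, graph)
    ic = None
    if config.measure in ("resnik", "rel"):
        background = None
        if config.background:
            background = [
                line.strip() for line in open(config.background)
                if line.strip() and not line.startswith("#")
            ]
        ic = compute_ic(corpus, graph, background=background)
    return graph, corpus, ic


def run_build_matrix(config: RunConfig) -> dict[str, Path]:
    """Input + functional-similarity layers: write the matrix TSV + sidecar."""
    config.require("labels")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, corpus, ic = load_inputs(config)
    labels = LabeledGeneSet.from_tsv(config.labels)
    weights = WangWeights(config.wang_w_is_a, config.wang_w_part_of)
    matrix = build_matrix(
        labels.genes, corpus, graph,
        measure=config.measure, combine=config.combine, ic=ic, weights=weights,
    )
    logger.info(
        "matrix built: %d genes kept, %d excluded for missing annotations",
        len(matrix.genes), len(matrix.excluded_genes),
    )
    matrix_path = outdir / f"matrix_{config.measure}_{config.combine}.tsv"
    matrix.to_tsv(matrix_path, sidecar={
        "aspect": config.aspect,
        "evidence_exclude": list(config.evidence_exclude),
    })
    manifest = write_manifest(outdir, config, "build_matrix", {
        "n_genes": len(matrix.genes),
        "excluded_genes": matrix.excluded_genes,
    })
    return {"matrix": matrix_path, "manifest": manifest}


def run_crossvalidate(config: RunConfig,
                      matrices: list[str] | None = None) -> dict[str, Path]:
    """Classifier + output layers: per-fold AUC table and summary TSVs.

    ``matrices`` may list several matrix files (e.g. one per measure);
    with ``method="all"`` every classifier runs on every matrix, giving a
    measure x method summary table.
    """
    config.require("labels")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if matrices is None:
        config.require("matrix")
        matrices = [config.matrix]
    labels = LabeledGeneSet.from_tsv(config.labels)
    methods = list(METHODS) if config.method == "all" else [config.method]
    perc = config.undersample_perc if config.undersample else None

    fold_frames, summary_rows = [], []
    for matrix_path in matrices:
        matrix = GeneSimilarityMatrix.from_tsv(matrix_path)
        if config.scheme == "heldout_restricted" and not any(
            labels.class_of(g) == "LD" for g in matrix.genes
        ):
            raise ValueError(
                "scheme heldout_restricted requires LD genes in the labels; "
                "none found among the matrix genes"
            )
        for method in methods:
            result = evaluate_cv(
                matrix, labels, ClassifierConfig(method=method),
                scheme=config.scheme, k=config.k, repeats=config.repeats,
                undersample_perc=perc, seed=config.seed,
            )
            frame = result.to_frame()
            frame.insert(0, "measure", matrix.measure)
            fold_frames.append(frame)
            summary_rows.append({
                "measure": matrix.measure,
                "combine": matrix.combine,
                "method": method,
                "scheme": config.scheme,
                "mean_auc": result.mean_auc,
                "mean_auc_by_repeat": result.mean_auc_by_repeat,
                "n_valid_folds": int(result.aucs.size),
            })

    folds_path = outdir / "fold_aucs.tsv"
    pd.concat(fold_frames, ignore_index=True).to_csv(
        folds_path, sep="\t", index=False
    )
    summary_path = outdir / "summary.tsv"
    pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
    manifest = write_manifest(outdir, config, "crossvalidate", {
        "matrices": [str(m) for m in matrices],
    })
    return {"folds": folds_path, "summary": summary_path, "manifest": manifest}


def run_predict(config: RunConfig) -> dict[str, Path]:
    """Train on the full labeled matrix and rank the candidate genes."""
    config.require("labels", "candidates")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, corpus, ic = load_inputs(config)
    labels = LabeledGeneSet.from_tsv(config.labels)
    weights = WangWeights(config.wang_w_is_a, config.wang_w_part_of)
    candidates = [
        line.strip() for line in open(config.candidates)
        if line.strip() and line.strip() != "gene_id"
    ]
    if not candidates:
        raise ValueError(f"candidates file {config.candidates} lists no genes")

    matrix = build_matrix(
        labels.genes, corpus, graph,
        measure=config.measure, combine=config.combine, ic=ic, weights=weights,
    )
    model = DiseaseGeneModel(
        matrix, labels, config=ClassifierConfig(method=config.method)
    )
    perc = config.undersample_perc if config.undersample else None
    results = model.fit(
        scheme=config.scheme, k=config.k, repeats=config.repeats,
        undersample_perc=perc, seed=config.seed,
    )
    predictions, exclusions = results.predict(
        candidates, corpus, graph, ic=ic, weights=weights
    )
    pred_path = outdir / "predictions.tsv"
    excl_path = outdir / "exclusions.tsv"
    predictions.to_csv(pred_path, sep="\t", index=False)
    exclusions.to_csv(excl_path, sep="\t", index=False)
    manifest = write_manifest(outdir, config, "predict", {
        "cv_mean_auc": results.mean_auc,
        "n_predicted": len(predictions),
        "n_excluded": len(exclusions),
    })
    return {"predictions": pred_path, "exclusions": excl_path,
            "manifest": manifest}


def sweep_ntree(
    config: RunConfig,
    ntrees: tuple[int, ...] = (100, 300, 500, 700),
    matrix: GeneSimilarityMatrix | None = None,
) -> pd.DataFrame:
    """Random-forest tree-count sweep: mean CV AUC per ntree value."""
    if matrix is None:
        config.require("matrix")
        matrix = GeneSimilarityMatrix.from_tsv(config.matrix)
    config.require("labels")
    labels = LabeledGeneSet.from_tsv(config.labels)
    perc = config.undersample_perc if config.undersample else None
    rows = []
    for ntree in ntrees:
        result = evaluate_cv(
            matrix, labels, ClassifierConfig(method="rf", ntree=ntree),
            scheme=config.scheme, k=config.k, repeats=config.repeats,
            undersample_perc=perc, seed=config.seed,
        )
        rows.append({"ntree": ntree, "mean_auc": result.mean_auc,
                     "n_valid_folds": int(result.aucs.size)})
    return pd.DataFrame(rows)
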