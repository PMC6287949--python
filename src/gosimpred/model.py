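"""Model/Results interface over the similarity-matrix classification pipeline.

:class:`DiseaseGeneModel` bundles a gene functional-similarity matrix with
class labels and a classifier configuration; :meth:`DiseaseGeneModel.fit`
runs the cross-validated evaluation, trains the final full-data
classifier, and returns a :class:`DiseaseGeneResults` carrying the
per-fold AUCs, their aggregates, a ``summary()`` table, and candidate
prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gosimpred.classify import (
    ClassifierConfig,
    EvaluationResult,
    FittedClassifier,
    LabeledGeneSet,
    evaluate_cv,
    predict_candidates,
    train_classifier,
    undersample,
)
from gosimpred.semsim import GeneSimilarityMatrix

logger = logging.getLogger(__name__)


class DiseaseGeneModel:
    """Disease-gene classifier over a gene functional-similarity matrix.

    Parameters
    ----------
    similarity : GeneSimilarityMatrix
        Square symmetric matrix; every gene must appear in ``labels``.
    labels : LabeledGeneSet
        HD / LD / negative class per gene.
    method : {"rf", "nb", "svm_linear", "svm_radial"}
    config : ClassifierConfig, optional
        Full hyperparameter set; overrides ``method`` when given.

    Examples
    --------
    >>> model = DiseaseGeneModel(matrix, labels, method="rf")   # doctest: +SKIP
    >>> res = model.fit(scheme="stratified", repeats=20,
    ...                 undersample_perc=30, seed=7)            # doctest: +SKIP
    >>> print(res.summary())                                    # doctest: +SKIP
    """

    def __init__(
        self,
        similarity: GeneSimilarityMatrix,
        labels: LabeledGeneSet,
        method: str = "rf",
        config: ClassifierConfig | None = None,
    ):
        self.similarity = similarity
        self.labels = labels.subset(similarity.genes)
        self.config = config or ClassifierConfig(method=method)
        if len(self.labels.positives) < 1 or len(self.labels.negatives) < 1:
            raise ValueError("need at least one positive and one negative gene")

    @classmethod
    def from_files(
        cls,
        matrix_path: str,
        labels_path: str,
        method: str = "rf",
        config: ClassifierConfig | None = None,
    ) -> "DiseaseGeneModel":
        """Build a model from a matrix TSV (+ JSON sidecar) and a labels TSV."""
        return cls(
            GeneSimilarityMatrix.from_tsv(matrix_path),
            LabeledGeneSet.from_tsv(labels_path),
            method=method,
            config=config,
        )

    def fit(
        self,
        scheme: str = "stratified",
        k: int = 5,
        repeats: int = 1,
        undersample_perc: float | None = None,
        seed: int = 0,
    ) -> "DiseaseGeneResults":
        """Cross-validate, then train the final classifier on all genes.

        The cross-validation supplies the performance estimate (per-fold
        AUCs); the final classifier, trained on the full square matrix
        (undersampled to the same target if configured), is what ranks
        new candidate genes.
        """
        evaluation = evaluate_cv(
            self.similarity, self.labels, self.config,
            scheme=scheme, k=k, repeats=repeats,
            undersample_perc=undersample_perc, seed=seed,
        )
        train_genes = list(self.similarity.genes)
        rows = np.arange(len(train_genes))
        if undersample_perc is not None:
            final_seed = int(
                np.random.SeedSequence([seed, 2**16]).generate_state(1)[0] % 2**31
            )
            sub = set(undersample(
                train_genes, self.labels, undersample_perc, seed=final_seed
            ))
            rows = np.array([i for i, g in enumerate(train_genes) if g in sub])
        classifier = train_classifier(
            self.config,
            self.similarity.values[rows],
            self.labels.binary_array([train_genes[i] for i in rows]),
            seed=int(np.random.SeedSequence([seed, 2**16 + 1]).generate_state(1)[0] % 2**31),
            feature_genes=train_genes,
        )
        return DiseaseGeneResults(
            model=self, evaluation=evaluation, classifier=classifier,
        )


@dataclass
class DiseaseGeneResults:
    """Fitted results: CV performance plus the final trained classifier."""

    model: DiseaseGeneModel
    evaluation: EvaluationResult
    classifier: FittedClassifier

    @property
    def mean_auc(self) -> float:
        return self.evaluation.mean_auc

    @property
    def fold_aucs(self) -> pd.DataFrame:
        return self.evaluation.to_frame()

    def predict(
        self,
        candidates,
        corpus,
        graph,
        ic=None,
        weights=None,
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Rank candidate genes; returns (predictions, exclusions)."""
        return predict_candidates(
            self.classifier,
            self.classifier.feature_genes,
            candidates,
            corpus,
            graph,
            measure=self.model.similarity.measure,
            combine=self.model.similarity.combine,
            ic=ic,
            weights=weights,
        )

    def summary(self) -> str:
        """A compact text report of the evaluation."""
        ev = self.evaluation
        aucs = ev.aucs
        labels = self.model.labels
        lines = [
            "Disease-gene similarity classifier",
            "=" * 54,
            f"{'method':<24}{ev.config.method}",
            f"{'measure / combine':<24}{self.model.similarity.measure} / "
            f"{self.model.similarity.combine}",
            f"{'scheme':<24}{ev.scheme}",
            f"{'genes (pos/neg)':<24}{len(labels)} "
            f"({len(labels.positives)}/{len(labels.negatives)})",
            f"{'folds x repeats':<24}{ev.k} x {ev.n_repeats}",
            f"{'undersample perc':<24}{ev.undersample_perc}",
            f"{'seed':<24}{ev.seed}",
            "-" * 54,
            f"{'mean AUC (all folds)':<24}{ev.mean_auc:.4f}",
            f"{'mean AUC (by repeat)':<24}{ev.mean_auc_by_repeat:.4f}",
            f"{'AUC sd':<24}{aucs.std(ddof=1) if aucs.size > 1 else float('nan'):.4f}",
            f"{'valid folds':<24}{aucs.size}/{len(ev.records)}",
            "=" * 54,
        ]
        return "\n".join(lines)
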