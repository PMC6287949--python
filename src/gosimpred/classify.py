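"""Classification and evaluation on gene similarity matrices.

Instances of the learning problem are genes; the feature vector of a gene
is its row of functional similarities to the *training* genes.  Because
features and instances are the same objects, naive cross-validation leaks
information through the test genes' own columns.  The split therefore
removes test genes from the feature columns of both blocks: the training
block is square (train x train) and the test block is (test x train), so
no test gene's self-similarity or column ever reaches the classifier.

Two evaluation schemes are supported: plain stratified k-fold, and a
"held-out restricted" variant in which every gene participates in training
but only high-confidence positives (HD) and negatives contribute to the
test-fold AUC — low-confidence (LD) genes are scored yet excluded from the
metric.  Class imbalance is handled by undersampling the negative majority
within each training fold so that positives make up a target percentage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from gosimpred.semsim import GeneSimilarityMatrix

logger = logging.getLogger(__name__)

CLASSES = ("HD", "LD", "negative")
POSITIVE_CLASSES = frozenset({"HD", "LD"})
METHODS = ("rf", "nb", "svm_linear", "svm_radial")
SCHEMES = ("stratified", "heldout_restricted")


@dataclass
class LabeledGeneSet:
    """Gene class labels: HD / LD (positives, +1) vs negative (-1)."""

    classes: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in CLASSES}
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}; allowed {CLASSES}")

    @property
    def genes(self) -> list[str]:
        return list(self.classes)

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.classes

    def class_of(self, gene: str) -> str:
        return self.classes[gene]

    def binary(self, gene: str) -> int:
        return 1 if self.classes[gene] in POSITIVE_CLASSES else -1

    def binary_array(self, genes: Sequence[str]) -> np.ndarray:
        return np.array([self.binary(g) for g in genes], dtype=int)

    @property
    def positives(self) -> list[str]:
        return [g for g, c in self.classes.items() if c in POSITIVE_CLASSES]

    @property
    def negatives(self) -> list[str]:
        return [g for g, c in self.classes.items() if c == "negative"]

    def subset(self, genes: Iterable[str]) -> "LabeledGeneSet":
        missing = [g for g in genes if g not in self.classes]
        if missing:
            raise KeyError(f"genes without labels: {missing[:5]}")
        return LabeledGeneSet({g: self.classes[g] for g in genes})

    # -- persistence -------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str) -> "LabeledGeneSet":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if list(frame.columns[:2]) != ["gene_id", "class"]:
            raise ValueError(
                f"labels file must have header gene_id\\tclass, got {list(frame.columns)}"
            )
        return cls(dict(zip(frame["gene_id"], frame["class"])))

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            handle.write("gene_id\tclass\n")
            for gene, cls_ in self.classes.items():
                handle.write(f"{gene}\t{cls_}\n")


@dataclass
class FoldAssignment:
    """A stratified partition of genes into k folds (fold ids 1..k)."""

    k: int
    seed: int
    fold_of: dict[str, int]

    def test_genes(self, fold: int) -> list[str]:
        return [g for g, f in self.fold_of.items() if f == fold]

    def train_genes(self, fold: int) -> list[str]:
        return [g for g, f in self.fold_of.items() if f != fold]


def stratified_folds(labels: LabeledGeneSet, k: int, seed: int) -> FoldAssignment:
    """Partition genes into k folds preserving the binary class balance.

    Deterministic given ``seed``; per-fold class counts differ from exact
    proportionality by at most one gene.  Raises if either binary class
    has fewer than k members.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    genes = labels.genes
    y = labels.binary_array(genes)
    for value, name in ((1, "positive"), (-1, "negative")):
        count = int((y == value).sum())
        if count < k:
            raise ValueError(
                f"class {name!r} has only {count} genes; needs >= k={k}"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y), 1):
        for i in test_idx:
            fold_of[genes[i]] = fold
    return FoldAssignment(k=k, seed=seed, fold_of={g: fold_of[g] for g in genes})


class MatrixSplit(NamedTuple):
    """One leakage-avoiding train/test split of a similarity matrix."""

    x_train: np.ndarray  # (n_train, n_train), diagonal retained
    x_test: np.ndarray   # (n_test, n_train)
    train_genes: list[str]
    test_genes: list[str]


def split_matrix(
    matrix: GeneSimilarityMatrix, folds: FoldAssignment, test_fold: int
) -> MatrixSplit:
    """Split a square similarity matrix for one test fold.

    Feature columns are exactly the training genes, in matrix order; test
    genes never appear among the features of either block.
    """
    if set(matrix.genes) != set(folds.fold_of):
        raise ValueError("fold assignment does not cover the matrix genes")
    train_idx = [i for i, g in enumerate(matrix.genes)
                 if folds.fold_of[g] != test_fold]
    test_idx = [i for i, g in enumerate(matrix.genes)
                if folds.fold_of[g] == test_fold]
    if not train_idx or not test_idx:
        raise ValueError(f"fold {test_fold} yields an empty train or test set")
    values = matrix.values
    return MatrixSplit(
        x_train=values[np.ix_(train_idx, train_idx)],
        x_test=values[np.ix_(test_idx, train_idx)],
        train_genes=[matrix.genes[i] for i in train_idx],
        test_genes=[matrix.genes[i] for i in test_idx],
    )


def undersample(
    genes: Sequence[str], labels: LabeledGeneSet, perc: float, seed: int
) -> list[str]:
    """Undersample negatives so positives are ``perc`` percent of the subset.

    All positives are kept; negatives are sampled without replacement to
    ``round(P * (100 - perc) / perc)``.  If fewer negatives are available
    they are all kept (logged).  Returned genes preserve input order.
    """
    if not 0 < perc < 100:
        raise ValueError(f"perc must be in (0, 100), got {perc}")
    positives = [g for g in genes if labels.binary(g) == 1]
    negatives = [g for g in genes if labels.binary(g) == -1]
    if not positives:
        raise ValueError("cannot undersample: no positive genes present")
    n_neg_target = round(len(positives) * (100.0 - perc) / perc)
    if len(negatives) <= n_neg_target:
        if len(negatives) < n_neg_target:
            logger.info(
                "undersampling target %d negatives exceeds available %d; keeping all",
                n_neg_target, len(negatives),
            )
        chosen = set(negatives)
    else:
        rng = np.random.default_rng(seed)
        chosen = set(rng.choice(negatives, size=n_neg_target, replace=False))
    keep = set(positives) | chosen
    return [g for g in genes if g in keep]


@dataclass
class ClassifierConfig:
    """Hyperparameters for the supported classifiers.

    Defaults: random forest with 500 trees, mtry = floor(sqrt(#features)),
    bootstrap sampling, no class weighting; SVMs with cost 1 and optimizer
    tolerance 0.001 (radial kernel gamma 0.02); Gaussian naive Bayes.
    """

    method: str = "rf"
    ntree: int = 500
    mtry: int | None = None  # None -> floor(sqrt(#features))
    cost: float = 1.0
    tol: float = 1e-3
    gamma: float = 0.02

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; allowed {METHODS}")
        if self.ntree <= 0 or self.cost <= 0 or self.tol <= 0 or self.gamma <= 0:
            raise ValueError("classifier parameters must be positive")


@dataclass
class FittedClassifier:
    """A trained model exposing a real-valued disease score per instance.

    ``score_kind`` is "probability" (RF, NB: P(positive)) or "decision"
    (SVM: signed distance to the hyperplane); in both cases higher means
    more disease-like.
    """

    estimator: object
    score_kind: str
    feature_genes: list[str] | None = None

    def score_samples(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.score_kind == "probability":
            proba = self.estimator.predict_proba(x)
            pos_col = list(self.estimator.classes_).index(1)
            return proba[:, pos_col]
        return self.estimator.decision_function(x)

    @property
    def call_threshold(self) -> float:
        return 0.5 if self.score_kind == "probability" else 0.0


def train_classifier(
    config: ClassifierConfig,
    x_train: np.ndarray,
    y_train: Sequence[int],
    seed: int | None = None,
    feature_genes: Sequence[str] | None = None,
) -> FittedClassifier:
    """Train one classifier on a (instances x features) similarity block."""
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if not np.isfinite(x_train).all():
        raise ValueError("training block contains non-finite values")
    if len(set(y_train)) < 2:
        raise ValueError("training labels contain a single class")

    if config.method == "rf":
        max_features = config.mtry if config.mtry is not None else "sqrt"
        estimator = RandomForestClassifier(
            n_estimators=config.ntree,
            max_features=max_features,
            bootstrap=True,
            class_weight=None,
            random_state=seed,
            n_jobs=1,
        )
        score_kind = "probability"
    elif config.method == "nb":
        estimator = GaussianNB()
        score_kind = "probability"
    elif config.method == "svm_linear":
        estimator = SVC(kernel="linear", C=config.cost, tol=config.tol)
        score_kind = "decision"
    else:  # svm_radial
        estimator = SVC(
            kernel="rbf", C=config.cost, tol=config.tol, gamma=config.gamma
        )
        score_kind = "decision"

    estimator.fit(x_train, y_train)
    return FittedClassifier(
        estimator=estimator,
        score_kind=score_kind,
        feature_genes=list(feature_genes) if feature_genes is not None else None,
    )


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with mid-rank tie handling.

    The probability that a uniformly chosen positive outscores a uniformly
    chosen negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC needs both classes; have {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(scores)
    rank_sum = ranks[pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class FoldRecord:
    """Outcome of one (repeat, fold) evaluation."""

    repeat: int
    fold: int
    auc: float | None
    n_test_evaluable: int
    valid: bool
    feature_genes: list[str] = field(default_factory=list)
    test_genes: list[str] = field(default_factory=list)


@dataclass
class EvaluationResult:
    """Per-fold/per-repeat AUCs for one classifier x matrix x scheme."""

    scheme: str
    k: int
    n_repeats: int
    undersample_perc: float | None
    seed: int
    seeds: dict
    config: ClassifierConfig
    records: list[FoldRecord]

    @property
    def aucs(self) -> np.ndarray:
        return np.array([r.auc for r in self.records if r.valid], dtype=float)

    @property
    def mean_auc(self) -> float:
        """Mean over all valid fold x repeat AUCs (the primary aggregate)."""
        return float(self.aucs.mean())

    @property
    def mean_auc_by_repeat(self) -> float:
        """Fold-averaged then repeat-averaged mean (secondary aggregate)."""
        by_repeat = [
            np.mean([r.auc for r in self.records if r.valid and r.repeat == rep])
            for rep in sorted({r.repeat for r in self.records})
        ]
        return float(np.mean(by_repeat))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "repeat": r.repeat,
                    "fold": r.fold,
                    "scheme": self.scheme,
                    "method": self.config.method,
                    "auc": r.auc,
                    "n_test_evaluable": r.n_test_evaluable,
                    "valid": r.valid,
                }
                for r in self.records
            ]
        )


def _spawn_seeds(seed: int, repeats: int, k: int) -> dict:
    """Expand a master seed into fold/undersample/classifier seeds (< 2^31)."""
    root = np.random.SeedSequence(seed)
    fold_ss, under_ss, clf_ss = root.spawn(3)
    return {
        "master": int(seed),
        "fold": int(fold_ss.generate_state(1)[0] % 2**31),
        "undersample": [
            int(s) for s in under_ss.generate_state(repeats) % 2**31
        ],
        "classifier": [
            int(s) for s in clf_ss.generate_state(repeats * k) % 2**31
        ],
    }


def evaluate_cv(
    matrix: GeneSimilarityMatrix,
    labels: LabeledGeneSet,
    config: ClassifierConfig,
    scheme: str = "stratified",
    k: int = 5,
    repeats: int = 1,
    undersample_perc: float | None = None,
    seed: int = 0,
) -> EvaluationResult:
    """Repeated stratified k-fold cross-validation on a similarity matrix.

    For each repeat and fold: split the matrix without leakage, optionally
    undersample the *training instances* (features remain the full
    training-fold genes), train, score the test instances, and compute the
    AUC.  Under ``heldout_restricted`` only HD and negative test genes
    enter the AUC; LD genes still train and are scored but are excluded
    from the metric.  Folds are fixed across repeats (one fold seed);
    undersampling and classifier seeds vary per repeat so repeats differ
    only in training-set composition and model randomness.

    A fold whose evaluable test set lacks a class is recorded as invalid
    with a warning and excluded from the mean.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; allowed {SCHEMES}")
    labels = labels.subset(matrix.genes)
    seeds = _spawn_seeds(seed, repeats, k)
    folds = stratified_folds(labels, k=k, seed=seeds["fold"])

    records: list[FoldRecord] = []
    for repeat in range(1, repeats + 1):
        for fold in range(1, k + 1):
            split = split_matrix(matrix, folds, fold)
            train_genes = split.train_genes
            train_rows = np.arange(len(train_genes))
            if undersample_perc is not None:
                sub = undersample(
                    train_genes, labels, undersample_perc,
                    seed=seeds["undersample"][repeat - 1],
                )
                keep = set(sub)
                train_rows = np.array(
                    [i for i, g in enumerate(train_genes) if g in keep]
                )
            y_train = labels.binary_array(
                [train_genes[i] for i in train_rows]
            )
            clf_seed = seeds["classifier"][(repeat - 1) * k + (fold - 1)]
            fitted = train_classifier(
                config, split.x_train[train_rows], y_train,
                seed=clf_seed, feature_genes=train_genes,
            )
            scores = fitted.score_samples(split.x_test)

            if scheme == "heldout_restricted":
                evaluable = np.array(
                    [labels.class_of(g) in ("HD", "negative")
                     for g in split.test_genes]
                )
            else:
                evaluable = np.ones(len(split.test_genes), dtype=bool)
            y_test = labels.binary_array(split.test_genes)[evaluable]
            n_eval = int(evaluable.sum())
            if len(set(y_test)) < 2:
                warnings.warn(
                    f"repeat {repeat} fold {fold}: evaluable test set lacks a "
                    "class; fold excluded from the mean AUC",
                    stacklevel=2,
                )
                records.append(FoldRecord(
                    repeat=repeat, fold=fold, auc=None,
                    n_test_evaluable=n_eval, valid=False,
                    feature_genes=train_genes, test_genes=split.test_genes,
                ))
                continue
            auc = compute_auc(scores[evaluable], y_test)
            records.append(FoldRecord(
                repeat=repeat, fold=fold, auc=auc,
                n_test_evaluable=n_eval, valid=True,
                feature_genes=train_genes, test_genes=split.test_genes,
            ))

    result = EvaluationResult(
        scheme=scheme, k=k, n_repeats=repeats,
        undersample_perc=undersample_perc, seed=seed, seeds=seeds,
        config=config, records=records,
    )
    if result.aucs.size:
        logger.info(
            "%s %s CV: mean AUC %.4f over %d valid folds",
            config.method, scheme, result.mean_auc, result.aucs.size,
        )
    return result


def predict_candidates(
    fitted: FittedClassifier,
    train_genes: Sequence[str],
    candidates: Sequence[str],
    corpus,
    graph,
    measure: str = "resnik",
    combine: str = "max",
    ic=None,
    weights=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and rank candidate genes against a fully trained classifier.

    Candidates overlapping the training set, or lacking usable
    annotations, are excluded and reported with reasons.  Each remaining
    candidate's feature vector is its similarity to every training gene
    (feature order = training-gene order used at fit time).  Output is
    sorted by score descending, with a binary call at the model's
    threshold (0.5 for probability scores, 0 for decision values).

    Returns ``(predictions, exclusions)`` data frames.
    """
    from gosimpred.semsim import WangWeights, gene_sim, usable_terms, _TermPairCache

    weights = weights or WangWeights()
    train_set = set(train_genes)
    exclusions = []
    scoreable = []
    seen = set()
    for cand in candidates:
        if cand in seen:
            continue
        seen.add(cand)
        if cand in train_set:
            exclusions.append({"gene_id": cand, "reason": "overlaps training set"})
        elif cand not in corpus or not usable_terms(cand, corpus, graph, measure, ic):
            exclusions.append({"gene_id": cand, "reason": "missing annotations"})
        else:
            scoreable.append(cand)
    if not scoreable:
        raise ValueError("no scoreable candidate genes remain after exclusions")

    cache = _TermPairCache(graph, measure, ic, weights)
    features = np.empty((len(scoreable), len(train_genes)))
    for i, cand in enumerate(scoreable):
        for j, gene in enumerate(train_genes):
            sim = gene_sim(
                cand, gene, corpus, graph, measure=measure, combine=combine,
                ic=ic, weights=weights, _cache=cache,
            )
            assert sim is not None  # both genes have usable terms
            features[i, j] = sim
    scores = fitted.score_samples(features)
    order = sorted(
        range(len(scoreable)), key=lambda i: (-scores[i], scoreable[i])
    )
    predictions = pd.DataFrame(
        {
            "gene_id": [scoreable[i] for i in order],
            "score": [float(scores[i]) for i in order],
            "call": [int(scores[i] >= fitted.call_threshold) for i in order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return predictions, pd.DataFrame(exclusions, columns=["gene_id", "reason"])
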