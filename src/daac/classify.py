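"""Per-GO-term classification of proteins by domain architecture similarity.

Training groups proteins under one class per GO term (using propagated,
experimentally evidenced annotations), computes the all-against-all DA
similarity matrix once, and tunes a class-specific similarity threshold
``T_Y`` on a fixed grid (0 to 1 in 0.02 steps) by stratified cross
validation, selecting the grid point with the best pooled F-score.

Prediction is multi-label: a query protein receives the GO term of every
class whose cross-validated F-score exceeds ``f_min`` and whose members'
mean DA similarity to the query reaches the tuned threshold.  Queries with
more than ``max_domains`` real domains are excluded — similarity over very
complex architectures is unreliable.

The central object is :class:`DomainArchitectureGoClassifier`, a
scikit-learn style estimator (``fit`` / ``predict``, ``get_params`` /
``set_params``, fitted attributes with trailing underscores).  The
module-level :func:`train` / :func:`predict` functions are thin wrappers
over it.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .alignment import ScoringParams, all_against_all, similarity
from .architectures import (
    DomainArchitecture,
    WeightTable,
    compute_weights,
    count_domains,
    read_da_table,
    read_weight_table,
    write_da_table,
    write_weight_table,
)
from .ontology import AnnotationSet

logger = logging.getLogger(__name__)


def threshold_grid(step: float = 0.02) -> np.ndarray:
    """The similarity threshold grid: 0 to 1 inclusive in ``step`` increments."""
    if not (0 < step <= 1):
        raise ValueError("grid step must be in (0, 1]")
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


@dataclass(frozen=True)
class GoClass:
    """One GO term's classifier state.

    ``threshold`` is the tuned similarity threshold T_Y (``None`` until
    tuned, or for untrainable classes); CV metrics are pooled across folds
    at the selected threshold.
    """

    term_id: str
    members: frozenset[str]
    threshold: Optional[float] = None
    cv_fscore: float = 0.0
    cv_precision: float = 0.0
    cv_recall: float = 0.0
    cv_auc: float = float("nan")
    trainable: bool = True


@dataclass(frozen=True)
class Prediction:
    """One emitted (protein, GO term) prediction with its evidence trail."""

    protein_id: str
    term_id: str
    mean_similarity: float
    threshold: float
    class_fscore: float


def build_classes(
    anns: AnnotationSet,
    das: Mapping[str, DomainArchitecture],
    min_members: int = 3,
) -> list[GoClass]:
    """Group annotated proteins into untuned per-term classes.

    Only proteins that possess a DA can be members; terms with fewer than
    ``min_members`` eligible proteins yield no class.
    """
    if not anns.propagated:
        logger.warning("building classes from an unpropagated annotation set")
    members_by_term: dict[str, set[str]] = {}
    n_no_da = 0
    for protein, term, _ in anns.records:
        if protein not in das:
            n_no_da += 1
            continue
        members_by_term.setdefault(term, set()).add(protein)
    if n_no_da:
        logger.info("%d annotation record(s) referenced proteins without DAs", n_no_da)
    return [
        GoClass(term_id=t, members=frozenset(ms))
        for t, ms in sorted(members_by_term.items())
        if len(ms) >= min_members
    ]


def mean_similarity(
    query: str,
    cls: GoClass,
    sims: pd.DataFrame,
) -> Optional[float]:
    """Mean DA similarity of ``query`` to the (other) members of a class.

    ``sims`` is a symmetric similarity matrix indexed by protein id.  If the
    query is itself a member it is excluded from the averaging set; returns
    ``None`` when that set is empty (class skipped for this query).
    """
    others = sorted(cls.members - {query})
    if not others:
        return None
    return float(sims.loc[query, others].to_numpy().mean())


def optimize_threshold(
    cls: GoClass,
    sim_matrix: pd.DataFrame,
    all_proteins: Sequence[str],
    folds: int = 5,
    grid_step: float = 0.02,
    random_state: int = 0,
) -> GoClass:
    """Tune the class threshold by stratified k-fold cross validation.

    Positives are class members, negatives all other training proteins.
    Every held-out protein is scored by its mean similarity to the members
    in the retained folds; confusion counts are pooled across folds at each
    grid threshold and the threshold with maximal F-score is selected (ties
    resolved toward the largest, i.e. the most precise, threshold).
    ``cv_auc`` is computed from the pooled held-out scores.  Classes that
    cannot support two stratified folds are marked untrainable.
    """
    ids = np.asarray(all_proteins)
    labels = np.array([p in cls.members for p in ids])
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    n_splits = min(folds, n_pos, n_neg)
    if n_splits < 2:
        logger.warning("class %s untrainable (%d pos / %d neg)",
                       cls.term_id, n_pos, n_neg)
        return replace(cls, trainable=False, threshold=None)

    sims = sim_matrix.loc[ids, ids].to_numpy()
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                          random_state=random_state)
    held_scores: list[float] = []
    held_labels: list[bool] = []
    for train_idx, test_idx in skf.split(ids, labels):
        member_idx = train_idx[labels[train_idx]]
        if member_idx.size == 0:
            logger.warning("class %s: fold without positives skipped", cls.term_id)
            continue
        fold_scores = sims[np.ix_(test_idx, member_idx)].mean(axis=1)
        held_scores.extend(fold_scores.tolist())
        held_labels.extend(labels[test_idx].tolist())
    scores = np.asarray(held_scores)
    lab = np.asarray(held_labels, dtype=bool)
    if scores.size == 0 or not lab.any() or lab.all():
        logger.warning("class %s untrainable (degenerate folds)", cls.term_id)
        return replace(cls, trainable=False, threshold=None)

    best_t, best_f, best_p, best_r = 0.0, -1.0, 0.0, 0.0
    for t in threshold_grid(grid_step):
        called = scores >= t
        tp = int((called & lab).sum())
        fp = int((called & ~lab).sum())
        fn = int((~called & lab).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = (2 * precision * recall / (precision + recall)
             if precision + recall else 0.0)
        if f >= best_f:  # >= : ties resolve toward the largest threshold
            best_t, best_f, best_p, best_r = float(t), f, precision, recall
    auc = float(roc_auc_score(lab, scores))
    return replace(
        cls,
        threshold=best_t,
        cv_fscore=best_f,
        cv_precision=best_p,
        cv_recall=best_r,
        cv_auc=auc,
        trainable=True,
    )


class DomainArchitectureGoClassifier(BaseEstimator):
    """Multi-label GO term classifier over domain architectures.

    Parameters
    ----------
    folds : int
        Cross-validation folds for per-class threshold tuning.
    grid_step : float
        Spacing of the similarity threshold grid on [0, 1].
    min_members : int
        Minimum annotated proteins (with DAs) for a term to form a class.
    f_min : float
        Only classes with cross-validated F-score strictly above this value
        emit predictions.
    max_domains : int
        Queries with more real domains than this are excluded.
    match, gap_open_ratio : see :class:`~daac.alignment.ScoringParams`;
        ``scoring`` may be passed directly to override all four values.
    random_state : int
        Seed for CV shuffling; fixes the model bit-for-bit.

    Attributes
    ----------
    protein_ids_ : list of training protein ids.
    training_das_ : dict protein id -> DomainArchitecture.
    weight_table_ : inverse domain frequency weights of the corpus.
    similarity_ : DataFrame, all-against-all training similarity matrix.
    classes_ : list of tuned :class:`GoClass`, sorted by term id.
    """

    def __init__(
        self,
        folds: int = 5,
        grid_step: float = 0.02,
        min_members: int = 3,
        f_min: float = 0.7,
        max_domains: int = 8,
        scoring: Optional[ScoringParams] = None,
        random_state: int = 0,
    ):
        self.folds = folds
        self.grid_step = grid_step
        self.min_members = min_members
        self.f_min = f_min
        self.max_domains = max_domains
        self.scoring = scoring
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        X: Sequence[DomainArchitecture],
        y: Sequence[Iterable[str]],
    ) -> "DomainArchitectureGoClassifier":
        """Fit from training DAs and their (propagated) GO term sets.

        ``X`` is a sequence of DAs with unique protein ids; ``y[i]`` is the
        collection of GO terms annotated to ``X[i]``.
        """
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        ids = [da.protein_id for da in X]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids in training set")
        scoring = self.scoring or ScoringParams()

        self.protein_ids_ = list(ids)
        self.training_das_ = {da.protein_id: da for da in X}
        self.weight_table_ = compute_weights(list(X))
        matrix = all_against_all(list(X), self.weight_table_, scoring)
        self.similarity_ = pd.DataFrame(matrix, index=ids, columns=ids)

        records = frozenset(
            (pid, term, "CV") for pid, terms in zip(ids, y) for term in terms
        )
        anns = AnnotationSet(records=records, propagated=True)
        untuned = build_classes(anns, self.training_das_, self.min_members)
        self.classes_ = [
            optimize_threshold(
                cls, self.similarity_, self.protein_ids_,
                folds=self.folds, grid_step=self.grid_step,
                random_state=self.random_state,
            )
            for cls in untuned
        ]
        n_selected = sum(
            1 for c in self.classes_ if c.trainable and c.cv_fscore > self.f_min
        )
        logger.info(
            "trained %d classes (%d passing f_min=%.2f) on %d proteins",
            len(self.classes_), n_selected, self.f_min, len(ids),
        )
        return self

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "classes_"):
            raise RuntimeError("classifier is not fitted")

    def selected_classes(self, f_min: Optional[float] = None) -> list[GoClass]:
        """Classes whose cross-validated F-score exceeds ``f_min``."""
        self._check_fitted()
        cut = self.f_min if f_min is None else f_min
        return [c for c in self.classes_
                if c.trainable and c.cv_fscore > cut]

    def predict_records(
        self,
        X: Sequence[DomainArchitecture],
        f_min: Optional[float] = None,
        max_domains: Optional[int] = None,
    ) -> list[Prediction]:
        """Multi-label predictions for query DAs.

        A query receives a term when its mean similarity to the class
        members reaches the class threshold.  Novel query domains absent
        from the training weight table fall back to weight 1 rather than
        aborting.  Output is sorted by (protein id, descending similarity).
        """
        self._check_fitted()
        max_d = self.max_domains if max_domains is None else max_domains
        eligible = self.selected_classes(f_min)
        scoring = self.scoring or ScoringParams()
        out: list[Prediction] = []
        for da in X:
            if count_domains(da) > max_d:
                logger.info(
                    "query %s excluded: %d real domains exceeds %d",
                    da.protein_id, count_domains(da), max_d,
                )
                continue
            cache: dict[str, float] = {}
            for cls in eligible:
                members = sorted(cls.members - {da.protein_id})
                if not members:
                    continue
                total = 0.0
                for m in members:
                    if m not in cache:
                        cache[m] = similarity(
                            da, self.training_das_[m], self.weight_table_,
                            scoring, strict=False,
                        )
                    total += cache[m]
                sim_av = total / len(members)
                if sim_av >= cls.threshold:
                    out.append(Prediction(
                        protein_id=da.protein_id,
                        term_id=cls.term_id,
                        mean_similarity=sim_av,
                        threshold=cls.threshold,
                        class_fscore=cls.cv_fscore,
                    ))
        out.sort(key=lambda p: (p.protein_id, -p.mean_similarity, p.term_id))
        return out

    def predict(self, X: Sequence[DomainArchitecture]) -> list[set[str]]:
        """Predicted GO term set for each query DA (order preserved)."""
        by_protein: dict[str, set[str]] = {}
        for p in self.predict_records(X):
            by_protein.setdefault(p.protein_id, set()).add(p.term_id)
        return [by_protein.get(da.protein_id, set()) for da in X]


#: The persisted trained state *is* the fitted estimator.
TrainedModel = DomainArchitectureGoClassifier


def train(
    das: Mapping[str, DomainArchitecture],
    anns: AnnotationSet,
    **params,
) -> DomainArchitectureGoClassifier:
    """Fit a classifier from a DA map and a propagated annotation set."""
    by_protein = anns.by_protein()
    X = [das[pid] for pid in das]
    y = [sorted(by_protein.get(pid, ())) for pid in das]
    return DomainArchitectureGoClassifier(**params).fit(X, y)


def predict(
    model: DomainArchitectureGoClassifier,
    queries: Sequence[DomainArchitecture],
    f_min: float = 0.7,
    max_domains: int = 8,
) -> list[Prediction]:
    """Predictions for query DAs under explicit quality filters."""
    return model.predict_records(queries, f_min=f_min, max_domains=max_domains)


# ---------------------------------------------------------------------------
# Plain-text model persistence

def config_hash(params: Mapping) -> str:
    """Stable short hash of a parameter mapping (for output headers)."""
    canon = yaml.safe_dump(
        {k: repr(v) for k, v in sorted(params.items())}, sort_keys=True
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def save_model(model: DomainArchitectureGoClassifier, path: Union[str, Path]) -> None:
    """Persist a fitted model as a directory of diffable plain-text files."""
    model._check_fitted()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    params = model.get_params()
    scoring = model.scoring or ScoringParams()
    snapshot = {
        k: v for k, v in params.items() if k != "scoring"
    }
    snapshot["scoring"] = {
        "match": scoring.match, "mismatch": scoring.mismatch,
        "gap_open": scoring.gap_open, "gap_extend": scoring.gap_extend,
        "gap_element_score": scoring.gap_element_score,
    }
    snapshot["config_hash"] = config_hash(params)
    (path / "config.yaml").write_text(yaml.safe_dump(snapshot, sort_keys=True))

    with open(path / "weights.tsv", "w") as fh:
        write_weight_table(model.weight_table_, fh)
    with open(path / "das.tsv", "w") as fh:
        write_da_table(model.training_das_, fh)
    with open(path / "classes.tsv", "w") as fh:
        fh.write("term_id\tthreshold\tcv_fscore\tcv_precision\tcv_recall"
                 "\tcv_auc\tn_members\tmembers\n")
        for c in model.classes_:
            thr = "NA" if c.threshold is None else f"{c.threshold:.2f}"
            auc = "NA" if math.isnan(c.cv_auc) else f"{c.cv_auc:.6f}"
            fh.write(
                f"{c.term_id}\t{thr}\t{c.cv_fscore:.6f}\t{c.cv_precision:.6f}"
                f"\t{c.cv_recall:.6f}\t{auc}\t{len(c.members)}"
                f"\t{','.join(sorted(c.members))}\n"
            )
    with open(path / "similarity.tsv", "w") as fh:
        fh.write("\t".join(["protein_id"] + model.protein_ids_) + "\n")
        arr = model.similarity_.to_numpy()
        for i, pid in enumerate(model.protein_ids_):
            fh.write(pid + "\t" + "\t".join(f"{v:.9f}" for v in arr[i]) + "\n")


def load_model(path: Union[str, Path]) -> DomainArchitectureGoClassifier:
    """Restore a fitted model from :func:`save_model` output."""
    path = Path(path)
    snapshot = yaml.safe_load((path / "config.yaml").read_text())
    scoring = ScoringParams(**snapshot.pop("scoring"))
    snapshot.pop("config_hash", None)
    model = DomainArchitectureGoClassifier(scoring=scoring, **snapshot)

    with open(path / "weights.tsv") as fh:
        model.weight_table_ = read_weight_table(fh)
    with open(path / "das.tsv") as fh:
        model.training_das_ = read_da_table(fh)
    sim = pd.read_csv(path / "similarity.tsv", sep="\t", index_col=0)
    model.similarity_ = sim
    model.protein_ids_ = list(sim.index)

    classes: list[GoClass] = []
    with open(path / "classes.tsv") as fh:
        next(fh)  # header
        for line in fh:
            (term, thr, f, p, r, auc, _n, members) = line.rstrip("\n").split("\t")
            classes.append(GoClass(
                term_id=term,
                members=frozenset(members.split(",")) if members else frozenset(),
                threshold=None if thr == "NA" else float(thr),
                cv_fscore=float(f),
                cv_precision=float(p),
                cv_recall=float(r),
                cv_auc=float("nan") if auc == "NA" else float(auc),
                trainable=thr != "NA",
            ))
    model.classes_ = classes
    return model
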