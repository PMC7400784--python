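"""Iterated-split ensemble learning: per-iteration subclassifiers, error
curves with the valid-classifier rule, model selection, and the
majority-vote master classifier.

Each of the n_iter train/validation splits contributes, for every probe
count k, one subclassifier trained on the top-k probes of that iteration's
ranked list. A subclassifier is *valid* only if all k probes individually
pass the BH-FDR gate on its training data. Error curves average training and
validation error over valid subclassifiers; growth in k stops as soon as
fewer than C_min iterations yield a valid classifier. The master classifier
is the majority vote of the valid subclassifiers at the selected k*. Because
learning is (by default) uncompensated under ~82% wt prevalence, the vote is
deliberately conservative — biased toward a wt call — which is what makes
its false positives trustworthy pseudomutant candidates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .core import ExpressionMatrix
from .ranking import RankedProbeList

logger = logging.getLogger(__name__)

LEARNERS = ("lda", "linsvm", "gsvm")
C_MIN_DEFAULT = 70


def make_learner(ml_method: str, class_weighting: bool = False):
    """Instantiate one of the three learners with fixed, untuned settings.

    SVM cost is 1 and the Gaussian kernel width is 1/(k * feature variance)
    (scikit-learn's 'scale'); no per-iteration hyperparameter tuning is
    performed. ``class_weighting`` turns on inverse-class-frequency weights
    (the optional imbalance compensation).
    """
    cw = "balanced" if class_weighting else None
    if ml_method == "lda":
        if class_weighting:
            # LDA has no class_weight; compensation handled via priors
            return LinearDiscriminantAnalysis(solver="lsqr", priors=[0.5, 0.5])
        return LinearDiscriminantAnalysis(solver="lsqr")
    if ml_method == "linsvm":
        return SVC(kernel="linear", C=1.0, class_weight=cw)
    if ml_method == "gsvm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", class_weight=cw)
    raise ValueError(f"unknown ML method {ml_method!r}; choose from {LEARNERS}")


@dataclass
class SubClassifier:
    """One k-probe classifier from one iteration, with its standardization."""

    iteration: int
    probes: list[str]
    ml_method: str
    estimator: object
    mean: np.ndarray
    std: np.ndarray
    shrinkage_applied: bool = False

    @property
    def k(self) -> int:
        return len(self.probes)

    def can_vote(self, em: ExpressionMatrix) -> bool:
        available = set(em.probe_ids)
        return all(p in available for p in self.probes)

    def _features(self, em: ExpressionMatrix, sample_ids) -> np.ndarray:
        X = em.data.loc[self.probes, list(sample_ids)].to_numpy().T
        return (X - self.mean) / self.std

    def predict(self, em: ExpressionMatrix, sample_ids) -> np.ndarray:
        return self.estimator.predict(self._features(em, sample_ids))

    def decision_score(self, em: ExpressionMatrix, sample_ids) -> np.ndarray:
        return self.estimator.decision_function(self._features(em, sample_ids))

    def to_dict(self) -> dict:
        est = self.estimator
        payload = {
            "iteration": self.iteration,
            "probes": self.probes,
            "ml_method": self.ml_method,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "shrinkage_applied": self.shrinkage_applied,
        }
        if self.ml_method in ("lda", "linsvm"):
            payload["coef"] = np.asarray(est.coef_).ravel().tolist()
            payload["intercept"] = float(np.asarray(est.intercept_).ravel()[0])
        else:  # rbf kernel: store the full dual representation
            payload["support_vectors"] = np.asarray(est.support_vectors_).tolist()
            payload["dual_coef"] = np.asarray(est.dual_coef_).ravel().tolist()
            payload["intercept"] = float(np.asarray(est.intercept_).ravel()[0])
            payload["gamma"] = float(est._gamma)
        return payload


def train_subclassifier(
    train_em: ExpressionMatrix,
    train_labels: np.ndarray,
    probes_k: list[str],
    ml_method: str,
    iteration: int = 0,
    class_weighting: bool = False,
) -> SubClassifier:
    """Fit one learner on the given probes, standardized by training stats.

    LDA falls back to a small fixed shrinkage toward the diagonal when the
    pooled covariance is ill-conditioned (k can approach the training size).
    """
    y = np.asarray(train_labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present in training data")
    missing = [p for p in probes_k if p not in set(train_em.probe_ids)]
    if missing:
        raise ValueError(f"probes absent from training matrix: {missing[:5]}")
    X = train_em.data.loc[probes_k].to_numpy().T
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xs = (X - mean) / std

    learner = make_learner(ml_method, class_weighting)
    shrinkage_applied = False
    if ml_method == "lda":
        try:
            with np.errstate(all="raise"):
                learner.fit(Xs, y)
            if not np.all(np.isfinite(learner.coef_)):
                raise FloatingPointError
        except (FloatingPointError, np.linalg.LinAlgError):
            learner = make_learner(ml_method, class_weighting)
            learner.set_params(shrinkage=0.1)
            learner.fit(Xs, y)
            shrinkage_applied = True
            logger.info("LDA covariance singular at k=%d; applied shrinkage 0.1", len(probes_k))
    else:
        learner.fit(Xs, y)
    return SubClassifier(
        iteration=iteration,
        probes=list(probes_k),
        ml_method=ml_method,
        estimator=learner,
        mean=mean,
        std=std,
        shrinkage_applied=shrinkage_applied,
    )


def classification_error(predicted, truth) -> tuple[float, dict]:
    """(FP + FN) / total, with the 2x2 confusion table; mut (1) is positive."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth vectors differ in length")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    total = predicted.size
    if total == 0:
        raise ValueError("empty label vectors")
    return (fp + fn) / total, {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


@dataclass
class ErrorCurve:
    """Per-k summary over valid subclassifiers, plus the stopping k.

    Entries are reported only for k where at least C_min iterations produced
    a valid classifier; SEM = std / sqrt(n_valid). With a single iteration
    the SEM is undefined and reported as 0 with ``sem_defined=False``.
    """

    ks: list[int]
    n_valid: list[int]
    train_mean: list[float]
    train_sem: list[float]
    val_mean: list[float]
    val_sem: list[float]
    c_min: int
    sem_defined: bool = True
    combo: tuple = ()

    @property
    def stopping_k(self) -> int:
        return self.ks[-1] if self.ks else 0

    def min_val_error(self) -> float:
        return float(np.min(self.val_mean))


@dataclass
class IterationRecord:
    """What one iteration contributes at one k: the trained subclassifier's
    identity and its validation-set predictions (needed later for the
    validation-majority pseudomutant rule)."""

    iteration: int
    k: int
    probes: list[str]
    val_ids: list[str]
    val_pred: np.ndarray
    train_error: float
    val_error: float


def build_error_curves(
    plan,
    em: ExpressionMatrix,
    labels_series,
    ranked_lists: list[RankedProbeList],
    ml_method: str,
    k_max: int | None = None,
    c_min: int = C_MIN_DEFAULT,
    class_weighting: bool = False,
) -> tuple[ErrorCurve, dict[int, list[IterationRecord]]]:
    """Grow k = 1, 2, ... adding one probe at a time; stop when the number of
    valid subclassifiers drops below ``c_min``.

    ``ranked_lists[i]`` is iteration i's ranked probe list (computed on that
    iteration's training samples). A subclassifier at k is valid iff the
    list's first k probes all pass the FDR gate. Returns the error curve and,
    per k, the iteration records used for error averaging and PM calling.
    """
    n_iter = plan.n_iter
    if len(ranked_lists) != n_iter:
        raise ValueError("one ranked list per iteration is required")
    if c_min > n_iter:
        raise ValueError("c_min cannot exceed the number of iterations")
    valid_len = [rl.n_valid_prefix() for rl in ranked_lists]
    hard_cap = max(valid_len) if valid_len else 0
    if k_max is not None:
        hard_cap = min(hard_cap, k_max)
    # n_valid at k is the number of lists whose FDR-valid prefix reaches k;
    # it is non-increasing in k, so the stopping k is known before training.
    k_stop = 0
    for k in range(1, hard_cap + 1):
        if sum(1 for v in valid_len if v >= k) < c_min:
            break
        k_stop = k
    if k_stop == 0:
        raise RuntimeError(
            f"no k reached {c_min} valid subclassifiers; "
            "consider more data or a laxer FDR threshold q"
        )

    labels = labels_series
    records: dict[int, list[IterationRecord]] = {k: [] for k in range(1, k_stop + 1)}
    for i in range(n_iter):
        train_ids, val_ids = plan.iterations[i]
        train_em = em.subset_samples(train_ids)
        y_train = np.asarray(labels.loc[train_ids])
        y_val = np.asarray(labels.loc[val_ids])
        for k in range(1, min(valid_len[i], k_stop) + 1):
            probes = ranked_lists[i].top(k)
            sub = train_subclassifier(
                train_em, y_train, probes, ml_method,
                iteration=i, class_weighting=class_weighting,
            )
            tr_err, _ = classification_error(sub.predict(em, train_ids), y_train)
            val_pred = sub.predict(em, val_ids)
            va_err, _ = classification_error(val_pred, y_val)
            records[k].append(
                IterationRecord(i, k, probes, list(val_ids), val_pred, tr_err, va_err)
            )

    ks, n_valid_l, tr_m, tr_s, va_m, va_s = [], [], [], [], [], []
    for k in range(1, k_stop + 1):
        iter_records = records[k]
        tr = np.array([r.train_error for r in iter_records])
        va = np.array([r.val_error for r in iter_records])
        nv = len(iter_records)
        ks.append(k)
        n_valid_l.append(nv)
        tr_m.append(float(tr.mean()))
        va_m.append(float(va.mean()))
        if nv > 1:
            tr_s.append(float(tr.std(ddof=1) / np.sqrt(nv)))
            va_s.append(float(va.std(ddof=1) / np.sqrt(nv)))
        else:
            tr_s.append(0.0)
            va_s.append(0.0)

    curve = ErrorCurve(
        ks=ks, n_valid=n_valid_l,
        train_mean=tr_m, train_sem=tr_s, val_mean=va_m, val_sem=va_s,
        c_min=c_min, sem_defined=n_iter > 1,
    )
    return curve, records


def select_model(curves: dict[tuple, ErrorCurve]) -> tuple[tuple, int]:
    """Choose (GL, GR, ML) and k* from the error curves.

    The combination with the lowest minimum mean validation error wins; its
    k* is then the smallest k with full validity (n_valid == n_iter, or the
    best available validity level if none is full) whose mean validation
    error lies within one SEM of that combination's minimum — a one-standard-
    error rule encoding the preference for shorter, more robust probe lists.
    """
    if not curves:
        raise ValueError("no error curves supplied")
    best_combo = min(curves, key=lambda c: (curves[c].min_val_error(), c))
    curve = curves[best_combo]
    va = np.array(curve.val_mean)
    sem = np.array(curve.val_sem)
    nv = np.array(curve.n_valid)
    full = nv == nv.max()
    idx_min = int(np.argmin(va))
    threshold = va[idx_min] + sem[idx_min]
    eligible = np.nonzero(full & (va <= threshold + 1e-12))[0]
    idx_star = int(eligible[0]) if eligible.size else idx_min
    return best_combo, curve.ks[idx_star]


@dataclass
class EnsembleModel:
    """The majority-vote master classifier: the valid subclassifiers at k*.

    A sample's label is mut iff mut votes strictly exceed half the cast
    votes; an exact tie is called wt (the documented conservative policy).
    Subclassifiers missing any required probe on a new platform abstain and
    are dropped from that sample's vote (logged), mirroring cross-cohort
    application where only part of the ensemble has full gene coverage.
    """

    combo: tuple
    k_star: int
    subclassifiers: list[SubClassifier]
    provenance: dict = field(default_factory=dict)

    @property
    def n_voters(self) -> int:
        return len(self.subclassifiers)

    def majority_vote_predict(self, em: ExpressionMatrix, sample_ids=None):
        """Per-sample label (0/1) and mut-vote fraction."""
        if sample_ids is None:
            sample_ids = em.sample_ids
        voters = [s for s in self.subclassifiers if s.can_vote(em)]
        n_dropped = self.n_voters - len(voters)
        if n_dropped:
            logger.info("%d/%d subclassifiers cannot vote on this platform", n_dropped, self.n_voters)
        if not voters:
            raise ValueError("no subclassifier has complete probe data for these samples")
        votes = np.stack([v.predict(em, sample_ids) for v in voters])  # voters x samples
        mut_votes = votes.sum(axis=0)
        cast = len(voters)
        labels = (mut_votes > cast / 2).astype(int)
        return labels, mut_votes / cast

    def mean_decision_scores(self, em: ExpressionMatrix, sample_ids=None) -> np.ndarray:
        if sample_ids is None:
            sample_ids = em.sample_ids
        voters = [s for s in self.subclassifiers if s.can_vote(em)]
        return np.stack([v.decision_score(em, sample_ids) for v in voters])

    def to_json(self, path) -> None:
        payload = {
            "combo": list(self.combo),
            "k_star": self.k_star,
            "provenance": self.provenance,
            "subclassifiers": [s.to_dict() for s in self.subclassifiers],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def majority_vote_predict(model: EnsembleModel, em: ExpressionMatrix, sample_ids=None):
    """Functional alias for :meth:`EnsembleModel.majority_vote_predict`."""
    return model.majority_vote_predict(em, sample_ids)


class _LinearRule:
    """Decision rule rebuilt from serialized linear coefficients."""

    def __init__(self, coef, intercept):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)

    def decision_function(self, X):
        return X @ self.coef + self.intercept

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


class _RBFRule:
    """Decision rule rebuilt from a serialized RBF-SVM dual representation."""

    def __init__(self, support_vectors, dual_coef, intercept, gamma):
        self.sv = np.asarray(support_vectors, dtype=float)
        self.dual = np.asarray(dual_coef, dtype=float)
        self.intercept = float(intercept)
        self.gamma = float(gamma)

    def decision_function(self, X):
        d2 = ((X[:, None, :] - self.sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual + self.intercept

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


def model_from_json(path) -> EnsembleModel:
    """Rebuild a serialized majority-vote model; decision rules are restored
    from their stored coefficients (primal for LDA/linear SVM, dual for the
    Gaussian SVM)."""
    with open(path) as fh:
        payload = json.load(fh)
    subs = []
    for d in payload["subclassifiers"]:
        if d["ml_method"] in ("lda", "linsvm"):
            rule = _LinearRule(d["coef"], d["intercept"])
        else:
            rule = _RBFRule(d["support_vectors"], d["dual_coef"], d["intercept"], d["gamma"])
        subs.append(
            SubClassifier(
                iteration=d["iteration"],
                probes=d["probes"],
                ml_method=d["ml_method"],
                estimator=rule,
                mean=np.asarray(d["mean"], dtype=float),
                std=np.asarray(d["std"], dtype=float),
                shrinkage_applied=d.get("shrinkage_applied", False),
            )
        )
    return EnsembleModel(
        combo=tuple(payload["combo"]),
        k_star=payload["k_star"],
        subclassifiers=subs,
        provenance=payload.get("provenance", {}),
    )


def mean_roc(model: EnsembleModel, em: ExpressionMatrix, labels, n_grid: int = 101):
    """Vertically averaged ROC over subclassifiers on a fixed FPR grid,
    plus the mean per-subclassifier AUC."""
    truth = np.asarray(labels, dtype=int)
    if len(set(truth.tolist())) < 2:
        raise ValueError("ROC undefined: truth contains a single class")
    grid = np.linspace(0, 1, n_grid)
    tprs, aucs = [], []
    scores = model.mean_decision_scores(em)
    for s in scores:
        fpr, tpr, _ = roc_curve(truth, s)
        tprs.append(np.interp(grid, fpr, tpr))
        aucs.append(sk_auc(fpr, tpr))
    return grid, np.mean(tprs, axis=0), float(np.mean(aucs))
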