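"""Model/Results front end for the pipeline.

``TP53ClassifierModel`` bundles an expression matrix with a labeled cohort
and, on ``fit(seed)``, runs the full iterated-split ensemble procedure:
two-level splitting, per-iteration probe ranking with the FDR validity
gate, error curves over k for each requested (GR, ML) combination, model
selection by the one-standard-error rule, training of the majority-vote
master classifier at k*, the one-shot test-set evaluation, and pseudomutant
calling by both the test-FP and validation-majority routes. The returned
``TP53ClassifierResults`` carries the estimates, their uncertainties,
diagnostics, and a ``summary()`` table, in the style of a statsmodels
results object.

``PathwayDeregulationModel`` does the same for principal-curve pathway
deregulation scoring against a normal-tissue reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clinical as _clinical
from .core import (
    ExpressionMatrix,
    LabeledCohort,
    ProbeAnnotation,
    SplitPlan,
    make_split_plan,
    restrict_to_gene_list,
)
from .ensemble import (
    C_MIN_DEFAULT,
    EnsembleModel,
    build_error_curves,
    classification_error,
    train_subclassifier,
)
from .pds import PDSMatrix, compute_pds_matrix, differential_pds, member_gene_followup
from .pm import PMCallSet, call_pm_test, call_pm_validation, pm_fraction, probe_usage_ranking
from .ranking import rank_probes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable pipeline settings; defaults follow the reference procedure
    (100 iterations, at least 70 valid subclassifiers, FDR gate q=0.05,
    20% test and 20% validation fractions, uncompensated learning)."""

    gr_methods: tuple = ("corr",)
    ml_methods: tuple = ("linsvm",)
    n_iter: int = 100
    c_min: int = C_MIN_DEFAULT
    n_max: int = 300
    q: float = 0.05
    test_frac: float = 0.2
    val_frac: float = 0.2
    class_weighting: bool = False
    k_max: int | None = None
    gene_list: list | None = None

    def to_dict(self) -> dict:
        return {
            "gr_methods": list(self.gr_methods),
            "ml_methods": list(self.ml_methods),
            "n_iter": self.n_iter,
            "c_min": self.c_min,
            "n_max": self.n_max,
            "q": self.q,
            "test_frac": self.test_frac,
            "val_frac": self.val_frac,
            "class_weighting": self.class_weighting,
            "k_max": self.k_max,
            "gene_list_size": len(self.gene_list) if self.gene_list else None,
        }


class TP53ClassifierModel:
    """Expression-based wt/mut TP53 classifier specification.

    Parameters
    ----------
    em : ExpressionMatrix
        Log2 expression, probes x samples (tumors; normals are ignored).
    cohort : LabeledCohort
        Sample annotations with binarized TP53 labels.
    annotation : ProbeAnnotation, optional
        Needed when ``config.gene_list`` restricts the feature universe.
    config : PipelineConfig
    """

    def __init__(
        self,
        em: ExpressionMatrix,
        cohort: LabeledCohort,
        annotation: ProbeAnnotation | None = None,
        config: PipelineConfig | None = None,
    ):
        self.config = config or PipelineConfig()
        self.cohort = cohort
        self.annotation = annotation
        tumor_ids = [s for s in em.sample_ids if s in set(cohort.tumor_ids)]
        em = em.subset_samples(tumor_ids)
        if self.config.gene_list is not None:
            if annotation is None:
                raise ValueError("gene_list restriction requires a probe annotation")
            em = restrict_to_gene_list(em, annotation, self.config.gene_list)
        self.em = em

    @classmethod
    def from_dataframes(cls, expr: pd.DataFrame, annot: pd.DataFrame, **kwargs):
        """Construct from raw pandas frames (probes x samples expression;
        cohort table indexed by sample_id)."""
        return cls(ExpressionMatrix(expr), LabeledCohort(annot), **kwargs)

    def fit(self, seed: int = 0) -> "TP53ClassifierResults":
        cfg = self.config
        plan = make_split_plan(
            _restricted_cohort(self.cohort, self.em.sample_ids),
            test_frac=cfg.test_frac,
            val_frac=cfg.val_frac,
            n_iter=cfg.n_iter,
            seed=seed,
        )
        em = self.em.drop_zero_variance(plan.learning_ids)
        labels = self.cohort.binary_labels(em.sample_ids)
        encoded = (labels == "mut").astype(int)

        # per-iteration ranked lists, per GR method (shared across ML methods)
        ranked_by_gr = {}
        for gr in cfg.gr_methods:
            kwargs = {"q": cfg.q}
            if gr in ("corr", "reg"):
                kwargs["n_max"] = cfg.n_max
            lists = []
            for train_ids, _ in plan.iterations:
                sub_em = em.subset_samples(train_ids).drop_zero_variance()
                lists.append(
                    rank_probes(gr, sub_em, encoded.loc[train_ids].to_numpy(), **kwargs)
                )
            ranked_by_gr[gr] = lists

        curves, records_by_combo = {}, {}
        for gr in cfg.gr_methods:
            for ml in cfg.ml_methods:
                curve, records = build_error_curves(
                    plan, em, encoded, ranked_by_gr[gr], ml,
                    k_max=cfg.k_max, c_min=cfg.c_min,
                    class_weighting=cfg.class_weighting,
                )
                curve.combo = (gr, ml)
                curves[(gr, ml)] = curve
                records_by_combo[(gr, ml)] = records

        from .ensemble import select_model

        combo, k_star = select_model(curves)
        gr_star, ml_star = combo
        records_k = records_by_combo[combo][k_star]

        # the master classifier: retrain the valid subclassifiers at k*
        subs = []
        for rec in records_k:
            train_ids, _ = plan.iterations[rec.iteration]
            subs.append(
                train_subclassifier(
                    em.subset_samples(train_ids),
                    encoded.loc[train_ids].to_numpy(),
                    rec.probes,
                    ml_star,
                    iteration=rec.iteration,
                    class_weighting=cfg.class_weighting,
                )
            )
        ensemble = EnsembleModel(
            combo=combo,
            k_star=k_star,
            subclassifiers=subs,
            provenance={"seed": seed, "config": cfg.to_dict()},
        )

        # one-shot test evaluation
        test_pred, test_frac_votes = ensemble.majority_vote_predict(em, plan.test_ids)
        test_truth = encoded.loc[plan.test_ids].to_numpy()
        test_error, confusion = classification_error(test_pred, test_truth)

        pm_test = call_pm_test(ensemble, em, labels.loc[plan.test_ids])
        pm_val = call_pm_validation(records_k, labels.loc[plan.learning_ids])
        pm_calls = pm_test.combine(pm_val)

        curve = curves[combo]
        idx = curve.ks.index(k_star)
        usage = probe_usage_ranking(ranked_by_gr[gr_star], k_star)
        return TP53ClassifierResults(
            model=self,
            em=em,
            labels=labels,
            plan=plan,
            curves=curves,
            error_curve=curve,
            combo=combo,
            k_star=k_star,
            ensemble=ensemble,
            records_k_star=records_k,
            validation_error=curve.val_mean[idx],
            validation_sem=curve.val_sem[idx],
            training_error=curve.train_mean[idx],
            training_sem=curve.train_sem[idx],
            test_error=test_error,
            confusion=confusion,
            test_votes=pd.Series(test_frac_votes, index=plan.test_ids),
            pm_calls=pm_calls,
            probe_usage=usage,
            seed=seed,
        )


def _restricted_cohort(cohort: LabeledCohort, sample_ids) -> LabeledCohort:
    table = cohort.table.loc[list(sample_ids)].copy()
    return LabeledCohort(table.drop(columns=["binary_label"]))


@dataclass
class TP53ClassifierResults:
    """Fit results: the majority-vote ensemble, its error estimates, the
    test-set confusion table, and the pseudomutant call set."""

    model: TP53ClassifierModel
    em: ExpressionMatrix
    labels: pd.Series
    plan: SplitPlan
    curves: dict
    error_curve: object
    combo: tuple
    k_star: int
    ensemble: EnsembleModel
    records_k_star: list
    validation_error: float
    validation_sem: float
    training_error: float
    training_sem: float
    test_error: float
    confusion: dict
    test_votes: pd.Series
    pm_calls: PMCallSet
    probe_usage: pd.Series
    seed: int
    _auc_cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------ core
    def predict(self, em: ExpressionMatrix, sample_ids=None):
        """Majority-vote wt/mut call (0/1) and mut-vote fraction for new
        samples; subclassifiers lacking probe coverage abstain."""
        return self.ensemble.majority_vote_predict(em, sample_ids)

    @property
    def pm_fraction(self) -> float:
        """Fraction of the cohort's wt-by-sequence samples called PM."""
        wt_ids = [s for s in self.em.sample_ids if self.labels[s] == "wt"]
        return pm_fraction(self.pm_calls, wt_ids)

    def mean_auc(self, split: str = "validation") -> float:
        """Mean per-subclassifier ROC AUC, each subclassifier scored on its
        own iteration's training or validation samples."""
        if split in self._auc_cache:
            return self._auc_cache[split]
        from sklearn.metrics import roc_auc_score

        encoded = (self.labels == "mut").astype(int)
        aucs = []
        for sub in self.ensemble.subclassifiers:
            train_ids, val_ids = self.plan.iterations[sub.iteration]
            ids = val_ids if split == "validation" else train_ids
            truth = encoded.loc[ids].to_numpy()
            if truth.min() == truth.max():
                continue
            scores = sub.decision_score(self.em, ids)
            aucs.append(roc_auc_score(truth, scores))
        value = float(np.mean(aucs))
        self._auc_cache[split] = value
        return value

    def embedding(self, method: str = "pca") -> pd.DataFrame:
        """2-D embedding of all samples in the space of the most-used probes."""
        from .pm import embed_2d

        em_top = self.em.subset_probes(list(self.probe_usage.index))
        return embed_2d(em_top, method=method, random_state=self.seed)

    # ------------------------------------------------------------- reporting
    def summary(self) -> str:
        c = self.confusion
        n_test = sum(c.values())
        pm_tab = self.pm_calls.table
        n_pm_test = int(((pm_tab["call"] == "PM") & (pm_tab["provenance"] == "test_FP")).sum())
        n_pm_val = int(((pm_tab["call"] == "PM") & (pm_tab["provenance"] == "validation_majority")).sum())
        lines = [
            "            TP53 wt/mut ensemble classifier",
            "=" * 60,
            f"Samples (learning/test):     {len(self.plan.learning_ids)} / {len(self.plan.test_ids)}",
            f"Iterations (valid at k*):    {self.plan.n_iter} ({self.ensemble.n_voters})",
            f"Selected GR* / ML*:          {self.combo[0]} / {self.combo[1]}",
            f"Selected probes k*:          {self.k_star}",
            f"Validation error:            {self.validation_error:.4f} +/- {self.validation_sem:.4f} (SEM)",
            f"Training error:              {self.training_error:.4f} +/- {self.training_sem:.4f} (SEM)",
            f"Test error (majority vote):  {self.test_error:.4f}",
            f"Test confusion (mut=pos):    TP={c['TP']} FP={c['FP']} FN={c['FN']} TN={c['TN']} (n={n_test})",
            f"Pseudomutants:               {len(self.pm_calls.pm_ids)} "
            f"({n_pm_test} test FP + {n_pm_val} validation-majority)",
            f"PM fraction of wt samples:   {self.pm_fraction:.4f}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot_error_curve(self, ax=None):
        """Mean training/validation error vs number of probes k, with SEM
        bands and the selected k* marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cv = self.error_curve
        ks = np.array(cv.ks)
        for mean, sem, label in (
            (cv.train_mean, cv.train_sem, "training"),
            (cv.val_mean, cv.val_sem, "validation"),
        ):
            mean, sem = np.array(mean), np.array(sem)
            ax.plot(ks, mean, label=label)
            ax.fill_between(ks, mean - sem, mean + sem, alpha=0.25)
        ax.axvline(self.k_star, ls="--", color="gray", label=f"k* = {self.k_star}")
        ax.set_xlabel("number of top-ranked probes k")
        ax.set_ylabel("classification error")
        ax.legend()
        return ax

    def plot_embedding(self, method: str = "pca", ax=None):
        """2-D embedding colored by wt/mut with PM samples circled."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        coords = self.embedding(method)
        pm = set(self.pm_calls.pm_ids)
        for group, color in (("wt", "tab:blue"), ("mut", "tab:red")):
            ids = [s for s in coords.index if self.labels.get(s) == group]
            ax.scatter(coords.loc[ids, "dim1"], coords.loc[ids, "dim2"],
                       s=12, c=color, label=group, alpha=0.6)
        pm_ids = [s for s in coords.index if s in pm]
        ax.scatter(coords.loc[pm_ids, "dim1"], coords.loc[pm_ids, "dim2"],
                   s=60, facecolors="none", edgecolors="black", label="PM")
        ax.set_xlabel(f"{method} 1")
        ax.set_ylabel(f"{method} 2")
        ax.legend()
        return ax

    # ------------------------------------------------------------- survival
    def survival_groups(self, hotspot_ids=None) -> pd.DataFrame:
        """Survival records grouped wt / mut / PM (/hotspot) using this
        fit's PM calls."""
        return _clinical.assign_survival_groups(
            _restricted_cohort(self.model.cohort, self.em.sample_ids),
            self.pm_calls.pm_ids,
            hotspot_ids=hotspot_ids,
        )


class PathwayDeregulationModel:
    """Principal-curve pathway deregulation scoring against a normal-tissue
    reference (tumors and normals are scored together)."""

    def __init__(
        self,
        em: ExpressionMatrix,
        pathways: dict,
        annotation: ProbeAnnotation,
        normal_ids,
        n_top_varying: int = 5000,
        rho_min: float = 0.75,
        n_subsamples: int = 20,
    ):
        self.em = em
        self.pathways = pathways
        self.annotation = annotation
        self.normal_ids = list(normal_ids)
        self.n_top_varying = n_top_varying
        self.rho_min = rho_min
        self.n_subsamples = n_subsamples

    def fit(self, seed: int = 0) -> "PDSResults":
        matrix = compute_pds_matrix(
            self.pathways,
            self.em,
            self.annotation,
            self.normal_ids,
            n_top_varying=self.n_top_varying,
            rho_min=self.rho_min,
            n_subsamples=self.n_subsamples,
            seed=seed,
        )
        return PDSResults(model=self, matrix=matrix, seed=seed)


@dataclass
class PDSResults:
    """Pathway x sample deregulation scores with stability flags and
    group-difference testing helpers."""

    model: PathwayDeregulationModel
    matrix: PDSMatrix
    seed: int

    @property
    def scores(self) -> pd.DataFrame:
        return self.matrix.scores

    @property
    def stable_pathways(self) -> list:
        return list(self.matrix.stable[self.matrix.stable].index)

    def group_means(self, groups: dict) -> pd.DataFrame:
        """Mean PDS per pathway for each named sample group (stable
        pathways only)."""
        stable = self.matrix.stable_scores()
        return pd.DataFrame(
            {name: stable[list(ids)].mean(axis=1) for name, ids in groups.items()}
        )

    def differential(self, group_a_ids, group_b_ids, q: float = 0.05) -> pd.DataFrame:
        """Welch t + BH-FDR per stable pathway between two groups."""
        return differential_pds(self.matrix.stable_scores(), group_a_ids, group_b_ids, q=q)

    def member_genes(self, significant: pd.DataFrame, group_a_ids, group_b_ids, q=0.05):
        """Probe-level follow-up across the member genes of pathways flagged
        in a ``differential`` result."""
        names = list(significant.index[significant["fdr_significant"]])
        sig_pathways = {n: self.model.pathways[n] for n in names}
        return member_gene_followup(
            sig_pathways, self.model.em, self.model.annotation,
            group_a_ids, group_b_ids, q=q,
        )

    def summary(self) -> str:
        n_total = len(self.model.pathways)
        n_scored = self.matrix.scores.shape[0]
        n_stable = len(self.stable_pathways)
        lines = [
            "       Pathway deregulation scoring (principal curves)",
            "=" * 60,
            f"Pathways supplied / scored:  {n_total} / {n_scored}",
            f"Stable pathways (rho >= {self.model.rho_min}): {n_stable}",
            f"Samples scored:              {self.matrix.scores.shape[1]}"
            f" ({len(self.model.normal_ids)} normals as reference)",
            f"Score range:                 [{self.matrix.scores.min().min():.3f},"
            f" {self.matrix.scores.max().max():.3f}]",
            "=" * 60,
        ]
        return "\n".join(lines)
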