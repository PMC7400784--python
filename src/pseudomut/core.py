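"""Core data model: expression matrices, probe annotation, labeled cohorts,
and the two-level random splitting scheme.

All containers are thin, validated wrappers around pandas objects so the rest
of the pipeline can rely on clean invariants: unique identifiers, finite
values, and a consistent wt/mut binarization of TP53 sequencing calls
(synonymous-only samples count as wild-type; missense and null alike count as
mutant). Normal-tissue samples carry no binary label and never enter
classifier learning; they serve only as the reference for pathway
deregulation scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

P53_CLASSES = ("wt", "missense", "null")
SUBTYPES = ("ER+Her2-", "ER-Her2-", "Her2+", "normal")


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one top-level seed.

    All randomness in the pipeline flows from a single integer through this
    hierarchical scheme (seed -> split plan -> per-iteration streams), so a
    run is fully reproducible from its top-level seed.
    """
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


class ExpressionMatrix:
    """Log2-intensity expression values, probes x samples."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate probe ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate sample ids: {dups}")
        if data.shape[0] < 1 or data.shape[1] < 2:
            raise ValueError("need at least 1 probe and 2 samples")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            # locate the first offending cell for the error message
            for col in data.columns:
                coerced = pd.to_numeric(data[col], errors="coerce")
                bad = coerced.isna() & data[col].notna()
                if bad.any():
                    row = data.index[bad.to_numpy().argmax()]
                    raise ValueError(f"non-numeric value at probe {row!r}, sample {col!r}")
            raise ValueError("non-numeric expression values")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at probe {data.index[bad[0]]!r}, sample {data.columns[bad[1]]!r}"
            )
        self.data = data.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(probes)])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)])

    def drop_zero_variance(self, sample_ids=None) -> "ExpressionMatrix":
        """Drop probes with zero variance across the given samples (default all).

        Correlation ranking is undefined for constant probes, so they are
        removed up front; the count removed is logged.
        """
        sub = self.data if sample_ids is None else self.data[list(sample_ids)]
        keep = sub.std(axis=1, ddof=0) > 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d zero-variance probes", n_dropped)
        return ExpressionMatrix(self.data.loc[keep])

    def to_tsv(self, path) -> None:
        # shortest-repr floats + round_trip parsing keep write/load lossless
        self.data.to_csv(path, sep="\t", index_label="probe_id")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


class ProbeAnnotation:
    """Mapping probe_id -> gene_symbol (several probes may share a gene)."""

    def __init__(self, mapping: pd.Series):
        if mapping.index.has_duplicates:
            raise ValueError("duplicate probe ids in annotation")
        if mapping.isna().any() or (mapping.astype(str).str.len() == 0).any():
            raise ValueError("empty gene symbol in annotation")
        self.mapping = mapping.astype(str)
        self.mapping.index = self.mapping.index.astype(str)

    def gene_of(self, probe_id: str) -> str:
        return self.mapping[probe_id]

    def probes_for_genes(self, genes) -> list[str]:
        genes = set(genes)
        return [p for p, g in self.mapping.items() if g in genes]

    @property
    def n_genes(self) -> int:
        return self.mapping.nunique()

    def subset(self, probes) -> "ProbeAnnotation":
        return ProbeAnnotation(self.mapping.loc[list(probes)])

    def to_csv(self, path) -> None:
        df = self.mapping.rename("gene_symbol").to_frame()
        df.to_csv(path, index_label="probe_id")


class LabeledCohort:
    """Per-sample annotations: TP53 class, binary label, subtype, cohort,
    survival, and (synthetic cohorts only) a ground-truth pseudomutant flag.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"p53_class", "subtype", "cohort_id"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if table.index.has_duplicates:
            raise ValueError("duplicate sample ids in cohort table")
        bad = set(table["p53_class"].dropna().unique()) - set(P53_CLASSES)
        if bad:
            raise ValueError(f"unknown p53_class values: {sorted(bad)}")
        table = table.copy()
        is_normal = table["subtype"] == "normal"
        binary = table["p53_class"].map(lambda c: "wt" if c == "wt" else "mut")
        binary[is_normal] = np.nan
        table["binary_label"] = binary
        self.table = table
        n_wt = int((binary == "wt").sum())
        n_mut = int((binary == "mut").sum())
        logger.info("cohort: %d wt, %d mut, %d normal", n_wt, n_mut, int(is_normal.sum()))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.table.index[self.table["subtype"] != "normal"])

    @property
    def normal_ids(self) -> list[str]:
        return list(self.table.index[self.table["subtype"] == "normal"])

    def binary_labels(self, sample_ids=None) -> pd.Series:
        """wt/mut labels for tumor samples (normals have none)."""
        labels = self.table["binary_label"]
        if sample_ids is not None:
            labels = labels.loc[list(sample_ids)]
        return labels

    def encoded_labels(self, sample_ids) -> np.ndarray:
        """Numeric encoding used throughout learning: wt=0, mut=1."""
        labels = self.binary_labels(sample_ids)
        if labels.isna().any():
            bad = labels.index[labels.isna()][:5].tolist()
            raise ValueError(f"samples without binary label (normals?): {bad}")
        return (labels == "mut").to_numpy(dtype=int)

    def wt_ids(self, among=None) -> list[str]:
        labels = self.binary_labels(among)
        return list(labels.index[labels == "wt"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="sample_id")


def binarize_labels(path) -> LabeledCohort:
    """Load a sample annotation CSV and binarize TP53 status.

    Samples without TP53 mutations (or with synonymous-only mutations,
    already recorded as class ``wt``) are labeled wt; missense and null
    mutations are both labeled mut.
    """
    table = pd.read_csv(path, index_col="sample_id")
    return LabeledCohort(table)


def load_expression_table(path, annotation_path) -> tuple[ExpressionMatrix, ProbeAnnotation]:
    """Read a probes-x-samples TSV plus a probe->gene annotation CSV.

    Probes lacking an annotation entry are dropped (logged); invariants
    (unique ids, finite numeric values) are enforced on load.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    raw.index = raw.index.astype(str)
    ann = pd.read_csv(annotation_path, index_col="probe_id")["gene_symbol"]
    ann.index = ann.index.astype(str)
    annotated = raw.index.intersection(ann.index)
    n_dropped = raw.shape[0] - len(annotated)
    if n_dropped:
        logger.info("dropped %d probes lacking annotation", n_dropped)
    em = ExpressionMatrix(raw.loc[[p for p in raw.index if p in set(annotated)]])
    return em, ProbeAnnotation(ann.loc[em.probe_ids])


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return genes


def restrict_to_gene_list(em: ExpressionMatrix, annotation: ProbeAnnotation, genes) -> ExpressionMatrix:
    """Keep exactly the probes annotated to genes in the list, preserving
    the original probe order (the knowledge-based feature-universe step)."""
    if not list(genes):
        raise ValueError("empty gene list")
    genes = set(genes)
    keep = [p for p in em.probe_ids if annotation.gene_of(p) in genes]
    if not keep:
        raise ValueError("gene list has empty intersection with annotated probes")
    return em.subset_probes(keep)


@dataclass
class SplitPlan:
    """One test/learning split plus ``n_iter`` train/validation splits of the
    learning set. The test set is drawn once and touched only once, at the
    very end; each iteration re-splits the learning set 80/20.
    """

    test_ids: list[str]
    learning_ids: list[str]
    iterations: list[tuple[list[str], list[str]]]  # (train_ids, validation_ids)
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def n_iter(self) -> int:
        return len(self.iterations)

    def validate(self) -> None:
        test, learning = set(self.test_ids), set(self.learning_ids)
        if test & learning:
            raise ValueError("test and learning sets overlap")
        for i, (train, val) in enumerate(self.iterations):
            train, val = set(train), set(val)
            if train | val != learning or train & val:
                raise ValueError(f"iteration {i} is not a partition of the learning set")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "test_ids": self.test_ids,
            "learning_ids": self.learning_ids,
            "iterations": [{"train": t, "validation": v} for t, v in self.iterations],
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            test_ids=payload["test_ids"],
            learning_ids=payload["learning_ids"],
            iterations=[(it["train"], it["validation"]) for it in payload["iterations"]],
            seed=payload["seed"],
            meta=payload.get("meta", {}),
        )


def _stratified_draw(ids_by_stratum: dict, frac: float, rng: np.random.Generator):
    """Draw ~frac of each stratum (rounded), returning (drawn, remaining)."""
    drawn, remaining = [], []
    for _, ids in sorted(ids_by_stratum.items()):
        ids = list(ids)
        k = int(round(frac * len(ids)))
        k = min(max(k, 1), len(ids) - 1) if len(ids) > 1 else k
        perm = rng.permutation(len(ids))
        drawn.extend(ids[i] for i in perm[:k])
        remaining.extend(ids[i] for i in perm[k:])
    return sorted(drawn), sorted(remaining)


def make_split_plan(
    cohort: LabeledCohort,
    test_frac: float = 0.2,
    val_frac: float = 0.2,
    n_iter: int = 100,
    seed: int = 0,
) -> SplitPlan:
    """Draw the two-level split plan.

    The test split is drawn once, stratified by binary label within each
    cohort_id (e.g. discovery/validation sub-cohorts are split separately);
    each of the ``n_iter`` iterations then splits the learning set into
    training (1 - val_frac) and validation (val_frac), stratified by binary
    label. Stratification guarantees both classes in every set despite the
    strong wt imbalance.
    """
    labels = cohort.binary_labels(cohort.tumor_ids)
    for cls in ("wt", "mut"):
        if (labels == cls).sum() < 5:
            raise ValueError(f"need at least 5 {cls} samples")
    seeds = derive_seeds(seed, n_iter + 1)
    rng = np.random.default_rng(seeds[0])

    strata = {}
    for sid in cohort.tumor_ids:
        key = (str(cohort.table.loc[sid, "cohort_id"]), labels[sid])
        strata.setdefault(key, []).append(sid)
    test_ids, learning_ids = _stratified_draw(strata, test_frac, rng)
    for cls in ("wt", "mut"):
        if not any(labels[s] == cls for s in learning_ids):
            raise ValueError(f"class {cls} absent from learning set")

    learn_strata = {}
    for sid in learning_ids:
        learn_strata.setdefault(labels[sid], []).append(sid)
    iterations = []
    for i in range(n_iter):
        it_rng = np.random.default_rng(seeds[i + 1])
        val, train = _stratified_draw(learn_strata, val_frac, it_rng)
        iterations.append((train, val))

    plan = SplitPlan(
        test_ids=test_ids,
        learning_ids=learning_ids,
        iterations=iterations,
        seed=seed,
        meta={"test_frac": test_frac, "val_frac": val_frac},
    )
    plan.validate()
    return plan


def read_gmt(path) -> dict[str, list[str]]:
    """Read pathway gene sets in GMT format (name, description, genes...)."""
    pathways = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            pathways[parts[0]] = [g for g in parts[2:] if g]
    return pathways


def write_gmt(pathways: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
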