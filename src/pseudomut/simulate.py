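"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the analysis assumes so every pipeline
stage can be tested against known answers: a wt/mut two-class expression
difference on a planted, block-correlated informative probe subset; strong
class imbalance (~82% wt, as in an ER+Her2- breast-cancer cohort of 1122 wt
vs 251 mut); a minority of wt-labeled samples drawn from the mut expression
distribution (planted pseudomutants); normal-tissue samples with reduced
variance; pathway probe sets driven nonlinearly by a latent per-sample
deregulation parameter ordered normal < wt < mut <= PM; and group-dependent
exponential survival (PM shares the mut hazard).

No attempt is made to imitate platform-level artifacts (bead-array probe
effects, RNA-seq count distributions); cross-platform application is modeled
abstractly by masking probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    LabeledCohort,
    ProbeAnnotation,
    derive_seeds,
)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Cohort sizes default to the ER+Her2- composition of the motivating
    dataset (1122 wt, 251 mut of which ~4% of wt are planted pseudomutants,
    144 normals). ``delta`` is the mut-vs-wt shift on informative probes in
    units of the probe noise SD; ``block_rho`` is the exchangeable
    correlation within blocks of 5 informative probes (co-regulated
    targets). ``probes_per_gene_excess`` is the fraction of genes carrying
    two probes (mimicking the ~425 probes / 272 genes ratio of curated
    lists). Hazards are per day; PM samples use the mut hazard.
    """

    n_wt: int = 1122
    n_mut: int = 251
    n_pm: int = 44
    n_normal: int = 144
    n_probes: int = 2000
    n_informative: int = 60
    delta: float = 1.0
    noise_sd: float = 1.0
    block_rho: float = 0.5
    block_size: int = 5
    probes_per_gene_excess: float = 0.5625
    missense_fraction: float = 0.61  # of mut samples (153 of 251)
    hotspot_fraction: float = 0.4  # of missense samples
    pm_mix: float = 1.0  # 1.0: PM drawn exactly from the mut distribution
    normal_var_shrink: float = 0.5
    n_pathways: int = 20
    n_noise_pathways: int = 2
    pathway_size: int = 15
    latent_sd: float = 0.3
    latent_means: dict = field(
        default_factory=lambda: {"normal": 0.0, "wt": 0.5, "mut": 1.5, "PM": 2.0}
    )
    pathway_noise_sd: float = 0.2
    hazard_wt: float = np.log(2) / 3650.0
    hazard_mut: float = 2 * np.log(2) / 3650.0
    censor_rate: float = np.log(2) / 5000.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_wt", "n_mut", "n_pm", "n_normal", "n_probes", "n_informative"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_informative > self.n_probes:
            raise ValueError("n_informative exceeds n_probes")
        if self.n_pm > self.n_wt:
            raise ValueError("planted PM samples are a subset of the wt-labeled samples")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if not (0 <= self.block_rho < 1):
            raise ValueError("block_rho must be in [0, 1)")
        if self.hazard_wt <= 0 or self.hazard_mut <= 0:
            raise ValueError("hazards must be > 0")
        if self.n_pathways >= 1 and self.pathway_size < 3:
            raise ValueError("pathway_size must be >= 3")


@dataclass
class SyntheticDataset:
    """Everything one synthetic study provides, with ground truth."""

    em: ExpressionMatrix
    annotation: ProbeAnnotation
    cohort: LabeledCohort
    pathways: dict
    latent: pd.Series
    survival: pd.DataFrame
    knowledge_genes: list
    config: SyntheticConfig

    @property
    def planted_pm_ids(self) -> list[str]:
        flags = self.cohort.table["pm_truth"]
        return list(flags.index[flags.fillna(False).astype(bool)])


def _make_annotation(probe_ids, excess: float) -> ProbeAnnotation:
    """Assign genes so that a fraction ``excess`` of genes carry two probes."""
    genes, i, g = [], 0, 0
    n = len(probe_ids)
    # deterministic interleaving: gene g carries two probes iff the running
    # fraction floor((g+1)*excess) advances, so the realized two-probe gene
    # fraction matches ``excess`` (e.g. 0.5625 -> 425 probes over 272 genes)
    while i < n:
        gene = f"GENE{g:05d}"
        take = 2 if int(np.floor((g + 1) * excess)) > int(np.floor(g * excess)) else 1
        for _ in range(min(take, n - i)):
            genes.append(gene)
            i += 1
        g += 1
    return ProbeAnnotation(pd.Series(genes, index=pd.Index(probe_ids, name="probe_id")))


def generate_expression(config: SyntheticConfig):
    """Expression matrix + probe annotation + labeled cohort with planted
    pseudomutants.

    wt samples follow the baseline Gaussian; mut samples are shifted by
    ``delta`` (random sign per probe) on the informative probes, which are
    correlated in exchangeable blocks; PM samples are drawn from the mut
    expression distribution (optionally mixed toward wt by ``pm_mix``) but
    labeled wt with ``pm_truth=True``; normals are baseline with shrunken
    variance.
    """
    config.validate()
    seeds = derive_seeds(config.seed, 4)
    rng = np.random.default_rng(seeds[0])

    n_tumor = config.n_wt + config.n_mut
    n_total = n_tumor + config.n_normal
    probe_ids = [f"PROBE{i:05d}" for i in range(config.n_probes)]
    sample_ids = (
        [f"WT{i:04d}" for i in range(config.n_wt)]
        + [f"MUT{i:04d}" for i in range(config.n_mut)]
        + [f"NORM{i:04d}" for i in range(config.n_normal)]
    )
    # the planted pseudomutants are the first n_pm wt-labeled samples;
    # identifiers carry no hint, the truth flag lives in the cohort table
    pm_idx = np.arange(config.n_pm)
    mut_idx = np.arange(config.n_wt, n_tumor)
    normal_idx = np.arange(n_tumor, n_total)

    baseline = rng.normal(7.0, 1.0, size=config.n_probes)
    noise = rng.standard_normal((config.n_probes, n_total))
    # exchangeable block correlation among informative probes
    m = config.n_informative
    if m and config.block_rho > 0:
        bs = config.block_size
        n_blocks = int(np.ceil(m / bs))
        shared = rng.standard_normal((n_blocks, n_total))
        for b in range(n_blocks):
            rows = slice(b * bs, min((b + 1) * bs, m))
            noise[rows] = (
                np.sqrt(config.block_rho) * shared[b]
                + np.sqrt(1 - config.block_rho) * noise[rows]
            )
    values = baseline[:, None] + config.noise_sd * noise
    values[:, normal_idx] = (
        baseline[:, None]
        + config.normal_var_shrink * config.noise_sd * noise[:, normal_idx]
    )
    # planted class shift: mut samples fully, PM samples with weight pm_mix
    signs = rng.choice([-1.0, 1.0], size=m)
    shift = (config.delta * config.noise_sd * signs)[:, None]
    values[:m, mut_idx] += shift
    if config.n_pm:
        values[:m, pm_idx] += config.pm_mix * shift

    em = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))
    annotation = _make_annotation(probe_ids, config.probes_per_gene_excess)

    n_missense = int(round(config.missense_fraction * config.n_mut))
    p53_class = (
        ["wt"] * config.n_wt
        + ["missense"] * n_missense
        + ["null"] * (config.n_mut - n_missense)
        + ["wt"] * config.n_normal
    )
    subtype = ["ER+Her2-"] * n_tumor + ["normal"] * config.n_normal
    cohort_rng = np.random.default_rng(seeds[1])
    cohort_id = np.where(cohort_rng.random(n_total) < 0.5, "discovery", "validation")
    cohort_id[normal_idx] = "normal_pool"
    n_hot = int(round(config.hotspot_fraction * n_missense))
    hotspot = np.zeros(n_total, dtype=bool)
    hotspot[config.n_wt : config.n_wt + n_hot] = True
    pm_truth = np.zeros(n_total, dtype=bool)
    pm_truth[pm_idx] = True
    table = pd.DataFrame(
        {
            "p53_class": p53_class,
            "subtype": subtype,
            "cohort_id": cohort_id,
            "hotspot": hotspot,
            "pm_truth": pm_truth,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return em, annotation, LabeledCohort(table)


def knowledge_gene_list(dataset_annotation: ProbeAnnotation, config: SyntheticConfig, em: ExpressionMatrix) -> list:
    """The knowledge-based feature universe: genes of the informative probes
    plus an equal number of background genes (a curated list contains true
    signal diluted with plausible but uninformative candidates)."""
    informative_probes = em.probe_ids[: config.n_informative]
    genes = []
    for p in informative_probes:
        g = dataset_annotation.gene_of(p)
        if g not in genes:
            genes.append(g)
    background = []
    for p in em.probe_ids[config.n_informative :]:
        g = dataset_annotation.gene_of(p)
        if g not in genes and g not in background:
            background.append(g)
        if len(background) >= len(genes):
            break
    return genes + background


def generate_pathways(config: SyntheticConfig, em: ExpressionMatrix, annotation: ProbeAnnotation, cohort: LabeledCohort):
    """Plant pathway structure into the expression matrix.

    Each true pathway's member probes become nonlinear functions
    (linear / quadratic / sigmoid mix) of a per-sample latent deregulation
    parameter plus noise, with group means ordered
    normal < wt < mut <= PM; noise pathways point at untouched background
    probes and should fail the stability filter. Returns the pathway gene
    sets, the latent parameter, and the updated expression matrix.
    """
    if config.n_pathways < 1:
        return {}, pd.Series(dtype=float), em
    if config.pathway_size < 3:
        raise ValueError("pathway_size must be >= 3")
    seeds = derive_seeds(config.seed, 4)
    rng = np.random.default_rng(seeds[2])

    table = cohort.table
    groups = np.where(
        table["subtype"] == "normal",
        "normal",
        np.where(
            table["pm_truth"].fillna(False).astype(bool),
            "PM",
            np.where(table["binary_label"] == "mut", "mut", "wt"),
        ),
    )
    means = np.array([config.latent_means[g] for g in groups])
    latent = pd.Series(
        means + config.latent_sd * rng.standard_normal(len(means)),
        index=table.index,
        name="latent_deregulation",
    )

    need = (config.n_pathways + config.n_noise_pathways) * config.pathway_size
    tail_start = config.n_probes - need
    if tail_start <= config.n_informative:
        raise ValueError("not enough probes to host the pathway blocks")
    values = em.data.to_numpy().copy()
    t = latent.loc[em.sample_ids].to_numpy()
    funcs = [
        lambda t: t,
        lambda t: 0.5 * t**2,
        lambda t: 1.0 / (1.0 + np.exp(-2.0 * (t - 1.0))),
    ]
    pathways: dict[str, list[str]] = {}
    for p in range(config.n_pathways):
        rows = [tail_start + p * config.pathway_size + j for j in range(config.pathway_size)]
        member_genes = []
        for j, row in enumerate(rows):
            amp = rng.uniform(1.5, 2.5)
            f = funcs[j % len(funcs)]
            base = values[row].mean()
            values[row] = (
                base + amp * f(t) + config.pathway_noise_sd * rng.standard_normal(len(t))
            )
            g = annotation.gene_of(em.probe_ids[row])
            if g not in member_genes:
                member_genes.append(g)
        pathways[f"PATHWAY_{p:03d}"] = member_genes
    for p in range(config.n_noise_pathways):
        rows = [
            tail_start + (config.n_pathways + p) * config.pathway_size + j
            for j in range(config.pathway_size)
        ]
        member_genes = []
        for row in rows:
            g = annotation.gene_of(em.probe_ids[row])
            if g not in member_genes:
                member_genes.append(g)
        pathways[f"NOISE_PATHWAY_{p:03d}"] = member_genes
    new_em = ExpressionMatrix(
        pd.DataFrame(values, index=em.probe_ids, columns=em.sample_ids)
    )
    return pathways, latent, new_em


def generate_survival(cohort: LabeledCohort, config: SyntheticConfig) -> pd.DataFrame:
    """Exponential event times with group hazards (PM shares the mut
    hazard) and independent exponential censoring; times in days."""
    seeds = derive_seeds(config.seed, 4)
    rng = np.random.default_rng(seeds[3])
    rows = []
    for sid in cohort.tumor_ids:
        rec = cohort.table.loc[sid]
        is_pm = bool(rec.get("pm_truth", False))
        hazard = config.hazard_mut if (rec["binary_label"] == "mut" or is_pm) else config.hazard_wt
        t_event = rng.exponential(1.0 / hazard)
        if config.censor_rate > 0:
            t_cens = rng.exponential(1.0 / config.censor_rate)
        else:
            t_cens = np.inf
        rows.append(
            {
                "sample_id": sid,
                "time_days": float(min(t_event, t_cens)),
                "event": bool(t_event <= t_cens),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_dataset(config: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """One-call generator: expression, annotation, labeled cohort (with
    survival columns filled in), pathways, latent parameter, knowledge list.
    Deterministic function of (config, config.seed)."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = SyntheticConfig(**{**asdict(config), **overrides})
    em, annotation, cohort = generate_expression(config)
    pathways, latent, em = generate_pathways(config, em, annotation, cohort)
    survival = generate_survival(cohort, config)
    table = cohort.table.copy()
    table["time_days"] = survival["time_days"]
    table["event"] = survival["event"]
    cohort = LabeledCohort(table.drop(columns=["binary_label"]))
    knowledge = knowledge_gene_list(annotation, config, em)
    return SyntheticDataset(
        em=em,
        annotation=annotation,
        cohort=cohort,
        pathways=pathways,
        latent=latent,
        survival=survival,
        knowledge_genes=knowledge,
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write the standard file layout: expr.tsv, probes.csv, annot.csv,
    pathways.gmt, truth.csv, knowledge_genes.txt."""
    import os

    from .core import write_gmt

    os.makedirs(outdir, exist_ok=True)
    dataset.em.to_tsv(os.path.join(outdir, "expr.tsv"))
    dataset.annotation.to_csv(os.path.join(outdir, "probes.csv"))
    dataset.cohort.to_csv(os.path.join(outdir, "annot.csv"))
    write_gmt(dataset.pathways, os.path.join(outdir, "pathways.gmt"))
    truth = dataset.cohort.table[["pm_truth"]].copy()
    truth["latent_deregulation"] = dataset.latent
    truth.to_csv(os.path.join(outdir, "truth.csv"), index_label="sample_id")
    with open(os.path.join(outdir, "knowledge_genes.txt"), "w") as fh:
        fh.write("\n".join(dataset.knowledge_genes) + "\n")
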