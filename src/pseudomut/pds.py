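"""Principal-curve Pathway Deregulation Scores (PDS).

For each pathway, a one-dimensional principal curve is fit through the
cloud of samples in the space of the pathway's (top-varying, standardized)
probes. A sample's PDS is its arc-length distance along that curve from the
projection of the normal-tissue centroid, normalized to [0, 1] — 0 means
"transcriptionally like normal tissue", 1 is the most deregulated sample.
The curve is fit with a Hastie–Stuetzle alternation: initialize with the
first principal component, then alternate projection onto the current curve
with per-coordinate scatter-plot smoothing against the projection index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, ProbeAnnotation
from .ranking import bh_fdr_filter

logger = logging.getLogger(__name__)


def select_top_varying_probes(em: ExpressionMatrix, n: int = 5000) -> list[str]:
    """The n probes with highest variance across all samples (tumors and
    normals together); ties broken by lexical probe order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    var = em.data.var(axis=1, ddof=1)
    order = sorted(range(len(var)), key=lambda i: (-var.iloc[i], em.probe_ids[i]))
    return [em.probe_ids[i] for i in order[:n]]


def _running_line_smooth(x_sorted: np.ndarray, y_sorted: np.ndarray, span: float) -> np.ndarray:
    """Fixed-span running local-linear smoother of y against sorted x.

    A least-squares line is fit in each sliding window and evaluated at the
    window's center point; unlike a running mean this reproduces linear
    trends exactly (no endpoint shrinkage), which a principal-curve smoother
    needs so that collinear data yield the line itself.
    """
    n = len(x_sorted)
    half = max(int(np.ceil(span * n / 2)), 2)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    cx = np.concatenate([[0.0], np.cumsum(x_sorted)])
    cy = np.concatenate([[0.0], np.cumsum(y_sorted)])
    cxx = np.concatenate([[0.0], np.cumsum(x_sorted**2)])
    cxy = np.concatenate([[0.0], np.cumsum(x_sorted * y_sorted)])
    m = hi - lo
    sx = cx[hi] - cx[lo]
    sy = cy[hi] - cy[lo]
    sxx = cxx[hi] - cxx[lo]
    sxy = cxy[hi] - cxy[lo]
    var = sxx - sx**2 / m
    cov = sxy - sx * sy / m
    slope = np.where(var > 1e-12, cov / np.where(var > 1e-12, var, 1.0), 0.0)
    return sy / m + slope * (x_sorted - sx / m)


def _project_to_polyline(points: np.ndarray, nodes: np.ndarray):
    """Project each point onto a polyline; return arc-length coordinates and
    squared distances.

    ``nodes`` is an ordered (m x d) array of curve nodes.
    """
    seg = nodes[1:] - nodes[:-1]  # (m-1) x d
    seg_len2 = (seg**2).sum(axis=1)
    seg_len2 = np.where(seg_len2 > 0, seg_len2, 1e-300)
    arc = np.concatenate([[0.0], np.cumsum(np.sqrt((seg**2).sum(axis=1)))])
    n = len(points)
    lam = np.empty(n)
    dist2 = np.empty(n)
    # block over points: the n x (m-1) x d tensor is too large at cohort scale
    block = max(1, int(2_000_000 // max(len(seg) * points.shape[1], 1)))
    for start in range(0, n, block):
        pts = points[start : start + block]
        diffs = pts[:, None, :] - nodes[None, :-1, :]  # b x (m-1) x d
        t = np.einsum("nsd,sd->ns", diffs, seg) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        proj = nodes[None, :-1, :] + t[:, :, None] * seg[None, :, :]
        d2 = ((pts[:, None, :] - proj) ** 2).sum(axis=2)
        best = d2.argmin(axis=1)
        idx = np.arange(len(pts))
        lam[start : start + block] = arc[best] + t[idx, best] * np.sqrt(seg_len2[best])
        dist2[start : start + block] = d2[idx, best]
    return lam, dist2


@dataclass
class PrincipalCurve:
    """A fitted principal curve: ordered nodes, per-sample arc-length
    coordinate, and convergence diagnostics."""

    nodes: np.ndarray
    arc_coord: np.ndarray
    mean_sq_dist: float
    converged: bool
    n_iter: int


def fit_principal_curve(
    points: np.ndarray,
    span: float = 0.3,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> PrincipalCurve:
    """Hastie–Stuetzle principal curve through ``points`` (samples x dims).

    Starts from the first-principal-component line; alternates projection
    onto the current polyline with per-coordinate local-linear smoothing of
    the data against the projection order, until the mean squared projection
    distance changes by less than ``tol`` (relative) or ``max_iter`` is hit
    (returned with ``converged=False``).
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    if n < 10:
        raise ValueError("need at least 10 samples to fit a principal curve")
    center = points.mean(axis=0)
    X = points - center
    # initialization: projection onto the first principal component
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    direction = vt[0]
    lam = X @ direction
    prev_msd = np.inf
    converged = False
    nodes = None
    for it in range(1, max_iter + 1):
        order = np.argsort(lam, kind="stable")
        smoothed = np.empty_like(X)
        for j in range(d):
            smoothed[order, j] = _running_line_smooth(lam[order], X[order, j], span)
        nodes = smoothed[order]
        # de-duplicate consecutive identical nodes to keep segments well posed
        keep = np.concatenate([[True], np.linalg.norm(np.diff(nodes, axis=0), axis=1) > 1e-12])
        nodes = nodes[keep]
        if len(nodes) < 2:
            nodes = np.vstack([X.min(axis=0), X.max(axis=0)])
        lam, d2 = _project_to_polyline(X, nodes)
        msd = float(d2.mean())
        if np.isfinite(prev_msd) and abs(prev_msd - msd) <= tol * max(prev_msd, 1e-12):
            converged = True
            prev_msd = msd
            break
        prev_msd = msd
    if not converged:
        logger.info("principal curve did not converge in %d iterations", max_iter)
    return PrincipalCurve(
        nodes=nodes + center,
        arc_coord=lam,
        mean_sq_dist=prev_msd,
        converged=converged,
        n_iter=it,
    )


def _pathway_probe_matrix(
    pathway_genes, em: ExpressionMatrix, annotation: ProbeAnnotation, retained_probes
):
    genes = set(pathway_genes)
    retained = set(retained_probes)
    probes = [p for p in em.probe_ids if p in retained and annotation.gene_of(p) in genes]
    return probes


def compute_pds(
    pathway_genes,
    em: ExpressionMatrix,
    annotation: ProbeAnnotation,
    normal_ids,
    retained_probes=None,
    span: float = 0.3,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> pd.Series:
    """Pathway Deregulation Score D(P, k) for every sample k.

    The principal curve is fit on all samples (tumors + normals) in the
    pathway's standardized probe space. The curve is oriented so the
    normal-sample centroid projects to the low-arc-length end; each sample's
    score is its signed arc-length distance from that reference projection,
    negatives clipped to 0, normalized by the maximum so scores span [0, 1].
    """
    normal_ids = list(normal_ids)
    if len(normal_ids) < 5:
        raise ValueError("need at least 5 normal samples as the PDS reference")
    if retained_probes is None:
        retained_probes = em.probe_ids
    probes = _pathway_probe_matrix(pathway_genes, em, annotation, retained_probes)
    if len(probes) < 3:
        raise ValueError(f"pathway maps to {len(probes)} retained probes (<3)")
    X = em.data.loc[probes].to_numpy().T  # samples x probes
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    curve = fit_principal_curve(X, span=span, max_iter=max_iter, tol=tol)
    lam = curve.arc_coord
    normal_pos = [em.sample_ids.index(s) for s in normal_ids]
    centroid = X[normal_pos].mean(axis=0, keepdims=True)
    # project the normal centroid onto the same (centered) curve frame
    center = X.mean(axis=0)
    lam0_arr, _ = _project_to_polyline(centroid - center, curve.nodes - center)
    lam0 = float(lam0_arr[0])
    # orient: normals at the low end
    if np.mean(lam[normal_pos]) > np.mean(lam):
        total = _polyline_length(curve.nodes)
        lam = total - lam
        lam0 = total - lam0
    scores = np.clip(lam - lam0, 0.0, None)
    m = scores.max()
    if m > 0:
        scores = scores / m
    return pd.Series(scores, index=em.sample_ids)


def _polyline_length(nodes: np.ndarray) -> float:
    return float(np.sqrt(((nodes[1:] - nodes[:-1]) ** 2).sum(axis=1)).sum())


@dataclass
class PDSMatrix:
    """Pathway x sample deregulation scores with per-pathway stability."""

    scores: pd.DataFrame  # pathways x samples, values in [0, 1]
    stable: pd.Series  # bool per pathway
    skipped: list[str] = field(default_factory=list)

    def stable_scores(self) -> pd.DataFrame:
        return self.scores.loc[self.stable[self.stable].index]

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="pathway")


def stability_filter(
    pathway_genes,
    em: ExpressionMatrix,
    annotation: ProbeAnnotation,
    normal_ids,
    full_pds: pd.Series,
    n_subsamples: int = 20,
    frac: float = 0.8,
    rho_min: float = 0.75,
    seed: int = 0,
    retained_probes=None,
) -> bool:
    """A pathway is stable if its PDS survives subsampling: recompute the
    score on random ``frac`` subsets of samples and require the median
    Spearman correlation with the full-data PDS (on shared samples) to reach
    ``rho_min``."""
    if n_subsamples == 0:
        warnings.warn("stability_filter with n_subsamples=0 is trivially stable")
        return True
    rng = np.random.default_rng(seed)
    sample_ids = np.array(em.sample_ids)
    normal_set = set(normal_ids)
    rhos = []
    for _ in range(n_subsamples):
        keep = rng.random(len(sample_ids)) < frac
        # the reference normals must survive subsampling
        keep |= np.isin(sample_ids, list(normal_set))
        sub_ids = sample_ids[keep]
        if len(sub_ids) < 10:
            continue
        sub_em = em.subset_samples(sub_ids)
        try:
            sub_pds = compute_pds(
                pathway_genes, sub_em, annotation, list(normal_set),
                retained_probes=retained_probes,
            )
        except ValueError:
            continue
        rho = stats.spearmanr(sub_pds.values, full_pds.loc[sub_ids].values).statistic
        rhos.append(rho)
    if not rhos:
        return False
    return bool(np.median(rhos) >= rho_min)


def compute_pds_matrix(
    pathways: dict[str, list[str]],
    em: ExpressionMatrix,
    annotation: ProbeAnnotation,
    normal_ids,
    n_top_varying: int = 5000,
    rho_min: float = 0.75,
    n_subsamples: int = 20,
    seed: int = 0,
) -> PDSMatrix:
    """PDS for every pathway that maps to >=3 retained probes, with the
    subsampling stability flag; unmappable pathways are skipped (logged)."""
    retained = set(select_top_varying_probes(em, n_top_varying))
    rows, stable, skipped = {}, {}, []
    for name, genes in pathways.items():
        try:
            pds = compute_pds(genes, em, annotation, normal_ids, retained_probes=retained)
        except ValueError as exc:
            logger.info("skipping pathway %s: %s", name, exc)
            skipped.append(name)
            continue
        rows[name] = pds
        stable[name] = stability_filter(
            genes, em, annotation, normal_ids, pds,
            n_subsamples=n_subsamples, rho_min=rho_min, seed=seed,
            retained_probes=retained,
        )
    scores = pd.DataFrame(rows).T
    return PDSMatrix(scores=scores, stable=pd.Series(stable, dtype=bool), skipped=skipped)


def differential_pds(
    pds: pd.DataFrame, group_a_ids, group_b_ids, q: float = 0.05
) -> pd.DataFrame:
    """Per-pathway Welch two-sided t-test between two sample groups with a
    BH-FDR flag across pathways (q = 0.05 for PM vs wt; the PM-vs-mut
    contrast uses a laxer q = 0.1)."""
    a = pds[list(group_a_ids)].to_numpy()
    b = pds[list(group_b_ids)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    tstat = np.empty(len(pds))
    pval = np.ones(len(pds))
    flagged_degenerate = np.zeros(len(pds), dtype=bool)
    for i in range(len(pds)):
        if a[i].std(ddof=1) == 0 and b[i].std(ddof=1) == 0:
            tstat[i], pval[i] = 0.0, 1.0
            flagged_degenerate[i] = True
        else:
            res = stats.ttest_ind(a[i], b[i], equal_var=False)
            tstat[i], pval[i] = res.statistic, res.pvalue
    return pd.DataFrame(
        {
            "t": tstat,
            "p": pval,
            "fdr_significant": bh_fdr_filter(pval, q),
            "zero_variance": flagged_degenerate,
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
        },
        index=pds.index,
    )


def member_gene_followup(
    significant_pathways: dict[str, list[str]],
    em: ExpressionMatrix,
    annotation: ProbeAnnotation,
    group_a_ids,
    group_b_ids,
    q: float = 0.05,
) -> pd.DataFrame:
    """Test every probe of the member genes of the significant pathways for
    differential expression between the two groups (Welch t + BH across the
    tested probes). Returns an empty frame when no pathway is supplied."""
    genes = set()
    for members in significant_pathways.values():
        genes |= set(members)
    probes = [p for p in em.probe_ids if annotation.gene_of(p) in genes]
    if not probes:
        return pd.DataFrame(columns=["gene", "t", "p", "fdr_significant"])
    a = em.data.loc[probes, list(group_a_ids)].to_numpy()
    b = em.data.loc[probes, list(group_b_ids)].to_numpy()
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    return pd.DataFrame(
        {
            "gene": [annotation.gene_of(p) for p in probes],
            "t": res.statistic,
            "p": pvals,
            "fdr_significant": bh_fdr_filter(pvals, q),
        },
        index=pd.Index(probes, name="probe_id"),
    )


def leaf_order(pds: pd.DataFrame, axis: str = "samples") -> list[str]:
    """Hierarchical average-linkage ordering with optimal leaf ordering,
    used to place samples (or pathways) with similar deregulation profiles
    next to each other in heatmaps."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    M = pds.to_numpy().T if axis == "samples" else pds.to_numpy()
    names = list(pds.columns) if axis == "samples" else list(pds.index)
    if len(names) < 3:
        return names
    dist = pdist(M, metric="euclidean")
    Z = hierarchy.linkage(dist, method="average")
    Z = hierarchy.optimal_leaf_ordering(Z, dist)
    return [names[i] for i in hierarchy.leaves_list(Z)]
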