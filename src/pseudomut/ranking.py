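"""Gene-probe ranking (GR) methods and the BH-FDR validity gate.

Four rankers order candidate probes by their association with the binary
TP53 label (wt=0, mut=1):

* ``correlation_rank`` — absolute Pearson correlation with the label.
* ``regression_rank`` — |t| of the slope of a univariate least-squares fit
  (order-equivalent to correlation at fixed n; kept as a distinct code path
  for pipeline fidelity).
* ``fsw_rank`` — forward-selection wrapper: greedily add the probe that most
  reduces the training error of a refit learner.
* ``omp_rank`` — orthogonal matching pursuit on standardized probes against
  the centered label.

Every ranked list is gated by Benjamini–Hochberg FDR at q on the per-probe
marginal (Pearson) p-values: a probe is only usable in a "valid" classifier
if it individually passes the gate. For the wrapper methods the candidate
pool is restricted to gate-passing probes up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix

N_MAX = 300


@dataclass
class RankedProbeList:
    """Ordered probes with their ranking scores and FDR gate flags.

    Probes are sorted by the method's criterion, larger score first, ties
    broken by probe_id lexical order; length is capped at ``n_max``.
    """

    probe_ids: list[str]
    scores: np.ndarray
    p_values: np.ndarray
    fdr_pass: np.ndarray
    method: str
    n_max: int = N_MAX
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probe_ids)

    def top(self, k: int) -> list[str]:
        if k > len(self.probe_ids):
            raise ValueError(f"requested top {k} of a {len(self.probe_ids)}-probe list")
        return self.probe_ids[:k]

    def n_valid_prefix(self) -> int:
        """Length of the longest prefix in which every probe passes FDR."""
        if not len(self.fdr_pass):
            return 0
        failing = np.nonzero(~self.fdr_pass)[0]
        return int(failing[0]) if len(failing) else len(self.fdr_pass)


def bh_fdr_filter(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up gate; boolean per p-value, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _check_labels(em: ExpressionMatrix, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape[0] != em.shape[1]:
        raise ValueError("label vector length does not match sample count")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be encoded 0 (wt) / 1 (mut)")
    for cls in (0, 1):
        if (labels == cls).sum() < 2:
            raise ValueError("need at least 2 samples per class")
    return labels.astype(float)


def _pearson_with_label(em: ExpressionMatrix, labels: np.ndarray):
    """Vectorized per-probe Pearson r with the label and its t-transform p."""
    X = em.data.to_numpy()
    y = labels - labels.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    if np.any(sx == 0):
        bad = [em.probe_ids[i] for i in np.nonzero(sx == 0)[0][:5]]
        raise ValueError(f"zero-variance probes reached ranking: {bad}")
    r = Xc @ y / (sx * np.sqrt((y**2).sum()))
    r = np.clip(r, -1.0, 1.0)
    n = X.shape[1]
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


def _order(scores: np.ndarray, probe_ids: list[str]) -> np.ndarray:
    """Descending by score, ties by probe_id lexical order."""
    return np.lexsort((np.array(probe_ids), -scores))


def _assemble(probe_ids, scores, p_values, method, q, n_max, keep_all=False, meta=None):
    fdr = bh_fdr_filter(p_values, q)
    order = _order(np.asarray(scores, float), list(probe_ids))
    if not keep_all:
        order = order[fdr[order]]
    order = order[:n_max]
    return RankedProbeList(
        probe_ids=[probe_ids[i] for i in order],
        scores=np.asarray(scores, float)[order],
        p_values=np.asarray(p_values, float)[order],
        fdr_pass=fdr[order],
        method=method,
        n_max=n_max,
        meta=meta or {},
    )


def correlation_rank(em: ExpressionMatrix, labels, q: float = 0.05, n_max: int = N_MAX) -> RankedProbeList:
    """Rank by |Pearson r| between each probe's expression and the label."""
    labels = _check_labels(em, labels)
    r, p = _pearson_with_label(em, labels)
    return _assemble(em.probe_ids, np.abs(r), p, "corr", q, n_max)


def regression_rank(em: ExpressionMatrix, labels, q: float = 0.05, n_max: int = N_MAX) -> RankedProbeList:
    """Rank by |t| of the slope of the per-probe univariate OLS fit of the
    label on expression (two-parameter fit: slope + intercept)."""
    labels = _check_labels(em, labels)
    X = em.data.to_numpy()
    n = X.shape[1]
    xm = X.mean(axis=1, keepdims=True)
    ym = labels.mean()
    sxx = ((X - xm) ** 2).sum(axis=1)
    if np.any(sxx == 0):
        bad = [em.probe_ids[i] for i in np.nonzero(sxx == 0)[0][:5]]
        raise ValueError(f"zero-variance probes reached ranking: {bad}")
    sxy = ((X - xm) * (labels - ym)).sum(axis=1)
    slope = sxy / sxx
    resid = (labels - ym) - slope[:, None] * (X - xm)
    rss = (resid**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (n - 2) / sxx)
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return _assemble(em.probe_ids, np.abs(t), p, "reg", q, n_max)


def fsw_rank(
    em: ExpressionMatrix,
    labels,
    ml_method: str = "linsvm",
    max_features: int = 20,
    q: float = 0.05,
) -> RankedProbeList:
    """Forward-selection wrapper: the ranking is the order of greedy addition.

    At step j the probe minimizing the training-set classification error of
    the learner refit on the j selected probes is added; ties are broken by
    higher |Pearson r| with the label, then lexical probe order. All probes
    are candidates — the wrapper can pick up jointly informative probes that
    are marginally null — but each selected probe carries its marginal
    Pearson BH-FDR flag, which the downstream validity rule consumes.
    """
    from .ensemble import make_learner  # deferred: avoids import cycle

    labels_f = _check_labels(em, labels)
    y = labels_f.astype(int)
    if max_features > N_MAX:
        raise ValueError("max_features exceeds the ranked-list cap")
    r, p = _pearson_with_label(em, labels_f)
    fdr = bh_fdr_filter(p, q)
    pool = list(range(len(em.probe_ids)))
    X = em.data.to_numpy().T  # samples x probes
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    probe_ids = em.probe_ids

    selected: list[int] = []
    errors: list[float] = []
    # tie-break order: |r| descending then lexical
    pref = {i: rank for rank, i in enumerate(_order(np.abs(r), probe_ids))}
    while len(selected) < min(max_features, len(pool)):
        best = None  # (error, pref_rank, index)
        for i in pool:
            if i in selected:
                continue
            cols = selected + [i]
            learner = make_learner(ml_method)
            try:
                learner.fit(X[:, cols], y)
            except Exception as exc:  # degenerate probe set
                raise RuntimeError(f"learner failed on probes {[probe_ids[c] for c in cols]}") from exc
            err = float((learner.predict(X[:, cols]) != y).mean())
            key = (err, pref[i], i)
            if best is None or key < best:
                best = key
        selected.append(best[2])
        errors.append(best[0])
    scores = -np.array(errors)  # larger = better, ordering preserved
    return RankedProbeList(
        probe_ids=[probe_ids[i] for i in selected],
        scores=scores,
        p_values=p[selected],
        fdr_pass=fdr[selected],
        method="fsw",
        meta={"ml_method": ml_method, "train_errors": errors},
    )


def omp_rank(
    em: ExpressionMatrix,
    labels,
    max_features: int = 50,
    q: float = 0.05,
) -> RankedProbeList:
    """Orthogonal matching pursuit: the selection order is the ranking.

    Probes are standardized over the training samples and the 0/1 label is
    centered. At each step the probe with maximal |inner product| with the
    current residual is selected; the least-squares fit on the selected set
    is refit and the residual updated. Stops early (logged in meta) if the
    selected design becomes rank-deficient. Selected probes carry their
    marginal Pearson BH-FDR flags for the downstream validity rule.
    """
    labels_f = _check_labels(em, labels)
    r, p = _pearson_with_label(em, labels_f)
    fdr = bh_fdr_filter(p, q)
    X = em.data.to_numpy().T  # samples x probes
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / sd
    y = labels_f - labels_f.mean()
    probe_ids = list(em.probe_ids)

    selected: list[int] = []
    gains: list[float] = []
    residual = y.copy()
    stopped_early = False
    for _ in range(min(max_features, X.shape[1])):
        corr = np.abs(X.T @ residual)
        corr[selected] = -np.inf
        # tie-break by lexical probe id
        best_val = corr.max()
        if not np.isfinite(best_val) or best_val <= 1e-12:
            stopped_early = True
            break
        cand = np.nonzero(np.isclose(corr, best_val))[0]
        j = min(cand, key=lambda i: probe_ids[i])
        trial = selected + [int(j)]
        A = X[:, trial]
        if np.linalg.matrix_rank(A) < len(trial):
            stopped_early = True
            break
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        selected = trial
        residual = y - A @ coef
        gains.append(float(best_val))
    return RankedProbeList(
        probe_ids=[probe_ids[i] for i in selected],
        scores=np.array(gains),
        p_values=p[selected],
        fdr_pass=fdr[selected],
        method="omp",
        meta={"stopped_early": stopped_early, "residual_norm": float(np.linalg.norm(residual))},
    )


RANKERS = {
    "corr": correlation_rank,
    "reg": regression_rank,
    "fsw": fsw_rank,
    "omp": omp_rank,
}


def rank_probes(method: str, em: ExpressionMatrix, labels, **kwargs) -> RankedProbeList:
    """Dispatch to one of the four GR methods by tag."""
    if method not in RANKERS:
        raise ValueError(f"unknown ranking method {method!r}; choose from {sorted(RANKERS)}")
    return RANKERS[method](em, labels, **kwargs)


def list_overlap_stats(lists: list[list[str]]) -> dict:
    """Ranking-stability report: mean/std pairwise intersection of the
    top-k lists across iterations and the total number of distinct probes
    appearing in any list."""
    n = len(lists)
    sets = [set(l) for l in lists]
    inter = [len(sets[i] & sets[j]) for i in range(n) for j in range(i + 1, n)]
    return {
        "mean_pairwise_intersection": float(np.mean(inter)) if inter else float("nan"),
        "std_pairwise_intersection": float(np.std(inter)) if inter else float("nan"),
        "total_distinct_probes": len(set().union(*sets)) if sets else 0,
    }
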