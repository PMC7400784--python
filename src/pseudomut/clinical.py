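"""Survival and marker comparisons among wt / mut / PM tumor groups.

Kaplan-Meier curves and log-rank tests (via lifelines) compare overall
survival of wt-by-sequence-and-classification tumors, authentic TP53
mutants, and pseudomutants; expression markers (e.g. the MKI67 proliferation
marker, or a mutant-p53 gain-of-function gene signature) are compared by
Welch two-sided t-tests with BH-FDR correction across probes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .core import ExpressionMatrix, LabeledCohort, ProbeAnnotation
from .ranking import bh_fdr_filter


def assign_survival_groups(cohort: LabeledCohort, pm_ids, hotspot_ids=None) -> pd.DataFrame:
    """Build per-sample survival records with group in {wt, mut, PM, hotspot}.

    PM overrides wt (a PM sample is wt by sequence); hotspot tumors are a
    subset of mut carrying one of the recurrent TP53 missense mutations and
    keep the group tag ``hotspot``. Normal samples have no survival record.
    """
    pm_ids = set(pm_ids)
    hotspot_ids = set(hotspot_ids or [])
    rows = []
    for sid in cohort.tumor_ids:
        rec = cohort.table.loc[sid]
        if pd.isna(rec.get("time_days")) or pd.isna(rec.get("event")):
            continue
        time = float(rec["time_days"])
        if time <= 0:
            raise ValueError(f"non-positive survival time for sample {sid!r}")
        label = rec["binary_label"]
        if sid in pm_ids:
            if label != "wt":
                raise ValueError(f"PM call on a non-wt sample {sid!r}")
            group = "PM"
        elif label == "wt":
            group = "wt"
        elif sid in hotspot_ids:
            group = "hotspot"
        else:
            group = "mut"
        rows.append({"sample_id": sid, "time": time, "event": bool(rec["event"]), "group": group})
    return pd.DataFrame(rows).set_index("sample_id")


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate for one group.

    Returns a right-continuous, non-increasing step function as a frame with
    columns ``time`` and ``survival``; censored times reduce the risk set
    only. Equals 1 - ECDF when no record is censored.
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    if (records["time"] <= 0).any():
        raise ValueError("non-positive survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"].astype(bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """Evaluate a KM step function at time t (right-continuous)."""
    mask = km["time"] <= t
    if not mask.any():
        return 1.0
    return float(km.loc[mask, "survival"].iloc[-1])


def logrank_test(records_a: pd.DataFrame, records_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its two-sided p-value."""
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both groups must be non-empty")
    if int(records_a["event"].sum()) + int(records_b["event"].sum()) == 0:
        raise ValueError("log-rank test requires at least one observed event")
    res = _ll_logrank(
        records_a["time"], records_b["time"],
        event_observed_A=records_a["event"].astype(bool),
        event_observed_B=records_b["event"].astype(bool),
    )
    return float(res.test_statistic), float(res.p_value)


def marker_comparison(
    em: ExpressionMatrix,
    annotation: ProbeAnnotation,
    group_a_ids,
    group_b_ids,
    gene: str | None = None,
    probe: str | None = None,
) -> pd.DataFrame:
    """Per-probe group means (log scale) and Welch two-sided t-test p between
    two named groups, for one gene's probes or one explicit probe."""
    if probe is not None:
        probes = [probe]
    elif gene is not None:
        probes = [p for p in em.probe_ids if annotation.gene_of(p) == gene]
    else:
        raise ValueError("specify a gene or a probe")
    missing = [p for p in probes if p not in set(em.probe_ids)]
    if missing or not probes:
        raise ValueError(f"probe(s) not found: {missing or [gene]}")
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("need at least 2 samples per group")
    a = em.data.loc[probes, a_ids].to_numpy()
    b = em.data.loc[probes, b_ids].to_numpy()
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return pd.DataFrame(
        {
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "t": np.atleast_1d(res.statistic),
            "p": np.atleast_1d(res.pvalue),
        },
        index=pd.Index(probes, name="probe_id"),
    )


def signature_foldchange(
    em: ExpressionMatrix,
    annotation: ProbeAnnotation,
    signature_genes,
    wt_ids,
    contrast_groups: dict[str, list],
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-probe fold change of a gene signature in each contrast group
    relative to the wt group, with Welch t + BH-FDR per contrast.

    Expression is log2 scale, so the reported ``fc_<group>`` is
    2**(mean difference); ``log2fc_<group>`` carries the raw difference.
    Typical contrast groups: mut vs wt, PM vs the remaining wt, hotspot
    (a mut subset) vs wt.
    """
    signature_genes = set(signature_genes)
    if not signature_genes:
        raise ValueError("empty signature gene list")
    probes = [p for p in em.probe_ids if annotation.gene_of(p) in signature_genes]
    if not probes:
        raise ValueError("signature has no probes in the expression matrix")
    wt_ids = list(wt_ids)
    base = em.data.loc[probes, wt_ids].to_numpy()
    out = pd.DataFrame(index=pd.Index(probes, name="probe_id"))
    out["gene"] = [annotation.gene_of(p) for p in probes]
    for name, ids in contrast_groups.items():
        grp = em.data.loc[probes, list(ids)].to_numpy()
        diff = grp.mean(axis=1) - base.mean(axis=1)
        res = stats.ttest_ind(grp, base, axis=1, equal_var=False)
        pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        out[f"log2fc_{name}"] = diff
        out[f"fc_{name}"] = 2.0 ** diff
        out[f"p_{name}"] = pvals
        out[f"fdr_significant_{name}"] = bh_fdr_filter(pvals, q)
    return out
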