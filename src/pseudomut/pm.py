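"""Pseudomutant (PM) calling, probe-usage ranking, and 2-D embedding.

A pseudomutant is a tumor that is wild-type TP53 by sequencing but is
classified as mutant from its expression profile — a deliberate,
interpreted false positive of the conservative ensemble. Two routes produce
PM calls:

* test-set route: wt test samples the majority vote labels mut;
* validation-majority route: a wt learning sample that, across the
  iterations in which it landed in the validation set, was classified mut in
  a strict majority of its appearances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import ExpressionMatrix
from .ensemble import EnsembleModel, IterationRecord


class PMCallSet:
    """Per wt-by-sequence sample: call in {PM, wt, uncallable}, provenance
    in {test_FP, validation_majority}, and the appearance/vote tallies."""

    def __init__(self, table: pd.DataFrame):
        bad = set(table["call"].unique()) - {"PM", "wt", "uncallable"}
        if bad:
            raise ValueError(f"invalid calls: {sorted(bad)}")
        self.table = table

    @property
    def pm_ids(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "PM"])

    @property
    def uncallable_ids(self) -> list[str]:
        return list(self.table.index[self.table["call"] == "uncallable"])

    def combine(self, other: "PMCallSet") -> "PMCallSet":
        overlap = self.table.index.intersection(other.table.index)
        if len(overlap):
            raise ValueError(f"call sets overlap on samples: {list(overlap[:5])}")
        return PMCallSet(pd.concat([self.table, other.table]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "PMCallSet":
        return cls(pd.read_csv(path, index_col="sample_id"))


def call_pm_test(model: EnsembleModel, test_em: ExpressionMatrix, test_labels: pd.Series) -> PMCallSet:
    """Label as PM the wt-by-sequence test samples that the majority vote
    classifies as mut. Mut-by-sequence samples predicted wt are false
    negatives, never PM."""
    sample_ids = list(test_labels.index)
    pred, frac = model.majority_vote_predict(test_em, sample_ids)
    rows = []
    for sid, p, f in zip(sample_ids, pred, frac):
        if test_labels[sid] != "wt":
            continue
        rows.append({
            "sample_id": sid,
            "call": "PM" if p == 1 else "wt",
            "provenance": "test_FP",
            "n_appearances": 1,
            "n_mut_votes": int(p),
            "vote_fraction": float(f),
        })
    table = pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame(
        columns=["call", "provenance", "n_appearances", "n_mut_votes", "vote_fraction"]
    )
    return PMCallSet(table)


def call_pm_validation(records_k_star: list[IterationRecord], learning_labels: pd.Series) -> PMCallSet:
    """Validation-majority rule for wt learning samples.

    For each wt sample, tally the iterations where it sat in the validation
    set (appearances a) and how often the iteration's k*-probe subclassifier
    called it mut (m). PM iff m > a/2 (a tie is not a majority); a sample
    never seen in validation is uncallable.
    """
    if not records_k_star:
        raise ValueError("no iteration records supplied")
    appearances: dict[str, int] = {}
    mut_votes: dict[str, int] = {}
    seen_iters = set()
    for rec in records_k_star:
        seen_iters.add(rec.iteration)
        for sid, p in zip(rec.val_ids, rec.val_pred):
            appearances[sid] = appearances.get(sid, 0) + 1
            mut_votes[sid] = mut_votes.get(sid, 0) + int(p)
    rows = []
    for sid, lab in learning_labels.items():
        if lab != "wt":
            continue
        a = appearances.get(sid, 0)
        m = mut_votes.get(sid, 0)
        if a == 0:
            call = "uncallable"
        else:
            call = "PM" if m > a / 2 else "wt"
        rows.append({
            "sample_id": sid,
            "call": call,
            "provenance": "validation_majority",
            "n_appearances": a,
            "n_mut_votes": m,
            "vote_fraction": m / a if a else np.nan,
        })
    return PMCallSet(pd.DataFrame(rows).set_index("sample_id"))


def pm_fraction(pm_calls: PMCallSet, wt_ids) -> float:
    """Fraction of a cohort's wt-by-sequence samples called PM; uncallable
    samples count in the denominator."""
    wt_ids = list(wt_ids)
    if not wt_ids:
        raise ValueError("cohort has no wt samples")
    pm = set(pm_calls.pm_ids)
    return sum(1 for s in wt_ids if s in pm) / len(wt_ids)


def probe_usage_ranking(ranked_lists, k_star: int) -> pd.Series:
    """Rank probes by how often they appear in the top-k* across iterations.

    Returns the top-k* most-used probes (count per probe, ties broken by
    lexical probe order) — the stabilized feature list used to represent
    samples for embedding.
    """
    counts: dict[str, int] = {}
    for rl in ranked_lists:
        probes = rl.probe_ids[:k_star] if hasattr(rl, "probe_ids") else list(rl)[:k_star]
        for p in probes:
            counts[p] = counts.get(p, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k_star]
    return pd.Series(dict(ordered), dtype=int)


def embed_2d(em: ExpressionMatrix, method: str = "pca", random_state: int = 0) -> pd.DataFrame:
    """2-D embedding of samples from (standardized) probe space.

    PCA is the primary method; tSNE is delegated to scikit-learn. Returns a
    samples x 2 coordinate frame.
    """
    if em.shape[0] < 2:
        raise ValueError("need at least 2 probes to embed")
    if em.shape[1] < 3:
        raise ValueError("need at least 3 samples to embed")
    X = em.data.to_numpy().T  # samples x probes
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if method == "pca":
        coords = PCA(n_components=2, random_state=random_state).fit_transform(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (X.shape[0] - 1) / 3)
        coords = TSNE(
            n_components=2, random_state=random_state, init="pca", perplexity=perplexity
        ).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=em.sample_ids, columns=["dim1", "dim2"])
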