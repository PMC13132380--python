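"""Chromatin bivalency states (CBS), transitions, and expression coupling.

Bivalent promoters are partitioned by the ratio of their H3K4me3 and
H3K27me3 intensities: cluster I (H3K4me3-high, ratio >= 1.5), cluster II
(H3K27me3-high, inverse ratio >= 1.5) and cluster III (within 1.5-fold of
equal).  Thresholds are inclusive, so a ratio of exactly 1.5 lands in the
high cluster.  Comparing two conditions' assignments yields a transition
table (the alluvial-plot counts); "bivalency resolution" switches — cluster
II or III resolving to cluster I — are coupled to expression change via the
fraction of switching genes whose expression goes up, and the overall
mark-change/expression-change relationship is summarised by a Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

__all__ = [
    "CLUSTER_I",
    "CLUSTER_II",
    "CLUSTER_III",
    "NONBIVALENT",
    "CBS_LABELS",
    "CBSClassifier",
    "classify_cbs",
    "StateAssignment",
    "assign_states",
    "TransitionTable",
    "transition_table",
    "DEFAULT_SWITCH_DEFINITION",
    "switch_expression_fraction",
    "CorrelationResult",
    "bivalency_expression_correlation",
    "kmeans_crosscheck",
]

CLUSTER_I = "cluster_I"  # H3K4me3-high
CLUSTER_II = "cluster_II"  # H3K27me3-high
CLUSTER_III = "cluster_III"  # equal
NONBIVALENT = "nonbivalent"
CBS_LABELS = (CLUSTER_I, CLUSTER_II, CLUSTER_III, NONBIVALENT)

#: bivalency-resolution switches: II -> I and III -> I
DEFAULT_SWITCH_DEFINITION = frozenset({(CLUSTER_II, CLUSTER_I), (CLUSTER_III, CLUSTER_I)})


class CBSClassifier(BaseEstimator):
    """Threshold classifier for chromatin bivalency states.

    ``predict`` maps (k4, k27) intensity pairs to cluster labels via the
    pseudocounted ratio ``r = (k4 + c) / (k27 + c)``: cluster I when
    ``r >= fc_threshold``, cluster II when ``1/r >= fc_threshold`` (both
    boundaries inclusive), cluster III otherwise.  The two high conditions
    are mutually exclusive for any fc_threshold > 1, so exactly one label is
    produced.  Stateless: ``fit`` only validates.
    """

    def __init__(self, fc_threshold: float = 1.5, pseudocount: float = 0.5):
        self.fc_threshold = fc_threshold
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        self._validate(X)
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        X = self._validate(X)
        c = self.pseudocount
        r = (X[:, 0] + c) / (X[:, 1] + c)
        labels = np.where(
            r >= self.fc_threshold,
            CLUSTER_I,
            np.where(1.0 / r >= self.fc_threshold, CLUSTER_II, CLUSTER_III),
        )
        return labels

    def _validate(self, X) -> np.ndarray:
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n_genes, 2) array of (k4, k27)")
        if np.any(~np.isfinite(X)) or np.any(X < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.pseudocount == 0 and np.any(X == 0):
            raise ValueError("zero intensities require a positive pseudocount")
        return X


def classify_cbs(
    k4_intensity: float,
    k27_intensity: float,
    fc_threshold: float = 1.5,
    pseudocount: float = 0.5,
) -> str:
    """Classify one promoter's (k4, k27) pair; see :class:`CBSClassifier`."""
    clf = CBSClassifier(fc_threshold=fc_threshold, pseudocount=pseudocount)
    return str(clf.predict([[k4_intensity, k27_intensity]])[0])


@dataclass
class StateAssignment:
    """Per-condition CBS labels with the intensities and threshold used."""

    condition: str
    labels: pd.Series  # gene_id -> label
    fc_threshold: float = 1.5
    intensities: pd.DataFrame | None = field(default=None, repr=False)

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(CBS_LABELS, fill_value=0)


def assign_states(
    k4: pd.Series,
    k27: pd.Series,
    bivalent: set[str],
    condition: str = "",
    fc_threshold: float = 1.5,
    pseudocount: float = 0.5,
) -> StateAssignment:
    """Label every gene: CBS cluster if bona fide bivalent, else nonbivalent."""
    if not k4.index.equals(k27.index):
        raise ValueError("k4 and k27 columns must share one gene universe")
    clf = CBSClassifier(fc_threshold=fc_threshold, pseudocount=pseudocount)
    labels = pd.Series(NONBIVALENT, index=k4.index, dtype=object)
    biv = [g for g in k4.index if g in bivalent]
    if biv:
        X = np.column_stack([k4.loc[biv].to_numpy(float), k27.loc[biv].to_numpy(float)])
        labels.loc[biv] = clf.predict(X)
    return StateAssignment(
        condition,
        labels,
        fc_threshold,
        pd.DataFrame({"k4": k4, "k27": k27}),
    )


@dataclass
class TransitionTable:
    """Per-gene state transitions between two conditions.

    ``records``: one row per shared gene with ``label_a``, ``label_b`` (and
    ``expression_lfc`` once attached); ``counts``: 4x4 label-pair counts.
    """

    condition_a: str
    condition_b: str
    records: pd.DataFrame
    counts: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Alluvial-ready long format: (from, to, n)."""
        long = self.counts.stack().rename("n").reset_index()
        long.columns = ["from", "to", "n"]
        return long[long["n"] > 0].reset_index(drop=True)


def transition_table(a: StateAssignment, b: StateAssignment) -> TransitionTable:
    """Cross-tabulate CBS labels between two conditions.

    Genes present in only one assignment are recorded with ``nonbivalent``
    on the missing side; the counts therefore sum to the size of the union
    universe.  Disjoint universes are rejected.
    """
    shared = a.labels.index.intersection(b.labels.index)
    if len(shared) == 0:
        raise ValueError("the two assignments share no genes")
    universe = a.labels.index.union(b.labels.index)
    la = a.labels.reindex(universe, fill_value=NONBIVALENT)
    lb = b.labels.reindex(universe, fill_value=NONBIVALENT)
    records = pd.DataFrame({"label_a": la, "label_b": lb})
    counts = (
        pd.crosstab(records["label_a"], records["label_b"])
        .reindex(index=CBS_LABELS, columns=CBS_LABELS, fill_value=0)
        .rename_axis(index="from", columns="to")
    )
    return TransitionTable(a.condition, b.condition, records, counts)


def switch_expression_fraction(
    table: TransitionTable,
    expression_lfc: pd.Series,
    switch_definition=DEFAULT_SWITCH_DEFINITION,
) -> tuple[float, int]:
    """Fraction of bivalency-switch genes with increased expression.

    A switch gene is one whose (label_a, label_b) pair is in
    ``switch_definition`` (default: II -> I and III -> I).  Every switch gene
    must carry an expression log2FC; the fraction counts strictly positive
    values.  Raises when no gene switches (undefined fraction).
    """
    rec = table.records
    pairs = list(zip(rec["label_a"], rec["label_b"]))
    is_switch = np.array([p in switch_definition for p in pairs])
    switch_genes = rec.index[is_switch]
    if len(switch_genes) == 0:
        raise ValueError("no genes match the switch definition")
    missing = [g for g in switch_genes if g not in expression_lfc.index]
    if missing:
        raise ValueError(f"switch genes lack expression values: {missing[:3]}")
    lfc = expression_lfc.loc[switch_genes].astype(float)
    if lfc.isna().any():
        raise ValueError("switch genes with NaN expression log2FC")
    return float((lfc > 0).mean()), int(len(switch_genes))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")


def bivalency_expression_correlation(
    delta_mark: pd.Series, delta_expr: pd.Series
) -> CorrelationResult:
    """Pearson correlation of mark log2FC against expression log2FC.

    Pairs the two series on their shared genes, requires >= 3 finite pairs
    and non-zero variance on each side; the p-value is the two-sided t-test
    with n - 2 degrees of freedom.
    """
    shared = delta_mark.index.intersection(delta_expr.index)
    x = delta_mark.loc[shared].astype(float)
    y = delta_expr.loc[shared].astype(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the paired vectors")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(len(x)))


def kmeans_crosscheck(
    k4: pd.Series,
    k27: pd.Series,
    bivalent: set[str],
    fc_threshold: float = 1.5,
    pseudocount: float = 0.5,
    seed: int = 0,
) -> float:
    """Diagnostic: agreement between threshold labels and k-means (k=3).

    Runs k-means (50 restarts, fixed seed) on (log2 k4, log2 k27) of the
    bivalent genes, names each centroid by its own ratio rule, and returns
    the fraction of genes on which the two labelings agree.  The threshold
    rule remains the primary classifier; this mirrors running a k-means
    clustering over the same two-mark space as a sanity check.
    """
    biv = sorted(set(bivalent) & set(k4.index))
    if len(biv) < 3:
        raise ValueError("need >= 3 bivalent genes for the cross-check")
    c = pseudocount
    X = np.column_stack(
        [
            np.log2(k4.loc[biv].to_numpy(float) + c),
            np.log2(k27.loc[biv].to_numpy(float) + c),
        ]
    )
    km = KMeans(n_clusters=3, n_init=50, random_state=seed).fit(X)
    clf = CBSClassifier(fc_threshold=fc_threshold, pseudocount=pseudocount)
    centroid_int = np.exp2(km.cluster_centers_) - c
    centroid_labels = clf.predict(np.clip(centroid_int, 0.0, None))
    km_labels = centroid_labels[km.labels_]
    thr_labels = clf.predict(
        np.column_stack([k4.loc[biv].to_numpy(float), k27.loc[biv].to_numpy(float)])
    )
    return float(np.mean(km_labels == thr_labels))
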