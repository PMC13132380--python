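"""Recurrent-NMF meta-programs.

Per-sample NMF is run across a sweep of ranks (k = 4..9 by default); each
factor yields a *program instance*, the top-90 genes by factor loading.
Programs that fail to recur within their sample across ranks are discarded,
and the survivors are greedily agglomerated by Jaccard similarity of their
gene sets into *meta-programs* — consensus programs supported by several
samples and several ranks.  The consensus gene set of a meta-program is the
top-90 genes ranked by membership frequency across its member instances
(ties by summed loading, then lexicographically).

All steps are deterministic given the random seed: NMF uses the NNDSVD-A
initialisation with the coordinate-descent solver, and every tie-break in
the clustering is explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import NMF

__all__ = [
    "ProgramInstance",
    "MetaProgram",
    "jaccard",
    "run_nmf_sweep",
    "cluster_programs",
    "MetaProgramNMF",
]

DEFAULT_KS = (4, 5, 6, 7, 8, 9)


@dataclass
class ProgramInstance:
    """One NMF factor of one sample at one rank."""

    sample_id: str
    k: int
    factor_index: int
    gene_set: list[str]  # ordered by loading, length min(n_top, n_genes)
    scores: pd.Series = field(repr=False)  # loading per gene_set gene

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.sample_id, self.k, self.factor_index)


@dataclass
class MetaProgram:
    """A consensus program recurring across ranks and samples."""

    mp_id: str
    members: list[ProgramInstance]
    consensus_genes: list[str]

    @property
    def n_samples(self) -> int:
        return len({m.sample_id for m in self.members})

    @property
    def n_ks(self) -> int:
        return len({m.k for m in self.members})


def jaccard(a, b) -> float:
    """|a n b| / |a u b|; 0 when both sets are empty (by convention)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def _preprocess(expr: pd.DataFrame, clip_quantile: float = 0.999) -> pd.DataFrame:
    """log1p then per-gene clipping at a high quantile (no centering)."""
    arr = np.log1p(expr.to_numpy(dtype=float))
    hi = np.quantile(arr, clip_quantile, axis=1, keepdims=True)
    return pd.DataFrame(np.minimum(arr, hi), index=expr.index, columns=expr.columns)


def run_nmf_sweep(
    expr: pd.DataFrame,
    ks=DEFAULT_KS,
    n_top: int = 90,
    seed: int = 0,
    sample_id: str = "sample",
    preprocess: bool = True,
    max_iter: int = 500,
) -> list[ProgramInstance]:
    """Factorize one sample's genes x cells matrix at every rank in ``ks``.

    Returns one :class:`ProgramInstance` per factor — sum(ks) instances for a
    full sweep.  Ranks exceeding min(matrix dims) are skipped with a warning.
    Raises on negative entries.
    """
    arr = expr.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("expression matrix must be non-negative")
    if preprocess:
        expr = _preprocess(expr)
        arr = expr.to_numpy(dtype=float)
    genes = expr.index
    instances: list[ProgramInstance] = []
    for k in ks:
        if k > min(arr.shape):
            warnings.warn(f"skipping k={k}: exceeds matrix dimensions {arr.shape}")
            continue
        model = NMF(
            n_components=k,
            init="nndsvda",
            solver="cd",
            max_iter=max_iter,
            random_state=seed,
            tol=1e-4,
        )
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(arr)
        for j in range(k):
            loading = pd.Series(W[:, j], index=genes)
            order = loading.sort_values(ascending=False, kind="mergesort")
            top = order.iloc[: min(n_top, len(genes))]
            instances.append(
                ProgramInstance(
                    sample_id=sample_id,
                    k=int(k),
                    factor_index=j,
                    gene_set=list(top.index),
                    scores=top,
                )
            )
    return instances


def _k_recurrent(
    instances: list[ProgramInstance], j_min: float, min_k_recurrence: int
) -> list[ProgramInstance]:
    """Keep instances whose program recurs at >= min_k_recurrence distinct
    ranks within the same sample (counting the instance's own rank)."""
    kept = []
    for inst in instances:
        ks = {inst.k}
        for other in instances:
            if (
                other.sample_id == inst.sample_id
                and other.k != inst.k
                and jaccard(inst.gene_set, other.gene_set) >= j_min
            ):
                ks.add(other.k)
        if len(ks) >= min_k_recurrence:
            kept.append(inst)
    return kept


def _consensus(members: list[ProgramInstance], n_top: int) -> list[str]:
    freq: dict[str, int] = {}
    score: dict[str, float] = {}
    for m in members:
        for g in m.gene_set:
            freq[g] = freq.get(g, 0) + 1
            score[g] = score.get(g, 0.0) + float(m.scores.get(g, 0.0))
    ranked = sorted(freq, key=lambda g: (-freq[g], -score[g], g))
    return ranked[:n_top]


def cluster_programs(
    instances: list[ProgramInstance],
    j_min: float = 0.2,
    min_samples: int = 2,
    min_k_recurrence: int = 2,
    n_top: int = 90,
) -> list[MetaProgram]:
    """Greedy Jaccard agglomeration of program instances into meta-programs.

    1. Discard instances that do not recur across ranks within their sample
       (Jaccard >= ``j_min`` with an instance at a different k).
    2. Seed a cluster from the most-partnered instance: partners are
       cross-sample instances at Jaccard >= ``j_min``, and candidates are
       ranked by total partner similarity (sum of Jaccard) so that a factor
       strongly shared across samples outranks a diffuse factor with many
       weak links (ties by (sample_id, k, factor_index)).
    3. Absorb every remaining instance with Jaccard >= ``j_min`` to the seed;
       the consensus is the ``n_top`` most frequent genes across members.
    4. Remove the members and repeat until no seed has a cross-sample
       partner.
    5. Drop clusters supported by fewer than ``min_samples`` distinct
       samples.

    Hard clustering: every instance joins at most one meta-program.
    Deterministic for fixed inputs.
    """
    if not instances:
        raise ValueError("no program instances to cluster")
    pool = _k_recurrent(instances, j_min, min_k_recurrence)
    metaprograms: list[MetaProgram] = []
    counter = 0
    while pool:
        n_cross = []
        strength = []
        for inst in pool:
            sims = [
                jaccard(inst.gene_set, other.gene_set)
                for other in pool
                if other.sample_id != inst.sample_id
            ]
            sims = [s for s in sims if s >= j_min]
            n_cross.append(len(sims))
            strength.append(sum(sims))
        # deterministic tie-break: strongest partnering, then smallest key
        order = sorted(
            range(len(pool)), key=lambda i: (-strength[i], pool[i].key)
        )
        best = order[0]
        if n_cross[best] == 0:
            break
        seed_inst = pool[best]
        members = [
            inst
            for inst in pool
            if inst is seed_inst
            or jaccard(seed_inst.gene_set, inst.gene_set) >= j_min
        ]
        counter += 1
        metaprograms.append(
            MetaProgram(
                mp_id=f"MP{counter}",
                members=members,
                consensus_genes=_consensus(members, n_top),
            )
        )
        member_keys = {m.key for m in members}
        pool = [inst for inst in pool if inst.key not in member_keys]
    kept = [mp for mp in metaprograms if mp.n_samples >= min_samples]
    for i, mp in enumerate(kept, start=1):
        mp.mp_id = f"MP{i}"
    return kept


class MetaProgramNMF(BaseEstimator):
    """End-to-end recurrent-NMF meta-program finder.

    ``fit`` takes a mapping sample_id -> genes x cells DataFrame, runs the
    rank sweep per sample and clusters the resulting program instances.

    Attributes
    ----------
    program_instances_ : list of ProgramInstance
    meta_programs_ : list of MetaProgram
    """

    def __init__(
        self,
        ks=DEFAULT_KS,
        n_top: int = 90,
        j_min: float = 0.2,
        min_samples: int = 2,
        min_k_recurrence: int = 2,
        random_state: int = 0,
        max_iter: int = 500,
    ):
        self.ks = ks
        self.n_top = n_top
        self.j_min = j_min
        self.min_samples = min_samples
        self.min_k_recurrence = min_k_recurrence
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X: dict[str, pd.DataFrame], y=None):
        if not X:
            raise ValueError("no samples provided")
        instances: list[ProgramInstance] = []
        for sample_id in sorted(X):
            instances.extend(
                run_nmf_sweep(
                    X[sample_id],
                    ks=self.ks,
                    n_top=self.n_top,
                    seed=self.random_state,
                    sample_id=sample_id,
                    max_iter=self.max_iter,
                )
            )
        self.program_instances_ = instances
        self.meta_programs_ = cluster_programs(
            instances,
            j_min=self.j_min,
            min_samples=self.min_samples,
            min_k_recurrence=self.min_k_recurrence,
            n_top=self.n_top,
        )
        return self

    def instances_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": i.sample_id,
                "k": i.k,
                "factor_index": i.factor_index,
                "genes": ",".join(i.gene_set),
            }
            for i in self.program_instances_
        ]
        return pd.DataFrame(rows)

    def meta_programs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mp_id": mp.mp_id,
                "n_members": len(mp.members),
                "n_samples": mp.n_samples,
                "n_ks": mp.n_ks,
                "consensus_genes": ",".join(mp.consensus_genes),
            }
            for mp in self.meta_programs_
        ]
        return pd.DataFrame(rows)
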