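"""Bona fide bivalent-promoter calling.

A promoter is *bivalent by separate ChIP* when both an H3K4me3 and an
H3K27me3 peak overlap its window, and *bivalent by sequential ChIP (re-ChIP)*
when a peak from the two-step H3K27me3 -> H3K4me3 immunoprecipitation does.
The intersection of the two calls — promoters supported by both assays — is
the bona fide bivalent set.  All intersections are gene-level: a gene with
several qualifying peaks counts once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import PeakSet, PromoterSet, overlap_promoters

__all__ = [
    "BivalencyCall",
    "VennSummary",
    "call_bivalent_separate",
    "call_bivalent_sequential",
    "bona_fide_bivalent",
    "cooccupancy_fraction",
]


@dataclass(frozen=True)
class BivalencyCall:
    gene_id: str
    by_separate: bool
    by_sequential: bool

    @property
    def bona_fide(self) -> bool:
        return self.by_separate and self.by_sequential


@dataclass(frozen=True)
class VennSummary:
    """Gene counts for the sequential-vs-separate Venn diagram."""

    n_sequential: int
    n_separate: int
    n_overlap: int

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_sequential, self.n_separate):
            raise ValueError("overlap exceeds an input set size")


def call_bivalent_separate(
    k4: PeakSet, k27: PeakSet, prom: PromoterSet
) -> set[str]:
    """Genes whose promoter carries >=1 peak of each separate mark."""
    if k4.label == k27.label:
        raise ValueError(
            f"both peak sets are labelled {k4.label!r}; likely a caller mix-up"
        )
    occ4 = overlap_promoters(k4, prom)["occupied"]
    occ27 = overlap_promoters(k27, prom)["occupied"]
    both = occ4 & occ27
    return set(both.index[both])


def call_bivalent_sequential(seq: PeakSet, prom: PromoterSet) -> set[str]:
    """Genes whose promoter carries >=1 sequential-ChIP peak."""
    if len(seq) == 0:
        return set()
    occ = overlap_promoters(seq, prom)["occupied"]
    return set(occ.index[occ])


def bona_fide_bivalent(
    sep: set[str], seq: set[str]
) -> tuple[pd.DataFrame, VennSummary]:
    """Intersect the separate and sequential calls.

    Returns a per-gene call table (indexed by gene_id, over the union of the
    two inputs, columns ``by_separate``, ``by_sequential``, ``bona_fide``)
    and the Venn counts.
    """
    universe = sorted(set(sep) | set(seq))
    calls = pd.DataFrame(
        {
            "by_separate": [g in sep for g in universe],
            "by_sequential": [g in seq for g in universe],
        },
        index=pd.Index(universe, name="gene_id"),
    )
    calls["bona_fide"] = calls["by_separate"] & calls["by_sequential"]
    venn = VennSummary(len(seq), len(sep), len(set(sep) & set(seq)))
    return calls, venn


def cooccupancy_fraction(
    factor: PeakSet, bivalent: set[str], prom: PromoterSet
) -> float:
    """Fraction of bivalent promoters carrying >=1 peak of ``factor``.

    Any-overlap semantics; raises on an empty bivalent set (the fraction is
    undefined).
    """
    if not bivalent:
        raise ValueError("cooccupancy fraction undefined for an empty bivalent set")
    missing = set(bivalent) - set(prom.windows)
    if missing:
        raise ValueError(f"bivalent genes missing promoters: {sorted(missing)[:3]}")
    if len(factor) == 0:
        return 0.0
    occ = overlap_promoters(factor, prom)["occupied"]
    return float(occ.loc[sorted(bivalent)].mean())
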