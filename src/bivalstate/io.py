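"""Core I/O: domain containers, BED/TSV readers and writers, promoter windows
and interval-overlap primitives.

Coordinate convention
---------------------
All intervals are 0-based, half-open ``[start, end)`` — BED-native.  Any
1-based input dialect must be converted at the reader boundary; everything
downstream assumes half-open arithmetic, so a peak ending exactly at a
promoter start does not overlap it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Interval",
    "GenomeAnnotation",
    "PeakSet",
    "PromoterSet",
    "SignalMatrix",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_annotation",
    "make_promoters",
    "overlap_promoters",
]

VALID_STRANDS = frozenset({"+", "-"})


class BedParseError(ValueError):
    """Raised for malformed BED records; carries the offending line number."""


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"start >= end ({self.start} >= {self.end}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class GenomeAnnotation:
    """Gene annotation table: one TSS per gene.

    Multi-TSS genes must be collapsed upstream; exactly one record per
    ``gene_id`` is required here.

    Parameters
    ----------
    records : DataFrame
        Columns ``gene_id, chrom, strand, tss, biotype``; ``tss`` is a 0-based
        coordinate, ``strand`` one of ``+``/``-``.
    """

    REQUIRED = ("gene_id", "chrom", "strand", "tss", "biotype")

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in records.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        records = records.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        if records["gene_id"].duplicated().any():
            dups = records.loc[records["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene_id values, e.g. {dups.iloc[0]!r}")
        bad_strand = ~records["strand"].isin(VALID_STRANDS)
        if bad_strand.any():
            raise ValueError(
                f"invalid strand value {records.loc[bad_strand, 'strand'].iloc[0]!r}"
            )
        records["tss"] = records["tss"].astype(np.int64)
        if (records["tss"] < 0).any():
            raise ValueError("negative TSS coordinate")
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeAnnotation) and self.records.equals(
            other.records
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


class PeakSet:
    """A labelled collection of peaks, optionally scored.

    Stored internally as a DataFrame with columns ``chrom, start, end, score``
    (``score`` is NaN where absent).  Scores, when present, must be
    non-negative and finite.
    """

    def __init__(self, label: str, peaks: pd.DataFrame | None = None):
        self.label = str(label)
        if peaks is None:
            peaks = pd.DataFrame(columns=["chrom", "start", "end", "score"])
        peaks = peaks.copy()
        if "score" not in peaks.columns:
            peaks["score"] = np.nan
        peaks = peaks.loc[:, ["chrom", "start", "end", "score"]].reset_index(
            drop=True
        )
        if len(peaks):
            peaks["chrom"] = peaks["chrom"].astype(str)
            peaks["start"] = peaks["start"].astype(np.int64)
            peaks["end"] = peaks["end"].astype(np.int64)
            peaks["score"] = peaks["score"].astype(float)
            if (peaks["start"] < 0).any():
                raise ValueError("negative peak start")
            if (peaks["start"] >= peaks["end"]).any():
                raise ValueError("peak with start >= end")
            sc = peaks["score"].to_numpy()
            with np.errstate(invalid="ignore"):
                if np.any(sc[~np.isnan(sc)] < 0) or np.any(np.isinf(sc)):
                    raise ValueError("peak scores must be finite and >= 0")
        self.peaks = peaks

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterable[tuple[Interval, float]]:
        for row in self.peaks.itertuples(index=False):
            yield Interval(row.chrom, int(row.start), int(row.end)), row.score

    @classmethod
    def from_intervals(
        cls,
        label: str,
        intervals: Iterable[Interval],
        scores: Iterable[float] | None = None,
    ) -> "PeakSet":
        ivs = list(intervals)
        frame = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in ivs],
                "start": [iv.start for iv in ivs],
                "end": [iv.end for iv in ivs],
                "score": list(scores) if scores is not None else np.nan,
            }
        )
        return cls(label, frame)


@dataclass
class PromoterSet:
    """Strand-aware promoter windows, one per gene.

    ``windows`` maps gene_id to its TSS +/- window interval; the window
    parameters used to build the set are recorded alongside.
    """

    upstream_bp: int
    downstream_bp: int
    windows: dict[str, Interval]
    annotation: GenomeAnnotation | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.windows)

    def gene_ids(self) -> list[str]:
        return list(self.windows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.windows),
                "chrom": [iv.chrom for iv in self.windows.values()],
                "start": [iv.start for iv in self.windows.values()],
                "end": [iv.end for iv in self.windows.values()],
            }
        )


class SignalMatrix:
    """Promoter signal intensities: genes x samples, all entries >= 0 and finite.

    ``sample_info`` carries per-column metadata (``mark``, ``condition``).
    """

    def __init__(self, values: pd.DataFrame, sample_info: pd.DataFrame | None = None):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids in signal matrix")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in signal matrix")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("signal intensities must be finite and >= 0")
        self.values = values.astype(float)
        if sample_info is not None:
            missing = set(values.columns) - set(sample_info.index)
            if missing:
                raise ValueError(f"sample_info missing samples: {sorted(missing)}")
        self.sample_info = sample_info

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def column(self, sample: str) -> pd.Series:
        return self.values[sample]

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        if sidecar is not None and self.sample_info is not None:
            self.sample_info.to_csv(sidecar, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls, path: str | Path, sidecar: str | Path | None = None
    ) -> "SignalMatrix":
        values = pd.read_csv(path, sep="\t", index_col="gene_id")
        info = (
            pd.read_csv(sidecar, sep="\t", index_col="sample_id")
            if sidecar is not None
            else None
        )
        return cls(values, info)


def read_bed(path: str | Path, label: str | None = None) -> PeakSet:
    """Read a BED3/BED5 file into a :class:`PeakSet`.

    Column 5, when present, is used as the peak score.  Coordinates are taken
    as BED-native 0-based half-open.  An empty file yields an empty PeakSet.

    Raises
    ------
    BedParseError
        On non-integer coordinates, negative start, or start >= end; the
        message names the 1-based line number.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    scores: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            if start < 0:
                raise BedParseError(f"line {lineno}: negative start {start}")
            if start >= end:
                raise BedParseError(f"line {lineno}: start >= end ({start} >= {end})")
            score = np.nan
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"line {lineno}: unparseable score {fields[4]!r}"
                    ) from exc
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            scores.append(score)
    frame = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "score": scores}
    )
    return PeakSet(label, frame)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as BED3 (unscored) or BED5 (scored; name column '.')."""
    df = peaks.peaks
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            if np.isnan(row.score):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")
            else:
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t.\t{row.score:.10g}\n"
                )


def read_annotation(path: str | Path) -> GenomeAnnotation:
    return GenomeAnnotation.from_tsv(path)


def make_promoters(
    ann: GenomeAnnotation,
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
    biotype_filter: str | None = None,
) -> PromoterSet:
    """Build strand-aware promoter windows of TSS - upstream / + downstream.

    For a "+" gene the window is ``[tss - upstream, tss + downstream)``; for a
    "-" gene, ``[tss - downstream, tss + upstream)``.  Windows are clamped at
    position 0 rather than dropped, keeping gene universes aligned across
    marks.  ``biotype_filter`` (e.g. ``"protein_coding"``) restricts the set.
    """
    if upstream_bp <= 0 or downstream_bp <= 0:
        raise ValueError("window sizes must be positive")
    rec = ann.records
    if biotype_filter is not None:
        rec = rec[rec["biotype"] == biotype_filter]
    if rec.empty:
        raise ValueError("no promoters: annotation empty after biotype filter")
    windows: dict[str, Interval] = {}
    for row in rec.itertuples(index=False):
        if row.strand == "+":
            start, end = row.tss - upstream_bp, row.tss + downstream_bp
        else:
            start, end = row.tss - downstream_bp, row.tss + upstream_bp
        windows[row.gene_id] = Interval(row.chrom, max(0, start), end)
    return PromoterSet(upstream_bp, downstream_bp, windows, annotation=ann)


def _promoter_trees(promoters: PromoterSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene_id, iv in promoters.windows.items():
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, gene_id)
    return trees


def overlap_promoters(peaks: PeakSet, promoters: PromoterSet) -> pd.DataFrame:
    """Per-gene promoter occupancy for one peak set.

    Returns a DataFrame indexed by gene_id with columns ``occupied`` (any
    >=1 bp overlap under half-open semantics) and ``intensity`` (maximum score
    among overlapping peaks; 0 when unoccupied or all scores absent).
    Chromosomes present only in the peaks contribute nothing.
    """
    if len(peaks) == 0 or len(promoters) == 0:
        raise ValueError("overlap_promoters requires non-empty peaks and promoters")
    trees = _promoter_trees(promoters)
    genes = promoters.gene_ids()
    occupied = dict.fromkeys(genes, False)
    intensity = dict.fromkeys(genes, 0.0)
    for row in peaks.peaks.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(row.start, row.end):
            gene = hit.data
            occupied[gene] = True
            if not np.isnan(row.score):
                intensity[gene] = max(intensity[gene], float(row.score))
    return pd.DataFrame(
        {"occupied": pd.Series(occupied), "intensity": pd.Series(intensity)}
    ).loc[genes]
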