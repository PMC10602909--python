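"""ChIP peak sets: BED I/O, score filtering, PBS overlap counting, ranking.

Coordinates are 0-based half-open throughout (native BED semantics), so
adjacent intervals such as [0,10) and [10,20) do not overlap. Strand is
ignored for overlap: ChIP peaks are unstranded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start {self.start} >= end {self.end}")
        if self.score < 0:
            raise ValueError(f"peak {self.name}: negative score {self.score}")


class BedFormatError(ValueError):
    pass


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3-BED6; malformed lines are rejected with their line numbers."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates")
            if start >= end:
                raise BedFormatError(f"{path}:{lineno}: start >= end")
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                raise BedFormatError(f"{path}:{lineno}: non-numeric score")
            peaks.append(
                Peak(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if len(fields) > 3 else ".",
                    score=score,
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            )
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = int(p.score) if float(p.score).is_integer() else p.score
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score}\t{p.strand}\n")


def filter_peaks(peaks: Iterable[Peak], min_score: float) -> list[Peak]:
    """Keep peaks with score strictly greater than ``min_score`` (order kept)."""
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    return [p for p in peaks if p.score > min_score]


@dataclass(frozen=True)
class OverlapReport:
    """Per-KZFP summary of peak/PBS overlap.

    ``n_overlapping_peaks`` counts each peak once however many PBS
    intervals it spans; ``per_pbs_counts`` gives the complementary view
    (peaks touching each PBS interval).
    """

    kzfp: str
    n_peaks: int
    n_overlapping_peaks: int
    mean_overlap_score: float
    per_pbs_counts: tuple[int, ...]


def count_overlaps(
    peaks: TypingSequence[Peak],
    pbs_intervals: TypingSequence[Peak],
    min_overlap_bp: int = 1,
    kzfp: str = "",
) -> OverlapReport:
    """Count peaks intersecting PBS intervals by at least ``min_overlap_bp``.

    Implemented with a per-chromosome interval tree over the PBS intervals.
    A warning is emitted when the two sets share no chromosome names (a
    likely genome-naming mismatch), and zero overlaps are reported.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for i, pbs in enumerate(pbs_intervals):
        trees.setdefault(pbs.chrom, IntervalTree()).addi(pbs.start, pbs.end, i)

    if peaks and pbs_intervals:
        if not ({p.chrom for p in peaks} & set(trees)):
            warnings.warn(
                "peak and PBS interval sets share no chromosome names; "
                "check genome naming",
                stacklevel=2,
            )

    per_pbs = [0] * len(pbs_intervals)
    n_overlapping = 0
    score_sum = 0.0
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        matched = False
        for iv in tree.overlap(peak.start, peak.end):
            if min(peak.end, iv.end) - max(peak.start, iv.begin) >= min_overlap_bp:
                per_pbs[iv.data] += 1
                matched = True
        if matched:
            n_overlapping += 1
            score_sum += peak.score
    return OverlapReport(
        kzfp=kzfp,
        n_peaks=len(peaks),
        n_overlapping_peaks=n_overlapping,
        mean_overlap_score=score_sum / n_overlapping if n_overlapping else 0.0,
        per_pbs_counts=tuple(per_pbs),
    )


def rank_binders(
    reports: TypingSequence[OverlapReport], top_n: int | None = None
) -> pd.DataFrame:
    """Rank KZFPs by overlapping-peak count (ties: mean score, then name)."""
    if not reports:
        raise ValueError("rank_binders requires at least one report")
    df = pd.DataFrame(
        [
            {
                "kzfp": r.kzfp,
                "n_peaks": r.n_peaks,
                "n_overlapping_peaks": r.n_overlapping_peaks,
                "mean_overlap_score": r.mean_overlap_score,
            }
            for r in reports
        ]
    )
    df = df.sort_values(
        by=["n_overlapping_peaks", "mean_overlap_score", "kzfp"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.head(top_n) if top_n else df
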