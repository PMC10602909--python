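"""Molecular dating of ERV insertions from 5'/3' LTR divergence.

The two LTRs of a provirus are identical at integration and diverge
neutrally afterwards, so their pairwise divergence is a molecular clock.
The calibration used throughout is 0.4% divergence per million years
(age in Myr = divergence% / 0.4).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .seq_core import Sequence, SubstitutionMatrix, global_align, read_fasta

#: % divergence per Myr: the linear LTR clock calibration.
DEFAULT_RATE_PCT_PER_MYR = 0.4
#: LTR pairs with a higher aligned gap fraction are flagged low-confidence.
MAX_GAP_FRACTION = 0.2


@dataclass(frozen=True)
class LTRPair:
    erv_id: str
    ltr5: Sequence
    ltr3: Sequence
    chrom: str = "chr1"
    start: int = 0
    end: int = 0


@dataclass(frozen=True)
class InsertionAge:
    erv_id: str
    divergence: float
    age_myr: float
    confidence: str = "high"  # "low" when the alignment is gap-heavy


class UndefinedDivergenceError(ValueError):
    """No aligned, unambiguous columns to estimate divergence from."""


def ltr_divergence(
    pair: LTRPair,
    min_length: int = 50,
    jukes_cantor: bool = False,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Pairwise divergence of the two LTRs of one provirus.

    The LTRs are globally aligned (DNA +5/-4 matrix, end gaps free) and the
    raw p-distance is taken over columns where both rows are non-gap and
    non-N; gap columns are excluded from numerator and denominator. With
    ``jukes_cantor=True`` the p-distance is corrected for multiple hits
    (d = -3/4 ln(1 - 4p/3)); at the small divergences typical of datable
    proviruses the two agree closely.
    """
    for ltr in (pair.ltr5, pair.ltr3):
        if len(ltr) < min_length:
            raise ValueError(
                f"{pair.erv_id}: LTR {ltr.id!r} shorter than {min_length} nt"
            )
    result = global_align(
        pair.ltr5,
        pair.ltr3,
        matrix=SubstitutionMatrix.dna_default(),
        gap_open=gap_open,
        gap_extend=gap_extend,
        end_gaps_free=True,
    )
    mismatched = comparable = 0
    for x, y in zip(result.aligned_a, result.aligned_b):
        if x == "-" or y == "-" or x == "N" or y == "N":
            continue
        comparable += 1
        if x != y:
            mismatched += 1
    if comparable == 0:
        raise UndefinedDivergenceError(
            f"{pair.erv_id}: no comparable alignment columns"
        )
    p = mismatched / comparable
    if jukes_cantor:
        if p >= 0.75:
            raise UndefinedDivergenceError(
                f"{pair.erv_id}: p-distance {p:.3f} saturates the JC correction"
            )
        return -0.75 * math.log1p(-4.0 * p / 3.0)
    return p


def alignment_gap_fraction(pair: LTRPair, **align_kwargs) -> float:
    """Fraction of alignment columns containing a gap (indel load)."""
    result = global_align(
        pair.ltr5,
        pair.ltr3,
        matrix=SubstitutionMatrix.dna_default(),
        end_gaps_free=True,
        **align_kwargs,
    )
    return result.gaps / result.length


def insertion_age(
    divergence: float, rate_pct_per_myr: float = DEFAULT_RATE_PCT_PER_MYR
) -> float:
    """Age in Myr from an LTR divergence fraction (0.004 -> 1.0 Myr at 0.4%/Myr)."""
    if divergence < 0 or divergence > 1:
        raise ValueError("divergence must be a fraction in [0, 1]")
    if rate_pct_per_myr <= 0:
        raise ValueError("rate must be > 0")
    return (divergence * 100.0) / rate_pct_per_myr


def date_ltr_pairs(
    pairs: Iterable[LTRPair],
    rate_pct_per_myr: float = DEFAULT_RATE_PCT_PER_MYR,
    jukes_cantor: bool = False,
) -> list[InsertionAge]:
    """Date each provirus; gap-heavy alignments are flagged low-confidence."""
    ages = []
    for pair in pairs:
        div = ltr_divergence(pair, jukes_cantor=jukes_cantor)
        gap_frac = alignment_gap_fraction(pair)
        ages.append(
            InsertionAge(
                erv_id=pair.erv_id,
                divergence=div,
                age_myr=insertion_age(div, rate_pct_per_myr),
                confidence="low" if gap_frac > MAX_GAP_FRACTION else "high",
            )
        )
    return ages


# ---------------------------------------------------------------------------
# Invasion profiles


@dataclass(frozen=True)
class InvasionProfile:
    """Histogram of insertion ages with the invasion-peak window.

    The peak window is the maximal contiguous run of bins, containing the
    modal bin, whose counts are all >= 50% of the modal count — a simple
    full-width-at-half-maximum reading of the invasion episode.
    """

    ages: tuple[float, ...]
    bin_width: float
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    peak_window: tuple[float, float]  # [start, end) in Myr

    def contains(self, age_myr: float) -> bool:
        lo, hi = self.peak_window
        return lo <= age_myr < hi

    @property
    def midpoint(self) -> float:
        lo, hi = self.peak_window
        return (lo + hi) / 2.0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "bin_width_myr": self.bin_width,
                "bin_edges_myr": list(self.bin_edges),
                "counts": list(self.counts),
                "peak_window_myr": list(self.peak_window),
                "n_ages": len(self.ages),
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def invasion_profile(
    ages: TypingSequence[float] | TypingSequence[InsertionAge],
    bin_width: float = 5.0,
) -> InvasionProfile:
    """Bin insertion ages over [0, max] and locate the invasion peak."""
    values = [a.age_myr if isinstance(a, InsertionAge) else float(a) for a in ages]
    if not values:
        raise ValueError("invasion_profile requires at least one age")
    if min(values) < 0:
        raise ValueError("ages must be >= 0")
    n_bins = max(1, math.ceil((max(values) + 1e-9) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    modal = int(np.argmax(counts))
    half = counts[modal] / 2.0
    lo = modal
    while lo > 0 and counts[lo - 1] >= half:
        lo -= 1
    hi = modal
    while hi + 1 < n_bins and counts[hi + 1] >= half:
        hi += 1
    return InvasionProfile(
        ages=tuple(values),
        bin_width=bin_width,
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        peak_window=(float(edges[lo]), float(edges[hi + 1])),
    )


# ---------------------------------------------------------------------------
# File interfaces


def read_ltr_pairs_fasta(path: str | Path) -> list[LTRPair]:
    """Read paired LTRs from FASTA with ids suffixed ``_5p``/``_3p``."""
    seqs = read_fasta(path, "dna")
    by_erv: dict[str, dict[str, Sequence]] = {}
    for s in seqs:
        if s.id.endswith("_5p"):
            by_erv.setdefault(s.id[:-3], {})["5p"] = s
        elif s.id.endswith("_3p"):
            by_erv.setdefault(s.id[:-3], {})["3p"] = s
        else:
            raise ValueError(f"LTR record {s.id!r} lacks a _5p/_3p suffix")
    pairs = []
    for erv_id, d in sorted(by_erv.items()):
        if set(d) != {"5p", "3p"}:
            raise ValueError(f"ERV {erv_id!r} is missing one LTR")
        pairs.append(LTRPair(erv_id=erv_id, ltr5=d["5p"], ltr3=d["3p"]))
    return pairs


def ages_to_dataframe(ages: Iterable[InsertionAge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "erv_id": a.erv_id,
                "divergence": a.divergence,
                "age_myr": a.age_myr,
                "confidence": a.confidence,
            }
            for a in ages
        ]
    )
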