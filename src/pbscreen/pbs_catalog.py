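"""Primer-binding-site (PBS) motifs: derivation, classification, scanning.

A retroviral PBS is the 18-nt element just downstream of the 5' LTR that is
complementary to the 3' end of a host tRNA and primes reverse transcription.
PBS types are named after the tRNA (PBS-Pro, PBS-Lys, ...); within a type
the first nine nucleotides are the conserved, discriminating half.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd

from .seq_core import Sequence, dna, reverse_complement, revcomp

PBS_LENGTH = 18
#: Windows with more Ns than this are not scanned.
MAX_N_PER_WINDOW = 6


@dataclass(frozen=True)
class PBSMotif:
    """An 18-nt PBS consensus tied to a tRNA identity."""

    trna_id: str
    consensus: str
    source_trna: Sequence | None = None

    def __post_init__(self) -> None:
        if len(self.consensus) != PBS_LENGTH:
            raise ValueError(
                f"PBS consensus for {self.trna_id} must be {PBS_LENGTH} nt, "
                f"got {len(self.consensus)}"
            )


@dataclass(frozen=True)
class PBSHit:
    """A PBS occurrence on a scanned sequence (0-based half-open interval)."""

    start: int
    end: int
    strand: str
    trna_id: str
    mismatches: int
    score: int


@dataclass(frozen=True)
class PBSClassification:
    types: tuple[str, ...]  # all minimizing types; >1 means ambiguous
    mismatches: int

    @property
    def ambiguous(self) -> bool:
        return len(self.types) > 1

    @property
    def trna_id(self) -> str:
        return self.types[0]


def derive_pbs_from_trna(trna: Sequence, trna_id: str | None = None) -> PBSMotif:
    """Derive the PBS consensus as the reverse complement of the tRNA 3' 18-mer.

    The PBS anneals to the tRNA 3' terminus, so the genomic (plus-strand)
    consensus is the reverse complement of the tRNA's last 18 nucleotides.
    """
    if trna.alphabet != "dna":
        raise ValueError("tRNA must be given as a DNA sequence")
    if len(trna) < PBS_LENGTH:
        raise ValueError(f"tRNA {trna.id!r} shorter than {PBS_LENGTH} nt")
    tail = trna.residues[-PBS_LENGTH:]
    return PBSMotif(
        trna_id=trna_id or trna.id,
        consensus=revcomp(tail),
        source_trna=trna,
    )


def hamming18(a: str, b: str) -> int:
    """Mismatch count between two 18-mers; N on either side counts as mismatch."""
    if len(a) != PBS_LENGTH or len(b) != PBS_LENGTH:
        raise ValueError("hamming18 requires 18-nt inputs")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def classify_pbs(seq18: str, catalog: TypingSequence[PBSMotif]) -> PBSClassification:
    """Assign an 18-mer to the catalog type with the fewest mismatches.

    Ties are reported as ambiguous, with all tied types listed in catalog
    order (the result is otherwise independent of catalog order).
    """
    seq18 = seq18.upper()
    if len(seq18) != PBS_LENGTH:
        raise ValueError(f"classify_pbs requires an {PBS_LENGTH}-nt input")
    if not catalog:
        raise ValueError("catalog is empty")
    dists = [(hamming18(seq18, m.consensus), m.trna_id) for m in catalog]
    best = min(d for d, _ in dists)
    types = tuple(t for d, t in dists if d == best)
    return PBSClassification(types=types, mismatches=best)


def distinctiveness_report(
    catalog: TypingSequence[PBSMotif], window: tuple[int, int] = (0, 9)
) -> pd.DataFrame:
    """Pairwise Hamming distances between catalog consensi over a window.

    The default window is the first nine nucleotides, the segment that
    separates PBS types from one another.
    """
    lo, hi = window
    rows = []
    for i, a in enumerate(catalog):
        for b in catalog[i + 1 :]:
            wa, wb = a.consensus[lo:hi], b.consensus[lo:hi]
            d = sum(1 for x, y in zip(wa, wb) if x != y)
            rows.append(
                {
                    "type_a": a.trna_id,
                    "type_b": b.trna_id,
                    "window_start": lo,
                    "window_end": hi,
                    "hamming": d,
                    "fraction_diff": d / (hi - lo),
                }
            )
    return pd.DataFrame(rows)


def pbs_score(mismatches: int, bonus: int = 0) -> int:
    """Confidence score: round(100 * (18 - m) / 18), plus a context bonus.

    The bonus (+10 by default in :func:`scan_pbs` when the hit sits just
    downstream of an annotated 5' LTR) lifts exact or near-exact hits in the
    expected proviral position above 100, making a strictly-greater-than-100
    filter meaningful.
    """
    return round(100 * (PBS_LENGTH - mismatches) / PBS_LENGTH) + bonus


def _mismatch_profile(target: np.ndarray, consensus: str) -> np.ndarray:
    """Per-window mismatch counts of ``consensus`` along an encoded target."""
    n = target.size - PBS_LENGTH + 1
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(target, PBS_LENGTH)
    n_code = ord("N")
    mism = (windows != cons) | (windows == n_code)
    if n_code in cons:
        mism |= cons == n_code
    return mism.sum(axis=1)


def scan_pbs(
    target: Sequence,
    catalog: TypingSequence[PBSMotif],
    max_mismatch: int = 3,
    both_strands: bool = True,
    ltr_ends: Iterable[int] | None = None,
    bonus_distance: int = 20,
    bonus: int = 10,
) -> list[PBSHit]:
    """Report every 18-mer window within ``max_mismatch`` of a catalog entry.

    For each window the best catalog type is reported (ties broken by
    catalog order). A +``bonus`` is added to the score when the hit starts
    within ``bonus_distance`` bp downstream of an annotated 5'-LTR end
    (``ltr_ends``, 0-based positions one past the LTR), the position a
    proviral PBS occupies. Hits are sorted by position then strand.
    """
    if not 0 <= max_mismatch <= PBS_LENGTH:
        raise ValueError("max_mismatch must be in [0, 18]")
    if target.alphabet != "dna":
        raise ValueError("scan target must be DNA")
    L = len(target)
    if L < PBS_LENGTH:
        return []
    ltr_end_list = sorted(ltr_ends) if ltr_ends is not None else []

    enc = np.frombuffer(target.residues.encode(), dtype=np.uint8)
    is_n = (enc == ord("N")).astype(np.int64)
    n_per_window = np.lib.stride_tricks.sliding_window_view(is_n, PBS_LENGTH).sum(axis=1)
    scannable = n_per_window <= MAX_N_PER_WINDOW

    strands = ["+", "-"] if both_strands else ["+"]
    hits: list[PBSHit] = []
    for strand in strands:
        for motif in catalog:
            cons = motif.consensus if strand == "+" else revcomp(motif.consensus)
            mism = _mismatch_profile(enc, cons)
            for pos in np.nonzero((mism <= max_mismatch) & scannable)[0]:
                hits.append((int(pos), strand, motif.trna_id, int(mism[pos])))

    # keep the best catalog type per (position, strand)
    best: dict[tuple[int, str], tuple[int, str]] = {}
    order = {m.trna_id: i for i, m in enumerate(catalog)}
    for pos, strand, trna_id, m in hits:
        key = (pos, strand)
        if key not in best or (m, order[trna_id]) < (best[key][0], order[best[key][1]]):
            best[key] = (m, trna_id)

    out: list[PBSHit] = []
    for (pos, strand), (m, trna_id) in sorted(best.items()):
        near_ltr = any(0 <= pos - e <= bonus_distance for e in ltr_end_list)
        out.append(
            PBSHit(
                start=pos,
                end=pos + PBS_LENGTH,
                strand=strand,
                trna_id=trna_id,
                mismatches=m,
                score=pbs_score(m, bonus if near_ltr else 0),
            )
        )
    return out


def hits_to_dataframe(hits: Iterable[PBSHit], chrom: str = "chr1") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": chrom,
                "start": h.start,
                "end": h.end,
                "name": f"PBS-{h.trna_id}",
                "score": h.score,
                "strand": h.strand,
                "mismatches": h.mismatches,
            }
            for h in hits
        ]
    )


def write_hits_bed(hits: Iterable[PBSHit], path: str | Path, chrom: str = "chr1") -> None:
    """Write hits as 6-column BED (name = PBS type, score = confidence)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{chrom}\t{h.start}\t{h.end}\tPBS-{h.trna_id}\t{h.score}\t{h.strand}\n"
            )
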