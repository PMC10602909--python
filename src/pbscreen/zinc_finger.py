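"""C2H2 zinc fingers: detection, fingerprints, recognition-code motifs.

A C2H2 zinc finger matches C-x(2,4)-C-x(12)-H-x(3,5)-H. The four
"fingerprint" residues sit at recognition-helix positions -1, 2, 3 and 6;
with the first histidine at helix position 7 these are sequence offsets
-7, -5, -4 and -1 from that histidine. The canonical Zif268 finger 1
(helix RSDELTR) yields fingerprint R,D,E,R and binds the triplet GCG,
which anchors both the offset convention and the shipped recognition code.

Fingers read their target 3'->5' along the coding strand: the C-terminal
finger binds the 5'-most triplet, so predicted motifs are emitted in
reverse finger order and are compared to a PBS on both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

from .seq_core import Sequence, revcomp
from .pbs_catalog import PBSMotif

C2H2_PATTERN = re.compile(r"C.{2,4}?C(.{12})H.{3,5}?H")

#: Fingerprint offsets within the fixed 12-residue C->H spacer
#: (helix -1, 2, 3, 6 == spacer indices 5, 7, 8, 11).
_SPACER_OFFSETS = (5, 7, 8, 11)


@dataclass(frozen=True)
class ZincFinger:
    index: int  # 1-based ordinal within the protein
    start: int  # 1-based inclusive residue interval
    end: int
    motif_seq: str
    fingerprint: str  # 4 residues in helix order -1, 2, 3, 6

    def __post_init__(self) -> None:
        if len(self.fingerprint) != 4:
            raise ValueError("fingerprint must have exactly 4 residues")


@dataclass(frozen=True)
class ZincFingerArray:
    protein_id: str
    fingers: tuple[ZincFinger, ...]

    def __len__(self) -> int:
        return len(self.fingers)

    @property
    def fingerprints(self) -> tuple[str, ...]:
        return tuple(f.fingerprint for f in self.fingers)


def extract_fingerprint(spacer12: str) -> str:
    """Fingerprint residues from the 12-residue C->H spacer of one finger."""
    if len(spacer12) != 12:
        raise ValueError("C->H spacer must be exactly 12 residues")
    return "".join(spacer12[i] for i in _SPACER_OFFSETS)


def find_c2h2(protein_seq: Sequence) -> ZincFingerArray:
    """Scan a protein left-to-right for non-overlapping C2H2 fingers.

    Matching is greedy earliest-start with shortest variable stretches, so
    tandem arrays resolve deterministically. The C->H spacer is fixed at 12
    residues, which keeps the fingerprint offsets well defined.
    """
    if protein_seq.alphabet != "protein":
        raise ValueError("find_c2h2 requires a protein sequence")
    fingers = []
    for i, m in enumerate(C2H2_PATTERN.finditer(protein_seq.residues), start=1):
        fingers.append(
            ZincFinger(
                index=i,
                start=m.start() + 1,
                end=m.end(),
                motif_seq=m.group(0),
                fingerprint=extract_fingerprint(m.group(1)),
            )
        )
    return ZincFingerArray(protein_id=protein_seq.id, fingers=tuple(fingers))


# ---------------------------------------------------------------------------
# Fingerprint array comparison


def _pair_score(fa: str, fb: str) -> int:
    return sum(1 for x, y in zip(fa, fb) if x == y)


def fingerprint_similarity(a: ZincFingerArray, b: ZincFingerArray) -> float:
    """Percent similarity between two fingerprint arrays.

    Fingers are aligned by a global dynamic program that preserves finger
    order (no re-ordering); each aligned finger pair contributes the number
    of positionally identical fingerprint residues (0-4) and gaps contribute
    nothing. The total is normalized by 4 x max(len(a), len(b)), so extra
    fingers dilute similarity.
    """
    if not a.fingers or not b.fingers:
        raise ValueError("fingerprint_similarity requires non-empty arrays")
    fa, fb = a.fingerprints, b.fingerprints
    m, n = len(fa), len(fb)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            dp[i][j] = max(
                dp[i - 1][j - 1] + _pair_score(fa[i - 1], fb[j - 1]),
                dp[i - 1][j],
                dp[i][j - 1],
            )
    return 100.0 * dp[m][n] / (4 * max(m, n))


# ---------------------------------------------------------------------------
# Recognition code


_BASE_TO_RESIDUE = {"G": "R", "A": "Q", "C": "E", "T": "T"}
_RESIDUE_TO_BASE = {v: k for k, v in _BASE_TO_RESIDUE.items()}
#: Helix position 2 contacts the complementary strand; held fixed in the
#: systematic code so a triplet maps to exactly one fingerprint.
_POSITION2_RESIDUE = "S"

#: Canonical, experimentally grounded entries (Zif268 fingers 1/3 and 2).
CANONICAL_CODE = {"RDER": "GCG", "RDHT": "TGG"}


class RecognitionCode:
    """Lookup from 4-residue fingerprints to preferred DNA triplets.

    Helix positions 6, 3 and -1 contact the 5', middle and 3' base of the
    triplet respectively. Besides a small canonical table, a complete
    systematic code (one fingerprint per triplet, built from a fixed
    base->residue map) is available; it is what the synthetic-data
    generator inverts when planting a binder.
    """

    def __init__(self, table: dict[str, str]):
        for fp, tri in table.items():
            if len(fp) != 4 or len(tri) != 3 or set(tri) - set("ACGT"):
                raise ValueError(f"bad code entry {fp!r} -> {tri!r}")
        self._table = dict(table)

    def __len__(self) -> int:
        return len(self._table)

    def lookup(self, fingerprint: str) -> str | None:
        """Triplet for a fingerprint, or None if unknown."""
        return self._table.get(fingerprint)

    def items(self):
        return self._table.items()

    def fingerprint_for_triplet(self, triplet: str) -> str:
        """Invert the code: the systematic fingerprint preferring ``triplet``.

        The 5' base maps to helix 6, the middle base to helix 3 and the 3'
        base to helix -1; helix 2 is fixed. Raises KeyError when the
        resulting fingerprint is not in the table (non-invertible code).
        """
        b5, bm, b3 = triplet
        fp = (
            _BASE_TO_RESIDUE[b3]
            + _POSITION2_RESIDUE
            + _BASE_TO_RESIDUE[bm]
            + _BASE_TO_RESIDUE[b5]
        )
        if fp not in self._table:
            raise KeyError(f"code is not invertible for triplet {triplet!r}")
        return fp

    @classmethod
    def canonical(cls) -> "RecognitionCode":
        return cls(dict(CANONICAL_CODE))

    @classmethod
    def complete(cls) -> "RecognitionCode":
        """Canonical entries plus one systematic fingerprint per triplet."""
        table = {}
        for b5 in "ACGT":
            for bm in "ACGT":
                for b3 in "ACGT":
                    fp = (
                        _BASE_TO_RESIDUE[b3]
                        + _POSITION2_RESIDUE
                        + _BASE_TO_RESIDUE[bm]
                        + _BASE_TO_RESIDUE[b5]
                    )
                    table[fp] = b5 + bm + b3
        table.update(CANONICAL_CODE)
        return cls(table)

    @classmethod
    def load_tsv(cls, path: str | Path) -> "RecognitionCode":
        """Load fingerprint->triplet entries from a 2+ column TSV."""
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                table[parts[0]] = parts[1]
        return cls(table)

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# fingerprint\ttriplet\n")
            for fp, tri in sorted(self._table.items()):
                fh.write(f"{fp}\t{tri}\n")


# ---------------------------------------------------------------------------
# Motif prediction and PBS comparison


@dataclass(frozen=True)
class PredictedMotif:
    """Consensus DNA motif predicted from a finger array (3 nt per finger)."""

    protein_id: str
    consensus: str
    finger_indices: tuple[int, ...]  # fingers used, N->C order
    unknown_fingers: tuple[int, ...]  # fingers emitted as NNN

    @property
    def reverse_complement(self) -> str:
        return revcomp(self.consensus)

    @property
    def all_unknown(self) -> bool:
        return set(self.consensus) <= {"N"}


def predict_motif(
    zfa: ZincFingerArray,
    code: RecognitionCode,
    fingers: TypingSequence[int] | None = None,
) -> PredictedMotif:
    """Predict the binding consensus of a finger array via the code.

    Triplets are emitted in reverse finger order (the C-terminal finger
    binds the 5'-most triplet). Fingers with fingerprints absent from the
    code contribute NNN and are flagged.
    """
    if fingers is None:
        used = list(zfa.fingers)
    else:
        by_index = {f.index: f for f in zfa.fingers}
        try:
            used = [by_index[i] for i in fingers]
        except KeyError as exc:
            raise ValueError(f"finger index {exc} not in array") from exc
    triplets = []
    unknown = []
    for f in reversed(used):
        tri = code.lookup(f.fingerprint)
        if tri is None:
            tri = "NNN"
            unknown.append(f.index)
        triplets.append(tri)
    return PredictedMotif(
        protein_id=zfa.protein_id,
        consensus="".join(triplets),
        finger_indices=tuple(f.index for f in used),
        unknown_fingers=tuple(unknown),
    )


@dataclass(frozen=True)
class MotifMatch:
    """Best ungapped placement of a predicted motif against an 18-nt PBS."""

    offset: int
    strand: str
    fraction: float
    undefined: bool = False


def motif_vs_pbs(motif: PredictedMotif | str, pbs: PBSMotif) -> MotifMatch:
    """Best sliding-window match fraction of a motif consensus vs a PBS.

    The shorter sequence slides fully inside the longer one; at each offset
    the fraction is matches over non-N consensus positions in the overlap.
    Both PBS strands are evaluated. An all-N motif is reported as fraction
    0 with ``undefined=True``.
    """
    consensus = motif if isinstance(motif, str) else motif.consensus
    informative = sum(1 for c in consensus if c != "N")
    if informative == 0:
        return MotifMatch(offset=0, strand="+", fraction=0.0, undefined=True)

    best = MotifMatch(offset=0, strand="+", fraction=-1.0)
    for strand in ("+", "-"):
        target = pbs.consensus if strand == "+" else revcomp(pbs.consensus)
        if len(consensus) <= len(target):
            short, long_, motif_is_short = consensus, target, True
        else:
            short, long_, motif_is_short = target, consensus, False
        for off in range(len(long_) - len(short) + 1):
            window = long_[off : off + len(short)]
            a, b = (short, window) if motif_is_short else (window, short)
            # a = motif side, b = PBS side
            num = den = 0
            for x, y in zip(a, b):
                if x == "N":
                    continue
                den += 1
                if x == y and y != "N":
                    num += 1
            frac = num / den if den else 0.0
            if frac > best.fraction:
                best = MotifMatch(offset=off, strand=strand, fraction=frac)
    return best


# ---------------------------------------------------------------------------
# Tabular output


def fingerprints_to_tsv(
    arrays: Iterable[ZincFingerArray], path: str | Path
) -> None:
    """Write per-finger fingerprints (protein_id, index, span, fingerprint)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tfinger_index\tstart\tend\tfingerprint\n")
        for zfa in arrays:
            for f in zfa.fingers:
                fh.write(
                    f"{zfa.protein_id}\t{f.index}\t{f.start}\t{f.end}\t{f.fingerprint}\n"
                )
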