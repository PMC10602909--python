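"""Sequence primitives and Needle-style global pairwise alignment.

The alignment conventions follow EMBOSS Needle, the standard tool for
pairwise KZFP comparisons: Needleman-Wunsch with affine gaps, end gaps
free by default, and identity/similarity percentages computed over the
full alignment length (gap columns count in the denominator). A column
is "similar" when its substitution score is strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """Residues outside the declared alphabet, or mixed-alphabet operands."""


@dataclass(frozen=True)
class Sequence:
    """An identified, upper-case sequence over a declared alphabet.

    ``alphabet`` is ``"dna"`` (ACGTN) or ``"protein"`` (20 amino acids + X).
    """

    id: str
    alphabet: str
    residues: str

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} has residues {sorted(bad)} outside "
                f"the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


def dna(seq_id: str, residues: str) -> Sequence:
    return Sequence(seq_id, "dna", residues.upper())


def protein(seq_id: str, residues: str) -> Sequence:
    return Sequence(seq_id, "protein", residues.upper())


def reverse_complement(seq: Sequence) -> Sequence:
    """Reverse complement of a DNA sequence (A<->T, C<->G, N<->N)."""
    if seq.alphabet != "dna":
        raise AlphabetError("reverse_complement requires a DNA sequence")
    return Sequence(seq.id, "dna", seq.residues.translate(_COMPLEMENT)[::-1])


def revcomp(residues: str) -> str:
    """Reverse complement of a raw DNA string."""
    return residues.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Substitution matrices


class SubstitutionMatrix:
    """Symmetric residue-pair scores over one alphabet.

    Ambiguity codes (N for DNA, X for protein) score 0 against everything,
    a neutral treatment that keeps them from inflating or deflating
    similarity percentages.
    """

    def __init__(self, name: str, alphabet: str, scores: dict[tuple[str, str], float]):
        self.name = name
        self.alphabet = alphabet
        self._scores: dict[tuple[str, str], float] = {}
        for (a, b), s in scores.items():
            self._scores[(a, b)] = s
            self._scores[(b, a)] = s
        for (a, b), s in self._scores.items():
            if self._scores[(b, a)] != s:
                raise ValueError(f"matrix {name} asymmetric at {(a, b)}")

    def score(self, a: str, b: str) -> float:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"matrix {self.name} has no score for pair {(a, b)!r}")

    def residues(self) -> list[str]:
        return sorted({a for a, _ in self._scores})

    def to_biopython(self) -> substitution_matrices.Array:
        letters = "".join(self.residues())
        arr = substitution_matrices.Array(alphabet=letters, dims=2)
        for a in letters:
            for b in letters:
                arr[a, b] = self._scores[(a, b)]
        return arr

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """BLOSUM62 over the 20 amino acids plus X (X scores forced to 0)."""
        raw = substitution_matrices.load("BLOSUM62")
        letters = sorted(PROTEIN_ALPHABET)
        scores: dict[tuple[str, str], float] = {}
        for a in letters:
            for b in letters:
                if a == "X" or b == "X":
                    scores[(a, b)] = 0.0
                else:
                    scores[(a, b)] = float(raw[a, b])
        return cls("BLOSUM62", "protein", scores)

    @classmethod
    def dna_default(cls, match: float = 5.0, mismatch: float = -4.0) -> "SubstitutionMatrix":
        """Match/mismatch DNA matrix (+5/-4 default, the EDNAFULL core); N scores 0."""
        scores: dict[tuple[str, str], float] = {}
        for a in "ACGTN":
            for b in "ACGTN":
                if a == "N" or b == "N":
                    scores[(a, b)] = 0.0
                else:
                    scores[(a, b)] = match if a == b else mismatch
        return cls(f"DNA(match={match:g},mismatch={mismatch:g})", "dna", scores)

    @classmethod
    def from_ncbi(cls, path: str | Path, alphabet: str = "protein") -> "SubstitutionMatrix":
        """Load a matrix in NCBI text format (as distributed with BLAST/EMBOSS)."""
        arr = substitution_matrices.read(str(path))
        letters = [c for c in arr.alphabet if c != "*"]
        scores = {(a, b): float(arr[a, b]) for a in letters for b in letters}
        return cls(Path(path).stem, alphabet, scores)


# ---------------------------------------------------------------------------
# Global alignment


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment with Needle-style summary percentages."""

    aligned_a: str
    aligned_b: str
    score: float
    length: int
    identity_pct: float
    similarity_pct: float
    gaps: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def global_align(
    a: Sequence,
    b: Sequence,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_free: bool = True,
) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment with affine gap costs.

    A gap of length L costs ``gap_open + L * gap_extend``; terminal gaps are
    free unless ``end_gaps_free=False``. Defaults (BLOSUM62 for protein,
    +5/-4 for DNA, open 10 / extend 0.5) mirror EMBOSS Needle's defaults.

    Parameters
    ----------
    a, b:
        Sequences over the same alphabet.
    matrix:
        Substitution matrix; defaults by alphabet as above.

    Returns
    -------
    AlignmentResult
        identity_pct and similarity_pct are percentages of *alignment
        columns* (gap columns included in the denominator).
    """
    if a.alphabet != b.alphabet:
        raise AlphabetError(f"alphabet mismatch: {a.alphabet} vs {b.alphabet}")
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be >= 0")
    if matrix is None:
        matrix = (
            SubstitutionMatrix.blosum62()
            if a.alphabet == "protein"
            else SubstitutionMatrix.dna_default()
        )

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix.to_biopython()
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if end_gaps_free:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # biopython < 1.88 attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0

    alignment = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = alignment[0], alignment[1]
    return _summarize(row_a, row_b, float(alignment.score), matrix)


def _summarize(
    row_a: str, row_b: str, score: float, matrix: SubstitutionMatrix
) -> AlignmentResult:
    length = len(row_a)
    identical = similar = gaps = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y:
            identical += 1
        if matrix.score(x, y) > 0:
            similar += 1
    return AlignmentResult(
        aligned_a=row_a,
        aligned_b=row_b,
        score=score,
        length=length,
        identity_pct=100.0 * identical / length,
        similarity_pct=100.0 * similar / length,
        gaps=gaps,
    )


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, alphabet: str) -> list[Sequence]:
    """Read a multi-record FASTA into Sequences of the given alphabet."""
    records = list(SeqIO.parse(str(path), "fasta"))
    return [Sequence(rec.id, alphabet, str(rec.seq).upper()) for rec in records]


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)
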