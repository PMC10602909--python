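"""Independent brute-force oracles used by the test suite.

Every oracle here deliberately avoids the implementation path it checks:
alignment scores come from exhaustive enumeration of all global
alignments, finger-array similarity from enumeration of all monotone
matchings, and overlap counts from a quadratic all-pairs scan.
"""

from __future__ import annotations

from pbscreen.seq_core import SubstitutionMatrix


def enumerate_alignment_score(
    a: str,
    b: str,
    matrix: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
    end_gaps_free: bool = True,
) -> float:
    """Max global-alignment score by exhaustive enumeration of alignments.

    A gap run of length L costs gap_open + L * gap_extend unless it touches
    the start or end of the alignment and end gaps are free. Exponential;
    only for tiny sequences.
    """

    best = [float("-inf")]

    def score(cols: list[tuple[str, str]]) -> float:
        total = 0.0
        for x, y in cols:
            if x != "-" and y != "-":
                total += matrix.score(x, y)
        for row in (0, 1):
            i = 0
            while i < len(cols):
                if cols[i][row] == "-":
                    j = i
                    while j < len(cols) and cols[j][row] == "-":
                        j += 1
                    terminal = i == 0 or j == len(cols)
                    if not (end_gaps_free and terminal):
                        total -= gap_open + gap_extend * (j - i)
                    i = j
                else:
                    i += 1
        return total

    def rec(i: int, j: int, cols: list[tuple[str, str]]) -> None:
        if i == len(a) and j == len(b):
            s = score(cols)
            if s > best[0]:
                best[0] = s
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


def enumerate_fingerprint_similarity(fa: list[str], fb: list[str]) -> float:
    """Best monotone finger matching by exhaustive recursion."""
    best = [0]

    def rec(i: int, j: int, acc: int) -> None:
        if acc > best[0]:
            best[0] = acc
        if i < len(fa) and j < len(fb):
            pair = sum(1 for x, y in zip(fa[i], fb[j]) if x == y)
            rec(i + 1, j + 1, acc + pair)
        if i < len(fa):
            rec(i + 1, j, acc)
        if j < len(fb):
            rec(i, j + 1, acc)

    rec(0, 0, 0)
    return 100.0 * best[0] / (4 * max(len(fa), len(fb)))


def quadratic_overlap_count(peaks, pbs_intervals, min_overlap_bp: int = 1) -> int:
    """Peaks intersecting >= 1 PBS interval, by all-pairs comparison."""
    n = 0
    for p in peaks:
        for q in pbs_intervals:
            if p.chrom == q.chrom and min(p.end, q.end) - max(p.start, q.start) >= min_overlap_bp:
                n += 1
                break
    return n


def best_motif_match_fraction(consensus: str, pbs18: str, revcomp_pbs: str) -> float:
    """Best ungapped match fraction over all offsets and both strands."""
    best = 0.0
    for target in (pbs18, revcomp_pbs):
        short, long_ = (consensus, target) if len(consensus) <= len(target) else (target, consensus)
        motif_first = len(consensus) <= len(target)
        for off in range(len(long_) - len(short) + 1):
            win = long_[off : off + len(short)]
            mot, tgt = (short, win) if motif_first else (win, short)
            num = den = 0
            for x, y in zip(mot, tgt):
                if x == "N":
                    continue
                den += 1
                if x == y and y != "N":
                    num += 1
            if den and num / den > best:
                best = num / den
    return best
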