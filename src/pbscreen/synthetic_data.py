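"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the real inputs of a PBS-targeting KZFP screen — a
genome with planted ERV proviruses, a KZFP protein panel with one true
binder, ChIP-like peak files, and ortholog/divergence tables — at desk
scale, with every planted quantity recorded so downstream stages can be
verified exactly (coordinates, ages, binder identity) or within stated
sampling tolerance (LTR dating).

All generators are pure functions of (parameters, seed): a given seed
yields byte-identical outputs. Substreams are derived from (seed, counter)
so per-ERV or per-protein draws stay stable under parameter reordering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence as TypingSequence

import numpy as np

from .seq_core import Sequence, dna, protein, revcomp, write_fasta
from .pbs_catalog import PBSMotif, PBS_LENGTH, derive_pbs_from_trna
from .zinc_finger import RecognitionCode, find_c2h2, predict_motif, motif_vs_pbs
from .ltr_dating import LTRPair, DEFAULT_RATE_PCT_PER_MYR
from .kzfp_age import OrthologTable, DivergenceTimes
from .peak_overlap import Peak, write_bed

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: Protein alphabet without C and H, so C2H2 fingers appear only where planted.
_SCAFFOLD_AA = "ADEFGIKLMNPQRSTVWY"

#: PBS consensi used by the default catalog. The Pro entry's first nine
#: nucleotides are the conserved TGGGGGCTC block of ERVP consensus
#: sequences; the Lys entry is the HIV-1 PBS-Lys3 18-mer; the remaining
#: types are synthetic stand-ins sharing only the universal TGG start
#: (the complement of the tRNA CCA terminus).
DEFAULT_PBS_CONSENSUS: dict[str, str] = {
    "Pro": "TGGGGGCTCGTCCGGGAT",
    "Lys": "TGGCGCCCGAACAGGGAC",
    "Leu": "TGGTAGCAGTGGGTGCCC",
    "Phe": "TGGTGCCGAAACCCAGGG",
    "Trp": "TGGCGTGTATTCCCAAGG",
}

#: Divergence times (Myr) from the reference to a ladder of species,
#: spanning great apes to birds. The 30-Myr rung is the Old World monkey
#: split, the epoch of the ERVP invasion the screen targets.
DEFAULT_REFERENCE_SPECIES = "Homo_sapiens"
DEFAULT_SPECIES_TIMES: dict[str, float] = {
    "Pan_troglodytes": 6.0,
    "Gorilla_gorilla": 9.0,
    "Pongo_abelii": 16.0,
    "Nomascus_leucogenys": 20.0,
    "Macaca_mulatta": 30.0,
    "Callithrix_jacchus": 43.0,
    "Carlito_syrichta": 60.0,
    "Mus_musculus": 90.0,
    "Monodelphis_domestica": 160.0,
    "Gallus_gallus": 300.0,
}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _random_scaffold(rng: np.random.Generator, length: int) -> str:
    letters = np.frombuffer(_SCAFFOLD_AA.encode(), dtype=np.uint8)
    return rng.choice(letters, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# tRNAs and the default PBS catalog


def default_trnas(body_length: int = 58) -> list[Sequence]:
    """Synthetic tRNAs whose 3' 18-mers reverse-complement to the catalog."""
    trnas = []
    for i, (name, consensus) in enumerate(sorted(DEFAULT_PBS_CONSENSUS.items())):
        body = _random_dna(_rng(1234, i), body_length)
        trnas.append(dna(f"tRNA-{name}", body + revcomp(consensus)))
    return trnas


def default_catalog() -> list[PBSMotif]:
    """The default PBS catalog, derived from the synthetic tRNA set."""
    return [
        derive_pbs_from_trna(t, trna_id=t.id.removeprefix("tRNA-"))
        for t in default_trnas()
    ]


# ---------------------------------------------------------------------------
# Genomes with planted proviruses


@dataclass(frozen=True)
class ERVAnnotation:
    """A planted provirus: 5'LTR + PBS + internal + 3'LTR, with truth."""

    erv_id: str
    chrom: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    pbs_start: int
    pbs_end: int
    pbs_type: str
    pbs_seq: str
    pbs_mismatches: int
    true_age_myr: float


@dataclass
class GenomeSim:
    genome: Sequence
    ervs: list[ERVAnnotation]
    seed: int
    params: dict

    @property
    def ltr_ends(self) -> list[int]:
        return [e.ltr5_end for e in self.ervs]

    @property
    def pbs_truth(self) -> list[Peak]:
        return [
            Peak(e.chrom, e.pbs_start, e.pbs_end, f"PBS-{e.pbs_type}", 100.0, "+")
            for e in self.ervs
        ]

    def ltr_pairs(self) -> list[LTRPair]:
        g = self.genome.residues
        return [
            LTRPair(
                erv_id=e.erv_id,
                ltr5=dna(f"{e.erv_id}_5p", g[e.ltr5_start : e.ltr5_end]),
                ltr3=dna(f"{e.erv_id}_3p", g[e.ltr3_start : e.ltr3_end]),
                chrom=e.chrom,
                start=e.start,
                end=e.end,
            )
            for e in self.ervs
        ]


def _mutate(rng: np.random.Generator, seq: np.ndarray, p: float) -> np.ndarray:
    """Point-substitute each site with probability p (always to a new base)."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < p)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_genome(
    seed: int,
    n_ervs: int = 8,
    genome_len: int = 150_000,
    ltr_len: int = 1000,
    internal_len: int = 1500,
    ages_myr: TypingSequence[float] | None = None,
    pbs_types: TypingSequence[str] | None = None,
    pbs_mismatches: int = 0,
    catalog: TypingSequence[PBSMotif] | None = None,
    rate_pct_per_myr: float = DEFAULT_RATE_PCT_PER_MYR,
    chrom: str = "chr1",
) -> GenomeSim:
    """Plant proviruses with known PBS sequences and LTR divergence ages.

    Each provirus is 5'LTR + PBS(18 nt, immediately downstream of the 5'
    LTR) + internal + 3'LTR. Both LTR copies descend from one ancestral
    LTR, each mutated at per-site probability age x rate / 2 (in fraction
    units), so their expected pairwise divergence is age x rate — the same
    linear clock the dating stage inverts. Requested PBS mismatches are
    placed uniformly outside the first nine nucleotides (the conserved,
    type-discriminating half).

    Default ages are Normal(30, 3) Myr truncated at 0: a single invasion
    episode at the Old World monkey epoch.
    """
    cat = {m.trna_id: m for m in (catalog or default_catalog())}
    age_rng = _rng(seed, 10_000)
    if ages_myr is None:
        ages_myr = [max(0.0, float(a)) for a in age_rng.normal(30.0, 3.0, size=n_ervs)]
    if len(ages_myr) != n_ervs:
        raise ValueError("ages_myr must have one entry per ERV")
    if pbs_types is None:
        pbs_types = ["Pro"] * n_ervs
    if pbs_mismatches > PBS_LENGTH - 9:
        raise ValueError("cannot place that many mismatches outside the first 9 nt")

    erv_len = 2 * ltr_len + PBS_LENGTH + internal_len
    slack = genome_len - n_ervs * erv_len
    if slack < 0:
        raise ValueError(
            f"{n_ervs} ERVs of {erv_len} bp do not fit in {genome_len} bp"
        )
    bg_rng = _rng(seed, 0)
    genome = np.frombuffer(
        _random_dna(bg_rng, genome_len).encode(), dtype=np.uint8
    ).copy()
    offsets = np.sort(bg_rng.integers(0, slack + 1, size=n_ervs))

    ervs = []
    for k in range(n_ervs):
        rng = _rng(seed, k + 1)
        start = int(offsets[k] + k * erv_len)
        age = float(ages_myr[k])
        p_each = age * (rate_pct_per_myr / 100.0) / 2.0
        ancestral = np.frombuffer(_random_dna(rng, ltr_len).encode(), dtype=np.uint8)
        ltr5 = _mutate(rng, ancestral, p_each)
        ltr3 = _mutate(rng, ancestral, p_each)

        motif = cat[pbs_types[k]]
        pbs = list(motif.consensus)
        if pbs_mismatches:
            sites = rng.choice(np.arange(9, PBS_LENGTH), size=pbs_mismatches, replace=False)
            for s in sites:
                pbs[s] = chr(rng.choice(_BASES[_BASES != ord(pbs[s])]))
        pbs_seq = "".join(pbs)

        internal = _random_dna(rng, internal_len)
        block = (
            ltr5.tobytes().decode() + pbs_seq + internal + ltr3.tobytes().decode()
        )
        genome[start : start + erv_len] = np.frombuffer(block.encode(), dtype=np.uint8)
        ervs.append(
            ERVAnnotation(
                erv_id=f"ERV{k + 1:03d}",
                chrom=chrom,
                start=start,
                end=start + erv_len,
                ltr5_start=start,
                ltr5_end=start + ltr_len,
                ltr3_start=start + erv_len - ltr_len,
                ltr3_end=start + erv_len,
                pbs_start=start + ltr_len,
                pbs_end=start + ltr_len + PBS_LENGTH,
                pbs_type=pbs_types[k],
                pbs_seq=pbs_seq,
                pbs_mismatches=pbs_mismatches,
                true_age_myr=age,
            )
        )
    return GenomeSim(
        genome=Sequence(chrom, "dna", genome.tobytes().decode()),
        ervs=ervs,
        seed=seed,
        params={
            "n_ervs": n_ervs,
            "genome_len": genome_len,
            "ltr_len": ltr_len,
            "internal_len": internal_len,
            "pbs_mismatches": pbs_mismatches,
            "rate_pct_per_myr": rate_pct_per_myr,
        },
    )


# ---------------------------------------------------------------------------
# KZFP protein panels


_FINGER_LINKER = "TGEKP"


def build_finger_unit(fingerprint: str) -> str:
    """A 21-residue C2H2 finger carrying the given fingerprint.

    Layout: C xx C <12-residue spacer> H xxx H, with the fingerprint at
    spacer offsets 5/7/8/11 (helix -1, 2, 3, 6) and all other positions
    drawn from a C/H-free filler so pattern matches are unambiguous.
    """
    if len(fingerprint) != 4:
        raise ValueError("fingerprint must be 4 residues")
    spacer = list("FSKSS" + "S" * 7)
    spacer[5], spacer[7], spacer[8], spacer[11] = fingerprint
    return "C" + "PE" + "C" + "".join(spacer) + "H" + "QRT" + "H"


def build_zf_protein(
    protein_id: str,
    fingerprints: TypingSequence[str],
    krab: str | None = None,
    linker_to_array: str = "",
) -> Sequence:
    """Assemble KRAB-like scaffold + tandem C2H2 array from fingerprints."""
    if krab is None:
        krab = _random_scaffold(_rng(4321, 0), 74)
    array = _FINGER_LINKER.join(build_finger_unit(fp) for fp in fingerprints)
    return protein(protein_id, "M" + krab + linker_to_array + array)


@dataclass
class PanelSim:
    proteins: list[Sequence]
    binder_id: str
    fingerprints: dict[str, tuple[str, ...]]
    pbs: PBSMotif
    window: tuple[int, int]
    code: RecognitionCode
    seed: int


def binder_fingerprints(
    pbs: PBSMotif, code: RecognitionCode, window: tuple[int, int] = (0, 9)
) -> tuple[str, ...]:
    """Invert the recognition code against a PBS window (finger order reversed).

    The returned fingerprints, N- to C-terminal, predict exactly the PBS
    window: the C-terminal finger binds the 5'-most triplet.
    """
    lo, hi = window
    if (hi - lo) % 3 != 0:
        raise ValueError("PBS window length must be a multiple of 3")
    triplets = [pbs.consensus[i : i + 3] for i in range(lo, hi, 3)]
    return tuple(code.fingerprint_for_triplet(t) for t in reversed(triplets))


def simulate_kzfp_panel(
    seed: int,
    n: int = 20,
    pbs: PBSMotif | None = None,
    code: RecognitionCode | None = None,
    window: tuple[int, int] = (0, 9),
    decoy_fingers: tuple[int, int] = (3, 8),
    max_decoy_match: float = 0.5,
    max_resample: int = 200,
) -> PanelSim:
    """A KZFP panel with one planted PBS binder among random decoys.

    The binder's fingerprints are built by inverting the recognition code
    against the PBS window, so its predicted motif matches the planted PBS
    exactly. Decoys draw random code-table fingerprints and are resampled
    until their predicted motifs match the PBS below ``max_decoy_match``
    on either strand. Every protein is a KRAB-like scaffold plus a C2H2
    array that the finger scanner detects exactly.
    """
    if pbs is None:
        pbs = default_catalog()[[m.trna_id for m in default_catalog()].index("Pro")]
    if code is None:
        code = RecognitionCode.complete()
    rng = _rng(seed, 20_000)
    ids = [f"KZFP{i + 1:02d}" for i in range(n)]
    binder_id = ids[int(rng.integers(n))]
    code_fps = sorted(fp for fp, _ in code.items())

    proteins = []
    fingerprints: dict[str, tuple[str, ...]] = {}
    for i, pid in enumerate(ids):
        prng = _rng(seed, 20_001 + i)
        if pid == binder_id:
            fps = binder_fingerprints(pbs, code, window)
        else:
            for _ in range(max_resample):
                k = int(prng.integers(decoy_fingers[0], decoy_fingers[1] + 1))
                fps = tuple(code_fps[j] for j in prng.integers(len(code_fps), size=k))
                motif = "".join(
                    code.lookup(fp) or "NNN" for fp in reversed(fps)
                )
                if motif_vs_pbs(motif, pbs).fraction < max_decoy_match:
                    break
            else:
                raise RuntimeError(
                    f"could not draw a decoy below match {max_decoy_match}"
                )
        krab = _random_scaffold(prng, 74)
        proteins.append(build_zf_protein(pid, fps, krab=krab))
        fingerprints[pid] = fps
    return PanelSim(
        proteins=proteins,
        binder_id=binder_id,
        fingerprints=fingerprints,
        pbs=pbs,
        window=window,
        code=code,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reference-binder stand-ins


def standin_reference_proteins() -> dict[str, dict]:
    """Synthetic stand-ins for the reference PBS-Pro binders and a paralog.

    These are NOT the real ZNF506/ZFP809/ZNF253 sequences (which require a
    database fetch); they are synthetic proteins that reproduce the
    documented *architecture*: a KRAB box at residues 1-75, and for the
    ZNF506 stand-in a C-terminal array of exactly 8 C2H2 fingers spanning
    residues 201-419 of a 419-residue protein. The ZNF253 stand-in shares
    a near-identical KRAB box with the ZNF506 stand-in, mimicking a recent
    duplicate; the ZFP809 stand-in is unrelated. Domain spans are returned
    alongside the sequences.
    """
    # ZNF506 stand-in: 419 aa; fingers fill residues 201..419 (1-based).
    krab506 = _random_scaffold(_rng(5550, 0), 74)  # residues 2..75
    linker506 = _random_scaffold(_rng(5550, 1), 125)  # residues 76..200
    fps506 = binder_fingerprints(
        default_catalog()[[m.trna_id for m in default_catalog()].index("Pro")],
        RecognitionCode.complete(),
        window=(0, 9),
    )
    extra = sorted(fp for fp, _ in RecognitionCode.complete().items())
    rng506 = _rng(5550, 2)
    fps506 = tuple(fps506) + tuple(
        extra[j] for j in rng506.integers(len(extra), size=5)
    )  # 8 fingers
    array506 = _FINGER_LINKER.join(build_finger_unit(fp) for fp in fps506)  # 203 aa
    pad = _random_scaffold(_rng(5550, 3), 219 - len(array506))
    seq506 = "M" + krab506 + linker506 + array506 + pad
    assert len(seq506) == 419

    # ZFP809 stand-in: unrelated scaffold, 7 fingers, 392 aa.
    krab809 = _random_scaffold(_rng(5551, 0), 74)
    linker809 = _random_scaffold(_rng(5551, 1), 110)
    rng809 = _rng(5551, 2)
    fps809 = tuple(extra[j] for j in rng809.integers(len(extra), size=7))
    array809 = _FINGER_LINKER.join(build_finger_unit(fp) for fp in fps809)
    seq809 = "M" + krab809 + linker809 + array809
    seq809 = seq809 + _random_scaffold(_rng(5551, 3), 392 - len(seq809))

    # ZNF253 stand-in: KRAB copied from the ZNF506 stand-in with one
    # substitution (a young duplicate), its own linker and 6 fingers.
    krab253 = list(krab506)
    krab253[10] = "A" if krab253[10] != "A" else "G"
    krab253 = "".join(krab253)
    rng253 = _rng(5552, 2)
    fps253 = tuple(extra[j] for j in rng253.integers(len(extra), size=6))
    array253 = _FINGER_LINKER.join(build_finger_unit(fp) for fp in fps253)
    seq253 = "M" + krab253 + _random_scaffold(_rng(5552, 1), 100) + array253

    return {
        "ZNF506_standin": {
            "sequence": protein("ZNF506_standin", seq506),
            "krab_span": (1, 75),
            "zf_array_span": (201, 419),
            "n_fingers": 8,
        },
        "ZFP809_standin": {
            "sequence": protein("ZFP809_standin", seq809),
            "krab_span": (1, 75),
            "n_fingers": 7,
        },
        "ZNF253_standin": {
            "sequence": protein("ZNF253_standin", seq253),
            "krab_span": (1, 75),
            "n_fingers": 6,
        },
    }


# ---------------------------------------------------------------------------
# ChIP-like peaks


@dataclass
class PeakSim:
    peaks: dict[str, list[Peak]]
    covered_pbs: dict[str, list[int]]
    seed: int


def simulate_peaks(
    seed: int,
    binder_id: str,
    decoy_ids: TypingSequence[str],
    pbs_intervals: TypingSequence[Peak],
    genome_len: int,
    cover_fraction: float = 0.85,
    width_range: tuple[int, int] = (200, 400),
    binder_scores: tuple[int, int] = (600, 1000),
    decoy_scores: tuple[int, int] = (100, 1000),
    chrom: str = "chr1",
) -> PeakSim:
    """Binder peaks centered on most PBS loci; decoy peaks uniform random.

    The binder receives one peak on ceil(cover_fraction x n_pbs) distinct
    PBS loci (>= 80% at the default), widths 200-400 bp and strong scores;
    each decoy receives the same number of peaks placed uniformly with
    scores spanning weak to strong.
    """
    n_pbs = len(pbs_intervals)
    n_cover = math.ceil(cover_fraction * n_pbs)
    peaks: dict[str, list[Peak]] = {}
    covered: dict[str, list[int]] = {}

    rng = _rng(seed, 30_000)
    chosen = sorted(rng.choice(n_pbs, size=n_cover, replace=False).tolist()) if n_pbs else []
    binder_peaks = []
    for j, idx in enumerate(chosen):
        pbs = pbs_intervals[idx]
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        center = (pbs.start + pbs.end) // 2
        start = max(0, min(center - width // 2, genome_len - width))
        binder_peaks.append(
            Peak(
                chrom,
                start,
                start + width,
                f"{binder_id}_peak{j + 1}",
                float(rng.integers(binder_scores[0], binder_scores[1] + 1)),
                ".",
            )
        )
    peaks[binder_id] = binder_peaks
    covered[binder_id] = chosen

    for d, did in enumerate(decoy_ids):
        drng = _rng(seed, 30_001 + d)
        decoy_peaks = []
        for j in range(n_cover):
            width = int(drng.integers(width_range[0], width_range[1] + 1))
            start = int(drng.integers(0, max(1, genome_len - width)))
            decoy_peaks.append(
                Peak(
                    chrom,
                    start,
                    start + width,
                    f"{did}_peak{j + 1}",
                    float(drng.integers(decoy_scores[0], decoy_scores[1] + 1)),
                    ".",
                )
            )
        peaks[did] = decoy_peaks
        covered[did] = []
    return PeakSim(peaks=peaks, covered_pbs=covered, seed=seed)


# ---------------------------------------------------------------------------
# Ortholog tables


@dataclass
class OrthologSim:
    table: OrthologTable
    times: DivergenceTimes
    realized_ages: dict[str, float]
    seed: int


def simulate_ortholog_table(
    seed: int,
    gene_ages: Mapping[str, float],
    species_times: Mapping[str, float] | None = None,
    patchiness: float = 0.0,
    reference: str = DEFAULT_REFERENCE_SPECIES,
) -> OrthologSim:
    """Ortholog presence tables encoding planted gene ages.

    A gene has orthologs exactly in the species whose divergence time from
    the reference is <= its age; with ``patchiness`` > 0, species younger
    than the oldest ortholog are dropped independently with that
    probability (the oldest is always kept), exercising the reliability
    flag without changing the recoverable age. The realized age (the
    oldest retained species' time, 0 if none) is recorded as truth.
    """
    if species_times is None:
        species_times = DEFAULT_SPECIES_TIMES
    times = DivergenceTimes.from_reference(reference, species_times)
    orthologs: dict[str, frozenset[str]] = {}
    realized: dict[str, float] = {}
    for g, (gene, age) in enumerate(sorted(gene_ages.items())):
        rng = _rng(seed, 40_000 + g)
        within = sorted(
            (sp for sp, t in species_times.items() if t <= age),
            key=lambda sp: (species_times[sp], sp),
        )
        if within:
            oldest = max(within, key=lambda sp: (species_times[sp], sp))
            kept = {
                sp
                for sp in within
                if sp == oldest or rng.random() >= patchiness
            }
            realized[gene] = species_times[oldest]
        else:
            kept = set()
            realized[gene] = 0.0
        orthologs[gene] = frozenset(kept | {reference})
    return OrthologSim(
        table=OrthologTable(reference=reference, orthologs=orthologs),
        times=times,
        realized_ages=realized,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# One-call bundle + file emission


@dataclass
class SimBundle:
    """Everything one screen run needs, plus the planted ground truth."""

    genome_sim: GenomeSim
    panel: PanelSim
    peak_sim: PeakSim
    ortholog_sim: OrthologSim
    trnas: list[Sequence]
    seed: int

    def truth_json(self) -> str:
        g = self.genome_sim
        return json.dumps(
            {
                "seed": self.seed,
                "parameters": g.params,
                "ervs": [asdict(e) for e in g.ervs],
                "binder_id": self.panel.binder_id,
                "fingerprints": {
                    k: list(v) for k, v in self.panel.fingerprints.items()
                },
                "gene_ages_myr": self.ortholog_sim.realized_ages,
                "covered_pbs": self.peak_sim.covered_pbs,
            },
            indent=2,
            sort_keys=True,
        )


def simulate_all(
    seed: int,
    n_kzfps: int = 20,
    n_ervs: int = 8,
    genome_len: int = 150_000,
    binder_age_myr: float = 30.0,
    patchiness: float = 0.0,
    out_dir: str | Path | None = None,
) -> SimBundle:
    """Generate one coherent synthetic study: genome, panel, peaks, orthologs.

    The planted binder's gene age equals ``binder_age_myr`` (the ERV
    invasion epoch); decoy ages are drawn from the species ladder. With
    ``out_dir`` set, all standard input files are written there
    (genome.fa, trnas.fa, kzfps.fa, ervs.bed, ltrs.bed, pbs_truth.bed,
    peaks/<id>.bed, orthologs.tsv, divergence_times.tsv,
    recognition_code.tsv, truth.json).
    """
    genome_sim = simulate_genome(seed, n_ervs=n_ervs, genome_len=genome_len)
    panel = simulate_kzfp_panel(seed, n=n_kzfps)
    peak_sim = simulate_peaks(
        seed,
        binder_id=panel.binder_id,
        decoy_ids=[p.id for p in panel.proteins if p.id != panel.binder_id],
        pbs_intervals=genome_sim.pbs_truth,
        genome_len=genome_len,
    )
    age_rng = _rng(seed, 50_000)
    ladder = sorted(DEFAULT_SPECIES_TIMES.values())
    gene_ages = {
        p.id: binder_age_myr
        if p.id == panel.binder_id
        else float(age_rng.choice(ladder))
        for p in panel.proteins
    }
    ortholog_sim = simulate_ortholog_table(
        seed, gene_ages, patchiness=patchiness
    )
    bundle = SimBundle(
        genome_sim=genome_sim,
        panel=panel,
        peak_sim=peak_sim,
        ortholog_sim=ortholog_sim,
        trnas=default_trnas(),
        seed=seed,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: SimBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    g = bundle.genome_sim
    write_fasta([g.genome], out / "genome.fa")
    write_fasta(bundle.trnas, out / "trnas.fa")
    write_fasta(bundle.panel.proteins, out / "kzfps.fa")
    with open(out / "ervs.bed", "w") as fh:
        for e in g.ervs:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.erv_id}\t0\t+\n")
    with open(out / "ltrs.bed", "w") as fh:
        for e in g.ervs:
            fh.write(f"{e.chrom}\t{e.ltr5_start}\t{e.ltr5_end}\t{e.erv_id}_5p\t0\t+\n")
            fh.write(f"{e.chrom}\t{e.ltr3_start}\t{e.ltr3_end}\t{e.erv_id}_3p\t0\t+\n")
    write_bed(g.pbs_truth, out / "pbs_truth.bed")
    peak_dir = out / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for kzfp, peaks in bundle.peak_sim.peaks.items():
        write_bed(peaks, peak_dir / f"{kzfp}.bed")
    bundle.ortholog_sim.table.to_tsv(out / "orthologs.tsv")
    bundle.ortholog_sim.times.to_tsv(out / "divergence_times.tsv")
    bundle.panel.code.save_tsv(out / "recognition_code.tsv")
    (out / "truth.json").write_text(bundle.truth_json() + "\n")
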