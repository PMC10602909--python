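"""Orchestration of the two-arm KZFP/PBS screen.

Arm A covers KZFPs with ChIP peak data: strong peaks are filtered, their
overlaps with high-confidence PBS annotations counted, and the panel
ranked. Arm B covers KZFPs without peak data: candidates must (i) have a
gene age co-occurring with the ERV invasion-peak window and (ii) carry a
recognition-code-predicted motif matching the target PBS; their
fingerprint similarity to declared reference binders is reported
alongside, with arrays under 50% flagged as dissimilar. Every input KZFP
lands in exactly one arm, and the report is byte-identical across runs
with the same inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence as TypingSequence

import pandas as pd
import yaml

from .seq_core import Sequence, read_fasta
from .pbs_catalog import PBSMotif, scan_pbs, derive_pbs_from_trna, write_hits_bed
from .zinc_finger import (
    RecognitionCode,
    ZincFingerArray,
    find_c2h2,
    fingerprint_similarity,
    motif_vs_pbs,
    predict_motif,
)
from .ltr_dating import LTRPair, InvasionProfile, date_ltr_pairs, invasion_profile
from .kzfp_age import (
    DivergenceTimes,
    OrthologTable,
    cooccurrence_screen,
    estimate_ages,
)
from .peak_overlap import Peak, count_overlaps, filter_peaks, rank_binders, read_bed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenThresholds:
    """All screen cut-offs, logged with every run.

    ``pbs_min_score`` (strictly greater) keeps only high-confidence PBS
    annotations; ``strong_peak`` (strictly greater) is the strong-peak
    score filter; ``arm_a_min_overlaps`` is the minimum strong-peak/PBS
    overlap count for an arm-A candidate; ``fingerprint_sim_max`` flags
    arm-B fingerprints below it as dissimilar to the reference binders;
    ``motif_match_min`` is the minimum predicted-motif/PBS match fraction;
    ``cooccur_tolerance_myr`` widens the invasion-peak window.
    """

    pbs_min_score: float = 100.0
    strong_peak: float = 500.0
    arm_a_min_overlaps: int = 3
    fingerprint_sim_max: float = 50.0
    motif_match_min: float = 0.7
    cooccur_tolerance_myr: float = 10.0
    pbs_max_mismatch: int = 3


@dataclass
class ScreenInputs:
    """In-memory inputs for one screen run."""

    catalog: TypingSequence[PBSMotif]
    target_pbs_type: str = "Pro"
    genome: Sequence | None = None
    ltr_ends: TypingSequence[int] | None = None
    pbs_annotations: TypingSequence[Peak] | None = None
    ltr_pairs: TypingSequence[LTRPair] | None = None
    proteins: TypingSequence[Sequence] = ()
    peaks: Mapping[str, TypingSequence[Peak]] = field(default_factory=dict)
    ortholog_table: OrthologTable | None = None
    divergence_times: DivergenceTimes | None = None
    code: RecognitionCode | None = None
    reference_binders: TypingSequence[Sequence] = ()
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    seed: int = 0


@dataclass
class ScreenReport:
    pbs_annotations: list[Peak]
    no_targets: bool
    profile: InvasionProfile | None
    arm_a: pd.DataFrame
    arm_a_candidates: list[str]
    arm_b: pd.DataFrame
    arm_b_candidates: list[str]
    thresholds: ScreenThresholds
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "thresholds": self.thresholds.__dict__,
                "n_pbs_annotations": len(self.pbs_annotations),
                "no_targets": self.no_targets,
                "invasion_peak_window_myr": list(self.profile.peak_window)
                if self.profile
                else None,
                "arm_a_ranking": self.arm_a.to_dict(orient="records"),
                "arm_a_candidates": self.arm_a_candidates,
                "arm_b": self.arm_b.to_dict(orient="records"),
                "arm_b_candidates": self.arm_b_candidates,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        self.arm_a.to_csv(out / "armA_ranking.tsv", sep="\t", index=False)
        self.arm_b.to_csv(out / "armB_candidates.tsv", sep="\t", index=False)
        with open(out / "pbs_annotations.bed", "w") as fh:
            for p in self.pbs_annotations:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{int(p.score)}\t{p.strand}\n"
                )


def _annotate_pbs(inputs: ScreenInputs) -> list[Peak]:
    th = inputs.thresholds
    if inputs.pbs_annotations is not None:
        annotations = list(inputs.pbs_annotations)
    elif inputs.genome is not None:
        hits = scan_pbs(
            inputs.genome,
            inputs.catalog,
            max_mismatch=th.pbs_max_mismatch,
            ltr_ends=inputs.ltr_ends,
        )
        annotations = [
            Peak(inputs.genome.id, h.start, h.end, f"PBS-{h.trna_id}", h.score, h.strand)
            for h in hits
            if h.trna_id == inputs.target_pbs_type
        ]
    else:
        raise ValueError("screen needs either pbs_annotations or a genome to scan")
    kept = [p for p in annotations if p.score > th.pbs_min_score]
    logger.info(
        "PBS annotation: %d raw, %d above score %s",
        len(annotations),
        len(kept),
        th.pbs_min_score,
    )
    return kept


def run_screen(inputs: ScreenInputs) -> ScreenReport:
    """Run the full two-arm screen on in-memory inputs.

    KZFPs with a peak set go through arm A (strong-peak/PBS overlap
    ranking); the rest go through arm B (age co-occurrence + predicted
    motif + fingerprint-similarity report). Raising any threshold never
    grows a candidate set.
    """
    th = inputs.thresholds
    if not inputs.peaks and not inputs.proteins:
        raise ValueError("screen needs at least one of: peak sets, proteins")
    pbs = _annotate_pbs(inputs)
    no_targets = len(pbs) == 0
    if no_targets:
        logger.warning("no PBS targets survive the score filter")

    profile = None
    if inputs.ltr_pairs:
        ages = date_ltr_pairs(inputs.ltr_pairs)
        profile = invasion_profile(ages)
        logger.info("invasion peak window: %s Myr", profile.peak_window)

    proteins_by_id = {p.id: p for p in inputs.proteins}
    arm_a_ids = sorted(inputs.peaks)
    arm_b_ids = sorted(set(proteins_by_id) - set(arm_a_ids))

    # --- arm A: ChIP-based overlap ranking
    reports = []
    for kzfp in arm_a_ids:
        strong = filter_peaks(inputs.peaks[kzfp], th.strong_peak)
        reports.append(count_overlaps(strong, pbs, kzfp=kzfp))
    if reports:
        arm_a = rank_binders(reports)
        arm_a_candidates = sorted(
            arm_a.loc[
                arm_a["n_overlapping_peaks"] >= th.arm_a_min_overlaps, "kzfp"
            ].tolist()
        ) if not no_targets else []
    else:
        arm_a = pd.DataFrame(
            columns=["rank", "kzfp", "n_peaks", "n_overlapping_peaks", "mean_overlap_score"]
        )
        arm_a_candidates = []
    logger.info("arm A: %d KZFPs, %d candidates", len(arm_a_ids), len(arm_a_candidates))

    # --- arm B: evolutionary + predictive screen
    target = next(
        (m for m in inputs.catalog if m.trna_id == inputs.target_pbs_type), None
    )
    reference_arrays = [find_c2h2(p) for p in inputs.reference_binders]
    age_by_gene = {}
    cooccurring: set[str] = set()
    if inputs.ortholog_table is not None and inputs.divergence_times is not None:
        estimates = estimate_ages(inputs.ortholog_table, inputs.divergence_times)
        age_by_gene = {a.gene: a for a in estimates}
        if profile is not None:
            hits = cooccurrence_screen(
                [a for a in estimates if a.gene in set(arm_b_ids)],
                profile,
                th.cooccur_tolerance_myr,
            )
            cooccurring = {a.gene for a in hits}

    rows = []
    arm_b_candidates = []
    for kzfp in arm_b_ids:
        zfa = find_c2h2(proteins_by_id[kzfp])
        est = age_by_gene.get(kzfp)
        match_fraction = 0.0
        if target is not None and len(zfa) and inputs.code is not None:
            motif = predict_motif(zfa, inputs.code)
            match_fraction = motif_vs_pbs(motif, target).fraction
        ref_sims = {
            f"similarity_vs_{ra.protein_id}": (
                fingerprint_similarity(zfa, ra) if len(zfa) and len(ra) else 0.0
            )
            for ra in reference_arrays
        }
        cooccurs = kzfp in cooccurring
        is_candidate = (
            not no_targets and cooccurs and match_fraction >= th.motif_match_min
        )
        if is_candidate:
            arm_b_candidates.append(kzfp)
        rows.append(
            {
                "kzfp": kzfp,
                "n_fingers": len(zfa),
                "age_myr": est.age_myr if est else float("nan"),
                "age_reliability": est.reliability if est else "unknown",
                "cooccurs_with_invasion": cooccurs,
                "motif_match_fraction": match_fraction,
                "candidate": is_candidate,
                **ref_sims,
                **{
                    k.replace("similarity_vs_", "dissimilar_to_"): v
                    < th.fingerprint_sim_max
                    for k, v in ref_sims.items()
                },
            }
        )
    arm_b = pd.DataFrame(
        rows,
        columns=[
            "kzfp",
            "n_fingers",
            "age_myr",
            "age_reliability",
            "cooccurs_with_invasion",
            "motif_match_fraction",
            "candidate",
            *[f"similarity_vs_{ra.protein_id}" for ra in reference_arrays],
            *[f"dissimilar_to_{ra.protein_id}" for ra in reference_arrays],
        ]
        if not rows
        else None,
    )
    logger.info("arm B: %d KZFPs, %d candidates", len(arm_b_ids), len(arm_b_candidates))

    return ScreenReport(
        pbs_annotations=pbs,
        no_targets=no_targets,
        profile=profile,
        arm_a=arm_a,
        arm_a_candidates=arm_a_candidates,
        arm_b=arm_b,
        arm_b_candidates=sorted(arm_b_candidates),
        thresholds=th,
        seed=inputs.seed,
    )


# ---------------------------------------------------------------------------
# File-based configuration


@dataclass
class ScreenConfig:
    """Paths and thresholds mirroring the YAML screen configuration."""

    trna_fasta: str | None = None
    target_fasta: str | None = None
    pbs_bed: str | None = None
    ltr_bed: str | None = None
    protein_fasta: str | None = None
    peak_beds: dict[str, str] = field(default_factory=dict)
    ortholog_tsv: str | None = None
    divergence_tsv: str | None = None
    recognition_code_tsv: str | None = None
    reference_binder_fasta: str | None = None
    reference_species: str = "Homo_sapiens"
    target_pbs_type: str = "Pro"
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        th = ScreenThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=th, **raw)


def load_inputs(config: ScreenConfig) -> ScreenInputs:
    """Materialize ScreenInputs from the files a config points at."""
    if config.trna_fasta:
        catalog = [derive_pbs_from_trna(t) for t in read_fasta(config.trna_fasta, "dna")]
        catalog = [
            PBSMotif(m.trna_id.removeprefix("tRNA-"), m.consensus, m.source_trna)
            for m in catalog
        ]
    else:
        from .synthetic_data import default_catalog

        catalog = default_catalog()

    genome = None
    if config.target_fasta:
        genome = read_fasta(config.target_fasta, "dna")[0]
    pbs_annotations = read_bed(config.pbs_bed) if config.pbs_bed else None

    ltr_ends = None
    ltr_pairs = None
    if config.ltr_bed and genome is not None:
        ltr_intervals = read_bed(config.ltr_bed)
        by_erv: dict[str, dict[str, Peak]] = {}
        for iv in ltr_intervals:
            if iv.name.endswith(("_5p", "_3p")):
                by_erv.setdefault(iv.name[:-3], {})[iv.name[-2:]] = iv
        ltr_ends = [d["5p"].end for d in by_erv.values() if "5p" in d]
        ltr_pairs = [
            LTRPair(
                erv_id=erv,
                ltr5=Sequence(f"{erv}_5p", "dna", genome.residues[d["5p"].start : d["5p"].end]),
                ltr3=Sequence(f"{erv}_3p", "dna", genome.residues[d["3p"].start : d["3p"].end]),
            )
            for erv, d in sorted(by_erv.items())
            if "5p" in d and "3p" in d
        ]

    return ScreenInputs(
        catalog=catalog,
        target_pbs_type=config.target_pbs_type,
        genome=genome,
        ltr_ends=ltr_ends,
        pbs_annotations=pbs_annotations,
        ltr_pairs=ltr_pairs,
        proteins=read_fasta(config.protein_fasta, "protein")
        if config.protein_fasta
        else (),
        peaks={k: read_bed(v) for k, v in sorted(config.peak_beds.items())},
        ortholog_table=OrthologTable.from_tsv(config.ortholog_tsv, config.reference_species)
        if config.ortholog_tsv
        else None,
        divergence_times=DivergenceTimes.from_tsv(config.divergence_tsv)
        if config.divergence_tsv
        else None,
        code=RecognitionCode.load_tsv(config.recognition_code_tsv)
        if config.recognition_code_tsv
        else RecognitionCode.complete(),
        reference_binders=read_fasta(config.reference_binder_fasta, "protein")
        if config.reference_binder_fasta
        else (),
        thresholds=config.thresholds,
        seed=config.seed,
    )


def run_screen_config(config: ScreenConfig, out_dir: str | Path | None = None) -> ScreenReport:
    report = run_screen(load_inputs(config))
    if out_dir is not None:
        report.write(out_dir)
    return report
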