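"""KZFP gene ages from ortholog distributions, and co-occurrence screening.

A gene's age is the divergence time between the reference species and the
most distantly related species carrying an ortholog. Patchy ortholog
distributions (many species younger than the oldest ortholog lacking the
gene) make that maximum unreliable and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TypingSequence

import pandas as pd

from .ltr_dating import InvasionProfile


class MissingDivergenceTimeError(KeyError):
    pass


@dataclass(frozen=True)
class OrthologTable:
    """Per-gene sets of species with an ortholog, plus the reference species."""

    reference: str
    orthologs: Mapping[str, frozenset[str]]

    def species_for(self, gene: str) -> frozenset[str]:
        try:
            present = self.orthologs[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in ortholog table")
        # the reference species always carries its own genes
        return present | {self.reference}

    @property
    def genes(self) -> list[str]:
        return sorted(self.orthologs)

    @classmethod
    def from_tsv(cls, path: str | Path, reference: str) -> "OrthologTable":
        """Read a (gene, species[, present]) TSV; present defaults to 1."""
        df = pd.read_csv(path, sep="\t")
        if "present" in df.columns:
            df = df[df["present"].astype(int) == 1]
        table: dict[str, set[str]] = {}
        for gene, species in zip(df["gene"], df["species"]):
            table.setdefault(str(gene), set()).add(str(species))
        return cls(reference=reference, orthologs={g: frozenset(s) for g, s in table.items()})

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene": g, "species": sp, "present": 1}
            for g in sorted(self.orthologs)
            for sp in sorted(self.orthologs[g])
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DivergenceTimes:
    """Symmetric species-pair divergence times in Myr (zero on the diagonal)."""

    times: Mapping[frozenset, float]

    def time(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        try:
            return self.times[frozenset((a, b))]
        except KeyError:
            raise MissingDivergenceTimeError(
                f"no divergence time for species pair ({a!r}, {b!r})"
            )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "DivergenceTimes":
        return cls(times={frozenset((a, b)): float(t) for a, b, t in pairs})

    @classmethod
    def from_reference(
        cls, reference: str, to_reference: Mapping[str, float]
    ) -> "DivergenceTimes":
        """Star-shaped table: each species' divergence time to the reference."""
        return cls.from_pairs(
            (reference, sp, t) for sp, t in to_reference.items() if sp != reference
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DivergenceTimes":
        df = pd.read_csv(path, sep="\t")
        return cls.from_pairs(
            zip(df["species_a"], df["species_b"], df["myr"].astype(float))
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"species_a": a, "species_b": b, "myr": t}
            for pair, t in self.times.items()
            for a, b in [sorted(pair)]
        ]
        pd.DataFrame(sorted(rows, key=lambda r: (r["species_a"], r["species_b"]))).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class AgeEstimate:
    gene: str
    age_myr: float
    oldest_ortholog_species: str
    reliability: str  # "high" | "low"
    reference_only: bool = False


def estimate_age(
    gene: str,
    table: OrthologTable,
    times: DivergenceTimes,
    min_coverage: float = 0.5,
) -> AgeEstimate:
    """Age of a gene as the divergence time to its oldest ortholog.

    Reliability is "low" when fewer than ``min_coverage`` of the species
    younger than the oldest ortholog also carry the gene — a patchy
    distribution in which a single distant hit sets the age.
    """
    species = table.species_for(gene)
    ref = table.reference
    aged = sorted(
        ((times.time(ref, sp), sp) for sp in species), key=lambda x: (-x[0], x[1])
    )
    age, oldest = aged[0]
    if age == 0.0:
        return AgeEstimate(
            gene=gene,
            age_myr=0.0,
            oldest_ortholog_species=ref,
            reliability="high",
            reference_only=True,
        )
    # coverage among all known species strictly younger than the oldest hit
    all_species = {sp for pair in times.times for sp in pair} | {ref}
    younger = {
        sp for sp in all_species if sp != oldest and times.time(ref, sp) < age
    }
    if younger:
        covered = len(younger & species) / len(younger)
    else:
        covered = 1.0
    return AgeEstimate(
        gene=gene,
        age_myr=age,
        oldest_ortholog_species=oldest,
        reliability="high" if covered >= min_coverage else "low",
    )


def estimate_ages(
    table: OrthologTable, times: DivergenceTimes, min_coverage: float = 0.5
) -> list[AgeEstimate]:
    return [estimate_age(g, table, times, min_coverage) for g in table.genes]


def cooccurrence_screen(
    ages: TypingSequence[AgeEstimate],
    profile: InvasionProfile,
    tolerance_myr: float = 10.0,
) -> list[AgeEstimate]:
    """Genes whose age co-occurs with the ERV invasion-peak window.

    A gene is a candidate when its age lies within the peak window widened
    by ``tolerance_myr`` on both sides; candidates are sorted by distance
    from the window midpoint (ties by gene name).
    """
    lo, hi = profile.peak_window
    lo, hi = lo - tolerance_myr, hi + tolerance_myr
    mid = profile.midpoint
    hits = [a for a in ages if lo <= a.age_myr <= hi]
    return sorted(hits, key=lambda a: (abs(a.age_myr - mid), a.gene))


def ages_to_dataframe(ages: Iterable[AgeEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": a.gene,
                "age_myr": a.age_myr,
                "oldest_ortholog_species": a.oldest_ortholog_species,
                "reliability": a.reliability,
                "reference_only": a.reference_only,
            }
            for a in ages
        ]
    )
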