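import pytest

from pbscreen.kzfp_age import (
    AgeEstimate,
    DivergenceTimes,
    MissingDivergenceTimeError,
    OrthologTable,
    ages_to_dataframe,
    cooccurrence_screen,
    estimate_age,
    estimate_ages,
)
from pbscreen.ltr_dating import invasion_profile
from pbscreen import synthetic_data as syn

TOY_TIMES = {"chimp": 6.0, "macaque": 30.0, "mouse": 90.0, "opossum": 160.0, "chicken": 300.0}


def _table(**genes):
    return OrthologTable(
        reference="human", orthologs={g: frozenset(sp) for g, sp in genes.items()}
    )


@pytest.fixture()
def toy_times():
    return DivergenceTimes.from_reference("human", TOY_TIMES)


class TestEstimateAge:
    def test_reference_only_gene_has_age_zero(self, toy_times):
        est = estimate_age("g", _table(g=["human"]), toy_times)
        assert est.age_myr == 0.0 and est.reference_only

    def test_equals_exhaustive_max_over_divergence_times(self, toy_times):
        import itertools

        species = list(TOY_TIMES)
        for r in range(1, 4):
            for combo in itertools.combinations(species, r):
                est = estimate_age("g", _table(g=list(combo)), toy_times)
                assert est.age_myr == max(TOY_TIMES[s] for s in combo)
                assert est.oldest_ortholog_species == max(combo, key=TOY_TIMES.get)

    def test_missing_divergence_time_names_the_species(self, toy_times):
        with pytest.raises(MissingDivergenceTimeError, match="martian"):
            estimate_age("g", _table(g=["martian"]), toy_times)

    def test_order_invariance_and_monotonicity(self, toy_times):
        a = estimate_age("g", _table(g=["chimp", "macaque"]), toy_times)
        b = estimate_age("g", _table(g=["macaque", "chimp"]), toy_times)
        assert a == b
        wider = estimate_age("g", _table(g=["chimp", "macaque", "mouse"]), toy_times)
        assert wider.age_myr >= a.age_myr

    def test_patchy_distribution_flagged_low(self, toy_times):
        # oldest hit is chicken (300) but nothing between macaque and chicken
        est = estimate_age("g", _table(g=["chimp", "chicken"]), toy_times)
        assert est.age_myr == 300.0
        assert est.reliability == "low"
        dense = estimate_age(
            "g", _table(g=["chimp", "macaque", "mouse", "opossum", "chicken"]), toy_times
        )
        assert dense.reliability == "high"


class TestSimulatedRecovery:
    def test_planted_ages_recovered_exactly_at_zero_patchiness(self):
        ladder = sorted(syn.DEFAULT_SPECIES_TIMES.values())
        gene_ages = {f"g{i}": age for i, age in enumerate(ladder)}
        for seed in (1, 2, 3):
            sim = syn.simulate_ortholog_table(seed, gene_ages, patchiness=0.0)
            for est in estimate_ages(sim.table, sim.times):
                assert est.age_myr == sim.realized_ages[est.gene]
                assert est.reliability == "high"

    def test_patchiness_fires_reliability_flags(self):
        gene_ages = {f"g{i}": 300.0 for i in range(12)}
        sim = syn.simulate_ortholog_table(5, gene_ages, patchiness=0.6)
        ests = estimate_ages(sim.table, sim.times)
        # ages still exact (the oldest ortholog is always retained) ...
        assert all(e.age_myr == 300.0 for e in ests)
        # ... but patchy distributions now trip the flag, and each flag
        # agrees with an independent coverage computation
        n_low = 0
        for e in ests:
            species = sim.table.species_for(e.gene)
            younger = {
                sp
                for sp, t in syn.DEFAULT_SPECIES_TIMES.items()
                if t < 300.0
            } | {"Homo_sapiens"}
            younger -= {"Gallus_gallus"}
            coverage = len(younger & species) / len(younger)
            assert (e.reliability == "low") == (coverage < 0.5)
            n_low += e.reliability == "low"
        assert n_low >= 1

    def test_single_species_tree_gives_age_zero(self):
        sim = syn.simulate_ortholog_table(1, {"g": 50.0}, species_times={})
        est = estimate_age("g", sim.table, sim.times)
        assert est.age_myr == 0.0


class TestCooccurrence:
    @pytest.fixture()
    def profile(self):
        return invasion_profile([29.0, 30.0, 31.0, 32.0])  # peak window [25,35)

    def _est(self, gene, age):
        return AgeEstimate(gene, age, "sp", "high")

    def test_midpoint_age_ranks_first(self, profile):
        ages = [self._est("far", 40.0), self._est("mid", profile.midpoint)]
        hits = cooccurrence_screen(ages, profile, tolerance_myr=10)
        assert hits[0].gene == "mid"

    def test_outside_window_plus_tolerance_excluded(self, profile):
        ages = [self._est("old", 300.0), self._est("in", 30.0)]
        hits = cooccurrence_screen(ages, profile, tolerance_myr=10)
        assert [h.gene for h in hits] == ["in"]

    def test_monotone_in_tolerance(self, profile):
        ages = [self._est(f"g{a}", float(a)) for a in range(0, 100, 5)]
        small = {h.gene for h in cooccurrence_screen(ages, profile, 5)}
        large = {h.gene for h in cooccurrence_screen(ages, profile, 20)}
        assert small <= large

    def test_planted_cooccurring_genes_recovered_exactly(self, profile):
        planted = {"a": 30.0, "b": 28.0, "c": 33.0}
        decoys = {f"d{i}": age for i, age in enumerate([0.0, 6.0, 90.0, 160.0, 300.0] * 4)}
        ages = [self._est(g, t) for g, t in {**planted, **decoys}.items()]
        hits = cooccurrence_screen(ages, profile, tolerance_myr=10)
        assert {h.gene for h in hits} == set(planted)


def test_tsv_round_trips(tmp_path):
    sim = syn.simulate_ortholog_table(2, {"g1": 30.0, "g2": 90.0})
    table_path, times_path = tmp_path / "orth.tsv", tmp_path / "times.tsv"
    sim.table.to_tsv(table_path)
    sim.times.to_tsv(times_path)
    table = OrthologTable.from_tsv(table_path, reference=sim.table.reference)
    times = DivergenceTimes.from_tsv(times_path)
    assert table.orthologs == dict(sim.table.orthologs)
    got = ages_to_dataframe(estimate_ages(table, times))
    assert got.set_index("gene")["age_myr"].to_dict() == sim.realized_ages
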