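"""Tests of the synthetic-data generator: MSC calibration against the
closed-form discordance probability and an independent coalescent simulator
(msprime), Jukes–Cantor mutation expectations, introgression surgery,
inversion labelling and byte-level determinism."""

import numpy as np
import pytest

from treescan.mafio import write_maf
from treescan.scan import canonicalize
from treescan.simulate import (
    IntrogressionEvent,
    InversionRegion,
    SimulationConfig,
    SpeciesTree,
    default_species_newick,
    demo_config,
    inversion_override_newick,
    mutate_and_emit,
    sample_msc_genealogy,
    sample_window_genealogy,
    simulate_maf,
)
from treescan.tree import Clade, patristic_distance


def quartet_tree(t1=20_000.0, dt=15_000.0, og=200_000.0):
    t2 = t1 + dt
    return f"(((A:{t1},B:{t1}):{dt},C:{t2}):{og - t2},O:{og});"


class TestGenealogySampling:
    def test_forced_replacement_pairs_recipient_with_donor(self):
        # probability 1.0 with tiny Ne: recipient's nearest neighbour is donor
        cfg = demo_config(
            seed=1,
            ne=10.0,
            chrom_lengths={"2L": 100_000},
            introgression_events=[
                IntrogressionEvent(
                    "gambiae", "fontenillei", "2L", 0, 100_000, 1000.0, 1.0
                )
            ],
            inversion_regions=[],
        )
        rng = np.random.default_rng(0)
        for _ in range(10):
            g, label = sample_window_genealogy(cfg, "2L", 0, 50_000, rng)
            assert label == "introgressed"
            d = patristic_distance(g, "fontenillei", "gambiae")
            for other in g.leaf_names():
                if other not in ("fontenillei", "gambiae"):
                    assert patristic_distance(g, "fontenillei", other) > d

    def test_zero_ils_limit_recovers_species_topology(self):
        cfg = demo_config(seed=2, ne=1.0, chrom_lengths={"2L": 100_000},
                          introgression_events=[], inversion_regions=[])
        sp_topo = canonicalize(Clade.from_newick(default_species_newick()))
        rng = np.random.default_rng(3)
        for _ in range(5):
            g, label = sample_window_genealogy(cfg, "2L", 0, 50_000, rng)
            assert label == "species"
            assert canonicalize(g) == sp_topo

    def test_interval_outside_chromosome_raises(self):
        cfg = demo_config(seed=0, chrom_lengths={"2L": 100_000},
                          introgression_events=[], inversion_regions=[])
        with pytest.raises(ValueError):
            sample_window_genealogy(
                cfg, "2L", 90_000, 160_000, np.random.default_rng(0)
            )

    def test_discordance_matches_closed_form(self):
        ne, dt = 10_000.0, 15_000.0
        sp = SpeciesTree.from_newick(quartet_tree(dt=dt), ne=ne)
        rng = np.random.default_rng(42)
        n = 2000
        disc = sum(
            canonicalize(sample_msc_genealogy(sp, rng), "O") != "((A,B),C)"
            for _ in range(n)
        )
        expected = (2.0 / 3.0) * np.exp(-dt / ne)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(disc / n - expected) < 3 * se

    def test_discordance_matches_msprime(self):
        msprime = pytest.importorskip("msprime")
        ne, t1, dt, og = 10_000.0, 20_000.0, 15_000.0, 200_000.0
        sp = SpeciesTree.from_newick(quartet_tree(t1, dt, og), ne=ne)
        rng = np.random.default_rng(7)
        n = 1500
        ours = (
            sum(
                canonicalize(sample_msc_genealogy(sp, rng), "O") != "((A,B),C)"
                for _ in range(n)
            )
            / n
        )
        dem = msprime.Demography()
        for pop in ("A", "B", "C", "O", "AB", "ABC", "R"):
            dem.add_population(name=pop, initial_size=ne)  # haploid copies at ploidy 1
        dem.add_population_split(time=t1, derived=["A", "B"], ancestral="AB")
        dem.add_population_split(time=t1 + dt, derived=["AB", "C"], ancestral="ABC")
        dem.add_population_split(time=og, derived=["ABC", "O"], ancestral="R")
        disc = 0
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1, "O": 1},
            demography=dem,
            ploidy=1,
            num_replicates=n,
            random_seed=99,
        )
        for ts in reps:
            tree = ts.first()
            mrca_ab = tree.mrca(0, 1)
            disc += int(tree.mrca(0, 2) == mrca_ab or tree.mrca(1, 2) == mrca_ab)
        se = np.sqrt(ours * (1 - ours) / n)
        assert abs(ours - disc / n) < 3 * np.sqrt(2) * se

    def test_species_topology_frequency_monotone_in_branch_length(self):
        ne = 10_000.0
        rng = np.random.default_rng(9)
        freqs = []
        for dt in (2_000.0, 8_000.0, 30_000.0):
            sp = SpeciesTree.from_newick(quartet_tree(dt=dt), ne=ne)
            n = 600
            ok = sum(
                canonicalize(sample_msc_genealogy(sp, rng), "O") == "((A,B),C)"
                for _ in range(n)
            )
            freqs.append(ok / n)
        assert freqs[0] < freqs[1] < freqs[2]


class TestMutation:
    def test_zero_rate_identical_sequences(self):
        g = Clade.from_newick("((A:1e6,B:1e6):1e5,C:1.1e6);")
        seqs = mutate_and_emit(g, 500, 0.0, np.random.default_rng(0))
        assert seqs["A"] == seqs["B"] == seqs["C"]

    def test_pairwise_divergence_matches_binomial_expectation(self):
        t, mu, L = 1e6, 1.1e-9, 50_000
        g = Clade.from_newick(f"(A:{t},B:{t});")
        rng = np.random.default_rng(4)
        p_exp = 0.75 * (1 - np.exp(-4 * mu * 2 * t / 3))  # ~ 2*t*mu for small mu*t
        diffs = []
        for _ in range(5):
            seqs = mutate_and_emit(g, L, mu, rng)
            a = np.frombuffer(seqs["A"].encode(), dtype="S1")
            b = np.frombuffer(seqs["B"].encode(), dtype="S1")
            diffs.append(float((a != b).mean()))
        se = np.sqrt(p_exp * (1 - p_exp) / (L * len(diffs)))
        assert abs(np.mean(diffs) - p_exp) < 3 * se
        assert abs(np.mean(diffs) - 2 * t * mu) < 3 * se + 1e-5

    def test_full_missingness_leaves_no_determined_column(self):
        g = Clade.from_newick("(A:10,B:10);")
        seqs = mutate_and_emit(
            g, 200, 1e-9, np.random.default_rng(1), missing_data_rate=1.0
        )
        assert set(seqs["A"]) == {"N"} and set(seqs["B"]) == {"N"}


class TestSimulateMaf:
    def test_block_count_matches_windows(self):
        cfg = demo_config(seed=0, chrom_lengths={"2L": 100_000},
                          window_size=50_000,
                          introgression_events=[], inversion_regions=[])
        blocks, truth = simulate_maf(cfg)
        assert len(blocks) == 2
        starts = [b.reference.start for b in blocks]
        assert starts == [0, 50_000]
        assert all(b.rows[0].src.startswith("gambiae.") for b in blocks)

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = demo_config(seed=33, chrom_lengths={"2L": 150_000},
                          window_size=50_000,
                          introgression_events=[], inversion_regions=[])
        paths = []
        for name in ("a.maf", "b.maf"):
            blocks, _ = simulate_maf(cfg)
            write_maf(blocks, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_inversion_windows_labelled_by_configured_fraction(self):
        # inversion covers 20% of a 1 Mb chromosome -> 4 of 20 windows
        cfg = demo_config(
            seed=5,
            chrom_lengths={"3L": 1_000_000},
            window_size=50_000,
            introgression_events=[],
            inversion_regions=[
                InversionRegion("3L", 400_000, 600_000, inversion_override_newick())
            ],
        )
        _, truth = simulate_maf(cfg)
        labels = truth.labels_for("3L")
        assert labels.count("inversion") == 4
        assert len(labels) == 20

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                species_newick=default_species_newick(),
                chrom_lengths={"2L": 100_000},
                reference="gambiae",
                outgroup="christyi",
                mu=-1.0,
            )
        with pytest.raises(ValueError):
            demo_config(
                introgression_events=[
                    IntrogressionEvent(
                        "gambiae", "fontenillei", "2L", 0, 99_000_000, 1.0, 1.0
                    )
                ]
            )
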