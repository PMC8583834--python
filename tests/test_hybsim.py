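"""Network-coalescent simulator: sorting modes, coalescent correctness,
sequence evolution, bundle reproducibility."""

import math

import numpy as np
import pytest

from phylodup import hybsim as hs, treekit as tk

NET = hs.SpeciesNetwork()
INGROUP = set("ABCDE")


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestAssignParentalOrigin:
    def test_single_parent_with_gamma_one_always_parent_one(self):
        net = hs.SpeciesNetwork(gamma=1.0)
        rng = _rng()
        for _ in range(50):
            o = hs.assign_parental_origin(net, "single_parent", rng)
            assert set(o.values()) == {1}

    def test_congruent_sorting_splits_flower_clades(self):
        rng = _rng(1)
        for _ in range(50):
            o = hs.assign_parental_origin(NET, "congruent_sorting", rng)
            assert len({o[s] for s in hs.MULTIFLOWERED}) == 1
            assert len({o[s] for s in hs.SINGLEFLOWERED}) == 1
            assert o["A"] != o["D"]

    def test_random_sorting_per_section_frequency(self):
        rng = _rng(2)
        n = 10_000
        count = {s: 0 for s in INGROUP}
        for _ in range(n):
            o = hs.assign_parental_origin(NET, "random_sorting", rng)
            for s in INGROUP:
                count[s] += o[s] == 1
        se = math.sqrt(0.25 / n)
        for s in INGROUP:
            assert abs(count[s] / n - 0.5) < 3 * se

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            hs.assign_parental_origin(NET, "weird", _rng())


class TestZeroILSLimit:
    params = hs.SimulationParams(N_e=0.0, seed=0)

    def test_single_parent_tree_equals_species_tree(self):
        for parent in (1, 2):
            t = hs.simulate_gene_tree(
                NET, {s: parent for s in INGROUP}, self.params, _rng()
            )
            assert tk.rf_distance(t, NET.species_tree()) == 0
            assert tk.tmrca(t, INGROUP) == pytest.approx(
                NET.radiation_ages["ABCDE"]
            )

    def test_two_parent_locus_coalesces_at_proto_split(self):
        origins = {"A": 1, "B": 1, "C": 2, "D": 1, "E": 2}
        t = hs.simulate_gene_tree(NET, origins, self.params, _rng())
        assert tk.tmrca(t, INGROUP) == pytest.approx(NET.proto_split_age)
        # sections sharing a parent coalesce along the species-tree path
        assert tk.tmrca(t, {"A", "B"}) == pytest.approx(
            NET.radiation_ages["AB"]
        )

    def test_congruent_sorting_keeps_species_topology_with_deeper_root(self):
        origins = hs.assign_parental_origin(
            hs.SpeciesNetwork(gamma=1.0), "congruent_sorting", _rng()
        )
        t = hs.simulate_gene_tree(NET, origins, self.params, _rng())
        assert tk.rf_distance(t, NET.species_tree()) == 0
        assert tk.tmrca(t, INGROUP) == pytest.approx(NET.proto_split_age)


class TestCoalescentMachinery:
    def test_three_lineage_within_branch_coalescence_matches_closed_form(self):
        # P(3 lineages -> 1 within t coalescent units)
        #   = 1 - 1.5 e^{-t} + 0.5 e^{-3t}
        t_len = 1.2
        want = 1 - 1.5 * math.exp(-t_len) + 0.5 * math.exp(-3 * t_len)
        rng = _rng(3)
        reps = 4000
        hits = 0
        for i in range(reps):
            lins = [hs._Lineage(str(k), 0.0, None, k) for k in range(3)]
            out = hs._coalesce_in_pop(lins, 0.0, t_len, 1.0, False, rng)
            hits += len(out) == 1
        se = math.sqrt(want * (1 - want) / reps)
        assert abs(hits / reps - want) < 3 * se

    def test_gene_trees_are_ultrametric_and_bounded_by_history(self):
        params = hs.SimulationParams(seed=1)
        rng = _rng(4)
        for mode in hs.SORTING_MODES:
            for _ in range(20):
                o = hs.assign_parental_origin(NET, mode, rng)
                t = hs.simulate_gene_tree(NET, o, params, rng)
                ages = tk.node_ages(t, rtol=1e-6)  # raises if not ultrametric
                # every coalescence predates the start of the history,
                # but never the root population by an implausible margin
                assert max(ages.values()) >= NET.root_age

    def test_mean_tmrca_matches_msprime_on_fixed_routing(self):
        # Cross-check against an independent coalescent implementation:
        # a single-parent locus reduces to the plain multispecies
        # coalescent on the dated species tree.
        import msprime

        params = hs.SimulationParams(seed=1)
        cu_gens = params.N_e  # haploid lineages
        myr = 1e6 / params.generation_time

        dem = msprime.Demography()
        # ploidy-1 simulation: pair coalescence rate 1/N per generation
        for pop in ["A", "B", "C", "D", "E", "F", "G", "AB", "ABC", "DE",
                    "HYB", "ANC", "ROOT"]:
            dem.add_population(name=pop, initial_size=cu_gens)
        r = NET.radiation_ages
        dem.add_population_split(time=r["AB"] * myr, derived=["A", "B"], ancestral="AB")
        dem.add_population_split(time=r["ABC"] * myr, derived=["AB", "C"], ancestral="ABC")
        dem.add_population_split(time=r["DE"] * myr, derived=["D", "E"], ancestral="DE")
        dem.add_population_split(time=r["ABCDE"] * myr, derived=["ABC", "DE"], ancestral="HYB")
        dem.add_population_split(time=NET.proto_split_age * myr,
                                 derived=["HYB", "F"], ancestral="ANC")
        dem.add_population_split(time=NET.root_age * myr,
                                 derived=["ANC", "G"], ancestral="ROOT")
        dem.sort_events()
        samples = {p: 1 for p in "ABCDEFG"}
        reps = 400
        ms_tmrcas = []
        for ts in msprime.sim_ancestry(
            samples=samples, demography=dem, ploidy=1, num_replicates=reps,
            random_seed=7,
        ):
            tree = ts.first()
            node = tree.mrca(*range(5))  # the five ingroup samples
            ms_tmrcas.append(tree.time(node) / myr)

        rng = _rng(5)
        own = []
        for _ in range(reps):
            t = hs.simulate_gene_tree(
                NET, {s: 1 for s in INGROUP}, params, rng
            )
            own.append(tk.tmrca(t, INGROUP))
        se = math.sqrt(
            np.var(own) / reps + np.var(ms_tmrcas) / reps
        )
        assert abs(np.mean(own) - np.mean(ms_tmrcas)) < 3 * se


class TestSimulateSequences:
    def test_zero_rate_copies_root_everywhere(self):
        t = NET.species_tree()
        params = hs.SimulationParams(clock_rate=1e-12, seq_length=50, seed=0)
        aln = hs.simulate_sequences(t, params, _rng(0))
        rows = set(aln.rows.values())
        assert len(rows) == 1

    def test_jc_saturation_approaches_quarter_identity(self):
        t = tk.parse_newick("(A:1,B:1);")
        params = hs.SimulationParams(clock_rate=50.0, seq_length=20_000, seed=0)
        aln = hs.simulate_sequences(t, params, _rng(1))
        a, b = aln.rows["A"], aln.rows["B"]
        ident = sum(x == y for x, y in zip(a, b)) / len(a)
        se = math.sqrt(0.25 * 0.75 / len(a))
        assert abs(ident - 0.25) < 4 * se

    def test_p_distance_matches_jc_expectation(self):
        depth, rate, L = 5.0, 0.01, 10_000
        t = tk.parse_newick(f"(A:{depth},B:{depth});")
        params = hs.SimulationParams(clock_rate=rate, seq_length=L, seed=0)
        aln = hs.simulate_sequences(t, params, _rng(2))
        d_true = 2 * depth * rate
        p_expect = 0.75 * (1 - math.exp(-4.0 / 3.0 * d_true))
        p_obs = sum(
            x != y for x, y in zip(aln.rows["A"], aln.rows["B"])
        ) / L
        se = math.sqrt(p_expect * (1 - p_expect) / L)
        assert abs(p_obs - p_expect) < 3 * se

    def test_hky_model_runs_and_differs_from_jc(self):
        t = tk.parse_newick("(A:2,B:2);")
        params = hs.SimulationParams(
            subst_model="HKY85", kappa=8.0, clock_rate=0.05,
            seq_length=4000, seed=0,
        )
        aln = hs.simulate_sequences(t, params, _rng(3))
        assert set("".join(aln.rows.values())) <= set("ACGT")


class TestStudyBundle:
    def test_default_panel_composition(self):
        bundle = hs.make_study_bundle(params=hs.SimulationParams(seed=9))
        modes = [m.mode for m in bundle.markers.values()]
        assert modes.count("single_parent") == 3
        assert modes.count("random_sorting") == 3
        assert modes.count("congruent_sorting") == 1

    def test_bit_identical_rerun_from_seed(self):
        p = hs.SimulationParams(seed=123)
        b1 = hs.make_study_bundle(params=p)
        b2 = hs.make_study_bundle(params=p)
        for name in b1.markers:
            assert b1.markers[name].alignment.rows == b2.markers[name].alignment.rows
            assert tk.write_newick(b1.markers[name].gene_tree) == tk.write_newick(
                b2.markers[name].gene_tree
            )

    def test_replay_from_manifest_alone(self):
        b1 = hs.make_study_bundle(params=hs.SimulationParams(seed=5, N_e=2e4))
        b2 = hs.bundle_from_manifest(b1.manifest())
        for name in b1.markers:
            assert b1.markers[name].origins == b2.markers[name].origins
            assert b1.markers[name].alignment.rows == b2.markers[name].alignment.rows

    def test_written_bundle_layout(self, tmp_path):
        bundle = hs.make_study_bundle(params=hs.SimulationParams(seed=2))
        hs.write_bundle(bundle, tmp_path)
        assert (tmp_path / "manifest.yaml").exists()
        assert (tmp_path / "origins.tsv").exists()
        for name in bundle.markers:
            assert (tmp_path / f"{name}.fasta").exists()
            assert (tmp_path / f"{name}.nwk").exists()
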