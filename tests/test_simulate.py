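"""Coalescent genealogies, sequence evolution, ascertained sampling."""

import numpy as np
import pytest

from mitoclock import (
    MutationClass,
    count_synonymous_sites,
    distance_profile,
    draw_sample,
    evolve_sequences,
    make_fixture,
    pseudo_haplogroup_split,
    simulate_genealogy,
    single_gene_annotation,
    variance_rank_sites,
)
from mitoclock.simulate import (
    Grouping,
    SimScenario,
    simulate_scenario,
    tmrca_generations,
)


class TestGenealogy:
    def test_two_samples_single_coalescence(self):
        sc = SimScenario(n_sequences=2, growth_rate=0.0)
        tree = simulate_genealogy(sc)
        assert len(tree.tips) == 2
        assert tmrca_generations(tree) > 0

    def test_mean_tmrca_matches_analytic_oracle(self):
        # constant size: E[TMRCA] = 2*Ne*(1 - 1/n) generations
        n, ne, reps = 10, 200, 300
        tm = [
            tmrca_generations(
                simulate_genealogy(
                    SimScenario(n_sequences=n, growth_rate=0.0,
                                effective_pop_size=ne, seed=s)
                )
            )
            for s in range(reps)
        ]
        expected = 2 * ne * (1 - 1 / n)
        assert np.mean(tm) == pytest.approx(expected, rel=0.10)

    def test_growth_shrinks_tmrca(self):
        base = [
            tmrca_generations(
                simulate_genealogy(
                    SimScenario(n_sequences=10, growth_rate=0.0,
                                effective_pop_size=200, seed=s)
                )
            )
            for s in range(100)
        ]
        grown = [
            tmrca_generations(
                simulate_genealogy(
                    SimScenario(n_sequences=10, growth_rate=5e-3,
                                effective_pop_size=200, seed=s)
                )
            )
            for s in range(100)
        ]
        assert np.mean(grown) < np.mean(base)

    def test_seeded_determinism(self):
        a = simulate_genealogy(SimScenario(n_sequences=20, seed=7))
        b = simulate_genealogy(SimScenario(n_sequences=20, seed=7))
        assert a.to_newick() == b.to_newick()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            simulate_genealogy(SimScenario(n_sequences=1))


class TestEvolution:
    def test_omega_zero_no_nonsynonymous_events(self):
        sc = SimScenario(n_sequences=20, seq_length=600,
                         omega_map={"default": 0.0}, seed=3)
        tree = simulate_genealogy(sc)
        res = evolve_sequences(tree, sc)
        assert all(
            e.mutation_class is MutationClass.SYNONYMOUS for e in res.events
        )
        assert len(res.events) > 0

    def test_neutral_realized_ratio_tracks_site_ratio(self):
        # omega=1: accepted N/S events track the Nei-Gojobori site ratio of
        # the root sequence (law of large numbers over ~1e4 events)
        sc = SimScenario(n_sequences=100, seq_length=3000,
                         mutation_rate=4e-4, seed=5)
        tree = simulate_genealogy(sc)
        res = evolve_sequences(tree, sc)
        assert len(res.events) > 5000
        n = sum(e.mutation_class is not MutationClass.SYNONYMOUS for e in res.events)
        s = len(res.events) - n
        sites = count_synonymous_sites(
            single_gene_annotation(3000), res.node_sequences[res.tree.root.node_id]
        )
        # stop-creating candidates are redrawn, trimming the nonsynonymous
        # share slightly below the raw site fraction
        assert n / s == pytest.approx(sites.nonsynonymous / sites.synonymous, rel=0.1)

    def test_rate_multiplier_halves_clade_distances(self):
        result = simulate_scenario("r0_slow", seed=2)
        tree = result.tree
        slow_tips = {t.node_id for t in tree.tips_below(tree.clade_node("SLOW"))}
        prof = distance_profile(tree, tree.root.node_id, "all")
        slow = np.mean([c for t, c in prof.counts.items() if t in slow_tips])
        rest = np.mean([c for t, c in prof.counts.items() if t not in slow_tips])
        assert slow == pytest.approx(rest / 2, rel=0.25)

    def test_event_log_matches_tree_paths(self):
        sc = SimScenario(n_sequences=50, seq_length=900, seed=13)
        tree = simulate_genealogy(sc)
        res = evolve_sequences(tree, sc)
        prof = distance_profile(res.tree, res.tree.root.node_id, "all")
        per_branch = {}
        for e in res.events:
            per_branch[e.branch] = per_branch.get(e.branch, 0) + 1
        for tip in res.tree.tips:
            path = res.tree.path_to_ancestor(tip, res.tree.root)
            assert prof.counts[tip.node_id] == sum(
                per_branch.get(n.node_id, 0) for n in path
            )

    def test_no_stop_codons_in_tip_sequences(self):
        from mitoclock import translate_codon

        sc = SimScenario(n_sequences=20, seq_length=300, mutation_rate=5e-4, seed=1)
        tree = simulate_genealogy(sc)
        res = evolve_sequences(tree, sc)
        for seq in res.tip_sequences.values():
            aas = [translate_codon(seq[i:i + 3]) for i in range(0, 300, 3)]
            assert "*" not in aas


class TestVarianceRanking:
    def test_fifty_fifty_site_ranked_first(self):
        aln = {f"s{i}": ("A" if i < 5 else "C") + "GGGG" for i in range(10)}
        ranked = variance_rank_sites(aln)
        assert ranked[0][0] == 1

    def test_matches_brute_force_scores(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("AC"), size=12)) for i in range(30)
        }
        ranked = dict(variance_rank_sites(seqs))
        for pos, score in ranked.items():
            col = [seqs[k][pos - 1] for k in seqs]
            p = np.array([col.count(b) for b in set(col)]) / len(col)
            assert score == pytest.approx(1 - np.sum(p**2))

    def test_order_permutation_invariant(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=8)) for i in range(20)}
        r1 = variance_rank_sites(seqs)
        items = list(seqs.items())
        rng.shuffle(items)
        r2 = variance_rank_sites(dict(items))
        assert r1 == r2

    def test_monomorphic_alignment_empty(self):
        assert variance_rank_sites({"a": "AAAA", "b": "AAAA"}) == []


class TestPseudoHaplogroups:
    def test_three_perfect_splits_give_eight_groups(self):
        # 160 sequences, 3 independent 50/50 biallelic sites -> 8 groups of 20
        ids = range(160)
        aln = {}
        for i in ids:
            bits = [(i >> k) & 1 for k in range(3)]
            aln[f"s{i}"] = "".join("A" if b else "C" for b in bits) + "GG"
        grouping = pseudo_haplogroup_split(aln, min_groups=5, min_size=20)
        assert grouping.ok
        assert len(grouping.groups) == 8
        assert all(len(m) == 20 for m in grouping.groups.values())

    def test_unreachable_criterion_flagged(self):
        aln = {f"s{i}": ("A" if i < 5 else "C") * 4 for i in range(10)}
        grouping = pseudo_haplogroup_split(aln, min_groups=5, min_size=20)
        assert not grouping.ok

    def test_deterministic(self):
        aln = {f"s{i}": ("AC" if i % 2 else "GT") + "AA" for i in range(40)}
        g1 = pseudo_haplogroup_split(aln)
        g2 = pseudo_haplogroup_split(aln)
        assert g1.assignments == g2.assignments and g1.sites_used == g2.sites_used


class TestDrawSample:
    def _grouping(self, sizes):
        assignments = {}
        i = 0
        for g, size in sizes.items():
            for _ in range(size):
                assignments[f"s{i}"] = g
                i += 1
        return Grouping(assignments, [1], ok=True)

    def test_equal_groups_uniform_allocation(self):
        g = self._grouping({"a": 50, "b": 50})
        sample = draw_sample(g, "ascertained", 40, seed=0)
        by_group = {k: sum(g.assignments[s] == k for s in sample) for k in "ab"}
        assert by_group == {"a": 20, "b": 20}

    def test_allocation_sums_to_requested_size(self):
        g = self._grouping({"a": 37, "b": 91, "c": 22, "d": 50})
        for size in (10, 40, 77):
            assert len(draw_sample(g, "ascertained", size, seed=1)) == size

    def test_allocation_proportions_match_frequencies(self):
        g = self._grouping({"a": 300, "b": 100, "c": 100})
        sample = draw_sample(g, "ascertained", 50, seed=2)
        counts = {k: sum(g.assignments[s] == k for s in sample) for k in "abc"}
        assert counts == {"a": 30, "b": 10, "c": 10}

    def test_random_design_uniform(self):
        g = self._grouping({"a": 10, "b": 10})
        sample = draw_sample(g, "random", 5, seed=3)
        assert len(sample) == len(set(sample)) == 5

    def test_oversized_sample_rejected(self):
        g = self._grouping({"a": 4})
        with pytest.raises(ValueError):
            draw_sample(g, "random", 5)


class TestFixtures:
    def test_unknown_scenario_lists_registry(self, tmp_path):
        with pytest.raises(ValueError, match="recodon_default"):
            make_fixture("nope", tmp_path)

    def test_bundle_byte_identical_under_seed(self, tmp_path):
        sc = dict(n_sequences=40, seq_length=600)
        p1 = make_fixture("recodon_default", tmp_path / "a", seed=4)
        p2 = make_fixture("recodon_default", tmp_path / "b", seed=4)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_truth_log_matches_emitted_tree(self, tmp_path):
        paths = make_fixture("recodon_default", tmp_path, seed=6)
        import pandas as pd

        from mitoclock import read_tree_tsv

        tree = read_tree_tsv(paths["branches"])
        truth = pd.read_csv(paths["truth"], sep="\t")
        per_branch = truth.groupby("branch").size().to_dict()
        prof = distance_profile(tree, tree.root.node_id, "all")
        for tip in tree.tips[:20]:
            path = tree.path_to_ancestor(tip, tree.root)
            assert prof.counts[tip.node_id] == sum(
                per_branch.get(n.node_id, 0) for n in path
            )

    def test_j_selection_writes_archetypes(self, tmp_path):
        paths = make_fixture("j_selection", tmp_path, seed=2)
        import pandas as pd

        arch = pd.read_csv(paths["archetypes"], sep="\t")
        assert len(arch) <= 6
        assert {"branch", "position", "archetype"} <= set(arch.columns)
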