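"""Gene-loss statistics: reclassification, loss-branch inference, category
counting, contingency tests, and both Monte-Carlo simulations."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from chemomine.lossstats import (
    GeneEvidence,
    Phylo,
    contingency_tests,
    count_losses_by_category,
    infer_loss_branches,
    reclassify_gene_status,
    simulate_random_losses,
    simulate_shared_missing,
)
from chemomine.synthdata import generate_loss_scenario
from conftest import yule_tree


class TestPhylo:
    def test_newick_round_trip_preserves_structure(self):
        t = Phylo.from_newick("((A:1,B:2)N1:0.5,C:3)root;")
        assert t.n_tips == 3
        assert len(t.branches) == 4
        t2 = Phylo.from_newick(t.to_newick())
        assert sorted(t2.labels) == sorted(t.labels)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Phylo.from_newick("((A:1,A:1):1,B:1);")

    def test_descendants_and_ancestors(self):
        t = Phylo.from_newick("((A:1,B:1)N1:1,(C:1,D:1)N2:1)root;")
        n1 = t.index_of("N1")
        labels = {t.labels[d] for d in t.descendants(n1)}
        assert labels == {"A", "B"}
        assert t.labels[t.ancestors(t.index_of("A"))[0]] == "N1"


class TestReclassify:
    def test_two_distant_stops_high_confidence(self):
        ev = GeneEvidence("pseudogene", {"premature_stop@40", "premature_stop@200"})
        assert reclassify_gene_status(ev) == "high_confidence_loss"

    def test_single_uncorroborated_low_confidence(self):
        ev = GeneEvidence("pseudogene", {"premature_stop@40"})
        assert reclassify_gene_status(ev) == "low_confidence_loss"

    def test_absent_with_intact_flanks_high_confidence(self):
        ev = GeneEvidence("absent", flanking_genes_found_same_scaffold=True)
        assert reclassify_gene_status(ev) == "high_confidence_loss"

    def test_absent_with_scattered_flanks_low_confidence(self):
        ev = GeneEvidence("absent", flanking_genes_found_same_scaffold=False)
        assert reclassify_gene_status(ev) == "low_confidence_loss"

    def test_sibling_assembly_rescues_complete(self):
        ev = GeneEvidence("truncated", sibling_assembly_statuses=["complete"])
        assert reclassify_gene_status(ev) == "complete"

    def test_fragments_merging_to_full_cds_complete(self):
        ev = GeneEvidence(
            "truncated", fragments=[(1, 180), (150, 310)], ref_codon_len=310
        )
        assert reclassify_gene_status(ev) == "complete"

    def test_sibling_corroborated_lof_high_confidence(self):
        ev = GeneEvidence(
            "pseudogene",
            {"premature_stop@40"},
            sibling_lof_sets=[{"premature_stop@40"}],
        )
        assert reclassify_gene_status(ev) == "high_confidence_loss"

    def test_unresolved_edge_is_undetermined(self):
        assert reclassify_gene_status(GeneEvidence("edge")) == "undetermined"

    def test_close_stops_stay_low_confidence(self):
        ev = GeneEvidence("pseudogene", {"premature_stop@40", "premature_stop@60"})
        assert reclassify_gene_status(ev) == "low_confidence_loss"

    def test_complete_with_lof_rejected(self):
        with pytest.raises(ValueError):
            GeneEvidence("complete", {"premature_stop@10"})


class TestInferLossBranches:
    def test_shared_stop_places_loss_on_mrca_branch(self):
        t = Phylo.from_newick("((A:1,B:1)N1:1,(C:1,D:1)N2:1)root;")
        lof = {"A": {"premature_stop@120"}, "B": {"premature_stop@120"},
               "C": set(), "D": set()}
        inf = infer_loss_branches(t, lof)
        assert inf.loss_branches == ["N1"]
        assert inf.support["N1"] == {"premature_stop@120"}

    def test_private_frameshift_terminal_loss(self):
        t = Phylo.from_newick("((A:1,B:1)N1:1,(C:1,D:1)N2:1)root;")
        lof = {"A": {"frameshift_deletion@55"}, "B": set(), "C": set(), "D": set()}
        inf = infer_loss_branches(t, lof)
        assert inf.loss_branches == ["A"]

    def test_no_lof_empty_inference(self):
        t = Phylo.from_newick("((A:1,B:1)N1:1,(C:1,D:1)N2:1)root;")
        inf = infer_loss_branches(t, {k: set() for k in "ABCD"})
        assert inf.loss_branches == []

    def test_sister_clades_with_different_keys_stay_separate(self):
        t = Phylo.from_newick("((A:1,B:1)N1:1,(C:1,D:1)N2:1)root;")
        lof = {"A": {"premature_stop@10"}, "B": {"premature_stop@10"},
               "C": {"premature_stop@99"}, "D": {"premature_stop@99"}}
        inf = infer_loss_branches(t, lof)
        assert sorted(inf.loss_branches) == ["N1", "N2"]

    def test_missing_tip_raises(self):
        t = Phylo.from_newick("((A:1,B:1):1,C:1)root;")
        with pytest.raises(KeyError):
            infer_loss_branches(t, {"A": set(), "B": set()})

    def test_no_nesting_invariant_on_random_scenarios(self):
        for seed in range(30):
            tree, losses, lof, _ = generate_loss_scenario(
                12, n_losses=3, seed=seed
            )
            inf = infer_loss_branches(tree, lof)
            idx = {tree.index_of(l) for l in inf.loss_branches}
            for i in idx:
                assert not any(a in idx for a in tree.ancestors(i))


class TestCountLosses:
    def _tree(self):
        t = Phylo.from_newick("((A:1,B:1)N1:1,(C:1,D:1)N2:1)root;")
        t.set_categories(
            {"A": "carnivore", "B": "carnivore", "N1": "carnivore",
             "C": "herbivore", "D": "herbivore", "N2": "herbivore"}
        )
        return t

    def test_hand_counted_example(self):
        counts = count_losses_by_category(self._tree(), ["N1"])
        assert counts["carnivore"] == {"independent_losses": 1, "intact_branches": 0}
        assert counts["herbivore"] == {"independent_losses": 0, "intact_branches": 3}

    def test_no_losses_all_intact(self):
        counts = count_losses_by_category(self._tree(), [])
        assert counts["carnivore"]["intact_branches"] == 3
        assert counts["herbivore"]["intact_branches"] == 3

    def test_nested_loss_counted_once(self):
        counts = count_losses_by_category(self._tree(), ["N1", "A"])
        assert counts["carnivore"]["independent_losses"] == 1

    def test_uncategorized_branch_raises(self):
        t = Phylo.from_newick("((A:1,B:1)N1:1,C:1)root;")
        t.set_categories({"A": "x", "B": "x", "C": "x"})  # N1 missing
        with pytest.raises(ValueError):
            count_losses_by_category(t, [])


class TestContingency:
    def test_fisher_2x2_hand_value(self):
        assert contingency_tests([[1, 0], [0, 3]])["fisher_p"] == pytest.approx(0.25)

    def test_flat_table(self):
        res = contingency_tests([[2, 2], [2, 2]])
        assert res["chi2_stat"] == pytest.approx(0.0)
        assert res["chi2_p"] == pytest.approx(1.0)
        assert res["fisher_p"] == pytest.approx(1.0)

    def test_fisher_closed_form_diagonal(self):
        res = contingency_tests([[10, 0], [0, 10]])
        assert res["fisher_p"] == pytest.approx(2 / math.comb(20, 10))

    def test_2xk_enumeration_matches_scipy_on_2x2(self):
        rng = np.random.default_rng(0)
        from chemomine.lossstats import _fisher_exact_2xk

        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum() == 0:
                continue
            _, expected = stats.fisher_exact(t)
            assert _fisher_exact_2xk(t) == pytest.approx(expected, abs=1e-10)

    def test_2x3_probabilities_sum_and_bound(self):
        res = contingency_tests([[5, 1, 0], [2, 6, 7]])
        assert 0 < res["fisher_p"] <= 1
        assert 0 < res["chi2_p"] < 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            contingency_tests([[1, -1], [2, 2]])


def enumerate_loss_distribution(tree: Phylo, n_draws: int, weighted: bool):
    """Exhaustive oracle: expected per-category independent-loss counts.

    Enumerates ordered draw sequences with their exact probabilities under
    the sequential scheme (draw among still-complete branches, a drawn
    branch kills its descendants; exhausted sequences are discarded and the
    distribution renormalized).
    """
    branches = list(tree.branches)
    lengths = {b: tree.length[b] for b in branches}
    desc = {b: set(int(d) for d in tree.descendants(b)) for b in branches}
    dist = {}
    total_p = 0.0

    def indep_counts(drawn):
        cats = {}
        for b in drawn:
            if not any(o != b and b in desc[o] for o in drawn):
                c = tree.category[b]
                cats[c] = cats.get(c, 0) + 1
        return tuple(sorted(cats.items()))

    def rec(drawn, complete, p):
        nonlocal total_p
        if len(drawn) == n_draws:
            key = indep_counts(drawn)
            dist[key] = dist.get(key, 0.0) + p
            total_p += p
            return
        if not complete:
            return  # discarded replicate
        weights = [lengths[b] if weighted else 1.0 for b in complete]
        z = sum(weights)
        for b, w in zip(list(complete), weights):
            nxt = [x for x in complete if x != b and x not in desc[b]]
            rec(drawn + [b], nxt, p * w / z)

    rec([], branches, 1.0)
    return {k: v / total_p for k, v in dist.items()}


SMALL_TREES = [
    # newick, categories per branch label
    ("(A:1,B:1)root;", {"A": "c", "B": "h"}),
    ("((A:1,B:2)N1:1,C:1)root;", {"A": "c", "B": "h", "N1": "c", "C": "h"}),
    ("((A:1,B:1)N1:1,(C:2,D:1)N2:2)root;",
     {"A": "c", "B": "c", "N1": "c", "C": "h", "D": "h", "N2": "h"}),
    ("(((A:1,B:1)N1:1,C:1)N2:1,D:2)root;",
     {"A": "c", "B": "h", "N1": "c", "C": "h", "N2": "c", "D": "h"}),
]


class TestSimulateRandomLosses:
    def test_two_branch_uniform_p_half(self):
        t = Phylo.from_newick("(A:3,B:1)root;")
        t.set_categories({"A": "carnivore", "B": "herbivore"})
        res = simulate_random_losses(t, 1, False, 40000, 1, {"carnivore": 1})
        assert res.p_values["carnivore"] == pytest.approx(0.5, abs=0.01)

    def test_two_branch_weighted_three_to_one(self):
        t = Phylo.from_newick("(A:3,B:1)root;")
        t.set_categories({"A": "carnivore", "B": "herbivore"})
        res = simulate_random_losses(t, 1, True, 40000, 1, {"carnivore": 1})
        assert res.p_values["carnivore"] == pytest.approx(0.75, abs=0.01)

    def test_too_many_draws_rejected(self):
        t = Phylo.from_newick("(A:1,B:1)root;")
        t.set_categories({"A": "c", "B": "h"})
        with pytest.raises(ValueError, match="cannot place"):
            simulate_random_losses(t, 3, False, 10, 1)

    def test_seeded_runs_bit_reproducible(self):
        t = yule_tree(12, 3)
        for i in range(1, len(t)):
            t.category[i] = "c" if i % 2 else "h"
        a = simulate_random_losses(t, 3, True, 500, 42, {"c": 2})
        b = simulate_random_losses(t, 3, True, 500, 42, {"c": 2})
        assert a.p_values == b.p_values
        for cat in a.distributions:
            assert np.array_equal(a.distributions[cat], b.distributions[cat])

    def test_first_draw_frequencies_uniform(self):
        t = yule_tree(6, 9)
        for i in range(1, len(t)):
            t.category[i] = f"cat{i}"  # one category per branch
        res = simulate_random_losses(t, 1, False, 40000, 5)
        counts = np.array(
            [res.distributions[f"cat{i}"].sum() for i in range(1, len(t))]
        )
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, len(counts) - 1)
        assert p > 0.001

    def test_p_monotone_in_observed(self):
        t = yule_tree(8, 2)
        for i in range(1, len(t)):
            t.category[i] = "c"
        ps = [
            simulate_random_losses(t, 3, False, 4000, 7, {"c": k}).p_values["c"]
            for k in range(0, 4)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("tree_idx", range(len(SMALL_TREES)))
    @pytest.mark.parametrize("n_draws", [1, 2])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_exhaustive_enumeration(self, tree_idx, n_draws, weighted):
        newick, cats = SMALL_TREES[tree_idx]
        t = Phylo.from_newick(newick)
        t.set_categories(cats)
        n_sims = 20000
        res = simulate_random_losses(t, n_draws, weighted, n_sims, 11)
        exact = enumerate_loss_distribution(t, n_draws, weighted)
        # compare P(independent losses in category c == k)
        for cat in sorted({c for c in cats.values()}):
            sim = res.distributions[cat]
            for k in range(n_draws + 1):
                p_exact = sum(
                    p for key, p in exact.items()
                    if dict(key).get(cat, 0) == k
                )
                p_sim = float(np.mean(sim == k))
                se = math.sqrt(max(p_exact * (1 - p_exact), 1e-9) / n_sims)
                assert abs(p_sim - p_exact) <= max(3 * se, 1e-3), (
                    cat, k, p_sim, p_exact
                )


class TestSimulateSharedMissing:
    def test_uniform_mean_matches_analytic(self):
        res = simulate_shared_missing([100, 200], [1] * 5, False, 40000, 3)
        assert res["mean"] == pytest.approx(2 * 0.5 ** 5, abs=0.005)

    def test_all_missing_gives_full_overlap(self):
        res = simulate_shared_missing([10, 20, 30], [3, 3], False, 200, 0)
        assert np.all(res["distribution"] == 3)

    def test_zero_length_gene_never_drawn_weighted(self):
        res = simulate_shared_missing(
            [0, 50, 50], [2, 2, 2], True, 2000, 1
        )
        # the zero-weight gene is never drawn, so both others always shared
        assert np.all(res["distribution"] == 2)

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError):
            simulate_shared_missing([10, 10], [3], False, 10, 0)

    def test_p_value_against_observed(self):
        res = simulate_shared_missing([1, 1, 1, 1], [2, 2], False, 5000, 2,
                                      observed=0)
        assert res["p_shared_ge_observed"] == pytest.approx(1.0)

    def test_weighted_mean_matches_enumeration_two_genes(self):
        # two genes, lengths 3:1, each of two species misses one gene:
        # P(both pick gene A) = (3/4)^2, P(both pick B) = (1/4)^2
        res = simulate_shared_missing([3, 1], [1, 1], True, 40000, 4)
        expect = (3 / 4) ** 2 + (1 / 4) ** 2
        assert res["mean"] == pytest.approx(expect, abs=0.01)

    def test_seeded_reproducibility(self):
        a = simulate_shared_missing([5, 5, 5], [2, 1], True, 500, 9)
        b = simulate_shared_missing([5, 5, 5], [2, 1], True, 500, 9)
        assert np.array_equal(a["distribution"], b["distribution"])


class TestScenarioRoundTrip:
    def test_planted_losses_exactly_recovered(self):
        for seed in range(40):
            tree, losses, lof, cats = generate_loss_scenario(
                16, n_losses=2, seed=seed
            )
            inf = infer_loss_branches(tree, lof)
            assert set(inf.loss_branches) == set(losses), seed

    def test_counts_match_generator_bookkeeping(self):
        for seed in range(20):
            tree, losses, lof, cats = generate_loss_scenario(
                14, n_losses=3, seed=seed
            )
            inf = infer_loss_branches(tree, lof)
            counts = count_losses_by_category(tree, inf.loss_branches)
            by_cat = {}
            for lab in losses:
                c = cats[lab]
                by_cat[c] = by_cat.get(c, 0) + 1
            for c, n in by_cat.items():
                assert counts[c]["independent_losses"] == n
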