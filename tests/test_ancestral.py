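"""Wagner/Sankoff ancestral gene content, events, and the LCA split."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from pancestry.ancestral import (
    AsrResult,
    UnrootedGuideError,
    WagnerConfig,
    classify_lca,
    summarize_events,
    wagner_parsimony,
)
from pancestry.panmatrix import PanMatrix, pan_matrix_from_presence
from pancestry.simulate import SimConfig, evolve_gene_content, simulate_tree


def rooted(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def matrix(rows: dict[str, dict[str, int]], genomes: list[str]) -> PanMatrix:
    return PanMatrix(
        pd.DataFrame(rows).T.reindex(columns=genomes).fillna(0).astype(int)
    )


def exhaustive_min_cost(
    tree: dendropy.Tree, leaf_state: dict[str, int], gain: float, loss: float
) -> float:
    """Brute-force minimum Wagner cost over all internal 0/1 assignments."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]

    def trans(s, t):
        return gain * max(t - s, 0) + loss * max(s - t, 0)

    best = np.inf
    for assignment in itertools.product((0, 1), repeat=len(internals)):
        states = {id(n): s for n, s in zip(internals, assignment)}
        for leaf in tree.leaf_node_iter():
            states[id(leaf)] = leaf_state[leaf.taxon.label]
        cost = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                cost += trans(states[id(node.parent_node)], states[id(node)])
        best = min(best, cost)
    return best


class TestWagnerParsimony:
    def test_invariant_family_present_everywhere_costless(self):
        m = matrix({"F1": {"a": 1, "b": 1, "c": 1, "d": 1}}, list("abcd"))
        asr = wagner_parsimony(m, rooted("((a,b),(c,d));"))
        assert asr.total_cost == 0
        for nid, states in asr.node_states.items():
            assert states[0] == 1
        assert all(g == l == frozenset() for g, l in asr.branch_events.values())

    def test_single_leaf_family_gained_on_terminal_branch(self):
        m = matrix(
            {"F1": {"a": 1}, "F2": {g: 1 for g in "abcd"}}, list("abcd")
        )
        asr = wagner_parsimony(m, rooted("((a,b),(c,d));"), WagnerConfig(2, 1))
        gains, _ = asr.branch_events["a"]
        assert gains == {"F1"}
        assert asr.per_family_cost[asr.family_ids.index("F1")] == 2.0

    def test_matches_exhaustive_enumeration_on_clade_family(self):
        """DP cost equals brute force for the 4-leaf clade pattern."""
        tree = rooted("((a,b)T,(c,d));")
        m = matrix({"F1": {"a": 1, "b": 1}}, list("abcd"))
        asr = wagner_parsimony(m, tree, WagnerConfig(2, 1))
        expected = exhaustive_min_cost(tree, {"a": 1, "b": 1, "c": 0, "d": 0}, 2, 1)
        assert asr.total_cost == expected

    def test_unrooted_guide_rejected(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d),e);", schema="newick")
        tree.is_rooted = False
        m = matrix({"F1": {g: 1 for g in "abcde"}}, list("abcde"))
        with pytest.raises(UnrootedGuideError):
            wagner_parsimony(m, tree)

    def test_leaf_mismatch_rejected(self):
        m = matrix({"F1": {"a": 1, "b": 1}}, ["a", "b"])
        with pytest.raises(ValueError):
            wagner_parsimony(m, rooted("((a,b),(c,d));"))

    def test_total_cost_equals_event_cost_sum(self):
        rng = np.random.default_rng(3)
        tree = simulate_tree(SimConfig(n_genomes=6, seed=4))
        genomes = sorted(l.taxon.label for l in tree.leaf_node_iter())
        counts = rng.integers(0, 2, size=(40, 6))
        counts[counts.sum(axis=1) == 0, 0] = 1
        m = PanMatrix(pd.DataFrame(counts, index=[f"F{i}" for i in range(40)],
                                   columns=genomes))
        cfg = WagnerConfig(2.0, 1.0)
        asr = wagner_parsimony(m, tree, cfg)
        event_cost = sum(
            cfg.gain_cost * len(g) + cfg.loss_cost * len(l)
            for g, l in asr.branch_events.values()
        )
        assert asr.total_cost == pytest.approx(event_cost)

    def test_gain_count_monotone_in_gain_cost(self):
        rng = np.random.default_rng(10)
        tree = simulate_tree(SimConfig(n_genomes=8, seed=6))
        genomes = sorted(l.taxon.label for l in tree.leaf_node_iter())
        counts = rng.integers(0, 2, size=(60, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        m = PanMatrix(pd.DataFrame(counts, index=[f"F{i}" for i in range(60)],
                                   columns=genomes))
        previous = None
        for gain in (0.5, 1.0, 2.0, 4.0, 8.0):
            asr = wagner_parsimony(m, tree.clone(depth=1), WagnerConfig(gain, 1.0))
            n_gains = sum(len(g) for g, _ in asr.branch_events.values())
            if previous is not None:
                assert n_gains <= previous
            previous = n_gains

    def test_count_mode_reconstructs_copy_numbers(self):
        m = matrix({"F1": {"a": 2, "b": 2, "c": 2, "d": 2}}, list("abcd"))
        asr = wagner_parsimony(
            m, rooted("((a,b),(c,d));"), WagnerConfig(2, 1, mode="count")
        )
        assert asr.total_cost == 0
        assert all(s[0] == 2 for s in asr.node_states.values())

    def test_recovers_planted_gains_in_high_signal_regime(self):
        cfg = SimConfig(n_genomes=20, root_families=200, gain_rate=20.0,
                        loss_rate=0.15, seed=7)
        tree = simulate_tree(cfg)
        hist = evolve_gene_content(tree, cfg)
        m = pan_matrix_from_presence(hist.node_families, hist.leaf_labels())
        asr = wagner_parsimony(m, tree.clone(depth=1), WagnerConfig(2, 1))
        observable = set(m.family_ids)
        tp = fn = 0
        for node_label, (gained, _lost) in hist.branch_events.items():
            true_g = {f for f in gained if f in observable}
            inf_g, _ = asr.branch_events.get(node_label, (frozenset(), frozenset()))
            tp += len(true_g & inf_g)
            fn += len(true_g - inf_g)
        assert tp / (tp + fn) >= 0.90
        root_true = len(hist.node_families[tree.seed_node.label])
        root_inf = int((asr.node_states[tree.seed_node.label] > 0).sum())
        assert abs(root_inf - root_true) / root_true <= 0.10


class TestSummarizeEvents:
    def test_frozen_history_all_zero_events(self):
        m = matrix({f"F{i}": {g: 1 for g in "abcd"} for i in range(5)}, list("abcd"))
        asr = wagner_parsimony(m, rooted("((a,b),(c,d));"))
        table = summarize_events(asr)
        assert (table.gains == 0).all() and (table.losses == 0).all()
        assert (table.families == 5).all()

    def test_conservation_identity_per_row(self):
        rng = np.random.default_rng(15)
        for seed in range(5):
            tree = simulate_tree(SimConfig(n_genomes=6, seed=seed))
            genomes = sorted(l.taxon.label for l in tree.leaf_node_iter())
            counts = rng.integers(0, 2, size=(30, 6))
            counts[counts.sum(axis=1) == 0, 0] = 1
            m = PanMatrix(pd.DataFrame(counts, index=[f"F{i}" for i in range(30)],
                                       columns=genomes))
            asr = wagner_parsimony(m, tree, WagnerConfig(2, 1))
            table = summarize_events(asr).set_index("node")
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                row = table.loc[node.label]
                parent_fams = table.loc[node.parent_node.label, "families"]
                assert row.families == parent_fams + row.gains - row.losses

    def test_matches_independent_recount_on_toy(self):
        m = matrix(
            {
                "F1": {g: 1 for g in "abcdef"},
                "F2": {"a": 1, "b": 1},
                "F3": {"e": 1},
            },
            list("abcdef"),
        )
        tree = rooted("(((a,b),(c,d)),(e,f));")
        asr = wagner_parsimony(m, tree, WagnerConfig(2, 1))
        table = summarize_events(asr).set_index("node")
        # independent recount from the reconstructed states themselves
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            child = asr.families_at(node.label)
            parent = asr.families_at(node.parent_node.label)
            assert table.loc[node.label, "gains"] == len(child - parent)
            assert table.loc[node.label, "losses"] == len(parent - child)


class TestClassifyLca:
    def build_toy(self):
        """1117 families shared with the parent + 1374 gained at the node."""
        genomes = list("ABCDEFGH")
        rows = {}
        for i in range(1117):
            rows[f"anc{i:05d}"] = {g: 1 for g in genomes}
        for i in range(1374):
            rows[f"der{i:05d}"] = {"A": 1, "B": 1}
        m = matrix(rows, genomes)
        tree = rooted("((((A,B)T,(C,D)),(E,F)),(G,H));")
        return wagner_parsimony(m, tree, WagnerConfig(2, 1))

    def test_reports_paper_scale_split(self):
        report = classify_lca(self.build_toy(), ["A", "B"])
        assert report.total_families == 2491
        assert len(report.ancestral) == 1117
        assert len(report.derived) == 1374
        assert report.ancestral_pct == 44.8
        assert report.derived_pct == 55.1

    def test_percentages_sum_to_100_within_rounding(self):
        report = classify_lca(self.build_toy(), "T")
        assert report.ancestral_pct + report.derived_pct == pytest.approx(100, abs=0.2)

    def test_no_gain_node_is_fully_ancestral(self):
        m = matrix({f"F{i}": {g: 1 for g in "abcd"} for i in range(4)}, list("abcd"))
        tree = rooted("((a,b)X,(c,d));")
        report = classify_lca(wagner_parsimony(m, tree), "X")
        assert report.derived == frozenset()
        assert report.ancestral_pct == 100.0

    def test_root_and_leaf_targets_refused(self):
        m = matrix({"F1": {g: 1 for g in "abcd"}}, list("abcd"))
        tree = rooted("((a,b),(c,d));")
        asr = wagner_parsimony(m, tree)
        with pytest.raises(ValueError, match="root"):
            classify_lca(asr, list("abcd"))
        with pytest.raises(ValueError, match="leaf"):
            classify_lca(asr, "a")
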