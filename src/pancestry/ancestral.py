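"""Wagner-parsimony ancestral gene content on a guide tree.

Gene-family presence (or copy number) at every internal node of a rooted
guide tree is reconstructed by Sankoff dynamic programming with asymmetric
per-unit transition costs: acquiring a family costs ``gain_cost`` (default
2, penalizing horizontal acquisition) and losing one costs ``loss_cost``
(default 1).  State changes along branches give per-branch gain and loss
event sets, and any internal node's family pool can be decomposed into
ancestral families (already present in its parent) and derived families
(gained on the branch entering the node).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .panmatrix import PanMatrix

BIG = 1e18


@dataclass(frozen=True)
class WagnerConfig:
    gain_cost: float = 2.0
    loss_cost: float = 1.0
    mode: str = "presence"  # or "count"
    max_count_cap: int = 10

    def __post_init__(self) -> None:
        if self.gain_cost < 0 or self.loss_cost < 0:
            raise ValueError("costs must be >= 0")
        if self.gain_cost == 0 and self.loss_cost == 0:
            raise ValueError("costs must not both be 0")
        if self.mode not in ("presence", "count"):
            raise ValueError("mode must be 'presence' or 'count'")
        if self.mode == "count" and self.max_count_cap < 1:
            raise ValueError("max_count_cap must be >= 1")


@dataclass
class AsrResult:
    """Reconstructed states, events, and costs on the guide tree.

    ``node_states`` maps node id to a per-family state vector (0/1 in
    presence mode, copy number in count mode) over ``family_ids``;
    ``branch_events`` maps a non-root node id to the (gained, lost) family
    id sets on its incoming branch.
    """

    tree: dendropy.Tree
    family_ids: list[str]
    node_states: dict[str, np.ndarray]
    branch_events: dict[str, tuple[frozenset[str], frozenset[str]]]
    per_family_cost: np.ndarray
    config: WagnerConfig

    @property
    def total_cost(self) -> float:
        return float(self.per_family_cost.sum())

    def families_at(self, node_id: str) -> frozenset[str]:
        states = self.node_states[node_id]
        return frozenset(f for f, s in zip(self.family_ids, states) if s > 0)

    def node_ids(self) -> list[str]:
        return [n.label for n in self.tree.preorder_node_iter()]


class UnrootedGuideError(ValueError):
    pass


def _label_guide(tree: dendropy.Tree) -> None:
    i = 0
    seen = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        elif not node.label or node.label in seen:
            i += 1
            while f"N{i}" in seen:
                i += 1
            node.label = f"N{i}"
        seen.add(node.label)


def wagner_parsimony(
    matrix: PanMatrix, guide: dendropy.Tree, config: WagnerConfig | None = None
) -> AsrResult:
    """Sankoff DP over {0,1} (or 0..cap) states, vectorized across families.

    Bottom-up pass computes minimal subtree costs per state; the top-down
    pass picks optimal states, breaking ties toward the parent's state
    (root ties toward absence/the smallest state) so reconstructions are
    deterministic and conservative about spurious events.
    """
    config = config or WagnerConfig()
    root = guide.seed_node
    if not guide.is_rooted or len(root.child_nodes()) != 2:
        raise UnrootedGuideError(
            "guide tree must be rooted (bifurcating root); root it on an "
            "outgroup first, e.g. trees.root_with_outgroup"
        )
    leaf_labels = sorted(l.taxon.label for l in guide.leaf_node_iter())
    if leaf_labels != sorted(matrix.genome_ids):
        raise ValueError("guide tree leaves must match pan-matrix genomes")
    _label_guide(guide)

    families = matrix.family_ids
    F = len(families)
    if config.mode == "presence":
        n_states = 2
        leaf_state = {
            g: (matrix.counts[g].values > 0).astype(int) for g in matrix.genome_ids
        }
    else:
        n_states = config.max_count_cap + 1
        leaf_state = {
            g: np.minimum(matrix.counts[g].values, config.max_count_cap)
            for g in matrix.genome_ids
        }

    s = np.arange(n_states)
    # trans[s, t]: cost of a parent in state s having a child in state t
    trans = config.gain_cost * np.maximum(s[None, :] - s[:, None], 0) + \
        config.loss_cost * np.maximum(s[:, None] - s[None, :], 0)

    cost: dict[str, np.ndarray] = {}  # node -> (n_states, F)
    for node in guide.postorder_node_iter():
        if node.is_leaf():
            c = np.full((n_states, F), BIG)
            c[leaf_state[node.taxon.label], np.arange(F)] = 0.0
            cost[node.label] = c
        else:
            total = np.zeros((n_states, F))
            for child in node.child_nodes():
                # min over child state t of trans[s, t] + cost_child[t]
                total += (trans[:, :, None] + cost[child.label][None, :, :]).min(axis=1)
            cost[node.label] = total

    node_states: dict[str, np.ndarray] = {}
    for node in guide.preorder_node_iter():
        c = cost[node.label]
        if node is root:
            # argmin with ties toward the smallest state (absence)
            node_states[node.label] = c.argmin(axis=0)
        else:
            parent_state = node_states[node.parent_node.label]
            choice = trans[parent_state, :].T + c  # (n_states, F)
            best = choice.min(axis=0)
            optimal = choice <= best[None, :] + 1e-9
            state = choice.argmin(axis=0)  # smallest optimal state
            keep_parent = optimal[parent_state, np.arange(F)]
            node_states[node.label] = np.where(keep_parent, parent_state, state)

    branch_events: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    fam_arr = np.array(families)
    for node in guide.preorder_node_iter():
        if node is root:
            continue
        parent = node_states[node.parent_node.label]
        child = node_states[node.label]
        gained = frozenset(fam_arr[(parent == 0) & (child > 0)])
        lost = frozenset(fam_arr[(parent > 0) & (child == 0)])
        branch_events[node.label] = (gained, lost)

    per_family = cost[root.label][
        node_states[root.label], np.arange(F)
    ].astype(float)
    return AsrResult(guide, list(families), node_states, branch_events, per_family, config)


def summarize_events(result: AsrResult) -> pd.DataFrame:
    """One row per node: family total and incoming-branch gain/loss counts."""
    rows = []
    for node in result.tree.preorder_node_iter():
        nid = node.label
        n_fam = int((result.node_states[nid] > 0).sum())
        if node is result.tree.seed_node:
            gains = losses = 0
        else:
            g, l = result.branch_events[nid]
            gains, losses = len(g), len(l)
        rows.append(
            {
                "node": nid,
                "is_leaf": node.is_leaf(),
                "families": n_fam,
                "gains": gains,
                "losses": losses,
            }
        )
    return pd.DataFrame(rows)


def _truncate_pct(x: float) -> float:
    """Truncate to one decimal (the reporting convention for LCA splits)."""
    return math.floor(x * 10.0) / 10.0


@dataclass(frozen=True)
class LcaReport:
    """Ancestral/derived decomposition of one internal node's family pool."""

    node_id: str
    total_families: int
    ancestral: frozenset[str]  # present at the node and at its parent
    derived: frozenset[str]  # gained on the branch entering the node
    losses_into_node: frozenset[str]
    ancestral_pct: float
    derived_pct: float

    def to_dict(self) -> dict:
        return {
            "node_id": self.node_id,
            "total_families": self.total_families,
            "n_ancestral": len(self.ancestral),
            "n_derived": len(self.derived),
            "n_losses_into_node": len(self.losses_into_node),
            "ancestral_pct": self.ancestral_pct,
            "derived_pct": self.derived_pct,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def classify_lca(
    result: AsrResult, target: str | Sequence[str]
) -> LcaReport:
    """Split a node's families into ancestral vs derived.

    ``target`` is an internal, non-root node id, or a collection of leaf
    labels whose MRCA is taken as the target.  Percentages are reported
    truncated to one decimal place.
    """
    tree = result.tree
    if isinstance(target, str):
        node = next((n for n in tree.preorder_node_iter() if n.label == target), None)
        if node is None:
            raise KeyError(f"no node labelled {target!r}")
    else:
        node = tree.mrca(taxon_labels=list(target))
    if node is tree.seed_node:
        raise ValueError("target is the root: it has no incoming branch to classify")
    if node.is_leaf():
        raise ValueError("target is a leaf: pick an internal node")

    present = result.families_at(node.label)
    parent_present = result.families_at(node.parent_node.label)
    gained, lost = result.branch_events[node.label]
    ancestral = present & parent_present
    derived = frozenset(present - parent_present)
    assert derived == frozenset(gained)
    total = len(present)
    return LcaReport(
        node_id=node.label,
        total_families=total,
        ancestral=ancestral,
        derived=derived,
        losses_into_node=lost,
        ancestral_pct=_truncate_pct(100.0 * len(ancestral) / total) if total else 0.0,
        derived_pct=_truncate_pct(100.0 * len(derived) / total) if total else 0.0,
    )


def write_events_tsv(result: AsrResult, path: str | Path) -> None:
    summarize_events(result).to_csv(path, sep="\t", index=False)
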