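"""End-to-end pipeline: QC filter -> orthology -> pan-matrix -> partition ->
size curves -> trees -> ancestral reconstruction -> LCA report.

All stage randomness derives from one master seed via spawned seed
sequences, so a rerun with the same configuration produces a byte-identical
summary.  Each stage writes its artifacts before the next starts; partial
outputs survive a downstream failure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import yaml

from . import ancestral, clustering, curves, msa, panmatrix, simulate, trees

log = logging.getLogger("pancestry")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration; every field has a sensible default.

    Exactly one of ``input_dir`` (per-genome .faa files plus qc.tsv) or
    ``simulate`` (synthetic pangenome parameters) must be provided.
    """

    output_dir: str = "pancestry_out"
    input_dir: str | None = None
    simulate: simulate.SimConfig | None = None
    seed: int = 0
    min_completeness: float = 99.0
    max_contamination: float = 5.0
    force_include: tuple[str, ...] = ()
    hit_filter: clustering.HitFilterConfig = field(default_factory=clustering.HitFilterConfig)
    mcl: clustering.MclConfig = field(default_factory=clustering.MclConfig)
    softcore_fraction: float = 0.95
    n_permutations: int = 10
    bootstrap_replicates: int = 500
    deletion: str = "complete"
    pan_tree_restarts: int = 10
    wagner: ancestral.WagnerConfig = field(default_factory=ancestral.WagnerConfig)
    lca_leaves: tuple[str, ...] = ()  # MRCA of these leaves is the ASR target
    outgroup: tuple[str, ...] = ()  # roots the core tree; midpoint if empty
    guide_tree: str | None = None  # externally computed rooted Newick

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, typ in (
            ("simulate", simulate.SimConfig),
            ("hit_filter", clustering.HitFilterConfig),
            ("mcl", clustering.MclConfig),
            ("wagner", ancestral.WagnerConfig),
        ):
            if isinstance(raw.get(key), dict):
                sub = raw[key]
                if key == "simulate" and "target_genes_per_genome_range" in sub:
                    sub["target_genes_per_genome_range"] = tuple(
                        sub["target_genes_per_genome_range"]
                    )
                raw[key] = typ(**sub)
        for key in ("force_include", "lca_leaves", "outgroup"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seeds(seed: int, names: Sequence[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) a machine-readable summary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler()
    file_handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    for h in (handler, file_handler):
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(logging.INFO)

    seeds = _stage_seeds(
        config.seed, ["simulate", "curves", "bootstrap", "pan_tree", "qc"]
    )
    summary: dict = {"config": _jsonable(config.to_dict()), "stage_seeds": seeds}
    try:
        return _run_stages(config, outdir, seeds, summary)
    finally:
        log.removeHandler(handler)
        log.removeHandler(file_handler)
        file_handler.close()


def _run_stages(config, outdir: Path, seeds, summary) -> dict:
    # --- inputs -----------------------------------------------------------
    if (config.input_dir is None) == (config.simulate is None):
        raise PipelineError("input", "provide exactly one of input_dir or simulate")
    if config.simulate is not None:
        log.info("simulating pangenome (%d genomes)", config.simulate.n_genomes)
        sim_cfg = config.simulate
        pangenome = simulate.simulate_pangenome(sim_cfg)
        input_dir = outdir / "inputs"
        simulate.write_proteomes(pangenome, input_dir)
        simulate.write_truth(pangenome.history, input_dir / "truth.json")
        simulate.write_qc_table(
            pangenome.proteomes.keys(), input_dir / "qc.tsv", seed=seeds["qc"]
        )
    else:
        input_dir = Path(config.input_dir)
    proteome_files = sorted(input_dir.glob("*.faa"))
    if not proteome_files:
        raise PipelineError("input", f"no .faa files found in {input_dir}")
    proteomes = simulate.read_proteomes(input_dir)

    # --- QC filter --------------------------------------------------------
    qc_path = input_dir / "qc.tsv"
    if qc_path.exists():
        records = panmatrix.read_qc_table(qc_path)
        retained = panmatrix.qc_filter_genomes(
            records, config.min_completeness, config.max_contamination,
            config.force_include,
        )
        retained = [g for g in retained if g in proteomes]
    else:
        log.warning("no qc.tsv found; retaining all genomes")
        retained = sorted(proteomes)
    proteomes = {g: proteomes[g] for g in retained}
    log.info("QC retained %d genomes", len(retained))
    (outdir / "qc_retained.txt").write_text("\n".join(retained) + "\n")
    if len(retained) < 3:
        raise PipelineError("qc", "fewer than 3 genomes after QC")
    summary["n_genomes"] = len(retained)

    # --- clustering -------------------------------------------------------
    log.info("clustering %d proteins", sum(len(v) for v in proteomes.values()))
    clusters = clustering.cluster_proteomes(proteomes, config.hit_filter, config.mcl)
    clustering.write_clusters(clusters, outdir / "clusters.tsv")
    summary["n_clusters"] = len(clusters)

    # --- pan-matrix and partition ----------------------------------------
    matrix = panmatrix.build_pan_matrix(clusters, retained)
    matrix.to_tsv(outdir / "pan_matrix.tsv")
    matrix.to_phylip_presence(outdir / "pan_matrix.phy")
    partition = panmatrix.partition_occupancy(matrix, config.softcore_fraction)
    panmatrix.write_partition_report(matrix, partition, outdir / "partition.tsv")
    strict = panmatrix.extract_strict_core(matrix, partition)
    summary["partition"] = {
        "core": len(partition.core),
        "softcore": len(partition.softcore_total),
        "shell": len(partition.shell),
        "cloud": len(partition.cloud),
        "strict_core": len(strict.family_ids),
    }
    log.info("partition: %s", summary["partition"])

    # --- size curves and openness ----------------------------------------
    pan_c, core_c, new_c = curves.sample_size_curves(
        matrix, config.n_permutations, seeds["curves"]
    )
    curves.write_curves_tsv((pan_c, core_c, new_c), outdir / "curves.tsv")
    fits = {c.kind: curves.fit_tettelin(c) for c in (pan_c, core_c, new_c)}
    (outdir / "tettelin_fits.json").write_text(
        json.dumps({k: json.loads(f.to_json()) for k, f in fits.items()},
                   indent=1, sort_keys=True)
    )
    openness, new_rate = curves.classify_openness(fits["new-genes"])
    summary["openness"] = openness
    summary["new_genes_per_genome"] = round(float(new_rate), 3)
    summary["core_saturation_n"] = fits["core"].saturation_n
    log.info("pangenome classified %s (tg(theta)=%.2f)", openness, new_rate)

    # --- core tree --------------------------------------------------------
    seq_by_pid = {pid: seq for pl in proteomes.values() for pid, seq in pl}
    cluster_by_id = {c.cluster_id: c for c in clusters}
    alignments = []
    for fid in sorted(strict.family_ids):
        members = [
            (genome, seq_by_pid[pid]) for genome, pid in cluster_by_id[fid].members
        ]
        alignments.append(msa.progressive_align(members, cluster_id=fid))
    if not alignments:
        raise PipelineError("core_tree", "empty strict core: no single-copy families")
    core_tree = trees.bootstrap_support(
        alignments,
        replicates=config.bootstrap_replicates,
        seed=seeds["bootstrap"],
        deletion=config.deletion,
    )
    trees.write_tree(core_tree, outdir / "core_tree.nwk")

    # --- pan tree ---------------------------------------------------------
    pan_result = trees.pan_parsimony_tree(
        matrix.presence(), config.pan_tree_restarts, seeds["pan_tree"]
    )
    trees.write_tree(pan_result.tree, outdir / "pan_tree.nwk")
    summary["pan_tree_score"] = pan_result.score

    # --- ancestral reconstruction ----------------------------------------
    if config.guide_tree:
        guide = trees.read_tree(config.guide_tree, rooted=True)
    elif config.outgroup:
        guide = trees.root_with_outgroup(core_tree, config.outgroup)
    else:
        guide = core_tree.clone(depth=1)
        guide.reroot_at_midpoint()
        guide.is_rooted = True
    for node in guide.preorder_node_iter():
        if not node.is_leaf():
            node.label = None  # drop bootstrap labels before ASR naming
    asr = ancestral.wagner_parsimony(matrix, guide, config.wagner)
    ancestral.write_events_tsv(asr, outdir / "asr_events.tsv")
    trees.write_tree(guide, outdir / "guide_tree.nwk")

    target: str | Sequence[str]
    if config.lca_leaves:
        target = config.lca_leaves
    else:
        root_children = guide.seed_node.child_nodes()
        internal = [c for c in root_children if not c.is_leaf()]
        if not internal:
            raise PipelineError("asr", "no internal non-root node to classify")
        target = max(
            internal, key=lambda n: len(n.leaf_nodes())
        ).label
    report = ancestral.classify_lca(asr, target)
    report.to_json(outdir / "lca_report.json")
    summary["lca"] = report.to_dict()
    summary["asr_total_cost"] = asr.total_cost
    log.info(
        "LCA %s: %d families (%.1f%% ancestral / %.1f%% derived)",
        report.node_id, report.total_families,
        report.ancestral_pct, report.derived_pct,
    )

    text = json.dumps(_jsonable(summary), indent=1, sort_keys=True)
    (outdir / "summary.json").write_text(text)
    return json.loads(text)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# evaluation against simulated ground truth


def evaluate_against_truth(
    output_dir: str | Path, history: simulate.TrueHistory
) -> dict:
    """Score a synthetic run against its ground-truth history.

    Reports clustering adjusted Rand index, core/pan tree Robinson-Foulds
    distances to the true tree, per-branch gain-event precision/recall
    (branches matched by child leaf set), and the relative error of the
    reconstructed root family count.
    """
    from sklearn.metrics import adjusted_rand_score

    outdir = Path(output_dir)
    inputs = outdir / "inputs"
    true_labels = simulate.true_family_labels(inputs)
    if not true_labels:
        raise ValueError("no family-annotated FASTA headers found for evaluation")

    assignment: dict[str, str] = {}
    with open(outdir / "clusters.tsv") as fh:
        for line in fh:
            cid, _rep, members = line.rstrip("\n").split("\t")
            for pid in members.split(","):
                assignment[pid] = cid
    shared = sorted(set(true_labels) & set(assignment))
    if not shared:
        raise ValueError("clustered proteins do not match ground-truth proteins")
    ari = adjusted_rand_score(
        [true_labels[p] for p in shared], [assignment[p] for p in shared]
    )

    true_tree = history.tree
    metrics = {"clustering_ari": float(ari)}
    for name in ("core_tree", "pan_tree"):
        path = outdir / f"{name}.nwk"
        if path.exists():
            inferred = trees.read_tree(path)
            metrics[f"{name}_rf"] = trees.robinson_foulds(inferred, true_tree)

    guide_path = outdir / "guide_tree.nwk"
    if guide_path.exists() and (outdir / "pan_matrix.tsv").exists():
        cluster_to_family = _majority_family(assignment, true_labels)
        metrics.update(_event_recovery(history, outdir, cluster_to_family))
    return metrics


def _majority_family(
    assignment: Mapping[str, str], true_labels: Mapping[str, str]
) -> dict[str, str]:
    """Map each inferred cluster to the most common true family among its members."""
    from collections import Counter

    votes: dict[str, Counter] = {}
    for pid, cid in assignment.items():
        if pid in true_labels:
            votes.setdefault(cid, Counter())[true_labels[pid]] += 1
    return {
        cid: sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        for cid, counter in votes.items()
    }


def _leafset_map(tree: dendropy.Tree) -> dict[frozenset, str]:
    out = {}
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        label = node.label if node.label else (
            node.taxon.label if node.taxon else None
        )
        out[leaves] = label
    return out


def _event_recovery(
    history: simulate.TrueHistory,
    outdir: Path,
    cluster_to_family: Mapping[str, str],
    wagner: ancestral.WagnerConfig | None = None,
) -> dict:
    """Gain-event precision/recall with branches matched by child leaf set.

    The reconstruction is recomputed from the written pan-matrix and guide
    tree (both deterministic artifacts), and inferred cluster-level gains
    are translated to true family ids via the majority map.
    """
    matrix = panmatrix.PanMatrix.from_tsv(outdir / "pan_matrix.tsv")
    guide = trees.read_tree(outdir / "guide_tree.nwk", rooted=True)
    asr = ancestral.wagner_parsimony(matrix, guide, wagner)

    guide_map = {
        frozenset(l.taxon.label for l in n.leaf_iter()): n.label
        for n in guide.preorder_node_iter()
    }
    true_map = _leafset_map(history.tree)

    true_total = inferred_total = recovered = 0
    for leaves, true_label in true_map.items():
        if true_label not in history.branch_events:
            continue
        true_gained, _ = history.branch_events[true_label]
        true_total += len(true_gained)
        node_label = guide_map.get(leaves)
        if node_label is None or node_label not in asr.branch_events:
            continue
        gained_clusters, _ = asr.branch_events[node_label]
        mapped = {cluster_to_family.get(c) for c in gained_clusters} - {None}
        inferred_total += len(mapped)
        recovered += len(mapped & set(true_gained))
    root_label = guide.seed_node.label
    inferred_root = int((asr.node_states[root_label] > 0).sum())
    true_root = len(history.node_families[history.tree.seed_node.label])
    return {
        "event_recall": recovered / true_total if true_total else 1.0,
        "event_precision": recovered / inferred_total if inferred_total else 1.0,
        "root_size_relative_error": abs(inferred_root - true_root) / true_root,
    }
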