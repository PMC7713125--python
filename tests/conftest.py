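"""Shared synthetic fixtures (generated at test time; nothing on disk)."""

from __future__ import annotations

import pytest

from pancestry import clustering, pipeline, simulate


@pytest.fixture(scope="session")
def sim12():
    """Default-condition pangenome: 12 genomes, 300 root families."""
    return simulate.simulate_pangenome(simulate.SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim12_clusters(sim12):
    """BDBH + MCL clusters of the 12-genome pangenome (the expensive step)."""
    proteomes = {
        g: [(pid, seq) for pid, _fid, seq in lst]
        for g, lst in sim12.proteomes.items()
    }
    return clustering.cluster_proteomes(proteomes)


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """One full pipeline run on an 8-genome pangenome, executed twice into
    the same output directory to probe determinism; returns
    (config, first summary bytes, second summary bytes, output dir)."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = pipeline.PipelineConfig(
        output_dir=str(outdir),
        simulate=simulate.SimConfig(
            n_genomes=8,
            root_families=80,
            gain_rate=10.0,
            loss_rate=0.1,
            seed=5,
        ),
        bootstrap_replicates=50,
        seed=42,
    )
    pipeline.run_pipeline(config)
    first = (outdir / "summary.json").read_bytes()
    pipeline.run_pipeline(config)
    second = (outdir / "summary.json").read_bytes()
    return config, first, second, outdir
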