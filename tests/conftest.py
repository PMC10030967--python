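import numpy as np
import pandas as pd
import pytest

from synnetflow.genome_io import GenomeTable


def make_genome(species, genes):
    """GenomeTable from (gene_id, chrom, start, end, strand) tuples."""
    df = pd.DataFrame(genes, columns=["gene_id", "chromosome", "start", "end", "strand"])
    return GenomeTable(species, df)


def ranked_genome(species, chrom_sizes):
    """Genome with ``chrom_sizes[c]`` genes per chromosome at unit spacing."""
    rows = []
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            rows.append((f"{species}_{chrom}_{i}", chrom, 1000 * i + 1, 1000 * i + 500, "+"))
    return make_genome(species, rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def zero_noise_run():
    """One demo-config simulation run through the full front half of the
    pipeline (blocks, network, clusters, profile), shared across tests."""
    from synnetflow.network import build_network, cluster_network
    from synnetflow.profiling import build_profile
    from synnetflow.simulate import demo_config, simulate
    from synnetflow.synteny import detect_all

    cfg = demo_config(seed=2024)
    genomes, hits, truth = simulate(cfg)
    blocks = detect_all(genomes, hits)
    graph = build_network(blocks)
    clusters = cluster_network(graph, seed=42)
    profile = build_profile(clusters, genomes)
    return {
        "config": cfg,
        "genomes": genomes,
        "hits": hits,
        "truth": truth,
        "blocks": blocks,
        "graph": graph,
        "clusters": clusters,
        "profile": profile,
    }
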