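"""End-to-end orchestration with one config and one root seed.

Runs the stage order homology → blocks → network → clusters → profile
→ correlations/sharing → tree (→ duplication classes → enrichment),
persisting every intermediate as a self-describing text file in a run
directory together with the resolved configuration, so a run can be
reproduced byte-identically from its directory alone.  All stage
randomness derives from the root seed via named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from synnetflow import dupclass as dc
from synnetflow import network as net
from synnetflow import phylo, profiling
from synnetflow.genome_io import read_annotation, read_homology, filter_hits, write_matrix
from synnetflow.simulate import SimConfig, simulate
from synnetflow.synteny import detect_all, write_collinearity

__all__ = ["PipelineConfig", "run_pipeline", "run_demo", "checksum_dir"]

log = logging.getLogger("synnetflow")

# stable substream indices: stage name -> offset added to the root seed
_STAGE_STREAMS = {"simulate": 1, "cluster": 2, "tree": 3, "bootstrap": 4}


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Serializable configuration of a full run."""

    seed: int = 42
    # inputs: either a simulation config (dict of SimConfig fields,
    # seed filled from the root seed) or annotation + homology files
    sim: dict | None = None
    annotations: list | None = None  # [(species, path, "gff3"|"bed")]
    homology: str | None = None
    # homology filtering / synteny
    top_k: int = 5
    min_anchors: int = 5
    max_gap: int = 25
    tandem_exclusion: int = 1
    # clustering
    cluster_method: str = "infomap"
    # profiling
    clades: dict | None = None
    min_presence: dict | None = None
    drop_species_specific: bool = True
    run_sharing: bool = True
    # tree
    tree_rate_categories: int = 2
    bootstrap_n: int = 0
    # duplication classification
    dupclass_species: list = field(default_factory=list)
    outgroups: list = field(default_factory=list)
    pd_max: int = 10
    # enrichment
    enrichment_terms: str | None = None
    enrichment_study: str | None = None
    enrichment_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if (self.sim is None) == (self.annotations is None):
            raise ValueError("config needs exactly one of 'sim' or 'annotations'")
        if self.annotations is not None and self.homology is None:
            raise ValueError("annotation input requires a homology file")
        if self.run_sharing and not self.clades:
            raise ValueError("sharing/clade profiling requested but no clades defined")
        if self.dupclass_species and not self.outgroups:
            log.warning("dupclass without outgroups: TRD detection will be disabled")


def checksum_dir(run_dir) -> str:
    """SHA-256 over every output file (sorted), for determinism checks."""
    h = hashlib.sha256()
    for p in sorted(Path(run_dir).rglob("*")):
        if p.is_file() and p.name != "run.log":
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages; returns the run directory.

    Rerunning with the same config and outdir contents produces
    byte-identical TSV/Newick outputs.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")

    # -- stage 1: inputs ----------------------------------------------
    truth = None
    if config.sim is not None:
        sim_cfg = SimConfig(**{**config.sim, "seed": _stage_seed(config.seed, "simulate")})
        log.info("simulating %d species", len(sim_cfg.clades) and sum(
            len(v) for v in sim_cfg.clades.values()) or 0)
        genomes, hits, truth = simulate(sim_cfg)
        (out / "true_tree.nwk").write_text(truth.tree + "\n")
    else:
        genomes = {}
        for species, path, fmt in config.annotations:
            genomes[species] = read_annotation(path, fmt, species)
        hits = read_homology(config.homology, top_k=config.top_k)
    for sp, gt in sorted(genomes.items()):
        gt.df.to_csv(out / f"genes_{sp}.tsv", sep="\t", index=False)

    species_of = {}
    for sp, gt in genomes.items():
        for g in gt.df["gene_id"]:
            species_of[g] = sp

    # -- stage 2: homology filtering ----------------------------------
    hits = filter_hits(hits, top_k=config.top_k, species_of=species_of)
    hits.to_csv(out / "homology_filtered.tsv", sep="\t", index=False)
    log.info("homology: %d filtered hits", len(hits))

    # -- stage 3: collinear blocks ------------------------------------
    blocks = detect_all(genomes, hits, {
        "min_anchors": config.min_anchors,
        "max_gap": config.max_gap,
        "tandem_exclusion": config.tandem_exclusion,
    })
    write_collinearity(blocks, out / "blocks.collinearity")
    anchor_rows = [
        (b.species_a, b.species_b, b.chrom_a, b.chrom_b, i, b.orientation,
         a.gene_a, a.gene_b, a.rank_a, a.rank_b)
        for i, b in enumerate(blocks) for a in b.anchors
    ]
    pd.DataFrame(anchor_rows, columns=[
        "species_a", "species_b", "chrom_a", "chrom_b", "block", "orientation",
        "gene_a", "gene_b", "rank_a", "rank_b",
    ]).to_csv(out / "anchors.tsv", sep="\t", index=False)
    log.info("synteny: %d blocks", len(blocks))

    # -- stage 4: network + clusters ----------------------------------
    graph = net.build_network(blocks)
    pd.DataFrame(sorted(graph.edges), columns=["gene_a", "gene_b"]).to_csv(
        out / "network_edges.tsv", sep="\t", index=False)
    clusters = net.cluster_network(
        graph, method=config.cluster_method, seed=_stage_seed(config.seed, "cluster"))
    pd.DataFrame(
        [(cid, g, species_of[g]) for cid, members in clusters for g in sorted(members)],
        columns=["cluster_id", "gene_id", "species"],
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    log.info("network: %d nodes, %d edges, %d clusters",
             graph.number_of_nodes(), graph.number_of_edges(), len(clusters))

    # -- stage 5: profiling -------------------------------------------
    profile = profiling.build_profile(clusters, genomes)
    write_matrix(profile.counts, out / "profile_counts.tsv", "tsv")
    write_matrix(profile.binary, out / "profile_binary.tsv", "tsv")
    write_matrix(profile.binary.T, out / "profile_binary.phy", "relaxed-phylip")
    corr = profiling.species_correlation(profile, on="binary")
    corr.to_csv(out / "species_correlation.tsv", sep="\t")
    composition, participation = net.cluster_stats(clusters, genomes)
    participation.to_csv(out / "cluster_participation.tsv", sep="\t")
    if config.clades:
        clade_def = profiling.CladeDefinition(
            {k: list(v) for k, v in config.clades.items()},
            dict(config.min_presence or {}),
        )
        if config.run_sharing:
            sharing = profiling.sharing_counts(
                profile, clade_def, drop_species_specific=config.drop_species_specific)
            sharing["clades"] = sharing["clades"].map(lambda t: "+".join(t))
            sharing.to_csv(out / "sharing_counts.tsv", sep="\t", index=False)
        rows = []
        for clade in sorted(clade_def.clades):
            for cid in sorted(profiling.clade_specific_clusters(profile, clade, clade_def)):
                rows.append((clade, cid))
        pd.DataFrame(rows, columns=["clade", "cluster_id"]).to_csv(
            out / "clade_specific_clusters.tsv", sep="\t", index=False)

    # -- stage 6: species tree ----------------------------------------
    binary_t = profile.binary.T  # species x characters
    if binary_t.shape[0] >= 4:
        if config.bootstrap_n > 0:
            tree, params, logl = phylo.bootstrap(
                binary_t, n_replicates=config.bootstrap_n,
                seed=_stage_seed(config.seed, "bootstrap"),
                n_rate_categories=config.tree_rate_categories)
        else:
            tree, params, logl = phylo.ml_search(
                binary_t, n_rate_categories=config.tree_rate_categories)
        (out / "microsynteny_tree.nwk").write_text(
            tree.to_newick(with_support=config.bootstrap_n > 0) + "\n")
        (out / "tree_model.yaml").write_text(yaml.safe_dump({
            "log_likelihood": float(logl),
            "pi0": float(params.pi0),
            "rates": [float(r) for r in params.rates],
            "weights": [float(w) for w in params.weights],
        }))
        log.info("tree: logL=%.2f pi0=%.3f", logl, params.pi0)

    # -- stage 7: duplication modes -----------------------------------
    for sp in config.dupclass_species:
        genome = genomes[sp]
        in_sp = hits["query_id"].map(species_of).eq(sp) & hits["subject_id"].map(species_of).eq(sp)
        intra_hits = hits[in_sp]
        intra_blocks = [b for b in blocks if b.species_a == sp and b.species_b == sp]
        og_blocks = [
            b for b in blocks
            if {b.species_a, b.species_b} & set(config.outgroups)
            and sp in (b.species_a, b.species_b) and b.species_a != b.species_b
        ] or None
        labels = dc.classify_pairs(genome, intra_hits, intra_blocks, og_blocks,
                                   pd_max=config.pd_max)
        labels.to_csv(out / f"dup_pairs_{sp}.tsv", sep="\t", index=False)
        gene_modes, proportions = dc.gene_mode_summary(labels, genome)
        proportions.to_csv(out / f"dup_proportions_{sp}.tsv", sep="\t")

    # -- stage 8: enrichment ------------------------------------------
    if config.enrichment_terms and config.enrichment_study:
        from synnetflow.enrichment import enrich
        term_map = pd.read_csv(config.enrichment_terms, sep="\t")
        study = [l.strip() for l in open(config.enrichment_study) if l.strip()]
        population = sorted(species_of)
        res = enrich(study, population, term_map)
        res.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    return out


def run_demo(outdir, seed: int = 42, bootstrap_n: int = 0) -> Path:
    """One-command reproduction of the three-clade synthetic experiment."""
    from synnetflow.simulate import DEMO_CLADES, DEMO_MIN_PRESENCE, demo_config

    sim = demo_config()
    config = PipelineConfig(
        seed=seed,
        sim={
            "tree": sim.tree,
            "root_genes": sim.root_genes,
            "chromosomes": sim.chromosomes,
            "clades": sim.clades,
            "planted_blocks": [list(b) for b in sim.planted_blocks],
        },
        clades={k: list(v) for k, v in DEMO_CLADES.items()},
        min_presence=dict(DEMO_MIN_PRESENCE),
        bootstrap_n=bootstrap_n,
        dupclass_species=["mag1"],
        outgroups=["mon1"],
    )
    return run_pipeline(config, outdir)
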