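"""Genome evolution simulator with full ground truth.

Evolves gene orders along a known species tree under inversion, gene
loss, tandem / proximal / dispersed duplication and optional
whole-genome duplication (WGD), then emits pipeline-ready inputs:
a rank-ordered :class:`~synnetflow.genome_io.GenomeTable` per extant
species and an all-vs-all style homology hit table derived from true
gene families, optionally corrupted with false-negative and
false-positive edges.  Every random event is logged as a concrete,
replayable record, so leaf genomes can be reproduced exactly from the
root genome and the log.

Events occur as a Poisson process along branches: the number of events
of each type on a branch is Poisson with mean ``rate × branch_length ×
n_genes`` (rates are per gene per branch-length unit), and the drawn
events are applied in random order.  Duplication placement follows the
rank conventions of the downstream classifier: a tandem copy is
inserted adjacent to its template (rank offset 1), a proximal copy at a
uniform rank offset in [2, 9], a dispersed copy at a uniform random
position on a random chromosome.  WGD copies every chromosome onto a
new homeologous chromosome and then deletes each copy independently
with probability ``1 − retention`` (instantaneous fractionation).

Homology bitscores follow a documented monotone scheme:
``bitscore = 100·exp(−d) + ε`` with ``d`` = patristic distance between
the two species plus ``0.25`` per duplication event in either gene's
history, and ``ε ~ Normal(0, 1)``; evalue and identity are monotone
transforms of the bitscore.  Each unordered homologous pair is emitted
once (the pipeline treats hits as undirected).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from synnetflow.genome_io import GenomeTable, HIT_COLUMNS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "EventRecord",
    "simulate",
    "apply_event",
    "replay",
    "plant_clade_block",
    "demo_config",
    "DEMO_TREE",
]

#: One gene during simulation: lineage id, family id, strand (+1/-1),
#: number of duplication events in its history.
Gene = namedtuple("Gene", ["gid", "fam", "strand", "depth"])

#: A simulated genome: chromosome name -> ordered list of Gene.
SimGenome = dict

DEFAULT_RATES = {
    "inversion": 0.02,
    "loss": 0.15,
    "tandem_dup": 0.05,
    "proximal_dup": 0.02,
    "dispersed_dup": 0.02,
}

#: Three-clade demo tree: 6 "magnoliid-like", 4 "eudicot-like" and 2
#: "monocot-like" species, with the first two clades as sisters.
DEMO_TREE = (
    "(((((mag1:0.08,mag2:0.08):0.05,(mag3:0.08,mag4:0.08):0.05):0.05,"
    "(mag5:0.10,mag6:0.10):0.08):0.12,"
    "((eud1:0.08,eud2:0.08):0.06,(eud3:0.08,eud4:0.08):0.06):0.12):0.10,"
    "(mon1:0.12,mon2:0.12):0.20):0.0;"
)

DEMO_CLADES = {
    "magnoliids": ["mag1", "mag2", "mag3", "mag4", "mag5", "mag6"],
    "eudicots": ["eud1", "eud2", "eud3", "eud4"],
    "monocots": ["mon1", "mon2"],
}

# ceil(2/3 · clade size): the proportional presence rule behind the
# ≥4-of-6 / ≥3-of-4 clade filters used for the real 16-species profile.
DEMO_MIN_PRESENCE = {"magnoliids": 4, "eudicots": 3, "monocots": 2}


@dataclass
class SimConfig:
    """Parameters of one simulation run.

    ``tree`` is a Newick string with branch lengths whose leaf labels
    name the species.  ``rates`` are per-gene per-branch-length-unit
    event rates.  ``wgd_branches`` lists branch ids (the label of the
    branch's child node; unlabeled internal nodes get preorder ids
    ``n0, n1, ...``).  ``planted_blocks`` is a list of ``(clade_name,
    length)`` pairs; ``clades`` maps clade names to species lists.
    ``homology_noise`` is ``(false_negative_rate, false_positive_rate)``.
    """

    tree: str
    root_genes: int = 2000
    chromosomes: int = 5
    rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    wgd_branches: list = field(default_factory=list)
    wgd_retention: float = 0.6
    planted_blocks: list = field(default_factory=list)
    clades: dict = field(default_factory=dict)
    homology_noise: tuple = (0.0, 0.0)
    seed: int = 42
    inversion_mean_len: int = 5

    def __post_init__(self):
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("event rates must be >= 0")
        if not 0.0 <= self.wgd_retention <= 1.0:
            raise ValueError("wgd_retention must be in [0, 1]")
        fn, fp = self.homology_noise
        if not (0.0 <= fn < 1.0 and 0.0 <= fp):
            raise ValueError("invalid homology_noise rates")


@dataclass(frozen=True)
class EventRecord:
    """A fully resolved, replayable event.

    ``payload`` contains every random choice already made (gene ids,
    list positions, retained WGD copies), so applying the record is
    deterministic.
    """

    branch: str
    etype: str
    payload: dict


def demo_config(**overrides) -> SimConfig:
    """The default three-clade configuration (12 species, 6/4/2).

    2,000 root gene families on 5 chromosomes, two planted 6-gene
    clade-specific blocks per clade, no WGD, zero homology noise.
    """
    cfg = dict(
        tree=DEMO_TREE,
        root_genes=2000,
        chromosomes=5,
        clades={k: list(v) for k, v in DEMO_CLADES.items()},
        planted_blocks=[
            ("magnoliids", 6),
            ("magnoliids", 6),
            ("eudicots", 6),
            ("eudicots", 6),
            ("monocots", 6),
            ("monocots", 6),
        ],
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


# ---------------------------------------------------------------------------
# event application (shared by simulation and replay)


def _apply_record(genome: SimGenome, rec: EventRecord) -> None:
    """Apply a resolved event record in place."""
    p = rec.payload
    t = rec.etype
    if t == "noop":
        return
    if t == "loss":
        chrom = genome[p["chrom"]]
        genome[p["chrom"]] = [g for g in chrom if g.gid != p["gid"]]
    elif t in ("tandem_dup", "proximal_dup", "dispersed_dup"):
        src = None
        for g in genome[p["src_chrom"]]:
            if g.gid == p["src_gid"]:
                src = g
                break
        if src is None:
            raise ValueError(f"replay: source gene {p['src_gid']} not found")
        copy = Gene(p["new_gid"], src.fam, src.strand, src.depth + 1)
        dest = genome[p["dest_chrom"]]
        dest.insert(min(p["pos"], len(dest)), copy)
    elif t == "inversion":
        chrom = genome[p["chrom"]]
        i, j = p["start"], p["end"]  # inclusive list indices
        seg = [Gene(g.gid, g.fam, -g.strand, g.depth) for g in reversed(chrom[i : j + 1])]
        genome[p["chrom"]] = chrom[:i] + seg + chrom[j + 1 :]
    elif t == "plant":
        chrom = genome[p["chrom"]]
        block = [Gene(gid, fam, 1, 0) for gid, fam in p["genes"]]
        genome[p["chrom"]] = chrom[: p["pos"]] + block + chrom[p["pos"] :]
    elif t == "wgd":
        for new_chrom, copies in p["copies"].items():
            by_gid = {g.gid: g for c in list(genome.values()) for g in c}
            genome[new_chrom] = [
                Gene(new_gid, by_gid[src_gid].fam, by_gid[src_gid].strand,
                     by_gid[src_gid].depth + 1)
                for src_gid, new_gid in copies
            ]
    else:
        raise ValueError(f"unknown event type: {t}")


class _IdSource:
    def __init__(self, start: int):
        self.next = start

    def take(self) -> int:
        v = self.next
        self.next += 1
        return v


def _gene_positions(genome: SimGenome) -> list:
    """(chrom, index) of every gene, in deterministic order."""
    return [(c, i) for c in sorted(genome) for i in range(len(genome[c]))]


def _draw_event(
    genome: SimGenome,
    etype: str,
    rng: np.random.Generator,
    ids: _IdSource,
    branch: str,
    retention: float = 1.0,
    inversion_mean_len: int = 5,
) -> EventRecord:
    """Draw one event's random choices against the current genome state."""
    positions = _gene_positions(genome)
    if not positions and etype != "wgd":
        return EventRecord(branch, "noop", {"reason": f"{etype} on empty genome"})
    if etype == "loss":
        chrom, i = positions[rng.integers(len(positions))]
        return EventRecord(branch, "loss", {"chrom": chrom, "gid": genome[chrom][i].gid})
    if etype == "tandem_dup":
        chrom, i = positions[rng.integers(len(positions))]
        return EventRecord(branch, "tandem_dup", {
            "src_chrom": chrom, "src_gid": genome[chrom][i].gid,
            "dest_chrom": chrom, "pos": i + 1, "new_gid": ids.take(),
        })
    if etype == "proximal_dup":
        chrom, i = positions[rng.integers(len(positions))]
        offset = int(rng.integers(2, 10))  # uniform rank offset in [2, 9]
        return EventRecord(branch, "proximal_dup", {
            "src_chrom": chrom, "src_gid": genome[chrom][i].gid,
            "dest_chrom": chrom, "pos": i + offset, "new_gid": ids.take(),
            "offset": offset,
        })
    if etype == "dispersed_dup":
        chrom, i = positions[rng.integers(len(positions))]
        dest = sorted(genome)[rng.integers(len(genome))]
        pos = int(rng.integers(0, len(genome[dest]) + 1))
        return EventRecord(branch, "dispersed_dup", {
            "src_chrom": chrom, "src_gid": genome[chrom][i].gid,
            "dest_chrom": dest, "pos": pos, "new_gid": ids.take(),
        })
    if etype == "inversion":
        chroms = [c for c in sorted(genome) if genome[c]]
        if not chroms:
            return EventRecord(branch, "noop", {"reason": "inversion on empty genome"})
        chrom = chroms[rng.integers(len(chroms))]
        n = len(genome[chrom])
        start = int(rng.integers(0, n))
        length = int(rng.geometric(1.0 / inversion_mean_len))
        end = min(start + length - 1, n - 1)
        return EventRecord(branch, "inversion", {"chrom": chrom, "start": start, "end": end})
    if etype == "wgd":
        copies = {}
        for chrom in sorted(genome):
            keep = rng.random(len(genome[chrom])) < retention
            retained = [
                (g.gid, ids.take())
                for g, k in zip(genome[chrom], keep)
                if k
            ]
            if retained:
                copies[f"{chrom}_w"] = retained
        return EventRecord(branch, "wgd", {"copies": copies})
    raise ValueError(f"unknown event type: {etype}")


def apply_event(
    genome: SimGenome,
    event: str,
    rng: np.random.Generator,
    *,
    ids: _IdSource | None = None,
    retention: float = 1.0,
    inversion_mean_len: int = 5,
    branch: str = "",
) -> tuple[SimGenome, EventRecord]:
    """Draw and apply one event in place; return (genome, record).

    Events on an empty genome are logged no-ops.  New gene ids come
    from ``ids`` (an internal counter) or continue after the current
    maximum gene id.
    """
    if ids is None:
        gids = [g.gid for c in genome.values() for g in c]
        ids = _IdSource(max(gids) + 1 if gids else 0)
    rec = _draw_event(genome, event, rng, ids, branch,
                      retention=retention, inversion_mean_len=inversion_mean_len)
    _apply_record(genome, rec)
    return genome, rec


def replay(root_genome: SimGenome, records: list) -> SimGenome:
    """Apply a sequence of event records to a copy of ``root_genome``."""
    genome = {c: list(genes) for c, genes in root_genome.items()}
    for rec in records:
        _apply_record(genome, rec)
    return genome


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    tree: str
    family_of: dict  # final gene id -> family id
    species_of: dict  # final gene id -> species
    event_log: dict  # branch id -> list[EventRecord], root->leaf order
    planted: dict  # clade name -> list of planted family ids
    root_genome: SimGenome
    leaf_paths: dict  # species -> list of branch ids root->leaf

    def presence(self) -> pd.DataFrame:
        """True family × species gene-count matrix."""
        fams = pd.Series(self.family_of, name="family")
        sps = pd.Series(self.species_of, name="species")
        df = pd.concat([fams, sps], axis=1)
        return pd.crosstab(df["family"], df["species"])

    def lineage_presence(self) -> pd.DataFrame:
        """True gene-lineage × species presence (bool) matrix.

        Orthologous genes share a lineage id (duplications mint new
        ones), so a lineage is a locus with one syntenic context — the
        granularity at which microsyntenic clusters resolve.
        """
        rows = [
            (int(g.rsplit("_", 1)[1]), sp) for g, sp in self.species_of.items()
        ]
        df = pd.DataFrame(rows, columns=["lineage", "species"])
        return pd.crosstab(df["lineage"], df["species"]) > 0

    def events_for(self, species: str) -> list:
        out = []
        for b in self.leaf_paths[species]:
            out.extend(self.event_log.get(b, []))
        return out

    def duplicate_pairs(self, species: str) -> pd.DataFrame:
        """True (template, copy, mode) pairs where both genes survive.

        Modes follow the classifier vocabulary: tandem → TD, proximal →
        PD, dispersed → DSD, WGD → WGD.  The simulator has no explicit
        transposed events; dispersed duplications subsume them.
        """
        mode_map = {"tandem_dup": "TD", "proximal_dup": "PD",
                    "dispersed_dup": "DSD"}
        present = {
            g for g, sp in self.species_of.items() if sp == species
        }
        gid_of = {}
        for g in present:
            gid_of[int(g.rsplit("_", 1)[1])] = g
        rows = []
        for rec in self.events_for(species):
            if rec.etype in mode_map:
                a = rec.payload["src_gid"]
                b = rec.payload["new_gid"]
                if a in gid_of and b in gid_of:
                    rows.append((gid_of[a], gid_of[b], mode_map[rec.etype]))
            elif rec.etype == "wgd":
                for copies in rec.payload["copies"].values():
                    for a, b in copies:
                        if a in gid_of and b in gid_of:
                            rows.append((gid_of[a], gid_of[b], "WGD"))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mode"])


# ---------------------------------------------------------------------------
# simulation proper


def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    i = 0
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            node.branch_id = node.taxon.label
        elif node.label:
            node.branch_id = node.label
        else:
            node.branch_id = f"n{i}"
        i += 1
    return tree


def _species_distances(tree: dendropy.Tree) -> dict:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    dist = {}
    for a in taxa:
        for b in taxa:
            dist[(a.label, b.label)] = pdm.patristic_distance(a, b) if a is not b else 0.0
    return dist


def plant_clade_block(
    sim_genomes: dict,
    clade: list,
    length: int,
    rng: np.random.Generator,
    ids: _IdSource,
    fam_ids: _IdSource,
) -> dict:
    """Insert a run of ``length`` new-family genes into every clade member.

    The block is placed at homologous relative positions: immediately
    after a host gene whose family is present in all clade members.
    Each of the ``length`` positions is one brand-new single-gene-per-
    species family shared across the clade and absent elsewhere.
    Returns ``{"families": [...], "gids": [...], "records": {species:
    EventRecord}}``; the records make planting replayable.
    """
    if not clade:
        raise ValueError("clade must be nonempty")
    if length < 2:
        raise ValueError("block length must be >= 2")
    fam_sets = []
    for sp in clade:
        fam_sets.append({g.fam for c in sim_genomes[sp].values() for g in c})
    shared = sorted(set.intersection(*fam_sets))
    if not shared:
        raise ValueError("no family shared by all clade members to host the block")
    host_fam = shared[rng.integers(len(shared))]
    new_gids = [ids.take() for _ in range(length)]
    new_fams = [fam_ids.take() for _ in range(length)]
    genes = list(zip(new_gids, new_fams))
    records = {}
    for sp in clade:
        genome = sim_genomes[sp]
        rec = None
        for chrom in sorted(genome):
            for i, g in enumerate(genome[chrom]):
                if g.fam == host_fam:
                    if length > len(genome[chrom]):
                        raise ValueError("block length exceeds chromosome size")
                    rec = EventRecord(sp, "plant",
                                      {"chrom": chrom, "pos": i + 1, "genes": genes})
                    break
            if rec is not None:
                break
        if rec is None:  # host family vanished from this member (cannot happen
            raise ValueError(f"host family {host_fam} missing in {sp}")  # by construction)
        _apply_record(genome, rec)
        records[sp] = rec
    return {"families": new_fams, "gids": new_gids, "records": records}


def _emit_genome(species: str, genome: SimGenome) -> GenomeTable:
    rows = []
    for chrom in sorted(genome):
        for rank, g in enumerate(genome[chrom]):
            start = 1000 * rank + 1
            rows.append((
                f"{species}_{g.gid}", chrom, start, start + 499,
                "+" if g.strand > 0 else "-",
            ))
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    return GenomeTable(species, df)


def _emit_homology(
    leaf_genomes: dict,
    dist: dict,
    noise: tuple,
    rng: np.random.Generator,
) -> pd.DataFrame:
    members = {}
    for sp in sorted(leaf_genomes):
        for chrom in sorted(leaf_genomes[sp]):
            for g in leaf_genomes[sp][chrom]:
                members.setdefault(g.fam, []).append((sp, f"{sp}_{g.gid}", g.depth))
    pairs_a, pairs_b, ds = [], [], []
    for fam in sorted(members):
        mem = members[fam]
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                sa, ga, da = mem[i]
                sb, gb, db = mem[j]
                pairs_a.append(ga)
                pairs_b.append(gb)
                ds.append(dist[(sa, sb)] + 0.25 * (da + db))
    n = len(pairs_a)
    d = np.asarray(ds)
    bitscore = np.maximum(5.0, np.round(100.0 * np.exp(-d) + rng.normal(0, 1.0, n), 1))
    fn, fp = noise
    keep = rng.random(n) >= fn if fn > 0 else np.ones(n, bool)
    df = pd.DataFrame({
        "query_id": pairs_a, "subject_id": pairs_b, "bitscore": bitscore,
    })[keep]
    if fp > 0 and n:
        fam_of = {g: fam for fam, mem in members.items() for _, g, _ in mem}
        all_genes = np.array(sorted(fam_of))
        n_fp = int(round(fp * n))
        ia = rng.integers(0, len(all_genes), n_fp)
        ib = rng.integers(0, len(all_genes), n_fp)
        fa, fb = all_genes[ia], all_genes[ib]
        ok = np.array([fam_of[a] != fam_of[b] for a, b in zip(fa, fb)])
        spurious = pd.DataFrame({
            "query_id": fa[ok], "subject_id": fb[ok],
            "bitscore": np.round(rng.uniform(30, 60, int(ok.sum())), 1),
        })
        df = pd.concat([df, spurious], ignore_index=True)
    df["identity_pct"] = np.round(np.clip(40 + 0.6 * df["bitscore"], 0, 100), 1)
    df["evalue"] = 10.0 ** (-df["bitscore"] / 5.0)
    df["length"] = 300
    df["mismatch"] = 0
    df["gapopen"] = 0
    df["qstart"] = 1
    df["qend"] = 300
    df["sstart"] = 1
    df["send"] = 300
    return df[HIT_COLUMNS].reset_index(drop=True)


def simulate(config: SimConfig) -> tuple[dict, pd.DataFrame, GroundTruth]:
    """Run the simulation.

    Returns ``(genomes, hits, truth)``: a ``{species: GenomeTable}``
    map, an unordered-pair homology hit table in 12-column layout, and
    the :class:`GroundTruth`.  The same seed yields byte-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    tree = _parse_tree(config.tree)
    leaf_names = [t.label for t in tree.taxon_namespace]
    branch_ids = {n.branch_id for n in tree.preorder_node_iter()}
    for b in config.wgd_branches:
        if b not in branch_ids:
            raise ValueError(f"wgd branch id {b!r} not in tree (have {sorted(branch_ids)})")

    # root genome: families 0..root_genes-1 spread evenly over chromosomes
    ids = _IdSource(config.root_genes)
    fam_ids = _IdSource(config.root_genes)
    per_chrom = np.array_split(np.arange(config.root_genes), config.chromosomes)
    root_genome: SimGenome = {
        f"chr{i + 1}": [Gene(int(g), int(g), 1, 0) for g in chunk]
        for i, chunk in enumerate(per_chrom)
    }

    event_log: dict = {}
    leaf_genomes: dict = {}
    leaf_paths: dict = {}

    def descend(node, genome, path):
        for child in node.child_nodes():
            cg = {c: list(genes) for c, genes in genome.items()}
            bid = child.branch_id
            recs = []
            if bid in config.wgd_branches:
                _, rec = apply_event(cg, "wgd", rng, ids=ids,
                                     retention=config.wgd_retention, branch=bid)
                recs.append(rec)
            blen = child.edge.length or 0.0
            n0 = sum(len(g) for g in cg.values())
            sequence = []
            for etype in sorted(config.rates):
                count = rng.poisson(config.rates[etype] * blen * n0)
                sequence.extend([etype] * count)
            rng.shuffle(sequence)
            for etype in sequence:
                _, rec = apply_event(
                    cg, etype, rng, ids=ids,
                    inversion_mean_len=config.inversion_mean_len, branch=bid,
                )
                recs.append(rec)
            event_log[bid] = recs
            if child.is_leaf():
                leaf_genomes[child.taxon.label] = cg
                leaf_paths[child.taxon.label] = path + [bid]
            else:
                descend(child, cg, path + [bid])

    descend(tree.seed_node, root_genome, [])

    planted: dict = {}
    for clade_name, length in config.planted_blocks:
        if clade_name not in config.clades:
            raise ValueError(f"planted block names unknown clade {clade_name!r}")
        info = plant_clade_block(
            leaf_genomes, config.clades[clade_name], length, rng, ids, fam_ids
        )
        planted.setdefault(clade_name, []).extend(info["families"])
        for sp, rec in info["records"].items():
            event_log[sp].append(rec)  # leaf branch id == species name

    genomes = {sp: _emit_genome(sp, leaf_genomes[sp]) for sp in sorted(leaf_genomes)}
    dist = _species_distances(tree)
    hits = _emit_homology(leaf_genomes, dist, config.homology_noise, rng)

    family_of, species_of = {}, {}
    for sp in sorted(leaf_genomes):
        for chrom in sorted(leaf_genomes[sp]):
            for g in leaf_genomes[sp][chrom]:
                gene_id = f"{sp}_{g.gid}"
                family_of[gene_id] = g.fam
                species_of[gene_id] = sp

    truth = GroundTruth(
        tree=config.tree,
        family_of=family_of,
        species_of=species_of,
        event_log=event_log,
        planted=planted,
        root_genome=root_genome,
        leaf_paths=leaf_paths,
    )
    return genomes, hits, truth
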