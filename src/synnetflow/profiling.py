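"""Phylogenomic profiling of microsyntenic clusters.

Turns a clustering into the cluster × species count matrix ``M`` and
its binarization ``B`` (``B[c,s] = 1`` iff species *s* has a gene in
cluster *c*), then supports the profile analyses: between-species
correlation of profiles, intersection ("sharing") counts over clade
combinations, and clade-specific cluster mining.

A clade *has* a cluster when at least ``min_presence`` of its species
carry it; a cluster is *specific* to a clade when it reaches
``min_presence`` inside and at most ``max_outside`` species outside
(default 0 — the strict reading of "specific to").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "PhyloProfile",
    "CladeDefinition",
    "build_profile",
    "species_correlation",
    "sharing_counts",
    "clade_specific_clusters",
]


@dataclass
class PhyloProfile:
    """Cluster × species count matrix and its binarization."""

    counts: pd.DataFrame  # rows: cluster ids, columns: species

    def __post_init__(self):
        if self.counts.index.duplicated().any() or self.counts.columns.duplicated().any():
            raise ValueError("profile labels must be unique")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("profile contains an all-zero cluster row")

    @property
    def binary(self) -> pd.DataFrame:
        return (self.counts > 0).astype(int)

    @property
    def species(self) -> list:
        return list(self.counts.columns)

    @property
    def clusters(self) -> list:
        return list(self.counts.index)


@dataclass
class CladeDefinition:
    """Named, disjoint species sets with per-clade presence thresholds."""

    clades: dict  # name -> list of species
    min_presence: dict = field(default_factory=dict)

    def __post_init__(self):
        names = sorted(self.clades)
        for a, b in combinations(names, 2):
            overlap = set(self.clades[a]) & set(self.clades[b])
            if overlap:
                raise ValueError(f"clades {a} and {b} share species {sorted(overlap)}")
        for name in names:
            thr = self.min_presence.setdefault(name, 1)
            if not 1 <= thr <= len(self.clades[name]):
                raise ValueError(
                    f"min_presence for {name} must be in [1, {len(self.clades[name])}]"
                )


def build_profile(clusters: list, genomes: dict) -> PhyloProfile:
    """Count matrix M[c,s] from a clustering; rows ordered by cluster id."""
    if not clusters:
        raise ValueError("no clusters to profile")
    species_of = {}
    for sp, gt in genomes.items():
        for g in gt.df["gene_id"]:
            species_of[g] = sp
    rows = []
    for cid, members in clusters:
        for g in members:
            rows.append((cid, species_of[g]))
    df = pd.DataFrame(rows, columns=["cluster_id", "species"])
    counts = pd.crosstab(df["cluster_id"], df["species"])
    counts = counts.sort_index().reindex(sorted(counts.columns), axis=1)
    return PhyloProfile(counts)


def species_correlation(profile: PhyloProfile, on: str = "binary") -> pd.DataFrame:
    """Pearson correlation between species profile columns.

    ``on="binary"`` correlates presence/absence columns (the phi
    coefficient); ``on="counts"`` uses the raw gene counts.  A species
    with a zero-variance column gets missing correlations and a
    warning.
    """
    if on == "binary":
        m = profile.binary
    elif on == "counts":
        m = profile.counts
    else:
        raise ValueError(f"unknown correlation basis: {on!r}")
    constant = m.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"zero-variance profile for species {list(m.columns[constant])}; "
            "their correlations are undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = m.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    corr.values[np.ix_(constant.to_numpy(), ~constant.to_numpy())] = np.nan
    corr.values[np.ix_(~constant.to_numpy(), constant.to_numpy())] = np.nan
    return corr


def _qualifying_clades(binary: pd.DataFrame, clades: CladeDefinition) -> pd.Series:
    """Per cluster, the frozenset of clades reaching their threshold."""
    quals = pd.Series([frozenset()] * len(binary), index=binary.index, dtype=object)
    memberships = []
    for name in sorted(clades.clades):
        cols = [s for s in clades.clades[name] if s in binary.columns]
        inside = (binary[cols].sum(axis=1) if cols
                  else pd.Series(0, index=binary.index))
        memberships.append((name, inside >= clades.min_presence[name]))
    for i, c in enumerate(binary.index):
        quals.iloc[i] = frozenset(n for n, m in memberships if bool(m.iloc[i]))
    return quals


def sharing_counts(
    profile: PhyloProfile,
    clades: CladeDefinition,
    drop_species_specific: bool = False,
) -> pd.DataFrame:
    """Cluster counts per clade combination (UpSet-style intersections).

    Each cluster is counted in exactly one combination: the exact set
    of clades in which it reaches the clade's ``min_presence``.  With
    ``drop_species_specific``, clusters present in exactly one species
    are removed first.  Clusters qualifying for no clade are not
    listed; counts therefore sum to the number of qualifying clusters.
    """
    binary = profile.binary
    if drop_species_specific:
        binary = binary[binary.sum(axis=1) > 1]
    quals = _qualifying_clades(binary, clades)
    quals = quals[quals.map(len) > 0]
    combos = quals.map(lambda s: tuple(sorted(s)))
    counts = combos.value_counts().sort_index()
    return pd.DataFrame({
        "clades": counts.index.to_list(),
        "n_clusters": counts.to_numpy(),
    })


def clade_specific_clusters(
    profile: PhyloProfile,
    clade: str,
    clades: CladeDefinition,
    min_presence: int | None = None,
    max_outside: int = 0,
) -> set:
    """Clusters with ≥ min_presence species inside the clade, ≤ max_outside out."""
    if clade not in clades.clades:
        raise ValueError(f"unknown clade {clade!r}")
    if min_presence is None:
        min_presence = clades.min_presence[clade]
    binary = profile.binary
    inside_cols = [s for s in clades.clades[clade] if s in binary.columns]
    outside_cols = [s for s in binary.columns if s not in set(inside_cols)]
    inside = binary[inside_cols].sum(axis=1)
    outside = binary[outside_cols].sum(axis=1) if outside_cols else 0
    mask = (inside >= min_presence) & (outside <= max_outside)
    return set(binary.index[mask])
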