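"""Genome annotation and homology I/O.

Normalizes per-species gene annotations (GFF3 gene rows or BED) into
rank-ordered gene tables — the coordinate system every downstream stage
shares — and reads 12-column tabular similarity hits with self-hit
removal, best-hit deduplication and per-target-species top-k filtering.

Coordinate conventions: GFF3 is 1-based inclusive, BED is 0-based
half-open; both are normalized to 1-based inclusive internally.  The
"gene distance" between two genes on one chromosome is the absolute
difference of their integer ranks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "GenomeTable",
    "read_annotation",
    "read_homology",
    "filter_hits",
    "write_matrix",
    "read_matrix",
    "HIT_COLUMNS",
]

#: Column order of the 12-column tabular hit format (BLAST outfmt 6).
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "identity_pct",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene model with its rank position on its chromosome."""

    gene_id: str
    species: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    rank: int


class GenomeTable:
    """Ordered gene models of one species, with integer rank positions.

    Genes are sorted (chromosome lexicographic, start ascending, end
    ascending, gene_id) and each chromosome's genes get ranks 0..n-1 in
    that order.  The rank, not the base-pair coordinate, is the
    positional substrate for gene-distance rules downstream.
    """

    def __init__(self, species: str, df: pd.DataFrame):
        required = {"gene_id", "chromosome", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
            raise ValueError(f"duplicate gene ids in {species}: {list(dups[:5])}")
        bad = df["start"] > df["end"]
        if bad.any():
            raise ValueError(
                f"start > end for genes {df.loc[bad, 'gene_id'].tolist()[:5]}"
            )
        df = df.sort_values(
            ["chromosome", "start", "end", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = df.groupby("chromosome", sort=False).cumcount()
        self.species = species
        self.df = df
        self._pos: dict[str, tuple[str, int]] = {
            g: (c, r)
            for g, c, r in zip(df["gene_id"], df["chromosome"], df["rank"])
        }

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._pos

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.df["chromosome"].unique())

    def position(self, gene_id: str) -> tuple[str, int]:
        """Return (chromosome, rank) of a gene."""
        return self._pos[gene_id]

    def chromosome_genes(self, chromosome: str) -> list[str]:
        """Gene ids on one chromosome in rank order."""
        sub = self.df[self.df["chromosome"] == chromosome]
        return sub["gene_id"].tolist()

    def gene_distance(self, gene_a: str, gene_b: str) -> int | None:
        """Rank offset |rank_a - rank_b|; None if on different chromosomes."""
        ca, ra = self._pos[gene_a]
        cb, rb = self._pos[gene_b]
        if ca != cb:
            return None
        return abs(ra - rb)

    def records(self) -> Iterator[GeneRecord]:
        for row in self.df.itertuples(index=False):
            yield GeneRecord(
                row.gene_id,
                self.species,
                row.chromosome,
                int(row.start),
                int(row.end),
                row.strand,
                int(row.rank),
            )

    def __repr__(self) -> str:
        return (
            f"GenomeTable({self.species!r}, {len(self)} genes, "
            f"{len(self.chromosomes)} chromosomes)"
        )


_GFF_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_annotation(path, format: str, species: str) -> GenomeTable:
    """Read a GFF3 (type == "gene" rows) or BED annotation into a GenomeTable.

    GFF3 coordinates are taken as 1-based inclusive; BED starts are
    0-based half-open and shifted to 1-based inclusive.  Unsorted input
    is tolerated (rows are sorted internally); a malformed row raises
    with its line number; duplicate gene ids are a hard error.
    """
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format: {format!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "gff3":
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 columns")
                    if fields[2] != "gene":
                        continue
                    m = _GFF_ID_RE.search(fields[8])
                    if not m:
                        raise ValueError("gene row without ID attribute")
                    rows.append(
                        (m.group(1), fields[0], int(fields[3]), int(fields[4]),
                         fields[6] if fields[6] in "+-" else "+")
                    )
                else:
                    if len(fields) < 4:
                        raise ValueError("fewer than 4 columns")
                    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
                    # BED: 0-based half-open -> 1-based inclusive
                    rows.append(
                        (fields[3], fields[0], int(fields[1]) + 1, int(fields[2]), strand)
                    )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])
    return GenomeTable(species, df)


def filter_hits(
    hits: pd.DataFrame,
    top_k: int = 5,
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Normalize a raw hit table: drop self-hits, deduplicate, apply top-k.

    Deduplication keeps, per ordered (query, subject) pair, the hit with
    the highest bitscore (tie: lower evalue, then first occurrence).
    Top-k then retains, per query and per subject species (one global
    pool when ``species_of`` is None), the ``top_k`` best hits by
    bitscore (tie: lower evalue, then lexicographic subject id).
    Idempotent: re-filtering a filtered table is a no-op.
    """
    df = hits[hits["query_id"] != hits["subject_id"]].copy()
    df = df.sort_values(
        ["query_id", "subject_id", "bitscore", "evalue"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop_duplicates(["query_id", "subject_id"], keep="first")
    if species_of is not None:
        df["_sp"] = df["subject_id"].map(species_of)
        if df["_sp"].isna().any():
            unknown = df.loc[df["_sp"].isna(), "subject_id"].unique()
            raise ValueError(f"subject ids with no species mapping: {list(unknown[:5])}")
    else:
        df["_sp"] = ""
    df = df.sort_values(
        ["query_id", "_sp", "bitscore", "evalue", "subject_id"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    df = df.groupby(["query_id", "_sp"], sort=False).head(top_k)
    df = df.drop(columns="_sp")
    return df.sort_values(["query_id", "subject_id"], kind="mergesort").reset_index(drop=True)


def read_homology(
    path,
    top_k: int = 5,
    species_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a 12-column tabular similarity file and filter it.

    Columns follow the BLAST outfmt-6 layout (see :data:`HIT_COLUMNS`).
    Non-numeric score columns raise with the offending line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS, comment="#")
    except Exception as exc:  # delegate format errors with context
        raise ValueError(f"{path}: cannot parse 12-column hit table: {exc}") from None
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, found {df.shape[1]}")
    for col in ("identity_pct", "evalue", "bitscore"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna())[0]) + 1
            raise ValueError(f"{path}: non-numeric {col} at data line {bad}")
        df[col] = vals
    return filter_hits(df, top_k=top_k, species_of=species_of)


def write_matrix(matrix: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write a labelled matrix as TSV or relaxed PHYLIP.

    PHYLIP output is for species × character binary matrices: header
    ``"n_rows n_cols"``, then one ``name<whitespace>row`` per species
    with the characters concatenated.  Writers round-trip bit-exactly
    through :func:`read_matrix`.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("refusing to write an empty matrix")
    if format == "tsv":
        matrix.to_csv(path, sep="\t")
    elif format == "relaxed-phylip":
        too_long = [str(i) for i in matrix.index if len(str(i)) > 250]
        if too_long:
            raise ValueError(f"taxon names over 250 characters: {too_long[:3]}")
        vals = matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("relaxed PHYLIP writer expects a binary matrix")
        with open(path, "w") as fh:
            fh.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
            for name, row in zip(matrix.index, vals):
                fh.write(f"{name}  {''.join(str(int(v)) for v in row)}\n")
    else:
        raise ValueError(f"unknown matrix format: {format!r}")


def read_matrix(path, format: str = "tsv") -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix`."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        # column labels come back as strings; restore integer labels
        if all(str(c).lstrip("-").isdigit() for c in df.columns):
            df.columns = [int(c) for c in df.columns]
        return df
    if format == "relaxed-phylip":
        with open(path) as fh:
            header = fh.readline().split()
            n_rows, n_cols = int(header[0]), int(header[1])
            names, rows = [], []
            for line in fh:
                if not line.strip():
                    continue
                name, chars = line.split(None, 1)
                chars = chars.strip()
                if len(chars) != n_cols:
                    raise ValueError(f"{path}: row {name} has {len(chars)} characters, expected {n_cols}")
                names.append(name)
                rows.append([int(c) for c in chars])
        if len(names) != n_rows:
            raise ValueError(f"{path}: expected {n_rows} rows, found {len(names)}")
        return pd.DataFrame(rows, index=names, columns=range(n_cols))
    raise ValueError(f"unknown matrix format: {format!r}")
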