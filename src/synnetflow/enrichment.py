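"""Functional-term over-representation testing.

One-sided hypergeometric tests (upper tail, computed in log space)
with Benjamini–Hochberg false-discovery-rate control — the standard
over-representation machinery behind GO/KEGG enrichment of gene sets
such as clade-specific clusters or tandem/proximal duplicates.
Depletion is out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_test", "bh_adjust", "enrich"]


def hypergeom_test(k: int, n: int, K: int, M: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(M, K, n).

    ``k`` study hits, ``n`` study size, ``K`` population hits,
    ``M`` population size.  Summation runs in log space for accuracy
    in deep tails.
    """
    if not (0 <= k <= n <= M and k <= K <= M):
        raise ValueError(f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, M={M}")
    if k == 0:
        return 1.0
    top = min(n, K)
    if k > top:
        return 0.0
    logs = hypergeom.logpmf(np.arange(k, top + 1), M, K, n)
    return float(min(1.0, np.exp(logsumexp(logs))))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(study_genes, population_genes, term_map: pd.DataFrame) -> pd.DataFrame:
    """Test every term with ≥1 study gene for over-representation.

    ``term_map`` needs columns ``gene_id`` and ``term_id`` (an optional
    ``term_name`` is carried through).  Study genes must be a subset of
    the population.  Returns one row per tested term with counts,
    raw p and BH FDR, sorted by p ascending.
    """
    study = set(study_genes)
    population = set(population_genes)
    stray = study - population
    if stray:
        raise ValueError(f"study genes absent from population: {sorted(stray)[:5]}")
    tm = term_map[term_map["gene_id"].isin(population)]
    names = {}
    if "term_name" in tm.columns:
        names = dict(zip(tm["term_id"], tm["term_name"]))
    M, n = len(population), len(study)
    rows = []
    for term, genes in tm.groupby("term_id")["gene_id"]:
        gset = set(genes)
        k = len(gset & study)
        if k == 0:
            continue
        K = len(gset)
        rows.append((term, names.get(term, ""), k, n, K, M, hypergeom_test(k, n, K, M)))
    res = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "study_count", "study_size",
                 "population_count", "population_size", "p_value"],
    )
    if len(res):
        res["bh_fdr"] = bh_adjust(res["p_value"].to_numpy())
        res = res.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        res["bh_fdr"] = []
    return res
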