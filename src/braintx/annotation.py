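"""Characterisation of the significant gene list.

Covers gene-set overlap enrichment (Fisher's exact test with BH-FDR over
sets), hub-gene extraction from a confidence-filtered protein-protein
interaction edge list (top decile of degree), and behavioural-relevance
scoring of term activation maps via the mean absolute gene-wise
correlation |r|_mean.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_fdr, extract_sphere_values, pearson_with_p
from .volume import VolumeMap

__all__ = [
    "fisher_overlap",
    "enrich_collection",
    "filter_edges",
    "hub_genes",
    "behavioral_relevance",
]


def fisher_overlap(gene_list, target_set, universe):
    """Two-sided Fisher exact test of the overlap between two gene sets.

    Genes outside the universe are dropped with a warning.  Returns
    ``(overlap_count, odds_ratio, p)`` where the odds ratio is the sample
    cross-product ratio ad/bc (inf when bc = 0 and ad > 0, NaN when both
    products vanish).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    gene_list = set(gene_list)
    target_set = set(target_set)
    stray = (gene_list | target_set) - universe
    if stray:
        warnings.warn(f"dropping {len(stray)} genes outside the universe", stacklevel=2)
        gene_list &= universe
        target_set &= universe

    a = len(gene_list & target_set)
    b = len(gene_list - target_set)
    c = len(target_set - gene_list)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a > 0:
        odds = math.inf  # covers the degenerate full-overlap table
    else:
        odds = math.nan
    return a, odds, float(p)


def enrich_collection(
    gene_list,
    collection: dict[str, list],
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher overlap per set with BH correction across sets."""
    if not collection:
        raise ValueError("gene-set collection must contain at least one set")
    names = sorted(collection)
    rows = []
    for name in names:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, odds, p = fisher_overlap(gene_list, collection[name], universe)
        rows.append({"set": name, "overlap": a, "odds_ratio": odds, "p": p})
    table = pd.DataFrame(rows).set_index("set")
    q, rejected = bh_fdr(table["p"].to_numpy(), alpha=alpha)
    table["q"] = q
    table["significant"] = rejected
    return table.sort_values(["q", "odds_ratio"], ascending=[True, False])


def filter_edges(
    edges: pd.DataFrame,
    min_score: float = 0.9,
    restrict_to=None,
) -> pd.DataFrame:
    """Keep edges with score strictly above ``min_score`` between allowed genes.

    Self-loops and duplicate undirected pairs are removed.
    """
    df = edges.copy()
    df = df[df["score"] > min_score]
    if restrict_to is not None:
        allowed = set(restrict_to)
        df = df[df["gene_a"].isin(allowed) & df["gene_b"].isin(allowed)]
    df = df[df["gene_a"] != df["gene_b"]]
    key = df.apply(lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1) \
        if len(df) else pd.Series(dtype=object)
    df = df.loc[~key.duplicated()] if len(df) else df
    return df.reset_index(drop=True)


def hub_genes(edges: pd.DataFrame, top_frac: float = 0.10) -> pd.DataFrame:
    """Top decile of degree among connected nodes, ties broken by gene id.

    The hub count is ceil(top_frac * number of connected nodes).
    """
    if len(edges) == 0:
        return pd.DataFrame(columns=["gene_id", "degree"]).set_index("gene_id")
    g = nx.Graph()
    g.add_edges_from(zip(edges["gene_a"], edges["gene_b"]))
    degrees = pd.Series(dict(g.degree()), name="degree")
    degrees = degrees[degrees > 0]
    n_hubs = math.ceil(top_frac * len(degrees))
    ranked = degrees.to_frame().assign(gene_id=degrees.index).sort_values(
        ["degree", "gene_id"], ascending=[False, True])
    hubs = ranked.iloc[:n_hubs][["degree"]]
    hubs.index.name = "gene_id"
    return hubs


def behavioral_relevance(
    matrix_sig: pd.DataFrame,
    term_maps: dict[str, VolumeMap],
    coords_mm: np.ndarray,
    radius_mm: float = 3.0,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Rank behavioural terms by mean absolute gene-wise correlation.

    Per term, the activation map is sphere-sampled at the tissue
    coordinates and correlated with every significant gene's expression;
    |r|_mean summarises the term's relevance regardless of sign.  Terms
    with |r|_mean above ``threshold`` are flagged as selected.
    """
    if matrix_sig.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    if matrix_sig.shape[1] < 1:
        raise ValueError("need at least one gene")
    rows = []
    for term, vmap in term_maps.items():
        vals, valid = extract_sphere_values(vmap, coords_mm, radius_mm=radius_mm,
                                            empty_policy="nearest")
        if np.std(vals[valid]) == 0:
            warnings.warn(f"term {term!r} has constant activation; skipped", stacklevel=2)
            continue
        r, _ = pearson_with_p(matrix_sig.loc[valid].to_numpy(), vals[valid])
        r = r[np.isfinite(r)]
        if len(r) == 0:
            continue
        rows.append({"term": term, "abs_r_mean": float(np.mean(np.abs(r))),
                     "n_genes": int(len(r))})
    table = pd.DataFrame(rows, columns=["term", "abs_r_mean", "n_genes"])
    table["selected"] = table["abs_r_mean"] > threshold
    return table.sort_values("abs_r_mean", ascending=False).reset_index(drop=True)
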