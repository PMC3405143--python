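"""Hypergeometric term enrichment over user-supplied term maps.

Mirrors a DAVID-style over-representation analysis: for each term with K
genes in a universe of N, a query list of n genes overlapping the term in k
has p = P(X >= k) under Hypergeometric(N, K, n).  Terms with p below the
reporting threshold are ranked ascending and truncated at the top-ten cut;
raw p-values drive the cut (a BH column is included for reference).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust

__all__ = ["TermMap", "read_term_map", "hypergeom_enrich", "unmeth_in_cell_meth_in_wb"]


class TermMap:
    """Term id -> gene set, with an explicit gene universe."""

    def __init__(self, terms: dict, universe):
        self.universe = frozenset(universe)
        self.terms = {}
        for term, genes in terms.items():
            genes = frozenset(genes)
            stray = genes - self.universe
            if stray:
                raise ValueError(f"term {term!r} has genes outside the universe: {sorted(stray)[:5]}")
            self.terms[term] = genes

    def __len__(self):
        return len(self.terms)


def read_term_map(path, universe=None) -> TermMap:
    """Two-column TSV (term, gene) -> TermMap.  Universe defaults to the
    union of all term genes."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["term", "gene"], dtype=str)
    terms: dict = {}
    for term, gene in zip(df["term"], df["gene"]):
        terms.setdefault(term, set()).add(gene)
    if universe is None:
        universe = set().union(*terms.values()) if terms else set()
    return TermMap(terms, universe)


def hypergeom_enrich(
    gene_list,
    term_map: TermMap,
    alpha_report: float = 0.05,
    top: int = 10,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list against every term.

    Returns the terms with p < alpha_report sorted by ascending p, truncated
    at ``top`` rows, with columns term, K (term size), k (overlap), p, q
    (BH over all tested terms) and the overlapping genes.
    """
    genes = {g.strip() for g in gene_list if g and g.strip()}
    stray = genes - term_map.universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    n_universe = len(term_map.universe)
    n_list = len(genes)
    rows = []
    for term, term_genes in term_map.terms.items():
        k = len(genes & term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(term_genes), n_list))
        rows.append((term, len(term_genes), k, p, ";".join(sorted(genes & term_genes))))
    if not rows:
        return pd.DataFrame(columns=["term", "K", "k", "p", "q", "genes"])
    df = pd.DataFrame(rows, columns=["term", "K", "k", "p", "genes"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return df[df["p"] < alpha_report].head(top)[["term", "K", "k", "p", "q", "genes"]]


def unmeth_in_cell_meth_in_wb(filtered: pd.DataFrame, annotation: pd.DataFrame) -> list:
    """Genes with at least one filtered probe called Unmethylated in the cell
    population and Methylated in whole blood.

    ``filtered`` is a discordance-filtered frame whose call_a is the cell
    population call and call_b the whole-blood call; state matching is
    strict (Marginal does not qualify).  May legitimately be empty.
    """
    hits = filtered[(filtered["call_a"] == "Unmethylated") & (filtered["call_b"] == "Methylated")]
    genes: set = set()
    for probe in hits["probe_id"]:
        genes.update(annotation.loc[probe, "genes"])
    return sorted(genes)
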