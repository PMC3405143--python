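"""Genomic-context classification and region summaries.

Region classes collapse the Illumina RefGene group tokens:
TSS200/TSS1500 -> TSS, 5'UTR/1st exon -> FivePrime, gene body ->
Intragenic, 3'UTR -> ThreePrime, no gene annotation -> Intergenic.  A probe
annotated to several groups (e.g. Body of one gene and TSS200 of another)
is resolved by the precedence TSS > FivePrime > ThreePrime > Intragenic.

CpG context from island intervals (BED, 0-based half-open): inside an
island -> Island, within 2 kb of an edge -> Shore, 2-4 kb -> Shelf,
farther -> OpenSea.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datamodel import REFGENE_GROUPS, pos_to_zero_based

__all__ = [
    "REGION_CLASSES",
    "classify_region",
    "classify_regions",
    "classify_cpg_context",
    "region_distribution",
    "subset_candidate_genes",
]

REGION_CLASSES = ("Intergenic", "TSS", "FivePrime", "Intragenic", "ThreePrime")

_GROUP_TO_REGION = {
    "TSS200": "TSS",
    "TSS1500": "TSS",
    "5UTR": "FivePrime",
    "1stExon": "FivePrime",
    "Body": "Intragenic",
    "3UTR": "ThreePrime",
}
_PRECEDENCE = ("TSS", "FivePrime", "ThreePrime", "Intragenic")

SHORE_BP = 2000
SHELF_BP = 4000


def classify_region(refgene_groups) -> str:
    """Single region class for a probe's RefGene group tokens."""
    groups = list(refgene_groups)
    if not groups:
        return "Intergenic"
    classes = set()
    for g in groups:
        if g not in _GROUP_TO_REGION:
            raise ValueError(f"unknown refgene group token {g!r}")
        classes.add(_GROUP_TO_REGION[g])
    for cls in _PRECEDENCE:
        if cls in classes:
            return cls
    raise AssertionError("unreachable")


def classify_regions(annotation: pd.DataFrame) -> pd.Series:
    """Vectorized region class over a manifest frame."""
    return pd.Series(
        [classify_region(g) for g in annotation["refgene_groups"]],
        index=annotation.index,
        name="region",
    )


def classify_cpg_context(chrom, pos, islands: dict) -> np.ndarray:
    """CpG context of 1-based positions against island intervals.

    ``islands`` maps chromosome -> (starts, ends) in 0-based half-open
    coordinates.  Distance is measured in base pairs from the nearest island
    edge; a position 1 bp past an island end is a Shore.
    """
    chrom = np.asarray(chrom, dtype=object)
    p0 = np.asarray(pos_to_zero_based(pos))
    scalar = p0.ndim == 0
    chrom = np.atleast_1d(chrom)
    p0 = np.atleast_1d(p0)
    out = np.full(len(p0), "OpenSea", dtype=object)
    for c in np.unique(chrom):
        mask = chrom == c
        if c not in islands:
            continue
        starts, ends = islands[c]
        pts = p0[mask]
        # nearest island on/after and before each point
        i = np.searchsorted(starts, pts, side="right") - 1
        dist = np.full(len(pts), np.inf)
        inside = np.zeros(len(pts), dtype=bool)
        valid = i >= 0
        inside[valid] = pts[valid] < ends[i[valid]]
        # gap to the island ending before the point
        dist[valid & ~inside] = pts[valid & ~inside] - ends[i[valid & ~inside]] + 1
        j = np.searchsorted(starts, pts, side="right")
        has_next = j < len(starts)
        nxt = np.full(len(pts), np.inf)
        nxt[has_next] = starts[j[has_next]] - pts[has_next]
        dist = np.minimum(dist, nxt)
        ctx = np.full(len(pts), "OpenSea", dtype=object)
        ctx[dist <= SHELF_BP] = "Shelf"
        ctx[dist <= SHORE_BP] = "Shore"
        ctx[inside] = "Island"
        out[mask] = ctx
    return out[0] if scalar else out


def region_distribution(probe_ids, annotation: pd.DataFrame, calls: pd.Series | None = None) -> pd.DataFrame:
    """Percentage of probes per region class, optionally per call state.

    Returns a DataFrame indexed by region class; one column 'percent' or one
    column per call state.  Each column sums to 100 within rounding; an
    empty stratum is zero with a warning.
    """
    probe_ids = list(probe_ids)
    if not probe_ids:
        warnings.warn("empty probe set; region distribution is all zero", stacklevel=2)
        return pd.DataFrame(0.0, index=list(REGION_CLASSES), columns=["percent"])
    regions = classify_regions(annotation.loc[probe_ids])
    if calls is None:
        counts = regions.value_counts()
        pct = pd.DataFrame(
            {"percent": [100.0 * counts.get(r, 0) / len(probe_ids) for r in REGION_CLASSES]},
            index=list(REGION_CLASSES),
        )
        return pct
    calls = calls.loc[probe_ids]
    from .methcall import CALL_STATES

    states = [s for s in CALL_STATES if s in set(calls)] + sorted(set(calls) - set(CALL_STATES))
    if set(calls) <= set(CALL_STATES):
        states = list(CALL_STATES)
    out = {}
    for state in states:
        sub = regions[calls == state]
        if len(sub) == 0:
            warnings.warn(f"empty call stratum {state!r}", stacklevel=2)
            out[state] = [0.0] * len(REGION_CLASSES)
            continue
        counts = sub.value_counts()
        out[state] = [100.0 * counts.get(r, 0) / len(sub) for r in REGION_CLASSES]
    return pd.DataFrame(out, index=list(REGION_CLASSES))


def subset_candidate_genes(annotation: pd.DataFrame, gene_list) -> tuple:
    """Probes annotated to any listed gene (case-sensitive after whitespace
    strip).

    Returns (probe_ids, per_gene_counts dict, zero_coverage list).  Genes in
    the list absent from the manifest appear in the zero-coverage report
    rather than raising.
    """
    genes = [g.strip() for g in gene_list if g and g.strip()]
    if not genes:
        raise ValueError("empty gene list")
    wanted = set(genes)
    hit_probes = []
    per_gene = {g: 0 for g in genes}
    for probe, probe_genes in zip(annotation.index, annotation["genes"]):
        overlap = wanted & set(probe_genes)
        if overlap:
            hit_probes.append(probe)
            for g in overlap:
                per_gene[g] += 1
    zero = [g for g in genes if per_gene[g] == 0]
    return hit_probes, per_gene, zero
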