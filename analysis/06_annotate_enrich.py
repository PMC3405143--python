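"""Genomic context of the filtered DM probes and term enrichment.

The call-filtered differentially methylated probes concentrate in gene
bodies (the generator plants them that way, emulating the tissue-DMR
pattern).  For the monocyte-like population, the genes with probes
unmethylated in the cell type and methylated in whole blood recover the
planted term as the top enrichment hit.
"""

from pathlib import Path

import pandas as pd

from bloodmeth.annotate import region_distribution
from bloodmeth.datamodel import read_manifest
from bloodmeth.enrich import TermMap, read_term_map, unmeth_in_cell_meth_in_wb

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"

ann = read_manifest(DATA / "manifest.csv")
filtered = pd.read_csv(ROOT / "scratch" / "filtered_probes.tsv", sep="\t")

dm_probes = sorted(set(filtered["probe_id"]))
dist = region_distribution(dm_probes, ann)
dist.round(2).to_csv(ROOT / "results" / "dm_region_distribution.tsv", sep="\t", index_label="region")
print("genomic distribution of filtered DM probes (%):")
print(dist.round(1).to_string())

tm = read_term_map(DATA / "term_map.tsv")
universe = {g for gs in ann["genes"] for g in gs} | tm.universe
tm = TermMap(tm.terms, universe)

rows = []
for pop, sub in filtered.groupby("population"):
    genes = unmeth_in_cell_meth_in_wb(sub, ann)
    genes = [g for g in genes if g in tm.universe]
    if not genes:
        print(f"\n{pop}: no unmethylated-in-cell / methylated-in-whole-blood genes")
        continue
    from bloodmeth.enrich import hypergeom_enrich

    table = hypergeom_enrich(genes, tm)
    rows.append(table.assign(population=pop, n_genes=len(genes)))
    if len(table):
        print(f"\n{pop}: top term {table.iloc[0]['term']} (k={table.iloc[0]['k']}/"
              f"K={table.iloc[0]['K']}, p={table.iloc[0]['p']:.2e}) from {len(genes)} genes")
if rows:
    pd.concat(rows, ignore_index=True).drop(columns=["genes"]).to_csv(
        ROOT / "results" / "enrichment.tsv", sep="\t", index=False
    )
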