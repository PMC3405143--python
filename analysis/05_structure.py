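"""Lineage structure: population dendrogram and per-sample PCA.

Median M-value profiles cluster by hematopoietic lineage (myeloid vs
lymphoid, with the composite fractions joining their dominant members), and
samples separate by population rather than by donor: the mean pairwise
distance within a population (across donors) is well below the mean
distance within a donor (across populations).
"""

from pathlib import Path

import pandas as pd

from bloodmeth.datamodel import MValueMatrix, SampleSheet
from bloodmeth.structure import (
    cluster_populations,
    median_profiles,
    sample_pca,
    within_between_distances,
)

ROOT = Path(__file__).resolve().parents[1]

df = pd.read_csv(ROOT / "scratch" / "mvalues.tsv", sep="\t", index_col=0, comment="#")
m = MValueMatrix(df.index.to_numpy(dtype=object), tuple(df.columns), df.to_numpy())
sheet = SampleSheet.from_frame(pd.read_csv(ROOT / "scratch" / "data" / "samplesheet.csv", comment="#"))

profiles = median_profiles(m, sheet)
newick = cluster_populations(profiles)
(ROOT / "results" / "population_tree.nwk").write_text(newick + "\n")

scores, evr = sample_pca(m)
scores.insert(0, "donor", [dict(zip(sheet.sample_ids, sheet.donor_ids))[s] for s in scores.index])
scores.insert(0, "population", [dict(zip(sheet.sample_ids, sheet.populations))[s] for s in scores.index])
scores.round(3).to_csv(ROOT / "results" / "pca_scores.tsv", sep="\t", index_label="sample_id")

within_pop, within_donor = within_between_distances(m, sheet)
print("tree:", newick)
print("explained variance (PC1-3):", [round(float(v), 3) for v in evr[:3]])
print(f"mean distance within population {within_pop:.1f} < within donor across populations {within_donor:.1f}")
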