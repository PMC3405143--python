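"""Optional full-scale validation against the deposited blood dataset.

Not part of the test suite (requires a download). The 60-sample purified
blood-cell methylation dataset is available from GEO under accession
GSE35069 as a series-matrix file. Given that file and a sample sheet
mapping its GSM columns to donor and population labels, this script runs
the probe-wise moderated-t analysis on all population pairs and compares
the resulting significant-probe count matrix against the published counts
for that dataset by rank agreement (Spearman over the 45 pairs) and order
of magnitude.

Usage:
    python analysis/08_validate_full_scale.py \
        --series-matrix GSE35069_series_matrix.txt \
        --samplesheet gse35069_samples.csv [--beta]

The sample sheet is a CSV with columns sample_id (GSM accession),
donor_id, population — population labels as in bloodmeth.datamodel
(WholeBlood, PBMC, Granulocytes, CD4T, CD8T, CD56NK, CD19B, CD14Mono,
Neutrophils, Eosinophils). Pass --beta when the matrix stores beta values
rather than M-values.
"""

import argparse

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from bloodmeth.datamodel import MValueMatrix, SampleSheet, read_series_matrix
from bloodmeth.diffmeth import all_pairwise
from bloodmeth.preprocess import beta_to_m

# published pairwise significant-probe counts for GSE35069 (q < 0.01),
# row/column order as below
PUBLISHED_ORDER = [
    "WholeBlood", "PBMC", "CD4T", "CD8T", "CD56NK",
    "CD19B", "CD14Mono", "Granulocytes", "Neutrophils", "Eosinophils",
]
PUBLISHED_UPPER = [
    [23226, 58980, 125713, 92238, 97377, 41063, 27365, 28581, 52431],
    [23168, 76847, 33642, 58485, 98771, 94601, 87348, 104631],
    [45015, 38396, 73318, 115235, 109933, 106881, 120620],
    [20629, 98306, 161524, 164184, 182881, 192075],
    [78880, 157180, 154816, 146413, 158727],
    [143376, 147665, 134890, 150548],
    [16011, 17440, 30949],
    [169, 22423],
    [16241],
]


def published_matrix() -> pd.DataFrame:
    n = len(PUBLISHED_ORDER)
    mat = pd.DataFrame(0, index=PUBLISHED_ORDER, columns=PUBLISHED_ORDER)
    for i, row in enumerate(PUBLISHED_UPPER):
        for k, v in enumerate(row):
            j = i + 1 + k
            mat.iloc[i, j] = v
            mat.iloc[j, i] = v
    return mat


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--series-matrix", required=True)
    ap.add_argument("--samplesheet", required=True)
    ap.add_argument("--beta", action="store_true", help="matrix stores beta values")
    ap.add_argument("--alpha", type=float, default=0.01)
    args = ap.parse_args()

    df = read_series_matrix(args.series_matrix)
    sheet = SampleSheet.from_frame(pd.read_csv(args.samplesheet, comment="#"))
    df = df[list(sheet.sample_ids)].dropna()
    values = df.to_numpy(dtype=float)
    if args.beta:
        values = beta_to_m(np.clip(values, 1e-6, 1 - 1e-6))[0]
    m = MValueMatrix(df.index.to_numpy(dtype=object), tuple(sheet.sample_ids), values)

    counts, _ = all_pairwise(m, sheet, alpha=args.alpha)
    counts = counts.loc[PUBLISHED_ORDER, PUBLISHED_ORDER]
    ref = published_matrix()

    iu = np.triu_indices(len(PUBLISHED_ORDER), k=1)
    ours = counts.to_numpy()[iu].astype(float)
    theirs = ref.to_numpy()[iu].astype(float)
    rho = spearmanr(ours, theirs).statistic
    ratio = np.log10(np.maximum(ours, 1) / theirs)

    print(counts.to_string())
    print(f"\nSpearman rank agreement over {len(ours)} pairs: {rho:.3f}")
    print(f"log10 count ratio: median {np.median(ratio):+.2f}, "
          f"range [{ratio.min():+.2f}, {ratio.max():+.2f}]")
    within = float(np.mean(np.abs(ratio) <= 1.0))
    print(f"pairs within one order of magnitude: {100 * within:.0f}%")


if __name__ == "__main__":
    main()
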