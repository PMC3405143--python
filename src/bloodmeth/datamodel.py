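"""Core containers and plain-text readers/writers.

All tabular I/O is TSV/CSV through pandas.  Intensity matrices are probes x
samples with probe identifiers in the first column; the sample sheet fixes
sample order everywhere downstream.  Manifest columns follow the Illumina
450K annotation names (CHR, MAPINFO, UCSC_RefGene_Name, UCSC_RefGene_Group,
Relation_to_UCSC_CpG_Island).

Coordinate conventions: manifest positions (MAPINFO) are 1-based; interval
files (CpG islands as BED) are 0-based half-open.  The single conversion
point is :func:`pos_to_zero_based`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BUILTIN_POPULATIONS",
    "PURE_POPULATIONS",
    "COMPOSITE_POPULATIONS",
    "REFGENE_GROUPS",
    "CPG_CONTEXTS",
    "MethylationDataset",
    "SampleSheet",
    "MValueMatrix",
    "DataValidationError",
    "pos_to_zero_based",
    "read_intensity_tables",
    "write_intensity_tables",
    "read_manifest",
    "read_series_matrix",
    "read_bed_intervals",
]

#: the ten population labels of the blood study design
PURE_POPULATIONS = (
    "CD4T",
    "CD8T",
    "CD56NK",
    "CD19B",
    "CD14Mono",
    "Neutrophils",
    "Eosinophils",
)
COMPOSITE_POPULATIONS = ("WholeBlood", "PBMC", "Granulocytes")
BUILTIN_POPULATIONS = COMPOSITE_POPULATIONS + PURE_POPULATIONS

REFGENE_GROUPS = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR")
CPG_CONTEXTS = ("Island", "Shore", "Shelf", "OpenSea")

#: Illumina relation-to-island tokens, N_/S_ prefixes collapsed
_RELATION_TO_CONTEXT = {
    "Island": "Island",
    "N_Shore": "Shore",
    "S_Shore": "Shore",
    "N_Shelf": "Shelf",
    "S_Shelf": "Shelf",
    "OpenSea": "OpenSea",
    "": "OpenSea",
}

CHANNELS = ("Grn", "Red", "Both")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


def pos_to_zero_based(pos):
    """Convert a 1-based genomic position to a 0-based coordinate."""
    return np.asarray(pos) - 1


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: unique sample id, donor, population label.

    Population labels are an open set; the ten study labels are available as
    :data:`BUILTIN_POPULATIONS`.
    """

    sample_ids: tuple
    donor_ids: tuple
    populations: tuple

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataValidationError("duplicate sample ids in sample sheet")
        if not (len(self.sample_ids) == len(self.donor_ids) == len(self.populations)):
            raise DataValidationError("sample sheet columns have unequal length")
        for s, p in zip(self.sample_ids, self.populations):
            if not p:
                raise DataValidationError(f"sample {s!r} has no population label")

    def __len__(self):
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "donor_id": list(self.donor_ids),
                "population": list(self.populations),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        required = {"sample_id", "donor_id", "population"}
        missing = required - set(df.columns)
        if missing:
            raise DataValidationError(f"sample sheet missing columns: {sorted(missing)}")
        return cls(
            tuple(df["sample_id"].astype(str)),
            tuple(df["donor_id"].astype(str)),
            tuple(df["population"].astype(str)),
        )

    def samples_of(self, population: str) -> list:
        return [s for s, p in zip(self.sample_ids, self.populations) if p == population]

    @property
    def population_set(self):
        # unique labels in first-appearance order
        seen = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return tuple(seen)


@dataclass
class MethylationDataset:
    """Two-channel intensity data: methylated and unmethylated signal.

    ``meth`` and ``unmeth`` are (n_probes, n_samples) float arrays of
    non-negative fluorescence intensities; ``channel`` holds the per-probe
    color-channel label (Grn / Red for single-channel chemistries, Both for
    probes read in both colors).
    """

    probe_ids: np.ndarray
    meth: np.ndarray
    unmeth: np.ndarray
    channel: np.ndarray
    samples: SampleSheet

    def __post_init__(self):
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.meth = np.asarray(self.meth, dtype=float)
        self.unmeth = np.asarray(self.unmeth, dtype=float)
        self.channel = np.asarray(self.channel, dtype=object)
        if self.meth.shape != self.unmeth.shape:
            raise DataValidationError(
                f"meth shape {self.meth.shape} != unmeth shape {self.unmeth.shape}"
            )
        if self.meth.shape[0] != len(self.probe_ids):
            raise DataValidationError("probe id count does not match matrix rows")
        if self.meth.shape[1] != len(self.samples):
            raise DataValidationError("sample sheet length does not match matrix columns")
        if len(self.channel) != len(self.probe_ids):
            raise DataValidationError("channel vector length does not match probes")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise DataValidationError("duplicate probe ids")
        bad = set(self.channel) - set(CHANNELS)
        if bad:
            raise DataValidationError(f"unknown channel labels: {sorted(bad)}")
        if np.isnan(self.meth).any() or np.isnan(self.unmeth).any():
            raise DataValidationError("missing intensities are not allowed")
        if (self.meth < 0).any() or (self.unmeth < 0).any():
            raise DataValidationError("negative intensities")

    @property
    def n_probes(self) -> int:
        return self.meth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]

    def copy(self) -> "MethylationDataset":
        return MethylationDataset(
            self.probe_ids.copy(),
            self.meth.copy(),
            self.unmeth.copy(),
            self.channel.copy(),
            self.samples,
        )


@dataclass
class MValueMatrix:
    """Normalized M-values (log2 meth/unmeth ratio), probes x samples."""

    probe_ids: np.ndarray
    sample_ids: tuple
    values: np.ndarray
    offset: float = 1.0

    def __post_init__(self):
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise DataValidationError("M matrix shape does not match probe/sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=list(self.sample_ids))

    def column(self, sample_id: str) -> np.ndarray:
        j = list(self.sample_ids).index(sample_id)
        return self.values[:, j]


def _read_matrix_tsv(path) -> pd.DataFrame:
    # round_trip parsing: write-then-read must be bit exact
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", float_precision="round_trip")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate probe ids in {path}: {dups[:5]}")
    return df


def read_intensity_tables(meth_path, unmeth_path, samplesheet_path, channel_path=None):
    """Read a methylated/unmethylated TSV pair plus a CSV sample sheet.

    Sample ordering is taken from the sample sheet.  Probes must be present
    (and identically ordered after alignment) in both intensity tables; a
    probe seen in only one file is an error rather than a silent drop.
    """
    meth = _read_matrix_tsv(meth_path)
    unmeth = _read_matrix_tsv(unmeth_path)
    sheet = SampleSheet.from_frame(pd.read_csv(samplesheet_path, comment="#"))

    only_m = set(meth.index) - set(unmeth.index)
    only_u = set(unmeth.index) - set(meth.index)
    if only_m or only_u:
        raise DataValidationError(
            f"probes present in only one channel file: {sorted(only_m | only_u)[:5]}"
        )
    unmeth = unmeth.loc[meth.index]

    for sid in sheet.sample_ids:
        if sid not in meth.columns or sid not in unmeth.columns:
            raise DataValidationError(f"sample not in intensity tables: {sid!r}")
    extra = set(meth.columns) - set(sheet.sample_ids)
    if extra:
        raise DataValidationError(f"sample not in sheet: {sorted(extra)[:5]}")
    meth = meth[list(sheet.sample_ids)]
    unmeth = unmeth[list(sheet.sample_ids)]

    if channel_path is not None:
        ch = pd.read_csv(channel_path, sep="\t", index_col=0, comment="#").iloc[:, 0]
        ch = ch.reindex(meth.index)
        if ch.isna().any():
            raise DataValidationError("channel file missing probes")
        channel = ch.to_numpy(dtype=object)
    else:
        channel = np.full(len(meth.index), "Both", dtype=object)

    return MethylationDataset(
        meth.index.to_numpy(dtype=object),
        meth.to_numpy(dtype=float),
        unmeth.to_numpy(dtype=float),
        channel,
        sheet,
    )


def write_intensity_tables(dataset, meth_path, unmeth_path, samplesheet_path, channel_path=None, header=None):
    """Write a dataset back to the TSV/CSV formats read_intensity_tables accepts.

    Full float precision (repr round-trip) so write-then-read is bit exact.
    """
    cols = list(dataset.samples.sample_ids)
    for mat, path in ((dataset.meth, meth_path), (dataset.unmeth, unmeth_path)):
        df = pd.DataFrame(mat, index=dataset.probe_ids, columns=cols)
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            df.to_csv(fh, sep="\t", index_label="probe_id", float_format="%.17g")
    with open(samplesheet_path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        dataset.samples.to_frame().to_csv(fh, index=False)
    if channel_path is not None:
        with open(channel_path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            pd.DataFrame({"channel": dataset.channel}, index=dataset.probe_ids).to_csv(
                fh, sep="\t", index_label="probe_id"
            )


def _split_semicolons(value) -> list:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    return [tok.strip() for tok in str(value).split(";") if tok.strip()]


def read_manifest(path) -> pd.DataFrame:
    """Read an Illumina-style probe manifest CSV.

    Returns a DataFrame indexed by probe_id with columns chrom (str),
    pos (int, 1-based), genes (list of symbols), refgene_groups (list of
    group tokens), cpg_context (Island/Shore/Shelf/OpenSea).  Multi-gene
    entries are preserved as lists; the per-gene pairing with groups is kept
    positional, as in the vendor annotation.
    """
    raw = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    required = {"probe_id", "CHR", "MAPINFO"}
    missing = required - set(raw.columns)
    if missing:
        raise DataValidationError(f"manifest missing columns: {sorted(missing)}")

    genes = [_split_semicolons(v) for v in raw.get("UCSC_RefGene_Name", [""] * len(raw))]
    groups = [_split_semicolons(v) for v in raw.get("UCSC_RefGene_Group", [""] * len(raw))]
    for probe, gs in zip(raw["probe_id"], groups):
        bad = set(gs) - set(REFGENE_GROUPS)
        if bad:
            raise DataValidationError(
                f"unknown refgene group token(s) {sorted(bad)} for probe {probe!r}"
            )
    for probe, g, gr in zip(raw["probe_id"], genes, groups):
        if bool(g) != bool(gr):
            raise DataValidationError(
                f"probe {probe!r}: refgene groups must be empty iff genes are empty"
            )

    relation = raw.get("Relation_to_UCSC_CpG_Island", pd.Series([""] * len(raw)))
    context = []
    for probe, rel in zip(raw["probe_id"], relation):
        rel = str(rel).strip()
        if rel not in _RELATION_TO_CONTEXT:
            raise DataValidationError(
                f"unknown Relation_to_UCSC_CpG_Island token {rel!r} for probe {probe!r}"
            )
        context.append(_RELATION_TO_CONTEXT[rel])

    pos = pd.to_numeric(raw["MAPINFO"]).astype(int)
    if (pos < 1).any():
        raise DataValidationError("manifest MAPINFO positions must be >= 1 (1-based)")

    out = pd.DataFrame(
        {
            "chrom": raw["CHR"].astype(str).to_numpy(),
            "pos": pos.to_numpy(),
            "genes": genes,
            "refgene_groups": groups,
            "cpg_context": context,
        },
        index=pd.Index(raw["probe_id"], name="probe_id"),
    )
    if out.index.has_duplicates:
        raise DataValidationError("duplicate probe ids in manifest")
    return out


def read_series_matrix(path) -> pd.DataFrame:
    """Read a GEO series-matrix-style TSV into a probes x samples DataFrame.

    Header lines begin with '!'; the value table sits between the
    '!series_matrix_table_begin' and '!series_matrix_table_end' markers.
    Used only for optional full-scale validation against the deposited data.
    """
    begin = end = None
    lines = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            stripped = line.strip()
            if stripped.lower().startswith("!series_matrix_table_begin"):
                begin = i
                lines = []
                continue
            if stripped.lower().startswith("!series_matrix_table_end"):
                end = i
                break
            if begin is not None:
                lines.append(line)
    if begin is None or end is None:
        raise DataValidationError("missing series_matrix_table_begin/end markers")
    if not lines:
        raise DataValidationError("empty series matrix table")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0, na_values=["NA", "null"])
    df.index.name = "probe_id"
    return df


def read_bed_intervals(path) -> dict:
    """Read a BED file (0-based half-open) into {chrom: (starts, ends)} arrays."""
    starts: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            starts.setdefault(chrom, []).append((start, end))
    out = {}
    for chrom, iv in starts.items():
        iv.sort()
        arr = np.array(iv, dtype=int)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out
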