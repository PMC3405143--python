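"""Synthetic leukocyte-mixture methylation data with known ground truth.

The generator emulates the blood study design: seven purified cell
populations plus three composites (whole blood, PBMC, granulocytes) that
are weighted mixtures of the pure profiles, measured for several donors on
a two-channel array.  Mixing is linear in beta space — cell fractions mix
methylated-molecule proportions physically — so the composite M-value is
*not* the weighted mean of pure M-values (the logistic transform breaks
linearity); this distinction is deliberate and tested.

Ground truth features:
  * per-probe base beta drawn from three archetypes (constitutively low
    ~0.1, constitutively high ~0.9, intermediate ~0.5);
  * population-specific planted differential effects (probe, population,
    delta-beta), hypomethylation-biased in myeloid populations as observed
    in blood;
  * a shared myeloid-vs-lymphoid lineage block (hypomethylated in all
    myeloid populations) so clustering has lineage structure;
  * donor effects on the logit scale shared between a donor's pure and
    composite samples (the within-donor design);
  * intensity-level effects: gamma-distributed total intensity, a red
    color-channel bias, additive background;
  * a probe manifest (genes, RefGene groups, island relations consistent
    with a generated island BED) and a term map with one planted enriched
    term covering exactly the genes that carry unmethylated-in-cell /
    methylated-in-whole-blood planted effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    COMPOSITE_POPULATIONS,
    PURE_POPULATIONS,
    MethylationDataset,
    SampleSheet,
    write_intensity_tables,
)

__all__ = [
    "GeneratorConfig",
    "CellMixtureTruth",
    "DEFAULT_WB_WEIGHTS",
    "MYELOID",
    "LYMPHOID",
    "make_truth",
    "mix_populations",
    "simulate_samples",
    "end_to_end_fixture",
]

#: whole-blood mixture weights (fraction of each purified population);
#: neutrophil-dominant, loosely realistic for healthy adult blood
DEFAULT_WB_WEIGHTS = {
    "Neutrophils": 0.60,
    "CD4T": 0.12,
    "CD8T": 0.08,
    "CD56NK": 0.06,
    "CD19B": 0.04,
    "CD14Mono": 0.07,
    "Eosinophils": 0.03,
}

#: members of the two composite fractions
PBMC_MEMBERS = ("CD4T", "CD8T", "CD56NK", "CD19B", "CD14Mono")
GRAN_MEMBERS = ("Neutrophils", "Eosinophils")

MYELOID = ("CD14Mono", "Neutrophils", "Eosinophils")
LYMPHOID = ("CD4T", "CD8T", "CD56NK", "CD19B")

_LN2 = float(np.log(2.0))

# region-class sampling for the manifest: planted probes are gene-body
# enriched (the blood study's observation); background probes less so
_PLANTED_REGION_P = {"Intragenic": 0.60, "TSS": 0.15, "FivePrime": 0.10, "ThreePrime": 0.05, "Intergenic": 0.10}
_BACKGROUND_REGION_P = {"Intragenic": 0.36, "TSS": 0.22, "FivePrime": 0.12, "ThreePrime": 0.08, "Intergenic": 0.22}
_REGION_TO_GROUPS = {
    "TSS": ("TSS200", "TSS1500"),
    "FivePrime": ("5UTR", "1stExon"),
    "Intragenic": ("Body",),
    "ThreePrime": ("3UTR",),
}


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic generator.

    Defaults are the emulated study design: 6 donors, 10 populations,
    neutrophil-dominant whole blood.  Noise defaults (donor_sigma on the
    logit scale, noise_sigma in M units) are sized so the 6-donor mean beta
    tracks truth within ~0.02 for 95% of probes.
    """

    n_probes: int = 20000
    n_donors: int = 6
    archetype_fractions: tuple = (0.4, 0.4, 0.2)  # low, high, intermediate
    n_planted: int | dict = 250  # per pure population (or {population: count})
    delta_beta_range: tuple = (0.45, 0.75)
    hypo_fraction_myeloid: float = 0.85
    hypo_fraction_lymphoid: float = 0.30
    n_lineage: int = 500
    lineage_delta: float = 0.40
    wb_weights: dict = field(default_factory=lambda: dict(DEFAULT_WB_WEIGHTS))
    donor_sigma: float = 0.10  # logit-scale donor effect SD
    noise_sigma: float = 0.08  # M-scale per-sample measurement noise SD
    intensity_scale: float = 10000.0  # mean total intensity per probe
    intensity_shape: float = 8.0
    channel_bias: float = 1.2  # max multiplicative red-channel bias
    background: float = 50.0  # additive residual background level (0 = none)
    n_terms: int = 40
    term_size_range: tuple = (15, 30)
    enrich_population: str = "CD14Mono"
    genic_fraction_planted: float = 0.90
    probes_per_gene: int = 8

    def __post_init__(self):
        if abs(sum(self.archetype_fractions) - 1.0) > 1e-9:
            raise ValueError("archetype fractions must sum to 1")
        w = sum(self.wb_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError("whole-blood weights must sum to 1")
        if any(v < 0 for v in self.wb_weights.values()):
            raise ValueError("negative mixture weight")
        lo, hi = self.delta_beta_range
        if not (0 < lo <= hi < 1):
            raise ValueError("delta_beta_range must satisfy 0 < lo <= hi < 1")


@dataclass
class CellMixtureTruth:
    """Ground truth: profiles, weights, planted effects, annotation, terms."""

    config: GeneratorConfig
    seed: int
    populations: tuple
    beta_profiles: pd.DataFrame  # probes x all populations (pure + composite)
    weights: pd.DataFrame  # composite x pure, rows sum to 1
    planted_dm: pd.DataFrame  # probe_id, population, base_beta, target_beta, delta_beta
    lineage_probes: tuple
    annotation: pd.DataFrame
    islands: dict
    term_map: dict  # term -> sorted gene list
    planted_term: str
    gene_universe: tuple

    @property
    def planted_pairs(self) -> set:
        return set(zip(self.planted_dm["probe_id"], self.planted_dm["population"]))

    def true_delta_vs(self, population: str, reference: str = "WholeBlood") -> pd.Series:
        """True beta difference (population minus reference) per probe."""
        return self.beta_profiles[population] - self.beta_profiles[reference]

    def to_json(self, path):
        payload = {
            "config": asdict(self.config),
            "seed": self.seed,
            "populations": list(self.populations),
            "probe_ids": self.beta_profiles.index.tolist(),
            "beta_profiles": {p: self.beta_profiles[p].tolist() for p in self.beta_profiles},
            "weights": {c: self.weights.loc[c].to_dict() for c in self.weights.index},
            "planted_dm": self.planted_dm.to_dict(orient="list"),
            "lineage_probes": list(self.lineage_probes),
            "annotation": {
                "probe_id": self.annotation.index.tolist(),
                "chrom": self.annotation["chrom"].tolist(),
                "pos": self.annotation["pos"].tolist(),
                "genes": [list(g) for g in self.annotation["genes"]],
                "refgene_groups": [list(g) for g in self.annotation["refgene_groups"]],
                "cpg_context": self.annotation["cpg_context"].tolist(),
            },
            "islands": {c: [list(map(int, s)), list(map(int, e))] for c, (s, e) in self.islands.items()},
            "term_map": {t: sorted(g) for t, g in self.term_map.items()},
            "planted_term": self.planted_term,
            "gene_universe": sorted(self.gene_universe),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "CellMixtureTruth":
        d = json.loads(Path(path).read_text())
        cfg_dict = d["config"]
        for key in ("archetype_fractions", "delta_beta_range", "term_size_range"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = GeneratorConfig(**cfg_dict)
        idx = pd.Index(d["probe_ids"], name="probe_id")
        profiles = pd.DataFrame({p: v for p, v in d["beta_profiles"].items()}, index=idx)
        weights = pd.DataFrame(d["weights"]).T
        annotation = pd.DataFrame(
            {
                "chrom": d["annotation"]["chrom"],
                "pos": d["annotation"]["pos"],
                "genes": d["annotation"]["genes"],
                "refgene_groups": d["annotation"]["refgene_groups"],
                "cpg_context": d["annotation"]["cpg_context"],
            },
            index=pd.Index(d["annotation"]["probe_id"], name="probe_id"),
        )
        islands = {c: (np.array(s), np.array(e)) for c, (s, e) in d["islands"].items()}
        return cls(
            config,
            d["seed"],
            tuple(d["populations"]),
            profiles,
            weights,
            pd.DataFrame(d["planted_dm"]),
            tuple(d["lineage_probes"]),
            annotation,
            islands,
            {t: set(g) for t, g in d["term_map"].items()},
            d["planted_term"],
            tuple(d["gene_universe"]),
        )


def mix_populations(beta_profiles: pd.DataFrame, weights_row: pd.Series) -> pd.Series:
    """Composite beta = weighted sum of pure betas (linear in beta space)."""
    if (weights_row < 0).any():
        raise ValueError("negative mixture weight")
    if abs(weights_row.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    cols = list(weights_row.index)
    return beta_profiles[cols].to_numpy() @ weights_row.to_numpy()


def _composite_weights(wb_weights: dict) -> pd.DataFrame:
    pure = [p for p in PURE_POPULATIONS if p in wb_weights]
    rows = {}
    rows["WholeBlood"] = {p: wb_weights[p] for p in pure}
    pbmc = {p: wb_weights[p] for p in pure if p in PBMC_MEMBERS}
    gran = {p: wb_weights[p] for p in pure if p in GRAN_MEMBERS}
    for name, members in (("PBMC", pbmc), ("Granulocytes", gran)):
        total = sum(members.values())
        if total > 0:
            rows[name] = {p: members.get(p, 0.0) / total for p in pure}
    return pd.DataFrame(rows).T.fillna(0.0)[pure]


def _sample_region(rng, probs: dict) -> str:
    classes = list(probs)
    return classes[rng.choice(len(classes), p=np.array([probs[c] for c in classes]))]


def _build_annotation(rng, probe_ids, planted_mask, config):
    """Manifest with genes, groups, positions and a consistent island BED."""
    n = len(probe_ids)
    n_genes = max(20, n // config.probes_per_gene)
    gene_names = [f"GENE{i:05d}" for i in range(n_genes)]

    chroms = [str(c) for c in range(1, 23)]
    chrom_of = np.array([chroms[i % len(chroms)] for i in range(n)], dtype=object)
    chrom_len = 10_000_000
    pos = rng.integers(1, chrom_len, size=n)  # 1-based

    # islands: 1 kb long, every 40 kb, per chromosome (0-based half-open)
    starts = np.arange(20_000, chrom_len - 20_000, 40_000)
    ends = starts + 1000
    islands = {c: (starts.copy(), ends.copy()) for c in chroms}

    from .annotate import classify_cpg_context

    context = classify_cpg_context(chrom_of, pos, islands)
    side = np.where((pos - 1) % 40_000 < 20_000 + 500, "S", "N")  # downstream vs upstream of nearest
    relation = []
    for ctx, sd in zip(context, side):
        if ctx in ("Shore", "Shelf"):
            relation.append(f"{sd}_{ctx}")
        elif ctx == "Island":
            relation.append("Island")
        else:
            relation.append("OpenSea")

    genes, groups = [], []
    for i in range(n):
        probs = _PLANTED_REGION_P if planted_mask[i] else _BACKGROUND_REGION_P
        region = _sample_region(rng, probs)
        if region == "Intergenic":
            genes.append([])
            groups.append([])
        else:
            gene = gene_names[int(rng.integers(0, n_genes))]
            token = _REGION_TO_GROUPS[region][int(rng.integers(0, len(_REGION_TO_GROUPS[region])))]
            genes.append([gene])
            groups.append([token])

    annotation = pd.DataFrame(
        {
            "chrom": chrom_of,
            "pos": pos,
            "genes": genes,
            "refgene_groups": groups,
            "cpg_context": context,
            "relation": relation,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return annotation, islands, gene_names


def make_truth(config: GeneratorConfig | None = None, seed: int = 0) -> CellMixtureTruth:
    """Build the deterministic ground truth for one simulated study."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = config.n_probes
    probe_ids = np.array([f"cg{i:07d}" for i in range(n)], dtype=object)

    # archetype base betas
    frac_low, frac_high, frac_mid = config.archetype_fractions
    arch = rng.choice(3, size=n, p=[frac_low, frac_high, frac_mid])
    base = np.empty(n)
    base[arch == 0] = rng.beta(2, 18, size=(arch == 0).sum())
    base[arch == 1] = rng.beta(18, 2, size=(arch == 1).sum())
    base[arch == 2] = rng.beta(3, 3, size=(arch == 2).sum())
    base = np.clip(base, 0.02, 0.98)

    pure = [p for p in PURE_POPULATIONS if p in config.wb_weights]
    profiles = {p: base.copy() for p in pure}

    lo, hi = config.delta_beta_range
    taken = np.zeros(n, dtype=bool)

    # lineage block: hypomethylated in all myeloid populations
    lineage_probes = []
    if config.n_lineage > 0:
        eligible = np.flatnonzero((base - config.lineage_delta >= 0.01) & (base >= 0.7) & ~taken)
        if len(eligible) < config.n_lineage:
            raise ValueError("not enough probes eligible for the lineage block")
        pick = rng.choice(eligible, size=config.n_lineage, replace=False)
        taken[pick] = True
        lineage_probes = probe_ids[pick].tolist()
        for p in pure:
            if p in MYELOID:
                profiles[p][pick] = np.clip(base[pick] - config.lineage_delta, 0.01, 0.99)

    # population-specific planted effects
    planted_rows = []
    for p in pure:
        hypo = config.hypo_fraction_myeloid if p in MYELOID else config.hypo_fraction_lymphoid
        n_pop = config.n_planted if isinstance(config.n_planted, int) else config.n_planted.get(p, 0)
        n_down = int(round(n_pop * hypo))
        n_up = n_pop - n_down
        for direction, count in (("down", n_down), ("up", n_up)):
            if count == 0:
                continue
            if direction == "down":
                eligible = np.flatnonzero((base - lo >= 0.01) & ~taken)
            else:
                eligible = np.flatnonzero((base + lo <= 0.99) & ~taken)
            if len(eligible) < count:
                raise ValueError(
                    f"infeasible delta_beta: only {len(eligible)} probes can take a "
                    f"{direction} effect of at least {lo} for population {p}"
                )
            pick = rng.choice(eligible, size=count, replace=False)
            taken[pick] = True
            for idx in pick:
                if direction == "down":
                    dmax = min(hi, base[idx] - 0.01)
                    delta = -rng.uniform(lo, dmax)
                else:
                    dmax = min(hi, 0.99 - base[idx])
                    delta = rng.uniform(lo, dmax)
                target = base[idx] + delta
                profiles[p][idx] = target
                planted_rows.append((probe_ids[idx], p, float(base[idx]), float(target), float(delta)))

    planted_dm = pd.DataFrame(
        planted_rows, columns=["probe_id", "population", "base_beta", "target_beta", "delta_beta"]
    )

    pure_df = pd.DataFrame(profiles, index=pd.Index(probe_ids, name="probe_id"))
    weights = _composite_weights(config.wb_weights)
    all_profiles = pure_df.copy()
    for comp in weights.index:
        all_profiles[comp] = mix_populations(pure_df, weights.loc[comp])

    planted_mask = np.isin(probe_ids, planted_dm["probe_id"].unique())
    annotation, islands, gene_names = _build_annotation(rng, probe_ids, planted_mask, config)

    # term map: planted term = genes carrying unmethylated-in-cell /
    # methylated-in-whole-blood planted effects of the enrichment population
    target_pop = config.enrich_population
    enrich_plants = planted_dm[
        (planted_dm["population"] == target_pop)
        & (planted_dm["delta_beta"] < 0)
        & (planted_dm["base_beta"] >= 0.7)
    ]
    planted_genes: set = set()
    for probe in enrich_plants["probe_id"]:
        planted_genes.update(annotation.loc[probe, "genes"])
    universe = set(gene_names)
    term_map: dict = {}
    lo_t, hi_t = config.term_size_range
    for t in range(config.n_terms):
        size = int(rng.integers(lo_t, hi_t + 1))
        term_map[f"TERM{t:03d}"] = set(rng.choice(gene_names, size=size, replace=False))
    planted_term = "TERM_PLANTED"
    if planted_genes:
        term_map[planted_term] = set(planted_genes)

    pops = tuple(list(weights.index) + pure)
    return CellMixtureTruth(
        config,
        seed,
        pops,
        all_profiles,
        weights,
        planted_dm,
        tuple(lineage_probes),
        annotation,
        islands,
        term_map,
        planted_term,
        tuple(sorted(universe)),
    )


def _logit(b):
    return np.log(b) - np.log1p(-b)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_samples(truth: CellMixtureTruth, n_donors: int | None = None, seed: int = 0) -> MethylationDataset:
    """Simulate two-channel intensities for every donor x population.

    Donor effects perturb logit(beta) per (donor, probe) and are shared
    between that donor's pure and composite samples; measurement noise
    (M-scale SD ``noise_sigma``) is per sample.  Intensities:
    meth = beta * T * bias, unmeth = (1 - beta) * T * bias, with
    T ~ Gamma(shape, scale) per probe-sample, a red-channel bias per sample,
    and additive background.
    """
    cfg = truth.config
    n_donors = n_donors or cfg.n_donors
    rng = np.random.default_rng(seed)
    n = len(truth.beta_profiles)
    pure = list(truth.weights.columns)
    composites = list(truth.weights.index)
    pops = composites + pure

    probe_ids = truth.beta_profiles.index.to_numpy(dtype=object)
    channel = rng.choice(np.array(["Grn", "Red", "Both"], dtype=object), size=n, p=[0.3, 0.3, 0.4])
    red = channel == "Red"

    # per-donor, per-probe effect on the logit scale, shared across populations
    donor_eff = rng.normal(0.0, cfg.donor_sigma, size=(n_donors, n)) if cfg.donor_sigma > 0 else np.zeros((n_donors, n))

    sample_ids, donor_ids, pop_labels = [], [], []
    meth_cols, unmeth_cols = [], []
    pure_beta_cache = {}
    for d in range(n_donors):
        for p in pure:
            b = truth.beta_profiles[p].to_numpy()
            pure_beta_cache[(d, p)] = _expit(_logit(np.clip(b, 1e-6, 1 - 1e-6)) + donor_eff[d])
        for p in pops:
            if p in composites:
                w = truth.weights.loc[p]
                beta_d = np.zeros(n)
                for q in pure:
                    if w[q] > 0:
                        beta_d = beta_d + w[q] * pure_beta_cache[(d, q)]
            else:
                beta_d = pure_beta_cache[(d, p)]
            if cfg.noise_sigma > 0:
                eps = rng.normal(0.0, cfg.noise_sigma * _LN2, size=n)
                beta_s = _expit(_logit(np.clip(beta_d, 1e-9, 1 - 1e-9)) + eps)
            else:
                beta_s = beta_d
            t = rng.gamma(cfg.intensity_shape, cfg.intensity_scale / cfg.intensity_shape, size=n)
            bias = rng.uniform(1.0, cfg.channel_bias) if cfg.channel_bias > 1 else 1.0
            scale = np.where(red, bias, 1.0)
            meth = beta_s * t * scale
            unmeth = (1.0 - beta_s) * t * scale
            if cfg.background > 0:
                meth = meth + rng.gamma(4.0, cfg.background / 4.0, size=n)
                unmeth = unmeth + rng.gamma(4.0, cfg.background / 4.0, size=n)
            sample_ids.append(f"{p}_D{d+1}")
            donor_ids.append(f"D{d+1}")
            pop_labels.append(p)
            meth_cols.append(meth)
            unmeth_cols.append(unmeth)

    sheet = SampleSheet(tuple(sample_ids), tuple(donor_ids), tuple(pop_labels))
    return MethylationDataset(
        probe_ids,
        np.column_stack(meth_cols),
        np.column_stack(unmeth_cols),
        channel,
        sheet,
    )


def _write_manifest_csv(annotation: pd.DataFrame, path):
    rows = []
    for probe, row in annotation.iterrows():
        rows.append(
            {
                "probe_id": probe,
                "CHR": row["chrom"],
                "MAPINFO": row["pos"],
                "UCSC_RefGene_Name": ";".join(row["genes"]),
                "UCSC_RefGene_Group": ";".join(row["refgene_groups"]),
                "Relation_to_UCSC_CpG_Island": row.get("relation", row["cpg_context"]),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


TINY_CONFIG = dict(
    n_probes=500,
    n_donors=3,
    n_planted=20,
    n_lineage=30,
    n_terms=8,
    term_size_range=(4, 8),
    probes_per_gene=5,
    wb_weights={"Neutrophils": 0.6, "CD4T": 0.2, "CD14Mono": 0.2},
)


def end_to_end_fixture(scale: str = "tiny", outdir=".", seed: int = 0, config: GeneratorConfig | None = None):
    """Write a complete input-file set (intensities, sample sheet, manifest,
    islands BED, candidate gene list, term map, truth JSON) to ``outdir``.

    ``tiny`` is a 500-probe, 3-donor, 4-population smoke fixture; ``default``
    is the full emulated design (20,000 probes, 6 donors, 10 populations).
    """
    if config is None:
        if scale == "tiny":
            config = GeneratorConfig(**TINY_CONFIG)
        elif scale == "default":
            config = GeneratorConfig()
        else:
            raise ValueError(f"unknown scale {scale!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = make_truth(config, seed=seed)
    dataset = simulate_samples(truth, seed=seed + 1)

    write_intensity_tables(
        dataset,
        outdir / "meth.tsv",
        outdir / "unmeth.tsv",
        outdir / "samplesheet.csv",
        outdir / "channel.tsv",
        header=f"bloodmeth synthetic fixture seed={seed}",
    )
    _write_manifest_csv(truth.annotation, outdir / "manifest.csv")
    with open(outdir / "islands.bed", "w") as fh:
        for chrom, (starts, ends) in truth.islands.items():
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\n")
    genic = sorted({g for gs in truth.annotation["genes"] for g in gs})
    (outdir / "genes.txt").write_text("\n".join(genic[: max(10, len(genic) // 10)]) + "\n")
    with open(outdir / "term_map.tsv", "w") as fh:
        for term, genes in truth.term_map.items():
            for g in sorted(genes):
                fh.write(f"{term}\t{g}\n")
    truth.to_json(outdir / "truth.json")
    return truth, dataset
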