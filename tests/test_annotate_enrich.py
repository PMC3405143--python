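"""Region classification, CpG context, candidate genes, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from bloodmeth.annotate import (
    REGION_CLASSES,
    classify_cpg_context,
    classify_region,
    region_distribution,
    subset_candidate_genes,
)
from bloodmeth.datamodel import REFGENE_GROUPS
from bloodmeth.enrich import TermMap, hypergeom_enrich, read_term_map, unmeth_in_cell_meth_in_wb


def _expected_region(groups):
    """Independent restatement of the collapse + precedence rule."""
    if not groups:
        return "Intergenic"
    if {"TSS200", "TSS1500"} & set(groups):
        return "TSS"
    if {"5UTR", "1stExon"} & set(groups):
        return "FivePrime"
    if "3UTR" in groups:
        return "ThreePrime"
    return "Intragenic"


class TestRegion:
    def test_exhaustive_over_all_group_subsets(self):
        for r in range(len(REFGENE_GROUPS) + 1):
            for subset in itertools.combinations(REFGENE_GROUPS, r):
                assert classify_region(subset) == _expected_region(subset)

    @pytest.mark.parametrize(
        "groups, expected",
        [
            (["TSS1500"], "TSS"),
            (["1stExon"], "FivePrime"),
            (["Body", "TSS200"], "TSS"),
            ([], "Intergenic"),
        ],
    )
    def test_worked_examples(self, groups, expected):
        assert classify_region(groups) == expected

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError, match="EXON9"):
            classify_region(["EXON9"])


class TestCpGContext:
    # one island occupying 0-based [1000, 2000)
    ISLANDS = {"1": (np.array([1000]), np.array([2000]))}

    @pytest.mark.parametrize(
        "pos_1based, expected",
        [
            (1500, "Island"),
            (1001, "Island"),  # first island base
            (2000, "Island"),  # last island base (0-based 1999)
            (2001, "Shore"),  # 1 bp past the end
            (4000, "Shore"),  # 2000 bp past the end
            (4001, "Shelf"),
            (6000, "Shelf"),  # 4000 bp past the end
            (6001, "OpenSea"),
            (1000, "Shore"),  # 1 bp before the start
            (9, "Shore"),  # 992 bp upstream of the start
        ],
    )
    def test_boundary_enumeration(self, pos_1based, expected):
        assert classify_cpg_context("1", pos_1based, self.ISLANDS) == expected

    def test_unknown_chromosome_is_open_sea(self):
        assert classify_cpg_context("2", 1500, self.ISLANDS) == "OpenSea"


def _annotation(rows):
    return pd.DataFrame(
        {
            "chrom": ["1"] * len(rows),
            "pos": range(1, len(rows) + 1),
            "genes": [r[0] for r in rows],
            "refgene_groups": [r[1] for r in rows],
            "cpg_context": ["OpenSea"] * len(rows),
        },
        index=pd.Index([f"cg{i}" for i in range(len(rows))], name="probe_id"),
    )


class TestRegionDistribution:
    def test_one_probe_per_class(self):
        ann = _annotation(
            [(["G"], ["TSS200"]), (["G"], ["5UTR"]), (["G"], ["Body"]), (["G"], ["3UTR"])]
        )
        dist = region_distribution(ann.index, ann)
        assert dist.loc["TSS", "percent"] == 25.0
        assert dist.loc["Intergenic", "percent"] == 0.0
        assert dist["percent"].sum() == pytest.approx(100.0)

    def test_split_by_call_with_empty_stratum(self):
        ann = _annotation([(["G"], ["Body"]), (["G"], ["Body"])])
        calls = pd.Series(["Unmethylated", "Unmethylated"], index=ann.index)
        with pytest.warns(UserWarning, match="empty call stratum"):
            dist = region_distribution(ann.index, ann, calls=calls)
        assert dist.loc["Intragenic", "Unmethylated"] == 100.0
        assert (dist["Methylated"] == 0).all()

    def test_empty_probe_set_warns(self):
        ann = _annotation([(["G"], ["Body"])])
        with pytest.warns(UserWarning, match="empty"):
            dist = region_distribution([], ann)
        assert (dist["percent"] == 0).all()


class TestCandidateGenes:
    ANN = _annotation(
        [
            (["GENE1"], ["Body"]),
            (["GENE1"], ["TSS200"]),
            (["GENE1", "GENE2"], ["Body", "Body"]),
            (["GENE2"], ["3UTR"]),
            ([], []),
        ]
    )

    def test_single_gene_probe_count(self):
        probes, per_gene, zero = subset_candidate_genes(self.ANN, ["GENE1"])
        assert len(probes) == 3 and per_gene["GENE1"] == 3 and zero == []

    def test_absent_gene_reported_not_raised(self):
        probes, per_gene, zero = subset_candidate_genes(self.ANN, ["GENE1", "GENEX"])
        assert zero == ["GENEX"] and len(probes) == 3

    def test_shared_probe_counted_once_in_union(self):
        probes, per_gene, _ = subset_candidate_genes(self.ANN, ["GENE1", "GENE2"])
        assert len(probes) == 4  # union; cg2 shared
        assert per_gene["GENE1"] == 3 and per_gene["GENE2"] == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            subset_candidate_genes(self.ANN, ["  "])


def hypergeom_enumeration(n_universe, term, query):
    """Exact P(X >= k) by enumerating all draws of |query| genes."""
    k_obs = len(set(term) & set(query))
    total = 0
    at_least = 0
    for draw in itertools.combinations(range(n_universe), len(query)):
        total += 1
        if len(set(draw) & set(term)) >= k_obs:
            at_least += 1
    return at_least / total


class TestHypergeom:
    def test_exact_enumeration_all_small_universes(self):
        rng = np.random.default_rng(7)
        for n_universe in range(4, 13):
            genes = [f"g{i}" for i in range(n_universe)]
            for _ in range(4):
                k_term = int(rng.integers(1, n_universe))
                n_query = int(rng.integers(1, n_universe))
                term = list(rng.choice(n_universe, size=k_term, replace=False))
                query = list(rng.choice(n_universe, size=n_query, replace=False))
                tm = TermMap({"T": [genes[i] for i in term]}, genes)
                table = hypergeom_enrich([genes[i] for i in query], tm, alpha_report=1.1)
                expected = hypergeom_enumeration(n_universe, term, query)
                assert table.iloc[0]["p"] == pytest.approx(expected, abs=1e-12)

    def test_full_overlap_worked_cases(self):
        genes10 = [f"g{i}" for i in range(10)]
        tm = TermMap({"T": genes10[:5]}, genes10)
        table = hypergeom_enrich(genes10[:5], tm)
        assert table.iloc[0]["p"] == pytest.approx(1 / math.comb(10, 5))  # 1/252

        genes4 = [f"g{i}" for i in range(4)]
        tm4 = TermMap({"T": genes4[:2]}, genes4)
        table4 = hypergeom_enrich(genes4[:2], tm4, alpha_report=1.1)
        assert table4.iloc[0]["p"] == pytest.approx(1 / 6)

    def test_zero_overlap_gives_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        tm = TermMap({"T": genes[:3]}, genes)
        table = hypergeom_enrich(genes[5:7], tm, alpha_report=1.1)
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        tm = TermMap({"T": ["g0"]}, ["g0", "g1"])
        with pytest.raises(ValueError, match="outside the universe"):
            hypergeom_enrich(["gX"], tm)

    def test_term_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            TermMap({"T": ["gX"]}, ["g0"])

    def test_read_term_map(self, tmp_path):
        path = tmp_path / "terms.tsv"
        path.write_text("T1\tg0\nT1\tg1\nT2\tg1\n")
        tm = read_term_map(path)
        assert tm.terms["T1"] == {"g0", "g1"} and tm.universe == {"g0", "g1"}


class TestUnmethInCell:
    ANN = _annotation([(["GENE1"], ["Body"]), (["GENE2"], ["Body"]), (["GENE3"], ["Body"])])

    def _filtered(self, pairs):
        return pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(len(pairs))],
                "call_a": [a for a, _ in pairs],
                "call_b": [b for _, b in pairs],
            }
        )

    def test_strict_state_match(self):
        kept = self._filtered(
            [
                ("Unmethylated", "Methylated"),  # qualifies -> GENE1
                ("Unmethylated", "Marginal"),  # excluded
                ("Methylated", "Unmethylated"),  # excluded (wrong direction)
            ]
        )
        assert unmeth_in_cell_meth_in_wb(kept, self.ANN) == ["GENE1"]

    def test_no_qualifying_probes_is_empty_list(self):
        kept = self._filtered([("Methylated", "Methylated")])
        assert unmeth_in_cell_meth_in_wb(kept, self.ANN) == []
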