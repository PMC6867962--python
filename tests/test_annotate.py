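"""Region classification, pfSNP decision table, gene-set derivation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from popdiff_pgx.annotate import (
    REGION_EVIDENCE,
    classify_snp_regions,
    derive_gene_sets,
    is_potentially_functional,
    pf_mask,
    promoter_window,
)
from popdiff_pgx.config import EVIDENCE_CATEGORIES, SimulationConfig
from popdiff_pgx.fst import PdCallSet
from popdiff_pgx.simulate import simulate_evidence_flags, simulate_gene_annotation

from conftest import make_snps


class TestClassifySnpRegions:
    def test_promoter_window_plus_strand(self, gene_fixture):
        genes, features = gene_fixture
        assert promoter_window(10_000, "+") == (4_500, 9_999)
        ann = classify_snp_regions(make_snps([("s1", 6_000)]), genes, features)
        assert ann.iloc[0].tolist() == ["s1", "gA", "promoter"]

    def test_promoter_window_minus_strand(self, gene_fixture):
        genes, features = gene_fixture
        assert promoter_window(60_000, "-") == (60_001, 65_500)
        ann = classify_snp_regions(make_snps([("s1", 62_000)]), genes, features)
        assert ann.iloc[0].tolist() == ["s1", "gB", "promoter"]

    @pytest.mark.parametrize("pos,cons,region", [
        (10_200, "", "utr5"),
        (11_000, "nonsynonymous", "nsSNP"),
        (11_000, "synonymous", "sSNP"),
        (14_000, "", "intron"),
        (19_500, "", "utr3"),
        (41_000, "", "utr3"),          # - strand: 3'UTR at the low end
        (59_500, "", "utr5"),
        (100_000, "", "intergenic"),
    ])
    def test_region_assignment(self, gene_fixture, pos, cons, region):
        genes, features = gene_fixture
        ann = classify_snp_regions(make_snps([("s1", pos, cons)]), genes, features)
        assert ann.iloc[0]["region"] == region

    def test_exon_takes_precedence_over_neighbor_promoter(self):
        # gB's promoter window overlaps gA's exon; the SNP annotates to both
        genes = pd.DataFrame({
            "gene_id": ["gA", "gB"], "chrom": ["1", "1"], "strand": ["+", "+"],
            "tss": [1_000, 8_000], "start": [1_000, 8_000], "end": [5_000, 9_000],
        })
        features = pd.DataFrame(
            [("gA", "exon", 1_000, 5_000), ("gB", "exon", 8_000, 9_000)],
            columns=["gene_id", "feature", "start", "end"])
        ann = classify_snp_regions(make_snps([("s1", 4_000, "nonsynonymous")]),
                                   genes, features)
        by_gene = ann.set_index("gene_id")["region"]
        assert by_gene["gA"] == "nsSNP"
        assert by_gene["gB"] == "promoter"

    def test_unknown_chromosome_is_intergenic_and_counted(self, gene_fixture):
        genes, features = gene_fixture
        snps = pd.DataFrame({"snp_id": ["s1"], "chrom": ["99"], "pos": [11_000],
                             "consequence": [""]})
        ann = classify_snp_regions(snps, genes, features)
        assert ann.iloc[0]["region"] == "intergenic"
        assert ann.attrs["n_unknown_chrom"] == 1

    def test_agrees_with_generator_truth(self):
        config = SimulationConfig(
            populations=("A", "B"), sample_sizes=(10, 10), n_snps=3_000,
            n_genes=40, chrom_length=4_000_000, n_drugs=5, seed=17)
        genes, features, snps = simulate_gene_annotation(config)
        ann = classify_snp_regions(snps, genes, features)
        precedence = {"nsSNP": 0, "sSNP": 0, "utr5": 1, "utr3": 1,
                      "intron": 2, "promoter": 3, "intergenic": 4}
        best = ann.loc[ann.groupby("snp_id")["region"].transform(
            lambda r: r.map(precedence)).groupby(ann["snp_id"]).idxmin()]
        best = best.set_index("snp_id")["region"]
        truth = snps.set_index("snp_id")["true_region"]
        assert (best.loc[truth.index] == truth).all()


class TestDecisionTable:
    # independent truth: explicit boolean expression per region
    ORACLE = {
        "nsSNP": lambda f: f["deleterious"] or f["domain_or_functional_region"]
        or f["modification_site"] or f["nmd_or_ese_ess"] or f["natural_selection_region"],
        "sSNP": lambda f: f["codon_usage_bias"] or f["domain_or_functional_region"]
        or f["modification_site"] or f["nmd_or_ese_ess"] or f["natural_selection_region"],
        "utr5": lambda f: f["tfbs_altering"] or f["natural_selection_region"],
        "promoter": lambda f: f["tfbs_altering"] or f["natural_selection_region"],
        "utr3": lambda f: f["utr3_conserved"] or f["mirna_binding"]
        or f["natural_selection_region"],
        "intron": lambda f: f["splice_site"] or f["intronic_splice_regulatory"]
        or f["natural_selection_region"],
        "intergenic": lambda f: False,
    }

    @pytest.mark.parametrize("region", list(ORACLE))
    def test_exhaustive_flag_combinations(self, region):
        cats = REGION_EVIDENCE[region]
        others = [c for c in EVIDENCE_CATEGORIES if c not in cats]
        for combo in itertools.product([False, True], repeat=len(cats)):
            flags = dict(zip(cats, combo))
            flags.update({c: True for c in others})  # irrelevant flags ignored...
            flags_irrelevant_true = dict(flags)
            flags.update({c: False for c in others})
            expected = self.ORACLE[region](
                {c: flags.get(c, False) for c in EVIDENCE_CATEGORIES})
            assert is_potentially_functional(region, flags) == expected
            assert is_potentially_functional(region, flags_irrelevant_true) == expected

    def test_single_evidence_calls(self):
        none = {c: False for c in EVIDENCE_CATEGORIES}
        assert is_potentially_functional("nsSNP", {**none, "deleterious": True})
        assert is_potentially_functional("sSNP", {**none, "codon_usage_bias": True})
        assert not is_potentially_functional("intron", none)
        assert not is_potentially_functional("intergenic", {**none, "deleterious": True})

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            is_potentially_functional("enhancer", {})

    def test_pf_mask_absent_snp_is_false(self):
        ann = pd.DataFrame({"snp_id": ["s1", "s2"], "gene_id": ["g", "g"],
                            "region": ["nsSNP", "nsSNP"]})
        ev = pd.DataFrame({"snp_id": ["s1"],
                           **{c: [c == "deleterious"] for c in EVIDENCE_CATEGORIES}})
        mask = pf_mask(ann, ev)
        assert mask.tolist() == [True, False]


class TestDeriveGeneSets:
    def test_empty_and_singleton(self):
        ann = pd.DataFrame({"snp_id": ["s1", "s2"], "gene_id": ["g1", ""],
                            "region": ["nsSNP", "intergenic"]})
        ev = pd.DataFrame({"snp_id": ["s1"],
                           **{c: [c == "deleterious"] for c in EVIDENCE_CATEGORIES}})
        calls = {"A-B": PdCallSet("A-B", 0.01, 0.5, {"s2"})}
        sets = derive_gene_sets(calls, ann, ev)
        assert sets["A-B"].pd_genes == set() and sets["A-B"].pf_pd_genes == set()
        calls = {"A-B": PdCallSet("A-B", 0.01, 0.5, {"s1"})}
        sets = derive_gene_sets(calls, ann, ev)
        assert sets["A-B"].pd_genes == {"g1"} == sets["A-B"].pf_pd_genes

    def test_matches_brute_force_set_builder(self):
        rng = np.random.default_rng(23)
        n_snps, n_genes = 200, 50
        snp_ids = [f"s{i}" for i in range(n_snps)]
        genes = [f"g{i}" for i in range(n_genes)]
        regions = rng.choice(["nsSNP", "sSNP", "intron", "utr3", "intergenic"], n_snps)
        gene_of = np.where(regions == "intergenic", "", rng.choice(genes, n_snps))
        ann = pd.DataFrame({"snp_id": snp_ids, "gene_id": gene_of, "region": regions})
        ev = pd.DataFrame({"snp_id": snp_ids,
                           **{c: rng.random(n_snps) < 0.3 for c in EVIDENCE_CATEGORIES}})
        pd_ids = set(rng.choice(snp_ids, 80, replace=False).tolist())
        calls = {"A-B": PdCallSet("A-B", 0.01, 0.0, pd_ids)}
        sets = derive_gene_sets(calls, ann, ev)

        # brute force, row by row
        ev_ix = ev.set_index("snp_id")
        exp_pd, exp_pf = set(), set()
        for row in ann.itertuples(index=False):
            if row.snp_id not in pd_ids or not row.gene_id:
                continue
            exp_pd.add(row.gene_id)
            flags = ev_ix.loc[row.snp_id].to_dict()
            if is_potentially_functional(row.region, flags):
                exp_pf.add(row.gene_id)
        assert sets["A-B"].pd_genes == exp_pd
        assert sets["A-B"].pf_pd_genes == exp_pf
        assert sets["A-B"].pf_pd_genes <= sets["A-B"].pd_genes
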