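"""Synthetic-data generator: drift model, panel, gene models, planted truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popdiff_pgx.config import ConfigError, PlantedDrug, SimulationConfig
from popdiff_pgx.fst import pairwise_fst
from popdiff_pgx.simulate import (
    read_vcf,
    simulate_drug_gene_map,
    simulate_evidence_flags,
    simulate_gene_annotation,
    simulate_genotype_panel,
    simulate_label_adr_tables,
    simulate_population_frequencies,
    write_vcf,
)


def cfg(**kw):
    base = dict(populations=("A", "B"), sample_sizes=(50, 50), n_snps=500,
                n_genes=30, chrom_length=3_000_000, n_drugs=20, seed=9)
    base.update(kw)
    return SimulationConfig(**base)


class TestPopulationFrequencies:
    def test_zero_divergence_returns_ancestral_exactly(self):
        anc, freqs = simulate_population_frequencies(cfg(divergence=0.0))
        assert np.all(freqs == anc[:, None])

    def test_determinism(self):
        a1, f1 = simulate_population_frequencies(cfg(seed=4))
        a2, f2 = simulate_population_frequencies(cfg(seed=4))
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(a1, a2)

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ConfigError):
            simulate_population_frequencies(cfg(divergence=1.0))

    def test_mean_realized_fst_monotone_in_drift(self):
        means = []
        for F in (0.01, 0.05, 0.1, 0.2):
            _, freqs = simulate_population_frequencies(
                cfg(n_snps=20_000, divergence=F, seed=21))
            _, _, f, elig = pairwise_fst(freqs[:, 0], 10_000, freqs[:, 1], 10_000)
            means.append(np.nanmean(f[elig]))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestGenotypePanel:
    def test_fixed_frequency_gives_homozygous_alternate(self):
        freqs = np.ones((10, 2))
        g, assign = simulate_genotype_panel(freqs, (5, 5), ("A", "B"), seed=0)
        assert np.all(g == 2)
        assert list(assign["population"]) == ["A"] * 5 + ["B"] * 5

    def test_realized_frequency_close_to_truth(self):
        freqs = np.full((5, 1), 0.5)
        g, _ = simulate_genotype_panel(freqs, (10_000,), ("A",), seed=1)
        realized = g.mean(axis=1) / 2.0
        assert np.all(np.abs(realized - 0.5) < 0.02)   # 3 sigma of Binomial(2n, .5)

    def test_zero_sample_size_rejected(self):
        with pytest.raises(ConfigError):
            simulate_genotype_panel(np.full((2, 1), 0.5), (0,), ("A",))

    def test_vcf_round_trip_preserves_allele_counts(self, tmp_path):
        config = cfg(n_snps=100, missing_rate=0.1)
        _, freqs = simulate_population_frequencies(config)
        g, assign = simulate_genotype_panel(freqs, config.sample_sizes,
                                            config.populations, config.seed,
                                            config.missing_rate)
        variants = pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, 101) * 10,
            "snp_id": [f"s{i}" for i in range(100)], "ref": "A", "alt": "G",
        })
        path = tmp_path / "panel.vcf"
        write_vcf(path, variants, g, assign["sample"].tolist())
        v2, g2, samples = read_vcf(path)
        assert samples == assign["sample"].tolist()
        np.testing.assert_array_equal(g2, g)
        np.testing.assert_array_equal(v2["pos"].to_numpy(), variants["pos"].to_numpy())


class TestGeneAnnotation:
    def test_truth_promoter_and_intergenic(self):
        genes, features, snps = simulate_gene_annotation(cfg(seed=5))
        prom = snps[snps["true_region"] == "promoter"]
        assert len(prom) > 0
        gene_ix = genes.set_index("gene_id")
        for row in prom.head(20).itertuples(index=False):
            g = gene_ix.loc[row.true_gene]
            if g["strand"] == "+":
                assert g["tss"] - 5500 <= row.pos <= g["tss"] - 1
            else:
                assert g["tss"] + 1 <= row.pos <= g["tss"] + 5500
        inter = snps[snps["true_region"] == "intergenic"]
        body_or_prom = []
        for g in genes.itertuples(index=False):
            lo = g.start - 5500 if g.strand == "+" else g.start
            hi = g.end if g.strand == "+" else g.end + 5500
            body_or_prom.append((lo, hi))
        for pos in inter["pos"].head(50):
            assert not any(lo <= pos <= hi for lo, hi in body_or_prom)

    def test_region_fractions_match_interval_lengths(self):
        config = cfg(n_snps=20_000, n_genes=40, chrom_length=4_000_000, seed=6)
        genes, features, snps = simulate_gene_annotation(config)
        # expected class probabilities from generated interval lengths
        covered = np.zeros(config.chrom_length + 1, dtype=np.uint8)
        code = {"exon": 4, "utr5": 3, "utr3": 3, "intron": 2}
        for f in features.itertuples(index=False):
            seg = covered[f.start:f.end + 1]
            np.maximum(seg, code[f.feature], out=seg)
        for g in genes.itertuples(index=False):
            lo, hi = (g.tss - 5500, g.tss - 1) if g.strand == "+" else (g.tss + 1, g.tss + 5500)
            seg = covered[max(lo, 1):hi + 1]
            np.maximum(seg, 1, out=seg)
        p_exon = np.mean(covered[1:] == 4)
        observed = snps["true_region"].isin(["nsSNP", "sSNP"]).mean()
        se = np.sqrt(p_exon * (1 - p_exon) / len(snps))
        assert abs(observed - p_exon) < 3 * se + 1e-9

    def test_infeasible_placement_raises(self):
        with pytest.raises(ConfigError):
            simulate_gene_annotation(cfg(n_genes=100, chrom_length=50_000))


class TestEvidenceFlags:
    def test_rate_zero_means_nothing_functional(self):
        _, _, snps = simulate_gene_annotation(cfg())
        flags = simulate_evidence_flags(snps, {c: 0.0 for c in cfg().evidence_rates}, 1)
        assert not flags["true_functional"].any()

    def test_rate_one_makes_every_genic_snp_functional(self):
        config = cfg()
        _, _, snps = simulate_gene_annotation(config)
        flags = simulate_evidence_flags(snps, {c: 1.0 for c in config.evidence_rates}, 1)
        genic = snps["true_region"] != "intergenic"
        assert flags.loc[genic.to_numpy(), "true_functional"].all()
        assert not flags.loc[(~genic).to_numpy(), "true_functional"].any()

    def test_deleterious_rate_binomial_bound(self):
        config = cfg(n_snps=20_000, n_genes=40, chrom_length=4_000_000, seed=8)
        _, _, snps = simulate_gene_annotation(config)
        rates = {c: 0.0 for c in config.evidence_rates}
        rates["deleterious"] = 0.1
        flags = simulate_evidence_flags(snps, rates, 2)
        ns = (snps["true_region"] == "nsSNP").to_numpy()
        n_ns = int(ns.sum())
        assert n_ns > 100
        count = int(flags.loc[ns, "true_functional"].sum())
        sigma = np.sqrt(n_ns * 0.1 * 0.9)
        assert abs(count - 0.1 * n_ns) < 3 * sigma

    def test_unknown_category_rejected(self):
        _, _, snps = simulate_gene_annotation(cfg())
        with pytest.raises(ConfigError):
            simulate_evidence_flags(snps, {"not_a_category": 0.5}, 0)


class TestDrugGeneMap:
    def setup_method(self):
        self.universe = [f"g{i:03d}" for i in range(200)]
        self.pf = {"A-B": set(self.universe[:20])}   # 10% background

    def test_source_union_restores_pathway(self):
        config = cfg(n_drugs=15, n_sources=4, source_overlap=0.3)
        tables, pathways, _ = simulate_drug_gene_map(config, self.universe, self.pf, 3)
        union = pd.concat(tables).groupby("drug_id")["gene_id"].agg(set)
        for drug, genes in pathways.items():
            assert union[drug] == genes

    def test_saturating_enrichment_fills_pathway_with_pf_genes(self):
        config = cfg(n_drugs=5,
                     planted_drugs=(PlantedDrug("planted", "A-B", 1000.0),),
                     pathway_size_range=(5, 15))
        _, pathways, planted = simulate_drug_gene_map(config, self.universe, self.pf, 4)
        assert planted == {("planted", "A-B"): True}
        assert pathways["planted"] <= self.pf["A-B"]

    def test_factor_one_indistinguishable_from_background(self):
        config = cfg(n_drugs=1,
                     planted_drugs=(PlantedDrug("planted", "A-B", 1.0),),
                     pathway_size_range=(40, 40))
        hits = []
        for seed in range(30):
            _, pathways, _ = simulate_drug_gene_map(
                cfg(n_drugs=1, planted_drugs=config.planted_drugs,
                    pathway_size_range=(40, 40), seed=seed),
                self.universe, self.pf, seed)
            hits.append(len(pathways["planted"] & self.pf["A-B"]))
        # Binomial(40, 0.1) mean per replicate; 3 sigma on the mean of 30
        mean_hits = np.mean(hits)
        se = np.sqrt(40 * 0.1 * 0.9 / 30)
        assert abs(mean_hits - 4.0) < 3 * se

    def test_pathway_exceeding_universe_rejected(self):
        with pytest.raises(ConfigError):
            simulate_drug_gene_map(cfg(pathway_size_range=(5, 500)),
                                   self.universe, self.pf, 0)


class TestLabelAdrTables:
    def test_zero_slope_gives_labels_independent_of_enrichment(self):
        config = cfg(n_drugs=1000, label_logistic_slope=0.0,
                     label_logistic_intercept=0.0)
        drugs = [f"d{i}" for i in range(1000)]
        counts = {d: (5 if i < 500 else 0) for i, d in enumerate(drugs)}
        tabs = simulate_label_adr_tables(drugs, counts, config, seed=13)
        labels = tabs["labels"].set_index("drug_id")["label"]
        enriched = np.array([counts[d] > 0 for d in drugs])
        labelled = (labels.loc[drugs] != "none").to_numpy()
        table = pd.crosstab(enriched, labelled)
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_positive_slope_raises_label_rate_for_enriched_drugs(self):
        config = cfg(n_drugs=1000, label_logistic_slope=1.5,
                     label_logistic_intercept=-2.0)
        drugs = [f"d{i}" for i in range(1000)]
        counts = {d: (5 if i < 500 else 0) for i, d in enumerate(drugs)}
        tabs = simulate_label_adr_tables(drugs, counts, config, seed=13)
        labels = tabs["labels"].set_index("drug_id")["label"]
        rate_enriched = (labels.loc[drugs[:500]] != "none").mean()
        rate_plain = (labels.loc[drugs[500:]] != "none").mean()
        assert rate_enriched > rate_plain + 0.3

    def test_zero_poisson_rate_gives_empty_adr_table(self):
        config = cfg(adr_rate_us=0.0)
        tabs = simulate_label_adr_tables(["d1", "d2"], {}, config, seed=0)
        assert len(tabs["adr_US"]) == 0

    def test_literature_table_lists_planted_cases(self):
        config = cfg(literature_n_cases=3)
        cases = [("d1", "A-B"), ("d2", "A-B"), ("d3", "A-B"), ("d4", "A-B")]
        tabs = simulate_label_adr_tables(["d1"], {}, config, 0, planted_cases=cases)
        assert len(tabs["literature"]) == 3
        assert set(tabs["literature"]["drug_id"]) <= {"d1", "d2", "d3"}
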