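"""End-to-end pipeline: simulate -> F_ST -> annotate -> enrich -> rank -> report.

Every stage reads and writes plain TSV/JSON under the output directory, so a
run is auditable file by file; rerunning with the same configuration and
seed reproduces byte-identical tables. The run manifest records the config
echo, per-stage row counts (the filter funnel: eligible SNPs >= pdSNPs >=
pf-pdSNPs; pdGenes >= pf-pdGenes), and wall time per stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotate, enrichment, fst, label_adr, ranking, simulate
from .config import RunConfig, SimulationConfig

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "fst", "annotate", "enrich", "rank", "report")


def truth_gene_sets(
    config: SimulationConfig,
    true_freqs: np.ndarray,
    snps: pd.DataFrame,
    flags: pd.DataFrame,
    q: float = 0.01,
) -> dict[str, set[str]]:
    """Truth pf-pdGene sets per pair from the noise-free allele frequencies.

    Used to plant drug-pathway enrichment before any genotype sampling, so
    recovery tests are defined on the truth labels rather than on downstream
    calls. F_ST is computed on the true frequencies with the panel sample
    sizes as weights.
    """
    n = np.tile(np.asarray(config.sample_sizes), (true_freqs.shape[0], 1))
    table = fst.AlleleFrequencyTable(
        snps["snp_id"].to_numpy(), list(config.populations), true_freqs, n)
    mat = fst.fst_matrix(table)
    calls = fst.call_pdsnps_all_pairs(mat, q=q)
    functional = dict(zip(flags["snp_id"], flags["true_functional"]))
    gene_of = dict(zip(snps["snp_id"], snps["true_gene"]))
    out: dict[str, set[str]] = {}
    for pair, call in calls.items():
        out[pair] = {
            gene_of[s] for s in call.snp_ids
            if gene_of.get(s) and functional.get(s, False)
        }
    return out


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "counts": {}, "seed": config.seed}
    stages = [s for s in STAGE_ORDER if s in config.stages]
    state: dict = {}
    try:
        for stage in stages:
            t0 = time.perf_counter()
            _STAGE_FUNCS[stage](config, out, state, manifest)
            manifest["stages"][stage] = {
                "completed": True,
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
    except Exception:
        _write_manifest(manifest, config, out)
        raise
    _write_manifest(manifest, config, out)
    return manifest


def _write_manifest(manifest: dict, config: RunConfig, out: Path) -> None:
    manifest["config"] = {
        "top_quantile": config.top_quantile, "z_threshold": config.z_threshold,
        "n_iter": config.n_iter, "matching": config.matching,
        "m_weighting": config.m_weighting, "seed": config.seed,
        "stages": list(config.stages),
    }
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    tmp.replace(out / "manifest.json")


# ------------------------------------------------------------------- stages

def _stage_simulate(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    sim = config.simulation
    ancestral, freqs = simulate.simulate_population_frequencies(sim)
    genes, features, snps = simulate.simulate_gene_annotation(sim)
    flags = simulate.simulate_evidence_flags(snps, sim.evidence_rates, sim.seed)
    genotypes, assignment = simulate.simulate_genotype_panel(
        freqs, sim.sample_sizes, sim.populations, sim.seed, sim.missing_rate)

    truth_sets = truth_gene_sets(sim, freqs, snps, flags, config.top_quantile)
    sources, pathways, planted = simulate.simulate_drug_gene_map(
        sim, genes["gene_id"].tolist(), truth_sets, sim.seed)
    planted_counts = {
        d: sum(1 for (dd, _), v in planted.items() if dd == d and v)
        for d in pathways
    }
    aux = simulate.simulate_label_adr_tables(
        sorted(pathways), planted_counts, sim, sim.seed,
        planted_cases=sorted(planted))

    simulate.write_vcf(out / "panel.vcf", snps[["chrom", "pos", "snp_id", "ref", "alt"]],
                       genotypes, assignment["sample"].tolist())
    _write(assignment, out / "populations.tsv")
    _write(genes, out / "genes.tsv")
    _write(features, out / "features.tsv")
    _write(snps.drop(columns=["true_region", "true_gene"]), out / "snps.tsv")
    _write(flags.drop(columns=["true_functional"]), out / "evidence.tsv")
    _write(pd.concat(sources, ignore_index=True), out / "drug_genes.tsv")
    for name, tab in aux.items():
        _write(tab, out / f"{name}.tsv")
    sim.to_yaml(out / "config_echo.yaml")

    truth = simulate.TruthTable(
        ancestral_freq=ancestral, true_freqs=freqs,
        snp_region=pd.Series(snps["true_region"].to_numpy(), index=snps["snp_id"]),
        snp_gene=pd.Series(snps["true_gene"].to_numpy(), index=snps["snp_id"]),
        snp_functional=pd.Series(flags["true_functional"].to_numpy(), index=flags["snp_id"]),
        planted_enriched=planted, pathways=pathways,
    )
    truth.to_json(out / "truth.json")
    state.update(truth=truth, genes=genes, features=features, snps=snps,
                 flags=flags, aux=aux)
    manifest["counts"]["n_snps"] = int(len(snps))
    manifest["counts"]["n_genes"] = int(len(genes))
    manifest["counts"]["n_drugs"] = int(len(pathways))
    manifest["counts"]["n_samples"] = int(len(assignment))


def _stage_fst(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    variants, genotypes, samples = simulate.read_vcf(out / "panel.vcf")
    assignment = pd.read_csv(out / "populations.tsv", sep="\t")
    pops = list(config.simulation.populations)
    pop_of = dict(zip(assignment["sample"], assignment["population"]))
    missing = [s for s in samples if s not in pop_of]
    if missing:
        raise ValueError(f"samples without population assignment: {missing[:5]}")
    table = fst.allele_frequencies(
        genotypes, [pop_of[s] for s in samples], pops, variants["snp_id"].to_numpy())
    mat = fst.fst_matrix(table, m_weighting=config.m_weighting)
    _write(mat.to_frame(), out / "fst_long.tsv")
    calls = fst.call_pdsnps_all_pairs(mat, q=config.top_quantile)
    rows = [(pair, c.threshold, s) for pair, c in calls.items() for s in sorted(c.snp_ids)]
    _write(pd.DataFrame(rows, columns=["pair", "threshold", "snp_id"]),
           out / "pdsnps.tsv")
    state.update(freq_table=table, fst_matrix=mat, pd_calls=calls)
    manifest["counts"]["n_pairs"] = len(mat.pairs)
    manifest["counts"]["n_eligible_min"] = int(mat.eligible.sum(axis=0).min())
    manifest["counts"]["n_pdsnps_total"] = int(sum(len(c.snp_ids) for c in calls.values()))


def _stage_annotate(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    snps = pd.read_csv(out / "snps.tsv", sep="\t", keep_default_na=False)
    genes = pd.read_csv(out / "genes.tsv", sep="\t")
    features = pd.read_csv(out / "features.tsv", sep="\t")
    flags = pd.read_csv(out / "evidence.tsv", sep="\t")
    ann = annotate.classify_snp_regions(snps, genes, features,
                                        config.simulation.promoter_bp)
    ann["pf"] = annotate.pf_mask(ann, flags)
    _write(ann, out / "annotations.tsv")
    gene_sets = annotate.derive_gene_sets(state["pd_calls"], ann, flags)
    rows = [(pair, g, g in gs.pf_pd_genes)
            for pair, gs in gene_sets.items() for g in sorted(gs.pd_genes)]
    _write(pd.DataFrame(rows, columns=["pair", "gene_id", "pf_pd"]),
           out / "gene_sets.tsv")
    state.update(annotations=ann, gene_sets=gene_sets, genes=genes)
    manifest["counts"]["n_pf_pdgenes_total"] = int(
        sum(len(gs.pf_pd_genes) for gs in gene_sets.values()))
    manifest["counts"]["n_pdgenes_total"] = int(
        sum(len(gs.pd_genes) for gs in gene_sets.values()))


def _stage_enrich(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    drug_tab = pd.read_csv(out / "drug_genes.tsv", sep="\t")
    drug_genes = enrichment.integrate_drug_gene_sources(
        [t for _, t in drug_tab.groupby("source")])
    universe = state["genes"][["gene_id", "length"]]
    zmat = enrichment.drug_pair_zmatrix(
        drug_genes, state["gene_sets"], universe,
        n_iter=config.n_iter, seed=config.seed, matching=config.matching,
        z_threshold=config.z_threshold)
    _write(zmat.table, out / "zmatrix.tsv")
    _write(zmat.summary(), out / "drug_summary.tsv")
    state.update(zmatrix=zmat, drug_genes=drug_genes)
    manifest["counts"]["n_drugs_scored"] = int(zmat.table["drug"].nunique())
    manifest["counts"]["n_drugs_significant"] = int(
        (zmat.significant_pair_counts() > 0).sum())


def _stage_rank(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    zmat = state["zmatrix"]
    scores = ranking.drug_scores(zmat.table, config.z_threshold, config.mode_decimals)
    membership = pd.read_csv(out / "membership.tsv", sep="\t")
    ranked = ranking.group_score_and_rank(membership, scores, config.top_k_groups)
    detail = ranking.member_detail(membership, scores, ranked, config.top_k_groups)
    _write(scores, out / "drug_scores.tsv")
    _write(ranked, out / "group_ranking.tsv")
    _write(detail, out / "group_member_detail.tsv")
    state.update(scores=scores, ranked=ranked)
    manifest["counts"]["n_groups_ranked"] = int(len(ranked))


def _stage_report(config: RunConfig, out: Path, state: dict, manifest: dict) -> None:
    zmat = state["zmatrix"]
    nsig = zmat.significant_pair_counts().rename("n_sig_pairs").reset_index() \
        .rename(columns={"drug": "drug_id"})
    labels = label_adr.collapse_labels(pd.read_csv(out / "labels.tsv", sep="\t"))
    merged = nsig.merge(labels, on="drug_id", how="left").fillna({"tier": "none"})
    merged["group"] = merged["tier"]
    cdf = label_adr.ecdf_by_group(merged, "group")
    _write(cdf, out / "label_cdf.tsv")

    comparisons = []
    by_tier = {t: g["n_sig_pairs"].to_numpy() for t, g in merged.groupby("tier")}
    for a, b in (("required", "none"),
                 ("recommended_actionable_informative", "none")):
        if a in by_tier and b in by_tier and len(by_tier[a]) >= 2 and len(by_tier[b]) >= 2:
            c = label_adr.compare_group_means(by_tier[a], by_tier[b])
            comparisons.append((a, b, c.t, c.p, c.mean_a, c.mean_b, c.se_a, c.se_b))
    _write(pd.DataFrame(comparisons, columns=["group_a", "group_b", "t", "p",
                                              "mean_a", "mean_b", "se_a", "se_b"]),
           out / "label_ttests.tsv")

    lit = pd.read_csv(out / "literature.tsv", sep="\t")
    if len(lit):
        rep = label_adr.literature_concordance(lit, zmat.table, config.z_threshold)
        _write(rep.detail, out / "concordance_detail.tsv")
        manifest["counts"]["literature_detection_rate"] = rep.detection_rate
    adr_tables = {
        src: pd.read_csv(out / f"adr_{src}.tsv", sep="\t")
        for src in ("US", "SG") if (out / f"adr_{src}.tsv").exists()
    }
    if adr_tables:
        prof = label_adr.adr_profile_compare(adr_tables, nsig, config.top_k_adr)
        _write(prof, out / "adr_profiles.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fst": _stage_fst,
    "annotate": _stage_annotate,
    "enrich": _stage_enrich,
    "rank": _stage_rank,
    "report": _stage_report,
}
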