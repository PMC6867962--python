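"""Synthetic multi-population PGx study generator.

Generates every input of the pipeline with known ground truth: a
multi-population genotype panel under the Balding-Nichols drift model, gene
models with promoter/UTR/exon/intron structure, pfSNP-style functional
evidence flags, multi-source drug-gene tables with optionally planted
pathway enrichment, drug-class/disease-group memberships, PGx warning
labels, ADR report counts and a literature-case table.

Under Balding-Nichols, each population's allele frequency at a SNP with
ancestral frequency p is Beta(p(1-F)/F, (1-p)(1-F)/F), where F in [0, 1) is
the drift coefficient; F = 0 degenerates to the ancestral frequency and the
expected pairwise F_ST grows with F. Diploid genotypes are then binomial
draws from the population frequency (no linkage disequilibrium, demography
or selection is modelled).

Every sub-generator draws from its own stream derived from the master seed
(see :mod:`popdiff_pgx.config`), so identical configs reproduce byte-identical
tables and stages can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate
from .config import (
    EVIDENCE_CATEGORIES,
    ConfigError,
    PlantedDrug,
    SimulationConfig,
    substream,
)

RAW_LABELS = ("testing_required", "testing_recommended", "actionable", "informative", "none")
REACTIONS = ("hepatotoxicity", "rash", "anaphylaxis", "nausea", "cardiotoxicity")


@dataclass
class TruthTable:
    """Ground truth of one simulated study; immutable once written."""

    ancestral_freq: np.ndarray           # (n_snps,)
    true_freqs: np.ndarray               # (n_snps, n_pops)
    snp_region: pd.Series                # per-SNP region class (highest precedence)
    snp_gene: pd.Series                  # per-SNP gene id ("" if intergenic)
    snp_functional: pd.Series            # per-SNP pf status
    planted_enriched: dict[tuple[str, str], bool] = field(default_factory=dict)
    pathways: dict[str, set[str]] = field(default_factory=dict)

    def planted_pair_count(self, drug_id: str) -> int:
        return sum(1 for (d, _), v in self.planted_enriched.items() if d == drug_id and v)

    def to_json(self, path) -> None:
        d = {
            "snp_region": self.snp_region.to_dict(),
            "snp_gene": self.snp_gene.to_dict(),
            "snp_functional": {k: bool(v) for k, v in self.snp_functional.items()},
            "planted_enriched": {f"{d_}|{p}": bool(v)
                                 for (d_, p), v in self.planted_enriched.items()},
            "pathways": {d_: sorted(g) for d_, g in self.pathways.items()},
            "ancestral_freq": self.ancestral_freq.tolist(),
            "true_freqs": self.true_freqs.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


# ---------------------------------------------------------------- frequencies

def simulate_population_frequencies(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-population allele frequencies (Balding-Nichols).

    Returns ``(ancestral, freqs)`` with shapes (n_snps,) and
    (n_snps, n_populations); deterministic given ``config.seed``.
    """
    config.validate()
    rng = substream(config.seed, "frequencies")
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=config.n_snps)
    F = config.divergence
    if F == 0.0:
        freqs = np.tile(p0[:, None], (1, config.n_populations))
    else:
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        freqs = rng.beta(a[:, None], b[:, None],
                         size=(config.n_snps, config.n_populations))
    return p0, freqs


# ------------------------------------------------------------------ genotypes

def simulate_genotype_panel(
    freqs: np.ndarray,
    sample_sizes: Sequence[int],
    populations: Sequence[str],
    seed: int = 0,
    missing_rate: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Diploid dosage matrix (n_snps, n_samples) plus the sample->population table.

    Each individual's ALT dosage is Binomial(2, p_pop); missing calls (coded
    -1) are dropped uniformly at ``missing_rate``.
    """
    if np.any(np.asarray(sample_sizes) <= 0):
        raise ConfigError("sample sizes must be positive")
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies outside [0, 1]")
    rng = substream(seed, "genotypes")
    blocks, samples, pops = [], [], []
    for j, (pop, n) in enumerate(zip(populations, sample_sizes)):
        g = rng.binomial(2, freqs[:, j][:, None], size=(freqs.shape[0], n)).astype(np.int8)
        if missing_rate > 0:
            miss = rng.random(g.shape) < missing_rate
            g = np.where(miss, np.int8(-1), g)
        blocks.append(g)
        samples.extend(f"{pop}_{i:04d}" for i in range(n))
        pops.extend([pop] * n)
    genotypes = np.concatenate(blocks, axis=1)
    assignment = pd.DataFrame({"sample": samples, "population": pops})
    return genotypes, assignment


def write_vcf(path, variants: pd.DataFrame, genotypes: np.ndarray,
              samples: Sequence[str]) -> None:
    """Write the panel as a minimal VCF v4.2 (1-based positions, GT only)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chrom"]):
            length = int(variants.loc[variants["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, v in enumerate(variants.itertuples(index=False)):
            gts = "\t".join(gt_str[int(g)] for g in genotypes[i])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.snp_id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a biallelic VCF back into (variants, dosage matrix, samples).

    Non-biallelic sites are skipped; the skip count is in
    ``variants.attrs["n_skipped_multiallelic"]``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        rows.append((var.CHROM, var.POS, var.ID, var.REF, var.ALT[0]))
        g = np.array([a + b if a >= 0 and b >= 0 else -1
                      for a, b, *_ in var.genotypes], dtype=np.int8)
        dosages.append(g)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "snp_id", "ref", "alt"])
    variants.attrs["n_skipped_multiallelic"] = n_skipped
    return variants, np.array(dosages, dtype=np.int8), samples


# --------------------------------------------------------------- gene models

def simulate_gene_annotation(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene models, feature intervals and SNP positions with truth regions.

    Genes are placed without overlap along one chromosome; each gene has a
    5'UTR, an alternating exon/intron body and a 3'UTR (a deliberately simple
    structure that exercises the region classifier, not a biological model).
    SNP positions are uniform over the chromosome. Returns
    ``(genes, features, snps)`` where ``snps`` includes the true region class
    (``true_region``) and primary gene (``true_gene``).
    """
    config.validate()
    rng = substream(config.seed, "genes")
    for attempt in range(20):
        lengths = np.exp(rng.normal(config.gene_length_log_mean,
                                    config.gene_length_log_sd, config.n_genes))
        lengths = np.clip(lengths, 2_000, 200_000).astype(np.int64)
        # keep room for promoter windows between genes
        spacer = config.promoter_bp + 1
        total = int(lengths.sum()) + spacer * (config.n_genes + 1)
        if total <= config.chrom_length:
            break
    else:
        raise ConfigError("cannot place genes on chromosome; increase chrom_length")
    free = config.chrom_length - total
    gaps = (rng.dirichlet(np.ones(config.n_genes + 1)) * free).astype(np.int64) + spacer

    genes_rows, feat_rows = [], []
    cursor = 1
    for i in range(config.n_genes):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i]) - 1
        cursor = end + 1
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i:04d}"
        tss = start if strand == "+" else end
        genes_rows.append((gid, config.chrom, strand, tss, start, end, int(lengths[i])))
        feat_rows.extend(_gene_features(gid, start, end, strand, rng))
    genes = pd.DataFrame(genes_rows, columns=["gene_id", "chrom", "strand",
                                              "tss", "start", "end", "length"])
    features = pd.DataFrame(feat_rows, columns=["gene_id", "feature", "start", "end"])

    positions = _draw_unique_positions(rng, config.chrom_length, config.n_snps)
    nonsyn = rng.random(config.n_snps) < config.nonsyn_fraction
    snps = _truth_regions(positions, nonsyn, genes, features, config)
    return genes, features, snps


def _gene_features(gid, start, end, strand, rng):
    """5'UTR / alternating exon-intron / 3'UTR intervals of one gene."""
    length = end - start + 1
    utr5_len = max(50, int(0.05 * length))
    utr3_len = max(100, int(0.10 * length))
    body = length - utr5_len - utr3_len
    n_exons = int(rng.integers(1, 8))
    exon_total = max(n_exons, int(0.4 * body))
    intron_total = body - exon_total
    exon_lens = _split(rng, exon_total, n_exons)
    intron_lens = _split(rng, intron_total, n_exons - 1) if n_exons > 1 else []
    segs = [("utr5", utr5_len)] if strand == "+" else [("utr3", utr3_len)]
    order = range(n_exons)
    for k in order:
        segs.append(("exon", exon_lens[k]))
        if k < n_exons - 1:
            segs.append(("intron", intron_lens[k]))
    segs.append(("utr3", utr3_len) if strand == "+" else ("utr5", utr5_len))
    rows, cursor = [], start
    for feature, seg_len in segs:
        rows.append((gid, feature, cursor, cursor + seg_len - 1))
        cursor += seg_len
    return rows


def _split(rng, total, parts):
    """Partition ``total`` into ``parts`` positive integer segments."""
    if parts <= 0:
        return []
    if total < parts:
        raise ConfigError("gene too short to partition into features")
    cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False)) \
        if parts > 1 else np.array([], dtype=int)
    bounds = np.concatenate(([0], cuts, [total]))
    return np.diff(bounds).astype(int).tolist()


def _draw_unique_positions(rng, chrom_length, n):
    seen: set[int] = set()
    while len(seen) < n:
        draw = rng.integers(1, chrom_length + 1, size=2 * (n - len(seen)))
        seen.update(int(x) for x in draw)
    return np.array(sorted(seen)[:n] if len(seen) == n else
                    sorted(rng.choice(sorted(seen), size=n, replace=False)))


def _truth_regions(positions, nonsyn, genes, features, config):
    """True region class and gene per SNP (precedence exon > UTR > intron > promoter)."""
    n = len(positions)
    region = np.full(n, "intergenic", dtype=object)
    gene_of = np.full(n, "", dtype=object)
    gene_starts = genes["start"].to_numpy()
    gene_ends = genes["end"].to_numpy()
    gene_ids = genes["gene_id"].to_numpy()
    idx = np.searchsorted(gene_starts, positions, side="right") - 1
    in_body = (idx >= 0) & (positions <= gene_ends[np.clip(idx, 0, None)])
    feat_sorted = features.sort_values("start")
    f_starts = feat_sorted["start"].to_numpy()
    f_ends = feat_sorted["end"].to_numpy()
    f_kind = feat_sorted["feature"].to_numpy()
    fi = np.searchsorted(f_starts, positions, side="right") - 1
    in_feat = (fi >= 0) & (positions <= f_ends[np.clip(fi, 0, None)])
    for i in np.flatnonzero(in_body):
        gene_of[i] = gene_ids[idx[i]]
        kind = f_kind[fi[i]] if in_feat[i] else "intron"
        if kind == "exon":
            region[i] = "nsSNP" if nonsyn[i] else "sSNP"
        else:
            region[i] = kind
    # promoter windows for the rest
    windows = []
    for g in genes.itertuples(index=False):
        lo, hi = annotate.promoter_window(g.tss, g.strand, config.promoter_bp)
        windows.append((max(lo, 1), hi, g.gene_id))
    windows.sort()
    w_lo = np.array([w[0] for w in windows])
    w_hi = np.array([w[1] for w in windows])
    w_id = np.array([w[2] for w in windows], dtype=object)
    wi = np.searchsorted(w_lo, positions, side="right") - 1
    in_prom = (wi >= 0) & (positions <= w_hi[np.clip(wi, 0, None)]) & ~in_body
    region[in_prom] = "promoter"
    gene_of[in_prom] = w_id[wi[in_prom]]

    consequence = np.where(region == "nsSNP", "nonsynonymous",
                           np.where(region == "sSNP", "synonymous", ""))
    return pd.DataFrame({
        "snp_id": [f"snp{i:06d}" for i in range(n)],
        "chrom": config.chrom,
        "pos": positions,
        "ref": "A",
        "alt": "G",
        "consequence": consequence,
        "true_region": region,
        "true_gene": gene_of,
    })


# ------------------------------------------------------------ evidence flags

#: category -> region classes where the category can fire
_CATEGORY_REGIONS: dict[str, set[str]] = {}
for _r, _cats in annotate.REGION_EVIDENCE.items():
    for _c in _cats:
        _CATEGORY_REGIONS.setdefault(_c, set()).add(_r)


def simulate_evidence_flags(
    snps: pd.DataFrame,
    evidence_rates: Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli evidence flags per SNP, restricted to region-relevant categories.

    ``snps`` needs ``snp_id`` and ``true_region``. Categories irrelevant to a
    SNP's region are always False; the pf truth is obtained by applying the
    annotation decision table to the drawn flags.
    """
    unknown = set(evidence_rates) - set(EVIDENCE_CATEGORIES)
    if unknown:
        raise ConfigError(f"unknown evidence categories: {sorted(unknown)}")
    rng = substream(seed, "evidence")
    region = snps["true_region"].to_numpy()
    out = {"snp_id": snps["snp_id"].to_numpy()}
    for cat in EVIDENCE_CATEGORIES:
        rate = float(evidence_rates.get(cat, 0.0))
        relevant = np.isin(region, list(_CATEGORY_REGIONS.get(cat, ())))
        out[cat] = relevant & (rng.random(len(snps)) < rate)
    flags = pd.DataFrame(out)
    functional = flags[list(EVIDENCE_CATEGORIES)].any(axis=1).to_numpy()
    flags["true_functional"] = functional
    return flags


# ------------------------------------------------------------- drug-gene map

def sample_planted_pathway(
    rng: np.random.Generator,
    universe: Sequence[str],
    pf_set: set[str],
    size: int,
    enrichment_factor: float,
) -> set[str]:
    """Draw one drug pathway whose expected pf-pdGene proportion is
    ``enrichment_factor x`` the universe background proportion (capped at 1).

    Each pathway slot is filled from ``pf_set`` with probability
    ``min(1, factor * background)`` (binomial count, then uniform draws
    without replacement within each stratum of the split)."""
    universe = np.asarray(list(universe))
    pf_arr = np.asarray(sorted(pf_set & set(universe.tolist())))
    background = len(pf_arr) / len(universe)
    prob = min(1.0, enrichment_factor * background)
    n_hit = min(int(rng.binomial(size, prob)), len(pf_arr))
    rest_pool = np.asarray(sorted(set(universe.tolist()) - set(pf_arr.tolist())))
    n_rest = min(size - n_hit, len(rest_pool))
    parts = []
    if n_hit:
        parts.append(rng.choice(pf_arr, size=n_hit, replace=False))
    if n_rest:
        parts.append(rng.choice(rest_pool, size=n_rest, replace=False))
    genes = np.concatenate(parts) if parts else np.array([], dtype=object)
    return set(np.asarray(genes, dtype=object).tolist())


def simulate_drug_gene_map(
    config: SimulationConfig,
    gene_universe: Sequence[str],
    pf_pd_truth: Mapping[str, set[str]],
    seed: int = 0,
) -> tuple[list[pd.DataFrame], dict[str, set[str]], dict[tuple[str, str], bool]]:
    """Multi-source drug-gene tables with optionally planted enrichment.

    Non-planted drugs draw pathway genes uniformly without replacement. A
    drug planted with enrichment factor ``e`` for pair ``q`` draws each
    pathway gene from the pair's truth pf-pdGene set with probability
    ``min(1, e * background)``, where background is the universe pf-pdGene
    proportion, so its expected pf-pd proportion is ``e ×`` background
    (capped at 1). Pathways are split across ``config.n_sources`` overlapping
    source tables whose union restores the pathway.

    Returns ``(source_tables, pathways, planted_enriched)``.
    """
    rng = substream(seed, "drug_map")
    universe = np.asarray(list(gene_universe))
    lo, hi = config.pathway_size_range
    if hi > len(universe):
        raise ConfigError("pathway size range exceeds gene universe")
    planted_by_id = {p.drug_id: p for p in config.planted_drugs}
    drug_ids = [f"drug{i:04d}" for i in range(config.n_drugs)]
    for pid in planted_by_id:
        if pid not in drug_ids:
            drug_ids.append(pid)

    pathways: dict[str, set[str]] = {}
    planted_enriched: dict[tuple[str, str], bool] = {}
    for drug in drug_ids:
        size = int(rng.integers(lo, hi + 1))
        plant = planted_by_id.get(drug)
        if plant is None:
            genes = rng.choice(universe, size=size, replace=False)
            pathways[drug] = set(np.asarray(genes, dtype=object).tolist())
        else:
            pathways[drug] = sample_planted_pathway(
                rng, universe, pf_pd_truth.get(plant.pair, set()),
                size, plant.enrichment_factor)
            planted_enriched[(drug, plant.pair)] = True

    sources = [[] for _ in range(config.n_sources)]
    for drug, genes in pathways.items():
        for gene in sorted(genes):
            primary = int(rng.integers(config.n_sources))
            sources[primary].append((drug, gene))
            if config.n_sources > 1 and rng.random() < config.source_overlap:
                other = int(rng.integers(config.n_sources - 1))
                other = other + 1 if other >= primary else other
                sources[other].append((drug, gene))
    tables = [
        pd.DataFrame(rows, columns=["drug_id", "gene_id"]).assign(source=f"source{k}")
        for k, rows in enumerate(sources)
    ]
    return tables, pathways, planted_enriched


# ------------------------------------------------- labels, ADR, memberships

def simulate_label_adr_tables(
    drug_ids: Sequence[str],
    planted_pair_counts: Mapping[str, int],
    config: SimulationConfig,
    seed: int = 0,
    planted_cases: Sequence[tuple[str, str]] = (),
) -> dict[str, pd.DataFrame]:
    """PGx labels, two-source ADR counts, group memberships and literature cases.

    Label severity follows a logistic link on the planted enriched-pair
    count: P(labelled) = sigmoid(intercept + slope * count), with the
    labelled drugs split over the four raw PGx levels. ADR counts are
    Poisson with source-specific base rates scaled by (1 + planted count).
    The literature table lists up to ``config.literature_n_cases`` planted
    (drug, pair) cases. Everything depends on the planted truth only, never
    on downstream calls.
    """
    rng = substream(seed, "labels_adr")
    drug_ids = list(drug_ids)
    counts = np.array([planted_pair_counts.get(d, 0) for d in drug_ids], dtype=float)

    logit = config.label_logistic_intercept + config.label_logistic_slope * counts
    p_labelled = 1.0 / (1.0 + np.exp(-logit))
    labelled = rng.random(len(drug_ids)) < p_labelled
    raw = np.where(
        labelled,
        rng.choice(RAW_LABELS[:4], size=len(drug_ids), p=(0.2, 0.3, 0.3, 0.2)),
        "none",
    )
    labels = pd.DataFrame({"drug_id": drug_ids, "label": raw})

    adr = {}
    for source, base in (("US", config.adr_rate_us), ("SG", config.adr_rate_sg)):
        lam = base * (1.0 + counts)
        n_reports = rng.poisson(lam)
        reaction = rng.choice(REACTIONS, size=len(drug_ids))
        tab = pd.DataFrame({"drug_id": drug_ids, "n_reports": n_reports,
                            "reaction": reaction})
        adr[source] = tab[tab["n_reports"] > 0].reset_index(drop=True)

    n_classes = max(3, len(drug_ids) // 10)
    n_diseases = max(3, len(drug_ids) // 5)
    rows = []
    for d in drug_ids:
        rows.append((f"class{int(rng.integers(n_classes)):03d}", "drug_class", d))
        for _ in range(int(rng.integers(1, 4))):
            rows.append((f"disease{int(rng.integers(n_diseases)):03d}", "disease_group", d))
    membership = pd.DataFrame(rows, columns=["group_id", "kind", "drug_id"]) \
        .drop_duplicates().reset_index(drop=True)

    cases = list(planted_cases)[: config.literature_n_cases]
    literature = pd.DataFrame(cases, columns=["drug_id", "pair"]) if cases else \
        pd.DataFrame(columns=["drug_id", "pair"])

    return {"labels": labels, "adr_US": adr["US"], "adr_SG": adr["SG"],
            "membership": membership, "literature": literature}
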