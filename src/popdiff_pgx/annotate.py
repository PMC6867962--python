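"""SNP region classification and potentially-functional (pf) SNP calling.

Region classes per (SNP, gene): nsSNP/sSNP (exonic, by supplied coding
consequence), 5'UTR, 3'UTR, intron, promoter (the 5,500 bases strictly
upstream of the TSS, strand-aware), or intergenic when no gene matches.
Within one gene the precedence is exon > UTR > intron > promoter.

A genic SNP is potentially functional when it carries region-appropriate
evidence: deleteriousness for nsSNPs, codon-usage bias for sSNPs (both coding
classes also accept protein domain/functional region, modification-site and
NMD/splice-enhancer evidence), TFBS alteration for promoter/5'UTR SNPs,
conserved-region or miRNA-binding evidence for 3'UTR SNPs, splice-site or
intronic splice-regulatory evidence for intronic SNPs, and a
natural-selection signal for any genic region. Intergenic SNPs are never
potentially functional here.

pdGene / pf-pdGene per population pair: a gene carrying at least one pdSNP,
respectively at least one pdSNP that is also potentially functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .fst import PdCallSet

REGIONS = ("nsSNP", "sSNP", "utr5", "utr3", "intron", "promoter", "intergenic")

#: Evidence categories that can qualify each region class.
REGION_EVIDENCE: dict[str, tuple[str, ...]] = {
    "nsSNP": ("deleterious", "domain_or_functional_region", "modification_site",
              "nmd_or_ese_ess", "natural_selection_region"),
    "sSNP": ("codon_usage_bias", "domain_or_functional_region", "modification_site",
             "nmd_or_ese_ess", "natural_selection_region"),
    "utr5": ("tfbs_altering", "natural_selection_region"),
    "promoter": ("tfbs_altering", "natural_selection_region"),
    "utr3": ("utr3_conserved", "mirna_binding", "natural_selection_region"),
    "intron": ("splice_site", "intronic_splice_regulatory", "natural_selection_region"),
    "intergenic": (),
}


def promoter_window(tss: int, strand: str, promoter_bp: int = 5500) -> tuple[int, int]:
    """1-based inclusive promoter interval, strictly upstream of the TSS."""
    if strand == "+":
        return tss - promoter_bp, tss - 1
    return tss + 1, tss + promoter_bp


def classify_snp_regions(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    features: pd.DataFrame,
    promoter_bp: int = 5500,
) -> pd.DataFrame:
    """Per-(SNP, gene) region classification.

    Parameters
    ----------
    snps : columns ``snp_id``, ``chrom``, ``pos`` (1-based), ``consequence``
        (``nonsynonymous``/``synonymous`` for exonic SNPs, empty otherwise).
    genes : columns ``gene_id``, ``chrom``, ``strand``, ``tss``, ``start``, ``end``.
    features : columns ``gene_id``, ``feature`` in {utr5, exon, intron, utr3},
        ``start``, ``end`` (1-based inclusive).

    Returns a frame with one row per (snp_id, gene_id) match, region class in
    ``region``; SNPs matching no gene get a single ``intergenic`` row with
    gene_id "".
    """
    snps = snps.reset_index(drop=True)
    feat_by_gene: dict[str, list[tuple[int, int, str]]] = {
        g: sorted(zip(f["start"], f["end"], f["feature"]))
        for g, f in features.groupby("gene_id")
    }
    known_chroms = set(genes["chrom"].astype(str))
    rows: list[tuple[object, str, str]] = []
    matched = np.zeros(len(snps), dtype=bool)
    n_unknown_chrom = int((~snps["chrom"].astype(str).isin(known_chroms)).sum())

    snp_ids = snps["snp_id"].to_numpy()
    conseq = snps.get("consequence", pd.Series([""] * len(snps))).fillna("").to_numpy()
    for chrom, chrom_snps in snps.groupby(snps["chrom"].astype(str)):
        order = np.argsort(chrom_snps["pos"].to_numpy(), kind="stable")
        sidx = chrom_snps.index.to_numpy()[order]
        pos_sorted = chrom_snps["pos"].to_numpy()[order]
        for g in genes[genes["chrom"].astype(str) == chrom].itertuples(index=False):
            plo, phi = promoter_window(int(g.tss), g.strand, promoter_bp)
            lo = min(int(g.start), plo)
            hi = max(int(g.end), phi)
            a, b = np.searchsorted(pos_sorted, (lo, hi + 1))
            feats = feat_by_gene.get(g.gene_id, [])
            for k in range(a, b):
                i = sidx[k]
                pos = int(pos_sorted[k])
                region = _classify_for_gene(pos, conseq[i], g, plo, phi, feats)
                if region is not None:
                    rows.append((snp_ids[i], g.gene_id, region))
                    matched[i] = True
    for i in np.flatnonzero(~matched):
        rows.append((snp_ids[i], "", "intergenic"))
    out = pd.DataFrame(rows, columns=["snp_id", "gene_id", "region"])
    out = out.sort_values(["snp_id", "gene_id"]).reset_index(drop=True)
    out.attrs["n_unknown_chrom"] = n_unknown_chrom
    return out


def _classify_for_gene(pos, consequence, gene, plo, phi, feats):
    """Region of a position w.r.t. one gene, or None if unrelated."""
    if not (int(gene.start) <= pos <= int(gene.end)):
        return "promoter" if plo <= pos <= phi else None
    hit_kinds = {kind for s, e, kind in feats if s <= pos <= e}
    for feature in ("exon", "utr5", "utr3", "intron"):   # precedence
        if feature in hit_kinds:
            if feature == "exon":
                return "nsSNP" if consequence == "nonsynonymous" else "sSNP"
            return feature
    # inside the gene span but in no feature: treat as intronic
    return "intron"


def is_potentially_functional(region: str, flags: Mapping[str, bool]) -> bool:
    """Apply the region-specific evidence decision table to one SNP."""
    if region not in REGIONS:
        raise ValueError(f"unknown region class: {region}")
    return any(bool(flags.get(cat, False)) for cat in REGION_EVIDENCE[region])


def pf_mask(annotations: pd.DataFrame, evidence: pd.DataFrame) -> pd.Series:
    """Vectorised pf call per (SNP, gene) annotation row.

    ``evidence`` is indexed (or indexable) by ``snp_id`` with one boolean
    column per category; SNPs absent from the table carry no evidence.
    """
    ev = evidence.set_index("snp_id") if "snp_id" in evidence.columns else evidence
    out = np.zeros(len(annotations), dtype=bool)
    present = annotations["snp_id"].isin(ev.index).to_numpy()
    sub = annotations.loc[present]
    ev_rows = ev.reindex(sub["snp_id"])
    vals = np.zeros(len(sub), dtype=bool)
    for region, cats in REGION_EVIDENCE.items():
        sel = (sub["region"] == region).to_numpy()
        if not sel.any() or not cats:
            continue
        block = ev_rows.iloc[sel][list(cats)].to_numpy(dtype=bool)
        vals[sel] = block.any(axis=1)
    out[present] = vals
    return pd.Series(out, index=annotations.index, name="pf")


@dataclass
class GeneSets:
    """pdGene and pf-pdGene sets of one population pair."""

    pair: str
    pd_genes: set[str] = field(default_factory=set)
    pf_pd_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.pf_pd_genes <= self.pd_genes:
            raise ValueError("pf-pdGene set must be a subset of the pdGene set")


def derive_gene_sets(
    pd_calls: Mapping[str, PdCallSet],
    annotations: pd.DataFrame,
    evidence: pd.DataFrame,
) -> dict[str, GeneSets]:
    """pdGene / pf-pdGene sets per pair from pdSNP calls and annotations."""
    genic = annotations[annotations["gene_id"] != ""].copy()
    genic["pf"] = pf_mask(genic, evidence)
    sets: dict[str, GeneSets] = {}
    for pair, call in pd_calls.items():
        hit = genic[genic["snp_id"].isin(call.snp_ids)]
        pd_genes = set(hit["gene_id"])
        pf_pd = set(hit.loc[hit["pf"], "gene_id"])
        sets[pair] = GeneSets(pair=pair, pd_genes=pd_genes, pf_pd_genes=pf_pd)
    return sets
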