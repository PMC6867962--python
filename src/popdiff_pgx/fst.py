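"""Nei-style pairwise F_ST and population-differentiated SNP calling.

For a biallelic SNP observed in two populations with allele frequencies
``p_1, p_2`` and diploid sample sizes ``n_1, n_2`` (``N = n_1 + n_2``),

    H_S = 1 - (1/N) * sum_k n_k [p_k^2 + (1 - p_k)^2]
    H_T = 1 - [M^2 + (1 - M)^2]
    F_ST = (H_T - H_S) / H_T

where ``M`` is by default the sample-size-weighted mean frequency
``(n_1 p_1 + n_2 p_2) / N``. With weighted ``M``, heterozygosity is concave
in the frequency, so ``H_T >= H_S`` and ``F_ST`` lies in [0, 1]. The
unweighted-mean variant is available for comparison; any negative values it
produces are clamped to 0 and counted.

A SNP is a pdSNP for a population pair when its F_ST ranks in the top 1%
(by default) of all eligible F_ST values for that pair; ties with the cutoff
value are all included.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class AlleleFrequencyTable:
    """Per-SNP, per-population alternate-allele frequency and called sample size."""

    snp_ids: np.ndarray          # (n_snps,) str
    populations: list[str]
    p: np.ndarray                # (n_snps, n_pops) frequency of the ALT allele
    n: np.ndarray                # (n_snps, n_pops) individuals with called genotypes

    def __post_init__(self) -> None:
        called = self.n > 0
        if np.any((self.p[called] < 0) | (self.p[called] > 1)):
            raise ValueError("allele frequencies outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for j, pop in enumerate(self.populations):
            recs.append(pd.DataFrame({
                "snp_id": self.snp_ids, "population": pop,
                "freq": self.p[:, j], "n_called": self.n[:, j],
            }))
        return pd.concat(recs, ignore_index=True)


def allele_frequencies(
    genotypes: np.ndarray,
    sample_populations: Sequence[str],
    populations: Sequence[str],
    snp_ids: Sequence[str] | None = None,
) -> AlleleFrequencyTable:
    """Per-population ALT allele frequencies from a dosage matrix.

    ``genotypes`` is (n_snps, n_samples) with entries 0/1/2 (ALT dosage) or
    -1 for a missing call. Missing genotypes are excluded from both the
    numerator and the denominator.
    """
    sample_populations = np.asarray(sample_populations)
    unknown = set(sample_populations) - set(populations)
    if unknown:
        raise ValueError(f"samples assigned to unknown populations: {sorted(unknown)}")
    n_snps = genotypes.shape[0]
    if snp_ids is None:
        snp_ids = np.array([f"snp{i}" for i in range(n_snps)])
    p = np.zeros((n_snps, len(populations)))
    n = np.zeros((n_snps, len(populations)), dtype=np.int64)
    for j, pop in enumerate(populations):
        g = genotypes[:, sample_populations == pop]
        called = g >= 0
        n[:, j] = called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, j] = np.where(n[:, j] > 0, alt / (2.0 * n[:, j]), 0.0)
    return AlleleFrequencyTable(np.asarray(snp_ids), list(populations), p, n)


def pairwise_fst(p1, n1, p2, n2, m_weighting: str = "weighted"):
    """Vectorised H_S, H_T, F_ST for one population pair.

    Returns ``(h_s, h_t, fst, eligible)``; a site is ineligible when either
    population has no called individuals or when H_T = 0 (monomorphic across
    both populations). Ineligible entries carry NaN.
    """
    p1, n1, p2, n2 = (np.asarray(a, dtype=float) for a in (p1, n1, p2, n2))
    if np.any((n1 < 0) | (n2 < 0)):
        raise ValueError("negative sample size")
    if p1.ndim == 0 and (n1 == 0 or n2 == 0):
        raise ValueError("zero sample size in pairwise_fst")
    has_n = (n1 > 0) & (n2 > 0)
    N = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        h_s = 1.0 - (n1 * (p1**2 + (1 - p1) ** 2) + n2 * (p2**2 + (1 - p2) ** 2)) / N
        if m_weighting == "weighted":
            M = (n1 * p1 + n2 * p2) / N
        elif m_weighting == "unweighted":
            M = (p1 + p2) / 2.0
        else:
            raise ValueError("m_weighting must be 'weighted' or 'unweighted'")
        h_t = 1.0 - (M**2 + (1 - M) ** 2)
        eligible = has_n & (h_t > 0)
        fst = np.where(eligible, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), np.nan)
    if m_weighting == "weighted":
        # H_T >= H_S holds exactly under weighted M; excursions are roundoff
        fst = np.where(eligible, np.clip(fst, 0.0, 1.0), fst)
    else:
        neg = eligible & (fst < 0)
        n_clamped = int(np.sum(neg))
        fst = np.where(neg, 0.0, fst)
        pairwise_fst.last_n_clamped = n_clamped
    h_s = np.where(has_n, h_s, np.nan)
    h_t = np.where(has_n, h_t, np.nan)
    return h_s, h_t, fst, eligible


pairwise_fst.last_n_clamped = 0


def population_pairs(populations: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered population pairs, in lexicographic panel order."""
    if len(populations) < 2:
        raise ValueError("need at least 2 populations")
    return list(itertools.combinations(populations, 2))


def pair_label(a: str, b: str) -> str:
    return f"{a}-{b}"


@dataclass
class FstMatrix:
    """SNP x population-pair F_ST with an eligibility mask."""

    snp_ids: np.ndarray
    pairs: list[str]                  # "POP1-POP2" labels
    fst: np.ndarray                   # (n_snps, n_pairs), NaN where ineligible
    eligible: np.ndarray              # (n_snps, n_pairs) bool
    h_s: np.ndarray | None = None
    h_t: np.ndarray | None = None

    def column(self, pair: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.pairs.index(pair)
        return self.fst[:, j], self.eligible[:, j]

    def to_frame(self) -> pd.DataFrame:
        n_snps, n_pairs = self.fst.shape
        return pd.DataFrame({
            "snp_id": np.repeat(self.snp_ids, n_pairs),
            "pair": np.tile(self.pairs, n_snps),
            "fst": self.fst.ravel(),
            "eligible": self.eligible.ravel(),
        })


def fst_matrix(freqs: AlleleFrequencyTable, m_weighting: str = "weighted") -> FstMatrix:
    """F_ST for every SNP and every unordered population pair."""
    pairs = population_pairs(freqs.populations)
    n_snps = len(freqs.snp_ids)
    fst = np.full((n_snps, len(pairs)), np.nan)
    elig = np.zeros((n_snps, len(pairs)), dtype=bool)
    hs_m = np.full_like(fst, np.nan)
    ht_m = np.full_like(fst, np.nan)
    idx = {pop: j for j, pop in enumerate(freqs.populations)}
    for c, (a, b) in enumerate(pairs):
        ja, jb = idx[a], idx[b]
        h_s, h_t, f, e = pairwise_fst(
            freqs.p[:, ja], freqs.n[:, ja], freqs.p[:, jb], freqs.n[:, jb],
            m_weighting=m_weighting,
        )
        fst[:, c], elig[:, c], hs_m[:, c], ht_m[:, c] = f, e, h_s, h_t
    labels = [pair_label(a, b) for a, b in pairs]
    return FstMatrix(freqs.snp_ids, labels, fst, elig, hs_m, ht_m)


@dataclass
class PdCallSet:
    """pdSNPs of one population pair: the top-q fraction of eligible F_ST values."""

    pair: str
    quantile: float
    threshold: float
    snp_ids: set[str] = field(default_factory=set)


def call_pdsnps(fst_col: np.ndarray, eligible: np.ndarray, snp_ids: np.ndarray,
                pair: str = "", q: float = 0.01) -> PdCallSet:
    """Call pdSNPs: rank eligible SNPs by F_ST descending, keep the top
    ``ceil(q * n_eligible)``, including every SNP tied with the cutoff value.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    vals = fst_col[eligible]
    ids = np.asarray(snp_ids)[eligible]
    n_elig = vals.size
    if n_elig == 0:
        raise ValueError("no eligible SNPs in column")
    k = math.ceil(q * n_elig)
    order = np.argsort(-vals, kind="stable")
    threshold = float(vals[order[k - 1]])
    members = ids[vals >= threshold]
    return PdCallSet(pair=pair, quantile=q, threshold=threshold, snp_ids=set(members.tolist()))


def call_pdsnps_all_pairs(mat: FstMatrix, q: float = 0.01) -> dict[str, PdCallSet]:
    return {
        pair: call_pdsnps(mat.fst[:, j], mat.eligible[:, j], mat.snp_ids, pair=pair, q=q)
        for j, pair in enumerate(mat.pairs)
    }
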