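"""Relating enrichment profiles to PGx labels, ADR reports and literature.

Drugs are grouped by pharmacogenomic warning-label tier or by the presence of
adverse-drug-reaction (ADR) reports, and the distributions of their
significant-population-pair counts are compared via empirical CDFs and a
pooled-variance two-sided Student's t-test (the groups are assumed
homoscedastic; a Welch option is exposed). Literature-reported
(drug, population-pair) response-difference cases are checked for concordance
with the enrichment calls: a case is detected when the drug's Z in the mapped
pair exceeds the threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LABEL_TIERS = ("required", "recommended_actionable_informative", "none")

#: Raw PharmGKB-style levels -> the three reporting tiers.
LABEL_COLLAPSE = {
    "testing_required": "required",
    "testing_recommended": "recommended_actionable_informative",
    "actionable": "recommended_actionable_informative",
    "informative": "recommended_actionable_informative",
    "none": "none",
}


def collapse_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Map raw PGx levels to the three analysis tiers (column ``tier``)."""
    out = labels.copy()
    unknown = set(out["label"]) - set(LABEL_COLLAPSE)
    if unknown:
        raise ValueError(f"unknown PGx labels: {sorted(unknown)}")
    out["tier"] = out["label"].map(LABEL_COLLAPSE)
    return out


def ecdf_by_group(counts: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Right-continuous empirical CDF of significant-pair counts per group.

    ``counts`` has columns ``drug_id``, ``n_sig_pairs`` and ``group_col``.
    Returns tidy rows (group, count, fraction) with fraction = F(count).
    """
    rows = []
    for group, sub in counts.groupby(group_col):
        x = np.sort(sub["n_sig_pairs"].to_numpy())
        if x.size == 0:
            logger.info("empty group %s omitted from CDF", group)
            continue
        uniq = np.unique(x)
        frac = np.searchsorted(x, uniq, side="right") / x.size
        rows.extend((group, int(u), float(f)) for u, f in zip(uniq, frac))
    return pd.DataFrame(rows, columns=[group_col, "count", "fraction"])


@dataclass
class GroupComparison:
    t: float
    p: float
    df: float
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float


def compare_group_means(a, b, welch: bool = False) -> GroupComparison:
    """Two-sided Student's t-test on two groups of per-drug counts.

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption. Zero pooled variance with equal means gives p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / a.size + vb / b.size
        if se2 == 0:
            return GroupComparison(0.0, 1.0, a.size + b.size - 2, ma, mb, 0.0, 0.0)
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    else:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / df
        if sp2 == 0:
            return GroupComparison(0.0, 1.0, df, ma, mb, 0.0, 0.0)
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(float(t), float(p), float(df), float(ma), float(mb),
                           float(np.sqrt(va / a.size)), float(np.sqrt(vb / b.size)))


@dataclass
class ConcordanceReport:
    detail: pd.DataFrame      # drug, pair, z, detected (+ optional F_ST extremes)
    excluded: list[str]       # case drugs absent from the Z matrix
    n_cases: int
    n_detected: int

    @property
    def detection_rate(self) -> float:
        return self.n_detected / self.n_cases if self.n_cases else 0.0


def literature_concordance(
    cases: pd.DataFrame,
    zmatrix_table: pd.DataFrame,
    threshold: float = 2.58,
    fst_extremes: pd.DataFrame | None = None,
) -> ConcordanceReport:
    """Concordance of literature-reported cases with the enrichment calls.

    ``cases`` has columns ``drug_id`` and ``pair`` (the mapped most-similar
    population pair, curated in the input). Case drugs without any Z-score
    are excluded and listed separately. ``fst_extremes`` (optional columns
    ``drug_id``, ``pair``, ``max_fst``, ``min_fst``) is attached when given.
    """
    ztab = zmatrix_table.set_index(["drug", "pair"])["z"]
    known_drugs = set(zmatrix_table["drug"])
    rows, excluded = [], []
    for case in cases.itertuples(index=False):
        if case.drug_id not in known_drugs:
            excluded.append(case.drug_id)
            continue
        z = float(ztab.get((case.drug_id, case.pair), float("nan")))
        detected = (not np.isnan(z)) and z > threshold
        rows.append((case.drug_id, case.pair, z, detected))
    detail = pd.DataFrame(rows, columns=["drug_id", "pair", "z", "detected"])
    if fst_extremes is not None and len(detail):
        detail = detail.merge(fst_extremes, on=["drug_id", "pair"], how="left")
    return ConcordanceReport(detail=detail, excluded=excluded,
                             n_cases=len(detail), n_detected=int(detail["detected"].sum()))


def adr_profile_compare(
    adr_tables: dict[str, pd.DataFrame],
    drug_summary: pd.DataFrame,
    top_k: int = 20,
    many_pairs_cutoff: int = 10,
) -> pd.DataFrame:
    """Compare per-source ADR report shares for the union of top-k drugs.

    ``adr_tables`` maps source id -> frame with ``drug_id`` and ``n_reports``;
    ``drug_summary`` has ``drug_id`` and ``n_sig_pairs``. Each drug's share is
    its fraction of the source's total reports. Drugs significant in at least
    ``many_pairs_cutoff`` pairs are flagged ``many_pairs`` (the inverse of the
    "halo" mark on drugs with fewer than 10 differentiated pairs).
    """
    shares = {}
    top_union: set[str] = set()
    for source, tab in adr_tables.items():
        agg = tab.groupby("drug_id")["n_reports"].sum()
        total = agg.sum()
        shares[source] = agg / total if total > 0 else agg.astype(float)
        top_union |= set(agg.sort_values(ascending=False).head(top_k).index)
    nsig = drug_summary.set_index("drug_id")["n_sig_pairs"]
    rows = []
    for drug in sorted(top_union):
        row = {"drug_id": drug}
        for source in adr_tables:
            row[f"share_{source}"] = float(shares[source].get(drug, 0.0))
        row["n_sig_pairs"] = int(nsig.get(drug, 0))
        row["many_pairs"] = row["n_sig_pairs"] >= many_pairs_cutoff
        rows.append(row)
    return pd.DataFrame(rows)
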