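"""Ranking of drug classes and disease groups by population differentiation.

Each drug's score is mode(Z) x (number of significantly enriched population
pairs), where the mode is taken over the drug's defined per-pair Z-scores
after rounding to one decimal (modal ties resolve to the largest value). A
group's score is the sum of its member scores normalised by the number of
scored members; only groups with at least three scored members are ranked.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def z_mode(z_values: np.ndarray, decimals: int = 1) -> float:
    """Most common Z after rounding; ties resolve to the largest modal value."""
    vals = np.round(np.asarray(z_values, dtype=float), decimals)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    counts = Counter(vals.tolist())
    best = max(counts.values())
    return max(v for v, c in counts.items() if c == best)


def drug_score(z_row: np.ndarray, threshold: float = 2.58, decimals: int = 1) -> float:
    """mode(Z) x count(Z > threshold); undefined Z values are excluded from
    both terms. All-undefined rows score 0."""
    z = np.asarray(z_row, dtype=float)
    defined = z[~np.isnan(z)]
    if defined.size == 0:
        logger.info("drug with no defined Z-scores scored 0")
        return 0.0
    n_sig = int(np.sum(defined > threshold))
    return z_mode(defined, decimals) * n_sig


def drug_scores(zmatrix_table: pd.DataFrame, threshold: float = 2.58,
                decimals: int = 1) -> pd.DataFrame:
    """Per-drug score table from the long-format Z matrix."""
    rows = []
    for drug, sub in zmatrix_table.groupby("drug"):
        z = sub["z"].to_numpy()
        defined = z[~np.isnan(z)]
        rows.append((drug, drug_score(z, threshold, decimals),
                     z_mode(defined, decimals) if defined.size else np.nan,
                     int(np.sum(defined > threshold))))
    return pd.DataFrame(rows, columns=["drug_id", "score", "z_mode", "n_sig_pairs"])


def group_score_and_rank(
    membership: pd.DataFrame,
    scores: pd.DataFrame,
    top_k: int = 30,
    min_members: int = 3,
) -> pd.DataFrame:
    """Rank groups by mean member score.

    ``membership`` has columns ``group_id``, ``kind``, ``drug_id``; ``scores``
    comes from :func:`drug_scores`. Drugs without a score (no defined Z) are
    excluded from both the numerator and the member count; groups with fewer
    than ``min_members`` scored members are excluded. Returns the ranked
    table with a ``top`` flag on the first ``top_k`` rows per kind.
    """
    merged = membership.merge(scores, on="drug_id", how="inner")
    merged = merged[~merged["score"].isna()]
    agg = merged.groupby(["kind", "group_id"]).agg(
        group_score=("score", "mean"),
        n_members=("drug_id", "nunique"),
        total_sig_pairs=("n_sig_pairs", "sum"),
    ).reset_index()
    agg = agg[agg["n_members"] >= min_members].copy()
    agg["rank"] = agg.groupby("kind")["group_score"].rank(
        ascending=False, method="dense").astype(int)
    agg = agg.sort_values(["kind", "rank", "group_id"]).reset_index(drop=True)
    agg["top"] = agg.groupby("kind")["group_score"].rank(
        ascending=False, method="first") <= top_k
    return agg


def member_detail(membership: pd.DataFrame, scores: pd.DataFrame,
                  ranked: pd.DataFrame, top_k: int = 30) -> pd.DataFrame:
    """Per-member significant-pair counts for the top-ranked groups."""
    top = ranked.loc[ranked["top"], ["kind", "group_id"]]
    detail = top.merge(membership, on=["kind", "group_id"]).merge(scores, on="drug_id")
    return detail[["kind", "group_id", "drug_id", "score", "n_sig_pairs"]]
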