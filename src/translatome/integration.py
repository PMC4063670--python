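"""Integration of shift calls with expression patterns, and set-level statistics.

A ribosome-load shift can be an active translational event or a passive
consequence of changing mRNA levels: newly made mRNA transiently sits in
lighter fractions (so rising levels, g1, depress apparent load) and decay
preferentially removes lighter mRNA (so falling levels, g2, inflate it).
Translation is therefore considered actively up-regulated unless mRNA
levels are decreasing (g2), and actively down-regulated unless mRNA
levels are increasing (g1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from .polysome import PROP_COLS

__all__ = [
    "REGULATION_CLASSES",
    "classify_regulation",
    "classify_regulation_table",
    "hypergeom_enrichment",
    "compare_score_groups",
    "orf_matched_control",
    "summarize_expression",
]

REGULATION_CLASSES = ("active_up", "passive_up", "active_down", "passive_down", "not_shifted")

_VALID_CALLS = {"up", "down", "none"}
_VALID_GROUPS = {"g0", "g1", "g2", "g3", "g4", "unassigned"}


def classify_regulation(call: str, group: str) -> str:
    """Combine a shift call and a pattern group into a regulation class.

    up + g2 -> passive_up (falling mRNA can explain the load increase);
    down + g1 -> passive_down (rising mRNA can explain the decrease);
    any other shifted combination is active; unshifted genes are
    not_shifted. 'unassigned' tracks count as non-g1/non-g2.
    """
    if call not in _VALID_CALLS:
        raise ValueError(f"unknown shift call {call!r}")
    if group not in _VALID_GROUPS:
        raise ValueError(f"unknown pattern group {group!r}")
    if call == "none":
        return "not_shifted"
    if call == "up":
        return "passive_up" if group == "g2" else "active_up"
    return "passive_down" if group == "g1" else "active_down"


def classify_regulation_table(calls: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Row-wise regulation classes for genes present in both tables."""
    merged = calls[["gene_id", "call"]].merge(groups[["gene_id", "group"]], on="gene_id", how="inner")
    merged["regulation"] = [
        classify_regulation(c, g) for c, g in zip(merged["call"], merged["group"])
    ]
    return merged


def hypergeom_enrichment(selection, annotation, universe) -> dict:
    """Upper-tail hypergeometric enrichment of an annotation set in a selection.

    With N = |universe|, K = |annotation ∩ universe|, n = |selection| and
    k = |selection ∩ annotation|, returns p = P(X >= k) for
    X ~ Hypergeometric(N, K, n).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selection = set(selection)
    if not selection <= universe:
        raise ValueError("selection must be a subset of the universe")
    annot = set(annotation) & universe
    k = len(selection & annot)
    N, K, n = len(universe), len(annot), len(selection)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return {"k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)}


def compare_score_groups(scores_by_group: dict, reference: str = "g0") -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests of each group against a reference."""
    if reference not in scores_by_group:
        raise ValueError(f"reference group {reference!r} missing")
    ref = np.asarray(scores_by_group[reference], dtype=float)
    rows = []
    for name, vals in scores_by_group.items():
        if name == reference:
            continue
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2 or ref.size < 2:
            raise ValueError(f"group {name!r} or reference has fewer than 2 observations")
        stat, p = mannwhitneyu(vals, ref, alternative="two-sided")
        rows.append({"group": name, "reference": reference, "n": vals.size, "u": stat, "p": p})
    return pd.DataFrame(rows)


def orf_matched_control(
    focal_gene: str,
    orf_lengths: pd.Series,
    dists: pd.DataFrame,
    window: int = 25,
) -> dict:
    """ORF-length-matched control group for one gene.

    Members are all other genes whose (longest-isoform) ORF length lies
    within ±``window`` nt of the focal gene's. Returns the member list and
    the mean pool distribution of the members per condition (an empty
    summary, flagged, when no gene matches).
    """
    if focal_gene not in orf_lengths.index:
        raise ValueError(f"no ORF length for focal gene {focal_gene!r}")
    focal_len = orf_lengths[focal_gene]
    members = orf_lengths.index[
        (np.abs(orf_lengths - focal_len) <= window) & (orf_lengths.index != focal_gene)
    ].tolist()
    summary = {"focal_gene": focal_gene, "window": window, "members": members, "empty": not members}
    if members:
        sub = dists[dists["gene_id"].isin(members) & dists["valid"]]
        summary["mean_distribution"] = sub.groupby("condition")[list(PROP_COLS)].mean()
    else:
        summary["mean_distribution"] = pd.DataFrame(columns=list(PROP_COLS))
    return summary


def summarize_expression(
    rpkm_table: pd.DataFrame,
    gene_sets: dict,
    before: str,
    after: str,
) -> pd.DataFrame:
    """Median rpkm before/after stimulation and fold induction per gene set.

    ``rpkm_table`` is gene x sample; the fold induction is the ratio of
    the after-median to the before-median.
    """
    for col in (before, after):
        if col not in rpkm_table.columns:
            raise ValueError(f"sample column {col!r} not in rpkm table")
    rows = []
    for name, members in gene_sets.items():
        sub = rpkm_table.loc[rpkm_table.index.intersection(list(members))]
        if sub.empty:
            raise ValueError(f"gene set {name!r} has no member in the rpkm table")
        med_before = float(sub[before].median())
        med_after = float(sub[after].median())
        fold = med_after / med_before if med_before > 0 else np.inf
        rows.append(
            {
                "set": name,
                "n": len(sub),
                "median_before": med_before,
                "median_after": med_after,
                "fold_induction": fold,
            }
        )
    return pd.DataFrame(rows)
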