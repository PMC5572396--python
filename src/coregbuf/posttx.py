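"""Post-transcriptional similarity predicates and buffering enrichment.

A gene pair co-regulated at both expression layers is *sustained*; one
co-regulated at the mRNA level only is *buffered*. Five predicates probe
whether a pair shares post-transcriptional control: similar mRNA
half-life (ratio of the more to the less stable < 1.5), at least one
shared targeting miRNA, correlated ribosome-occupancy profiles
(PCC > 0.5, BH-adjusted p < 0.001), at least one non-exponentially
degraded (NED) protein, and similar coding length (longer protein
< 1.5-fold the shorter). Fisher's exact test compares predicate rates
between sustained and buffered pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError

RATIO_THRESHOLD = 1.5
ASSOCIATION_SCORE_THRESHOLD = 0.7
PARALOG_MIN_IDENTITY = 25.0

PREDICATES = (
    "similar_half_life",
    "shared_mirna",
    "correlated_ribosome",
    "any_ned",
    "similar_length",
)


def _ratio_similar(a: pd.Series, b: pd.Series, threshold: float) -> pd.Series:
    """max/min ratio < threshold; NaN where either side is absent."""
    va = a.to_numpy(float)
    vb = b.to_numpy(float)
    if np.nanmin(np.concatenate([va[np.isfinite(va)], vb[np.isfinite(vb)]])) <= 0:
        raise DataError("half-lives and lengths must be positive")
    with np.errstate(invalid="ignore"):
        ratio = np.maximum(va, vb) / np.minimum(va, vb)
    out = pd.Series(ratio < threshold, dtype=object)
    out[~np.isfinite(ratio)] = np.nan
    return out


def posttx_predicates(
    pairs: pd.DataFrame,
    half_life: pd.Series | None = None,
    mirna_targets: dict[str, frozenset] | None = None,
    ribosome_results: pd.DataFrame | None = None,
    ned: pd.Series | None = None,
    length: pd.Series | None = None,
    ratio_threshold: float = RATIO_THRESHOLD,
) -> pd.DataFrame:
    """Evaluate the five post-transcriptional predicates per pair.

    Absent annotations yield NaN for that predicate (the pair drops out of
    that predicate's denominator downstream). ``ribosome_results`` is a
    co-regulation call table on the ribosome layer for the same pairs.
    """
    out = pairs[["gene_a", "gene_b"]].copy().reset_index(drop=True)
    ga, gb = out["gene_a"], out["gene_b"]
    nan_col = pd.Series(np.nan, index=out.index, dtype=object)

    if half_life is not None:
        out["similar_half_life"] = _ratio_similar(
            half_life.reindex(ga).reset_index(drop=True),
            half_life.reindex(gb).reset_index(drop=True),
            ratio_threshold,
        )
    else:
        out["similar_half_life"] = nan_col

    if mirna_targets is not None:
        shared = [
            bool(mirna_targets.get(a, frozenset()) & mirna_targets.get(b, frozenset()))
            if (a in mirna_targets or b in mirna_targets)
            else np.nan
            for a, b in zip(ga, gb)
        ]
        out["shared_mirna"] = pd.Series(shared, dtype=object)
    else:
        out["shared_mirna"] = nan_col

    if ribosome_results is not None:
        key = ribosome_results["gene_a"] + "|" + ribosome_results["gene_b"]
        calls = pd.Series(
            ribosome_results["co_regulated"].to_numpy(), index=key
        )
        defined = pd.Series(ribosome_results["defined"].to_numpy(), index=key)
        pk = ga + "|" + gb
        vals = calls.reindex(pk).to_numpy(object)
        und = ~defined.reindex(pk).fillna(False).to_numpy(bool)
        col = pd.Series(vals, index=out.index, dtype=object)
        col[und] = np.nan
        out["correlated_ribosome"] = col
    else:
        out["correlated_ribosome"] = nan_col

    if ned is not None:
        na = ned.reindex(ga).reset_index(drop=True)
        nb = ned.reindex(gb).reset_index(drop=True)
        any_ned = (na.fillna(False).astype(bool)) | (nb.fillna(False).astype(bool))
        undef = na.isna() & nb.isna()
        col = any_ned.astype(object)
        col[undef] = np.nan
        out["any_ned"] = col
    else:
        out["any_ned"] = nan_col

    if length is not None:
        out["similar_length"] = _ratio_similar(
            length.reindex(ga).reset_index(drop=True),
            length.reindex(gb).reset_index(drop=True),
            ratio_threshold,
        )
    else:
        out["similar_length"] = nan_col
    return out


def sustained_vs_buffered(
    results_mrna: pd.DataFrame, results_protein: pd.DataFrame
) -> pd.DataFrame:
    """Classify pairs as sustained / buffered / neither from two call tables.

    Sustained: co-regulated at both layers; buffered: mRNA only; neither
    otherwise. Pairs lacking a defined call at either layer are excluded
    (their count is reported in the ``n_excluded`` attribute).
    """
    key_m = results_mrna["gene_a"] + "|" + results_mrna["gene_b"]
    key_p = results_protein["gene_a"] + "|" + results_protein["gene_b"]
    m = pd.DataFrame(
        {
            "gene_a": results_mrna["gene_a"].to_numpy(),
            "gene_b": results_mrna["gene_b"].to_numpy(),
            "m_call": results_mrna["co_regulated"].to_numpy(),
            "m_def": results_mrna["defined"].to_numpy(),
        },
        index=key_m,
    )
    p = pd.DataFrame(
        {"p_call": results_protein["co_regulated"].to_numpy(),
         "p_def": results_protein["defined"].to_numpy()},
        index=key_p,
    )
    joined = m.join(p, how="inner")
    defined = joined["m_def"].astype(bool) & joined["p_def"].astype(bool)
    n_excluded = int((~defined).sum()) + abs(len(m) - len(joined))
    joined = joined[defined]
    cat = np.where(
        joined["m_call"].astype(bool) & joined["p_call"].astype(bool),
        "sustained",
        np.where(joined["m_call"].astype(bool), "buffered", "neither"),
    )
    out = joined[["gene_a", "gene_b"]].copy()
    out["category"] = cat
    out = out.reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    return out


def enrichment_test(
    flag: pd.Series,
    groups: pd.Series,
    sided: str = "one",
) -> dict:
    """Fisher's exact test of a predicate between sustained and buffered pairs.

    ``flag`` and ``groups`` are aligned by index; NaN flags drop out. The
    2×2 table is [[sustained & flag, sustained & not], [buffered & flag,
    buffered & not]]; one-sided tests enrichment in the sustained group.
    Degenerate margins give p = 1 with a warning. Counts are returned for
    audit.
    """
    df = pd.DataFrame({"flag": flag, "group": groups}).dropna()
    df = df[df["group"].isin(["sustained", "buffered"])]
    if (df["group"] == "sustained").sum() == 0 or (df["group"] == "buffered").sum() == 0:
        raise DataError("both groups must be non-empty")
    f = df["flag"].astype(bool)
    g = df["group"]
    table = np.array(
        [
            [int((f & (g == "sustained")).sum()), int((~f & (g == "sustained")).sum())],
            [int((f & (g == "buffered")).sum()), int((~f & (g == "buffered")).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate margin in enrichment table; p set to 1")
        return {"odds_ratio": np.nan, "p_value": 1.0, "table": table}
    alternative = "greater" if sided == "one" else "two-sided"
    odds, p = stats.fisher_exact(table, alternative=alternative)
    # Haldane-Anscombe corrected OR for reporting when a cell is zero
    if 0 in table:
        t = table + 0.5
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {"odds_ratio": float(odds), "p_value": float(p), "table": table}


def derive_mirna_sharing(mirna_table: pd.DataFrame) -> dict[str, frozenset]:
    """gene -> set of targeting miRNAs from a two-column (mirna, gene) table."""
    cols = list(mirna_table.columns[:2])
    grouped = mirna_table.groupby(cols[1])[cols[0]].agg(frozenset)
    return grouped.to_dict()


def filter_paralogs(paralogs: pd.DataFrame, min_identity: float = PARALOG_MIN_IDENTITY) -> pd.DataFrame:
    """Keep paralogous pairs with at least ``min_identity`` % sequence identity."""
    return paralogs[paralogs["percent_identity"] >= min_identity].reset_index(drop=True)
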