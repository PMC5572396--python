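"""Gene expression noise and the three clustering-degree metrics.

Noise is the coefficient of variation of offset log2 ratios across
samples (a constant of 10 is added so the mean cannot be near zero).
Local gene density is summarised per gene by three "clustering degrees":
mean bp distance to the three nearest same-chromosome genes (lower =
denser), and mean Hi-C contact to the three strongest intra- or
interchromosomal partners (higher = denser; the sign convention is
inverted relative to the bp metric because contacts measure closeness).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigError, ExpressionMatrix

NOISE_OFFSET = 10.0
MIN_SEQ_SEPARATION = 500_000
N_NEIGHBOURS = 3


def expression_noise(m: ExpressionMatrix, offset: float = NOISE_OFFSET) -> pd.Series:
    """Per-gene CV of (log2 ratio + offset); sample sd (n−1).

    Genes with fewer than 2 non-missing values are NaN.
    """
    shifted = m.values + offset
    n = shifted.notna().sum(axis=1)
    mean = shifted.mean(axis=1, skipna=True)
    sd = shifted.std(axis=1, ddof=1, skipna=True)
    cv = sd / mean
    cv[n < 2] = np.nan
    cv.name = f"noise_{m.layer}"
    return cv


def clustering_degree_seq(ann: pd.DataFrame, k: int = N_NEIGHBOURS) -> pd.Series:
    """Mean bp distance to the k nearest same-chromosome genes by TSS.

    Undefined (NaN) on chromosomes with fewer than k+1 dataset genes.
    Only genes in the supplied annotation count as neighbours.
    """
    out = pd.Series(np.nan, index=ann.index, name="degree_seq")
    for _, grp in ann.groupby("chromosome", sort=False):
        if len(grp) < k + 1:
            continue
        order = np.argsort(grp["tss"].to_numpy(np.int64), kind="stable")
        tss = grp["tss"].to_numpy(np.int64)[order]
        ids = grp.index.to_numpy()[order]
        n = len(tss)
        vals = np.empty(n)
        for i in range(n):
            # k nearest by |dTSS| lie among the k left and k right neighbours
            cand = []
            for j in range(max(0, i - k), min(n, i + k + 1)):
                if j != i:
                    cand.append(abs(int(tss[j]) - int(tss[i])))
            cand.sort()
            vals[i] = float(np.mean(cand[:k]))
        out.loc[ids] = vals
    return out


def clustering_degree_3d(
    ann: pd.DataFrame,
    contacts: pd.DataFrame,
    mode: str = "intra",
    min_seq_sep: int = MIN_SEQ_SEPARATION,
    k: int = N_NEIGHBOURS,
) -> pd.Series:
    """Mean contact frequency of each gene's k strongest eligible partners.

    ``contacts`` is a pair table with columns gene_a, gene_b, contact (one
    row per unordered pair). In ``intra`` mode only same-chromosome
    partners at least ``min_seq_sep`` bp away (by TSS) are eligible, to
    capture folding rather than sequence proximity; in ``inter`` mode only
    partners on other chromosomes. Genes with fewer than k eligible
    partners are NaN. Higher values mean denser 3D packing.
    """
    if mode not in ("intra", "inter"):
        raise ConfigError("mode must be 'intra' or 'inter'")
    df = contacts.dropna(subset=["contact"])
    chrom = ann["chromosome"]
    tss = ann["tss"]
    ca = chrom.reindex(df["gene_a"]).to_numpy()
    cb = chrom.reindex(df["gene_b"]).to_numpy()
    same = ca == cb
    if mode == "intra":
        da = tss.reindex(df["gene_a"]).to_numpy(np.int64)
        db = tss.reindex(df["gene_b"]).to_numpy(np.int64)
        keep = same & (np.abs(da - db) >= min_seq_sep)
    else:
        keep = ~same
    df = df[keep]
    # directed view so every gene sees all its partners
    directed = pd.DataFrame(
        {
            "gene": np.concatenate([df["gene_a"].to_numpy(), df["gene_b"].to_numpy()]),
            "contact": np.concatenate([df["contact"].to_numpy(float)] * 2),
        }
    )
    name = f"degree_{mode}3d"
    out = pd.Series(np.nan, index=ann.index, name=name)
    grouped = directed.groupby("gene")["contact"]
    counts = grouped.count()
    eligible = counts.index[counts >= k]
    topk = (
        directed[directed["gene"].isin(eligible)]
        .sort_values("contact", ascending=False)
        .groupby("gene")["contact"]
        .head(k)
        .groupby(directed["gene"])
        .mean()
    )
    out.loc[topk.index.intersection(out.index)] = topk
    return out


def extreme_group_comparison(
    values: pd.Series,
    grouping: pd.Series,
    tail: float = 0.05,
) -> dict:
    """Compare a value between the top and bottom tail of a grouping metric.

    Genes are ranked by the grouping metric (ties broken deterministically
    by gene id); the top and bottom ``tail`` fractions are compared with a
    two-sample two-sided Kolmogorov–Smirnov test on the value
    distributions. Returns medians, group sizes, the KS statistic and p,
    plus Tukey boxplot summaries.
    """
    df = pd.DataFrame({"value": values, "group": grouping}).dropna()
    n_tail = int(np.floor(tail * len(df)))
    if n_tail < 1 or len(df) < 2 * n_tail:
        raise ConfigError(f"too few genes ({len(df)}) for tail={tail}")
    df = df.iloc[np.lexsort((df.index.to_numpy(), df["group"].to_numpy()))]
    bottom = df.iloc[:n_tail]
    top = df.iloc[-n_tail:]
    ks = stats.ks_2samp(top["value"], bottom["value"], alternative="two-sided")

    def _tukey(x: pd.Series) -> dict:
        q1, q2, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        return {"q1": q1, "median": q2, "q3": q3, "whisker_lo": lo, "whisker_hi": hi}

    return {
        "median_top": float(top["value"].median()),
        "median_bottom": float(bottom["value"].median()),
        "n_per_group": n_tail,
        "ks_statistic": float(ks.statistic),
        "p_value": float(ks.pvalue),
        "top_genes": list(top.index),
        "bottom_genes": list(bottom.index),
        "boxplot_top": _tukey(top["value"]),
        "boxplot_bottom": _tukey(bottom["value"]),
    }
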