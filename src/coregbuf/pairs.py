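"""Gene-pair classification by genomic relationship.

A pair is *bidirectional* when the two genes sit head-to-head on opposite
strands with < 1 kb between their TSSs and transcribe away from each
other (shared-promoter geometry: the − strand gene's TSS lies left of the
+ strand gene's TSS on the reference). Pairs with TSSs < 50 kb apart that
are not bidirectional are *closeby*; remaining same-chromosome pairs are
*same_chrom_far*; pairs on different chromosomes are *interchromosomal*.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .core import ConfigError

BIDIRECTIONAL_MAX_BP = 1_000
CLOSEBY_MAX_BP = 50_000

ORIENTATION_CLASSES = (
    "bidirectional",
    "closeby",
    "same_chrom_far",
    "interchromosomal",
)


def _is_divergent(strand_a: str, tss_a: int, strand_b: str, tss_b: int) -> bool:
    """Head-to-head test: opposite strands, transcription pointing apart.

    With the − strand member's TSS at ``m`` and the + strand member's at
    ``p``, transcription points apart iff ``m < p`` (the − gene runs left
    from m, the + gene runs right from p, the shared promoter lies between).
    """
    if strand_a == strand_b:
        return False
    if strand_a == "-":
        m, p = tss_a, tss_b
    else:
        m, p = tss_b, tss_a
    return m < p


def classify_pair(a: pd.Series, b: pd.Series) -> dict:
    """Classify one gene pair from two annotation rows.

    Returns a dict with gene_a/gene_b (lexicographically ordered),
    same_chromosome, tss_distance (NaN for interchromosomal pairs) and
    orientation_class. Symmetric in its arguments.
    """
    if a["gene_id"] > b["gene_id"]:
        a, b = b, a
    rec = {
        "gene_a": a["gene_id"],
        "gene_b": b["gene_id"],
        "same_chromosome": a["chromosome"] == b["chromosome"],
    }
    if not rec["same_chromosome"]:
        rec["tss_distance"] = np.nan
        rec["orientation_class"] = "interchromosomal"
        return rec
    d = int(abs(int(a["tss"]) - int(b["tss"])))
    rec["tss_distance"] = d
    divergent = _is_divergent(a["strand"], int(a["tss"]), b["strand"], int(b["tss"]))
    if divergent and d < BIDIRECTIONAL_MAX_BP:
        rec["orientation_class"] = "bidirectional"
    elif d < CLOSEBY_MAX_BP:
        rec["orientation_class"] = "closeby"
    else:
        rec["orientation_class"] = "same_chrom_far"
    return rec


def enumerate_pairs(ann: pd.DataFrame, scope: str = "all", window: int | None = None) -> pd.DataFrame:
    """Enumerate unique unordered gene pairs within a scope.

    scope: ``"all"`` (every pair), ``"intra"`` (same chromosome) or
    ``"window"`` (same chromosome with tss_distance < ``window`` bp).
    Returns the classified pair table.
    """
    if len(ann) < 2:
        raise ConfigError("need at least 2 genes")
    if scope == "window":
        if window is None or window <= 0:
            raise ConfigError("window scope requires a positive window size")
        return _window_pairs(ann, window)
    if scope == "intra":
        frames = [
            _all_pairs(grp) for _, grp in ann.groupby("chromosome", sort=False) if len(grp) >= 2
        ]
        if not frames:
            return _empty_pairs()
        return pd.concat(frames, ignore_index=True)
    if scope == "all":
        return _all_pairs(ann)
    raise ConfigError(f"unknown scope {scope!r}")


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene_a", "gene_b", "same_chromosome", "tss_distance", "orientation_class"]
    )


def _all_pairs(ann: pd.DataFrame) -> pd.DataFrame:
    rows = [
        classify_pair(ann.iloc[i], ann.iloc[j])
        for i, j in itertools.combinations(range(len(ann)), 2)
    ]
    return pd.DataFrame(rows) if rows else _empty_pairs()


def _window_pairs(ann: pd.DataFrame, window: int) -> pd.DataFrame:
    """Same-chromosome pairs with TSS distance < window, via a sorted sweep."""
    rows = []
    for _, grp in ann.groupby("chromosome", sort=False):
        order = np.lexsort((grp.index.to_numpy(), grp["tss"].to_numpy()))
        grp = grp.iloc[order]
        tss = grp["tss"].to_numpy(np.int64)
        for i in range(len(grp)):
            j = i + 1
            while j < len(grp) and tss[j] - tss[i] < window:
                rows.append(classify_pair(grp.iloc[i], grp.iloc[j]))
                j += 1
    return pd.DataFrame(rows) if rows else _empty_pairs()


def classify_pairs_vectorized(ann: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Classify many (gene_a, gene_b) rows at once.

    Faster path used by the pipeline; equivalent to mapping
    :func:`classify_pair` over the rows.
    """
    a = ann.loc[pairs["gene_a"]]
    b = ann.loc[pairs["gene_b"]]
    swap = (a["gene_id"].to_numpy() > b["gene_id"].to_numpy())
    ga = np.where(swap, b["gene_id"].to_numpy(), a["gene_id"].to_numpy())
    gb = np.where(swap, a["gene_id"].to_numpy(), b["gene_id"].to_numpy())
    a = ann.loc[ga]
    b = ann.loc[gb]
    same_chrom = a["chromosome"].to_numpy() == b["chromosome"].to_numpy()
    tss_a = a["tss"].to_numpy(np.int64)
    tss_b = b["tss"].to_numpy(np.int64)
    dist = np.abs(tss_a - tss_b).astype(float)
    dist[~same_chrom] = np.nan
    sa = a["strand"].to_numpy()
    sb = b["strand"].to_numpy()
    m = np.where(sa == "-", tss_a, tss_b)
    p = np.where(sa == "-", tss_b, tss_a)
    divergent = (sa != sb) & (m < p)
    cls = np.full(len(pairs), "same_chrom_far", dtype=object)
    cls[~same_chrom] = "interchromosomal"
    cls[same_chrom & (dist < CLOSEBY_MAX_BP)] = "closeby"
    cls[same_chrom & divergent & (dist < BIDIRECTIONAL_MAX_BP)] = "bidirectional"
    return pd.DataFrame(
        {
            "gene_a": ga,
            "gene_b": gb,
            "same_chromosome": same_chrom,
            "tss_distance": dist,
            "orientation_class": cls,
        }
    )


def pair_key(df: pd.DataFrame) -> pd.Index:
    """Canonical 'gene_a|gene_b' key for joining pair tables."""
    return pd.Index(df["gene_a"].astype(str) + "|" + df["gene_b"].astype(str))
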