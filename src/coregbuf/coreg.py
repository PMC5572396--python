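"""Pairwise co-regulation statistics, calls and chromosome maps.

Co-regulation of a gene pair is coordinated up/down movement of its log2
ratios across samples, measured by Pearson's correlation over
pairwise-complete observations. A pair is called co-regulated when
PCC > 0.5 and the Benjamini-Hochberg adjusted two-sided p-value < 0.001;
anti-regulation (PCC < −0.5 at the same significance) is recorded
separately. Adjustment is always performed within the pair set of one
named analysis, never across analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ConfigError, DataError, ExpressionMatrix

PCC_THRESHOLD = 0.5
ADJ_P_THRESHOLD = 0.001
DEFAULT_MIN_OVERLAP = 30


def _pcc_p_value(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for a Pearson r via the t-transform with n-2 df."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = n - 2
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isclose(np.abs(r), 1.0) & (df > 0), 0.0, p)
    p = np.where(df <= 0, np.nan, p)
    return p


def pair_pcc(
    m: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[float, int, float]:
    """Pearson correlation of two genes over pairwise-complete samples.

    Returns ``(pcc, n_obs, p_value)``; pcc and p are NaN when fewer than
    ``min_overlap`` paired observations exist or either gene has zero
    variance over the complete pairs.
    """
    for g in (gene_a, gene_b):
        if g not in m.genes:
            raise DataError(f"gene {g!r} absent from {m.layer} matrix")
    x = m.values.loc[gene_a].to_numpy(float)
    y = m.values.loc[gene_b].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < max(min_overlap, 2):
        return (np.nan, n, np.nan)
    xs, ys = x[ok], y[ok]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    den = np.sqrt((xs * xs).sum() * (ys * ys).sum())
    if den == 0:
        return (np.nan, n, np.nan)
    r = float(np.clip((xs * ys).sum() / den, -1.0, 1.0))
    return (r, n, float(_pcc_p_value(r, n)))


def pair_pcc_permutation_p(
    m: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[float, int, float]:
    """Permutation alternative to the t-based p-value (useful at tiny n).

    Permutes one gene's values over the complete pairs; the two-sided p is
    the fraction of permutations with |r| at least as large (add-one
    corrected).
    """
    r, n, _ = pair_pcc(m, gene_a, gene_b, min_overlap)
    if not np.isfinite(r):
        return (r, n, np.nan)
    x = m.values.loc[gene_a].to_numpy(float)
    y = m.values.loc[gene_b].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    xs = x[ok] - x[ok].mean()
    ys = y[ok] - y[ok].mean()
    den = np.sqrt((xs * xs).sum() * (ys * ys).sum())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ys)
        if abs((xs * perm).sum() / den) >= abs(r) - 1e-15:
            hits += 1
    return (r, n, (hits + 1) / (n_permutations + 1))


def pairwise_pcc(
    values: np.ndarray,
    ia: np.ndarray,
    ib: np.ndarray,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    chunk: int = 100_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised pairwise-complete PCC for many (row_a, row_b) index pairs.

    Returns arrays (pcc, n_obs, p_value) aligned with the input pairs.
    """
    ia = np.asarray(ia)
    ib = np.asarray(ib)
    out_r = np.empty(len(ia))
    out_n = np.empty(len(ia), dtype=np.int64)
    for lo in range(0, len(ia), chunk):
        hi = min(lo + chunk, len(ia))
        X = values[ia[lo:hi]]
        Y = values[ib[lo:hi]]
        ok = np.isfinite(X) & np.isfinite(Y)
        Xo = np.where(ok, X, 0.0)
        Yo = np.where(ok, Y, 0.0)
        n = ok.sum(axis=1)
        nf = np.maximum(n, 1).astype(float)
        sx = Xo.sum(axis=1) / nf
        sy = Yo.sum(axis=1) / nf
        Xc = np.where(ok, Xo - sx[:, None], 0.0)
        Yc = np.where(ok, Yo - sy[:, None], 0.0)
        num = (Xc * Yc).sum(axis=1)
        den = np.sqrt((Xc * Xc).sum(axis=1) * (Yc * Yc).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / den
        r[den == 0] = np.nan
        r[n < max(min_overlap, 2)] = np.nan
        out_r[lo:hi] = np.clip(r, -1.0, 1.0)
        out_n[lo:hi] = n
    out_p = _pcc_p_value(out_r, out_n)
    out_p[~np.isfinite(out_r)] = np.nan
    return out_r, out_n, out_p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_coregulation(
    m: ExpressionMatrix,
    pairs: pd.DataFrame,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """PCC + BH over exactly this pair list, with boolean calls.

    Pairs whose PCC is undefined (too few paired samples, zero variance)
    receive no call (NaN statistics, co_regulated False is *not* implied;
    the ``defined`` column flags them). BH adjustment runs over the
    defined p-values of this pair set only.
    """
    if len(pairs) == 0:
        raise ConfigError("pairs must be non-empty")
    idx = pd.Index(m.genes)
    missing = set(pairs["gene_a"]).union(pairs["gene_b"]) - set(idx)
    if missing:
        raise DataError(f"genes absent from {m.layer} matrix: {sorted(missing)[:5]}")
    ia = idx.get_indexer(pairs["gene_a"])
    ib = idx.get_indexer(pairs["gene_b"])
    r, n, p = pairwise_pcc(m.values.to_numpy(float), ia, ib, min_overlap)
    out = pairs.copy().reset_index(drop=True)
    out["layer"] = m.layer
    out["pcc"] = r
    out["n_obs"] = n
    out["p_value"] = p
    adj = np.full(len(out), np.nan)
    defined = np.isfinite(p)
    if defined.any():
        adj[defined] = bh_adjust(p[defined])
    out["adj_p"] = adj
    out["defined"] = defined
    out["co_regulated"] = defined & (r > PCC_THRESHOLD) & (adj < ADJ_P_THRESHOLD)
    out["anti_regulated"] = defined & (r < -PCC_THRESHOLD) & (adj < ADJ_P_THRESHOLD)
    return out


def distance_curve(
    results: pd.DataFrame,
    smoother_span: float = 0.3,
    n_points: int = 200,
) -> pd.DataFrame:
    """Smoothed trend of PCC against TSS distance.

    Local weighted mean with a tricube kernel whose bandwidth at each
    evaluation point covers ``smoother_span`` of the data; being a weighted
    average, the curve is bounded by the PCC values inside each window.
    """
    df = results.dropna(subset=["tss_distance", "pcc"])
    if len(df) < 10:
        raise DataError("need at least 10 intrachromosomal results for a curve")
    if not 0 < smoother_span <= 1:
        raise ConfigError("smoother_span must be in (0, 1]")
    x = df["tss_distance"].to_numpy(float)
    y = df["pcc"].to_numpy(float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    k = max(int(np.ceil(smoother_span * len(x))), 2)
    xs = np.linspace(x[0], x[-1], min(n_points, len(x)))
    out = np.empty_like(xs)
    for i, x0 in enumerate(xs):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            out[i] = y[d == 0].mean()
            continue
        w = (1 - np.clip(d / h, 0, 1) ** 3) ** 3
        if w.sum() == 0:
            w = (d <= h).astype(float)
        out[i] = (w * y).sum() / w.sum()
    return pd.DataFrame({"tss_distance": xs, "mean_pcc": out})


@dataclass
class CoregulationMap:
    """Dense pairwise-PCC matrix over genes in chromosomal order."""

    matrix: pd.DataFrame  # index = row genes, columns = col genes
    layer: str
    genes_rows: list[str] | None = None
    genes_cols: list[str] | None = None

    def __post_init__(self) -> None:
        self.genes_rows = list(self.matrix.index)
        self.genes_cols = list(self.matrix.columns)

    @property
    def is_square(self) -> bool:
        return self.genes_rows == self.genes_cols


def build_map(
    m: ExpressionMatrix,
    genes_rows,
    genes_cols=None,
    min_overlap: int = 2,
) -> CoregulationMap:
    """Full pairwise PCC matrix for an ordered gene list.

    ``genes_cols`` switches to a rectangular (interchromosomal) map. The
    diagonal of a square map is 1 wherever a gene has >= 2 observations.
    """
    genes_rows = list(genes_rows)
    genes_cols = list(genes_cols) if genes_cols is not None else genes_rows
    if len(genes_rows) < 2 or len(genes_cols) < 2:
        raise ConfigError("need at least 2 genes per axis")
    all_genes = list(dict.fromkeys(genes_rows + genes_cols))
    sub = m.values.loc[all_genes].T  # samples x genes
    corr = sub.corr(min_periods=max(min_overlap, 2))
    return CoregulationMap(matrix=corr.loc[genes_rows, genes_cols], layer=m.layer)


def write_map(cmap: CoregulationMap, path, gene_order_path=None) -> None:
    """Write a map as (optionally gzip) TSV plus a gene-order sidecar."""
    path = str(path)
    if path.endswith(".gz"):
        import gzip

        # fixed mtime so repeated runs are byte-identical
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(cmap.matrix.to_csv(sep="\t", na_rep="NA").encode())
    else:
        cmap.matrix.to_csv(path, sep="\t", na_rep="NA")
    if gene_order_path is not None:
        pd.DataFrame(
            {"gene_id": cmap.genes_rows}
        ).to_csv(gene_order_path, sep="\t", index=False)
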