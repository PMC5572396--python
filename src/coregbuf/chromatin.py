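"""Heterochromatin upstream profiles, Mahalanobis epigenetic similarity,
and the similarity × spatial-proximity binning of co-regulation.

Epigenetic similarity between two genes is the Mahalanobis distance of
their gene-body epigenomic feature vectors under the covariance estimated
from all genes; the covariance term matters because several histone marks
(e.g. H3K9ac and H3K4me3) strongly covary and would otherwise be
double-counted. GC content, gene length and replication timing are not
part of the similarity feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .core import ConfigError, DataError, IntervalTrack, INACTIVE_STATE_LABELS

PROFILE_UPSTREAM_BP = 50_000
PROFILE_DOWNSTREAM_BP = 10_000
PROFILE_STEP_BP = 100


def heterochromatin_profile(
    ann: pd.DataFrame,
    track: IntervalTrack,
    inactive_labels=INACTIVE_STATE_LABELS,
    upstream: int = PROFILE_UPSTREAM_BP,
    downstream: int = PROFILE_DOWNSTREAM_BP,
    step: int = PROFILE_STEP_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Fraction of genes with heterochromatin at each offset around the TSS.

    The five inactive chromatin states are merged into one heterochromatin
    state; offsets run from −upstream to +downstream in ``step`` bp
    windows, strand-oriented (negative offsets are 5′ of the TSS). A gene
    whose window at an offset would extend past the chromosome start is
    excluded from that offset's denominator.
    """
    merged = track.subset(inactive_labels).merged()
    offsets = np.arange(-upstream, downstream + step, step)
    frac = np.zeros(len(offsets))
    denom = np.zeros(len(offsets))
    for chrom, grp in ann.groupby("chromosome", sort=False):
        tss = grp["tss"].to_numpy(np.int64)
        minus = (grp["strand"] == "-").to_numpy()
        starts, ends = merged.get(chrom, (np.array([], np.int64), np.array([], np.int64)))
        clen = (chrom_lengths or {}).get(chrom)
        for oi, off in enumerate(offsets):
            # window covering offsets [off, off+step) in transcription orientation
            a = np.where(minus, tss - off - step, tss + off)
            b = a + step
            valid = a >= 0
            if clen is not None:
                valid &= b <= clen
            denom[oi] += valid.sum()
            if starts.size == 0 or not valid.any():
                continue
            av, bv = a[valid], b[valid]
            idx = np.searchsorted(starts, bv, side="left") - 1
            hit = (idx >= 0) & (ends[np.clip(idx, 0, len(ends) - 1)] > av)
            frac[oi] += hit.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(denom > 0, frac / denom, np.nan)
    return pd.DataFrame({"offset": offsets, "fraction": fraction, "n_genes": denom.astype(int)})


@dataclass
class EpigeneticSimilarity:
    """Whitened feature space for Mahalanobis distances between genes."""

    whitened: pd.DataFrame  # gene x feature, coordinates in whitened space
    covariance: pd.DataFrame  # regularised feature covariance (of z-scores)

    def distance(self, gene_a: str, gene_b: str) -> float:
        d = self.whitened.loc[gene_a].to_numpy() - self.whitened.loc[gene_b].to_numpy()
        return float(np.sqrt((d * d).sum()))

    def pair_distances(self, pairs: pd.DataFrame) -> np.ndarray:
        A = self.whitened.reindex(pairs["gene_a"]).to_numpy()
        B = self.whitened.reindex(pairs["gene_b"]).to_numpy()
        return np.sqrt(((A - B) ** 2).sum(axis=1))

    def full_matrix(self) -> pd.DataFrame:
        from scipy.spatial.distance import squareform, pdist

        d = squareform(pdist(self.whitened.to_numpy()))
        return pd.DataFrame(d, index=self.whitened.index, columns=self.whitened.index)


def epigenetic_similarity(
    epigenome: pd.DataFrame, regularization: float = 1e-6
) -> EpigeneticSimilarity:
    """Whiten gene-body feature vectors for Mahalanobis distances.

    Features are standardised (z-scores over genes), their covariance is
    estimated from all genes and ridge-regularised by
    ``regularization × trace / n_features`` on the diagonal, and genes are
    mapped through the inverse Cholesky factor so Euclidean distance in
    the returned space equals the Mahalanobis distance.
    """
    if epigenome.isna().to_numpy().any():
        raise DataError("epigenome matrix must be complete")
    n, p = epigenome.shape
    if n < p + 2:
        raise DataError(f"need at least n_features+2={p + 2} genes, got {n}")
    X = epigenome.to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(epigenome.columns[sd == 0])
        raise DataError(f"constant features cannot be standardised: {bad}")
    Z = (X - mu) / sd
    cov = np.cov(Z, rowvar=False, ddof=1)
    cov = cov + regularization * (np.trace(cov) / p) * np.eye(p)
    try:
        L = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise DataError("feature covariance singular even after regularisation") from exc
    W = linalg.solve_triangular(L, Z.T, lower=True).T
    return EpigeneticSimilarity(
        whitened=pd.DataFrame(W, index=epigenome.index, columns=epigenome.columns),
        covariance=pd.DataFrame(cov, index=epigenome.columns, columns=epigenome.columns),
    )


def bin2d_coregulation(
    pairs: pd.DataFrame,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Bin pairs by epigenetic similarity and spatial proximity.

    ``pairs`` must carry columns similarity (higher = more similar, i.e.
    −Mahalanobis distance), contact, co_regulated_mrna and
    co_regulated_protein. Pairs are assigned to axis-specific quantile
    bins (bin index increases with the axis value) and the table reports
    per-bin pair counts, % co-regulated per layer, mean contact and mean
    similarity. Empty bins appear with count 0 and undefined percentages.
    """
    need = {"similarity", "contact", "co_regulated_mrna", "co_regulated_protein"}
    if not need <= set(pairs.columns):
        raise DataError(f"pair table needs columns {sorted(need)}")
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    df = pairs.dropna(subset=["similarity", "contact"]).copy()
    df["sim_bin"] = _quantile_bin(df["similarity"], n_bins)
    df["con_bin"] = _quantile_bin(df["contact"], n_bins)
    rows = []
    for si in range(n_bins):
        for ci in range(n_bins):
            sub = df[(df["sim_bin"] == si) & (df["con_bin"] == ci)]
            n = len(sub)
            rows.append(
                {
                    "sim_bin": si,
                    "contact_bin": ci,
                    "n_pairs": n,
                    "pct_coregulated_mrna": 100.0 * sub["co_regulated_mrna"].mean() if n else np.nan,
                    "pct_coregulated_protein": 100.0 * sub["co_regulated_protein"].mean() if n else np.nan,
                    "mean_contact": float(sub["contact"].mean()) if n else np.nan,
                    "mean_similarity": float(sub["similarity"].mean()) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _quantile_bin(x: pd.Series, n_bins: int) -> np.ndarray:
    """Quantile bin index in 0..n_bins-1 (ties collapse edges as needed)."""
    ranks = x.rank(method="first")
    binned = pd.qcut(ranks, q=n_bins, labels=False, duplicates="drop")
    return binned.to_numpy()
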