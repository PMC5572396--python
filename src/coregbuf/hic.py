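"""Gene-level contact extraction from binned Hi-C maps and subcompartments.

Contact maps arrive as normalised binned triplets (KR-style balancing is
assumed to have happened upstream). The contact frequency of a gene pair
is the median over the pixel block formed by all bins overlapping a
±window (default 40 kb) region around each TSS; absent sparse entries
count as 0, NaN entries (failed balancing) are excluded, and a block with
no stored finite entry is flagged as zero-coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .core import ConfigError, DataError, IntervalTrack

DEFAULT_WINDOW_BP = 40_000
DEFAULT_INTRA_BIN = 10_000
DEFAULT_INTER_BIN = 50_000


@dataclass
class ContactMap:
    """Binned contact matrix for one chromosome (pair).

    ``matrix`` is sparse CSR, shape (n_bins_a, n_bins_b); intrachromosomal
    maps are stored fully symmetric. Stored values may be NaN where
    normalisation failed.
    """

    bin_size: int
    chrom_a: str
    chrom_b: str
    matrix: sparse.csr_matrix
    chrom_a_length: int = 0
    chrom_b_length: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ConfigError("bin_size must be positive")
        data = self.matrix.data
        if data.size and np.nanmin(data) < 0:
            raise DataError("contact counts must be non-negative")
        if not self.chrom_a_length:
            self.chrom_a_length = self.matrix.shape[0] * self.bin_size
        if not self.chrom_b_length:
            self.chrom_b_length = self.matrix.shape[1] * self.bin_size

    @property
    def intra(self) -> bool:
        return self.chrom_a == self.chrom_b


def contact_map_from_triplets(
    triplets: pd.DataFrame,
    bin_size: int,
    chrom_a: str,
    chrom_b: str,
    chrom_a_length: int,
    chrom_b_length: int | None = None,
    symmetrize: bool = True,
) -> ContactMap:
    """Build a ContactMap from (bin_i, bin_j, count) rows.

    For intrachromosomal maps an upper-triangle input is mirrored unless
    ``symmetrize=False`` (in which case the input must already contain
    both triangles consistently).
    """
    if chrom_b_length is None:
        chrom_b_length = chrom_a_length
    na = int(np.ceil(chrom_a_length / bin_size))
    nb = int(np.ceil(chrom_b_length / bin_size))
    i = triplets["bin_i"].to_numpy(np.int64)
    j = triplets["bin_j"].to_numpy(np.int64)
    v = triplets["count"].to_numpy(float)
    if (i < 0).any() or (j < 0).any() or (i >= na).any() or (j >= nb).any():
        raise DataError("bin index outside chromosome bounds")
    mat = sparse.coo_matrix((v, (i, j)), shape=(na, nb))
    if chrom_a == chrom_b and symmetrize:
        off = i != j
        mat = mat + sparse.coo_matrix((v[off], (j[off], i[off])), shape=(na, nb))
    return ContactMap(
        bin_size=bin_size,
        chrom_a=chrom_a,
        chrom_b=chrom_b,
        matrix=mat.tocsr(),
        chrom_a_length=chrom_a_length,
        chrom_b_length=chrom_b_length,
    )


def read_contact_map(path) -> ContactMap:
    """Read a triplet TSV with '#key=value' header lines.

    Required header keys: bin_size, chrom_a, chrom_b, chrom_a_length,
    chrom_b_length. Body columns: bin_i, bin_j, count. Intrachromosomal
    files store the upper triangle (i <= j).
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        body = pd.read_csv(fh, sep="\t")
    for key in ("bin_size", "chrom_a", "chrom_b", "chrom_a_length", "chrom_b_length"):
        if key not in meta:
            raise DataError(f"{path}: missing header line #{key}=...")
    return contact_map_from_triplets(
        body,
        bin_size=int(meta["bin_size"]),
        chrom_a=meta["chrom_a"],
        chrom_b=meta["chrom_b"],
        chrom_a_length=int(meta["chrom_a_length"]),
        chrom_b_length=int(meta["chrom_b_length"]),
    )


def write_contact_map(cmap: ContactMap, path) -> None:
    coo = cmap.matrix.tocoo()
    if cmap.intra:
        keep = coo.row <= coo.col
        coo = sparse.coo_matrix(
            (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
        )
    order = np.lexsort((coo.col, coo.row))
    body = pd.DataFrame(
        {"bin_i": coo.row[order], "bin_j": coo.col[order], "count": coo.data[order]}
    )
    with open(path, "w") as fh:
        fh.write(f"#bin_size={cmap.bin_size}\n")
        fh.write(f"#chrom_a={cmap.chrom_a}\n")
        fh.write(f"#chrom_b={cmap.chrom_b}\n")
        fh.write(f"#chrom_a_length={cmap.chrom_a_length}\n")
        fh.write(f"#chrom_b_length={cmap.chrom_b_length}\n")
        body.to_csv(fh, sep="\t", index=False)


def _window_bins(tss: int, window: int, bin_size: int, n_bins: int) -> tuple[int, int]:
    """Inclusive bin range overlapping [tss - window, tss + window]."""
    lo = max((tss - window) // bin_size, 0)
    hi = min((tss + window) // bin_size, n_bins - 1)
    return int(lo), int(hi)


def pair_contact(
    cmap: ContactMap,
    a: pd.Series,
    b: pd.Series,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> tuple[float, bool]:
    """Median contact over the TSS-window pixel block of a gene pair.

    Returns ``(contact, covered)``; ``covered`` is False when the block
    holds no stored finite entry (zero-coverage), in which case the
    contact is 0 by the normalised-Hi-C zero convention.
    """
    tss_a, tss_b = int(a["tss"]), int(b["tss"])
    if a["chromosome"] != cmap.chrom_a or b["chromosome"] != cmap.chrom_b:
        if cmap.intra and a["chromosome"] == cmap.chrom_b and b["chromosome"] == cmap.chrom_a:
            a, b = b, a
            tss_a, tss_b = tss_b, tss_a
        else:
            raise DataError("gene chromosomes do not match the contact map")
    if not (0 <= tss_a < cmap.chrom_a_length) or not (0 <= tss_b < cmap.chrom_b_length):
        raise DataError("TSS outside chromosome bounds")
    na, nb = cmap.matrix.shape
    r0, r1 = _window_bins(tss_a, window_bp, cmap.bin_size, na)
    c0, c1 = _window_bins(tss_b, window_bp, cmap.bin_size, nb)
    block = cmap.matrix[r0 : r1 + 1, c0 : c1 + 1]
    dense = np.asarray(block.todense(), dtype=float)
    stored = block.tocoo()
    covered = bool(np.isfinite(stored.data).any())
    finite = dense[np.isfinite(dense)]
    if finite.size == 0:
        return 0.0, False
    return float(np.median(finite)), covered


def contacts_for_pairs(
    maps: dict[tuple[str, str], ContactMap],
    ann: pd.DataFrame,
    pairs: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Contact frequency for each pair row (gene_a, gene_b).

    ``maps`` is keyed by (chrom_a, chrom_b). Pairs whose chromosome (pair)
    has no map get NaN. Adds columns contact and contact_covered.
    """
    out = pairs.copy().reset_index(drop=True)
    contact = np.full(len(out), np.nan)
    covered = np.zeros(len(out), dtype=bool)
    chrom_a = ann.loc[out["gene_a"], "chromosome"].to_numpy()
    chrom_b = ann.loc[out["gene_b"], "chromosome"].to_numpy()
    for k in range(len(out)):
        key = (chrom_a[k], chrom_b[k])
        cmap = maps.get(key) or maps.get((key[1], key[0]))
        if cmap is None:
            continue
        a = ann.loc[out.at[k, "gene_a"]]
        b = ann.loc[out.at[k, "gene_b"]]
        if a["chromosome"] != cmap.chrom_a:
            a, b = b, a
        contact[k], covered[k] = pair_contact(cmap, a, b, window_bp)
    out["contact"] = contact
    out["contact_covered"] = covered
    return out


def gene_contact_matrix(
    cmap: ContactMap,
    ann_rows: pd.DataFrame,
    ann_cols: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Dense gene × gene contact table for one map (vectorised).

    Rows are genes on ``cmap.chrom_a``, columns genes on ``cmap.chrom_b``.
    Equivalent to calling :func:`pair_contact` for every combination.
    """
    dense = np.asarray(cmap.matrix.todense(), dtype=float)
    na, nb = dense.shape
    G, H = len(ann_rows), len(ann_cols)
    if G == 0 or H == 0:
        return pd.DataFrame(np.empty((G, H)), index=ann_rows.index, columns=ann_cols.index)
    rb = np.array([_window_bins(int(t), window_bp, cmap.bin_size, na) for t in ann_rows["tss"]])
    cb = np.array([_window_bins(int(t), window_bp, cmap.bin_size, nb) for t in ann_cols["tss"]])
    r_lo, r_hi = rb[:, 0], rb[:, 1]
    c_lo, c_hi = cb[:, 0], cb[:, 1]
    wr = r_hi - r_lo + 1
    wc = c_hi - c_lo + 1
    wr_max, wc_max = int(wr.max()), int(wc.max())
    # gather the (<= wr_max x wc_max) block per gene pair; slots outside a
    # pair's true window are NaN and excluded from the median
    slabs = np.empty((G, H, wr_max * wc_max))
    k = 0
    uniform = bool((wr == wr_max).all() and (wc == wc_max).all())
    for dr in range(wr_max):
        ri = np.clip(r_lo + dr, 0, na - 1)
        row_ok = dr < wr
        for dc in range(wc_max):
            ci = np.clip(c_lo + dc, 0, nb - 1)
            col_ok = dc < wc
            slab = dense[ri[:, None], ci[None, :]]
            if not uniform:
                slab = np.where(row_ok[:, None] & col_ok[None, :], slab, np.nan)
            slabs[:, :, k] = slab
            k += 1
    if uniform and not np.isnan(dense).any():
        out = np.median(slabs, axis=2)
    else:
        with warnings_ignore_all_nan():
            out = np.nanmedian(slabs, axis=2)
        out = np.where(np.isfinite(out), out, 0.0)
    return pd.DataFrame(out, index=ann_rows.index, columns=ann_cols.index)


class warnings_ignore_all_nan:
    """Silence the all-NaN-slice RuntimeWarning from nanmedian."""

    def __enter__(self):
        import warnings

        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        import warnings as w

        w.simplefilter("ignore", RuntimeWarning)

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


def map_correlation(map_a: pd.DataFrame, map_b: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of two gene-level maps over the upper triangle.

    Both matrices must share the gene ordering on both axes; the diagonal
    is excluded and only pairwise-complete entries enter.
    """
    if list(map_a.index) != list(map_b.index) or list(map_a.columns) != list(map_b.columns):
        raise DataError("gene ordering mismatch between maps")
    a = map_a.to_numpy(float)
    b = map_b.to_numpy(float)
    iu = np.triu_indices(a.shape[0], k=1) if a.shape[0] == a.shape[1] else tuple(
        np.indices(a.shape).reshape(2, -1)
    )
    va, vb = a[iu], b[iu]
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 3:
        raise DataError("fewer than 3 complete entries for map correlation")
    from scipy import stats

    r, p = stats.pearsonr(va[ok], vb[ok])
    return float(r), float(p)


def assign_subcompartment(ann: pd.DataFrame, track: IntervalTrack) -> pd.Series:
    """Subcompartment label of the interval containing each TSS.

    Intervals are half-open, so a TSS exactly at a boundary belongs to the
    downstream interval. Gaps yield "unassigned".
    """
    labels = pd.Series("unassigned", index=ann.index, dtype=object)
    for chrom, grp in track.intervals.groupby("chromosome", sort=False):
        genes = ann[ann["chromosome"] == chrom]
        if genes.empty:
            continue
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        labs = grp["label"].to_numpy()
        tss = genes["tss"].to_numpy(np.int64)
        idx = np.searchsorted(starts, tss, side="right") - 1
        inside = (idx >= 0) & (tss < ends[np.clip(idx, 0, len(ends) - 1)])
        labels.loc[genes.index[inside]] = labs[idx[inside]]
    return labels


def subcompartment_enrichment(
    cluster_members: dict[str, list], labels: pd.Series
) -> pd.DataFrame:
    """Observed vs expected subcompartment percentage per cluster.

    Observed % = labelled members with the label / labelled members of the
    cluster; expected % = dataset-wide fraction of the label among all
    labelled genes.
    """
    labelled = labels[labels != "unassigned"]
    overall = labelled.value_counts(normalize=True) * 100.0
    rows = []
    for cluster, members in cluster_members.items():
        mem = labelled.reindex([g for g in members if g in labelled.index]).dropna()
        for lab in overall.index:
            obs = 100.0 * (mem == lab).sum() / len(mem) if len(mem) else np.nan
            rows.append(
                {
                    "cluster": cluster,
                    "label": lab,
                    "observed_pct": obs,
                    "expected_pct": float(overall[lab]),
                    "n_labelled": int(len(mem)),
                }
            )
    return pd.DataFrame(rows)
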