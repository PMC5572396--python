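"""Core data containers and preprocessing for matched expression layers.

The analysis operates on gene × sample tables of log2 abundance ratios
relative to a common reference sample (log2 RPKM ratios for mRNA, log2
SILAC L/H ratios for protein, ribosome-occupancy ratios for the ribosome
layer). Missing values are carried as NaN throughout. All genomic
coordinates are 0-based, half-open internally; GFF3 input (1-based,
closed) is converted on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("mrna", "protein", "ribosome")

#: chromatin-state labels collapsed into a single "heterochromatin" state
INACTIVE_STATE_LABELS = (
    "Heterochromatin",
    "Repressed",
    "Repetitive",
    "Poised_Promoter",
    "Insulator",
)

SUBCOMPARTMENT_LABELS = ("A1", "A2", "B1", "B2", "B3", "B4")


class CoregbufError(Exception):
    """Base class for package errors."""


class ConfigError(CoregbufError):
    """Invalid configuration or arguments."""


class DataError(CoregbufError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Gene × sample matrix of log2 abundance ratios.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample columns; NaN marks a
        missing measurement.
    layer
        One of ``"mrna"``, ``"protein"``, ``"ribosome"``.
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ConfigError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate sample identifiers")
        self.values = self.values.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, layer=self.layer)


def load_expression(
    path,
    layer: str,
    reference_column: str | None = None,
    missing_tokens: tuple[str, ...] = ("NA", ""),
    linear: bool = False,
) -> ExpressionMatrix:
    """Read a gene × sample TSV into an :class:`ExpressionMatrix`.

    The first column holds gene ids, the header row sample ids. Values are
    assumed to be log2 already unless ``linear=True``, in which case log2
    is applied (non-positive values are an error: a linear abundance of
    zero or less cannot be log-transformed). If ``reference_column`` is
    given, it is subtracted row-wise from every other sample and dropped,
    producing ratios relative to that reference.
    """
    raw = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        na_values=list(missing_tokens),
        keep_default_na=False,
    )
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate gene ids in {path}: {dupes[:5]}")
    if raw.shape[1] < 2:
        raise DataError(f"{path}: need a gene-id column and >= 2 sample columns")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        where = [(values.index[r], values.columns[c]) for r, c in zip(rows[:5], cols[:5])]
        raise DataError(f"non-numeric cells (gene, sample): {where}")
    if linear:
        if (values <= 0).to_numpy().any():
            raise DataError("linear input contains non-positive values; cannot log2")
        values = np.log2(values)
    if reference_column is not None:
        if reference_column not in values.columns:
            raise DataError(f"reference column {reference_column!r} not found")
        ref = values[reference_column]
        values = values.drop(columns=[reference_column]).sub(ref, axis=0)
    return ExpressionMatrix(values=values, layer=layer)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write an ExpressionMatrix as TSV (NaN serialised as ``NA``)."""
    m.values.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")


def filter_by_detection(
    m: ExpressionMatrix, min_samples: int, strict: bool = False
) -> ExpressionMatrix:
    """Drop genes detected in too few samples.

    With ``strict=False`` (mRNA convention) genes with fewer than
    ``min_samples`` non-missing values are removed; with ``strict=True``
    (protein convention) genes with ``min_samples`` or fewer are removed.
    Gene order is preserved.
    """
    if min_samples < 1:
        raise ConfigError("min_samples must be >= 1")
    counts = m.values.notna().sum(axis=1)
    keep = counts > min_samples if strict else counts >= min_samples
    if not keep.any():
        raise DataError(
            f"no genes retained at min_samples={min_samples} "
            f"(strict={strict}); lower the threshold"
        )
    return m.copy_with(m.values.loc[keep])


def match_layers(
    mrna: ExpressionMatrix,
    protein: ExpressionMatrix,
    id_map: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two layers to unambiguously 1:1-mapped genes and shared samples.

    ``id_map`` is a two-column table (mRNA gene id, protein id); genes with
    ambiguous mappings in either direction are removed. When ``id_map`` is
    None the two matrices are assumed to share an id space and are simply
    intersected. Both outputs carry the mRNA gene ids in identical order.
    """
    if id_map is None:
        pairs = pd.DataFrame(
            {"mrna_id": mrna.genes.intersection(protein.genes)}
        )
        pairs["protein_id"] = pairs["mrna_id"]
    else:
        pairs = id_map.iloc[:, :2].copy()
        pairs.columns = ["mrna_id", "protein_id"]
        pairs = pairs.drop_duplicates()
        # 1:1 only: ambiguity is judged on the full map, so a protein hit by
        # two mRNAs disqualifies both links even if one mRNA is otherwise unique
        ambiguous = pairs["mrna_id"].duplicated(keep=False) | pairs[
            "protein_id"
        ].duplicated(keep=False)
        pairs = pairs[~ambiguous]
        pairs = pairs[
            pairs["mrna_id"].isin(mrna.genes) & pairs["protein_id"].isin(protein.genes)
        ]
    samples = mrna.samples.intersection(protein.samples)
    if len(pairs) == 0 or len(samples) == 0:
        raise DataError("no overlap between mRNA and protein layers")
    # keep mRNA gene order
    pairs = pairs.set_index("mrna_id").loc[
        [g for g in mrna.genes if g in set(pairs["mrna_id"])]
    ]
    m_out = mrna.values.loc[pairs.index, samples]
    p_out = protein.values.loc[pairs["protein_id"], samples]
    p_out.index = pairs.index
    return (
        ExpressionMatrix(values=m_out, layer=mrna.layer),
        ExpressionMatrix(values=p_out, layer=protein.layer),
    )


def center_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Set each sample's median log2 ratio to zero.

    Removes sample-level offsets (e.g. uneven mixing of light/heavy SILAC
    material) that would otherwise inflate every pairwise correlation.
    Idempotent; the missing pattern is unchanged.
    """
    n_valid = m.values.notna().sum(axis=0)
    if (n_valid == 0).any():
        bad = list(m.samples[n_valid == 0])
        raise DataError(f"samples with no non-missing values: {bad}")
    med = m.values.median(axis=0, skipna=True)
    return m.copy_with(m.values.sub(med, axis=1))


# ---------------------------------------------------------------------------
# gene annotation


def make_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a gene annotation table.

    Expects columns gene_id, chromosome, strand, body_start, body_end
    (0-based half-open). The TSS is derived from the strand: body_start
    for + genes, body_end for − genes (outermost transcript convention).
    """
    ann = df.copy()
    required = {"gene_id", "chromosome", "strand", "body_start", "body_end"}
    missing = required - set(ann.columns)
    if missing:
        raise DataError(f"annotation missing columns: {sorted(missing)}")
    if ann["gene_id"].duplicated().any():
        raise DataError("duplicate gene ids in annotation")
    if not ann["strand"].isin(["+", "-"]).all():
        raise DataError("strand must be '+' or '-'")
    ann["body_start"] = ann["body_start"].astype(np.int64)
    ann["body_end"] = ann["body_end"].astype(np.int64)
    if (ann["body_start"] >= ann["body_end"]).any():
        raise DataError("body_start must be < body_end")
    ann["tss"] = np.where(ann["strand"] == "+", ann["body_start"], ann["body_end"])
    return ann.set_index("gene_id", drop=False)


def read_annotation_bed(path) -> pd.DataFrame:
    """Read gene annotations from BED6 (name = gene id)."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chromosome", "body_start", "body_end", "gene_id", "score", "strand"],
    )
    return make_annotation(
        bed[["gene_id", "chromosome", "strand", "body_start", "body_end"]]
    )


def write_annotation_bed(ann: pd.DataFrame, path) -> None:
    out = ann[["chromosome", "body_start", "body_end", "gene_id", "strand"]].copy()
    out.insert(4, "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_gff3(path) -> pd.DataFrame:
    """Read gene lines from GFF3 (1-based closed -> 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise DataError(f"GFF3 gene line without ID attribute: {line[:80]}")
            rows.append(
                {
                    "gene_id": gid.removeprefix("gene:"),
                    "chromosome": f[0],
                    "strand": f[6],
                    "body_start": int(f[3]) - 1,
                    "body_end": int(f[4]),
                }
            )
    if not rows:
        raise DataError(f"no gene lines in {path}")
    return make_annotation(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# interval tracks (chromatin states, subcompartments)


@dataclass
class IntervalTrack:
    """Labelled genomic intervals (0-based, half-open)."""

    intervals: pd.DataFrame  # chromosome, start, end, label

    def __post_init__(self) -> None:
        need = {"chromosome", "start", "end", "label"}
        if not need <= set(self.intervals.columns):
            raise DataError(f"interval track needs columns {sorted(need)}")
        iv = self.intervals
        if (iv["start"] >= iv["end"]).any():
            raise DataError("interval start must be < end")
        self.intervals = iv.sort_values(["chromosome", "start"]).reset_index(drop=True)

    def subset(self, labels) -> "IntervalTrack":
        keep = self.intervals["label"].isin(set(labels))
        return IntervalTrack(self.intervals[keep].reset_index(drop=True))

    def merged(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged (starts, ends) arrays, label-agnostic."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in self.intervals.groupby("chromosome", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            ms, me = [], []
            for s, e in zip(starts, ends):
                if ms and s <= me[-1]:
                    me[-1] = max(me[-1], e)
                else:
                    ms.append(s)
                    me.append(e)
            out[chrom] = (np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64))
        return out


def read_bed4(path) -> IntervalTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chromosome", "start", "end", "label"],
        usecols=[0, 1, 2, 3],
    )
    return IntervalTrack(df)


def write_bed4(track: IntervalTrack, path) -> None:
    track.intervals[["chromosome", "start", "end", "label"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# epigenome matrix


#: features excluded from epigenetic similarity by construction
SIMILARITY_EXCLUDED_FEATURES = ("GC_content", "gene_length", "replication_timing")


def load_epigenome(path, fill_missing: float = 0.0) -> pd.DataFrame:
    """Read a gene × feature TSV of mean gene-body signals.

    Genes lacking signal for a feature get ``fill_missing`` (default 0)
    with a warning, so the matrix is complete after construction.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise DataError("duplicate gene ids in epigenome table")
    if df.isna().to_numpy().any():
        import warnings

        n = int(df.isna().to_numpy().sum())
        warnings.warn(f"epigenome table: {n} missing values filled with {fill_missing}")
        df = df.fillna(fill_missing)
    return df.astype(float)


def gene_body_signal(
    ann: pd.DataFrame, bedgraph: pd.DataFrame, feature: str
) -> pd.Series:
    """Mean signal over each gene body from a bedGraph table.

    ``bedgraph`` has columns chromosome, start, end, value. The mean is
    taken per base over the gene body; bases without signal count as 0.
    """
    out = pd.Series(0.0, index=ann.index, name=feature)
    for chrom, grp in bedgraph.groupby("chromosome", sort=False):
        genes = ann[ann["chromosome"] == chrom]
        if genes.empty:
            continue
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        vals = grp["value"].to_numpy(float)
        order = np.argsort(starts)
        starts, ends, vals = starts[order], ends[order], vals[order]
        for gid, gs, ge in zip(genes.index, genes["body_start"], genes["body_end"]):
            lo = np.searchsorted(ends, gs, side="right")
            hi = np.searchsorted(starts, ge, side="left")
            if hi <= lo:
                continue
            ov = np.minimum(ends[lo:hi], ge) - np.maximum(starts[lo:hi], gs)
            ov = np.clip(ov, 0, None)
            out.loc[gid] = float((vals[lo:hi] * ov).sum() / (ge - gs))
    return out
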