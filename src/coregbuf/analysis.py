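"""High-level analysis stages over a study bundle.

Each function consumes the in-memory :class:`~coregbuf.simulate.Bundle`
(or equivalently data loaded from files) plus the prepared expression
layers, and returns plain tables. The orchestration layer
(:mod:`coregbuf.pipeline`) wires these together and handles file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import chromatin, clusters, coreg, hic, noise, pairs as pairs_mod, posttx
from .core import ExpressionMatrix, center_samples, filter_by_detection, match_layers
from .simulate import Bundle, pair_truth_labels, truth_report


@dataclass
class PreparedLayers:
    """Detection-filtered, matched, median-centered expression layers."""

    mrna: ExpressionMatrix
    protein: ExpressionMatrix
    ribosome: ExpressionMatrix
    annotation: pd.DataFrame  # restricted to matched genes


def prepare_layers(bundle: Bundle, min_detect: int = 30) -> PreparedLayers:
    """Apply the detection filters, match the layers and center samples.

    mRNA uses the lenient convention (genes detected in fewer than
    ``min_detect`` samples are removed), protein the strict one (detected
    in ``min_detect`` samples or fewer removed).
    """
    m = filter_by_detection(bundle.mrna, min_detect, strict=False)
    p = filter_by_detection(bundle.protein, min_detect, strict=True)
    m, p = match_layers(m, p)
    m = center_samples(m)
    p = center_samples(p)
    r = center_samples(
        ExpressionMatrix(bundle.ribosome.values.loc[m.genes, m.samples], "ribosome")
    )
    ann = bundle.annotation.loc[m.genes]
    return PreparedLayers(mrna=m, protein=p, ribosome=r, annotation=ann)


def close_pair_coregulation(
    layers: PreparedLayers, window: int = 50_000, min_overlap: int = 30
) -> pd.DataFrame:
    """Co-regulation calls at both layers for all pairs with TSSs < window.

    Returns one row per pair with the orientation class and per-layer
    statistics (suffixes _mrna / _protein). BH adjustment is per layer
    within this pair set.
    """
    pr = pairs_mod.enumerate_pairs(layers.annotation, scope="window", window=window)
    res_m = coreg.call_coregulation(layers.mrna, pr, min_overlap)
    res_p = coreg.call_coregulation(layers.protein, pr, min_overlap)
    stat_cols = ["pcc", "n_obs", "p_value", "adj_p", "defined", "co_regulated", "anti_regulated"]
    out = res_m.drop(columns=["layer"]).rename(columns={c: c + "_mrna" for c in stat_cols})
    for c in stat_cols:
        out[c + "_protein"] = res_p[c].to_numpy()
    return out


def coregulation_summary(close_pairs: pd.DataFrame) -> pd.DataFrame:
    """Per orientation class: pair counts and % co-regulated per layer."""
    rows = []
    for cls, grp in close_pairs.groupby("orientation_class"):
        dm = grp[grp["defined_mrna"]]
        dp = grp[grp["defined_protein"]]
        rows.append(
            {
                "orientation_class": cls,
                "n_pairs": len(grp),
                "pct_coregulated_mrna": 100.0 * dm["co_regulated_mrna"].mean() if len(dm) else np.nan,
                "pct_coregulated_protein": 100.0 * dp["co_regulated_protein"].mean() if len(dp) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def chromosome_maps(
    bundle: Bundle, layers: PreparedLayers, chromosome: str, window_bp: int = 40_000
):
    """Co-regulation maps for one chromosome plus the Hi-C comparison.

    Returns (mrna_map, protein_map, contact gene matrix, correlations dict).
    """
    ann = layers.annotation
    genes = ann[ann["chromosome"] == chromosome].sort_values(["tss", "gene_id"])
    order = list(genes.index)
    map_m = coreg.build_map(layers.mrna, order)
    map_p = coreg.build_map(layers.protein, order)
    cmap = bundle.contact_maps[(chromosome, chromosome)]
    contacts = hic.gene_contact_matrix(cmap, genes, genes, window_bp)
    r_m, p_m = hic.map_correlation(map_m.matrix, contacts)
    r_p, p_p = hic.map_correlation(map_p.matrix, contacts)
    corr = {
        "chromosome": chromosome,
        "pcc_mrna_vs_hic": r_m,
        "p_mrna_vs_hic": p_m,
        "pcc_protein_vs_hic": r_p,
        "p_protein_vs_hic": p_p,
    }
    return map_m, map_p, contacts, corr


def intra_pair_contacts(
    bundle: Bundle, layers: PreparedLayers, pairs: pd.DataFrame, window_bp: int = 40_000
) -> pd.Series:
    """Contact frequency per intrachromosomal pair via per-chromosome
    gene-level contact matrices (vectorised equivalent of pair_contact)."""
    ann = layers.annotation
    out = np.full(len(pairs), np.nan)
    chrom_a = ann["chromosome"].reindex(pairs["gene_a"]).to_numpy()
    chrom_b = ann["chromosome"].reindex(pairs["gene_b"]).to_numpy()
    for chrom in pd.unique(chrom_a):
        sel = np.flatnonzero((chrom_a == chrom) & (chrom_b == chrom))
        if len(sel) == 0 or (chrom, chrom) not in bundle.contact_maps:
            continue
        genes = ann[ann["chromosome"] == chrom]
        M = hic.gene_contact_matrix(bundle.contact_maps[(chrom, chrom)], genes, genes, window_bp)
        gi = M.index.get_indexer(pairs["gene_a"].to_numpy()[sel])
        gj = M.columns.get_indexer(pairs["gene_b"].to_numpy()[sel])
        out[sel] = M.to_numpy()[gi, gj]
    return pd.Series(out, index=pairs.index, name="contact")


def mechanism_bin_analysis(
    bundle: Bundle,
    layers: PreparedLayers,
    max_distance: int = 2_000_000,
    n_bins: int = 3,
    min_overlap: int = 30,
    exclude_functional: bool = True,
) -> pd.DataFrame:
    """Similarity × proximity binning of co-regulation (mechanism separation).

    Intrachromosomal pairs with TSSs < ``max_distance`` apart are binned
    by epigenetic similarity (−Mahalanobis distance) and Hi-C contact;
    the per-bin percentage of co-regulated pairs is reported for both
    layers. Planted functional pairs are excluded by default so the table
    reflects non-functional co-regulation mechanisms only.
    """
    pr = pairs_mod.enumerate_pairs(layers.annotation, scope="window", window=max_distance)
    if exclude_functional:
        labels = pair_truth_labels(bundle, pr)
        pr = pr[labels != "functional"].reset_index(drop=True)
    res_m = coreg.call_coregulation(layers.mrna, pr, min_overlap)
    res_p = coreg.call_coregulation(layers.protein, pr, min_overlap)
    sim = chromatin.epigenetic_similarity(bundle.epigenome.loc[layers.annotation.index])
    tab = pr.copy()
    tab["similarity"] = -sim.pair_distances(pr)
    tab["contact"] = intra_pair_contacts(bundle, layers, pr).to_numpy()
    tab["co_regulated_mrna"] = res_m["co_regulated"].to_numpy()
    tab["co_regulated_protein"] = res_p["co_regulated"].to_numpy()
    keep = res_m["defined"].to_numpy() & res_p["defined"].to_numpy()
    return chromatin.bin2d_coregulation(tab[keep], n_bins=n_bins)


def functional_recovery(
    bundle: Bundle,
    layers: PreparedLayers,
    n_background: int = 5_000,
    seed: int = 0,
    min_overlap: int = 30,
) -> dict:
    """Recovery of planted functional pairs as sustained pairs.

    Evaluates co-regulation at both layers over the planted functional
    pairs plus a reproducible random background of non-functional pairs,
    classifies pairs sustained/buffered/neither and scores the sustained
    call against the planted label.
    """
    rng = np.random.default_rng(seed)
    genes = layers.annotation.index.to_numpy()
    gene_set = set(genes)
    func = bundle.truth_pairs[
        bundle.truth_pairs["gene_a"].isin(gene_set)
        & bundle.truth_pairs["gene_b"].isin(gene_set)
    ][["gene_a", "gene_b"]]
    a = rng.choice(genes, size=2 * n_background)
    bg = pd.DataFrame({"gene_a": a[:n_background], "gene_b": a[n_background:]})
    bg = bg[bg["gene_a"] != bg["gene_b"]]
    swap = bg["gene_a"] > bg["gene_b"]
    bg.loc[swap, ["gene_a", "gene_b"]] = bg.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    all_pairs = pd.concat([func, bg], ignore_index=True).drop_duplicates(
        ["gene_a", "gene_b"]
    ).reset_index(drop=True)
    all_pairs = pairs_mod.classify_pairs_vectorized(layers.annotation, all_pairs)
    res_m = coreg.call_coregulation(layers.mrna, all_pairs, min_overlap)
    res_p = coreg.call_coregulation(layers.protein, all_pairs, min_overlap)
    cats = posttx.sustained_vs_buffered(res_m, res_p)
    key = pairs_mod.pair_key(cats)
    truth = pair_truth_labels(bundle, cats).set_axis(key)
    sustained = pd.Series(cats["category"].to_numpy() == "sustained", index=key)
    report = truth_report(truth, sustained, positive_label="functional")
    report["n_pairs_evaluated"] = len(cats)
    report["categories"] = cats
    return report


def noise_density_analysis(
    bundle: Bundle,
    layers: PreparedLayers,
    tail: float = 0.05,
    window_bp: int = 40_000,
    min_seq_sep: int = 500_000,
    include_inter: bool = True,
) -> dict:
    """Expression noise vs the three clustering degrees.

    Returns per-gene metrics and the extreme-group (densest vs sparsest
    ``tail``) KS comparisons, following the convention that degree_seq is
    a distance (lower = denser) while the 3D degrees are contacts
    (higher = denser).
    """
    ann = layers.annotation
    metrics = pd.DataFrame(index=ann.index)
    metrics["noise_mrna"] = noise.expression_noise(layers.mrna)
    metrics["noise_protein"] = noise.expression_noise(layers.protein)
    metrics["degree_seq"] = noise.clustering_degree_seq(ann)

    intra_frames = []
    for chrom in pd.unique(ann["chromosome"]):
        key = (chrom, chrom)
        if key not in bundle.contact_maps:
            continue
        genes = ann[ann["chromosome"] == chrom]
        M = hic.gene_contact_matrix(bundle.contact_maps[key], genes, genes, window_bp)
        iu = np.triu_indices(len(genes), k=1)
        intra_frames.append(
            pd.DataFrame(
                {
                    "gene_a": genes.index.to_numpy()[iu[0]],
                    "gene_b": genes.index.to_numpy()[iu[1]],
                    "contact": M.to_numpy()[iu],
                }
            )
        )
    if intra_frames:
        intra = pd.concat(intra_frames, ignore_index=True)
        metrics["degree_intra3d"] = noise.clustering_degree_3d(
            ann, intra, mode="intra", min_seq_sep=min_seq_sep
        )
    if include_inter:
        inter_frames = []
        for (ca, cb), cmap in bundle.contact_maps.items():
            if ca == cb:
                continue
            ga = ann[ann["chromosome"] == ca]
            gb = ann[ann["chromosome"] == cb]
            if ga.empty or gb.empty:
                continue
            M = hic.gene_contact_matrix(cmap, ga, gb, window_bp)
            ii, jj = np.indices(M.shape)
            inter_frames.append(
                pd.DataFrame(
                    {
                        "gene_a": ga.index.to_numpy()[ii.ravel()],
                        "gene_b": gb.index.to_numpy()[jj.ravel()],
                        "contact": M.to_numpy().ravel(),
                    }
                )
            )
        if inter_frames:
            inter = pd.concat(inter_frames, ignore_index=True)
            metrics["degree_inter3d"] = noise.clustering_degree_3d(
                ann, inter, mode="inter"
            )

    comparisons = {}
    # sequence degree is a distance: the densest tail is the *bottom* tail
    comparisons["seq_mrna"] = noise.extreme_group_comparison(
        metrics["noise_mrna"], metrics["degree_seq"], tail
    )
    comparisons["seq_protein"] = noise.extreme_group_comparison(
        metrics["noise_protein"], metrics["degree_seq"], tail
    )
    if "degree_intra3d" in metrics:
        comparisons["intra3d_mrna"] = noise.extreme_group_comparison(
            metrics["noise_mrna"], metrics["degree_intra3d"], tail
        )
    correlations = {}
    if "degree_intra3d" in metrics:
        ok = metrics[["degree_seq", "degree_intra3d"]].dropna()
        r, p = stats.pearsonr(ok["degree_seq"], ok["degree_intra3d"])
        correlations["seq_vs_intra3d"] = {"pcc": float(r), "p": float(p)}
    if "degree_inter3d" in metrics:
        ok = metrics[["degree_seq", "degree_inter3d"]].dropna()
        r, p = stats.pearsonr(ok["degree_seq"], ok["degree_inter3d"])
        correlations["seq_vs_inter3d"] = {"pcc": float(r), "p": float(p)}
    return {"metrics": metrics, "comparisons": comparisons, "correlations": correlations}


def heterochromatin_analysis(
    bundle: Bundle,
    layers: PreparedLayers,
    close_pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Upstream heterochromatin profiles of neighbour-co-regulated genes.

    A gene is flagged co-regulated-with-neighbours when it is mRNA
    co-regulated with at least one gene whose TSS is < 50 kb away.
    Returns the offset profile for the flagged and unflagged groups.
    """
    called = close_pairs[close_pairs["co_regulated_mrna"].astype(bool)]
    flagged = set(called["gene_a"]).union(called["gene_b"])
    ann = layers.annotation
    grp_yes = ann[ann.index.isin(flagged)]
    grp_no = ann[~ann.index.isin(flagged)]
    frames = []
    for name, grp in (("coregulated_with_neighbours", grp_yes), ("not_coregulated", grp_no)):
        if grp.empty:
            continue
        prof = chromatin.heterochromatin_profile(
            grp, bundle.chromatin_states, chrom_lengths=bundle.chrom_lengths
        )
        prof["group"] = name
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)


def cluster_analysis(
    bundle: Bundle,
    layers: PreparedLayers,
    k_mrna: int = 4,
    k_protein: int = 3,
    n_starts: int = 5,
    seed: int = 0,
) -> dict:
    """Regulation groups per layer with compartment and feature enrichment."""
    fit_m = clusters.fit_regulation_clusters(layers.mrna, k_mrna, n_starts, seed)
    fit_p = clusters.fit_regulation_clusters(layers.protein, k_protein, n_starts, seed)
    cross = clusters.cluster_cross_correlation(fit_m, fit_p, layers.mrna, layers.protein)
    within_m = clusters.cluster_cross_correlation(fit_m, fit_m, layers.mrna, layers.mrna)
    labels = hic.assign_subcompartment(layers.annotation, bundle.subcompartments)
    members = {
        f"T{c + 1}": list(fit_m.assignment.index[fit_m.assignment == c])
        for c in range(fit_m.k)
    }
    subc = hic.subcompartment_enrichment(members, labels)
    feat = clusters.feature_enrichment(
        fit_m.assignment, bundle.epigenome.loc[fit_m.assignment.index]
    )
    return {
        "mrna": fit_m,
        "protein": fit_p,
        "cross_correlation": cross,
        "within_mrna_correlation": within_m,
        "subcompartment_enrichment": subc,
        "feature_enrichment": feat,
    }


def posttx_analysis(
    bundle: Bundle,
    layers: PreparedLayers,
    close_pairs: pd.DataFrame,
    min_overlap: int = 30,
    sided: str = "one",
) -> dict:
    """Post-transcriptional predicate enrichment, sustained vs buffered.

    The evaluated pair set is the close-pair set plus the planted
    functional pairs (so both groups are populated); ribosome-layer calls
    are computed on the same set.
    """
    gene_set = set(layers.annotation.index)
    func = bundle.truth_pairs[
        bundle.truth_pairs["gene_a"].isin(gene_set)
        & bundle.truth_pairs["gene_b"].isin(gene_set)
    ][["gene_a", "gene_b"]]
    base = pd.concat(
        [close_pairs[["gene_a", "gene_b"]], func], ignore_index=True
    ).drop_duplicates(["gene_a", "gene_b"]).reset_index(drop=True)
    res_m = coreg.call_coregulation(layers.mrna, base, min_overlap)
    res_p = coreg.call_coregulation(layers.protein, base, min_overlap)
    res_r = coreg.call_coregulation(layers.ribosome, base, min_overlap)
    cats = posttx.sustained_vs_buffered(res_m, res_p)
    preds = posttx.posttx_predicates(
        cats,
        half_life=bundle.half_life,
        mirna_targets=bundle.mirna_targets,
        ribosome_results=res_r,
        ned=bundle.ned,
        length=bundle.protein_length,
    )
    groups = pd.Series(cats["category"].to_numpy(), index=cats.index)
    results = {}
    for pred in posttx.PREDICATES:
        flag = pd.Series(preds[pred].to_numpy(), index=cats.index)
        results[pred] = posttx.enrichment_test(flag, groups, sided=sided)
    return {"categories": cats, "predicates": preds, "enrichment": results}
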