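"""Synthetic study generator with known ground truth.

The generator emulates the mechanistic picture behind non-functional mRNA
co-regulation and its protein-level buffering:

* chromosomes are tiled with chromatin domains; each domain has a latent
  per-sample activity that all its genes share (stochastic chromatin
  fluctuation). Domains come in a few chromatin *types*; domains of the
  same type respond partly to a common factor (a fluctuating
  chromatin-modifying activity), so epigenetically similar genes co-vary
  even when far apart;
* genes additionally receive a distance-weighted share of their < 50 kb
  neighbours' transcriptional signal (regulatory interference,
  exp(−d / 20 kb) kernel);
* a small set of *functional* gene pairs shares a regulatory program that
  is propagated to the protein layer; everything else is buffered: with
  ``buffering_on`` the protein level keeps only the program signal plus
  post-transcriptional noise;
* gene-dense domains are transcriptionally stable (low volatility), so
  densely packed genes have low expression noise; sparse, volatile
  domains are flanked by heterochromatin intervals (stochastic spreading
  is what makes them volatile);
* Hi-C contacts decay with genomic distance as a power law, boosted for
  same-domain and same-subcompartment bins; A-type subcompartments
  (hosting dense domains) interact more;
* per-domain-type epigenomic signatures give genes of the same type
  similar gene-body feature vectors (with a built-in strongly correlated
  mark pair, H3K9ac ~ H3K4me3);
* samples carry a global offset (uneven reference mixing) removed later
  by median-centering, and measurements are masked missing at the
  configured rates.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse

from .core import ConfigError, DataError, ExpressionMatrix, IntervalTrack
from .hic import ContactMap, contact_map_from_triplets

EPIGENOME_FEATURES = (
    "H2AFZ",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K27ac",
    "H3K79me2",
    "H3K9ac",
    "H3K9me3",
    "H4K20me1",
    "H3K27me3",
    "H3K36me3",
    "CpG_methylation",
)

INACTIVE_LABELS = (
    "Heterochromatin",
    "Repressed",
    "Repetitive",
    "Poised_Promoter",
    "Insulator",
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study (defaults = study conditions)."""

    seed: int = 1
    n_chromosomes: int = 4
    genes_per_chromosome: int = 500
    chromosome_length: int = 25_000_000
    n_samples: int = 60
    # genome organisation
    domain_size_mean: int = 400_000
    frac_bidirectional: float = 0.10
    frac_functional_pairs: float = 0.08
    functional_close_frac: float = 0.4
    dense_domain_frac: float = 0.5
    dense_gene_weight: float = 3.0
    # expression mechanisms
    domain_fluctuation_sd: float = 0.55
    domain_type_count: int = 4
    type_coupling: float = 0.65
    dense_volatility: float = 0.6
    sparse_volatility: float = 1.5
    het_volatility_boost: float = 1.3
    interference_weight: float = 0.35
    interference_scale_bp: float = 20_000.0
    functional_program_sd: float = 1.5
    mrna_noise_sd: float = 0.3
    protein_posttx_sd: float = 0.15
    buffering_on: bool = True
    sample_batch_sd: float = 0.3
    missing_rate_mrna: float = 0.02
    missing_rate_protein: float = 0.067
    # heterochromatin spreading
    heterochromatin_on: bool = True
    heterochromatin_domain_frac: float = 0.7
    # contacts
    hic_decay_exponent: float = 1.0
    domain_contact_boost: float = 2.0
    compartment_boosts: dict = field(
        default_factory=lambda: {"A1": 3.0, "A2": 2.5, "B1": 1.2, "B2": 1.2, "B3": 1.2}
    )
    # interchromosomal clustering is dominated by inactive, gene-poor
    # regions, so B-type same-compartment contacts are boosted across
    # chromosomes while A-type loci interact mostly within their own
    inter_compartment_boosts: dict = field(
        default_factory=lambda: {"A1": 1.3, "A2": 1.3, "B1": 2.5, "B2": 2.5, "B3": 2.5}
    )
    intra_bin_size: int = 20_000
    inter_bin_size: int = 100_000
    max_contact_distance: int = 5_000_000
    inter_base_contact: float = 0.01
    contact_noise_sd: float = 0.25
    # epigenome
    epigenome_gene_noise_sd: float = 0.3
    # post-transcriptional annotations
    posttx_sharing: bool = True
    ribosome_mrna_weight: float = 0.45
    ribosome_program_count: int = 7
    ribosome_noise_sd: float = 0.5

    def validate(self) -> None:
        for name in (
            "domain_fluctuation_sd", "functional_program_sd", "mrna_noise_sd",
            "protein_posttx_sd", "sample_batch_sd", "contact_noise_sd",
            "epigenome_gene_noise_sd", "ribosome_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in (
            "frac_bidirectional", "frac_functional_pairs", "functional_close_frac",
            "dense_domain_frac", "missing_rate_mrna", "missing_rate_protein",
            "heterochromatin_domain_frac",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0 <= self.type_coupling <= 1:
            raise ConfigError("type_coupling must be in [0, 1]")
        # geometric feasibility: genes need ~1 kb of elbow room each
        if self.genes_per_chromosome * 2_000 > self.chromosome_length:
            raise ConfigError(
                "infeasible geometry: genes x minimal spacing exceeds chromosome length"
            )


@dataclass
class Bundle:
    """One generated study: every pipeline input plus ground truth."""

    config: GeneratorConfig
    annotation: pd.DataFrame
    mrna: ExpressionMatrix
    protein: ExpressionMatrix
    ribosome: ExpressionMatrix
    contact_maps: dict
    epigenome: pd.DataFrame
    chromatin_states: IntervalTrack
    subcompartments: IntervalTrack
    half_life: pd.Series
    ned: pd.Series
    protein_length: pd.Series
    mirna_targets: dict
    association_scores: pd.DataFrame
    paralogs: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_pairs: pd.DataFrame  # planted functional pairs
    chrom_lengths: dict


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def _place_chromosome(cfg: GeneratorConfig, rng: np.random.Generator, chrom: str):
    """Place domains and genes along one chromosome.

    Returns (genes dataframe, domains dataframe). Gene placement density
    follows the domain's density class; a fraction of adjacent pairs is
    rearranged into divergent (<1 kb) or functional closeby anchors.
    """
    L = cfg.chromosome_length
    n_dom = max(int(round(L / cfg.domain_size_mean)), 1)
    widths = rng.uniform(0.6, 1.4, n_dom)
    bounds = np.concatenate([[0.0], np.cumsum(widths)]) / widths.sum() * L
    dom = pd.DataFrame(
        {
            "start": bounds[:-1].astype(np.int64),
            "end": bounds[1:].astype(np.int64),
        }
    )
    dom["chromosome"] = chrom
    dom["dense"] = rng.random(n_dom) < cfg.dense_domain_frac
    dom["dtype"] = rng.integers(0, cfg.domain_type_count, n_dom)
    half = cfg.domain_type_count / 2
    dom["compartment"] = np.where(
        dom["dense"],
        np.where(dom["dtype"] < half, "A1", "A2"),
        np.array(["B1", "B2", "B3"])[dom["dtype"].to_numpy() % 3],
    )
    dom["het_flanked"] = (
        cfg.heterochromatin_on
        & ~dom["dense"]
        & (rng.random(n_dom) < cfg.heterochromatin_domain_frac)
    )
    vol = np.where(dom["dense"], cfg.dense_volatility, cfg.sparse_volatility)
    vol = vol * np.where(dom["het_flanked"], cfg.het_volatility_boost, 1.0)
    dom["volatility"] = vol

    weights = (dom["end"] - dom["start"]).to_numpy(float)
    weights *= np.where(dom["dense"], cfg.dense_gene_weight, 1.0)
    counts = rng.multinomial(cfg.genes_per_chromosome, weights / weights.sum())
    tss = np.empty(0, dtype=np.int64)
    dom_of_gene = np.empty(0, dtype=np.int64)
    # keep gene bodies and upstream windows inside the chromosome
    margin = min(40_000, L // 20)
    for d in range(n_dom):
        lo = max(int(dom.at[d, "start"]), margin)
        hi = min(int(dom.at[d, "end"]), L - margin)
        if counts[d] == 0 or hi - lo < 10_000:
            counts[d] = 0
            continue
        if dom.at[d, "het_flanked"] and counts[d] >= 2:
            # heterochromatin-flanked domains hold loose gene pairs: the
            # stochastic spreading silences a pair together, so these
            # genes have a close neighbour to be co-regulated with while
            # the domain as a whole stays gene-poor
            n_anchor = (counts[d] + 1) // 2
            anchors = np.sort(rng.integers(lo, hi - 45_000, n_anchor)).astype(np.int64)
            partners = anchors + rng.integers(8_000, 40_000, n_anchor)
            pos = np.sort(np.concatenate([anchors, partners])[: counts[d]])
        else:
            pos = np.sort(rng.integers(lo, hi, counts[d])).astype(np.int64)
        tss = np.concatenate([tss, pos])
        dom_of_gene = np.concatenate([dom_of_gene, np.full(counts[d], d, np.int64)])
    # top up genes lost to degenerate domains
    short = cfg.genes_per_chromosome - len(tss)
    if short > 0:
        pos = rng.integers(margin, L - margin, short).astype(np.int64)
        tss = np.concatenate([tss, pos])
        didx = np.searchsorted(dom["end"].to_numpy(), pos, side="right")
        didx = np.clip(didx, 0, n_dom - 1)
        dom_of_gene = np.concatenate([dom_of_gene, didx.astype(np.int64)])
    order = np.argsort(tss, kind="stable")
    tss, dom_of_gene = tss[order], dom_of_gene[order]
    tss = _deduplicate(tss, rng)

    n = len(tss)
    strand = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    pair_role = np.full(n, "", dtype=object)  # 'bidir' / 'func_close' anchor marker
    partner = np.full(n, -1, dtype=np.int64)

    # rearrange adjacent same-domain pairs into divergent < 1 kb pairs
    n_bid = int(round(cfg.frac_bidirectional * n / 2))
    adjacent = np.array(
        [i for i in range(n - 1) if dom_of_gene[i] == dom_of_gene[i + 1]], dtype=np.int64
    )
    rng.shuffle(adjacent)
    used = np.zeros(n, dtype=bool)
    n_func_close_target = int(
        round(cfg.functional_close_frac * cfg.frac_functional_pairs * n / 2)
    )
    picked_bid, picked_func = [], []
    for i in adjacent:
        if used[i] or used[i + 1]:
            continue
        if len(picked_bid) < n_bid:
            picked_bid.append(i)
        elif len(picked_func) < n_func_close_target:
            picked_func.append(i)
        else:
            break
        used[i] = used[i + 1] = True
    for i in picked_bid:
        gap = int(rng.integers(150, 950))
        tss[i + 1] = tss[i] + gap
        strand[i] = "-"   # lower TSS transcribes leftward,
        strand[i + 1] = "+"  # upper rightward: divergent
        pair_role[i] = "bidir"
        partner[i] = i + 1
        partner[i + 1] = i
    for i in picked_func:
        gap = int(rng.integers(5_000, 45_000))
        tss[i + 1] = tss[i] + gap
        pair_role[i] = "func_close"
        partner[i] = i + 1
        partner[i + 1] = i

    # keep TSS sorted after the rearrangements (clip runaway positions)
    tss = np.clip(tss, margin, L - margin)
    order = np.argsort(tss, kind="stable")
    inv = np.empty(n, dtype=np.int64)
    inv[order] = np.arange(n)
    tss = tss[order]
    tss = _deduplicate(tss, rng)
    dom_of_gene = dom_of_gene[order]
    strand = strand[order]
    pair_role = pair_role[order]
    partner = np.where(partner[order] >= 0, inv[partner[order]], -1)

    length = rng.integers(2_000, 30_000, n)
    body_start = np.where(strand == "+", tss, np.maximum(tss - length, 0))
    body_end = np.where(strand == "+", np.minimum(tss + length, L), tss)
    genes = pd.DataFrame(
        {
            "chromosome": chrom,
            "tss": tss,
            "strand": strand,
            "body_start": body_start.astype(np.int64),
            "body_end": body_end.astype(np.int64),
            "domain": dom_of_gene,
            "pair_role": pair_role,
            "partner": partner,
        }
    )
    return genes, dom


def _deduplicate(tss: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Nudge duplicate TSS positions apart (keeps the array sorted)."""
    tss = tss.copy()
    for i in range(1, len(tss)):
        if tss[i] <= tss[i - 1]:
            tss[i] = tss[i - 1] + 1
    return tss


def generate(cfg: GeneratorConfig) -> Bundle:
    """Generate a complete synthetic study; deterministic given cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- genome geometry -------------------------------------------------
    gene_frames, dom_frames = [], []
    for c in range(cfg.n_chromosomes):
        genes, dom = _place_chromosome(cfg, rng, _chrom_name(c))
        dom["chrom_index"] = c
        genes["chrom_index"] = c
        gene_frames.append(genes)
        dom_frames.append(dom)
    domains = pd.concat(dom_frames, ignore_index=True)
    genes = pd.concat(gene_frames, ignore_index=True)
    # global domain ids
    dom_offset = np.concatenate(
        [[0], np.cumsum([len(d) for d in dom_frames])[:-1]]
    ).astype(np.int64)
    gene_offset = np.concatenate(
        [[0], np.cumsum([len(g) for g in gene_frames])[:-1]]
    ).astype(np.int64)
    genes["domain_id"] = genes["domain"].to_numpy() + dom_offset[genes["chrom_index"]]
    part = genes["partner"].to_numpy()
    genes["partner"] = np.where(
        part >= 0, part + gene_offset[genes["chrom_index"].to_numpy()], -1
    )
    genes["gene_id"] = [
        f"g{genes.at[i, 'chrom_index'] + 1}_{j:04d}"
        for i, j in zip(genes.index, genes.groupby("chrom_index").cumcount())
    ]
    genes = genes.set_index("gene_id", drop=False)
    n_genes = len(genes)
    chrom_lengths = {_chrom_name(c): cfg.chromosome_length for c in range(cfg.n_chromosomes)}

    # --- functional programs ---------------------------------------------
    prog_of_gene = np.full(n_genes, -1, dtype=np.int64)
    func_pairs: list[tuple[str, str]] = []
    next_prog = 0
    pos_index = {g: k for k, g in enumerate(genes.index)}
    # close functional pairs marked during placement
    for gid in genes.index[genes["pair_role"] == "func_close"]:
        k = pos_index[gid]
        p = genes.iloc[int(genes.at[gid, "partner"])]
        prog_of_gene[k] = next_prog
        prog_of_gene[pos_index[p.name]] = next_prog
        func_pairs.append(tuple(sorted((gid, p.name))))
        next_prog += 1
    n_func_total = int(round(cfg.frac_functional_pairs * n_genes / 2))
    n_far = max(n_func_total - len(func_pairs), 0)
    free = np.flatnonzero(prog_of_gene < 0)
    chosen = rng.choice(free, size=min(2 * n_far, len(free) // 2 * 2), replace=False)
    for a, b in zip(chosen[0::2], chosen[1::2]):
        prog_of_gene[a] = next_prog
        prog_of_gene[b] = next_prog
        func_pairs.append(tuple(sorted((genes.index[a], genes.index[b]))))
        next_prog += 1

    # --- expression -------------------------------------------------------
    S = cfg.n_samples
    n_dom_total = len(domains)
    c_type = rng.normal(size=(cfg.domain_type_count, S))
    eps_dom = rng.normal(size=(n_dom_total, S))
    rho = cfg.type_coupling
    a_dom = (
        cfg.domain_fluctuation_sd
        * domains["volatility"].to_numpy()[:, None]
        * (np.sqrt(rho) * c_type[domains["dtype"].to_numpy()] + np.sqrt(1 - rho) * eps_dom)
    )
    f_prog = cfg.functional_program_sd * rng.normal(size=(max(next_prog, 1), S))
    prog_term = np.zeros((n_genes, S))
    has_prog = prog_of_gene >= 0
    prog_term[has_prog] = f_prog[prog_of_gene[has_prog]]
    base = prog_term + a_dom[genes["domain_id"].to_numpy()]

    W = _interference_weights(cfg, genes)
    interf = cfg.interference_weight * (W @ base)
    mrna_core = base + interf

    batch_m = rng.normal(0, cfg.sample_batch_sd, S)
    batch_p = rng.normal(0, cfg.sample_batch_sd, S)
    batch_r = rng.normal(0, cfg.sample_batch_sd, S)
    noise_m = rng.normal(0, cfg.mrna_noise_sd, size=(n_genes, S))
    noise_p = rng.normal(0, cfg.protein_posttx_sd, size=(n_genes, S))
    mrna_vals = mrna_core + noise_m + batch_m
    if cfg.buffering_on:
        protein_vals = prog_term + noise_p + batch_p
    else:
        protein_vals = mrna_core + noise_m + noise_p + batch_p

    # ribosome layer: reflects mRNA plus a translation regime
    k_trans = rng.integers(0, cfg.ribosome_program_count, n_genes)
    if cfg.posttx_sharing:
        for a, b in func_pairs:
            k_trans[pos_index[b]] = k_trans[pos_index[a]]
    u_trans = rng.normal(size=(cfg.ribosome_program_count, S))
    ribo_vals = (
        cfg.ribosome_mrna_weight * mrna_core
        + u_trans[k_trans]
        + rng.normal(0, cfg.ribosome_noise_sd, size=(n_genes, S))
        + batch_r
    )

    samples = [f"LCL{j + 1:03d}" for j in range(S)]
    mrna_df = pd.DataFrame(mrna_vals, index=genes.index, columns=samples)
    protein_df = pd.DataFrame(protein_vals, index=genes.index, columns=samples)
    ribo_df = pd.DataFrame(ribo_vals, index=genes.index, columns=samples)
    mrna_df = mrna_df.mask(rng.random(mrna_df.shape) < cfg.missing_rate_mrna)
    protein_df = protein_df.mask(rng.random(protein_df.shape) < cfg.missing_rate_protein)

    # --- contacts ----------------------------------------------------------
    contact_maps = {}
    bin_labels = {}
    for c in range(cfg.n_chromosomes):
        chrom = _chrom_name(c)
        dsub = domains[domains["chrom_index"] == c].reset_index(drop=True)
        cmap, labels = _intra_contacts(cfg, rng, chrom, dsub)
        contact_maps[(chrom, chrom)] = cmap
        bin_labels[chrom] = labels
    for c1 in range(cfg.n_chromosomes):
        for c2 in range(c1 + 1, cfg.n_chromosomes):
            ca, cb = _chrom_name(c1), _chrom_name(c2)
            contact_maps[(ca, cb)] = _inter_contacts(cfg, rng, ca, cb, bin_labels)

    # --- epigenome ----------------------------------------------------------
    p = len(EPIGENOME_FEATURES)
    # orthonormal type signatures: distinct chromatin flavours are equally
    # separated, so epigenetic similarity cleanly tracks the domain type
    q, _ = np.linalg.qr(rng.normal(size=(p, p)))
    signatures = q[: cfg.domain_type_count] * np.sqrt(p / 2)
    Z = signatures[domains["dtype"].to_numpy()[genes["domain_id"].to_numpy()]]
    Z = Z + rng.normal(0, cfg.epigenome_gene_noise_sd, size=(n_genes, p))
    i_k4me3 = EPIGENOME_FEATURES.index("H3K4me3")
    i_k9ac = EPIGENOME_FEATURES.index("H3K9ac")
    Z[:, i_k9ac] = 0.85 * Z[:, i_k4me3] + 0.3 * rng.normal(size=n_genes)
    epigenome = pd.DataFrame(
        np.exp(0.6 * Z + 1.0), index=genes.index, columns=list(EPIGENOME_FEATURES)
    )

    # --- chromatin states and subcompartments -------------------------------
    chromatin_states = _chromatin_state_track(cfg, rng, genes, domains)
    subcompartments = IntervalTrack(
        domains.rename(columns={"compartment": "label"})[
            ["chromosome", "start", "end", "label"]
        ].copy()
    )

    # --- post-transcriptional annotations -----------------------------------
    half_life = pd.Series(
        np.exp(rng.normal(np.log(6.0), 0.8, n_genes)), index=genes.index, name="half_life"
    )
    ned = pd.Series(rng.random(n_genes) < 0.15, index=genes.index, name="ned")
    length_aa = pd.Series(
        np.exp(rng.normal(6.2, 0.6, n_genes)).round().astype(int) + 50,
        index=genes.index,
        name="length_aa",
    )
    n_mirna = 60
    mirna_names = [f"miR-{i + 1}" for i in range(n_mirna)]
    targets = {
        g: set(rng.choice(n_mirna, size=rng.poisson(3), replace=False).tolist())
        for g in genes.index
    }
    if cfg.posttx_sharing:
        for a, b in func_pairs:
            # shared regimes for functional pairs
            if rng.random() < 0.85:
                half_life[b] = half_life[a] * rng.uniform(1.0, 1.35)
            if rng.random() < 0.8:
                shared = int(rng.integers(0, n_mirna))
                targets[a].add(shared)
                targets[b].add(shared)
            if rng.random() < 0.6:
                ned[a if rng.random() < 0.5 else b] = True
            if rng.random() < 0.85:
                length_aa[b] = max(int(length_aa[a] * rng.uniform(1.0, 1.35)), 51)
    mirna_targets = {
        g: frozenset(mirna_names[i] for i in sorted(t)) for g, t in targets.items()
    }

    assoc_rows = [
        {"gene_a": a, "gene_b": b, "association_score": float(rng.uniform(0.7, 1.0))}
        for a, b in func_pairs
    ]
    # background scores for a sample of non-functional pairs
    bg = rng.choice(n_genes, size=(200, 2))
    for a, b in bg:
        if a == b:
            continue
        if prog_of_gene[a] >= 0 and prog_of_gene[a] == prog_of_gene[b]:
            continue
        ga, gb = sorted((genes.index[a], genes.index[b]))
        assoc_rows.append(
            {"gene_a": ga, "gene_b": gb,
             "association_score": float(rng.uniform(0.0, 0.6))}
        )
    association_scores = pd.DataFrame(assoc_rows).drop_duplicates(["gene_a", "gene_b"])

    par_rows = []
    for a, b in func_pairs:
        if rng.random() < 0.3:
            par_rows.append(
                {"gene_a": a, "gene_b": b,
                 "percent_identity": float(rng.uniform(25, 95))}
            )
    paralogs = pd.DataFrame(par_rows, columns=["gene_a", "gene_b", "percent_identity"])

    # --- ground truth -------------------------------------------------------
    truth_genes = pd.DataFrame(
        {
            "gene_id": genes.index,
            "chromosome": genes["chromosome"].to_numpy(),
            "tss": genes["tss"].to_numpy(),
            "domain_id": genes["domain_id"].to_numpy(),
            "domain_type": domains["dtype"].to_numpy()[genes["domain_id"].to_numpy()],
            "density_class": np.where(
                domains["dense"].to_numpy()[genes["domain_id"].to_numpy()], "dense", "sparse"
            ),
            "het_flanked": domains["het_flanked"].to_numpy()[genes["domain_id"].to_numpy()],
            "compartment": domains["compartment"].to_numpy()[genes["domain_id"].to_numpy()],
            "program_id": prog_of_gene,
        }
    ).set_index("gene_id", drop=False)
    truth_pairs = pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "label": "functional"} for a, b in sorted(func_pairs)]
    )

    annotation = genes[
        ["gene_id", "chromosome", "tss", "strand", "body_start", "body_end"]
    ].copy()

    return Bundle(
        config=cfg,
        annotation=annotation,
        mrna=ExpressionMatrix(values=mrna_df, layer="mrna"),
        protein=ExpressionMatrix(values=protein_df, layer="protein"),
        ribosome=ExpressionMatrix(values=ribo_df, layer="ribosome"),
        contact_maps=contact_maps,
        epigenome=epigenome,
        chromatin_states=chromatin_states,
        subcompartments=subcompartments,
        half_life=half_life,
        ned=ned,
        protein_length=length_aa,
        mirna_targets=mirna_targets,
        association_scores=association_scores,
        paralogs=paralogs,
        truth_genes=truth_genes,
        truth_pairs=truth_pairs,
        chrom_lengths=chrom_lengths,
    )


def _interference_weights(cfg: GeneratorConfig, genes: pd.DataFrame) -> sparse.csr_matrix:
    """Sparse neighbour weight matrix: exp(−d/scale) for TSS distance < 50 kb."""
    n = len(genes)
    rows, cols, vals = [], [], []
    for _, grp in genes.groupby("chromosome", sort=False):
        idx = np.array([genes.index.get_loc(g) for g in grp.index])
        tss = grp["tss"].to_numpy(np.int64)
        order = np.argsort(tss, kind="stable")
        idx, tss = idx[order], tss[order]
        j = 0
        for i in range(len(tss)):
            k = i + 1
            while k < len(tss) and tss[k] - tss[i] < 50_000:
                w = float(np.exp(-(tss[k] - tss[i]) / cfg.interference_scale_bp))
                rows += [idx[i], idx[k]]
                cols += [idx[k], idx[i]]
                vals += [w, w]
                k += 1
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _intra_contacts(cfg, rng, chrom: str, dsub: pd.DataFrame):
    """Banded power-law intra map with domain and compartment boosts."""
    bs = cfg.intra_bin_size
    n = int(np.ceil(cfg.chromosome_length / bs))
    mid = (np.arange(n) + 0.5) * bs
    didx = np.searchsorted(dsub["end"].to_numpy(), mid, side="right")
    didx = np.clip(didx, 0, len(dsub) - 1)
    labels = dsub["compartment"].to_numpy()[didx]
    boosts = np.array([cfg.compartment_boosts.get(l, 1.0) for l in labels])
    kmax = min(cfg.max_contact_distance // bs, n - 1)
    tri_i, tri_j, tri_v = [], [], []
    for d in range(kmax + 1):
        i = np.arange(0, n - d)
        j = i + d
        c = float(max(d, 1)) ** (-cfg.hic_decay_exponent)
        v = np.full(len(i), c)
        same_comp = labels[i] == labels[j]
        v = np.where(same_comp, v * np.sqrt(boosts[i] * boosts[j]), v)
        v = v * np.where(didx[i] == didx[j], cfg.domain_contact_boost, 1.0)
        sig = cfg.contact_noise_sd
        v = v * rng.lognormal(-0.5 * sig * sig, sig, len(i))
        tri_i.append(i)
        tri_j.append(j)
        tri_v.append(v)
    triplets = pd.DataFrame(
        {
            "bin_i": np.concatenate(tri_i),
            "bin_j": np.concatenate(tri_j),
            "count": np.concatenate(tri_v),
        }
    )
    cmap = contact_map_from_triplets(
        triplets, bin_size=bs, chrom_a=chrom, chrom_b=chrom,
        chrom_a_length=cfg.chromosome_length,
    )
    return cmap, (didx, labels, boosts)


def _inter_contacts(cfg, rng, ca: str, cb: str, bin_labels) -> ContactMap:
    """Compartment-boosted interchromosomal map at coarse resolution."""
    bs = cfg.inter_bin_size
    n = int(np.ceil(cfg.chromosome_length / bs))
    mid = (np.arange(n) + 0.5) * bs
    ratio = bs // cfg.intra_bin_size
    la = bin_labels[ca][1][np.minimum(np.arange(n) * ratio, len(bin_labels[ca][1]) - 1)]
    lb = bin_labels[cb][1][np.minimum(np.arange(n) * ratio, len(bin_labels[cb][1]) - 1)]
    ba = np.array([cfg.inter_compartment_boosts.get(l, 1.0) for l in la])
    bb = np.array([cfg.inter_compartment_boosts.get(l, 1.0) for l in lb])
    same = la[:, None] == lb[None, :]
    v = cfg.inter_base_contact * np.where(same, np.sqrt(ba[:, None] * bb[None, :]), 1.0)
    sig = cfg.contact_noise_sd
    v = v * rng.lognormal(-0.5 * sig * sig, sig, size=v.shape)
    ii, jj = np.indices(v.shape)
    triplets = pd.DataFrame(
        {"bin_i": ii.ravel(), "bin_j": jj.ravel(), "count": v.ravel()}
    )
    return contact_map_from_triplets(
        triplets, bin_size=bs, chrom_a=ca, chrom_b=cb,
        chrom_a_length=cfg.chromosome_length, chrom_b_length=cfg.chromosome_length,
        symmetrize=False,
    )


def _chromatin_state_track(cfg, rng, genes: pd.DataFrame, domains: pd.DataFrame) -> IntervalTrack:
    """Heterochromatin intervals upstream of genes in het-flanked domains,
    plus active filler intervals elsewhere."""
    rows = []
    het_doms = set(domains.index[domains["het_flanked"]])
    for gid, g in genes.iterrows():
        if g["domain_id"] in het_doms and rng.random() < 0.8:
            off = int(rng.integers(2_000, 25_000))
            width = int(rng.integers(4_000, 12_000))
            if g["strand"] == "+":
                start, end = g["tss"] - off - width, g["tss"] - off
            else:
                start, end = g["tss"] + off, g["tss"] + off + width
            if start >= 0:
                rows.append(
                    {
                        "chromosome": g["chromosome"],
                        "start": int(start),
                        "end": int(end),
                        "label": INACTIVE_LABELS[int(rng.integers(0, len(INACTIVE_LABELS)))],
                    }
                )
    for _, d in domains.iterrows():
        if not d["het_flanked"]:
            rows.append(
                {
                    "chromosome": d["chromosome"],
                    "start": int(d["start"]),
                    "end": int(d["end"]),
                    "label": "Active_Promoter",
                }
            )
    return IntervalTrack(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ground-truth utilities


def pair_truth_labels(bundle: Bundle, pairs: pd.DataFrame) -> pd.Series:
    """Mechanistic label per queried pair.

    functional: planted shared program; domain_coupled: same chromatin
    domain (not functional); interference_coupled: TSSs < 50 kb apart in
    different domains (not functional); none: everything else.
    """
    tg = bundle.truth_genes
    prog_a = tg["program_id"].reindex(pairs["gene_a"]).to_numpy()
    prog_b = tg["program_id"].reindex(pairs["gene_b"]).to_numpy()
    dom_a = tg["domain_id"].reindex(pairs["gene_a"]).to_numpy()
    dom_b = tg["domain_id"].reindex(pairs["gene_b"]).to_numpy()
    chrom_a = tg["chromosome"].reindex(pairs["gene_a"]).to_numpy()
    chrom_b = tg["chromosome"].reindex(pairs["gene_b"]).to_numpy()
    tss_a = tg["tss"].reindex(pairs["gene_a"]).to_numpy(np.int64)
    tss_b = tg["tss"].reindex(pairs["gene_b"]).to_numpy(np.int64)
    functional = (prog_a >= 0) & (prog_a == prog_b)
    same_dom = dom_a == dom_b
    close = (chrom_a == chrom_b) & (np.abs(tss_a - tss_b) < 50_000)
    label = np.full(len(pairs), "none", dtype=object)
    label[close & ~same_dom] = "interference_coupled"
    label[same_dom] = "domain_coupled"
    label[functional] = "functional"
    return pd.Series(label, index=pairs.index, name="truth_label")


def truth_report(
    truth_labels: pd.Series, predicted_positive: pd.Series, positive_label: str
) -> dict:
    """Precision/recall of a boolean prediction against a planted label.

    Both series must be aligned on the same pair index; a mismatch is an
    error. Returns per-label confusion counts plus precision and recall
    for ``positive_label``.
    """
    if not truth_labels.index.equals(predicted_positive.index):
        raise DataError("truth and prediction indexes do not match")
    pred = predicted_positive.astype(bool)
    per_label = {
        str(lab): {
            "n": int((truth_labels == lab).sum()),
            "n_called": int((pred & (truth_labels == lab)).sum()),
        }
        for lab in truth_labels.unique()
    }
    tp = int((pred & (truth_labels == positive_label)).sum())
    fp = int((pred & (truth_labels != positive_label)).sum())
    fn = int((~pred & (truth_labels == positive_label)).sum())
    return {
        "per_label": per_label,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
        "recall": tp / (tp + fn) if tp + fn else np.nan,
    }
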