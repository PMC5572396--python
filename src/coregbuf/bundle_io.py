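"""Serialisation of a generated study to the pipeline's input formats.

Everything is plain text: expression TSVs, BED for annotation and tracks,
triplet TSVs for contact maps, small TSVs for the pair annotations, and a
JSON copy of the generator configuration and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import core
from .hic import read_contact_map, write_contact_map
from .simulate import Bundle, GeneratorConfig


def write_bundle(bundle: Bundle, outdir) -> list[Path]:
    """Write every bundle component under ``outdir``; returns file list."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "contacts").mkdir(exist_ok=True)
    written: list[Path] = []

    def _w(path: Path):
        written.append(path)
        return path

    core.write_expression(bundle.mrna, _w(out / "mrna.tsv"))
    core.write_expression(bundle.protein, _w(out / "protein.tsv"))
    core.write_expression(bundle.ribosome, _w(out / "ribosome.tsv"))
    core.write_annotation_bed(bundle.annotation, _w(out / "genes.bed"))
    pd.DataFrame(
        sorted(bundle.chrom_lengths.items()), columns=["chromosome", "length"]
    ).to_csv(_w(out / "chrom_lengths.tsv"), sep="\t", index=False)
    for (ca, cb), cmap in sorted(bundle.contact_maps.items()):
        write_contact_map(cmap, _w(out / "contacts" / f"{ca}__{cb}.tsv"))
    bundle.epigenome.to_csv(_w(out / "epigenome.tsv"), sep="\t", index_label="gene_id")
    core.write_bed4(bundle.chromatin_states, _w(out / "chromatin_states.bed"))
    core.write_bed4(bundle.subcompartments, _w(out / "subcompartments.bed"))
    pd.DataFrame(
        {
            "gene_id": bundle.half_life.index,
            "half_life": bundle.half_life.to_numpy(),
            "ned": bundle.ned.to_numpy(),
            "length_aa": bundle.protein_length.to_numpy(),
        }
    ).to_csv(_w(out / "gene_posttx.tsv"), sep="\t", index=False)
    rows = [
        {"mirna": m, "gene_id": g}
        for g, ms in bundle.mirna_targets.items()
        for m in sorted(ms)
    ]
    pd.DataFrame(rows, columns=["mirna", "gene_id"]).to_csv(
        _w(out / "mirna_targets.tsv"), sep="\t", index=False
    )
    bundle.association_scores.to_csv(_w(out / "association_scores.tsv"), sep="\t", index=False)
    bundle.paralogs.to_csv(_w(out / "paralogs.tsv"), sep="\t", index=False)
    bundle.truth_genes.to_csv(_w(out / "truth_genes.tsv"), sep="\t", index=False)
    bundle.truth_pairs.to_csv(_w(out / "truth_pairs.tsv"), sep="\t", index=False)
    with open(_w(out / "generator_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(bundle.config), fh, indent=2, sort_keys=True)
    return written


def read_bundle(indir) -> Bundle:
    """Reload a written bundle (inverse of :func:`write_bundle`)."""
    d = Path(indir)
    with open(d / "generator_config.json") as fh:
        cfg = GeneratorConfig(**json.load(fh))
    ann = core.read_annotation_bed(d / "genes.bed")
    chrom_lengths = dict(
        pd.read_csv(d / "chrom_lengths.tsv", sep="\t").itertuples(index=False, name=None)
    )
    contact_maps = {}
    for path in sorted((d / "contacts").glob("*.tsv")):
        cmap = read_contact_map(path)
        contact_maps[(cmap.chrom_a, cmap.chrom_b)] = cmap
    posttx = pd.read_csv(d / "gene_posttx.tsv", sep="\t", index_col=0)
    mirna = pd.read_csv(d / "mirna_targets.tsv", sep="\t")
    mirna_targets = {
        g: frozenset(sub["mirna"]) for g, sub in mirna.groupby("gene_id")
    }
    truth_genes = pd.read_csv(d / "truth_genes.tsv", sep="\t", index_col=0)
    truth_genes.insert(0, "gene_id", truth_genes.index)
    return Bundle(
        config=cfg,
        annotation=ann,
        mrna=core.load_expression(d / "mrna.tsv", "mrna"),
        protein=core.load_expression(d / "protein.tsv", "protein"),
        ribosome=core.load_expression(d / "ribosome.tsv", "ribosome"),
        contact_maps=contact_maps,
        epigenome=core.load_epigenome(d / "epigenome.tsv"),
        chromatin_states=core.read_bed4(d / "chromatin_states.bed"),
        subcompartments=core.read_bed4(d / "subcompartments.bed"),
        half_life=posttx["half_life"],
        ned=posttx["ned"].astype(bool),
        protein_length=posttx["length_aa"],
        mirna_targets=mirna_targets,
        association_scores=pd.read_csv(d / "association_scores.tsv", sep="\t"),
        paralogs=pd.read_csv(d / "paralogs.tsv", sep="\t"),
        truth_genes=truth_genes,
        truth_pairs=pd.read_csv(d / "truth_pairs.tsv", sep="\t"),
        chrom_lengths=chrom_lengths,
    )
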