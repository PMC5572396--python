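# coregbuf

Co-regulation of spatially proximal genes, and its buffering at the protein level.

Neighbouring genes in mammalian genomes — bidirectional promoter pairs, genes
within the same chromatin domain, loci brought together by chromosome folding —
are frequently *co-regulated* at the mRNA level even when they have nothing to
do with each other functionally. `coregbuf` is a pipeline for quantifying this
phenomenon from paired expression panels and genome-structure data, and for
testing whether the transcript-level co-variation is propagated to, or buffered
at, the protein level.

It is aimed at researchers with matched mRNA and protein abundance panels
across many samples (e.g. a cell-line panel quantified by RNA-seq and SILAC
proteomics relative to a common reference), plus standard genome-structure
inputs: gene annotations, binned Hi-C contact matrices, subcompartment and
chromatin-state intervals, and gene-body epigenomic signals.

## The statistics at the core

For genes *i, j* with centered log2 abundance ratios across samples, the pair
is **co-regulated** when the Pearson correlation over pairwise-complete samples
satisfies

&nbsp;&nbsp;&nbsp;&nbsp;*r<sub>ij</sub>* > 0.5 and BH-adjusted *p* < 0.001,

with the Benjamini–Hochberg adjustment computed within each analysis's pair
set. A pair co-regulated at both layers is **sustained**; one co-regulated at
the mRNA level only is **buffered**. Around this call the pipeline provides:

- gene-pair classification (bidirectional = head-to-head, TSSs < 1 kb; closeby
  = TSSs < 50 kb) and chromosome co-regulation maps compared against Hi-C
  contact maps (median normalized count over ± 40 kb TSS windows);
- *k*-means regulation groups per layer with subcompartment (A1/A2/B1–B4) and
  epigenomic feature enrichments;
- expression noise (CV of offset log2 ratios) against three clustering
  degrees: mean distance to the 3 nearest genes in bp, and mean Hi-C contact
  of the 3 strongest intra-/interchromosomal partners;
- epigenetic similarity between genes as the Mahalanobis distance of gene-body
  feature vectors (covariance-aware, since marks like H3K9ac and H3K4me3
  strongly covary), binned jointly with spatial proximity to separate
  chromatin-fluctuation from regulatory-interference co-regulation;
- Fisher-exact enrichment of five shared post-transcriptional regimes
  (mRNA half-life ratio < 1.5, shared miRNA, correlated ribosome occupancy,
  non-exponentially degraded proteins, protein length ratio < 1.5) in
  sustained versus buffered pairs.

Because the analyses only make sense end-to-end, the package ships a
synthetic-study generator (`coregbuf.simulate`) that emits every input format
the pipeline consumes with planted ground truth: chromatin domains with latent
per-sample activities, domain types with shared factors and epigenomic
signatures, distance-weighted regulatory interference between < 50 kb
neighbours, functional pairs with shared programs, protein-level buffering,
power-law Hi-C contacts with compartment structure, and heterochromatin-flanked
volatile domains. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from coregbuf import GeneratorConfig, generate
from coregbuf import analysis

bundle = generate(GeneratorConfig(seed=1))          # synthetic study
layers = analysis.prepare_layers(bundle)            # filter, match, center
pairs = analysis.close_pair_coregulation(layers)    # all < 50 kb pairs
print(analysis.coregulation_summary(pairs).to_string(index=False))

_, _, _, corr = analysis.chromosome_maps(bundle, layers, "chr1")
print(f"chr1 map vs Hi-C: mRNA PCC = {corr['pcc_mrna_vs_hic']:.2f}, "
      f"protein PCC = {corr['pcc_protein_vs_hic']:.2f}")
```

prints

```
orientation_class  n_pairs  pct_coregulated_mrna  pct_coregulated_protein
    bidirectional      111             98.198198                   0.0000
          closeby     2412             86.194030                   1.3267
chr1 map vs Hi-C: mRNA PCC = 0.28, protein PCC = 0.00
```

Read: of the 111 divergent promoter pairs in this synthetic panel, 98% have
co-regulated mRNAs but none keep that co-regulation at the protein level, and
the 2,412 closeby pairs behave the same way (86% vs 1.3%) — the generator's
protein layer buffers everything except the planted functional programs. The
chromosome-wide mRNA co-regulation map correlates with the Hi-C contact map
(PCC 0.28) while the protein map does not (PCC 0.00): transcript co-variation
tracks spatial genome organisation, protein co-variation does not.

## Command line

```bash
coregbuf run-all --seed 42 --out results/run     # all stages + manifest
coregbuf generate --seed 1 --out mystudy/        # just the synthetic bundle
```

`run-all` writes the generated inputs under `inputs/`, every analysis table
under `outputs/` (TSV; co-regulation maps as gzip TSV with a gene-order
sidecar), and a `manifest.json` with config hash, file checksums and stage
timings. Reruns skip up-to-date stages; a modified input file is reported as a
checksum mismatch. A YAML config mirroring `PipelineConfig` can replace the
flags (`--config run.yaml`).

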