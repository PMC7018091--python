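# barcodiv

Tools for evaluating how well candidate DNA barcodes discriminate closely
related species. The motivating setting is the authentication of medicinal
plants such as *Fritillaria* bulbs (Chuanbeimu), where congeneric adulterant
species are sold in place of the genuine medicine and the usual plant
barcodes (*rbcL*, *matK*, *trnH*-*psbA*, ITS/ITS2) can lack the variation to
tell the species apart. The package compares three kinds of marker on equal
footing: **universal barcodes** (single standard loci and their
combinations), the **super-barcode** (the whole plastid genome), and
**specific barcodes** (lineage-specific divergence hotspots nominated from a
genome scan).

## What it computes

Given aligned multi-individual datasets and a sample-to-species table, the
pipeline produces, per dataset:

- **Alignment variability**: variable sites, parsimony-informative sites,
  minimum mutation count η = Σ per column (distinct bases − 1), indel
  events, GC content, and nucleotide diversity
  π = (2 / n(n−1)) Σ_{i<j} d_ij under complete deletion.
- **Sliding-window π scans** (default 600 bp window / 200 bp step) to locate
  divergence hotspots as candidate specific barcodes.
- **Barcoding-gap analysis**: uncorrected p-distances (pairwise deletion by
  default), partitioned into intra- and inter-specific sets with ranges,
  mean ± SE, shared-grid histograms, a strict-gap verdict
  (min inter > max intra), and the overlap fraction
  P(inter ≤ max intra).
- **Neighbor-joining trees** (Saitou–Nei Q-criterion on p-distances),
  outgroup rooting, and nonparametric bootstrap support.
- **Species discrimination** by the monophyly criterion: a species is
  discriminated iff all of its individuals form an exclusive clade on the
  rooted tree; the per-dataset rate is the percentage of ingroup species
  that pass.

A synthetic-data generator (`barcodiv.simulate`) produces aligned datasets
with controlled intra-/inter-specific divergence, indels, an optional
divergence hotspot, and an optional polyphyletic species whose individuals
descend from two distinct lineages — with the true tree and expected
verdicts known by construction, it is the test substrate for the whole
pipeline. Region extraction from annotated GenBank plastomes (genes,
introns, intergenic spacers, literal spans) and per-sample concatenation of
aligned blocks cover the data-preparation steps; multiple sequence alignment
itself is left to external tools (e.g. MAFFT) and the pipeline consumes
aligned FASTA.

## Worked example

```python
from barcodiv import (SimConfig, simulate_dataset, p_distance_matrix,
                      partition_distances, neighbor_joining, root_with_outgroup,
                      discrimination_report, summarize, gap_overlap_metric)

# 8 species x 4 individuals + outgroup, 20 kb, one species made polyphyletic
cfg = SimConfig(seed=42, polyphyletic_species="sp03", donor_lineages=("sp01", "sp06"))
aln, meta, truth = simulate_dataset(cfg)

stats = summarize(aln)
print(f"sites={stats.n_sites} variable={stats.n_variable} "
      f"informative={stats.n_parsimony_informative} pi={stats.pi:.5f}")

dm = p_distance_matrix(aln)
gap = partition_distances(dm, meta)
print(f"intra: {gap.intra_range[0]:.4f}-{gap.intra_range[1]:.4f} mean {gap.intra_mean_se[0]:.4f}")
print(f"inter: {gap.inter_range[0]:.4f}-{gap.inter_range[1]:.4f} mean {gap.inter_mean_se[0]:.4f}")
print(f"strict gap: {gap.strict_gap}  overlap fraction: {gap_overlap_metric(gap):.3f}")

tree = root_with_outgroup(neighbor_joining(dm), ["out_1"])
report = discrimination_report(tree, meta, dataset_name="demo")
print(f"discrimination rate: {report.rate}%")
for sp, v in report.per_species.items():
    if not v.monophyletic:
        print(f"  {sp}: not monophyletic ({v.n_individuals} individuals)")
```

prints

```
sites=20000 variable=1937 informative=1149 pi=0.01817
intra: 0.0011-0.0134 mean 0.0027
inter: 0.0063-0.0275 mean 0.0188
strict gap: False  overlap fraction: 0.181
discrimination rate: 87.5%
  sp03: not monophyletic (4 individuals)
```

The injected polyphyletic species inflates the intraspecific distances (its
individuals sit on two different lineages), destroys the strict barcoding
gap, and is the one species the tree-based criterion fails — so 7 of 8
species are discriminated, a rate of 87.5%.

The same stages are available from the shell via the `barcodiv` command
(`extract`, `stats`, `scan`, `dist`, `tree`, `discriminate`, `simulate`,
`run`, `report`); `barcodiv run --config run.yaml` executes every configured
dataset and writes a combined summary table.

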