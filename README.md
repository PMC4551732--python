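# lepcompgen

Desk-scale comparative-genomics toolkit for highly heterozygous diploid
genomes, built around the analyses used when characterising newly sequenced
butterfly (Lepidoptera) genomes against their relatives.

Assembling a wild-caught insect is hard because the two haplotypes of one
individual can differ at 1.5–2.5 % of positions.  That heterozygosity leaves
fingerprints everywhere: a bimodal k-mer coverage histogram, duplicate
half-coverage "haplotig" scaffolds, block-structured SNP-rate tracks, and
excess amino-acid substitutions in some proteins.  This package implements
the statistics that read those fingerprints, plus a gene-order rearrangement
phylogeny for placing the species among its relatives — all runnable on
synthetic data with known ground truth.

## What is inside

| module | contents |
|---|---|
| `lepcompgen.kmercov` | canonical k-mer histograms (default k=17); het/hom peak detection; coverage-based scaffold and repeat classification |
| `lepcompgen.hapmerge` | the haplotig merge rule: a half-coverage scaffold is merged into a longer scaffold when coverage > 90 %, uncovered < 500 bp, identity > 95 % and the target region is itself under-covered |
| `lepcompgen.snpdist` | region partition (exon > intron > repeat > intergenic), SNP rates in overlapping 1000-bp windows, SNP-free segments, 1- vs 2-component Gaussian-mixture EM with BIC selection, synonymous/non-synonymous calls |
| `lepcompgen.subenrich` | per-protein binomial substitution tests `P[X >= m], X ~ Bin(N, p̄)` with Benjamini–Hochberg FDR at Q < 0.1, GO-term binomial enrichment, product-of-p-values cross-species scores, hypergeometric set overlap |
| `lepcompgen.rearrphylo` | 4-state strand-orientation encoding of co-scaffolded gene-family pairs (A=(+,+), B=(−,−), C=(+,−), D=(−,+)), Hamming distances, BioNJ, relaxed-PHYLIP export, alignment-column consistency/sampling, majority-rule consensus, Robinson–Foulds |
| `lepcompgen.famexp` | family merging via shared closest reference homolog; the 1.5× count-and-length gene-expansion criterion; ortholog-category report |
| `lepcompgen.synthio` | generators with known truth: block-mixture diploid genomes, uniform reads, split assemblies, evolved gene orders, planted substitution enrichment |
| `lepcompgen.io` | FASTA/GFF3/VCF/BED/Newick plumbing; everything internal is 0-based half-open |

A thin CLI (`lepcompgen simulate|kmer|hapmerge|enrich|rearr-tree|consensus|sample-columns`)
wraps the library.

## Worked example

```python
import numpy as np
from lepcompgen import synthio, kmercov, snpdist, rearrphylo
from lepcompgen.io import parse_newick

truth = synthio.simulate_diploid(200_000, seed=7)
print("simulated SNP rate: %.3f%%" % (100 * len(truth.snp_positions) / truth.length))

reads = synthio.simulate_reads(truth, depth=60, read_len=250, seed=7)
peaks = kmercov.detect_peaks(kmercov.kmer_histogram(reads, k=17))
print("k-mer peaks: hom %dx, het %dx, height ratio %.2f"
      % (peaks.hom_depth, peaks.het_depth, peaks.height_ratio))

rates = np.array([r for r in truth.block_rates if r > 0])
fit1, fit2 = snpdist.fit_mixture(rates, 1), snpdist.fit_mixture(rates, 2)
best = snpdist.select_model(fit1, fit2)
print("mixture: k=%d selected, means %.2f%% / %.2f%%"
      % (best.n_components, 100 * best.means[0], 100 * best.means[-1]))

ref = parse_newick(rearrphylo.TRADITIONAL_NEWICK)
orders = synthio.simulate_gene_orders(ref, seed=7)
fams = rearrphylo.families_from_tables(orders.tables)
tree, matrix = rearrphylo.rearrangement_tree(fams, sorted(orders.tables))
print("orientation characters:", len(matrix.pairs))
print("topology:", rearrphylo.topology_report(tree))
```

prints

```
simulated SNP rate: 1.202%
k-mer peaks: hom 56x, het 28x, height ratio 0.61
mixture: k=2 selected, means 0.32% / 2.46%
orientation characters: 596
topology: traditional
```

Reading the output: the 17-mer histogram of 60× reads shows the homozygous
peak near the sequencing depth and the heterozygous peak near half of it
(k-mers per read are slightly fewer than bases, hence 56 rather than 60);
the height ratio rises with heterozygosity.  The per-block SNP rates are
recognised as a two-component mixture with one population of blocks near
0.35 % and a second near 2.5 %.  The gene-order pipeline encodes 596
family-pair orientations into 4-state strings and the BioNJ tree over their
Hamming distances recovers the topology the gene orders were simulated on.

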