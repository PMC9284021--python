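# ystrpop

Forensic and population-genetic analysis of Y-chromosome short tandem
repeat (Y-STR) haplotypes. The package was built around the analysis of a
518-man survey of five Croatian regional subpopulations typed at the
27-locus Yfiler Plus panel, and generalizes to any wide-format Y-STR
haplotype table.

Because the Y chromosome is inherited father-to-son without recombination
(outside the pseudoautosomal regions), the ordered allele vector across
loci — the *haplotype* — is a single linked marker. `ystrpop` covers the
standard analysis stack for such data:

* **Diversity statistics** — per-locus allele frequency spectra, gene
  diversity GD = 1 − Σpᵢ² (with Nei's unbiased n/(n−1) variant),
  haplotype diversity HD = (1 − Σpᵢ²)·n/(n−1), match probability
  MP = Σpᵢ², and discrimination capacity DC = (#distinct haplotypes)/n.
* **Rst genetic distances** — one-way AMOVA on repeat counts per locus,
  variance components summed across loci,
  Rst = σ²ₐ/(σ²ₐ + σ²w), with permutation p-values
  p = (b+1)/(m+1) from shuffling individuals between populations.
* **Structure summaries** — classical (Torgerson) multidimensional
  scaling of the Rst matrix and Saitou–Nei neighbor-joining trees with
  Newick output.
* **Haplogroup prediction** — a Bayesian allele-frequency classifier:
  score(h) = prior(h)·Π max(f_h(allele), ε) over scored loci, posteriors
  by normalization, plus regional haplogroup composition tables.
* **Synthetic data** — a stepwise mutation model (SMM) simulator for
  multi-population panels with controllable divergence, haplogroup-labeled
  panels around modal haplotypes, and planted novel microvariants, so the
  whole stack is testable without external downloads.

Bundled reference data (`ystrpop.datasets`) include the published pooled
Croatian 27-locus allele-frequency table (n = 518), the regional
haplogroup counts, and the published pairwise regional Rst/p matrix.

## Worked example

```python
import ystrpop as ys
from ystrpop import datasets

# Gene diversity at the least / most polymorphic Croatian loci
specs = datasets.croatia_allele_frequencies()
print(round(ys.gene_diversity(specs["DYS392"], unbiased=True), 3))  # 0.251
print(round(ys.gene_diversity(specs["DYS481"], unbiased=True), 3))  # 0.886

# Haplotype diversity implied by 497 singleton + 5 doubleton haplotypes
rep = ys.diversity_from_multiplicities({1: 497, 2: 5})
print(round(rep.haplotype_diversity, 4))                            # 1.0

# Neighbor-joining tree of the published five-region Rst matrix
tree = ys.neighbor_joining(datasets.croatia_regional_rst())
print(tree.ascii_art())
```

The tree groups Hvar with Split on one cherry, Osijek with Pula and
Varaždin on the opposite side — Varaždin sitting on the longest path from
every other region:

```
          /-Osijek
         |
         |          /-Pula
---------|---------|
         |          \-Varazdin
         |
         |          /-Hvar
          \--------|
                    \-Split
```

A full synthetic analysis from the shell:

```sh
ystrpop simulate -p 3 -n 50 -t 600 --seed 5 -o panel.csv
ystrpop rst panel.csv -m 999 --seed 5
ystrpop njtree rst.csv -o tree.nwk        # after saving the matrix with -o
ystrpop run config.yaml                   # config-driven full pipeline
```

`ystrpop run` executes the whole study design: registry-based microvariant
filtering (STR statistics use only validated haplotypes; haplogroup
prediction scores every sample), diversity report, Rst matrix with
permutation p-values, MDS coordinates, NJ tree and prediction tables, all
written as one deterministic report bundle with a manifest.

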