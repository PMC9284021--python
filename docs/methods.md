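# Methods

## Data model

A haplotype table is a samples × loci matrix of numeric repeat counts with
one population label per sample. Alleles are positive numbers below 100
whose fractional part is restricted to .0/.1/.2/.3 — partial-repeat
microvariants (e.g. 13.2 = 13 repeats + 2 bases) are stored as exact
decimals and treated throughout as distinct allelic categories: they are
separate bins in frequency spectra and enter Rst at their numeric value.
Missing calls are `NaN` (`NA` on disk).

Multi-copy markers (DYS385, DYS387S1) yield two unphased alleles per man;
capillary electrophoresis cannot assign them to copies. The default policy
writes the smaller allele to the `a` column (`sorted_ascending`), which is
the YHRD convention, makes column assignment deterministic, and is
idempotent; `as_reported` is available for data already phased by
convention. The haplogroup classifier additionally sorts each query pair
before scoring, so predictions never depend on copy order.

Novel-microvariant screening is registry-based: a sample is flagged when
any called allele is absent (at 0.1-repeat resolution) from a user-editable
per-locus registry of known alleles. Which allelic ladder defines "known"
is a user decision; the shipped registry lists the alleles of the bundled
Croatian frequency table. The pipeline mirrors the study design: flagged
samples are excluded from STR statistics but still receive haplogroup
predictions.

## Diversity statistics

Gene diversity defaults to the plain 1 − Σpᵢ²; `unbiased=True` applies
Nei's n/(n−1) correction. The distinction matters: the published per-locus
values (0.251 for DYS392, 0.886 for DYS481, mean 0.656) are reproduced by
the *unbiased* form at n = 518 — the uncorrected form gives 0.884 at
DYS481 — so the software used in the source study evidently reported
unbiased gene diversity, while its text prints the uncorrected formula.
Both are exposed; the worked examples and the acceptance script use the
unbiased form.

Haplotype-level statistics (HD, MP, DC, multiplicity spectrum) treat the
complete ordered allele vector as the unit. Samples missing any allele are
excluded from haplotype-level statistics (logged) because an incomplete
haplotype cannot be compared for identity, but they still contribute to
per-locus spectra where called. HD carries Nei's variance-based standard
error as a clearly labeled optional output; note that on the published
multiplicity structure (497 singletons, 5 doubletons, n = 507) this
estimator gives ≈ 0.0001, not the ± 0.0014 printed in the source study,
which could not be reproduced from the printed counts. MP and DC are
reported at full precision.

Bundled published spectra are renormalized to sum to one (printed
frequencies are rounded to 3 decimals; the correction is < 0.1% per
locus).

## Rst via AMOVA

Per locus, a one-way random-effects ANOVA on raw repeat counts:
SSwithin/df → σ²w, (MSamong − MSwithin)/n₀ → σ²ₐ with the standard unequal
sample-size coefficient n₀ = (N − Σn_g²/N)/(k−1). Variance components are
summed across loci before forming the ratio (not averaged per-locus),
matching Arlequin/YHRD behavior and keeping the estimator defined at
monomorphic loci. Loci where either population has fewer than two called
samples are skipped for that pair (logged); a sample missing one locus is
dropped for that locus only.

σ²ₐ may be negative (unbiased moment estimator); Rst is reported raw, and
with two copies of the same population it is *systematically* negative
(−MSW/n₀ per locus), approaching 0 only as n grows. The embedding/tree
view clamps at zero, since negative estimates are sampling noise and break
metric assumptions.

Permutation tests shuffle individuals between the two populations
preserving group sizes; p = (b+1)/(m+1) with b the number of permuted
Rst ≥ observed. The add-one estimator avoids p = 0 artifacts and enforces
the 1/(m+1) floor. The engine is vectorized: all m assignment vectors are
evaluated as matrix products over (samples × loci), so the study default
m = 10 000 costs milliseconds per pair at survey scale. Matrix
construction spawns an independent child seed per unordered pair from the
master seed, making results independent of pair evaluation order.

## MDS and neighbor joining

Classical (Torgerson) MDS: B = −½·J·D²·J, eigendecomposition, coordinates
from the top eigenpairs scaled by √λ. Axes are sorted by descending
eigenvalue and sign-fixed so each axis's first nonzero coordinate is
positive; requesting more axes than positive eigenvalues pads with zeros
and warns. The full eigenvalue list and the captured share of
positive-eigenvalue mass are reported. Whether the source study's plots
used metric or non-metric MDS is not documented; Torgerson is implemented,
non-metric scaling would be a natural extension.

Neighbor joining follows Saitou–Nei: minimize
Q(i,j) = (r−2)·d(i,j) − Rᵢ − Rⱼ, limb lengths
ℓᵢ = d(i,j)/2 + (Rᵢ−Rⱼ)/(2(r−2)). Ties in Q (within 1e-12) are broken by
the lexicographically smallest label pair, so output is independent of
input order. Negative limb estimates — possible on non-additive input —
are clamped to zero with the deficit moved to the sibling limb, preserving
the pair's path length. The result is intrinsically unrooted and is
represented with a trifurcating root; on additive matrices the tree's
leaf-to-leaf path lengths reproduce the input exactly, which the tests
verify against an independent NJ implementation.

## Haplogroup classifier

Athey-style Bayesian allele-frequency scoring. Reference panels hold
per-haplogroup per-locus empirical allele frequencies; unseen alleles are
scored at the smoothing floor ε = 1e-4, so a single novel allele penalizes
a candidate by ~4 orders of magnitude instead of zeroing it. Priors
default to uniform; any positive weighting is accepted and normalized.
Scoring runs in log10 space; posteriors are the normalized scores, the
call is the argmax with alphabetical tie-break, and a fitness score — the
winner's mean per-locus log10 likelihood — flags low-confidence calls
(0 means every allele was the haplogroup's mode). Loci absent from panel
or query are skipped; per-version locus weighting schemes of the original
tool are not documented and are not implemented (unweighted product form).
The shipped reference data contain no real haplogroup frequency tables
(provenance/licensing of the original tables is unclear); panels are
trained from labeled tables or simulated.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not a full genealogy. Populations sit in a star: each population ancestor
drifts t/2 generations from a shared root (pairwise divergence t), and
each sampled lineage adds its own within-population drift (`within_time`,
default 200 generations, a plausible within-population coalescent depth
for Y lineages). Mutation counts per lineage are Binomial(t, μ) —
per-generation mutation probability μ defaults to 0.002, the accepted
average Y-STR rate of ~0.2% per generation — and each mutation is a ±1
repeat step; only the net displacement is sampled. Under this model
E[(X₁−X₂)²] = 2μτ for lineages separated by 2τ generations, so mean Rst
rises monotonically with divergence time, which is what the Rst stack
measures; the tests verify the linear law and the monotonicity.

What the generator does *not* emulate: coalescent variance in lineage
depth, locus-specific mutation rates, multi-step mutations, allele-range
constraints beyond a floor at 5 repeats (reflecting boundary), and linkage
between haplogroup membership and population of origin. Passing tests
therefore demonstrate correctness of the estimators under idealized SMM
structure, not calibration against real Y-STR panels.

Haplogroup panels are built from modal haplotypes kept pairwise ≥ 6
mutational steps apart (drawn with rejection, or validated if supplied),
with per-locus noise: each locus mutates one ±1 step with probability
`noise`. Train and test sets are drawn independently with exact requested
label counts. Microvariant planting shifts one called allele of k distinct
samples by +0.2, guaranteeing novelty against an integer-valued registry.
All generators are pure functions of (config, seed).

## Numerical and design choices

* Allele identity is evaluated at 0.1-repeat resolution everywhere
  (registry membership, spectra binning, panel lookup).
* Permutation count defaults to 10 000 (the study's setting); tests use
  99–999 for speed. Test problem sizes (e.g. 100 null datasets × m = 999;
  200 replicates × 4 divergence times at 50 samples × 17 loci; a
  14-haplogroup panel with 500 held-out samples) were chosen as the
  smallest scales at which the targeted statistical properties are stable.
* Report bundles are written to a temporary directory and moved into
  place only after every file succeeded, so failures leave no partial
  bundle; reruns with identical inputs and seed are byte-identical apart
  from wall-clock timings in the manifest.
* The published regional p-values "< 0.0001" are stored as 0.0001 in the
  bundled matrix (only Rst values feed the tree/MDS).
* The command-line interface is a thin layer over the library; every
  subcommand corresponds to one library call.

## Known limitations

* Only two-level (among/within population) AMOVA; no hierarchical
  designs, and no Fst/Φst variants.
* No bootstrap support values on NJ trees.
* Interpopulation comparisons against external published populations run
  fine if the user supplies their haplotype tables, but such tables are
  not bundled.
* The HD standard error printed in the source study could not be
  reconciled with Nei's estimator (see above); the package reports the
  standard estimator.
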