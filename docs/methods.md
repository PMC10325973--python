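# Methods

## Problem and model

Tumor-only panel sequencing cannot distinguish inherited variants from
tumor-acquired mutations by subtraction against a matched normal. The
pipeline implemented here exploits three population-level signals instead:

1. most germline variation is already catalogued (exact-match site filter);
2. a variant recurring in many unrelated dogs is almost certainly germline,
   and its zygosity is readable from the variant allele fraction (VAF)
   across carriers — heterozygous carriers cluster at VAF ≈ 0.5,
   homozygous carriers near 1.0, while somatic mutations, whose VAF depends
   on purity and clonality, spread broadly;
3. a rare mutation whose human orthologous change is an established human
   somatic mutation is very likely somatic in the dog as well.

Everything not captured by these rules stays *unclassifiable* and is
excluded from downstream somatic analyses (TMB, hotspots, enrichment).

## Classifier parameters

| parameter | default | meaning |
|---|---|---|
| `recurrence_threshold` | 5 dogs | split between the VAF branch (≥ 5 carriers) and the human-counterpart branch (< 5) |
| `het_delta` (δ) | 0.10 | half-width of the heterozygous median window around 0.5 |
| `het_iqr_max` (w) | 0.15 | maximum interquartile range for a "clustered" VAF sample |
| `hom_min` (h) | 0.90 | minimum median VAF for a homozygous call |
| `codon_level_match` | off | match human somatic mutations at codon rather than exact amino-acid-change granularity |

"Clustered around 50% / near 100%" is inherently qualitative; the
median-plus-IQR operationalization was chosen so that, with binomial read
sampling at depth ≥ 100 and a latent heterozygous VAF spread of ~0.05,
a true heterozygous variant falls inside the window with probability
> 0.99, while a broad somatic VAF sample (IQR of the scaled Beta(1.2, 1.2)
model ≈ 0.4) essentially never satisfies the dispersion bound. All three
thresholds are exposed on the command line. The boundary convention is
exact: 5 carriers go to the VAF branch, 4 to the rare branch, and the QC
thresholds are strict inequalities (FS = 30.0, QD = 2.0, depth = 10 pass).
Recurrence always counts distinct dogs, never call rows. Calls missing FS
or QD pass those sub-filters: an absent annotation is not a failing one.

## VAF statistics

Distributions are compared on 20 equal-width bins over [0, 1] (binning is
a parameter; no binning convention is canonical). The Jensen–Shannon
divergence uses base-2 logarithms so its range is exactly [0, 1]. The
permutation test pools both groups, reshuffles labels at the original
group sizes, and reports p as the proportion of permuted divergences
*strictly greater* than observed, with no +1 correction — this estimator
cannot produce p-values below 1/n_perm, so the result carries that floor
(`p_floor`) explicitly and a reported p of 0 means p < 1/n_perm. In the
fully degenerate case (all pooled values identical) every permuted
divergence ties the observed 0 and the strict convention yields p = 0;
the floor disambiguates it. Permutations are vectorized (one-hot bin
matrix × permuted label blocks), making 10⁵ permutations cheap.

## TMB

TMB = somatic mutations / (callable bases / 10⁶), per sample, counting
only rollup-somatic calls. Samples with < 11,143 callable bases are
excluded from TMB reporting; the boundary is inclusive at 11,143.

## Hotspots

Mutations at different nucleotide offsets of the same codon, and different
substitution types (synonymous included), pool into one codon-level
candidate; a sample counts once per codon however many calls hit it.
Candidates need ≥ 4 carrier samples *before* testing. The background model
is deliberately simple: under the null a gene's n sample-codon events fall
uniformly over its L codons, so a codon carried by k samples scores
p = P(X ≥ k), X ~ Binomial(n, 1/L), BH-corrected across candidates. This
stand-in ignores trinucleotide context and per-position mutability that
richer positional models use; with panel-scale gene counts it is
well-powered for the concentrated hotspots it is meant to flag, and the
uniform-null false-positive rate is verified by simulation in the test
suite. Cross-species status maps the canine codon through the per-gene
codon map (identity for KRAS/NRAS, +12 for BRAF, −5 for FBXW7, or an
alignment-derived codon-pair table) and looks it up in a human hotspot
list: `shared`, `canine_specific`, or `unmapped` when no map exists.

## Enrichment and exclusivity

Each (feature, group) test is a two-sided Fisher exact test on the 2×2
table of mutated × in-group sample counts. Two-sidedness follows the
minimum-likelihood convention (sum over tables with probability ≤
observed); ties at the observed probability are included, matching
exhaustive enumeration. Sample odds ratios use Haldane's 0.5 correction
only when a cell is zero; a zero margin is reported as p = 1 / OR = 1 with
a degeneracy flag rather than an error. One BH family spans all tests of a
scan invocation. Scores are −log10(adjusted p), signed by the direction of
association. Features require > 5 mutated dogs and tumor-type/breed groups
> 20 samples (strict inequalities); supertypes, age bins ({<7, 7–10, >10}
years) and weight quartiles are always tested; mixed-breed dogs form their
own breed group. Pairwise co-occurrence/mutual-exclusivity uses the same
Fisher machinery on the both/only-A/only-B/neither table within a sample
subset (e.g. splenic hemangiosarcoma).

## Synthetic cohorts

The generator is the package's study-conditions definition, not a fixture:

- **Scale**: 300 dogs, ~60 heterozygous + ~30 homozygous germline and ~3
  somatic calls per sample (~28k calls) — a desk-scale rendering of a
  671-dog clinical cohort whose call set was ~97% germline.
- **Depths**: negative binomial around 500× (shape 10); alt counts are
  Binomial(depth, VAF), so observed VAFs carry realistic sampling noise.
- **Latent VAFs**: Beta models — heterozygous mean 0.5 (sd 0.05),
  homozygous mean 0.97 (sd 0.02), somatic Beta(1.2, 1.2) scaled to
  [0.05, 0.95].
- **Sharing**: germline sites get a population allele frequency from
  Beta(0.3, 0.3); carriers are drawn per dog, producing both private and
  highly recurrent germline variants. Zygosity is a site-level property
  (each site is a het-site or a hom-site), so each site's carrier VAF
  sample forms a single cluster — the structure the VAF branch assumes.
- **Spectra**: somatic substitutions are 55% C>T (G>A) versus a flatter
  germline spectrum, over the 6 pyrimidine-collapsed classes.
- **Hotspots**: planted with tumor-type-specific carrier probabilities
  (defaults: a V588E-like BRAF hotspot concentrated in urothelial
  carcinoma, PIK3CA H1047R and NRAS Q61R in hemangiosarcoma, ERBB2 V659E
  in pulmonary adenocarcinoma). Hotspot codons are engineered into the
  random panel genome so annotation yields the configured protein change.
- **Resources**: the known-germline database covers 95% of germline sites;
  95% of somatic mutations have a human-database counterpart (planted
  hotspots always do — they model famous human hotspot mutations); codon
  maps carry the per-gene offsets above.
- **QC failures**: 5% of calls get a failing FS, QD or depth annotation.

Truth labels (latent class, hotspot flag, database membership, QC status)
are written to a sidecar table, never into the VCFs. Somatic positions
never collide with germline sites or planted hotspots, so each unique
variant key has a single latent class.

What the generator does *not* emulate: tumor purity and copy number (the
somatic VAF model absorbs purity implicitly), FFPE artifacts, mapping or
caller error modes beyond the FS/QD/depth flags, indel realignment
ambiguity, trinucleotide context, linkage between germline sites, and
breed population structure. Passing recovery tests therefore demonstrates
that the pipeline's decision rules recover the assumed statistical
structure — not that the rules are robust to every artifact of real FFPE
panel data.

## Numerical choices and degenerate inputs

- Percent reporting uses round-half-up at the printed precision.
- Multi-allelic VCF records split into one call per ALT; per-sample
  duplicate keys collapse keeping the max-depth record (logged).
- VCF positions are 1-based; internal CDS offsets 0-based, conversion
  localized in the annotator. Reverse-strand annotation complements
  alleles before codon lookup and is checked against a whole-CDS
  re-translation oracle.
- Indel protein changes use coordinate style (`1038_1040del`); net length
  divisible by 3 → in-frame, else frameshift; stop-gain SNVs → truncation.
- Empty pipeline input yields empty outputs with zero counts; an empty
  permutation group or n_perm < 1 is an error; a transcript model with
  overlapping CDS intervals is rejected at construction.

## Known limitations

- The VAF-branch thresholds are an explicit stand-in for a visual
  "clustered" judgement; mutations with heavily skewed but tight VAF
  samples near the window edges are sensitive to δ and w.
- The binomial hotspot background underestimates p-value inflation in
  genes with strong positional mutability structure.
- The rare-branch rescue inherits the human database's ascertainment bias:
  canine-specific somatic mutations without human counterparts land in
  *unclassifiable*, so somatic recall against truth is bounded by the
  database coverage.
- Codon-offset maps assume a constant alignment offset over the whole
  gene; genes with internal indels between the species need the explicit
  alignment-derived codon-pair table.
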