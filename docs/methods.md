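# Methods

## The gcHap model

A gene–CDS–haplotype (gcHap) is the equivalence class of varieties whose
coding sequence at a locus is identical. The CDS is reconstructed per
variety by splicing the annotated CDS exons (1-based inclusive GFF3
coordinates), applying that variety's homozygous variant alleles in
ascending genomic position with indel offsets tracked, and
reverse-complementing minus-strand genes into transcript orientation.
The GFF3 phase column is ignored: the haplotype is defined purely by the
exon coordinates. Haplotype labels Hap1, Hap2, … are per-analysis
frequency ranks over the whole panel (ties broken by first-occurrence
variety order); they are not stable global identifiers, so the assignment
TSV is the reconciliation artifact between runs.

Genotypes are treated as inbred-line calls. A heterozygous GT is mapped
to missing by default (`use-first-allele` is available); any variety with
a missing genotype at a CDS site is excluded from that locus with reason
`missing_genotype` rather than imputed — exclusion is conservative and
auditable, and the per-locus exclusion report makes it visible.
Multiallelic records are handled natively and never split.

## Diversity and differentiation

Shannon's evenness of a haplotype frequency vector p is

    E_H = −Σᵢ pᵢ ln pᵢ / ln N,

with N the number of haplotypes observed (pᵢ > 0) **in that population at
that locus**, natural logarithms, 0·ln 0 := 0, and E_H := 0 for a
monomorphic locus. The normalization base is a design choice (the
evenness convention is not uniquely fixed in the literature this index
comes from); normalizing by the locally observed N makes E_H = 0 ⇔
monomorphic and E_H ≤ 1 hold per population. The choice is isolated in
`diversity.shannon_evenness` for easy substitution.

Nei's genetic identity between populations x and y, over the union of
haplotypes (absent haplotype → frequency 0):

    I = Σᵢ xᵢ yᵢ / √(Σᵢ xᵢ² · Σᵢ yᵢ²)  ∈ [0, 1].

The 0.35 cutoff for "strong differentiation" is a reporting flag, not a
hypothesis test. Major gcHaps are those with frequency ≥ 1 % in the set
of varieties under analysis (threshold configurable).

## Breeding-signature tests

For a landrace group A and modern group B at one locus:

- **ΔE_H Z test.** There is no closed-form variance for the evenness of
  haplotype counts, so SE(E_H) per group comes from a seeded multinomial
  bootstrap of varieties within the group (default 1000 resamples);
  Z = ΔE_H / √(SE_A² + SE_B²), two-sided normal p, stars ** p<0.01,
  * p<0.05. A Hutcheson-style delta-method variance is provided as a
  cross-check. Groups below 10 varieties report Z as undefined. The test
  acts on E_H (the diversity statement), while frequency drift is handled
  separately:
- **F(P) drift.** Pearson chi-square on the 2×2 carriers/non-carriers
  table of group A's dominant haplotype, df = 1, no continuity
  correction; undefined (flagged NaN) when a margin is zero.
- **New gcHaps** are counted on raw presence (≥1 carrier in B, none in
  A), not major status. The artificial-selection label is `up`/`down`
  by the sign of ΔE_H (`none` at exactly 0).

Calibration: under a null in which one 5-haplotype population
(frequencies 0.5/0.25/0.15/0.07/0.03) is randomly split into two groups
of 200, the Z test rejects at α = 0.05 in ≈ 4–5 % of 500 splits
(slightly conservative, as bootstrap SEs on a bounded statistic tend to
be).

## Trait association

One-way fixed-effects ANOVA of a trait across major gcHaps with ≥ 5
phenotyped carriers (smaller groups are dropped and recorded), followed
by Tukey HSD on all pairs. The compact letter display is built from the
maximal cliques of the graph joining non-significant pairs, lettered in
order of descending group mean — for the ≤ 10-group cases arising here
this is exact: two haplotypes share a letter if and only if their Tukey
adjusted p ≥ α. Associations with p < 10⁻⁷ are flagged "very
significant". No multiple-testing correction enters the flags (a
Bonferroni column is emitted for transparency only). Duncan-style
multiple range testing is deliberately not implemented; one-way ANOVA +
Tukey is the method of record here.

The favorable haplotype of a locus is its most frequent major gcHap, the
unfavorable one the lowest-frequency major gcHap (ties broken by rank,
resolved away from the favorable pick so the pair is always distinct);
their per-trait contrast is a Welch two-sample test with pairwise
deletion of missing values. Per trait, the *trait-favorable* haplotype
is the analysed major gcHap with the best mean in an explicit direction
map (higher-is-better for TGW, GL, GW, PL, CN by default; other traits
require an explicit direction).

## Haplotype networks

Pairwise haplotype distance is the count of differing aligned positions,
with a maximal run of gap columns counting as a single step (one indel
event; per-position counting is available). Unequal-length haplotypes —
only possible when an indel haplotype exists — are pairwise globally
aligned first. The network is the **minimum spanning network**: an edge
(u, v, w) is retained exactly when w ≤ minimax(u, v) + ε, where
minimax(u, v) is the largest edge weight on the MST path between u and v
(the weight at which the two components first merge in a Kruskal sweep).
For ε = 0 and distinct distances the MSN is exactly the MST; ties retain
all equal-cost alternatives. Median-joining inference of unobserved
intermediate haplotypes is out of scope.

## NG86 Ka/Ks

Synonymous/non-synonymous site counts per codon are the per-position
fractions of single-base changes preserving the amino acid, with changes
to stop codons excluded from the denominators; site totals are averaged
between the two sequences. Differences at multi-substitution codons are
averaged over all minimal pathways, discarding pathways through stop
codons (if every pathway is blocked — effectively unreachable in real
CDS data — all changes count as non-synonymous). Jukes–Cantor
correction Ks = −¾ ln(1 − 4pS/3) (Ka analogous) is flagged undefined at
the 0.75 singularity; Ka/Ks is undefined when Ks = 0. The estimator
choice (NG86 + JC) is one of several in common use and is isolated so
ML-style estimators could be added; exact published values from other
tools are therefore estimator-dependent and not targets.

## qPCR (Livak 2^−ΔΔCt)

Technical replicates are averaged to one Ct per biological sample;
ΔCt = Ct_target − Ct_reference within the sample; ΔΔCt subtracts the
mean control ΔCt (the 0 h timepoint of the same condition by default —
whether the control is the same-treatment 0 h or an untreated parallel
is configurable); fold = 2^−ΔΔCt per biological replicate. Stars come
from a Welch test of treated vs control ΔCt on the four-level grid
(**** < 10⁻⁴ … * < 0.05), `nd` with a single replicate; a one-way
ANOVA across timepoints is also emitted. Primer-efficiency (Pfaffl)
correction is out of scope.

## Synthetic panel generator

The generator emulates a 3KRG-like panel at desk scale. Defaults (chosen
once as a realistic miniature and then left alone): five populations —
Xian 200, Geng 150, Aus 100, Bas 75, admix 75 varieties (600 total),
with 60 % landrace / 40 % modern substructure in Xian and Geng and
subpopulation labels in the XI-…/GJ-… style; six genes of 300–900 bp CDS
in 1–3 exons on alternating strands, with 3–10 haplotypes per locus.
Per-population haplotype spectra have one dominant haplotype (0.60–0.95)
and a geometric tail; Aus carries an alternative dominant haplotype at
two loci (creating strong Aus–Xian/Aus–Geng differentiation); modern
varieties drift the dominant haplotype by −0.10 (Xian) / −0.05 (Geng)
toward the second haplotype. Haplotype j > 0 carries a private CDS SNP
(optionally a 3-bp in-frame deletion), so haplotypes are pairwise
distinct by construction. Phenotypes follow
y = μ_trait + population offset + Σ hap effects + N(0, σ_trait), with
trait means/σ set to typical rice magnitudes (e.g. TGW 25 ± 2 g, DTH
95 ± 7 d) and a few planted effects (e.g. +2 g TGW on Gene1's second
haplotype). One `numpy` Generator seeded from the config drives all
sampling in a fixed order (panel → haplotypes → phenotypes), making the
emitted FASTA/GFF3/VCF/TSV fixture set byte-identical across reruns.

What the generator does **not** emulate: coalescent genealogies,
recombination within genes, linkage between genes, genotyping error or
missingness structure, and environment-dependent trait expression.
Passing tests therefore demonstrate correctness of the statistical
machinery under a clean additive model, not robustness to the messiness
of real resequencing panels.

## Numerical and procedural choices

- All coordinates in the data model are 1-based inclusive; conversion to
  Python slicing is confined to the I/O layer and property-tested.
- Output TSVs print floats at 6 significant digits; the reader uses
  round-trip float parsing so written tables reload exactly.
- Frequency-vector validity is enforced at 1e-9; oracle comparisons in
  the tests run at 1e-10–1e-12.
- Dominant-haplotype ties break by haplotype rank; CLD letter order
  follows descending group means.
- Statistical calibration tests use exact binomial intervals (99.9 %)
  for count recovery — a per-cell 3σ normal band is mis-calibrated for
  the sub-5 expected counts of rare haplotypes in small populations.
- Problem sizes in the test and acceptance runs (600-variety panel, 500
  null replicates, 100 power seeds, 200 network oracle cases) are chosen
  as the smallest sizes at which the calibration intervals above are
  meaningful.

## Known limitations

Phased diplotypes and heterozygous material are out of scope (the
het-as-missing policy is only sensible for inbred panels). Promoter/UTR
haplotypes are not built. The bootstrap Z test is approximate for very
small groups or near-monomorphic loci (SE → 0 collapses the statistic);
those cases are reported as undefined rather than forced. GraphML/TSV
export covers network interchange; no interactive visualization is
provided.
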