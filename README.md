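# gchapkit

Population-genetic analysis of **gene–CDS–haplotypes (gcHaps)** in crop
panels, built for the kind of study done on the 3K Rice Genomes panel:
which haplotypes of a gene family segregate across rice populations, how
modern breeding reshaped their frequencies, and which haplotypes carry
favorable effects on agronomic traits.

A gcHap is the haplotype defined by all variant sites inside a gene's
coding sequence: two varieties share a gcHap exactly when their CDS
nucleotide sequences are identical. Starting from a reference FASTA, gene
models (GFF3), per-variety genotypes (VCF), and variety metadata and
phenotype tables (TSV), the package computes:

- **gcHap calling** — per-variety CDS reconstruction (exon splicing,
  strand, SNPs and in-frame indels), collapsing identical sequences into
  frequency-ranked haplotypes Hap1, Hap2, …
- **Diversity** — per locus and population: the haplotype count gcHapN,
  the number of major gcHaps (frequency ≥ 1 %), Shannon's evenness
  `E_H = −Σ pᵢ ln pᵢ / ln N ∈ [0, 1]`, and the dominant haplotype's
  frequency F(P).
- **Differentiation** — Nei's genetic identity between populations,
  `I = Σ xᵢyᵢ / √(Σ xᵢ² · Σ yᵢ²)`, with pairs below 0.35 flagged as
  strongly differentiated.
- **Breeding signatures** — landrace (LAN) vs modern variety (MV)
  contrasts: ΔE_H with a bootstrap Z test, new gcHaps gained under
  breeding, and the 2×2 chi-square drift of the dominant haplotype.
- **Trait association** — one-way ANOVA of each trait across major
  gcHaps with Tukey HSD compact letters, favorable-vs-unfavorable
  haplotype contrasts (Welch tests), and favorable-allele frequency
  profiles per subpopulation.
- **Haplotype networks** — minimum spanning networks whose edges are
  minimum mutation steps (a gap run counts as one step).
- **Molecular evolution & expression** — NG86 Ka/Ks with Jukes–Cantor
  correction, and Livak 2^−ΔΔCt qPCR fold changes with significance
  stars.
- **Synthetic panel generator** — a seeded 3KRG-like simulator
  (populations with LAN/MV substructure, dominant-haplotype spectra,
  LAN→MV drift, additive trait effects) with full ground truth, so every
  stage is testable without any download.

## Worked example

```bash
python examples/03_trait_association.py
```

```
Gene1 x TGW: F = 34.99, p = 4.26e-15 (very significant)
  Hap1: n =  484  mean =  25.36 g  sd = 2.02  letters = b
  Hap2: n =   77  mean =  27.43 g  sd = 1.86  letters = a
  Hap3: n =   39  mean =  25.49 g  sd = 2.24  letters = b
```

The simulator plants a +2 g thousand-grain-weight effect on Gene1's
second haplotype; the ANOVA recovers it (27.43 − 25.36 ≈ 2.1 g), Hap2
gets its own Tukey letter, and the association clears the p < 10⁻⁷
"very significant" bar. The other examples cover simulation + calling,
LAN/MV breeding tables, networks, Ka/Ks and qPCR; each prints a line
explaining its numbers.

The pipeline can also be driven from the shell:

```bash
gchapkit run-all --seed 42 --outdir results/run42
gchapkit kaks --fasta-a a.fa --fasta-b b.fa
```

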