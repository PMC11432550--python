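"""Construction of gene-CDS-haplotypes (gcHaps) from reference + variants.

A gcHap is the haplotype defined by all variant sites falling inside a
gene's coding sequence: two varieties share a gcHap exactly when their CDS
nucleotide sequences are identical.  Varieties with a missing genotype at
any CDS site (including heterozygous calls under the default inbred-line
policy, resolved upstream in :mod:`gchapkit.io`) are excluded from the
locus rather than imputed.

Haplotype labels Hap1, Hap2, ... are per-analysis frequency ranks over the
whole panel, ties broken by first-occurrence variety order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io import GeneModel, VariantRecord, VarietyPanel, MISSING

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GcHapTable:
    """Per-variety haplotype assignment at one locus.

    ``assignments`` maps variety_id -> hap_id for every non-excluded
    variety; ``hap_sequences`` maps hap_id -> CDS sequence (transcript
    orientation); ``excluded`` records (variety_id, reason) pairs.  The
    carriers of all haps plus the excluded varieties partition the panel.
    """

    gene_id: str
    hap_sequences: dict[str, str]
    assignments: dict[str, str]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def carriers(self, hap_id: str) -> list[str]:
        return [v for v, h in self.assignments.items() if h == hap_id]

    def carrier_counts(self) -> dict[str, int]:
        counts = Counter(self.assignments.values())
        return {h: counts.get(h, 0) for h in self.hap_sequences}

    @property
    def hap_ids(self) -> list[str]:
        return list(self.hap_sequences)


@dataclass
class FrequencyVector:
    """Haplotype frequencies over the non-excluded varieties of one subset."""

    population: str
    freqs: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(p < 0 for p in self.freqs.values()):
            raise ValueError("negative frequency")


def build_cds_sequence(
    reference: dict[str, str],
    gene: GeneModel,
    substitutions: list[tuple[int, str, str]] | None = None,
) -> str:
    """CDS sequence of one variety: exons spliced, substitutions applied.

    ``substitutions`` is a list of (pos, ref_allele, alt_allele) with 1-based
    genomic positions; indel alleles change the sequence length.  Exons are
    extracted in genomic order and concatenated; for minus-strand genes the
    concatenation is reverse-complemented into transcript orientation.
    Variants are applied in ascending genomic position with insertion/deletion
    offsets tracked, so several indels within one gene compose correctly.
    """
    substitutions = sorted(substitutions or [], key=lambda s: s[0])
    chrom_seq = reference[gene.chrom]
    seen_pos: set[int] = set()
    covered_until = -1
    for pos, ref, _alt in substitutions:
        if pos in seen_pos or pos <= covered_until:
            raise ValueError(
                f"overlapping variants at position {pos} in {gene.gene_id}"
            )
        seen_pos.add(pos)
        covered_until = pos + len(ref) - 1
        if chrom_seq[pos - 1: pos - 1 + len(ref)].upper() != ref.upper():
            raise ValueError(
                f"variant REF allele at {gene.chrom}:{pos} inconsistent with "
                f"reference base"
            )
    pieces = []
    for start, end in gene.cds_exons:
        exon = chrom_seq[start - 1: end]
        local = []
        cursor = start  # next genomic position not yet emitted
        for pos, ref, alt in substitutions:
            if pos < start or pos > end:
                continue
            if pos + len(ref) - 1 > end:
                raise ValueError(
                    f"variant at {pos} spans the exon boundary of {gene.gene_id}"
                )
            local.append(exon[cursor - start: pos - start])
            local.append(alt)
            cursor = pos + len(ref)
        local.append(exon[cursor - start:])
        pieces.append("".join(local))
    cds = "".join(pieces).upper()
    if gene.strand == "-":
        cds = reverse_complement(cds)
    return cds


def call_gchaps(
    reference: dict[str, str],
    gene: GeneModel,
    variants: list[VariantRecord],
    panel: VarietyPanel,
) -> GcHapTable:
    """Assign every panel variety to a gcHap at one locus.

    Identical CDS sequences collapse to one haplotype.  A variety with a
    missing genotype at any CDS variant is excluded with reason
    "missing_genotype".  Hap numbering is panel-frequency ranked.
    """
    footprint = gene.cds_footprint()
    cds_variants = [
        v for v in variants
        if v.chrom == gene.chrom and any(s <= v.pos <= e for s, e in footprint)
    ]
    sequences: dict[str, str] = {}
    excluded: list[tuple[str, str]] = []
    for variety in panel.variety_ids:
        subs = []
        missing = False
        for var in cds_variants:
            allele = var.genotypes.get(variety, MISSING)
            if allele is MISSING or allele is None:
                missing = True
                break
            if allele == 0:
                continue
            subs.append((var.pos, var.ref_allele, var.alt_alleles[allele - 1]))
        if missing:
            excluded.append((variety, "missing_genotype"))
            continue
        sequences[variety] = build_cds_sequence(reference, gene, subs)
    if not sequences:
        raise ValueError(f"gene {gene.gene_id}: no non-excluded varieties")
    # collapse identical sequences; rank by count desc, then first occurrence
    first_seen: dict[str, int] = {}
    counts: Counter = Counter()
    for i, (_, seq) in enumerate(sequences.items()):
        counts[seq] += 1
        first_seen.setdefault(seq, i)
    ranked = sorted(counts, key=lambda s: (-counts[s], first_seen[s]))
    hap_of_seq = {seq: f"Hap{i + 1}" for i, seq in enumerate(ranked)}
    return GcHapTable(
        gene_id=gene.gene_id,
        hap_sequences={hap_of_seq[s]: s for s in ranked},
        assignments={v: hap_of_seq[s] for v, s in sequences.items()},
        excluded=excluded,
    )


def frequency_vector(
    table: GcHapTable,
    subset: list[str],
    population: str = "",
) -> FrequencyVector:
    """Haplotype frequencies over the non-excluded varieties of ``subset``."""
    members = [v for v in subset if v in table.assignments]
    if not members:
        raise ValueError(f"empty subset after exclusions at {table.gene_id}")
    counts = Counter(table.assignments[v] for v in members)
    n = len(members)
    ordered = sorted(counts, key=lambda h: table.hap_ids.index(h))
    return FrequencyVector(
        population=population,
        freqs={h: counts[h] / n for h in ordered},
        counts={h: counts[h] for h in ordered},
    )


def classify_major_gchaps(
    table: GcHapTable,
    subset: list[str],
    threshold: float = 0.01,
) -> list[str]:
    """Haplotypes with frequency >= threshold in the subset (major gcHaps)."""
    if not 0 < threshold <= 1:
        raise ValueError("major-hap threshold must be in (0, 1]")
    fv = frequency_vector(table, subset)
    return [h for h, p in fv.freqs.items() if p >= threshold]


def assignment_frame(table: GcHapTable):
    """Long-format assignment table (variety_id, gene_id, hap_id)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"variety_id": v, "gene_id": table.gene_id, "hap_id": h}
            for v, h in table.assignments.items()
        ]
    )


def table_from_assignments(gene_id: str, assignments: dict[str, str],
                           hap_sequences: dict[str, str] | None = None) -> GcHapTable:
    """Build a GcHapTable from a pre-computed assignment map.

    Entry point for externally supplied assignment tables (e.g. the
    RFGB-style TSV of variety_id, gene_id, hap_id) that bypass calling.
    Sequences are optional placeholders in that path.
    """
    haps = sorted(set(assignments.values()),
                  key=lambda h: (-Counter(assignments.values())[h], h))
    seqs = hap_sequences or {h: "" for h in haps}
    return GcHapTable(gene_id=gene_id, hap_sequences={h: seqs.get(h, "") for h in haps},
                      assignments=dict(assignments))
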