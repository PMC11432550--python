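"""Input parsing and the pipeline data model.

Reads the four standard inputs — reference FASTA, gene models from GFF3,
per-variety genotypes from VCF, and TSV metadata/phenotype tables — into
plain dataclasses/DataFrames, and writes all tabular outputs.  All
coordinates in the data model are 1-based inclusive, as in GFF3/VCF;
conversion to Python half-open slicing is confined to this module and to
:func:`gchapkit.calling.build_cds_sequence`.

Genotypes are treated as inbred-line calls: a heterozygous GT is by default
mapped to missing for haplotype purposes (configurable to use the first
allele instead), and "./." or "." is always missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING = None

POPULATIONS = ("Xian", "Geng", "Aus", "Bas", "admix")
IMPROVEMENT = ("LAN", "MV", "other")

#: trait panel: code -> (description, unit)
TRAITS = {
    "DTH": ("days to heading", "day"),
    "PH": ("plant height", "cm"),
    "FLL": ("flag leaf length", "cm"),
    "FLW": ("flag leaf width", "cm"),
    "PN": ("panicle number", "count"),
    "PL": ("panicle length", "cm"),
    "CN": ("culm number", "count"),
    "GL": ("grain length", "mm"),
    "GW": ("grain width", "mm"),
    "GLWR": ("grain length/width ratio", "ratio"),
    "TGW": ("thousand grain weight", "g"),
    "LRI": ("leaf rolling index", "%"),
    "SH": ("seedling height", "cm"),
    "LL": ("ligule length", "mm"),
}


@dataclass
class GeneModel:
    """One transcript's CDS model in 1-based inclusive reference coordinates."""

    gene_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]]
    transcript_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS exons")
        if any(e < s for s, e in exons):
            raise ValueError(f"{self.gene_id}: exon end before start")
        self.cds_exons = exons
        if self.cds_length == 0:
            raise ValueError(f"{self.gene_id}: zero-length CDS")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    def cds_footprint(self) -> list[tuple[int, int]]:
        return list(self.cds_exons)


@dataclass
class VariantRecord:
    """One VCF record restricted to what haplotype calling needs."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    genotypes: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self):
        for v, a in self.genotypes.items():
            if a is not MISSING and not 0 <= a <= len(self.alt_alleles):
                raise ValueError(
                    f"allele index {a} out of bounds at {self.chrom}:{self.pos}"
                )


class VarietyPanel:
    """Variety metadata: population, subpopulation, improvement status."""

    def __init__(self, frame: pd.DataFrame):
        required = {"variety_id", "population", "improvement"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        dup = frame["variety_id"][frame["variety_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate variety_id: {dup.iloc[0]!r}")
        bad = set(frame["population"]) - set(POPULATIONS)
        if bad:
            raise ValueError(f"unknown population label(s): {sorted(bad)}")
        bad = set(frame["improvement"]) - set(IMPROVEMENT)
        if bad:
            raise ValueError(f"unknown improvement label(s): {sorted(bad)}")
        if "subpopulation" not in frame.columns:
            frame = frame.assign(subpopulation="")
        self.frame = frame.reset_index(drop=True)

    @property
    def variety_ids(self) -> list[str]:
        return list(self.frame["variety_id"])

    def __len__(self) -> int:
        return len(self.frame)

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.frame["population"]))

    def subpopulations(self) -> list[str]:
        return list(dict.fromkeys(self.frame["subpopulation"]))

    def members(
        self,
        population: str | None = None,
        improvement: str | None = None,
        subpopulation: str | None = None,
    ) -> list[str]:
        f = self.frame
        mask = pd.Series(True, index=f.index)
        if population is not None:
            mask &= f["population"] == population
        if improvement is not None:
            mask &= f["improvement"] == improvement
        if subpopulation is not None:
            mask &= f["subpopulation"] == subpopulation
        return list(f.loc[mask, "variety_id"])


class PhenotypeTable:
    """Per-variety trait values; NaN marks missing measurements."""

    def __init__(self, frame: pd.DataFrame, trait_codes=None):
        codes = tuple(trait_codes or TRAITS)
        unknown = set(frame.columns) - set(codes) - {"variety_id"}
        if unknown:
            raise ValueError(f"unknown trait code(s): {sorted(unknown)}")
        if "variety_id" in frame.columns:
            frame = frame.set_index("variety_id")
        self.frame = frame.astype(float)
        self.trait_codes = [c for c in codes if c in frame.columns]

    def values(self, trait: str, varieties: list[str]) -> pd.Series:
        if trait not in self.frame.columns:
            raise ValueError(f"unknown trait code: {trait!r}")
        present = [v for v in varieties if v in self.frame.index]
        return self.frame.loc[present, trait].dropna()


def load_reference_and_annotation(
    fasta_path, gff3_path, genes: list[str] | None = None
) -> tuple[dict[str, str], list[GeneModel]]:
    """Load reference sequences and per-transcript CDS gene models.

    CDS features are grouped per transcript via their ``Parent`` attribute;
    the transcript's parent gene supplies ``gene_id``.  If ``genes`` is
    given, any listed gene without CDS features raises an error naming it.
    """
    import gffutils

    reference = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    by_transcript: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        for parent in cds.attributes.get("Parent", [cds.id]):
            by_transcript.setdefault(parent, []).append(cds)
    models = []
    for tid, cds_list in by_transcript.items():
        try:
            parent_gene = next(db.parents(tid, featuretype="gene")).id
        except (StopIteration, gffutils.FeatureNotFoundError):
            parent_gene = tid
        chrom = cds_list[0].seqid
        if chrom not in reference:
            raise ValueError(
                f"chromosome {chrom!r} in GFF3 absent from FASTA"
            )
        models.append(
            GeneModel(
                gene_id=parent_gene,
                chrom=chrom,
                strand=cds_list[0].strand,
                cds_exons=[(c.start, c.end) for c in cds_list],
                transcript_id=tid,
            )
        )
    if genes is not None:
        have = {m.gene_id for m in models}
        for g in genes:
            if g not in have:
                raise ValueError(f"no CDS features found for gene {g!r}")
        models = [m for m in models if m.gene_id in genes]
    return reference, models


def load_variants(
    vcf_path,
    region: tuple[str, int, int] | None = None,
    panel: VarietyPanel | None = None,
    het_policy: str = "as-missing",
) -> list[VariantRecord]:
    """Read VCF genotypes as per-variety allele indices.

    ``region`` is (chrom, start, end) 1-based inclusive; records outside it
    are dropped.  Missing calls map to the missing marker; heterozygous
    calls follow ``het_policy`` ("as-missing" or "use-first-allele").
    Multiallelic records are preserved, not split.
    """
    import pysam

    if het_policy not in ("as-missing", "use-first-allele"):
        raise ValueError(f"unknown het policy {het_policy!r}")
    records = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        if panel is not None:
            diff = set(samples) ^ set(panel.variety_ids)
            if diff:
                raise ValueError(
                    f"VCF samples and panel disagree; symmetric difference: "
                    f"{sorted(diff)}"
                )
        if region is not None and region[0] not in vcf.header.contigs:
            logger.warning(
                "chromosome %s absent from VCF header; returning no records",
                region[0],
            )
            return []
        for rec in vcf:
            if region is not None:
                chrom, start, end = region
                if rec.chrom != chrom or not start <= rec.pos <= end:
                    continue
            genotypes: dict[str, int | None] = {}
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None:
                    raise ValueError(f"malformed GT at {rec.chrom}:{rec.pos}")
                alleles = [a for a in gt if a is not None]
                if not alleles:
                    genotypes[sample] = MISSING
                elif len(set(alleles)) > 1:
                    genotypes[sample] = (
                        alleles[0] if het_policy == "use-first-allele" else MISSING
                    )
                else:
                    genotypes[sample] = alleles[0]
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=list(rec.alts or ()),
                    genotypes=genotypes,
                )
            )
    return records


def load_panel_tables(
    metadata_path, phenotype_path=None
) -> tuple[VarietyPanel, PhenotypeTable | None]:
    """Load metadata and (optionally) phenotype TSVs joined on variety_id.

    Varieties present in the phenotype table but absent from the metadata
    are rejected and reported via a warning.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    panel = VarietyPanel(meta)
    if phenotype_path is None:
        return panel, None
    pheno = pd.read_csv(phenotype_path, sep="\t", na_values=["NA", "."])
    pheno["variety_id"] = pheno["variety_id"].astype(str)
    orphans = set(pheno["variety_id"]) - set(panel.variety_ids)
    if orphans:
        logger.warning(
            "%d phenotype rows without panel metadata rejected: %s",
            len(orphans), sorted(orphans)[:10],
        )
        pheno = pheno[~pheno["variety_id"].isin(orphans)]
    return panel, PhenotypeTable(pheno)


def load_assignment_tsv(path) -> dict[str, dict[str, str]]:
    """RFGB-style assignment TSV (variety_id, gene_id, hap_id) -> per-gene maps."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, dict[str, str]] = {}
    for gene, sub in frame.groupby("gene_id"):
        out[gene] = dict(zip(sub["variety_id"], sub["hap_id"]))
    return out


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> Path:
    """Write an output table as TSV with floats at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
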