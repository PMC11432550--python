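"""Synthetic rice-panel generator with known ground truth.

Emulates the structure of a 3K-Rice-Genomes-style panel at desk scale:
a handful of populations (Xian, Geng, Aus, Bas, admix) with landrace (LAN)
and modern-variety (MV) substructure, per-locus haplotype frequency
spectra with one dominant haplotype, a configurable LAN->MV frequency
drift, and additive haplotype effects on agronomic traits with Gaussian
noise.  Everything downstream (haplotype calling, diversity, breeding
signatures, associations, networks) can then be tested against the planted
truth without any download.

A single pseudo-random stream seeded from the config drives all sampling,
consumed in a documented order (panel -> haplotypes -> phenotypes), so the
emitted fixture set is byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    TRAITS, GeneModel, PhenotypeTable, VariantRecord, VarietyPanel,
)

_DNA = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PopulationSpec:
    name: str
    n_varieties: int
    lan_fraction: float = 0.0
    mv_fraction: float = 0.0
    subpopulations: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_varieties < 1:
            raise ValueError(f"{self.name}: n_varieties must be >= 1")
        for frac in (self.lan_fraction, self.mv_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"{self.name}: improvement fractions must be in [0, 1]"
                )
        if self.lan_fraction + self.mv_fraction > 1.0 + 1e-9:
            raise ValueError(f"{self.name}: LAN + MV fractions exceed 1")


@dataclass
class GeneSpec:
    gene_id: str
    n_cds_exons: int
    cds_length: int
    n_haplotypes: int
    strand: str = "+"
    indel_hap: bool = False

    def __post_init__(self):
        if self.cds_length % 3:
            raise ValueError(f"{self.gene_id}: CDS length must be divisible by 3")
        if self.n_haplotypes < 1:
            raise ValueError(f"{self.gene_id}: n_haplotypes must be >= 1")
        if self.n_haplotypes - 1 > self.cds_length:
            raise ValueError(
                f"{self.gene_id}: more haplotypes requested than "
                f"distinguishable CDS sites available"
            )


@dataclass
class SimulationConfig:
    seed: int
    populations: list[PopulationSpec]
    genes: list[GeneSpec]
    #: gene_id -> population -> base (LAN) haplotype frequencies, sum 1
    hap_freqs: dict[str, dict[str, list[float]]]
    #: gene_id -> population -> additive MV drift per haplotype, sum 0
    mv_drift: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    #: (gene_id, hap_index, trait) -> additive effect on the trait
    trait_effects: dict[tuple[str, int, str], float] = field(default_factory=dict)
    trait_means: dict[str, float] = field(default_factory=dict)
    trait_sd: dict[str, float] = field(default_factory=dict)
    #: population -> trait -> additive offset
    pop_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    traits: list[str] = field(default_factory=lambda: list(TRAITS))

    def __post_init__(self):
        for gene in self.genes:
            for pop in self.populations:
                freqs = np.asarray(self.hap_freqs[gene.gene_id][pop.name])
                if len(freqs) != gene.n_haplotypes:
                    raise ValueError(
                        f"{gene.gene_id}/{pop.name}: frequency vector length "
                        f"!= n_haplotypes"
                    )
                if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
                    raise ValueError(
                        f"{gene.gene_id}/{pop.name}: frequencies must be "
                        f"non-negative and sum to 1"
                    )
                drift = np.asarray(
                    self.mv_drift.get(gene.gene_id, {}).get(
                        pop.name, [0.0] * gene.n_haplotypes
                    )
                )
                if abs(drift.sum()) > 1e-9:
                    raise ValueError(
                        f"{gene.gene_id}/{pop.name}: MV drift must sum to 0"
                    )
                if ((freqs + drift) < -1e-12).any() or ((freqs + drift) > 1 + 1e-12).any():
                    raise ValueError(
                        f"{gene.gene_id}/{pop.name}: drifted frequencies "
                        f"leave [0, 1]"
                    )
        for (gene_id, hap_idx, trait), _ in self.trait_effects.items():
            gene = self._gene(gene_id)
            if hap_idx >= gene.n_haplotypes:
                raise ValueError(
                    f"effect references hap index {hap_idx} beyond "
                    f"{gene_id}'s {gene.n_haplotypes} haplotypes"
                )
            if trait not in self.traits:
                raise ValueError(f"unknown trait code in effects: {trait!r}")
        for trait in list(self.trait_means) + list(self.trait_sd):
            if trait not in self.traits:
                raise ValueError(f"unknown trait code: {trait!r}")

    def _gene(self, gene_id: str) -> GeneSpec:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise ValueError(f"unknown gene {gene_id!r} in config")

    def mv_freqs(self, gene_id: str, pop: str) -> np.ndarray:
        gene = self._gene(gene_id)
        base = np.asarray(self.hap_freqs[gene_id][pop], dtype=float)
        drift = np.asarray(
            self.mv_drift.get(gene_id, {}).get(pop, [0.0] * gene.n_haplotypes)
        )
        out = np.clip(base + drift, 0.0, 1.0)
        return out / out.sum()

    def population_freqs(self, gene_id: str, pop_spec: PopulationSpec) -> np.ndarray:
        """Expected haplotype frequencies of a whole population (LAN+MV mix)."""
        base = np.asarray(self.hap_freqs[gene_id][pop_spec.name], dtype=float)
        mv = self.mv_freqs(gene_id, pop_spec.name)
        w_mv = pop_spec.mv_fraction
        return (1.0 - w_mv) * base + w_mv * mv


@dataclass
class GroundTruth:
    """Planted truth of one simulation run."""

    #: gene_id -> variety_id -> simulated haplotype index (0-based)
    assignments: dict[str, dict[str, int]]
    #: gene_id -> hap index -> CDS sequence in transcript orientation
    hap_cds: dict[str, dict[int, str]]
    #: (gene_id, population) -> expected E_H from the configured frequencies
    expected_e_h: dict[tuple[str, str], float]
    #: (gene_id, population) -> expected dominant hap index
    expected_dominant: dict[tuple[str, str], int]
    #: planted additive trait effects, as in the config
    effects: dict[tuple[str, int, str], float]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    panel: VarietyPanel
    reference: dict[str, str]
    gene_models: list[GeneModel]
    variants: list[VariantRecord]
    truth: GroundTruth
    phenotypes: PhenotypeTable


# ---------------------------------------------------------------- defaults

_DEFAULT_MEANS = {
    "DTH": 95.0, "PH": 110.0, "FLL": 30.0, "FLW": 1.5, "PN": 10.0,
    "PL": 23.0, "CN": 9.0, "GL": 8.5, "GW": 2.8, "GLWR": 3.0,
    "TGW": 25.0, "LRI": 20.0, "SH": 20.0, "LL": 15.0,
}
_DEFAULT_SD = {
    "DTH": 7.0, "PH": 8.0, "FLL": 4.0, "FLW": 0.2, "PN": 2.5,
    "PL": 2.0, "CN": 2.0, "GL": 0.5, "GW": 0.2, "GLWR": 0.3,
    "TGW": 2.0, "LRI": 8.0, "SH": 3.0, "LL": 3.0,
}


def _spectrum(n_haps: int, dominant: float, dominant_idx: int = 0) -> list[float]:
    """One dominant haplotype plus a geometric tail over the rest."""
    if n_haps == 1:
        return [1.0]
    tail = np.power(0.6, np.arange(n_haps - 1))
    tail = (1.0 - dominant) * tail / tail.sum()
    freqs = np.concatenate([[dominant], tail])
    if dominant_idx:
        freqs[[0, dominant_idx]] = freqs[[dominant_idx, 0]]
    freqs[-1] += 1.0 - freqs.sum()  # absorb float round-off
    return list(freqs)


def default_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale default: 5 populations / 600 varieties, 6 genes, 3-10 haps.

    Qualitatively mirrors a 3KRG-like panel: a dominant haplotype per locus,
    LAN->MV drift in Xian and Geng, an alternative dominant haplotype in Aus
    at two loci (creating strong between-population differentiation), and a
    few planted haplotype effects on yield traits.
    """
    populations = [
        PopulationSpec("Xian", 200, 0.6, 0.4, ["XI-1A", "XI-1B", "XI-2"]),
        PopulationSpec("Geng", 150, 0.6, 0.4, ["GJ-tmp", "GJ-sbtrp", "GJ-trp"]),
        PopulationSpec("Aus", 100, 1.0, 0.0),
        PopulationSpec("Bas", 75, 1.0, 0.0),
        PopulationSpec("admix", 75, 0.0, 0.0),
    ]
    genes = [
        GeneSpec("Gene1", 1, 300, 3, "+"),
        GeneSpec("Gene2", 2, 450, 4, "-"),
        GeneSpec("Gene3", 1, 300, 5, "+"),
        GeneSpec("Gene4", 3, 600, 6, "-"),
        GeneSpec("Gene5", 2, 900, 8, "+"),
        GeneSpec("Gene6", 1, 300, 10, "-"),
    ]
    hap_freqs: dict[str, dict[str, list[float]]] = {}
    mv_drift: dict[str, dict[str, list[float]]] = {}
    for i, gene in enumerate(genes):
        d = 0.85 - 0.05 * i
        per_pop = {
            "Xian": _spectrum(gene.n_haplotypes, d),
            "Geng": _spectrum(gene.n_haplotypes, min(d + 0.05, 0.95)),
            "Aus": _spectrum(gene.n_haplotypes, d - 0.05,
                             dominant_idx=1 if i >= 4 else 0),
            "Bas": _spectrum(gene.n_haplotypes, d),
            "admix": _spectrum(gene.n_haplotypes, max(d - 0.15, 0.4)),
        }
        hap_freqs[gene.gene_id] = per_pop
        k = gene.n_haplotypes
        drift_x = [0.0] * k
        drift_g = [0.0] * k
        if k >= 2:
            drift_x[0], drift_x[1] = -0.10, 0.10
            drift_g[0], drift_g[1] = -0.05, 0.05
        mv_drift[gene.gene_id] = {"Xian": drift_x, "Geng": drift_g}
    trait_effects = {
        ("Gene1", 1, "TGW"): 2.0,
        ("Gene1", 1, "GL"): 0.4,
        ("Gene2", 1, "PL"): 1.5,
        ("Gene4", 2, "PH"): -6.0,
        ("Gene5", 1, "DTH"): 4.0,
        ("Gene6", 1, "CN"): 1.5,
    }
    pop_offsets = {
        "Geng": {"TGW": 1.0, "DTH": 5.0},
        "Aus": {"DTH": -5.0},
    }
    return SimulationConfig(
        seed=seed,
        populations=populations,
        genes=genes,
        hap_freqs=hap_freqs,
        mv_drift=mv_drift,
        trait_effects=trait_effects,
        trait_means=dict(_DEFAULT_MEANS),
        trait_sd=dict(_DEFAULT_SD),
        pop_offsets=pop_offsets,
    )


# ------------------------------------------------------------- simulation

def simulate_panel(config: SimulationConfig) -> VarietyPanel:
    """Variety metadata table with exact per-population LAN/MV counts."""
    rows = []
    for pop in config.populations:
        n_lan = int(round(pop.n_varieties * pop.lan_fraction))
        n_mv = int(round(pop.n_varieties * pop.mv_fraction))
        if n_lan + n_mv > pop.n_varieties:
            n_mv = pop.n_varieties - n_lan
        for i in range(pop.n_varieties):
            improvement = "LAN" if i < n_lan else (
                "MV" if i < n_lan + n_mv else "other"
            )
            subpop = (
                pop.subpopulations[i % len(pop.subpopulations)]
                if pop.subpopulations else f"{pop.name}-all"
            )
            rows.append({
                "variety_id": f"{pop.name}_{i:04d}",
                "population": pop.name,
                "subpopulation": subpop,
                "improvement": improvement,
            })
    return VarietyPanel(pd.DataFrame(rows))


def _random_chromosome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_DNA, size=length))


def _transcript_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position in the plus-strand CDS splice."""
    off = 0
    for start, end in gene.cds_exons:
        if start <= pos <= end:
            return off + pos - start
        off += end - start + 1
    raise ValueError(f"position {pos} outside the CDS of {gene.gene_id}")


def simulate_gene_haplotypes(
    config: SimulationConfig,
    panel: VarietyPanel,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[GeneModel], list[VariantRecord], GroundTruth]:
    """Reference, gene models, homozygous VCF genotypes and planted truth.

    Haplotype 0 is the reference sequence; haplotype j > 0 carries the ALT
    allele at its private CDS site (a SNP, or a 3-bp in-frame deletion for
    an indel haplotype), so all haplotypes are pairwise distinct.  Varieties
    draw their haplotype from the configured LAN or (drifted) MV frequency
    vector of their population.
    """
    reference: dict[str, str] = {}
    models: list[GeneModel] = []
    variants: list[VariantRecord] = []
    assignments: dict[str, dict[str, int]] = {}
    hap_cds: dict[str, dict[int, str]] = {}
    expected_e_h: dict[tuple[str, str], float] = {}
    expected_dominant: dict[tuple[str, str], int] = {}
    improvement = dict(zip(panel.frame["variety_id"], panel.frame["improvement"]))
    population = dict(zip(panel.frame["variety_id"], panel.frame["population"]))

    for gi, gene in enumerate(config.genes):
        chrom = f"chr{gi + 1}"
        # exon layout: 100 bp flanks, 60 bp introns, CDS split evenly
        exon_len = gene.cds_length // gene.n_cds_exons
        lengths = [exon_len] * gene.n_cds_exons
        lengths[-1] += gene.cds_length - sum(lengths)
        exons = []
        cursor = 101
        for L in lengths:
            exons.append((cursor, cursor + L - 1))
            cursor += L + 60
        chrom_len = cursor + 100
        seq = _random_chromosome(rng, chrom_len)
        reference[chrom] = seq
        model = GeneModel(
            gene_id=gene.gene_id, chrom=chrom, strand=gene.strand,
            cds_exons=exons, transcript_id=f"{gene.gene_id}.1",
        )
        models.append(model)

        # pick one private segregating site per non-reference haplotype;
        # keep a margin inside exons so an indel never crosses a boundary
        candidate_pos = [
            p for s, e in exons for p in range(s + 1, e - 4)
        ]
        k = gene.n_haplotypes
        if k - 1 > len(candidate_pos):
            raise ValueError(
                f"{gene.gene_id}: more haplotypes requested than "
                f"distinguishable sites available"
            )
        sites = sorted(
            int(p) for p in rng.choice(candidate_pos, size=k - 1, replace=False)
        )
        site_alleles: list[tuple[int, str, str]] = []
        for j, pos in enumerate(sites):
            indel = gene.indel_hap and j == 0 and k >= 2
            if indel:
                ref_allele = seq[pos - 1: pos + 3]
                alt_allele = seq[pos - 1]
            else:
                ref_base = seq[pos - 1]
                alt_allele = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                ref_allele = ref_base
            site_alleles.append((pos, ref_allele, alt_allele))

        # truth CDS per haplotype, built by direct string surgery (kept
        # independent of calling.build_cds_sequence on purpose)
        plus_cds = "".join(seq[s - 1: e] for s, e in exons)
        hap_cds[gene.gene_id] = {}
        for j in range(k):
            if j == 0:
                cds = plus_cds
            else:
                pos, ref_allele, alt_allele = site_alleles[j - 1]
                off = _transcript_offset(model, pos)
                cds = plus_cds[:off] + alt_allele + plus_cds[off + len(ref_allele):]
            if gene.strand == "-":
                cds = cds.translate(_COMPLEMENT)[::-1]
            hap_cds[gene.gene_id][j] = cds

        # haplotype sampling per variety
        gene_assign: dict[str, int] = {}
        for pop in config.populations:
            base = np.asarray(config.hap_freqs[gene.gene_id][pop.name])
            mv = config.mv_freqs(gene.gene_id, pop.name)
            members = panel.members(population=pop.name)
            for variety in members:
                freqs = mv if improvement[variety] == "MV" else base
                gene_assign[variety] = int(rng.choice(k, p=freqs))
            mix = config.population_freqs(gene.gene_id, pop)
            from .diversity import shannon_evenness
            expected_e_h[(gene.gene_id, pop.name)] = shannon_evenness(mix)
            expected_dominant[(gene.gene_id, pop.name)] = int(np.argmax(mix))
        assignments[gene.gene_id] = gene_assign

        # one multiallelic-free variant record per site, homozygous calls
        for j, (pos, ref_allele, alt_allele) in enumerate(site_alleles):
            genotypes = {
                v: (1 if gene_assign[v] == j + 1 else 0)
                for v in panel.variety_ids
            }
            variants.append(VariantRecord(
                chrom=chrom, pos=pos, ref_allele=ref_allele,
                alt_alleles=[alt_allele], genotypes=genotypes,
            ))

    truth = GroundTruth(
        assignments=assignments,
        hap_cds=hap_cds,
        expected_e_h=expected_e_h,
        expected_dominant=expected_dominant,
        effects=dict(config.trait_effects),
    )
    _ = population  # population map retained for symmetry; not needed further
    return reference, models, variants, truth


def simulate_phenotypes(
    config: SimulationConfig,
    panel: VarietyPanel,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> PhenotypeTable:
    """Additive trait model: mean + population offset + hap effects + noise."""
    varieties = panel.variety_ids
    population = dict(zip(panel.frame["variety_id"], panel.frame["population"]))
    data = {}
    for trait in config.traits:
        mu = config.trait_means.get(trait, _DEFAULT_MEANS.get(trait, 0.0))
        sd = config.trait_sd.get(trait, _DEFAULT_SD.get(trait, 1.0))
        y = np.full(len(varieties), mu)
        for i, v in enumerate(varieties):
            y[i] += config.pop_offsets.get(population[v], {}).get(trait, 0.0)
            for gene_id, assign in truth.assignments.items():
                eff = config.trait_effects.get((gene_id, assign[v], trait))
                if eff:
                    y[i] += eff
        y = y + rng.normal(0.0, sd, size=len(varieties))
        data[trait] = y
    frame = pd.DataFrame(data, index=pd.Index(varieties, name="variety_id"))
    return PhenotypeTable(frame.reset_index())


def simulate_all(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator with one seeded stream (panel -> haps -> traits)."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config)
    reference, models, variants, truth = simulate_gene_haplotypes(
        config, panel, rng
    )
    phenotypes = simulate_phenotypes(config, panel, truth, rng)
    return SimulatedDataset(
        config=config, panel=panel, reference=reference,
        gene_models=models, variants=variants, truth=truth,
        phenotypes=phenotypes,
    )


# ------------------------------------------------------------- fixture IO

def _write_fasta(reference: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


def _write_gff3(models: list[GeneModel], reference: dict[str, str],
                path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in reference.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for m in models:
            start = min(s for s, _ in m.cds_exons)
            end = max(e for _, e in m.cds_exons)
            fh.write(
                f"{m.chrom}\tgchapkit\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tgchapkit\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for s, e in m.cds_exons:
                fh.write(
                    f"{m.chrom}\tgchapkit\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID=cds:{m.transcript_id};Parent={m.transcript_id}\n"
                )


def _write_vcf(variants: list[VariantRecord], reference: dict[str, str],
               samples: list[str], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in sorted(variants, key=lambda r: (r.chrom, r.pos)):
            gts = []
            for s in samples:
                a = rec.genotypes.get(s)
                gts.append("./." if a is None else f"{a}/{a}")
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref_allele}\t"
                f"{','.join(rec.alt_alleles)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def write_fixture_set(dataset: SimulatedDataset, outdir) -> dict:
    """Write FASTA + GFF3 + VCF + metadata/phenotype TSVs plus a manifest.

    Re-running with the same config/seed produces byte-identical files; the
    manifest lists each path with its sha256 checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fasta",
        "gff3": outdir / "genes.gff3",
        "vcf": outdir / "variants.vcf",
        "metadata": outdir / "panel.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    _write_fasta(dataset.reference, paths["fasta"])
    _write_gff3(dataset.gene_models, dataset.reference, paths["gff3"])
    _write_vcf(dataset.variants, dataset.reference,
               dataset.panel.variety_ids, paths["vcf"])
    dataset.panel.frame.to_csv(paths["metadata"], sep="\t", index=False)
    dataset.phenotypes.frame.reset_index().to_csv(
        paths["phenotypes"], sep="\t", index=False, float_format="%.4f"
    )
    manifest = {"seed": dataset.config.seed, "files": {}}
    for key, p in paths.items():
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest["files"][key] = {"path": p.name, "sha256": digest}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
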