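"""End-to-end orchestration: simulate/load -> call -> diversity ->
differentiation -> breeding -> association -> network, with a checksummed
run manifest.

Every stage writes its documented TSV so stages compose via files, and the
manifest records each output path with a sha256 checksum.  Identical
config + seed gives byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association as assoc
from . import breeding as breed
from . import calling, diversity, network, simulate
from .io import (
    PhenotypeTable, VarietyPanel, load_panel_tables,
    load_reference_and_annotation, load_variants, write_tsv,
)

logger = logging.getLogger(__name__)

#: the four agronomic traits scanned in the main association panel
ASSOCIATION_TRAITS = ["PN", "PL", "PH", "TGW"]


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: simulate.SimulationConfig | None = None
    fasta: str | None = None
    gff3: str | None = None
    vcf: str | None = None
    metadata: str | None = None
    phenotypes: str | None = None
    genes: list[str] | None = None
    major_threshold: float = 0.01
    inei_threshold: float = 0.35
    alpha: float = 0.05
    very_significant: float = 1e-7
    n_boot: int = 1000
    association_traits: list[str] = field(
        default_factory=lambda: list(ASSOCIATION_TRAITS)
    )

    def __post_init__(self):
        if not 0 < self.major_threshold <= 1:
            raise ValueError("major-hap threshold must be in (0, 1]")
        if not 0 <= self.inei_threshold <= 1:
            raise ValueError("I_Nei threshold must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_boot < 200:
            raise ValueError("n_boot must be >= 200")
        if self.simulate is None and not (
            self.fasta and self.gff3 and self.vcf and self.metadata
        ):
            raise ValueError(
                "config needs either a simulate block or the four input paths"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log: dict = {"seed": config.seed, "thresholds": {
        "major_hap": config.major_threshold,
        "I_Nei": config.inei_threshold,
        "alpha": config.alpha,
        "very_significant": config.very_significant,
    }, "stages": []}
    stage = "inputs"
    try:
        if config.simulate is not None:
            dataset = simulate.simulate_all(config.simulate)
            fixture_manifest = simulate.write_fixture_set(
                dataset, outdir / "fixtures"
            )
            for key, meta in fixture_manifest["files"].items():
                outputs[f"fixture_{key}"] = outdir / "fixtures" / meta["path"]
            panel, phenotypes = dataset.panel, dataset.phenotypes
            reference, models = dataset.reference, dataset.gene_models
            variants = dataset.variants
        else:
            reference, models = load_reference_and_annotation(
                config.fasta, config.gff3, genes=config.genes
            )
            panel, phenotypes = load_panel_tables(
                config.metadata, config.phenotypes
            )
            variants = load_variants(config.vcf, panel=panel)
        if config.genes:
            models = [m for m in models if m.gene_id in config.genes]
        log["stages"].append(stage)

        stage = "call"
        tables: dict[str, calling.GcHapTable] = {}
        assign_frames = []
        for model in models:
            table = calling.call_gchaps(reference, model, variants, panel)
            tables[model.gene_id] = table
            assign_frames.append(calling.assignment_frame(table))
            log.setdefault("exclusions", {})[model.gene_id] = len(table.excluded)
        outputs["assignments"] = write_tsv(
            pd.concat(assign_frames, ignore_index=True),
            outdir / "gchap_assignments.tsv",
        )
        log["stages"].append(stage)

        stage = "diversity"
        records = []
        for table in tables.values():
            records.extend(diversity.diversity_summary(
                table, panel, major_threshold=config.major_threshold
            ))
        outputs["diversity"] = write_tsv(
            diversity.diversity_table(records), outdir / "diversity.tsv"
        )
        log["stages"].append(stage)

        stage = "differentiation"
        rows = []
        for table in tables.values():
            try:
                diff = diversity.pairwise_differentiation(
                    table, panel, threshold=config.inei_threshold
                )
            except ValueError as exc:
                logger.warning("differentiation skipped: %s", exc)
                continue
            for i, a in enumerate(diff.populations):
                for b in diff.populations[i + 1:]:
                    rows.append({
                        "gene_id": table.gene_id, "pop_a": a, "pop_b": b,
                        "I_Nei": diff.identity.loc[a, b],
                        "differentiated": (a, b) in diff.flagged,
                    })
        outputs["differentiation"] = write_tsv(
            pd.DataFrame(rows), outdir / "differentiation.tsv"
        )
        log["stages"].append(stage)

        stage = "breeding"
        comparisons = []
        for pop in panel.populations():
            lan = panel.members(population=pop, improvement="LAN")
            mv = panel.members(population=pop, improvement="MV")
            if len(lan) < breed.MIN_GROUP_SIZE or len(mv) < breed.MIN_GROUP_SIZE:
                continue
            for gi, table in enumerate(tables.values()):
                comparisons.append(breed.compare_groups(
                    table, lan, mv,
                    label_a=f"LANs-{pop}", label_b=f"MVs-{pop}",
                    n_boot=config.n_boot, seed=config.seed + gi,
                ))
        outputs["breeding"] = write_tsv(
            breed.breeding_table(comparisons), outdir / "breeding.tsv"
        )
        log["stages"].append(stage)

        stage = "association"
        if phenotypes is None:
            logger.warning("no phenotype table; association stage skipped")
            log["stages"].append(f"{stage} (skipped: no phenotypes)")
        else:
            results = []
            for table in tables.values():
                for trait in config.association_traits:
                    try:
                        results.append(assoc.gchap_trait_anova(
                            table, phenotypes, trait,
                            major_threshold=config.major_threshold,
                            alpha=config.alpha,
                        ))
                    except ValueError as exc:
                        logger.warning("association skipped: %s", exc)
            outputs["association"] = write_tsv(
                assoc.association_table(results), outdir / "association.tsv"
            )
            contrast_rows = []
            for table in tables.values():
                try:
                    pair = assoc.label_favorable_unfavorable(
                        table, list(table.assignments), config.major_threshold
                    )
                except ValueError as exc:
                    logger.warning("contrast skipped: %s", exc)
                    continue
                assoc.contrast_traits(
                    pair, table, phenotypes, alpha=config.alpha
                )
                for trait, c in pair.contrasts.items():
                    contrast_rows.append({
                        "gene_id": pair.gene_id,
                        "favorable": pair.favorable_hap,
                        "unfavorable": pair.unfavorable_hap,
                        "trait": trait,
                        "difference": c.difference,
                        "p": c.pvalue,
                        "significant": c.significant,
                        "status": c.status,
                    })
            outputs["contrasts"] = write_tsv(
                pd.DataFrame(contrast_rows), outdir / "contrasts.tsv"
            )
            fav_frames = []
            for r in results:
                direction = assoc.DEFAULT_DIRECTIONS.get(r.trait)
                if direction:
                    fav_frames.append(assoc.favorable_allele_frequencies(
                        tables[r.gene_id], panel, r, direction
                    ))
            if fav_frames:
                outputs["favorable_frequencies"] = write_tsv(
                    pd.concat(fav_frames, ignore_index=True),
                    outdir / "favorable_frequencies.tsv",
                )
            log["stages"].append(stage)

        stage = "network"
        for gene_id, table in tables.items():
            net = network.hap_network(table, panel)
            outputs[f"network_{gene_id}_graphml"] = network.export_network(
                net, outdir / f"network_{gene_id}.graphml", "graphml"
            )
            outputs[f"network_{gene_id}_edges"] = network.export_network(
                net, outdir / f"network_{gene_id}_edges.tsv", "edgelist"
            )
        log["stages"].append(stage)
    except Exception as exc:
        partial = {
            "log": log,
            "error": f"stage {stage}: {exc}",
            "files": {k: {"path": str(p), "sha256": _sha256(p)}
                      for k, p in outputs.items() if p.exists()},
        }
        with open(outdir / "manifest.json.partial", "w") as fh:
            json.dump(partial, fh, indent=2, sort_keys=True)
        raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest = {
        "log": log,
        "files": {
            k: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for k, p in outputs.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
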