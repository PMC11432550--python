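import numpy as np
import pandas as pd
import pytest

from gchapkit import simulate as sim
from gchapkit.calling import GcHapTable
from gchapkit.io import PhenotypeTable, VarietyPanel


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded run of the default desk-scale simulation, shared per session."""
    return sim.simulate_all(sim.default_config(11))


@pytest.fixture(scope="session")
def fixture_dir(default_dataset, tmp_path_factory):
    """The default dataset written out as FASTA/GFF3/VCF/TSV files."""
    outdir = tmp_path_factory.mktemp("fixtures")
    sim.write_fixture_set(default_dataset, outdir)
    return outdir


@pytest.fixture
def toy_reference():
    return {"chr1": "ATGAAATTTCCC"}


@pytest.fixture
def toy_gene():
    from gchapkit.io import GeneModel

    return GeneModel(
        gene_id="toy", chrom="chr1", strand="+",
        cds_exons=[(1, 6), (10, 12)], transcript_id="toy.1",
    )


def make_table(gene_id: str, counts: dict[str, int],
               sequences: dict[str, str] | None = None) -> GcHapTable:
    """GcHapTable with synthetic varieties v0, v1, ... carrying given haps."""
    assignments = {}
    i = 0
    for hap, n in counts.items():
        for _ in range(n):
            assignments[f"v{i}"] = hap
            i += 1
    seqs = sequences or {h: "A" * (3 * (k + 1)) for k, h in enumerate(counts)}
    return GcHapTable(gene_id=gene_id, hap_sequences=seqs,
                      assignments=assignments)


def make_panel(n: int, population: str = "Xian") -> VarietyPanel:
    return VarietyPanel(pd.DataFrame({
        "variety_id": [f"v{i}" for i in range(n)],
        "population": [population] * n,
        "subpopulation": [""] * n,
        "improvement": ["LAN"] * n,
    }))


def make_phenotypes(values: dict[str, dict[str, float]]) -> PhenotypeTable:
    """values: trait -> variety_id -> value."""
    frame = pd.DataFrame(values)
    frame.index.name = "variety_id"
    return PhenotypeTable(frame.reset_index())
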