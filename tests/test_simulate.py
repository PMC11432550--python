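import hashlib
import itertools

import numpy as np
import pytest
from scipy import stats

from gchapkit import simulate as sim
from gchapkit.calling import call_gchaps


def small_config(seed=0, **overrides):
    cfg = sim.SimulationConfig(
        seed=seed,
        populations=[sim.PopulationSpec("Xian", 100, 0.7, 0.3)],
        genes=[sim.GeneSpec("GeneA", 1, 300, 2)],
        hap_freqs={"GeneA": {"Xian": [0.9, 0.1]}},
        **overrides,
    )
    return cfg


class TestPanel:
    def test_exact_improvement_counts(self):
        panel = sim.simulate_panel(small_config(1))
        assert len(panel.members(population="Xian", improvement="LAN")) == 70
        assert len(panel.members(population="Xian", improvement="MV")) == 30

    def test_deterministic_given_seed(self):
        p1 = sim.simulate_panel(small_config(1))
        p2 = sim.simulate_panel(small_config(1))
        assert p1.frame.equals(p2.frame)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            sim.PopulationSpec("Xian", 100, 1.2, 0.0)

    def test_invalid_frequency_vector_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sim.SimulationConfig(
                seed=0,
                populations=[sim.PopulationSpec("Xian", 10, 1.0, 0.0)],
                genes=[sim.GeneSpec("GeneA", 1, 300, 2)],
                hap_freqs={"GeneA": {"Xian": [0.9, 0.2]}},
            )

    def test_drift_must_sum_to_zero(self):
        with pytest.raises(ValueError, match="drift"):
            sim.SimulationConfig(
                seed=0,
                populations=[sim.PopulationSpec("Xian", 10, 1.0, 0.0)],
                genes=[sim.GeneSpec("GeneA", 1, 300, 2)],
                hap_freqs={"GeneA": {"Xian": [0.9, 0.1]}},
                mv_drift={"GeneA": {"Xian": [0.1, 0.1]}},
            )


class TestHaplotypes:
    def test_haplotypes_pairwise_distinct(self, default_dataset):
        for gene_id, haps in default_dataset.truth.hap_cds.items():
            for a, b in itertools.combinations(haps.values(), 2):
                assert sum(x != y for x, y in zip(a, b)) >= 1

    def test_dominant_frequency_within_binomial_interval(self):
        cfg = sim.SimulationConfig(
            seed=5,
            populations=[sim.PopulationSpec("Xian", 2000, 1.0, 0.0)],
            genes=[sim.GeneSpec("GeneA", 1, 300, 2)],
            hap_freqs={"GeneA": {"Xian": [0.9, 0.1]}},
        )
        ds = sim.simulate_all(cfg)
        assign = ds.truth.assignments["GeneA"]
        observed = sum(1 for h in assign.values() if h == 0)
        lo, hi = stats.binom.interval(0.99, 2000, 0.9)
        assert lo <= observed <= hi

    def test_single_haplotype_emits_no_variants(self):
        cfg = sim.SimulationConfig(
            seed=0,
            populations=[sim.PopulationSpec("Xian", 10, 1.0, 0.0)],
            genes=[sim.GeneSpec("GeneA", 1, 300, 1)],
            hap_freqs={"GeneA": {"Xian": [1.0]}},
        )
        ds = sim.simulate_all(cfg)
        assert ds.variants == []

    def test_vcf_genotypes_homozygous_and_consistent(self, default_dataset):
        ds = default_dataset
        for rec in ds.variants:
            assert all(a in (0, 1) for a in rec.genotypes.values())

    def test_indel_haplotype_shortens_cds(self):
        cfg = sim.SimulationConfig(
            seed=2,
            populations=[sim.PopulationSpec("Xian", 20, 1.0, 0.0)],
            genes=[sim.GeneSpec("GeneA", 1, 300, 2, indel_hap=True)],
            hap_freqs={"GeneA": {"Xian": [0.5, 0.5]}},
        )
        ds = sim.simulate_all(cfg)
        lengths = {len(s) for s in ds.truth.hap_cds["GeneA"].values()}
        assert lengths == {300, 297}

    def test_too_many_haplotypes_rejected(self):
        with pytest.raises(ValueError, match="distinguishable"):
            sim.GeneSpec("GeneA", 1, 3, 10)

    def test_calling_recovers_truth_end_to_end(self, default_dataset):
        ds = default_dataset
        for model in ds.gene_models:
            table = call_gchaps(ds.reference, model, ds.variants, ds.panel)
            assert not table.excluded
            truth = ds.truth
            for v, hap in table.assignments.items():
                assert table.hap_sequences[hap] == \
                    truth.hap_cds[model.gene_id][truth.assignments[model.gene_id][v]]


class TestPhenotypes:
    def test_zero_noise_zero_effects_exact(self):
        cfg = small_config(
            3,
            trait_means={"TGW": 25.0},
            trait_sd={"TGW": 0.0},
            pop_offsets={"Xian": {"TGW": 1.5}},
            traits=["TGW"],
        )
        ds = sim.simulate_all(cfg)
        assert (ds.phenotypes.frame["TGW"] == 26.5).all()

    def test_planted_effect_recovered_in_group_means(self):
        cfg = sim.SimulationConfig(
            seed=8,
            populations=[sim.PopulationSpec("Xian", 1000, 1.0, 0.0)],
            genes=[sim.GeneSpec("GeneA", 1, 300, 2)],
            hap_freqs={"GeneA": {"Xian": [0.5, 0.5]}},
            trait_effects={("GeneA", 1, "TGW"): 2.0},
            trait_means={"TGW": 25.0},
            trait_sd={"TGW": 1.0},
            traits=["TGW"],
        )
        ds = sim.simulate_all(cfg)
        assign = ds.truth.assignments["GeneA"]
        y = ds.phenotypes.frame["TGW"]
        g1 = y[[v for v, h in assign.items() if h == 1]]
        g0 = y[[v for v, h in assign.items() if h == 0]]
        assert g1.mean() - g0.mean() == pytest.approx(2.0, abs=0.2)

    def test_seed_changes_values_not_expectations(self):
        cfg_a = small_config(1, trait_means={"TGW": 25.0},
                             trait_sd={"TGW": 1.0}, traits=["TGW"])
        cfg_b = small_config(2, trait_means={"TGW": 25.0},
                             trait_sd={"TGW": 1.0}, traits=["TGW"])
        ya = sim.simulate_all(cfg_a).phenotypes.frame["TGW"]
        yb = sim.simulate_all(cfg_b).phenotypes.frame["TGW"]
        assert not np.allclose(ya, yb)
        assert ya.mean() == pytest.approx(yb.mean(), abs=0.5)

    def test_unknown_trait_in_effects_rejected(self):
        with pytest.raises(ValueError, match="WINGSPAN"):
            small_config(0, trait_effects={("GeneA", 1, "WINGSPAN"): 1.0})


class TestFixtureSet:
    def test_manifest_lists_five_files(self, fixture_dir):
        import json

        manifest = json.loads((fixture_dir / "manifest.json").read_text())
        assert set(manifest["files"]) == {
            "fasta", "gff3", "vcf", "metadata", "phenotypes"
        }

    def test_byte_identity_same_seed(self, tmp_path):
        ds = sim.simulate_all(small_config(7, traits=["TGW"]))
        m1 = sim.write_fixture_set(ds, tmp_path / "a")
        ds2 = sim.simulate_all(small_config(7, traits=["TGW"]))
        m2 = sim.write_fixture_set(ds2, tmp_path / "b")
        assert {k: v["sha256"] for k, v in m1["files"].items()} == \
            {k: v["sha256"] for k, v in m2["files"].items()}

    def test_different_seed_changes_vcf_checksum(self, tmp_path):
        m1 = sim.write_fixture_set(
            sim.simulate_all(small_config(1, traits=["TGW"])), tmp_path / "a"
        )
        m2 = sim.write_fixture_set(
            sim.simulate_all(small_config(2, traits=["TGW"])), tmp_path / "b"
        )
        assert m1["files"]["vcf"]["sha256"] != m2["files"]["vcf"]["sha256"]

    def test_file_round_trip_recovers_truth(self, default_dataset, fixture_dir):
        from gchapkit.io import (
            load_panel_tables, load_reference_and_annotation, load_variants,
        )

        ref, models = load_reference_and_annotation(
            fixture_dir / "reference.fasta", fixture_dir / "genes.gff3"
        )
        panel, pheno = load_panel_tables(
            fixture_dir / "panel.tsv", fixture_dir / "phenotypes.tsv"
        )
        variants = load_variants(fixture_dir / "variants.vcf", panel=panel)
        ds = default_dataset
        assert len(models) == len(ds.gene_models)
        model = next(m for m in models if m.gene_id == "Gene2")
        table = call_gchaps(ref, model, variants, panel)
        truth = ds.truth
        for v, hap in table.assignments.items():
            assert table.hap_sequences[hap] == \
                truth.hap_cds["Gene2"][truth.assignments["Gene2"][v]]
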