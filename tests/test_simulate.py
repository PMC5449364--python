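import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from lectinkit.models import ConfigurationError
from lectinkit.simulate import (
    SimulationConfig,
    gene_universe,
    simulate_all,
    simulate_eul_proteins,
    simulate_expression,
    simulate_genome,
    simulate_population_snps,
    simulate_promoters_and_motifs,
)


class TestConfigValidation:
    def test_zero_genes_per_chromosome_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_genome(SimulationConfig(genes_per_chromosome=0))

    def test_unknown_array_chromosome_rejected(self):
        cfg = SimulationConfig(n_chromosomes=2,
                               tandem_array_spec=(("EUL", 3, "chr9"),))
        with pytest.raises(ConfigurationError):
            simulate_genome(cfg)

    def test_reference_fraction_outside_unit_interval_rejected(self, genome_sim,
                                                               small_config):
        cfg = dataclasses.replace(small_config,
                                  subpop_spec=(("P", 10, 1.2),))
        with pytest.raises(ConfigurationError):
            simulate_population_snps(cfg, genome_sim.gene_models)

    def test_unknown_module_gene_rejected(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            module_spec=(("M1", ("no_such_gene",), 8.0, (("drought", 2.0),), 0.1),))
        with pytest.raises(ConfigurationError):
            simulate_expression(cfg)

    def test_negative_noise_sd_rejected(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            module_spec=(("M1", 5, 8.0, (("drought", 2.0),), -0.1),))
        with pytest.raises(ConfigurationError):
            simulate_expression(cfg)

    def test_motif_longer_than_promoter_rejected(self, small_config):
        cfg = dataclasses.replace(small_config, promoter_length=6, motif_width=8)
        with pytest.raises(ConfigurationError):
            simulate_promoters_and_motifs(cfg)

    def test_plant_probability_outside_unit_interval_rejected(self, small_config):
        cfg = dataclasses.replace(small_config,
                                  motif_plant_spec=("M", 1.2, 0.0))
        with pytest.raises(ConfigurationError):
            simulate_promoters_and_motifs(cfg)


class TestDeterminism:
    def test_simulated_bundle_is_byte_identical(self, small_config, tmp_path):
        simulate_all(small_config, tmp_path / "a")
        simulate_all(small_config, tmp_path / "b")
        files_a = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert "truth.json" in files_a
        for name in files_a:
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_different_seed_changes_genome(self, small_config):
        g1 = simulate_genome(small_config)
        g2 = simulate_genome(dataclasses.replace(small_config, seed=99))
        assert g1.genome != g2.genome


class TestGenome:
    def test_genes_non_overlapping_and_ordered(self, genome_sim):
        by_chrom = {}
        for m in genome_sim.gene_models.values():
            by_chrom.setdefault(m.chromosome, []).append(m)
        for models in by_chrom.values():
            models.sort(key=lambda m: m.start)
            for a, b in zip(models, models[1:]):
                assert a.end <= b.start

    def test_manifest_records_each_planted_array_once(self, genome_sim,
                                                      small_config):
        arrays = genome_sim.manifest["tandem_arrays"]
        assert len(arrays) == len(small_config.tandem_array_spec)
        spec = small_config.tandem_array_spec[0]
        assert arrays[0]["family"] == spec[0]
        assert len(arrays[0]["members"]) == spec[1]
        assert arrays[0]["chromosome"] == spec[2]

    def test_cds_lengths_divisible_by_three(self, genome_sim):
        for m in genome_sim.gene_models.values():
            assert m.cds_length % 3 == 0


class TestSNPs:
    def test_fraction_one_gives_all_reference(self, genome_sim, small_config):
        cfg = dataclasses.replace(small_config,
                                  subpop_spec=(("P", 20, 1.0),),
                                  missing_rate=0.0)
        sim = simulate_population_snps(cfg, genome_sim.gene_models)
        assert (sim.genotypes.to_numpy() == 0).all()

    def test_zero_snps_gives_empty_table(self, genome_sim, small_config):
        cfg = dataclasses.replace(small_config, n_snps=0)
        sim = simulate_population_snps(cfg, genome_sim.gene_models)
        assert len(sim.snp_table) == 0 and sim.genotypes.shape[0] == 0

    def test_manifest_stores_per_subpop_fractions(self, genome_sim, small_config):
        sim = simulate_population_snps(small_config, genome_sim.gene_models)
        for name, _, frac in small_config.subpop_spec:
            assert sim.manifest["true_fractions"][name] == [frac] * small_config.n_snps

    def test_ref_allele_matches_genome_base(self, genome_sim, small_config):
        sim = simulate_population_snps(small_config, genome_sim.gene_models,
                                       genome_sim.genome)
        for r in sim.snp_table.itertuples():
            assert genome_sim.genome[r.chrom][r.position] == r.ref
            assert r.ref != r.alt


class TestExpression:
    def test_zero_noise_fold_change_is_exact(self, small_config):
        cfg = dataclasses.replace(
            small_config, background_sd=0.0,
            module_spec=(("M1", 4, 10.0, (("drought", 4.0),), 0.0),))
        sim = simulate_expression(cfg)
        member = sim.manifest["modules"][0]["members"][1]
        row = sim.matrix.loc[member]
        drought = sim.samples[sim.samples["condition"] == "drought"]["sample"]
        control = sim.samples[sim.samples["condition"] == "control"]["sample"]
        assert np.allclose(row[drought] / row[control].iloc[0], 4.0)

    def test_zero_noise_members_perfectly_correlated(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            module_spec=(("M1", 4, 10.0, (("drought", 4.0),), 0.0),))
        sim = simulate_expression(cfg)
        a, b = sim.manifest["modules"][0]["members"][:2]
        r = np.corrcoef(sim.matrix.loc[a], sim.matrix.loc[b])[0, 1]
        assert r == pytest.approx(1.0)

    def test_member_nonmember_correlation_near_zero_across_seeds(self):
        """Monte-Carlo mean of member vs background correlation stays near 0."""
        cfg0 = SimulationConfig(
            n_background_genes=6,
            module_spec=(("M1", 2, 8.0, (("drought", 4.0),), 0.2),))
        rs = []
        for seed in range(300):
            sim = simulate_expression(dataclasses.replace(cfg0, seed=seed))
            member = sim.manifest["modules"][0]["members"][0]
            non = [g for g in sim.matrix.index
                   if g not in sim.manifest["modules"][0]["members"]][0]
            rs.append(np.corrcoef(np.log2(sim.matrix.loc[member]),
                                  np.log2(sim.matrix.loc[non]))[0, 1])
        assert abs(float(np.mean(rs))) < 0.05

    def test_unmapped_fraction_applied(self, small_config):
        sim = simulate_expression(small_config)
        expected = round(small_config.unmapped_fraction
                         * small_config.n_background_genes)
        assert len(sim.id_map) == small_config.n_background_genes - expected


class TestPromoters:
    def test_plant_probability_one_covers_every_member(self, small_config):
        cfg = dataclasses.replace(small_config,
                                  motif_plant_spec=("M", 1.0, 0.0))
        sim = simulate_promoters_and_motifs(cfg)
        planted_genes = {p["gene_id"] for p in sim.manifest["planted_instances"]}
        assert set(sim.manifest["module_members"]) <= planted_genes

    def test_zero_background_probability_plants_nothing_outside_module(
            self, small_config):
        cfg = dataclasses.replace(small_config,
                                  motif_plant_spec=("M", 1.0, 0.0))
        sim = simulate_promoters_and_motifs(cfg)
        members = set(sim.manifest["module_members"])
        for inst in sim.manifest["planted_instances"]:
            assert inst["gene_id"] in members

    def test_planted_coordinates_within_promoter(self, small_config):
        sim = simulate_promoters_and_motifs(small_config)
        L = small_config.promoter_length
        for inst in sim.manifest["planted_instances"]:
            assert 0 <= inst["start"] < inst["end"] <= L

    def test_planted_instance_is_exact_consensus(self, small_config):
        sim = simulate_promoters_and_motifs(small_config)
        consensus = sim.manifest["planted_motif"]["consensus"]
        for inst in sim.manifest["planted_instances"]:
            seq = sim.promoters[inst["gene_id"]]
            assert seq[inst["start"]:inst["end"]] == consensus

    def test_regions_cover_configured_fraction(self, small_config):
        cfg = dataclasses.replace(small_config,
                                  motif_plant_spec=("M", 0.0, 0.0))
        sim = simulate_promoters_and_motifs(cfg)
        L = cfg.promoter_length
        for g, ivs in list(sim.regions.items())[:50]:
            covered = sum(e - s for s, e in ivs)
            assert covered == round(cfg.region_coverage * L)
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                assert e0 <= s1  # non-overlapping

    def test_planted_instances_always_covered_by_a_region(self, small_config):
        sim = simulate_promoters_and_motifs(small_config)  # cover fraction 1.0
        for inst in sim.manifest["planted_instances"]:
            s, e = inst["start"], inst["end"]
            ivs = sim.regions[inst["gene_id"]]
            assert any(min(e, re) - max(s, rs) >= (e - s) for rs, re in ivs)

    def test_module_membership_consistent_with_expression(self, small_config):
        esim = simulate_expression(small_config)
        psim = simulate_promoters_and_motifs(small_config)
        assert sorted(esim.manifest["modules"][0]["members"]) == \
            psim.manifest["module_members"]


class TestEULProteins:
    def test_architecture_counts(self, small_config):
        sim = simulate_eul_proteins(small_config)
        assert (sim.architecture["type"] == "S").sum() == small_config.eul_spec[0]
        assert (sim.architecture["type"] == "D").sum() == small_config.eul_spec[1]

    def test_zero_substitution_gives_identical_domains(self, small_config):
        cfg = dataclasses.replace(small_config, eul_spec=(3, 2, 0.0), fl_mix=1.0)
        sim = simulate_eul_proteins(cfg)
        domains = set(sim.msa.values())
        assert len(domains) == 1
        assert next(iter(domains)) == sim.manifest["consensus"]

    def test_landmarks_present_in_every_domain(self, small_config):
        sim = simulate_eul_proteins(small_config)
        for dom in sim.msa.values():
            assert len(dom) == 151
            assert dom[33] == "Q" and dom[35] == "W"
            assert dom[115] == "D" and dom[142] == "N" and dom[143] == "Q"
            assert dom[117] in "FL" and dom[135] == "W"

    def test_fl_mix_matches_binomial_expectation(self):
        cfg = dataclasses.replace(SimulationConfig(seed=2), eul_spec=(400, 0, 0.0),
                                  fl_mix=0.63)
        sim = simulate_eul_proteins(cfg)
        frac_l = np.mean([d[117] == "L" for d in sim.msa.values()])
        # 4 binomial sds around 0.37 at n = 400
        assert abs(frac_l - 0.37) < 4 * np.sqrt(0.63 * 0.37 / 400)

    def test_substitution_probability_bounds(self, small_config):
        with pytest.raises(ConfigurationError):
            simulate_eul_proteins(dataclasses.replace(small_config,
                                                      eul_spec=(1, 1, 1.0)))


def test_gene_universe_ids_unique(small_config):
    ids = gene_universe(small_config)
    assert len(ids) == len(set(ids)) == small_config.n_background_genes
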