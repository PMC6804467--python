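import numpy as np
import pandas as pd
import pytest

from synlink import (
    ArtifactSpec,
    AssayDesign,
    DrugParams,
    GeneticMap,
    QTL,
    TraitModel,
    simulate_genotypes,
    simulate_pedigrees,
    simulate_plates,
    simulate_trait,
)
from synlink.simulate import (
    haldane_theta,
    latent_to_ci,
    median_effect_viability,
    solve_combination_fa,
)


def mendelian_errors(ped, geno):
    """Count child alleles unobtainable from the respective parent."""
    errors = 0
    for ind in ped.nonfounders():
        child = geno.alleles[geno.row(ind.id)]
        pat = geno.alleles[geno.row(ind.father_id)]
        mat = geno.alleles[geno.row(ind.mother_id)]
        errors += int((~np.isin(child[:, 0], pat) | ~np.isin(child[:, 1], mat)).sum())
    return errors


class TestHaldane:
    def test_zero_distance_never_recombines(self):
        assert haldane_theta(0.0) == 0.0

    def test_infinite_distance_half(self):
        assert haldane_theta(1e9) == pytest.approx(0.5)

    def test_monotone(self):
        d = np.linspace(0, 300, 50)
        assert (np.diff(haldane_theta(d)) > 0).all()


class TestGeneticMap:
    def test_uniform_shape(self):
        gmap = GeneticMap.uniform(4, 60, 2.0)
        assert len(gmap) == 240
        assert gmap.chromosomes == [1, 2, 3, 4]
        assert gmap.positions(3)[-1] == pytest.approx(118.0)

    def test_decreasing_positions_rejected(self):
        df = pd.DataFrame(
            {"chromosome": [1, 1], "marker_id": ["a", "b"], "position_cM": [5.0, 1.0]}
        )
        with pytest.raises(ValueError):
            GeneticMap(df)

    def test_duplicate_markers_rejected(self):
        df = pd.DataFrame(
            {"chromosome": [1, 2], "marker_id": ["a", "a"], "position_cM": [0.0, 0.0]}
        )
        with pytest.raises(ValueError):
            GeneticMap(df)


class TestSimulateGenotypes:
    def test_no_mendelian_errors(self, small_pedigree, small_map, small_genotypes):
        assert mendelian_errors(small_pedigree, small_genotypes) == 0

    def test_zero_distance_markers_never_recombine(self):
        # all markers at 0 cM: every gamete is a single parental haplotype
        ped = simulate_pedigrees(30, 2, seed=5)
        df = pd.DataFrame(
            {
                "chromosome": 1,
                "marker_id": [f"m{i}" for i in range(10)],
                "position_cM": 0.0,
            }
        )
        gmap = GeneticMap(df)
        # founders get distinct alleles per individual so haplotypes are traceable
        n_markers = 10
        geno = simulate_genotypes(ped, gmap, seed=6)
        for ind in ped.nonfounders():
            pat_hap = geno.alleles[geno.row(ind.id), :, 0]
            father = geno.alleles[geno.row(ind.father_id)]
            same0 = (pat_hap == father[:, 0]).all()
            same1 = (pat_hap == father[:, 1]).all()
            assert same0 or same1  # no switch within the chromosome

    def test_monomorphic_marker(self, small_pedigree, small_map):
        geno = simulate_genotypes(
            small_pedigree, small_map, founder_allele_freqs=[1.0], seed=1
        )
        assert (geno.alleles == 1).all()

    def test_bad_frequencies_rejected(self, small_pedigree, small_map):
        with pytest.raises(ValueError, match="sum"):
            simulate_genotypes(
                small_pedigree, small_map, founder_allele_freqs=[0.6, 0.5], seed=1
            )

    def test_deterministic(self, small_pedigree, small_map):
        a = simulate_genotypes(small_pedigree, small_map, seed=3)
        b = simulate_genotypes(small_pedigree, small_map, seed=3)
        assert np.array_equal(a.alleles, b.alleles)

    def test_founder_allele_frequency(self, small_map):
        # large founder-only pedigree: empirical frequency near the target
        ped = simulate_pedigrees(500, 0, seed=2)
        geno = simulate_genotypes(ped, small_map, founder_allele_freqs=[0.3, 0.7], seed=4)
        freq1 = (geno.alleles == 1).mean()
        assert freq1 == pytest.approx(0.3, abs=0.01)


class TestTraitModel:
    def test_from_h2_consistency(self):
        m = TraitModel.from_h2(0.3, qtl_fraction=0.5)
        assert m.h2() == pytest.approx(0.3, abs=1e-12)
        m.check_h2()

    def test_bad_h2_rejected(self):
        with pytest.raises(ValueError):
            TraitModel.from_h2(1.2)
        with pytest.raises(ValueError):
            TraitModel(target_h2=-0.1)

    def test_inconsistent_target_rejected(self):
        m = TraitModel(polygenic_variance=1.0, environmental_variance=1.0, target_h2=0.9)
        with pytest.raises(ValueError, match="inconsistent"):
            m.check_h2()

    def test_qtl_variance_hardy_weinberg(self):
        qtl = QTL(1, 0.0, {1: 0.0, 2: 1.0})
        # 2 p q a^2 with p = q = 0.5, a = 1 (allele-substitution scale)
        assert qtl.variance(np.array([0.5, 0.5])) == pytest.approx(0.5)


class TestSimulateTrait:
    def test_mendelian_sampling_variance(self):
        # pure polygenic trait: offspring deviation from midparent has Var Vg/2
        ped = simulate_pedigrees(4000, 1, seed=8)
        model = TraitModel(polygenic_variance=1.0, environmental_variance=0.0)
        tr = simulate_trait(ped, None, model, seed=9)
        devs = []
        for ind in ped.nonfounders():
            mid = 0.5 * (tr[ind.father_id] + tr[ind.mother_id])
            devs.append(tr[ind.id] - mid)
        assert np.var(devs) == pytest.approx(0.5, abs=0.05)

    def test_pure_noise_no_parent_offspring_covariance(self):
        ped = simulate_pedigrees(4000, 1, seed=10)
        model = TraitModel(polygenic_variance=0.0, environmental_variance=1.0)
        tr = simulate_trait(ped, None, model, seed=11)
        parent = np.array([tr[i.father_id] for i in ped.nonfounders()])
        child = np.array([tr[i.id] for i in ped.nonfounders()])
        r = np.corrcoef(parent, child)[0, 1]
        assert abs(r) < 0.05

    def test_variance_bookkeeping_founders(self):
        # Var(G) across founders ~ QTL variance + polygenic variance
        ped = simulate_pedigrees(1000, 0, seed=12)  # 2000 founders
        gmap = GeneticMap.uniform(1, 5, 2.0)
        geno = simulate_genotypes(ped, gmap, seed=13)
        model = TraitModel.from_h2(
            1.0, qtl_fraction=0.4, qtl_chromosome=1, qtl_position_cM=4.0
        )
        tr = simulate_trait(ped, geno, model, seed=14, gmap=gmap)
        target = model.genetic_variance()
        # 3 standard errors of a variance estimate at n = 2000
        se = target * np.sqrt(2.0 / 2000)
        assert abs(np.var(tr.to_numpy()) - target) < 3 * se

    def test_qtl_outside_map_rejected(self):
        ped = simulate_pedigrees(2, 1, seed=0)
        gmap = GeneticMap.uniform(1, 5, 2.0)
        geno = simulate_genotypes(ped, gmap, seed=0)
        model = TraitModel(
            qtl=QTL(1, 50.0, {1: 0.0, 2: 1.0}), environmental_variance=1.0
        )
        with pytest.raises(ValueError, match="outside map range"):
            simulate_trait(ped, geno, model, seed=0, gmap=gmap)


class TestLatentToCI:
    def test_additive_at_zero(self):
        assert latent_to_ci(0.0) == pytest.approx(1.0)

    def test_clipped_to_range(self):
        z = np.array([-5.0, 0.0, 5.0])
        ci = latent_to_ci(z, (0.3, 2.0))
        assert ci[0] == 0.3 and ci[2] == 2.0

    def test_monotone(self):
        z = np.linspace(-0.5, 0.5, 20)
        assert (np.diff(latent_to_ci(z)) >= 0).all()


class TestSolveCombinationFa:
    def test_additive_sham(self):
        # one drug split in two at half dose each: CI = 1 at Fa = 0.5 when
        # d1 + d2 = Dm
        fa = solve_combination_fa(1.0, 1.0, 2.0, 1.0, 2.0, 1.0, 1.0)
        assert fa == pytest.approx(0.5, abs=1e-10)

    def test_round_trip(self):
        dm1, m1, dm2, m2 = 4.0, 1.5, 1.0, 2.0
        for ci in (0.3, 0.7, 1.0, 1.8):
            fa = solve_combination_fa(2.0, 0.5, dm1, m1, dm2, m2, ci)
            r = fa / (1 - fa)
            back = 2.0 / (dm1 * r ** (1 / m1)) + 0.5 / (dm2 * r ** (1 / m2))
            assert back == pytest.approx(ci, rel=1e-9)


class TestSimulatePlates:
    def test_full_viability_rfu(self, constant_latent):
        design = AssayDesign.default()
        dp = {"drugA": DrugParams(4.0, 1.5), "drugB": DrugParams(1.0, 2.0)}
        plates, _ = simulate_plates(
            ["L1"], constant_latent(["L1"], 1.0), design, dp,
            ArtifactSpec(), seed=1,
        )
        veh = plates[plates.role == "vehicle_control"]
        assert (veh.rfu == 10000.0).all()
        neg = plates[plates.role == "negative_control"]
        assert (neg.rfu == 500.0).all()

    def test_median_effect_exactness_at_dm(self, constant_latent):
        # noise-free: normalized viability at the line's Dm is exactly 0.5
        design = AssayDesign.default()
        dp = {"drugA": DrugParams(4.0, 1.5), "drugB": DrugParams(1.0, 2.0)}
        plates, truth = simulate_plates(
            ["L1"], constant_latent(["L1"], 1.0), design, dp,
            ArtifactSpec(), seed=1,
        )
        at_dm = plates[(plates.drug1 == "drugA") & (plates.dose1 == 4.0)
                       & (plates.role == "single_drug")]
        viability = (at_dm.rfu - 500.0) / 9500.0
        assert np.allclose(viability, 0.5)

    def test_dead_plates_below_threshold(self, constant_latent):
        design = AssayDesign.default()
        dp = {"drugA": DrugParams(4.0, 1.5), "drugB": DrugParams(1.0, 2.0)}
        plates, truth = simulate_plates(
            ["L1", "L2"], constant_latent(["L1", "L2"], 1.0), design, dp,
            ArtifactSpec(dead_plate_rate=1.0), seed=1,
        )
        assert len(truth.dead_plates) == plates.plate_id.nunique()
        assert (plates.rfu < 1500.0).all()

    def test_deviant_mask_matches_wells(self, constant_latent):
        design = AssayDesign.default()
        dp = {"drugA": DrugParams(4.0, 1.5), "drugB": DrugParams(1.0, 2.0)}
        lines = [f"L{i}" for i in range(10)]
        plates, truth = simulate_plates(
            lines, constant_latent(lines, 1.0), design, dp,
            ArtifactSpec(deviant_rate=0.05), seed=2,
        )
        assert len(truth.deviant_wells) > 0
        merged = truth.deviant_wells.merge(plates, on=["plate_id", "row", "col"])
        assert len(merged) == len(truth.deviant_wells)

    def test_byte_identical_determinism(self, constant_latent):
        design = AssayDesign.default()
        dp = {"drugA": DrugParams(4.0, 1.5, 0.3), "drugB": DrugParams(1.0, 2.0, 0.3)}
        lines = ["L1", "L2"]
        args = (lines, constant_latent(lines, 0.8), design, dp,
                ArtifactSpec(noise_sd=100.0, deviant_rate=0.1))
        p1, _ = simulate_plates(*args, seed=9)
        p2, _ = simulate_plates(*args, seed=9)
        assert p1.equals(p2)

    def test_missing_drug_params_rejected(self, constant_latent):
        design = AssayDesign.default()
        with pytest.raises(ValueError, match="missing drug parameters"):
            simulate_plates(
                ["L1"], constant_latent(["L1"], 1.0), design,
                {"drugA": DrugParams(4.0, 1.5)}, None, seed=1,
            )


class TestAssayDesign:
    def test_default_grid_contains_dm(self):
        d = AssayDesign.default()
        assert 4.0 in d.doses["drugA"] and 1.0 in d.doses["drugB"]
        assert len(d.combination_pairs) == 6

    def test_nonpositive_doses_rejected(self):
        with pytest.raises(ValueError):
            AssayDesign(doses={"a": [0.0, 1.0], "b": [1.0, 2.0]}, pair=("a", "b"))

    def test_design_must_fit_plate(self):
        with pytest.raises(ValueError, match="fit"):
            AssayDesign(
                doses={"a": np.arange(1, 60.0), "b": np.arange(1, 60.0)},
                pair=("a", "b"),
            )
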