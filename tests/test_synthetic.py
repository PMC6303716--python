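import json

import numpy as np
import pytest

from fishdiv import (
    Config,
    TaxonomyShape,
    TrueEffects,
    WorldConfig,
    emit_table,
    generate_taxonomy,
    generate_world,
    parse_species_table,
    run_suite,
    simulate_study,
    simulate_traits,
)
from fishdiv.rarefaction import (
    RarefactionConfig,
    allele_freq_distribution,
    estimate_rarefied_na,
)
from fishdiv.species import SpeciesRecord
from fishdiv.taxonomy import brownian_covariance


class TestTaxonomyGeneration:
    def test_balanced_shape_product(self):
        shapes = (TaxonomyShape("C", 2, 2, 2, 2),)
        skeleton = generate_taxonomy(shapes, seed=0)
        assert len(skeleton) == 16

    def test_same_seed_same_labels(self):
        shapes = (TaxonomyShape("C", 2, 2, 2, 3, 20),)
        a = generate_taxonomy(shapes, seed=7)
        b = generate_taxonomy(shapes, seed=7)
        assert a == b

    def test_congeners_have_08_covariance(self):
        skeleton = generate_taxonomy((TaxonomyShape("C", 1, 1, 1, 3),), seed=0)
        recs = [
            SpeciesRecord(habitat="marine", n_individuals=10, n_loci=1,
                          mean_alleles=2.0, **sk)
            for sk in skeleton
        ]
        V = brownian_covariance(recs).matrix
        off = V[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.8)

    def test_overfull_target_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_taxonomy((TaxonomyShape("C", 1, 1, 1, 2, 5),), seed=0)


class TestTraitSimulation:
    def test_zero_brownian_variance_gives_mean_structure(self):
        shapes = (TaxonomyShape("C", 2, 2, 2, 2),)
        skeleton = generate_taxonomy(shapes, seed=1)
        cfg = WorldConfig(
            shapes=shapes, sigma2_bm=0.0,
            effects=TrueEffects(habitat_delta_alleles=10.0, slope_age=0.0,
                                slope_fecundity=0.0, conservation_delta=0.0),
        )
        traits = simulate_traits(skeleton, cfg, seed=2)
        expected_shift = {"marine": 10.0, "mixed": 5.0, "freshwater": 0.0}
        expected = cfg.base_alleles + np.array(
            [expected_shift[str(h)] for h in traits["habitat"]]
        )
        np.testing.assert_allclose(traits["latent"], expected, atol=1e-12)

    def test_brownian_covariance_reproduced_empirically(self):
        """Empirical covariance of replicate Brownian draws matches
        sigma2_bm * V elementwise within Monte-Carlo error."""
        shapes = (TaxonomyShape("C", 1, 2, 2, 2),)
        skeleton = generate_taxonomy(shapes, seed=3)
        n = len(skeleton)
        cfg = WorldConfig(shapes=shapes, sigma2_bm=4.0,
                          effects=TrueEffects(0, 0, 0, 0, 0))
        reps = 400
        draws = np.empty((reps, n))
        for r in range(reps):
            traits = simulate_traits(skeleton, cfg, seed=1000 + r)
            # remove the (habitat/covariate) mean structure: effects are 0,
            # but age/fecundity centering leaves base only
            draws[r] = traits["latent"]
        recs = [SpeciesRecord(habitat="marine", n_individuals=10, n_loci=1,
                              mean_alleles=2.0, **sk) for sk in skeleton]
        V = brownian_covariance(recs).matrix
        emp = np.cov(draws, rowvar=False)
        se = 4.0 * np.sqrt((1 + V**2) / reps)  # normal-theory SE of cov
        assert np.all(np.abs(emp - 4.0 * V) < 4 * se + 0.5)

    def test_congener_correlation_exceeds_cross_family(self):
        shapes = (TaxonomyShape("C", 1, 2, 2, 2),)
        skeleton = generate_taxonomy(shapes, seed=3)
        cfg = WorldConfig(shapes=shapes, sigma2_bm=9.0,
                          effects=TrueEffects(0, 0, 0, 0, 0))
        reps = 300
        draws = np.stack([
            simulate_traits(skeleton, cfg, seed=5000 + r)["latent"]
            for r in range(reps)
        ])
        corr = np.corrcoef(draws, rowvar=False)
        genus = [sk["genus_rank"] for sk in skeleton]
        family = [sk["family_rank"] for sk in skeleton]
        congener, cross_family = [], []
        n = len(skeleton)
        for i in range(n):
            for j in range(i + 1, n):
                if genus[i] == genus[j]:
                    congener.append(corr[i, j])
                elif family[i] != family[j]:
                    cross_family.append(corr[i, j])
        assert np.mean(congener) > np.mean(cross_family)


class TestStudySimulation:
    def test_observed_alleles_bounded_by_truth(self):
        for seed in range(5):
            _, alleles = simulate_study(2, n=10, n_loci=5, seed=seed)
            assert alleles <= 2

    def test_deep_sampling_recovers_truth_and_hwe_het(self):
        het, alleles = simulate_study(2, n=20_000, n_loci=4, seed=1)
        assert alleles == pytest.approx(2.0)
        assert het == pytest.approx(0.32, abs=0.01)

    def test_observed_alleles_increase_with_sample_size(self):
        shallow = np.mean([simulate_study(20, 10, 6, s)[1] for s in range(8)])
        deep = np.mean([simulate_study(20, 200, 6, s)[1] for s in range(8)])
        assert deep > shallow

    def test_rarefaction_closure_on_simulated_studies(self):
        """Feeding the generator's observed counts back through the
        estimator recovers the true allele count within +/-2 (medians over
        replicates; full grid in the acceptance suite)."""
        cfg = RarefactionConfig(fast_path=True)
        for true_na in (5, 15):
            errs = []
            for seed in range(3):
                _, observed = simulate_study(true_na, n=60, n_loci=10, seed=seed)
                res = estimate_rarefied_na(observed, 60, cfg, seed=seed)
                errs.append(res.rarefied_na - true_na)
            assert abs(np.median(errs)) <= 2


class TestWorldEmission:
    def test_default_world_is_paper_sized_and_parses_strictly(self, tmp_path):
        world = generate_world(seed=5)
        assert len(world.records) == 463
        classes = [r.class_rank for r in world.records]
        assert classes.count("Osteichthyes") == 426
        csv_path, truth_path = emit_table(world, tmp_path)
        back = parse_species_table(csv_path, strict=True)
        assert len(back) == 463

    def test_truth_round_trips(self, tmp_path, small_world):
        _, truth_path = emit_table(small_world, tmp_path)
        truth = json.loads(truth_path.read_text())
        assert truth == json.loads(json.dumps(small_world.truth_dict()))
        assert truth["config"]["effects"]["habitat_delta_alleles"] == pytest.approx(
            small_world.config.effects.habitat_delta_alleles
        )

    def test_same_seed_byte_identical_csv(self, tmp_path):
        cfg = WorldConfig(shapes=(TaxonomyShape("C", 2, 2, 2, 2, 12),))
        blobs = []
        for d in ("x", "y"):
            world = generate_world(cfg, seed=9)
            csv_path, _ = emit_table(world, tmp_path / d)
            blobs.append(csv_path.read_bytes())
        assert blobs[0] == blobs[1]


class TestPipelineClosure:
    def test_effect_signs_recovered_across_replicates(self, small_world):
        """Across seeded replicate worlds the suite recovers the signs of
        the injected habitat and life-history effects in >=90% of runs."""
        cfg = Config()
        cfg.rarefaction.fast_path = True
        cfg.pgls.bootstrap_iterations = 150
        cfg.suite.min_n = 8
        wcfg = small_world.config
        hits = []
        for rep in range(10):
            world = generate_world(wcfg, seed=3000 + rep)
            res = run_suite(world.records, None, cfg, seed=rep)
            ok = True
            hab = res.model("habitat_alleles")
            if hab.ci is None or (hab.ci.estimates["marine"]
                                  <= hab.ci.estimates["freshwater"]):
                ok = False
            for mid in ("age_alleles_marine", "age_alleles_freshwater"):
                m = res.model(mid)
                if m.ci is not None and m.ci.estimates["age_at_maturity"] >= 0.5:
                    ok = False
            hits.append(ok)
        assert np.mean(hits) >= 0.9
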