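import numpy as np
import pytest

from fishdiv import SpeciesRecord, TaxonomyShape, WorldConfig, generate_world


def make_record(species_id, genus="Gadus", family="Gadidae", order="Gadiformes",
                cls="Osteichthyes", habitat="marine", n=50, alleles=8.0,
                het=0.7, **kw):
    return SpeciesRecord(
        species_id=species_id,
        class_rank=cls,
        order_rank=order,
        family_rank=family,
        genus_rank=genus,
        habitat=habitat,
        n_individuals=n,
        n_loci=10,
        mean_obs_het=het,
        mean_alleles=alleles,
        **kw,
    )


@pytest.fixture
def four_species():
    """Two congeners plus two unrelated species; V has one 0.8 entry."""
    return [
        make_record("Gadus morhua"),
        make_record("Gadus macrocephalus"),
        make_record("Salmo salar", genus="Salmo", family="Salmonidae",
                    order="Salmoniformes", habitat="freshwater"),
        make_record("Perca fluviatilis", genus="Perca", family="Percidae",
                    order="Perciformes", habitat="freshwater"),
    ]


@pytest.fixture(scope="session")
def small_world():
    """60-species single-class world, cheap enough for repeated suite runs."""
    cfg = WorldConfig(shapes=(TaxonomyShape("Osteichthyes", 4, 2, 2, 4, 60),))
    return generate_world(cfg, seed=20240901)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
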