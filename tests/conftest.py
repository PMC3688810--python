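"""Shared fixtures: small synthetic cohorts reused across test modules."""

import pandas as pd
import pytest

from mhcdab import genotyping, simulate, tags


@pytest.fixture(scope="session")
def tagset():
    cands = tags.enumerate_candidate_tags()
    return tags.select_tag_set(cands, min_hamming=3, target_size=40, seed=0)


@pytest.fixture(scope="session")
def pool():
    return simulate.generate_allele_pool(8, seed=1)


@pytest.fixture(scope="session")
def cohort(pool, tagset):
    """Noiseless cohort: genotypes, layout, reads and truth tables."""
    genos = (simulate.simulate_genotypes(pool, 14, species="A",
                                         population="p1", seed=1)
             + simulate.simulate_genotypes(pool, 14, species="B",
                                           population="p2", seed=2))
    layout = tags.build_plate_layout(tagset, 12, 8,
                                     [g.specimen_id for g in genos])
    cfg = simulate.ReadSimConfig(coverage=(150, 400), error_rate=0.0,
                                 chimera_fraction=0.0, seed=7)
    reads, read_truth, amp_truth = simulate.simulate_read_set(
        genos, pool, layout, cfg)
    meta = pd.DataFrame([{"specimen": g.specimen_id,
                          "population": g.population,
                          "species": g.species} for g in genos])
    return {"pool": pool, "genotypes": genos, "layout": layout,
            "reads": reads, "read_truth": read_truth,
            "amplicon_truth": amp_truth, "metadata": meta}


@pytest.fixture(scope="session")
def genotyping_result(cohort):
    return genotyping.genotype_cohort(
        cohort["reads"], cohort["layout"],
        cohort["pool"].reference_sequences(), cohort["metadata"])
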