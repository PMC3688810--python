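"""Synthetic-data generator: allele pools, genotypes, reads, microsatellites."""

import numpy as np
import pytest

from mhcdab import simulate, tags
from mhcdab.errors import ConfigurationError, FrameError
from mhcdab.simulate import LINEAGES


def _dist(a, b):
    return sum(x != y for x, y in zip(a, b))


class TestAllelePool:
    def test_exon2_core_length_and_frame(self, pool):
        for a in pool.alleles:
            assert len(a.sequence) == 276
            assert simulate.translate_ok(a.sequence)

    def test_lineages_form_separated_clusters(self, pool):
        within, between = [], []
        for i, a in enumerate(pool.alleles):
            for b in pool.alleles[i + 1:]:
                d = _dist(a.sequence, b.sequence)
                (within if a.lineage == b.lineage else between).append(d)
        assert min(between) > max(within)

    def test_zero_divergence_single_allele(self):
        p = simulate.generate_allele_pool(1, divergence=0.0, seed=4)
        seqs = {a.lineage: a.sequence for a in p.alleles}
        assert seqs["DAB1"] != seqs["DAB3"]

    def test_determinism_under_fixed_seed(self):
        p1 = simulate.generate_allele_pool(10, seed=11)
        p2 = simulate.generate_allele_pool(10, seed=11)
        assert [a.sequence for a in p1.alleles] == [a.sequence for a in p2.alleles]
        assert p1.species_assignment == p2.species_assignment

    def test_shared_alleles_present(self, pool):
        assert "shared" in set(pool.species_assignment.values())

    def test_frame_error(self):
        with pytest.raises(FrameError):
            simulate.generate_allele_pool(2, exon2_length=277)


class TestGenotypes:
    def test_caps_hold_at_scale(self, pool):
        genos = simulate.simulate_genotypes(pool, 1000, species="B", seed=5)
        assert max(g.n_alleles for g in genos) <= 8
        for g in genos:
            for lin in LINEAGES:
                assert len(g.alleles.get(lin, [])) <= 4

    def test_degenerate_weights_force_pattern(self, pool):
        genos = simulate.simulate_genotypes(
            pool, 50, species="B", pattern_weights={(1, 2): 1.0}, seed=6)
        assert all(g.n_alleles == 3 for g in genos)

    def test_species_a_mostly_lacks_dab1(self, pool):
        genos = simulate.simulate_genotypes(pool, 400, species="A", seed=7)
        no_dab1 = sum(1 for g in genos if not g.alleles.get("DAB1"))
        assert no_dab1 > len(genos) / 2

    def test_missing_lineage_raises(self, pool):
        only_dab1 = simulate.AllelePool(
            alleles=pool.lineage_alleles("DAB1"), exon2_length=276,
            species_assignment={a.id: "shared"
                                for a in pool.lineage_alleles("DAB1")})
        with pytest.raises(ConfigurationError):
            simulate.simulate_genotypes(only_dab1, 5, species="A",
                                        pattern_weights={(0, 1): 1.0}, seed=0)


class TestReads:
    def test_noiseless_reads_match_templates(self, cohort):
        pool = cohort["pool"]
        truth = cohort["read_truth"]
        by_id = dict(cohort["reads"])
        sample = truth.sample(100, random_state=0)
        for r in sample.itertuples(index=False):
            seq = by_id[r.read_id]
            template = seq[7 + len(tags.PRIMERS[r.marker]["forward"].sequence):
                           -(7 + len(tags.PRIMERS[r.marker]["reverse"].sequence))]
            assert template == pool.by_id(r.allele_id).sequence

    def test_truth_table_is_complete(self, cohort):
        ids = [rid for rid, _ in cohort["reads"]]
        assert sorted(ids) == sorted(cohort["read_truth"]["read_id"])
        assert cohort["read_truth"]["read_id"].is_unique

    def test_chimera_fraction_within_binomial_bounds(self, pool, tagset):
        genos = simulate.simulate_genotypes(pool, 10, species="B", seed=9)
        layout = tags.build_plate_layout(tagset, 12, 8,
                                         [g.specimen_id for g in genos])
        cfg = simulate.ReadSimConfig(coverage=(400, 600), error_rate=0.0,
                                     chimera_fraction=0.05, seed=3)
        _reads, truth, _amp = simulate.simulate_read_set(genos, pool, layout, cfg)
        # only multi-allele amplicons can host chimeras
        multi = truth.groupby(["specimen", "marker"])["allele_id"].transform(
            "nunique") > 1
        frac = truth.loc[multi, "is_chimera"].mean()
        n = int(multi.sum())
        sd = np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < 3 * sd

    def test_modal_variant_is_true_sequence_under_errors(self, pool, tagset):
        genos = simulate.simulate_genotypes(pool, 4, species="B", seed=12)
        layout = tags.build_plate_layout(tagset, 12, 8,
                                         [g.specimen_id for g in genos])
        cfg = simulate.ReadSimConfig(coverage=(500, 500), error_rate=0.01,
                                     chimera_fraction=0.0, seed=4)
        reads, truth, _amp = simulate.simulate_read_set(genos, pool, layout, cfg)
        by_id = dict(reads)
        for (spec, marker, allele), grp in truth.groupby(
                ["specimen", "marker", "allele_id"]):
            from collections import Counter
            counts = Counter(by_id[r] for r in grp["read_id"])
            modal, _n = counts.most_common(1)[0]
            fwd = tags.PRIMERS[marker]["forward"].sequence
            rev = tags.PRIMERS[marker]["reverse"].sequence
            template = modal[7 + len(fwd):-(7 + len(rev))]
            assert template == pool.by_id(allele).sequence


class TestMicrosats:
    def test_determinism(self):
        p1 = simulate.simulate_microsat_panel(10, (20, 20), fst=0.2, seed=5)
        p2 = simulate.simulate_microsat_panel(10, (20, 20), fst=0.2, seed=5)
        assert p1.genotypes.equals(p2.genotypes)

    def test_admixture_rows_sum_to_one(self):
        p = simulate.simulate_microsat_panel(5, (10, 10), fst=0.2,
                                             n_hybrids=5, seed=6)
        assert np.allclose(p.admixture.sum(axis=1), 1.0)

    def test_config_errors(self):
        with pytest.raises(ConfigurationError):
            simulate.simulate_microsat_panel(0, (10, 10))
        with pytest.raises(ConfigurationError):
            simulate.simulate_microsat_panel(5, (10, 10), fst=1.0)
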