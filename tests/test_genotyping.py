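"""Demultiplexing, variant tabulation, MPAF classification and naming."""

import numpy as np
import pandas as pd
import pytest

from mhcdab import genotyping, simulate, tags
from mhcdab.errors import ConfigurationError, NamingError
from mhcdab.genotyping import AmpliconBin, classify_and_call, tabulate_variants


def _mutate(seq, pos, base):
    return seq[:pos] + base + seq[pos + 1:]


class TestDemultiplex:
    def test_all_clean_tagged_reads_assigned(self, cohort):
        assigned, unassigned = genotyping.demultiplex_reads(
            cohort["reads"], cohort["layout"], allow_mismatch=0)
        clean = cohort["read_truth"]["tags_intact"].sum()
        assert sum(len(v) for v in assigned.values()) == clean
        assert clean + len(unassigned) == len(cohort["reads"])

    def test_read_with_unknown_tag_unassigned(self, cohort):
        layout = cohort["layout"]
        rid, seq = cohort["reads"][0]
        bad = "AAAAAAA" + seq[7:]
        assigned, unassigned = genotyping.demultiplex_reads(
            [("x", bad)], layout, allow_mismatch=0)
        assert unassigned and unassigned[0][2] == "no_tag_match"

    def test_one_mismatch_recovered_with_tolerance(self, cohort):
        layout = cohort["layout"]
        rid, seq = cohort["reads"][0]
        ftag = seq[:7]
        mutated = _mutate(ftag, 3, "A" if ftag[3] != "A" else "C") + seq[7:]
        a0, u0 = genotyping.demultiplex_reads([("x", mutated)], layout, 0)
        a1, u1 = genotyping.demultiplex_reads([("x", mutated)], layout, 1)
        assert not any(a0.values()) and u0
        assert sum(len(v) for v in a1.values()) == 1

    def test_demultiplex_assignments_match_truth(self, cohort):
        assigned, _un = genotyping.demultiplex_reads(
            cohort["reads"], cohort["layout"], allow_mismatch=0)
        truth_spec = cohort["read_truth"].set_index("read_id")["specimen"]
        well_spec = {w: s for w, (_f, _r, s) in cohort["layout"].wells.items()}
        for well, reads in assigned.items():
            for rid, _seq in reads:
                assert truth_spec[rid] == well_spec[well]


class TestMarkerAssignment:
    def test_exact_and_noisy_assignment(self, pool):
        refs = {m: genotyping.untagged_reference(m, t)
                for m, t in pool.reference_sequences().items()}
        a1 = pool.lineage_alleles("DAB1")[1]
        seq = genotyping.untagged_reference("DAB1", a1.sequence)
        assert genotyping.assign_marker(seq, refs) == "DAB1"
        noisy = _mutate(_mutate(seq, 10, "A" if seq[10] != "A" else "C"),
                        100, "G" if seq[100] != "G" else "T")
        assert genotyping.assign_marker(noisy, refs) == "DAB1"

    def test_random_sequence_unassigned(self, pool):
        refs = {m: genotyping.untagged_reference(m, t)
                for m, t in pool.reference_sequences().items()}
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 342))
        assert genotyping.assign_marker(junk, refs) is None

    def test_empty_references_error(self):
        with pytest.raises(ConfigurationError):
            genotyping.assign_marker("ACGT", {})


def _bins_from(spec_reads):
    """spec_reads: dict (specimen, marker) -> list of template sequences."""
    return [AmpliconBin(s, m, list(reads))
            for (s, m), reads in spec_reads.items()]


class TestTabulate:
    def test_mpaf_is_max_over_amplicons(self):
        v = "ACG" * 10
        w = _mutate(v, 4, "T")
        bins = _bins_from({("s1", "DAB1"): [v] * 10 + [w] * 90,
                           ("s2", "DAB1"): [v] * 40 + [w] * 160})
        vt = tabulate_variants(bins)
        row = vt.summary.set_index("sequence").loc[v]
        assert row["mpaf"] == pytest.approx(0.20)  # max(10/100, 40/200)
        assert row["n_amplicons"] == 2

    def test_frequencies_sum_to_one_per_amplicon(self, genotyping_result):
        vt = genotyping_result.variant_table
        sums = vt.counts.groupby("amplicon_id")["freq"].sum()
        assert np.allclose(sums, 1.0)

    def test_singleton_has_one_amplicon(self):
        v = "ACG" * 10
        bins = _bins_from({("s1", "DAB1"): [v] * 5})
        vt = tabulate_variants(bins)
        assert (vt.summary["n_amplicons"] == 1).all()


@pytest.fixture()
def constructed_table(pool):
    """One amplicon holding two majority alleles plus constructed artefacts."""
    a = pool.lineage_alleles("DAB1")[0].sequence
    b = pool.lineage_alleles("DAB1")[3].sequence
    sub = _mutate(a, 17, "A" if a[17] != "A" else "C")   # 1-bp substitution
    chim = a[:140] + b[140:]                              # single crossover
    assert chim not in (a, b)
    reads = [a] * 450 + [b] * 430 + [sub] * 30 + [chim] * 25
    # replicate the two real alleles in a second amplicon (not singletons)
    bins = _bins_from({("s1", "DAB1"): reads,
                       ("s2", "DAB1"): [a] * 100 + [b] * 100})
    refs = {"DAB1": a}
    return classify_and_call(tabulate_variants(bins), refs), refs


class TestClassify:
    def test_substitution_artefact(self, constructed_table, pool):
        vt, _refs = constructed_table
        a = pool.lineage_alleles("DAB1")[0].sequence
        sub = _mutate(a, 17, "A" if a[17] != "A" else "C")
        assert vt.summary.set_index("sequence").loc[sub, "status"] \
            == "artefact_substitution"

    def test_chimera_artefact(self, constructed_table, pool):
        vt, _refs = constructed_table
        a = pool.lineage_alleles("DAB1")[0].sequence
        b = pool.lineage_alleles("DAB1")[3].sequence
        chim = a[:140] + b[140:]
        assert vt.summary.set_index("sequence").loc[chim, "status"] \
            == "artefact_chimera"

    def test_majority_variants_are_true_alleles(self, constructed_table, pool):
        vt, _refs = constructed_table
        a = pool.lineage_alleles("DAB1")[0].sequence
        b = pool.lineage_alleles("DAB1")[3].sequence
        statuses = vt.summary.set_index("sequence")["status"]
        assert statuses[a] == "true_allele"
        assert statuses[b] == "true_allele"

    def test_high_mpaf_variant_accepted_outright(self):
        v = "ACGTGA" * 20
        bins = _bins_from({("s1", "DAB1"): [v] * 60 + ["TCGTGA" + v[6:]] * 40})
        vt = classify_and_call(tabulate_variants(bins), {"DAB1": v})
        assert vt.summary.set_index("sequence").loc[v, "status"] == "true_allele"

    def test_frameshift_excluded(self):
        v = "ACGTGA" * 20
        delv = v[:30] + v[31:]
        bins = _bins_from({("s1", "DAB1"): [v] * 90 + [delv] * 10,
                           ("s2", "DAB1"): [delv] * 5 + [v] * 95})
        vt = classify_and_call(tabulate_variants(bins), {"DAB1": v})
        assert vt.summary.set_index("sequence").loc[delv, "status"] \
            == "excluded_frameshift"

    def test_singleton_policy_floor(self):
        v = "ACGTGA" * 20
        w = _mutate(_mutate(_mutate(v, 5, "C"), 40, "A"), 80, "T")
        # w present in a single amplicon at MPAF 0.25 >= floor -> kept
        bins = _bins_from({("s1", "DAB1"): [v] * 75 + [w] * 25,
                           ("s2", "DAB1"): [v] * 50})
        vt = classify_and_call(tabulate_variants(bins), {"DAB1": v})
        assert vt.summary.set_index("sequence").loc[w, "status"] == "true_allele"
        # same variant at MPAF 0.04 in one amplicon -> excluded singleton
        bins2 = _bins_from({("s1", "DAB1"): [v] * 96 + [w] * 4,
                            ("s2", "DAB1"): [v] * 50})
        vt2 = classify_and_call(tabulate_variants(bins2), {"DAB1": v})
        assert vt2.summary.set_index("sequence").loc[w, "status"] \
            == "excluded_singleton"

    def test_classification_is_idempotent(self, genotyping_result, pool):
        vt = genotyping_result.variant_table
        again = classify_and_call(vt, pool.reference_sequences())
        assert list(again.summary["status"]) == list(vt.summary["status"])


class TestNomenclatureAndPresence:
    def test_prefixes_follow_species_occurrence(self, genotyping_result, cohort):
        catalog = genotyping_result.catalog.table
        pool = cohort["pool"]
        seq_to_assignment = {a.sequence: pool.species_assignment[a.id]
                             for a in pool.alleles}
        calls = genotyping_result.calls
        species_of = cohort["metadata"].set_index("specimen")["species"]
        for r in catalog.itertuples(index=False):
            vids = calls[calls["variant_id"] == r.variant_id]
            occ = set(vids["specimen"].map(species_of))
            prefix = r.name.split("-")[0]
            if occ == {"A"}:
                assert prefix == "Pato"
            elif occ == {"B"}:
                assert prefix == "Chna"
            elif {"A", "B"} <= occ:
                assert prefix == "Pctn"

    def test_names_stable_across_reruns(self, genotyping_result, cohort):
        again = genotyping.assign_nomenclature(
            genotyping_result.variant_table, genotyping_result.calls,
            cohort["metadata"])
        assert list(again.table["name"]) == \
            list(genotyping_result.catalog.table["name"])

    def test_hybrid_only_allele_gets_pctn_prefix(self):
        summ = pd.DataFrame([
            {"variant_id": "v1", "sequence": "ACG", "marker": "DAB3",
             "mpaf": 0.6, "mpaf_amplicon": "h1|DAB3", "n_amplicons": 2,
             "n_amplicons_supported": 2, "status": "true_allele",
             "explained_by": ""}])
        vt = genotyping.VariantTable(
            summary=summ, counts=pd.DataFrame(),
            amplicon_totals=pd.Series(dtype=float),
            amplicon_info=pd.DataFrame())
        calls = pd.DataFrame([{"specimen": "h1", "marker": "DAB3",
                               "variant_id": "v1", "count": 10, "freq": 0.6}])
        meta = pd.DataFrame([{"specimen": "h1", "population": "p",
                              "species": "hybrid"}])
        cat = genotyping.assign_nomenclature(vt, calls, meta)
        assert cat.table["name"].iloc[0].startswith("Pctn-DAB3")

    def test_unobserved_allele_raises_naming_error(self):
        summ = pd.DataFrame([
            {"variant_id": "v1", "sequence": "ACG", "marker": "DAB3",
             "mpaf": 0.6, "mpaf_amplicon": "a", "n_amplicons": 2,
             "n_amplicons_supported": 2, "status": "true_allele",
             "explained_by": ""}])
        vt = genotyping.VariantTable(
            summary=summ, counts=pd.DataFrame(),
            amplicon_totals=pd.Series(dtype=float),
            amplicon_info=pd.DataFrame())
        with pytest.raises(NamingError):
            genotyping.assign_nomenclature(
                vt, pd.DataFrame(columns=["specimen", "variant_id"]),
                pd.DataFrame([{"specimen": "x", "population": "p",
                               "species": "A"}]))

    def test_presence_matrix_row_sums_match_calls(self, genotyping_result):
        pm = genotyping_result.presence
        calls = genotyping_result.calls
        named = calls[calls["variant_id"].isin(
            genotyping_result.catalog.table["variant_id"])]
        per_spec = named.groupby("specimen")["variant_id"].nunique()
        for spec, n in per_spec.items():
            assert pm.matrix.loc[spec].sum() == n
        assert set(np.unique(pm.matrix.to_numpy())) <= {0, 1}

    def test_empty_specimen_retained_as_zero_row(self, genotyping_result,
                                                 cohort):
        meta = pd.concat([cohort["metadata"],
                          pd.DataFrame([{"specimen": "ghost",
                                         "population": "p1",
                                         "species": "A"}])],
                         ignore_index=True)
        pm = genotyping.build_presence_matrix(
            genotyping_result.calls, genotyping_result.catalog, meta)
        assert pm.matrix.loc["ghost"].sum() == 0


class TestSummaries:
    def test_population_summary_arithmetic(self):
        mat = pd.DataFrame([[1, 0], [1, 1]], index=["s1", "s2"],
                           columns=["x", "y"])
        pops = pd.Series(["g", "g"], index=["s1", "s2"])
        catalog = genotyping.AlleleCatalog(table=pd.DataFrame(
            [{"name": "x", "variant_id": "v1", "sequence": "A",
              "lineage": "DAB1", "occurrence": "A"},
             {"name": "y", "variant_id": "v2", "sequence": "C",
              "lineage": "DAB3", "occurrence": "B"}]))
        pm = genotyping.PresenceMatrix(matrix=mat, populations=pops)
        out = genotyping.summarize_population(pm, catalog)
        row = out.iloc[0]
        assert row["n_alleles"] == 2
        assert row["alleles_per_specimen_min"] == 1
        assert row["alleles_per_specimen_max"] == 2
        assert row["alleles_per_specimen_mean"] == pytest.approx(1.5)

    def test_private_alleles_counted_once(self, genotyping_result):
        out = genotyping.summarize_population(genotyping_result.presence,
                                              genotyping_result.catalog)
        mat = genotyping_result.presence.matrix
        pops = genotyping_result.presence.populations
        p1 = set(mat.columns[mat[pops == "p1"].sum() > 0])
        p2 = set(mat.columns[mat[pops == "p2"].sum() > 0])
        expect = {"p1": len(p1 - p2), "p2": len(p2 - p1)}
        got = out.set_index("group")["n_private"].to_dict()
        assert got == expect

    def test_summary_matches_simulated_truth(self, genotyping_result, cohort):
        """End-to-end: per-group allele totals equal the simulated truth."""
        amp = cohort["amplicon_truth"]
        pool = cohort["pool"]
        out = genotyping.summarize_population(genotyping_result.presence,
                                              genotyping_result.catalog)
        for grp in out.itertuples(index=False):
            true_n = amp.loc[amp["population"] == grp.group,
                             "allele_id"].nunique()
            assert grp.n_alleles == true_n
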