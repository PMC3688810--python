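"""NG86 dN/dS against an independent exhaustive-pathway oracle."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from mhcdab import ng86
from mhcdab.errors import SaturationError

BASES = "TCAG"
STOPS = {"TAA", "TAG", "TGA"}
SENSE = [a + b + c for a, b, c in itertools.product(BASES, BASES, BASES)
         if a + b + c not in STOPS]


def _aa(codon):
    return str(Seq(codon).translate())


def oracle_sites(codon):
    """Site counts by direct definition, using Biopython translation."""
    s = 0.0
    for pos in range(3):
        syn = sum(_aa(codon[:pos] + b + codon[pos + 1:]) == _aa(codon)
                  for b in BASES if b != codon[pos])
        s += syn / 3.0
    return 3.0 - s, s


def oracle_paths(c1, c2):
    """Average (nonsyn, syn) differences over minimal stop-free pathways,
    enumerated from scratch."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    blocked = []
    for order in itertools.permutations(diffs):
        cur, nd, sd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
                break
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (results if ok else blocked).append((nd, sd))
    use = results or _all_paths_ignoring_stops(c1, c2, diffs)
    nd = np.mean([x[0] for x in use])
    sd = np.mean([x[1] for x in use])
    return nd, sd


def _all_paths_ignoring_stops(c1, c2, diffs):
    out = []
    for order in itertools.permutations(diffs):
        cur, nd, sd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        out.append((nd, sd))
    return out


def test_sites_match_oracle_for_all_sense_codons():
    for codon in SENSE:
        assert ng86.codon_sites(codon) == pytest.approx(oracle_sites(codon))


def test_pathway_counts_match_oracle_for_all_codon_pairs():
    """Complete enumeration: every pair of sense codons (<= 3 differences)."""
    for c1, c2 in itertools.product(SENSE, SENSE):
        got = ng86.codon_path_differences(c1, c2)
        want = oracle_paths(c1, c2)
        assert got == pytest.approx(want), (c1, c2)


def test_single_third_position_change():
    r = ng86.ng86_pairwise("TTT", "TTA")  # Phe -> Leu, nonsynonymous
    assert r.nd == 1 and r.sd == 0


def test_identical_sequences_zero_rates():
    r = ng86.ng86_pairwise("ATGAAA", "ATGAAA")
    assert r.d_n == 0.0 and r.d_s == 0.0


def test_random_pairs_match_oracle_aggregates():
    rng = np.random.default_rng(3)
    for _ in range(20):
        c1s = [SENSE[i] for i in rng.integers(0, len(SENSE), 30)]
        c2s = [SENSE[i] for i in rng.integers(0, len(SENSE), 30)]
        s1, s2 = "".join(c1s), "".join(c2s)
        try:
            r = ng86.ng86_pairwise(s1, s2)
        except SaturationError:
            continue
        N = S = Nd = Sd = 0.0
        for a, b in zip(c1s, c2s):
            na, sa = oracle_sites(a)
            nb, sb = oracle_sites(b)
            N += (na + nb) / 2
            S += (sa + sb) / 2
            nd, sd = oracle_paths(a, b)
            Nd += nd
            Sd += sd
        assert r.n_sites == pytest.approx(N)
        assert r.nd == pytest.approx(Nd)
        assert r.sd == pytest.approx(Sd)


class TestPartitionRates:
    def test_identical_sequences_all_zero(self):
        seqs = {"a": "ATGAAACCC", "b": "ATGAAACCC", "c": "ATGAAACCC"}
        r = ng86.partition_rates(seqs, "all", bootstrap_reps=50, seed=0)
        assert r.d_n == 0.0 and r.d_s == 0.0

    def test_neutral_simulation_dn_close_to_ds(self):
        from mhcdab import codonmodel as cm
        tree = cm.random_tree(12, seed=4, mean_branch=0.08)
        seqs, _ = cm.simulate_codon_alignment(tree, 120, omegas=[1.0],
                                              weights=[1.0], seed=21)
        r = ng86.partition_rates(seqs, "all", bootstrap_reps=300, seed=1)
        assert abs(r.d_n - r.d_s) < 2 * r.se_diff + 1e-9

    def test_abs_and_nonabs_partitions_cover_alignment(self, pool):
        seqs = {a.id: a.sequence for a in pool.alleles[:6]}
        mask = [p - 1 for p in ng86.BROWN_ABS_BETA1 if p <= 92]
        r_abs = ng86.partition_rates(seqs, "abs", abs_mask=mask,
                                     bootstrap_reps=100, seed=2)
        r_non = ng86.partition_rates(seqs, "non-abs", abs_mask=mask,
                                     bootstrap_reps=100, seed=2)
        assert r_abs.n_codons + r_non.n_codons == 92

    def test_z_test_sign_convention(self):
        r = ng86.NGResult("all", 0.1, 0.1, 0.01, 0.01, 0.0, 0.0, 1.0, 10, 3, 0)
        z, p = ng86.z_test_selection(r)
        assert z == 0.0 and p >= 0.5


def test_mask_loader_roundtrip(tmp_path):
    path = tmp_path / "mask.txt"
    path.write_text("1 5 9\n12\n")
    assert ng86.load_abs_mask(path) == [0, 4, 8, 11]
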