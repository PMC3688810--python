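"""Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction and Z-tests.

Rates are computed for a whole alignment or restricted to a codon
partition -- all sites, antigen-binding sites (ABS) or non-ABS sites -- with
standard errors from a codon-resampling bootstrap and a one-tailed Z test of
positive selection (dN > dS).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from ._rng import substream
from .errors import DataError, SaturationError

BASES = "TCAG"
STOP_CODONS = ("TAA", "TAG", "TGA")

_CODON_TABLE = {}
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(itertools.product(BASES, BASES, BASES)):
    _CODON_TABLE[_a + _b + _c] = _AA[_i]


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper().replace("U", "T")]


# Antigen-binding-site residues of the beta-1 domain inferred from the human
# MHC class II DRB1 crystal structure (peptide-contacting positions,
# amino-acid numbering of the mature beta chain).  Map onto an exon-2 codon
# alignment with an explicit offset; the mask is an input, not a constant of
# the method.
BROWN_ABS_BETA1 = (9, 11, 13, 28, 30, 32, 37, 38, 47, 56, 60, 61, 65, 68, 70,
                   71, 74, 78, 81, 82, 85, 86, 88, 89)


def load_abs_mask(path) -> list:
    """Read 1-based codon indices (whitespace/newline separated) and return
    0-based indices."""
    with open(path) as fh:
        vals = [int(tok) for tok in fh.read().split()]
    if any(v < 1 for v in vals):
        raise DataError("ABS mask indices are 1-based and must be >= 1")
    return [v - 1 for v in vals]


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple:
    """(nonsyn sites, syn sites) for one codon.

    Each position contributes a synonymous fraction equal to the share of
    its three possible changes that leave the amino acid unchanged; changes
    to stop codons count as nonsynonymous.  N + S = 3 per codon.
    """
    if codon in STOP_CODONS:
        raise DataError(f"stop codon {codon} in alignment")
    s = 0.0
    aa = translate_codon(codon)
    for pos in range(3):
        syn = sum(translate_codon(codon[:pos] + b + codon[pos + 1:]) == aa
                  for b in BASES if b != codon[pos])
        s += syn / 3.0
    return 3.0 - s, s


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple:
    """(nonsyn differences, syn differences) between two codons, averaged
    over all minimal mutational pathways; pathways passing through a stop
    codon are excluded (all-blocked pairs fall back to unrestricted
    averaging)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(exclude_stops: bool):
        totals = []
        for order in itertools.permutations(diff_pos):
            cur = c1
            nd = sd = 0
            ok = True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if exclude_stops and nxt in STOP_CODONS:
                    ok = False
                    break
                if translate_codon(cur) == translate_codon(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                totals.append((nd, sd))
        return totals

    totals = walk(exclude_stops=True)
    if not totals:
        totals = walk(exclude_stops=False)
    nd = sum(t[0] for t in totals) / len(totals)
    sd = sum(t[1] for t in totals) / len(totals)
    return nd, sd


def _jc(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 0.75; Jukes-Cantor "
                              "correction undefined")
    return -0.75 * np.log1p(-4.0 / 3.0 * p)


@dataclass
class NGPairwise:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    p_n: float
    p_s: float
    d_n: float
    d_s: float


def _split_codons(seq: str) -> list:
    if len(seq) % 3 != 0:
        raise DataError("sequence length is not a multiple of 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def ng86_pairwise(seq1: str, seq2: str) -> NGPairwise:
    """Nei-Gojobori proportions and Jukes-Cantor distances for one pair.

    Site totals are the average of the two sequences' per-codon site counts;
    multi-hit codons average their difference counts over all minimal
    stop-free mutational pathways.
    """
    if len(seq1) != len(seq2):
        raise DataError("sequences must have equal length")
    c1s, c2s = _split_codons(seq1.upper()), _split_codons(seq2.upper())
    N = S = Nd = Sd = 0.0
    for a, b in zip(c1s, c2s):
        n1, s1 = codon_sites(a)
        n2, s2 = codon_sites(b)
        N += (n1 + n2) / 2
        S += (s1 + s2) / 2
        nd, sd = codon_path_differences(a, b)
        Nd += nd
        Sd += sd
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    return NGPairwise(N, S, Nd, Sd, pN, pS, _jc(pN), _jc(pS))


# ---------------------------------------------------------------------------
# Partitioned rates with bootstrap SEs

@dataclass
class NGResult:
    """Mean pairwise dN and dS over a codon partition, with bootstrap SEs
    and the one-tailed Z test of positive selection."""
    partition: str
    d_n: float
    d_s: float
    se_d_n: float
    se_d_s: float
    se_diff: float
    z: float
    p_value: float
    n_codons: int
    n_pairs: int
    bootstrap_reps: int


def _per_pair_codon_arrays(seqs: dict, codon_idx: np.ndarray):
    names = list(seqs)
    codons = {n: _split_codons(seqs[n].upper()) for n in names}
    pairs = list(itertools.combinations(names, 2))
    C = codon_idx.size
    nd = np.zeros((len(pairs), C))
    sd = np.zeros((len(pairs), C))
    nsit = np.zeros((len(pairs), C))
    ssit = np.zeros((len(pairs), C))
    for k, (a, b) in enumerate(pairs):
        ca, cb = codons[a], codons[b]
        for j, c in enumerate(codon_idx):
            x, y = ca[c], cb[c]
            n1, s1 = codon_sites(x)
            n2, s2 = codon_sites(y)
            nsit[k, j] = (n1 + n2) / 2
            ssit[k, j] = (s1 + s2) / 2
            d = codon_path_differences(x, y)
            nd[k, j], sd[k, j] = d
    return pairs, nd, sd, nsit, ssit


def _mean_rates(nd, sd, nsit, ssit):
    """Mean pairwise dN and dS given per-pair per-codon sums (saturating
    proportions are capped just below 3/4 so bootstrap replicates cannot
    abort)."""
    pN = nd.sum(1) / np.maximum(nsit.sum(1), 1e-12)
    pS = sd.sum(1) / np.maximum(ssit.sum(1), 1e-12)
    pN = np.minimum(pN, 0.7499)
    pS = np.minimum(pS, 0.7499)
    dN = -0.75 * np.log1p(-4.0 / 3.0 * pN)
    dS = -0.75 * np.log1p(-4.0 / 3.0 * pS)
    return dN.mean(), dS.mean()


def partition_rates(seqs: dict, partition: str = "all",
                    abs_mask: list | None = None, bootstrap_reps: int = 1000,
                    seed: int = 0) -> NGResult:
    """Mean pairwise NG86 rates over a codon partition with bootstrap SEs.

    ``partition`` is 'all', 'abs' or 'non-abs'; ``abs_mask`` holds 0-based
    codon indices of the antigen-binding sites (required unless 'all').
    SEs come from resampling partition codons with replacement
    (``bootstrap_reps`` replicates).
    """
    any_seq = next(iter(seqs.values()))
    n_codons_total = len(any_seq) // 3
    if partition == "all":
        idx = np.arange(n_codons_total)
    elif partition in ("abs", "non-abs"):
        if abs_mask is None:
            raise DataError("abs_mask required for ABS partitions")
        mask = np.zeros(n_codons_total, dtype=bool)
        mask[np.asarray(abs_mask, dtype=int)] = True
        idx = np.flatnonzero(mask if partition == "abs" else ~mask)
    else:
        raise ValueError(f"unknown partition {partition!r}")
    if idx.size == 0:
        raise DataError(f"partition {partition!r} is empty")
    pairs, nd, sd, nsit, ssit = _per_pair_codon_arrays(seqs, idx)
    dN, dS = _mean_rates(nd, sd, nsit, ssit)
    rng = substream(seed, f"ng86-bootstrap-{partition}")
    C = idx.size
    reps_dn = np.empty(bootstrap_reps)
    reps_ds = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        cols = rng.integers(0, C, size=C)
        reps_dn[r], reps_ds[r] = _mean_rates(nd[:, cols], sd[:, cols],
                                             nsit[:, cols], ssit[:, cols])
    se_dn = float(reps_dn.std(ddof=1))
    se_ds = float(reps_ds.std(ddof=1))
    se_diff = float((reps_dn - reps_ds).std(ddof=1))
    if se_diff <= 0:
        z, p = 0.0, 1.0
    else:
        z = (dN - dS) / se_diff
        p = float(norm.sf(z))
    return NGResult(partition=partition, d_n=float(dN), d_s=float(dS),
                    se_d_n=se_dn, se_d_s=se_ds, se_diff=se_diff, z=float(z),
                    p_value=p, n_codons=int(C), n_pairs=len(pairs),
                    bootstrap_reps=bootstrap_reps)


def z_test_selection(result: NGResult) -> tuple:
    """(Z, one-tailed p) for the positive-selection test dN > dS."""
    return result.z, result.p_value
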