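"""Detection of candidate gene-conversion fragments between aligned alleles.

A fragment is an aligned pair of segments between two sequences bounded by
either two discordant (mismatching polymorphic) sites, or by one discordant
site and an end of the alignment.  Inner fragments (unusually long runs of
agreement between a sequence pair at polymorphic sites) are evidence of
conversion between ancestors of two sequences in the alignment; outer
fragments (runs of sites where one sequence is unique) point to donors from
outside the alignment.

A run of l matching polymorphic sites in a pair whose per-site mismatch
proportion is d scores -l * ln(1 - d), the log-probability surprise of the
run; a run of l private sites in a sequence whose private-site density is f
scores -l * ln(f).  The weighting makes scores comparable across pairs of
different divergence, so the global test (the maximum score anywhere in the
alignment) is not dominated by near-identical pairs.  Significance comes
from permuting the order of polymorphic columns, which preserves every
pair's divergence, with a Bonferroni correction across pairs for the
pairwise tests.

By default no mismatches are tolerated inside a fragment (the original
program's gscale = 0 convention).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .errors import DataError


@dataclass
class FragmentHit:
    kind: str            # 'inner' or 'outer'
    seq1: str
    seq2: str | None     # None for outer fragments
    start: int           # 1-based alignment column of first site in fragment
    end: int             # 1-based alignment column of last site
    n_poly_sites: int    # polymorphic sites spanned by the run
    score: float         # surprise-weighted run length
    sim_p: float | None = None
    bc_ka_p: float | None = None


def _to_matrix(seqs: dict):
    names = list(seqs)
    lens = {len(s) for s in seqs.values()}
    if len(lens) != 1:
        raise DataError("sequences must be aligned")
    arr = np.frombuffer("".join(seqs[n] for n in names).encode(),
                        dtype="S1").reshape(len(names), -1)
    return names, arr


def polymorphic_columns(seqs: dict) -> np.ndarray:
    """0-based indices of columns with more than one state."""
    _names, arr = _to_matrix(seqs)
    return np.flatnonzero((arr != arr[0]).any(axis=0))


def _max_run(row: np.ndarray) -> int:
    if not row.any():
        return 0
    x = row.astype(np.int32)
    cs = np.cumsum(x)
    reset = np.where(row, 0, cs)
    return int((cs - np.maximum.accumulate(reset)).max())


def _max_runs(M: np.ndarray) -> np.ndarray:
    """Per-row maximal run of True, vectorised."""
    if M.shape[1] == 0:
        return np.zeros(M.shape[0], dtype=np.int32)
    X = M.astype(np.int32)
    cs = np.cumsum(X, axis=1)
    reset = np.where(M, 0, cs)
    return (cs - np.maximum.accumulate(reset, axis=1)).max(axis=1)


def _runs_with_bounds(row: np.ndarray):
    """(start index, end index, length) of each maximal run of True."""
    out = []
    start = None
    for i, v in enumerate(row):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - 1, i - start))
            start = None
    if start is not None:
        out.append((start, len(row) - 1, len(row) - start))
    return out


def _inner_rows(arr: np.ndarray, names: list):
    pairs = list(itertools.combinations(range(len(names)), 2))
    M = np.stack([arr[i] == arr[j] for i, j in pairs]) if pairs else \
        np.zeros((0, arr.shape[1]), bool)
    return pairs, M


def _outer_rows(arr: np.ndarray):
    # site is 'private' to sequence i if its state occurs exactly once there
    n, P = arr.shape
    M = np.zeros((n, P), dtype=bool)
    for j in range(P):
        col = arr[:, j]
        vals, counts = np.unique(col, return_counts=True)
        singles = set(vals[counts == 1])
        if singles:
            M[:, j] = np.isin(col, list(singles))
    return M


def _inner_weights(M: np.ndarray) -> np.ndarray:
    """-ln(match proportion) per pair: the per-site surprise of a match."""
    match = M.mean(axis=1) if M.size else np.zeros(M.shape[0])
    return -np.log(np.clip(match, 1e-12, 1.0))


def _outer_weights(M: np.ndarray) -> np.ndarray:
    """-ln(private-site density) per sequence."""
    dens = M.mean(axis=1) if M.size else np.zeros(M.shape[0])
    return np.where(dens > 0, -np.log(np.clip(dens, 1e-12, 1.0)), 0.0)


def find_inner_fragments(seqs: dict, min_sites: int = 2) -> list:
    """Maximal runs of agreement at polymorphic sites for every sequence
    pair, scored by -l * ln(match proportion) and sorted by score."""
    names, arr = _to_matrix(seqs)
    if len(names) < 3:
        raise DataError("inner fragments need at least 3 sequences")
    poly = polymorphic_columns(seqs)
    if poly.size == 0:
        warnings.warn("no polymorphic sites; no fragments definable")
        return []
    sub = arr[:, poly]
    pairs, M = _inner_rows(sub, names)
    w = _inner_weights(M)
    hits = []
    for (i, j), row, wt in zip(pairs, M, w):
        for s, e, length in _runs_with_bounds(row):
            if length >= min_sites:
                hits.append(FragmentHit(
                    kind="inner", seq1=names[i], seq2=names[j],
                    start=int(poly[s]) + 1, end=int(poly[e]) + 1,
                    n_poly_sites=length, score=float(length * wt)))
    hits.sort(key=lambda h: (-h.score, h.seq1, h.seq2, h.start))
    return hits


def find_outer_fragments(seqs: dict, min_sites: int = 2) -> list:
    """Maximal runs of private (unique-state) polymorphic sites per
    sequence, scored by -l * ln(private-site density)."""
    names, arr = _to_matrix(seqs)
    if len(names) < 3:
        raise DataError("outer fragments need at least 3 sequences")
    poly = polymorphic_columns(seqs)
    if poly.size == 0:
        warnings.warn("no polymorphic sites; no fragments definable")
        return []
    M = _outer_rows(arr[:, poly])
    w = _outer_weights(M)
    hits = []
    for i, (row, wt) in enumerate(zip(M, w)):
        for s, e, length in _runs_with_bounds(row):
            if length >= min_sites:
                hits.append(FragmentHit(
                    kind="outer", seq1=names[i], seq2=None,
                    start=int(poly[s]) + 1, end=int(poly[e]) + 1,
                    n_poly_sites=length, score=float(length * wt)))
    hits.sort(key=lambda h: (-h.score, h.seq1, h.start))
    return hits


@dataclass
class GeneconvResult:
    inner: list
    outer: list
    global_inner_p: float
    global_outer_p: float
    n_perm: int


def permutation_significance(seqs: dict, n_perm: int = 10000, seed: int = 0,
                             min_sites: int = 2) -> GeneconvResult:
    """Permutation significance for inner and outer fragments.

    The order of polymorphic columns is permuted ``n_perm`` times.  Each
    hit's ``sim_p`` is the rank of its score among the permuted global
    maxima (the global test); ``bc_ka_p`` is the rank among that pair's (or
    sequence's) own permuted maxima, Bonferroni-scaled by the number of
    pairs (or sequences).  The minimum achievable p is 1/(n_perm + 1).
    """
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    names, arr = _to_matrix(seqs)
    poly = polymorphic_columns(seqs)
    inner = find_inner_fragments(seqs, min_sites=min_sites)
    outer = find_outer_fragments(seqs, min_sites=min_sites)
    if poly.size == 0:
        return GeneconvResult(inner, outer, 1.0, 1.0, n_perm)
    sub = arr[:, poly]
    pairs, M_in = _inner_rows(sub, names)
    M_out = _outer_rows(sub)
    w_in = _inner_weights(M_in)
    w_out = _outer_weights(M_out)
    rng = substream(seed, "geneconv-perm")
    P = poly.size
    n_pairs = max(len(pairs), 1)
    n_seq = len(names)
    glob_in = np.empty(n_perm)
    glob_out = np.empty(n_perm)
    pair_max = np.empty((n_perm, len(pairs)))
    seq_max = np.empty((n_perm, n_seq))
    for r in range(n_perm):
        perm = rng.permutation(P)
        runs_in = _max_runs(M_in[:, perm]) * w_in
        runs_out = _max_runs(M_out[:, perm]) * w_out
        pair_max[r] = runs_in
        seq_max[r] = runs_out
        glob_in[r] = runs_in.max() if runs_in.size else 0
        glob_out[r] = runs_out.max() if runs_out.size else 0
    pair_index = {(names[i], names[j]): k for k, (i, j) in enumerate(pairs)}
    seq_index = {nm: k for k, nm in enumerate(names)}
    tol = 1e-9
    for h in inner:
        h.sim_p = float((1 + (glob_in >= h.score - tol).sum()) / (n_perm + 1))
        k = pair_index[(h.seq1, h.seq2)]
        p_pair = (1 + (pair_max[:, k] >= h.score - tol).sum()) / (n_perm + 1)
        h.bc_ka_p = float(min(1.0, p_pair * n_pairs))
    for h in outer:
        h.sim_p = float((1 + (glob_out >= h.score - tol).sum()) / (n_perm + 1))
        p_seq = (1 + (seq_max[:, seq_index[h.seq1]] >= h.score - tol).sum()) / (n_perm + 1)
        h.bc_ka_p = float(min(1.0, p_seq * n_seq))
    obs_in = max((h.score for h in inner), default=0.0)
    obs_out = max((h.score for h in outer), default=0.0)
    g_in = float((1 + (glob_in >= obs_in - tol).sum()) / (n_perm + 1)) if inner else 1.0
    g_out = float((1 + (glob_out >= obs_out - tol).sum()) / (n_perm + 1)) if outer else 1.0
    return GeneconvResult(inner=inner, outer=outer, global_inner_p=g_in,
                          global_outer_p=g_out, n_perm=n_perm)
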