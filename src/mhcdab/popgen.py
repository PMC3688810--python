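"""Population structure and diversity from binary MHC presence/absence data
and codominant microsatellite genotypes.

Each validated MHC allele is treated as a dominant binary locus (band
present/absent).  F_st comes in three flavours: a variance-components
estimator on band frequencies for dominant data, a Wright-style estimator on
allele ("haplotype") frequency vectors, and the Weir-Cockerham theta for
codominant microsatellites; all with bootstrap-over-loci confidence
intervals.  Admixture clustering is a Gibbs sampler over latent ancestries
and cluster allele frequencies (dominant data handled by latent genotype
imputation), with Evanno's delta-K for choosing K and label-switching
alignment of replicate runs.  Mantel tests (Spearman, permutation) compare
distance matrices between marker systems.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from scipy.stats import spearmanr

from ._rng import substream, spawn_seed
from .errors import ConfigurationError, DataError


# ---------------------------------------------------------------------------
# F_st estimators

@dataclass
class FstEstimate:
    pop_pair: tuple
    estimator: str     # 'dominant_binary' | 'haplotype_freq' | 'microsat_codominant'
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    bootstrap_reps: int = 0


def _binary_components(x: np.ndarray, labels: np.ndarray):
    """Per-locus variance components (among, within) for binary band data."""
    pops = np.unique(labels)
    r = pops.size
    n_i = np.array([(labels == p).sum() for p in pops], float)
    N = n_i.sum()
    n_c = (N - (n_i ** 2).sum() / N) / (r - 1)
    a_l = np.empty(x.shape[1])
    w_l = np.empty(x.shape[1])
    for l in range(x.shape[1]):
        p_i = np.array([x[labels == p, l].mean() for p in pops])
        p_bar = (n_i * p_i).sum() / N
        msa = (n_i * (p_i - p_bar) ** 2).sum() / (r - 1)
        ssw = (n_i * p_i * (1 - p_i)).sum()
        msw = ssw / (N - r) if N > r else 0.0
        a_l[l] = (msa - msw) / n_c
        w_l[l] = msw
    return a_l, w_l


def fst_binary(matrix: pd.DataFrame, populations: pd.Series,
               pop_pair: tuple | None = None, bootstrap_reps: int = 20000,
               seed: int = 0) -> FstEstimate:
    """Dominant-marker F_st on a binary presence/absence matrix.

    AMOVA-style variance components on band frequencies per locus, ratio of
    sums over loci; 95% CI by resampling loci with replacement.
    """
    labels = populations.reindex(matrix.index).to_numpy()
    if pop_pair is not None:
        keep = np.isin(labels, pop_pair)
        matrix, labels = matrix.loc[keep], labels[keep]
    else:
        pop_pair = tuple(sorted(pd.unique(labels)))
    if min((labels == p).sum() for p in np.unique(labels)) < 2:
        raise DataError("each population needs n >= 2")
    x = matrix.to_numpy(dtype=float)
    poly = x.std(axis=0) > 0
    if not poly.any():
        raise DataError("monomorphic matrix: F_st undefined")
    x = x[:, poly]
    a_l, w_l = _binary_components(x, labels)
    denom = (a_l + w_l).sum()
    if denom == 0:
        raise DataError("zero total variance: F_st undefined")
    theta = a_l.sum() / denom
    ci_low = ci_high = None
    if bootstrap_reps:
        rng = substream(seed, "fst-binary-boot")
        L = a_l.size
        idx = rng.integers(0, L, size=(bootstrap_reps, L))
        num = a_l[idx].sum(axis=1)
        den = (a_l + w_l)[idx].sum(axis=1)
        vals = np.where(den != 0, num / np.where(den == 0, 1, den), 0.0)
        ci_low, ci_high = np.percentile(vals, [2.5, 97.5])
    return FstEstimate(pop_pair=tuple(pop_pair), estimator="dominant_binary",
                       value=float(theta), ci_low=ci_low, ci_high=ci_high,
                       bootstrap_reps=bootstrap_reps)


def fst_haplotype(counts: pd.DataFrame, pop_pair: tuple | None = None
                  ) -> FstEstimate:
    """Wright-style F_st = (H_T - H_S)/H_T from per-population allele
    counts (rows = populations, columns = alleles; counts of individuals
    carrying each allele)."""
    if pop_pair is not None:
        counts = counts.loc[list(pop_pair)]
    else:
        pop_pair = tuple(counts.index)
    c = counts.to_numpy(dtype=float)
    if (c.sum(axis=1) == 0).any():
        raise DataError("a population has zero allele observations")
    p = c / c.sum(axis=1, keepdims=True)
    h_s = (1 - (p ** 2).sum(axis=1)).mean()
    p_bar = p.mean(axis=0)
    h_t = 1 - (p_bar ** 2).sum()
    if h_t == 0:
        raise DataError("no variation: F_st undefined")
    return FstEstimate(pop_pair=tuple(pop_pair), estimator="haplotype_freq",
                       value=float((h_t - h_s) / h_t))


def _genotype_array(genotypes: pd.DataFrame, loci: list):
    """(n, L, 2) integer allele array from a two-column-per-locus table."""
    cols = []
    for locus in loci:
        cols.append(genotypes[[f"{locus}_1", f"{locus}_2"]].to_numpy())
    return np.stack(cols, axis=1)


def _wc_components(geno: np.ndarray, labels: np.ndarray):
    """Weir-Cockerham (1984) per-locus variance components a, b, c summed
    over alleles; geno is (n, L, 2)."""
    pops = np.unique(labels)
    r = pops.size
    n_i = np.array([(labels == p).sum() for p in pops], float)
    n_bar = n_i.mean()
    n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
    L = geno.shape[1]
    a_l = np.zeros(L)
    b_l = np.zeros(L)
    c_l = np.zeros(L)
    for l in range(L):
        alleles = np.unique(geno[:, l, :])
        for al in alleles:
            p_i = np.empty(r)
            h_i = np.empty(r)
            for k, p in enumerate(pops):
                g = geno[labels == p, l, :]
                p_i[k] = (g == al).mean()
                h_i[k] = ((g == al).sum(axis=1) == 1).mean()
            p_bar = (n_i * p_i).sum() / n_i.sum()
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / n_i.sum()
            a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar)
                                       - s2 * (r - 1) / r - h_bar / 4)
                                 / (n_bar - 1))
            b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                         - s2 * (r - 1) / r
                                         - h_bar * (2 * n_bar - 1) / (4 * n_bar))
            c = h_bar / 2
            a_l[l] += a
            b_l[l] += b
            c_l[l] += c
    return a_l, b_l, c_l


def fst_microsat(genotypes: pd.DataFrame, loci: list,
                 pop_pair: tuple | None = None, bootstrap_reps: int = 20000,
                 seed: int = 0) -> FstEstimate:
    """Weir-Cockerham theta for codominant diploid genotypes, with
    bootstrap-over-loci 95% CI."""
    labels = genotypes["population"].to_numpy()
    if pop_pair is not None:
        keep = np.isin(labels, pop_pair)
        genotypes, labels = genotypes.loc[keep], labels[keep]
    else:
        pop_pair = tuple(sorted(pd.unique(labels)))
    geno = _genotype_array(genotypes, loci)
    a_l, b_l, c_l = _wc_components(geno, labels)
    denom = (a_l + b_l + c_l).sum()
    if denom == 0:
        raise DataError("no variation: F_st undefined")
    theta = a_l.sum() / denom
    ci_low = ci_high = None
    if bootstrap_reps:
        rng = substream(seed, "fst-wc-boot")
        L = a_l.size
        idx = rng.integers(0, L, size=(bootstrap_reps, L))
        den = (a_l + b_l + c_l)[idx].sum(axis=1)
        vals = a_l[idx].sum(axis=1) / np.where(den == 0, np.nan, den)
        ci_low, ci_high = np.nanpercentile(vals, [2.5, 97.5])
    return FstEstimate(pop_pair=tuple(pop_pair), estimator="microsat_codominant",
                       value=float(theta), ci_low=ci_low, ci_high=ci_high,
                       bootstrap_reps=bootstrap_reps)


def pairwise_fst(estimator, items, min_n: int = 9, **kwargs) -> pd.DataFrame:
    """All pairwise F_st values between populations with n > ``min_n - 1``.

    ``estimator`` is one of the fst_* callables; ``items`` supplies its
    per-call positional data.  Returns a long-form table.
    """
    rows = []
    for pa, pb in itertools.combinations(items, 2):
        est = estimator(pop_pair=(pa, pb), **kwargs)
        rows.append({"pop1": pa, "pop2": pb, "fst": est.value,
                     "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(rows)


def fst_to_distance_matrix(table: pd.DataFrame, pops: list) -> np.ndarray:
    out = np.zeros((len(pops), len(pops)))
    index = {p: i for i, p in enumerate(pops)}
    for r in table.itertuples(index=False):
        i, j = index[r.pop1], index[r.pop2]
        out[i, j] = out[j, i] = max(r.fst, 0.0)
    return out


# ---------------------------------------------------------------------------
# Admixture clustering (STRUCTURE-like Gibbs sampler)

@dataclass
class QMatrix:
    """Posterior-mean ancestry proportions and the likelihood trace of one
    run."""
    q: pd.DataFrame          # individuals x K
    loglik_trace: np.ndarray
    k: int

    @property
    def mean_loglik(self) -> float:
        return float(self.loglik_trace.mean())

    @property
    def ln_prob(self) -> float:
        """Model log-probability estimate: mean of the likelihood trace
        minus half its variance (the usual harmonic-style deviance
        correction; penalises over-clustered runs whose chains mix over
        redundant configurations)."""
        return float(self.loglik_trace.mean() - self.loglik_trace.var() / 2.0)


def _sample_categorical(rng, weights: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw from an (n, K) weight matrix."""
    cdf = np.cumsum(weights, axis=1)
    cdf /= cdf[:, -1:]
    u = rng.random((weights.shape[0], 1))
    return (u > cdf).sum(axis=1)


def admixture_infer(data, K: int, n_sweeps: int = 2000, burn_in: int = 500,
                    seed: int = 0, data_type: str = "dominant",
                    alpha: float = 1.0, loci: list | None = None) -> QMatrix:
    """Gibbs sampler for the admixture model.

    dominant: ``data`` is a binary individuals x loci DataFrame
    (presence/absence); the two latent diploid copies per locus are imputed
    under the constraint that a band is present iff at least one copy
    carries the band allele.  codominant: ``data`` is a genotype table with
    two columns per locus (``loci`` names them).  Cluster allele frequencies
    take conjugate Beta/Dirichlet updates; individual ancestry vectors q get
    Dirichlet(alpha + counts) updates.  Returns the posterior-mean q and the
    data log-likelihood trace (used by Evanno's delta-K).
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    if n_sweeps <= burn_in:
        raise ConfigurationError("n_sweeps must exceed burn_in")
    rng = substream(seed, f"admixture-K{K}")
    if data_type == "dominant":
        X = data.to_numpy(dtype=int)
        individuals = list(data.index)
        N, L = X.shape
        q = np.full((N, K), 1.0 / K)
        p = rng.random((K, L)) * 0.8 + 0.1  # band-allele frequency per cluster
        q_sum = np.zeros((N, K))
        trace = []
        ii, ll = np.nonzero(X)          # band-present cells
        ii0, ll0 = np.nonzero(X == 0)
        a_combo = np.array([(1, 0), (0, 1), (1, 1)])
        combos = [(z1, z2, a1, a2) for z1 in range(K) for z2 in range(K)
                  for a1, a2 in a_combo]
        for sweep in range(n_sweeps):
            count1 = np.zeros((K, L))
            count0 = np.zeros((K, L))
            zcnt = np.zeros((N, K))
            # band-absent cells: two independent copies, allele 0
            if ii0.size:
                w = q[ii0] * (1 - p[:, ll0].T)  # (cells, K)
                for _copy in range(2):
                    z = _sample_categorical(rng, w)
                    np.add.at(count0, (z, ll0), 1)
                    np.add.at(zcnt, (ii0, z), 1)
            # band-present cells: joint draw of both copies
            if ii.size:
                W = np.empty((ii.size, len(combos)))
                for c, (z1, z2, a1, a2) in enumerate(combos):
                    f1 = p[z1, ll] if a1 else 1 - p[z1, ll]
                    f2 = p[z2, ll] if a2 else 1 - p[z2, ll]
                    W[:, c] = q[ii, z1] * f1 * q[ii, z2] * f2
                choice = _sample_categorical(rng, W)
                for c, (z1, z2, a1, a2) in enumerate(combos):
                    cells = choice == c
                    if not cells.any():
                        continue
                    lc = ll[cells]
                    np.add.at(count1 if a1 else count0, (np.full(lc.size, z1), lc), 1)
                    np.add.at(count1 if a2 else count0, (np.full(lc.size, z2), lc), 1)
                    ic = ii[cells]
                    np.add.at(zcnt, (ic, np.full(ic.size, z1)), 1)
                    np.add.at(zcnt, (ic, np.full(ic.size, z2)), 1)
            p = rng.beta(1 + count1, 1 + count0)
            q = _dirichlet_rows(rng, alpha + zcnt)
            if sweep >= burn_in:
                q_sum += q
                # marginal band probability per cell
                no_band = (q @ (1 - p)) ** 2
                prob = np.where(X == 1, 1 - no_band, no_band)
                trace.append(float(np.log(np.maximum(prob, 1e-300)).sum()))
        q_mean = q_sum / (n_sweeps - burn_in)
    elif data_type == "codominant":
        if loci is None:
            raise ConfigurationError("codominant data needs the loci list")
        geno = _genotype_array(data, loci)  # (N, L, 2)
        individuals = list(data["individual"]) if "individual" in data else \
            list(data.index)
        N, L, _ = geno.shape
        codes = []
        n_alleles = []
        for l in range(L):
            vals = np.unique(geno[:, l, :])
            lut = {v: i for i, v in enumerate(vals)}
            codes.append(np.vectorize(lut.get)(geno[:, l, :]))
            n_alleles.append(len(vals))
        q = np.full((N, K), 1.0 / K)
        p = [_dirichlet_rows(rng, np.ones((K, n_alleles[l]))) for l in range(L)]
        q_sum = np.zeros((N, K))
        trace = []
        for sweep in range(n_sweeps):
            zcnt = np.zeros((N, K))
            counts = [np.zeros((K, n_alleles[l])) for l in range(L)]
            for l in range(L):
                for copy in range(2):
                    al = codes[l][:, copy]
                    w = q * p[l][:, al].T
                    z = _sample_categorical(rng, w)
                    np.add.at(counts[l], (z, al), 1)
                    np.add.at(zcnt, (np.arange(N), z), 1)
            for l in range(L):
                p[l] = _dirichlet_rows(rng, 1.0 + counts[l])
            q = _dirichlet_rows(rng, alpha + zcnt)
            if sweep >= burn_in:
                q_sum += q
                ll_val = 0.0
                for l in range(L):
                    for copy in range(2):
                        al = codes[l][:, copy]
                        ll_val += float(np.log(np.maximum(
                            (q * p[l][:, al].T).sum(axis=1), 1e-300)).sum())
                trace.append(ll_val)
        q_mean = q_sum / (n_sweeps - burn_in)
    else:
        raise ConfigurationError(f"unknown data_type {data_type!r}")
    if not np.all(np.isfinite(trace)):
        raise DataError("chain diverged: non-finite likelihood")
    qdf = pd.DataFrame(q_mean, index=individuals,
                       columns=[f"cluster{k + 1}" for k in range(K)])
    return QMatrix(q=qdf, loglik_trace=np.asarray(trace), k=K)


def _dirichlet_rows(rng, alpha: np.ndarray) -> np.ndarray:
    g = rng.gamma(np.maximum(alpha, 1e-6))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=1, keepdims=True)


@dataclass
class DeltaKTable:
    table: pd.DataFrame  # K, mean_loglik, sd_loglik, delta_k

    @property
    def best_k(self) -> int:
        t = self.table.dropna(subset=["delta_k"])
        return int(t.loc[t["delta_k"].idxmax(), "K"])


def evanno_delta_k(runs_by_k: dict) -> DeltaKTable:
    """Evanno's delta-K from replicate run log-likelihoods per K.

    ``runs_by_k`` maps K -> list of per-run mean log-likelihoods (>= 2 runs
    for at least the interior K values).  delta K = mean|L(K+1) - 2 L(K) +
    L(K-1)| / SD[L(K)], defined for interior K only.
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3:
        raise DataError("delta-K needs at least 3 consecutive K values")
    mean_l = {k: float(np.mean(runs_by_k[k])) for k in ks}
    sd_l = {k: float(np.std(runs_by_k[k], ddof=1)) if len(runs_by_k[k]) > 1
            else 0.0 for k in ks}
    rows = []
    for i, k in enumerate(ks):
        dk = np.nan
        if 0 < i < len(ks) - 1:
            num = abs(mean_l[ks[i + 1]] - 2 * mean_l[k] + mean_l[ks[i - 1]])
            if sd_l[k] == 0:
                warnings.warn(f"zero SD at K={k}; delta-K infinite")
                dk = np.inf
            else:
                dk = num / sd_l[k]
        rows.append({"K": k, "mean_loglik": mean_l[k], "sd_loglik": sd_l[k],
                     "delta_k": dk})
    return DeltaKTable(table=pd.DataFrame(rows))


def align_replicate_runs(qmatrices: list) -> QMatrix:
    """Align cluster labels across replicate runs (CLUMPP-style) and return
    the consensus (mean of aligned q)."""
    if not qmatrices:
        raise DataError("no runs to align")
    k = qmatrices[0].k
    inds = list(qmatrices[0].q.index)
    for qm in qmatrices[1:]:
        if qm.k != k or list(qm.q.index) != inds:
            raise DataError("runs must share K and individuals")
    ref = qmatrices[0].q.to_numpy()
    acc = ref.copy()
    for qm in qmatrices[1:]:
        m = qm.q.to_numpy()
        # similarity between reference clusters and this run's clusters
        sim = ref.T @ m
        _ri, ci = linear_sum_assignment(-sim)
        acc += m[:, ci]
    cons = acc / len(qmatrices)
    cons /= cons.sum(axis=1, keepdims=True)
    qdf = pd.DataFrame(cons, index=inds,
                       columns=[f"cluster{j + 1}" for j in range(k)])
    traces = np.concatenate([qm.loglik_trace for qm in qmatrices])
    return QMatrix(q=qdf, loglik_trace=traces, k=k)


# ---------------------------------------------------------------------------
# Mantel test and Spearman correlations

def mantel_test(d1: np.ndarray, d2: np.ndarray, labels: list,
                n_perm: int = 10000, method: str = "spearman",
                seed: int = 0, alternative: str = "two-sided") -> tuple:
    """(r, p) Mantel test between two distance matrices (same labels),
    permuting rows/columns jointly.  Delegates to scikit-bio."""
    from skbio import DistanceMatrix
    from skbio.stats.distance import mantel
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    if d1.shape[0] < 3:
        raise DataError("Mantel test needs at least 3 objects")
    for d in (d1, d2):
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise DataError("inputs must be symmetric with zero diagonal")
    np.random.seed(spawn_seed(seed, "mantel"))
    dm1 = DistanceMatrix(d1, ids=labels)
    dm2 = DistanceMatrix(d2, ids=labels)
    res = mantel(dm1, dm2, method=method, permutations=n_perm,
                 alternative=alternative)
    try:
        r, p = float(res[0]), float(res[1])
    except (TypeError, KeyError):  # newer scikit-bio returns a dataframe-like
        r, p = float(res["statistic"]), float(res["p-value"])
    return r, p


def spearman_correlation(x, y) -> tuple:
    """(R, p) Spearman rank correlation with tie handling."""
    r, p = spearmanr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Diversity summaries

def allelic_richness(genotypes: pd.DataFrame, loci: list, floor: int = 9
                     ) -> pd.Series:
    """Rarefied allelic richness per population (mean over loci of the
    expected allele count in a standard sample of gene copies).

    The rarefaction size is twice the smallest population at or above the
    ``floor``; populations below the floor are reported as NaN (not
    evaluated)."""
    sizes = genotypes.groupby("population").size()
    eligible = sizes[sizes >= floor]
    if eligible.empty:
        raise DataError("no population reaches the rarefaction floor")
    g = 2 * int(eligible.min())
    out = {}
    for pop, grp in genotypes.groupby("population"):
        if len(grp) < floor:
            out[pop] = np.nan
            continue
        rich = []
        for locus in loci:
            copies = np.concatenate([grp[f"{locus}_1"], grp[f"{locus}_2"]])
            N = copies.size
            vals, counts = np.unique(copies, return_counts=True)
            # expected number of alleles in a subsample of g copies
            def log_c(n, k):
                return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            pr_absent = np.where(N - counts >= g,
                                 np.exp(log_c(N - counts, g) - log_c(N, g)),
                                 0.0)
            rich.append((1 - pr_absent).sum())
        out[pop] = float(np.mean(rich))
    return pd.Series(out, name="allelic_richness")


def microsat_diversity(genotypes: pd.DataFrame, loci: list, floor: int = 9
                       ) -> pd.DataFrame:
    """Per-population N_a (mean alleles/locus), private alleles and rarefied
    allelic richness."""
    pops = list(pd.unique(genotypes["population"]))
    allele_sets = {(pop, locus): set(
        np.concatenate([genotypes.loc[genotypes["population"] == pop, f"{locus}_1"],
                        genotypes.loc[genotypes["population"] == pop, f"{locus}_2"]]))
        for pop in pops for locus in loci}
    rows = []
    rich = allelic_richness(genotypes, loci, floor=floor)
    for pop in pops:
        n_a = np.mean([len(allele_sets[(pop, l)]) for l in loci])
        private = 0
        for l in loci:
            others = set().union(*(allele_sets[(p, l)] for p in pops if p != pop))
            private += len(allele_sets[(pop, l)] - others)
        rows.append({"population": pop, "n": int((genotypes["population"] == pop).sum()),
                     "n_a": float(n_a), "private_alleles": int(private),
                     "allelic_richness": float(rich[pop])})
    return pd.DataFrame(rows)


def diversity_and_correlation(presence: pd.DataFrame, populations: pd.Series,
                              genotypes: pd.DataFrame, loci: list,
                              floor: int = 9):
    """Population-level diversity for both marker systems plus the Spearman
    correlation between microsatellite allelic richness and the mean number
    of MHC alleles per specimen."""
    micro = microsat_diversity(genotypes, loci, floor=floor)
    mhc_mean = presence.sum(axis=1).groupby(populations).mean()
    micro = micro.set_index("population")
    table = micro.join(mhc_mean.rename("mhc_alleles_per_specimen"), how="inner")
    valid = table.dropna(subset=["allelic_richness", "mhc_alleles_per_specimen"])
    if len(valid) >= 3:
        r, p = spearman_correlation(valid["allelic_richness"],
                                    valid["mhc_alleles_per_specimen"])
    else:
        r, p = np.nan, np.nan
    return table.reset_index(), (r, p)
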