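"""Maximum-likelihood codon site models of selection (M0-M8) with LRTs and
Bayes empirical Bayes identification of positively selected sites.

The substitution process is a 61-state reversible codon model: the rate from
codon i to codon j is nonzero only for single-nucleotide changes and equals
pi_j, times kappa for transitions, times omega for nonsynonymous changes
(the Goldman-Yang parameterisation with F3x4 codon frequencies by default).
Site models place omega in a mixture of site classes:

* M0  one ratio            omega
* M1a nearly neutral       (p0, omega0 < 1), (p1, 1)
* M2a positive selection   (p0, omega0 < 1), (p1, 1), (p2, omega2 > 1)
* M3  discrete, 3 classes  (p0, omega0), (p1, omega1), (p2, omega2)
* M7  beta                 10 equal-probability beta(p, q) categories
* M8  beta & omega         beta categories (weight p0) + spike omega_s > 1

Likelihoods are maximised over model parameters, kappa and a global scale on
the input branch lengths; nested pairs (M0/M3, M1a/M2a, M7/M8) form
likelihood-ratio tests of positive selection, and the Bayes empirical Bayes
(BEB) scheme integrates the posterior probability of the positive-selection
class per codon over a parameter grid, accounting for uncertainty in the
mixture parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from ._rng import substream
from .errors import ConfigurationError, ConvergenceError, DataError

BASES = "TCAG"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(a + b + c for a, b, c in itertools.product(BASES, BASES, BASES)
                     if a + b + c not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_STATES = 61

_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ALL = [a + b + c for a, b, c in itertools.product(BASES, BASES, BASES)]
AMINO = {c: _AA[i] for i, c in enumerate(_ALL)}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

# single-nucleotide neighbour pairs: indices, transition flag, nonsyn flag
_PI, _PJ, _TS, _NS = [], [], [], []
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [(a, b) for a, b in zip(_ci, _cj) if a != b]
        if len(diffs) == 1:
            _PI.append(_i)
            _PJ.append(_j)
            _TS.append(diffs[0] in _TRANSITIONS)
            _NS.append(AMINO[_ci] != AMINO[_cj])
_PI = np.asarray(_PI)
_PJ = np.asarray(_PJ)
_TS = np.asarray(_TS)
_NS = np.asarray(_NS)


# ---------------------------------------------------------------------------
# Alignment container

@dataclass
class CodonAlignment:
    """In-frame codon alignment encoded as sense-codon state indices."""
    taxa: list
    codons: np.ndarray  # (n_taxa, n_codons) int
    abs_mask: list = field(default_factory=list)  # 0-based codon indices

    @classmethod
    def from_sequences(cls, seqs: dict, abs_mask=None) -> "CodonAlignment":
        taxa = list(seqs)
        lens = {len(s) for s in seqs.values()}
        if len(lens) != 1 or next(iter(lens)) % 3 != 0:
            raise DataError("sequences must be aligned and a multiple of 3")
        rows = []
        for t in taxa:
            s = seqs[t].upper().replace("U", "T")
            row = []
            for i in range(0, len(s), 3):
                codon = s[i:i + 3]
                if codon in STOP_CODONS:
                    raise DataError(f"internal stop codon in {t} at codon {i // 3 + 1}")
                if codon not in CODON_INDEX:
                    raise DataError(f"unrecognised codon {codon!r} in {t}")
                row.append(CODON_INDEX[codon])
            rows.append(row)
        return cls(taxa=taxa, codons=np.asarray(rows, dtype=np.int16),
                   abs_mask=list(abs_mask or []))

    @classmethod
    def from_fasta(cls, path, abs_mask=None) -> "CodonAlignment":
        from Bio import SeqIO
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls.from_sequences(seqs, abs_mask=abs_mask)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def patterns(self):
        cols, inverse, counts = np.unique(self.codons, axis=1,
                                          return_inverse=True,
                                          return_counts=True)
        return cols, counts.astype(float), inverse

    def f3x4(self) -> np.ndarray:
        """F3x4 codon frequencies: products of empirical positional
        nucleotide frequencies over sense codons, renormalised."""
        pos_freq = np.zeros((3, 4))
        flat = self.codons.ravel()
        for ci, codon in enumerate(SENSE_CODONS):
            n = int((flat == ci).sum())
            for pos in range(3):
                pos_freq[pos, BASES.index(codon[pos])] += n
        pos_freq = (pos_freq + 0.1) / (pos_freq + 0.1).sum(axis=1, keepdims=True)
        pi = np.array([pos_freq[0, BASES.index(c[0])]
                       * pos_freq[1, BASES.index(c[1])]
                       * pos_freq[2, BASES.index(c[2])] for c in SENSE_CODONS])
        return pi / pi.sum()


# ---------------------------------------------------------------------------
# Tree handling

class _Tree:
    """Postorder arrays extracted from a newick string (rooted arbitrarily;
    the process is reversible, so the likelihood is root-invariant)."""

    def __init__(self, newick: str, taxa: list):
        t = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(t.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): k for k, nd in enumerate(nodes)}
        self.children: list = [[] for _ in nodes]
        self.lengths = np.zeros(self.n_nodes)
        self.leaf_row = np.full(self.n_nodes, -1, dtype=int)
        taxon_row = {name: r for r, name in enumerate(taxa)}
        leaves_seen = set()
        for k, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.lengths[k] = max(nd.edge.length or 0.0, 0.0)
            for ch in nd.child_nodes():
                self.children[k].append(index[id(ch)])
            if nd.is_leaf():
                label = nd.taxon.label.replace(" ", "_") if nd.taxon else None
                if label not in taxon_row:
                    raise DataError(f"tree leaf {label!r} not in alignment")
                self.leaf_row[k] = taxon_row[label]
                leaves_seen.add(label)
        if leaves_seen != set(taxa):
            missing = set(taxa) - leaves_seen
            raise DataError(f"alignment taxa missing from tree: {sorted(missing)}")
        self.root = self.n_nodes - 1


# ---------------------------------------------------------------------------
# Rate matrix and likelihood

def _build_q(pi: np.ndarray, kappa: float, omega: float):
    """Unnormalised GY codon rate matrix; returns (Q, mean rate)."""
    Q = np.zeros((N_STATES, N_STATES))
    rates = pi[_PJ] * np.where(_TS, kappa, 1.0) * np.where(_NS, omega, 1.0)
    Q[_PI, _PJ] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = float(-(pi * np.diag(Q)).sum())
    return Q, mean_rate


def _eig(pi, kappa, omega):
    Q, rate = _build_q(pi, kappa, omega)
    sq = np.sqrt(pi)
    A = (Q * sq[:, None]) / sq[None, :]
    A = 0.5 * (A + A.T)  # symmetric up to rounding
    w, U = np.linalg.eigh(A)
    V = U / sq[:, None]
    Vinv = U.T * sq[None, :]
    return w, V, Vinv, rate


def _class_transition_mats(pi, kappa, omegas, weights, lengths, scale,
                           eig_fn=None):
    """P matrices (n_class, n_branch, 61, 61); branch lengths are expected
    substitutions/codon under the mixture (mixture-average normalisation)."""
    eig_fn = eig_fn or (lambda k, om: _eig(pi, k, om))
    eigs = [eig_fn(kappa, om) for om in omegas]
    norm = sum(wt * e[3] for wt, e in zip(weights, eigs))
    norm = max(norm, 1e-12)
    t = lengths * scale / norm
    P = np.empty((len(omegas), lengths.size, N_STATES, N_STATES))
    for k, (w, V, Vinv, _r) in enumerate(eigs):
        E = np.exp(np.outer(t, w))  # (n_branch, 61)
        P[k] = np.einsum("ik,bk,kj->bij", V, E, Vinv)
    np.clip(P, 1e-300, None, out=P)
    return P


def _site_class_loglik(tree: _Tree, pattern_cols: np.ndarray, pi, kappa,
                       omegas, weights, scale, eig_fn=None) -> np.ndarray:
    """Per-class per-pattern log-likelihoods, shape (n_class, n_patterns)."""
    K = len(omegas)
    P = _class_transition_mats(pi, kappa, np.asarray(omegas, float),
                               np.asarray(weights, float), tree.lengths, scale,
                               eig_fn=eig_fn)
    n_pat = pattern_cols.shape[1]
    partial = {}
    logscale = {}
    for node in range(tree.n_nodes):
        if tree.leaf_row[node] >= 0:
            continue
        prod = np.ones((K, n_pat, N_STATES))
        lsc = np.zeros((K, n_pat))
        for ch in tree.children[node]:
            if tree.leaf_row[ch] >= 0:
                codons = pattern_cols[tree.leaf_row[ch]]
                msg = P[:, ch, :, codons]          # (n_pat, K, 61)
                msg = np.transpose(msg, (1, 0, 2))  # (K, n_pat, 61)
            else:
                msg = np.einsum("kpj,kij->kpi", partial.pop(ch), P[:, ch])
                lsc += logscale.pop(ch)
            prod *= msg
        mx = prod.max(axis=2, keepdims=True)
        mx = np.maximum(mx, 1e-300)
        prod /= mx
        lsc += np.log(mx[:, :, 0])
        partial[node] = prod
        logscale[node] = lsc
    root = tree.root
    lik = np.einsum("kpi,i->kp", partial[root], pi)
    return np.log(np.maximum(lik, 1e-300)) + logscale[root]


# ---------------------------------------------------------------------------
# Model specifications

N_BETA_CATS = 10


def _beta_omegas(p, q, ncat=N_BETA_CATS):
    qs = (2 * np.arange(ncat) + 1) / (2 * ncat)
    return np.clip(beta_dist.ppf(qs, p, q), 1e-8, 1 - 1e-8)


def _mixture(model: str, th: dict):
    """(omegas, weights) for a model's parameter dict."""
    if model == "M0":
        return [th["omega"]], [1.0]
    if model == "M1a":
        return [th["omega0"], 1.0], [th["p0"], 1 - th["p0"]]
    if model == "M2a":
        p0, p1 = th["p0"], (1 - th["p0"]) * th["p1f"]
        return ([th["omega0"], 1.0, th["omega2"]],
                [p0, p1, 1 - p0 - p1])
    if model == "M3":
        p0, p1 = th["p0"], (1 - th["p0"]) * th["p1f"]
        return ([th["omega0"], th["omega1"], th["omega2"]],
                [p0, p1, 1 - p0 - p1])
    if model == "M7":
        oms = _beta_omegas(th["p"], th["q"])
        return list(oms), [1.0 / N_BETA_CATS] * N_BETA_CATS
    if model == "M8":
        oms = list(_beta_omegas(th["p"], th["q"])) + [th["omega_s"]]
        w = [th["p0"] / N_BETA_CATS] * N_BETA_CATS + [1 - th["p0"]]
        return oms, w
    raise ConfigurationError(f"unknown model {model!r}")


_EPS = 1e-6
MODEL_SPECS = {
    # name: (param names, bounds, default init, number of free omega-structure
    # parameters -- the count used for LRT degrees of freedom)
    "M0": (["omega"], [(1e-4, 99.0)], [0.5], 1),
    "M1a": (["p0", "omega0"], [(_EPS, 1 - _EPS), (1e-4, 1 - 1e-4)], [0.7, 0.2], 1),
    "M2a": (["p0", "p1f", "omega0", "omega2"],
            [(_EPS, 1 - _EPS), (_EPS, 1 - _EPS), (1e-4, 1 - 1e-4), (1.0, 99.0)],
            [0.6, 0.7, 0.2, 1.5], 3),
    "M3": (["p0", "p1f", "omega0", "omega1", "omega2"],
           [(_EPS, 1 - _EPS), (_EPS, 1 - _EPS), (1e-4, 99.0), (1e-4, 99.0),
            (1e-4, 99.0)],
           [0.5, 0.6, 0.1, 1.0, 5.0], 5),
    "M7": (["p", "q"], [(0.005, 99.0), (0.005, 99.0)], [0.5, 0.5], 2),
    "M8": (["p0", "p", "q", "omega_s"],
           [(_EPS, 1 - _EPS), (0.005, 99.0), (0.005, 99.0), (1.0, 99.0)],
           [0.85, 0.5, 0.5, 3.0], 4),
}

LRT_PAIRS = {("M0", "M3"), ("M1a", "M2a"), ("M7", "M8")}


def warm_start_from(null_fit) -> dict:
    """An alternative-model starting point sitting at (essentially) the
    fitted null: M2a from M1a (spike weight -> 0 at omega2 just above 1),
    M8 from M7, M3 from M0."""
    p = null_fit.params
    if null_fit.model == "M1a":
        return {"kappa": p["kappa"], "scale": p.get("scale", 1.0),
                "p0": p["p0"], "omega0": p["omega0"], "p1f": 1 - 1e-4,
                "omega2": 1.0 + 1e-3}
    if null_fit.model == "M7":
        return {"kappa": p["kappa"], "scale": p.get("scale", 1.0),
                "p": p["p"], "q": p["q"], "p0": 1 - 1e-4, "omega_s": 1.0 + 1e-3}
    if null_fit.model == "M0":
        return {"kappa": p["kappa"], "scale": p.get("scale", 1.0),
                "p0": 1 - 2e-4, "p1f": 0.5,
                "omega0": p["omega"], "omega1": p["omega"],
                "omega2": p["omega"]}
    raise ConfigurationError(f"no warm start defined from {null_fit.model}")


# ---------------------------------------------------------------------------
# Model / Results

class CodonSiteModel:
    """ML codon site model bound to an alignment and a fixed tree topology.

    Parameters
    ----------
    alignment : CodonAlignment or dict of name -> nucleotide sequence
    tree : newick string with branch lengths (e.g. the NJ tree)
    model : one of M0, M1a, M2a, M3, M7, M8
    codon_freq : 'F3x4' (default) or 'equal'
    branch_mode : 'scale' optimises one global factor on the input branch
        lengths; 'fixed' keeps them as given.
    """

    def __init__(self, alignment, tree: str, model: str = "M0",
                 codon_freq: str = "F3x4", branch_mode: str = "scale"):
        if model not in MODEL_SPECS:
            raise ConfigurationError(f"unknown model {model!r}")
        if isinstance(alignment, dict):
            alignment = CodonAlignment.from_sequences(alignment)
        self.alignment = alignment
        self.model = model
        self.tree_newick = tree
        self._tree = _Tree(tree, alignment.taxa)
        self.pi = (alignment.f3x4() if codon_freq == "F3x4"
                   else np.full(N_STATES, 1.0 / N_STATES))
        self.branch_mode = branch_mode
        cols, counts, inverse = alignment.patterns()
        self._cols, self._counts, self._inverse = cols, counts, inverse
        self._eig_cache: dict = {}

    def _eig_cached(self, kappa: float, omega: float):
        key = (round(kappa, 12), round(omega, 12))
        hit = self._eig_cache.get(key)
        if hit is None:
            if len(self._eig_cache) > 512:
                self._eig_cache.clear()
            hit = self._eig_cache[key] = _eig(self.pi, kappa, omega)
        return hit

    # -- likelihood ---------------------------------------------------------

    def class_loglik(self, params: dict) -> np.ndarray:
        omegas, weights = _mixture(self.model, params)
        scale = params.get("scale", 1.0)
        return _site_class_loglik(self._tree, self._cols, self.pi,
                                  params["kappa"], omegas, weights, scale,
                                  eig_fn=self._eig_cached)

    def loglike(self, params: dict) -> float:
        """Log-likelihood at the given parameter dict (must contain kappa
        and, for branch_mode='scale', scale)."""
        omegas, weights = _mixture(self.model, params)
        lf = self.class_loglik(params)
        lw = np.log(np.maximum(np.asarray(weights, float), 1e-300))
        site = logsumexp(lf + lw[:, None], axis=0)
        return float((site * self._counts).sum())

    # -- fitting ------------------------------------------------------------

    def _pack(self, params: dict):
        names, _b, _x0, _nf = MODEL_SPECS[self.model]
        x = [params["kappa"]]
        if self.branch_mode == "scale":
            x.append(params["scale"])
        x.extend(params[n] for n in names)
        return np.asarray(x, float)

    def _unpack(self, x):
        names, _b, _x0, _nf = MODEL_SPECS[self.model]
        params = {"kappa": float(x[0])}
        k = 1
        if self.branch_mode == "scale":
            params["scale"] = float(x[1])
            k = 2
        for i, n in enumerate(names):
            params[n] = float(x[k + i])
        return params

    def _bounds(self):
        _n, bounds, _x0, _nf = MODEL_SPECS[self.model]
        out = [(0.05, 50.0)]  # kappa
        if self.branch_mode == "scale":
            out.append((1e-3, 50.0))
        return out + list(bounds)

    def fit(self, n_starts: int = 3, seed: int = 0, maxiter: int = 500,
            tol: float = 1e-8, start: dict | None = None) -> "SiteModelResults":
        """Maximise the log-likelihood with multi-start bounded quasi-Newton
        (L-BFGS-B, numerical gradients).

        ``start`` overrides entries of the default initial point -- e.g. a
        warm start from a fitted null model, which guarantees the
        alternative's likelihood cannot fall below the null's.
        """
        names, bounds_m, x0_m, n_free = MODEL_SPECS[self.model]
        rng = substream(seed, f"fit-{self.model}")
        base = {"kappa": 2.0, "scale": 1.0}
        base.update(dict(zip(names, x0_m)))
        if start:
            base.update({k: v for k, v in start.items() if k in base})
        starts = [self._pack(base)]
        lo = np.array([b[0] for b in self._bounds()])
        hi = np.array([b[1] for b in self._bounds()])
        for _ in range(max(0, n_starts - 1)):
            jit = starts[0] * np.exp(rng.normal(0, 0.5, size=starts[0].size))
            starts.append(np.clip(jit, lo, hi))

        def objective(x):
            try:
                ll = self.loglike(self._unpack(x))
            except (FloatingPointError, np.linalg.LinAlgError):
                return 1e12
            if not np.isfinite(ll):
                return 1e12
            return -ll

        best = None
        for x0 in starts:
            res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                    bounds=self._bounds(),
                                    options={"maxiter": maxiter, "ftol": tol})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
            raise ConvergenceError("codon model optimisation failed",
                                   best=best)
        params = self._unpack(best.x)
        omegas, weights = _mixture(self.model, params)
        return SiteModelResults(
            model=self.model, params=params, loglik=float(-best.fun),
            n_free_omega=n_free, class_omegas=list(map(float, omegas)),
            class_weights=list(map(float, weights)),
            converged=bool(best.success), n_starts=len(starts),
            _parent=self)


@dataclass
class SiteModelResults:
    """Fitted codon site model: estimates, likelihood and site inference."""
    model: str
    params: dict
    loglik: float
    n_free_omega: int
    class_omegas: list
    class_weights: list
    converged: bool
    n_starts: int
    _parent: CodonSiteModel = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"Codon site model {self.model}",
                 f"  log-likelihood  {self.loglik:.3f}",
                 f"  kappa           {self.params['kappa']:.3f}"]
        if "scale" in self.params:
            lines.append(f"  tree scale      {self.params['scale']:.3f}")
        for k, (om, wt) in enumerate(zip(self.class_omegas, self.class_weights)):
            lines.append(f"  class {k}: omega = {om:.4f}  weight = {wt:.4f}")
        extras = {k: v for k, v in self.params.items()
                  if k not in ("kappa", "scale")}
        if extras:
            lines.append("  parameters: "
                         + ", ".join(f"{k} = {v:.4f}" for k, v in extras.items()))
        return "\n".join(lines)

    def lrt(self, null: "SiteModelResults"):
        return likelihood_ratio_test(null, self)

    def beb(self) -> "BEBResult":
        return beb_site_posteriors(self)


def likelihood_ratio_test(fit0: SiteModelResults, fit1: SiteModelResults,
                          tol: float = 0.02) -> tuple:
    """(2*delta lnL, df, p) for a nested model pair.

    df is the difference in free omega-structure parameter counts
    (M0 vs M3: 4; M1a vs M2a: 2; M7 vs M8: 2).
    """
    if (fit0.model, fit1.model) not in LRT_PAIRS:
        raise ConfigurationError(
            f"{fit0.model} is not the recognised null of {fit1.model}")
    stat = 2.0 * (fit1.loglik - fit0.loglik)
    if stat < -tol:
        raise ConvergenceError(
            f"alternative model {fit1.model} has lower likelihood than "
            f"{fit0.model} ({fit1.loglik:.4f} < {fit0.loglik:.4f}); "
            "optimisation failure")
    stat = max(stat, 0.0)
    df = fit1.n_free_omega - fit0.n_free_omega
    return stat, df, float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Bayes empirical Bayes

@dataclass
class BEBResult:
    """Per-codon posteriors of the positive-selection class."""
    post_positive: np.ndarray   # P(positive class | data), per codon
    post_mean_omega: np.ndarray
    pss_95: list                # 1-based codon indices, P > 0.95
    pss_99: list

    def to_frame(self):
        import pandas as pd
        n = self.post_positive.size
        return pd.DataFrame({"codon": np.arange(1, n + 1),
                             "post_positive": self.post_positive,
                             "post_mean_omega": self.post_mean_omega})


def _grid_mid(n, lo=0.0, hi=1.0):
    return lo + (hi - lo) * (2 * np.arange(n) + 1) / (2 * n)


def beb_site_posteriors(fit: SiteModelResults, n_grid: int = 10) -> BEBResult:
    """BEB posteriors for M2a or M8.

    Mixture parameters are integrated over a uniform grid (proportions over
    the simplex, omega0 on (0,1), omega2/omega_s on (1,11), beta shapes on
    (0,2)); kappa, codon frequencies and branch lengths stay at their MLEs.
    Site classes with posterior mean omega > 1 at P > 0.95 (and 0.99) are
    reported as positively selected sites.
    """
    if fit.model not in ("M2a", "M8"):
        raise ConfigurationError("BEB is defined for models M2a and M8 only")
    model = fit._parent
    tree, cols, counts, inverse = (model._tree, model._cols, model._counts,
                                   model._inverse)
    pi, kappa = model.pi, fit.params["kappa"]
    scale = fit.params.get("scale", 1.0)
    # Freeze branch-length normalisation at the MLE mixture
    omegas_mle = np.asarray(fit.class_omegas)
    weights_mle = np.asarray(fit.class_weights)
    rates = np.array([_build_q(pi, kappa, om)[1] for om in omegas_mle])
    norm_mle = float((weights_mle * rates).sum())

    def site_loglik(omega):
        """log f(pattern | omega) with the frozen normalisation."""
        w, V, Vinv, _r = _eig(pi, kappa, omega)
        t = tree.lengths * scale / max(norm_mle, 1e-12)
        E = np.exp(np.outer(t, w))
        P = np.einsum("ik,bk,kj->bij", V, E, Vinv)[None]
        lf = _site_class_loglik_from_P(tree, cols, pi, P)
        return lf[0]

    if fit.model == "M2a":
        w0_grid = _grid_mid(n_grid, 0, 1)
        w2_grid = _grid_mid(n_grid, 1, 11)
        f_w0 = np.stack([site_loglik(w) for w in w0_grid])
        f_w1 = site_loglik(1.0)
        f_w2 = np.stack([site_loglik(w) for w in w2_grid])
        p_grid = _grid_mid(n_grid, 0, 1)
        cells = [(i, j) for i in range(n_grid) for j in range(n_grid)
                 if p_grid[i] + p_grid[j] < 1.0]
        log_prior = -np.log(len(cells) * n_grid * n_grid)
        n_pat = cols.shape[1]
        acc_post = np.zeros(n_pat)       # positive-class posterior numerator
        acc_mean = np.zeros(n_pat)
        log_marg = []
        per_point = []
        for (i, j) in cells:
            p0, p1 = p_grid[i], p_grid[j]
            p2 = 1 - p0 - p1
            lw = np.log([p0, p1, p2])
            for k0 in range(n_grid):
                for k2 in range(n_grid):
                    F = np.stack([f_w0[k0], f_w1, f_w2[k2]])
                    mix = logsumexp(F + lw[:, None], axis=0)
                    lnL = float((mix * counts).sum())
                    log_marg.append(lnL + log_prior)
                    per_point.append((F, lw, mix,
                                      np.array([w0_grid[k0], 1.0, w2_grid[k2]])))
        log_marg = np.asarray(log_marg)
        post_g = np.exp(log_marg - logsumexp(log_marg))
        for pg, (F, lw, mix, oms) in zip(post_g, per_point):
            if pg < 1e-12:
                continue
            resp = np.exp(F + lw[:, None] - mix[None, :])  # class resp per pattern
            acc_post += pg * resp[2]
            acc_mean += pg * (resp * oms[:, None]).sum(axis=0)
    else:  # M8
        p0_grid = _grid_mid(n_grid, 0, 1)
        pq_grid = _grid_mid(n_grid, 0, 2)
        ws_grid = _grid_mid(n_grid, 1, 11)
        f_ws = np.stack([site_loglik(w) for w in ws_grid])
        n_pat = cols.shape[1]
        acc_post = np.zeros(n_pat)
        acc_mean = np.zeros(n_pat)
        entries = []
        log_marg = []
        for p in pq_grid:
            for q in pq_grid:
                oms_b = _beta_omegas(p, q)
                Fb = np.stack([site_loglik(w) for w in np.unique(oms_b)])
                # map categories to rows of Fb
                uniq = {w: r for r, w in enumerate(np.unique(oms_b))}
                rows = np.array([uniq[w] for w in oms_b])
                Fbeta = Fb[rows]
                for ip0, p0 in enumerate(p0_grid):
                    for iws, ws in enumerate(ws_grid):
                        lw = np.log(np.concatenate(
                            [np.full(N_BETA_CATS, p0 / N_BETA_CATS), [1 - p0]]))
                        F = np.vstack([Fbeta, f_ws[iws][None]])
                        mix = logsumexp(F + lw[:, None], axis=0)
                        lnL = float((mix * counts).sum())
                        log_marg.append(lnL)
                        entries.append((F, lw, mix,
                                        np.concatenate([oms_b, [ws]])))
        log_marg = np.asarray(log_marg) - np.log(len(log_marg))
        post_g = np.exp(log_marg - logsumexp(log_marg))
        for pg, (F, lw, mix, oms) in zip(post_g, entries):
            if pg < 1e-12:
                continue
            resp = np.exp(F + lw[:, None] - mix[None, :])
            acc_post += pg * resp[-1]
            acc_mean += pg * (resp * oms[:, None]).sum(axis=0)

    post_site = acc_post[inverse]
    mean_site = acc_mean[inverse]
    pss95 = [int(i + 1) for i in np.flatnonzero(post_site > 0.95)]
    pss99 = [int(i + 1) for i in np.flatnonzero(post_site > 0.99)]
    return BEBResult(post_positive=post_site, post_mean_omega=mean_site,
                     pss_95=pss95, pss_99=pss99)


def _site_class_loglik_from_P(tree, pattern_cols, pi, P):
    """Pruning with precomputed transition matrices (n_class, n_branch, ...)."""
    K = P.shape[0]
    n_pat = pattern_cols.shape[1]
    partial = {}
    logscale = {}
    for node in range(tree.n_nodes):
        if tree.leaf_row[node] >= 0:
            continue
        prod = np.ones((K, n_pat, N_STATES))
        lsc = np.zeros((K, n_pat))
        for ch in tree.children[node]:
            if tree.leaf_row[ch] >= 0:
                codons = pattern_cols[tree.leaf_row[ch]]
                msg = np.transpose(P[:, ch, :, codons], (1, 0, 2))
            else:
                msg = np.einsum("kpj,kij->kpi", partial.pop(ch), P[:, ch])
                lsc += logscale.pop(ch)
            prod *= msg
        mx = np.maximum(prod.max(axis=2, keepdims=True), 1e-300)
        prod /= mx
        lsc += np.log(mx[:, :, 0])
        partial[node] = prod
        logscale[node] = lsc
    lik = np.einsum("kpi,i->kp", partial[tree.root], pi)
    return np.log(np.maximum(lik, 1e-300)) + logscale[tree.root]


# ---------------------------------------------------------------------------
# Simulation under the model (for parameter-recovery and power studies)

def random_tree(n_taxa: int, seed: int = 0, mean_branch: float = 0.1,
                prefix: str = "t") -> str:
    """Random topology by sequential attachment with exponential branch
    lengths; returns newick."""
    rng = substream(seed, "random-tree")
    names = [f"{prefix}{i + 1}" for i in range(n_taxa)]

    def bl():
        return max(rng.exponential(mean_branch), 1e-3)

    subtrees = [f"{nm}:{bl():.6f}" for nm in names]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b}):{bl():.6f}")
    return f"({','.join(subtrees)});"


def simulate_codon_alignment(tree: str, n_codons: int, kappa: float = 2.0,
                             omegas=(0.5,), weights=(1.0,),
                             site_classes: np.ndarray | None = None,
                             pi: np.ndarray | None = None,
                             seed: int = 0):
    """Evolve codon sequences along a tree under a site-class mixture.

    Branch lengths are expected substitutions/codon under the mixture (same
    normalisation as the likelihood).  Returns (sequences dict, site class
    index per codon).
    """
    rng = substream(seed, "codon-sim")
    if pi is None:
        pi = np.full(N_STATES, 1.0 / N_STATES)
    omegas = np.asarray(omegas, float)
    weights = np.asarray(weights, float)
    if site_classes is None:
        site_classes = rng.choice(omegas.size, size=n_codons, p=weights)
    site_classes = np.asarray(site_classes)
    t = dendropy.Tree.get(data=tree, schema="newick")
    eigs = [_eig(pi, kappa, om) for om in omegas]
    norm = max(sum(w * e[3] for w, e in zip(weights, eigs)), 1e-12)
    states = {}
    seqs = {}
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            states[id(nd)] = rng.choice(N_STATES, size=n_codons, p=pi)
            continue
        bl = max(nd.edge.length or 0.0, 0.0) / norm
        parent = states[id(nd.parent_node)]
        child = np.empty(n_codons, dtype=int)
        for k, (w, V, Vinv, _r) in enumerate(eigs):
            sites = np.flatnonzero(site_classes == k)
            if sites.size == 0:
                continue
            P = (V * np.exp(w * bl)) @ Vinv
            P = np.clip(P, 0, None)
            P /= P.sum(axis=1, keepdims=True)
            for s in sites:
                child[s] = rng.choice(N_STATES, p=P[parent[s]])
        states[id(nd)] = child
        if nd.is_leaf():
            label = nd.taxon.label.replace(" ", "_")
            seqs[label] = "".join(SENSE_CODONS[c] for c in child)
    return seqs, site_classes
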