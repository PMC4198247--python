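"""Bayesian ancestral gene-content reconstruction on a species tree.

The presence/absence of each gene family across taxa is modelled as a binary
trait evolving along the rooted species tree under a two-state
continuous-time Markov chain with gain rate q01 (absent -> present) and loss
rate q10 (present -> absent) per unit branch length.  Likelihoods are
computed with Felsenstein's pruning algorithm; rates are estimated by maximum
likelihood or sampled by a random-walk Metropolis MCMC with gamma priors
(optionally hyperprior-governed).  The per-family posterior probability of
presence at a target ancestral node is the chain average of the
Rao–Blackwellized node marginal P(state = present | data, sampled rates).

The module follows the statsmodels convention: :class:`GainLossModel` is
built from the data and its ``fit``/``fit_mcmc`` methods return results
objects carrying estimates, uncertainties, diagnostics and ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import statsmodels.api as sm

from . import trees

__all__ = [
    "transition_matrix",
    "pruning_loglik",
    "McmcConfig",
    "GainLossModel",
    "GainLossMLResults",
    "AncestralResults",
    "call_ancestral_content",
    "genome_size_regression",
    "GenomeSizeFit",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


# ---------------------------------------------------------------------------
# two-state CTMC
# ---------------------------------------------------------------------------

def transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form 2x2 transition matrix of the gain/loss chain over time t.

    With s = q01 + q10:  P(0->1) = (q01/s)(1 - exp(-s t)) and complements;
    s = 0 degenerates to the identity.  Rows index the starting state
    (0 = absent, 1 = present) and sum to 1.
    """
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be non-negative")
    s = q01 + q10
    if s == 0:
        return np.eye(2)
    f = -math.expm1(-s * t)  # 1 - e^{-st}, accurate for small st
    p01 = (q01 / s) * f
    p10 = (q10 / s) * f
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


# ---------------------------------------------------------------------------
# pruning machinery (vectorized across families)
# ---------------------------------------------------------------------------

class _PrunedTree:
    """Post-order flattening of a rooted tree for vectorized pruning.

    Holds node order, per-node child lists with branch lengths, and the
    mapping from matrix columns to leaf nodes.  Branch lengths default to 0
    when absent.
    """

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str]):
        if len(tree.seed_node.child_nodes()) == 0:
            raise ValueError("tree has no structure")
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.n_nodes = len(self.nodes)
        self.root_index = self.index[id(tree.seed_node)]
        taxon_col = {lab: j for j, lab in enumerate(taxa)}
        self.leaf_cols: list[tuple[int, Optional[int]]] = []
        self.internal: list[tuple[int, list[tuple[int, float]]]] = []
        leaf_labels_seen = set()
        for i, n in enumerate(self.nodes):
            if n.is_leaf():
                lab = n.taxon.label
                leaf_labels_seen.add(lab)
                self.leaf_cols.append((i, taxon_col.get(lab)))
            else:
                ch = [(self.index[id(c)], float(c.edge.length or 0.0))
                      for c in n.child_nodes()]
                self.internal.append((i, ch))
        missing_taxa = set(taxa) - leaf_labels_seen
        if missing_taxa:
            raise ValueError(
                f"matrix columns not found among tree leaves: {sorted(missing_taxa)[:5]}")

    def loglik(
        self,
        X: np.ndarray,
        q01: float,
        q10: float,
        root_prior: np.ndarray,
        clamp: Optional[tuple[int, int]] = None,
    ) -> np.ndarray:
        """Log-likelihood per family (row of X; entries 0, 1 or NaN).

        ``clamp=(node_index, state)`` restricts the state of one node, which
        partitions the likelihood: L = L_clamp0 + L_clamp1 exactly.
        Impossible configurations return -inf.
        """
        n_fam = X.shape[0]
        partial = np.empty((self.n_nodes, n_fam, 2))
        logscale = np.zeros(n_fam)
        for i, col in self.leaf_cols:
            if col is None:
                partial[i] = 1.0
            else:
                x = X[:, col]
                miss = np.isnan(x)
                one = np.nan_to_num(x) == 1.0
                partial[i, :, 0] = np.where(miss, 1.0, np.where(one, 0.0, 1.0))
                partial[i, :, 1] = np.where(miss, 1.0, np.where(one, 1.0, 0.0))
        clamp_i = clamp[0] if clamp is not None else -1
        for i, children in self.internal:
            acc = np.ones((n_fam, 2))
            for ci, bl in children:
                P = transition_matrix(q01, q10, bl)
                if ci == clamp_i:
                    child = np.zeros_like(partial[ci])
                    child[:, clamp[1]] = partial[ci][:, clamp[1]]
                else:
                    child = partial[ci]
                acc *= child @ P.T
            if i == clamp_i:
                keep = acc[:, clamp[1]].copy()
                acc[:] = 0.0
                acc[:, clamp[1]] = keep
            m = acc.max(axis=1)
            safe = np.where(m > 0, m, 1.0)
            partial[i] = acc / safe[:, None]
            logscale += np.where(m > 0, np.log(safe), -np.inf)
        lik = partial[self.root_index] @ root_prior
        with np.errstate(divide="ignore"):
            return np.where(lik > 0, np.log(np.maximum(lik, 1e-300)), -np.inf) + logscale


def pruning_loglik(
    tree: dendropy.Tree,
    tip_states: Mapping[str, Optional[int]],
    q01: float,
    q10: float,
    root_prior=(0.5, 0.5),
) -> float:
    """Log-likelihood of one family's tip states under the gain/loss chain.

    ``tip_states`` maps leaf labels to 0, 1 or None (missing; both states
    allowed).  Leaves absent from the mapping are treated as missing.  Raises
    on tip labels not in the tree or when every state is missing.
    """
    labels = trees.leaf_labels(tree)
    unknown = set(tip_states) - set(labels)
    if unknown:
        raise ValueError(f"tip states for labels not in tree: {sorted(unknown)}")
    observed = [l for l, s in tip_states.items() if s is not None]
    if not observed:
        raise ValueError("all tip states missing")
    taxa = labels
    row = np.full((1, len(taxa)), np.nan)
    for j, lab in enumerate(taxa):
        s = tip_states.get(lab)
        if s is not None:
            row[0, j] = float(s)
    pt = _PrunedTree(tree, taxa)
    return float(pt.loglik(row, q01, q10, np.asarray(root_prior, dtype=float))[0])


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a families x taxa presence/absence TSV with cells in {0, 1, ?}."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = df.replace({"?": np.nan}).astype(float)
    bad = ~(out.isin([0.0, 1.0]) | out.isna())
    if bad.any().any():
        raise ValueError("matrix cells must be 0, 1 or ?")
    return out


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy().astype(object)
    out = out.where(~matrix.isna(), "?")
    out = out.mask(matrix == 1.0, "1").mask(matrix == 0.0, "0")
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    """MCMC settings for the ancestral reconstruction.

    Defaults mirror a long production run (1,050,000 cycles, 50,000 burn-in);
    scale ``iterations``/``burnin`` down for exploratory work.  ``prior_shape``
    and ``prior_scale`` fix the gamma prior on each rate; leaving them None
    derives the prior from an initial ML fit (scale chosen so the prior mean
    equals the ML rate).  With ``hyperprior=True`` the gamma parameters are
    themselves sampled, uniformly bounded by ``hyper_shape_max`` and twice the
    ML rate estimates.
    """

    iterations: int = 1_050_000
    burnin: int = 50_000
    thinning: int = 1
    seed: Optional[int] = None
    prior_shape: Optional[float] = None
    prior_scale: Optional[float] = None
    hyperprior: bool = False
    hyper_shape_max: float = 10.0
    step: float = 0.5
    adapt: bool = False  # tune the rate-move step toward ~30% acceptance in burn-in

    def __post_init__(self) -> None:
        if self.burnin >= self.iterations:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial positive autocorrelation sequence."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


@dataclass
class GainLossMLResults:
    """Maximum-likelihood gain/loss rate estimates."""

    model: "GainLossModel"
    q01: float
    q10: float
    loglik: float
    at_bound: bool
    per_family: Optional[pd.DataFrame] = None  # columns q01, q10, loglik

    def summary(self) -> str:
        lines = [
            "Gain/loss CTMC — maximum likelihood",
            "=" * 42,
            f"families: {len(self.model.families):>6d}   taxa: {len(self.model.taxa)}",
            f"gain rate q01: {self.q01:.6g}",
            f"loss rate q10: {self.q10:.6g}",
            f"log-likelihood: {self.loglik:.4f}",
        ]
        if self.at_bound:
            lines.append("warning: an estimate lies on the optimizer bound")
        if self.per_family is not None:
            lines.append(f"per-family fits: {len(self.per_family)} rows (see .per_family)")
        return "\n".join(lines)


@dataclass
class AncestralResults:
    """Posterior summary of the ancestral-content MCMC.

    ``posteriors`` holds, per family, the posterior probability that the
    target node carried the family (mean over retained cycles of the
    Rao–Blackwellized node marginal).
    """

    model: "GainLossModel"
    target_label: str
    config: McmcConfig
    posteriors: pd.Series
    rate_means: pd.DataFrame  # per family (or single row), columns q01, q10
    acceptance_rate: float
    ess: dict
    mode: str

    def call_content(self, threshold: float = 0.5) -> tuple[list, int]:
        """Families called present at the target node (posterior >= threshold)."""
        called = sorted(self.posteriors.index[self.posteriors >= threshold])
        return called, len(called)

    def summary(self, threshold: float = 0.5) -> str:
        called, n = self.call_content(threshold)
        p = self.posteriors
        lines = [
            "Ancestral gene-content reconstruction (MCMC)",
            "=" * 46,
            f"target node: {self.target_label}",
            f"families: {len(p)}   mode: {self.mode}",
            f"iterations: {self.config.iterations}  burn-in: {self.config.burnin}"
            f"  thinning: {self.config.thinning}",
            f"acceptance rate: {self.acceptance_rate:.3f}",
            f"min ESS (rates): {min(self.ess.values()):.0f}",
            f"posterior presence: median {p.median():.3f}  "
            f"quartiles [{p.quantile(.25):.3f}, {p.quantile(.75):.3f}]",
            f"families called present at threshold {threshold}: {n}",
        ]
        return "\n".join(lines)

    def plot_posteriors(self, ax=None, bins: int = 20):
        """Histogram of per-family posterior presence probabilities."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.posteriors.values, bins=bins, range=(0, 1), color="#4878b0")
        ax.set_xlabel("posterior P(present at target node)")
        ax.set_ylabel("families")
        return ax

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"posterior": self.posteriors})
        for c in self.rate_means.columns:
            if len(self.rate_means) == len(out):
                out[f"mean_{c}"] = self.rate_means[c].values
        out.to_csv(path, sep="\t", index_label="family_id")


def call_ancestral_content(posteriors: pd.Series, threshold: float = 0.5):
    """Stand-alone presence call: families with posterior >= threshold."""
    called = sorted(posteriors.index[posteriors >= threshold])
    return called, len(called)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class GainLossModel:
    """Binary gain/loss CTMC for gene-family presence on a rooted species tree.

    Parameters
    ----------
    matrix
        Families x taxa DataFrame with entries 1 (present), 0 (absent) or NaN
        (missing).  Every column must name a leaf of ``tree``; leaves without
        a column are treated as missing data.
    tree
        Rooted species tree with branch lengths.
    model
        ``"asymmetric"`` (independent q01, q10) or ``"symmetric"`` (q01 = q10).
    root_prior
        ``"uniform"`` (1/2, 1/2) or ``"stationary"`` (q10/s, q01/s).
    """

    def __init__(self, matrix: pd.DataFrame, tree: dendropy.Tree,
                 model: str = "asymmetric", root_prior: str = "uniform"):
        if model not in ("asymmetric", "symmetric"):
            raise ValueError("model must be 'asymmetric' or 'symmetric'")
        if root_prior not in ("uniform", "stationary"):
            raise ValueError("root_prior must be 'uniform' or 'stationary'")
        if matrix.isna().all(axis=1).any():
            bad = matrix.index[matrix.isna().all(axis=1)][:5].tolist()
            raise ValueError(f"families with no observed state: {bad}")
        self.matrix = matrix
        self.tree = tree
        self.model = model
        self.root_prior_kind = root_prior
        self.families = list(matrix.index)
        self.taxa = list(matrix.columns)
        self.X = matrix.to_numpy(dtype=float)
        self._pt = _PrunedTree(tree, self.taxa)

    @classmethod
    def from_files(cls, matrix_path, tree_path, **kw) -> "GainLossModel":
        tree = trees.read_newick(tree_path)[0]
        return cls(read_matrix_tsv(matrix_path), tree, **kw)

    # -- likelihood ------------------------------------------------------
    def _root_prior(self, q01: float, q10: float) -> np.ndarray:
        if self.root_prior_kind == "uniform" or q01 + q10 == 0:
            return np.array([0.5, 0.5])
        s = q01 + q10
        return np.array([q10 / s, q01 / s])

    def loglik(self, q01: float, q10: float, rows: Optional[np.ndarray] = None,
               clamp: Optional[tuple[int, int]] = None) -> np.ndarray:
        X = self.X if rows is None else self.X[rows]
        return self._pt.loglik(X, q01, q10, self._root_prior(q01, q10), clamp=clamp)

    # -- maximum likelihood ----------------------------------------------
    _LOG_BOUNDS = (-10.0, 5.0)

    def _fit_rows(self, rows=None):
        lo, hi = self._LOG_BOUNDS
        k = 1 if self.model == "symmetric" else 2

        def nll(theta):
            q01 = math.exp(theta[0])
            q10 = q01 if k == 1 else math.exp(theta[1])
            ll = self.loglik(q01, q10, rows=rows)
            val = ll.sum()
            return 1e10 if not np.isfinite(val) else -val

        best = None
        for start in ([-1.0] * k, [0.5] * k, [-3.0, 0.0][:k]):
            res = scipy.optimize.minimize(
                nll, np.array(start), method="L-BFGS-B", bounds=[(lo, hi)] * k)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("rate optimization failed")
        q01 = math.exp(best.x[0])
        q10 = q01 if k == 1 else math.exp(best.x[1])
        at_bound = bool(np.any(np.isclose(best.x, lo, atol=1e-3)) or
                        np.any(np.isclose(best.x, hi, atol=1e-3)))
        return q01, q10, -best.fun, at_bound

    def fit(self, per_family: bool = False) -> GainLossMLResults:
        """Maximize the pruning likelihood over the rates.

        With ``per_family=True`` rates are additionally optimized family by
        family (the global fit is still reported as the headline estimate).
        Estimates pinned at the search bound are flagged; a rate at the lower
        bound (~e-10) is effectively zero, e.g. when no loss is ever observed.
        """
        q01, q10, ll, at_bound = self._fit_rows()
        pf = None
        if per_family:
            rows = []
            for i, fam in enumerate(self.families):
                a, b, l, _ = self._fit_rows(rows=np.array([i]))
                rows.append((fam, a, b, l))
            pf = pd.DataFrame(rows, columns=["family_id", "q01", "q10", "loglik"]
                              ).set_index("family_id")
        return GainLossMLResults(self, q01, q10, ll, at_bound, pf)

    # -- MCMC --------------------------------------------------------------
    def resolve_target(self, leaf_sets) -> tuple[int, str]:
        """MRCA node index (postorder) of the union of the given leaf sets."""
        if isinstance(leaf_sets, str):
            leaf_sets = [s.split(",") for s in leaf_sets.split(";") if s]
        labels = set()
        for s in leaf_sets:
            labels |= {x.strip() for x in s} if not isinstance(s, str) else {s.strip()}
        node = trees.mrca(self.tree, labels)
        idx = self._pt.index[id(node)]
        label = "mrca(" + ",".join(sorted(labels)[:4]) + (",..." if len(labels) > 4 else "") + ")"
        return idx, label

    def fit_mcmc(self, target, config: McmcConfig, mode: str = "per-family",
                 ml_results: Optional[GainLossMLResults] = None) -> AncestralResults:
        """Sample the rate posterior and the ancestral state at ``target``.

        ``target`` is a node index, a collection of leaf-label sets, or a
        string ``"leaf1,leaf2;leaf3,..."``; the target node is the MRCA of
        the union.  ``mode`` is ``"per-family"`` (an independent chain per
        family, the default bookkeeping) or ``"global"`` (one chain with
        rates shared across families; far faster for large matrices).

        The per-cycle contribution to each family's presence probability is
        the exact node marginal given the sampled rates, obtained from two
        clamped pruning passes (L = L_absent + L_present).
        """
        if isinstance(target, (int, np.integer)):
            target_idx, target_label = int(target), f"node[{int(target)}]"
        else:
            target_idx, target_label = self.resolve_target(target)
        if mode not in ("per-family", "global"):
            raise ValueError("mode must be 'per-family' or 'global'")
        if ml_results is None and (config.prior_shape is None or config.hyperprior):
            ml_results = self.fit()
        shape0 = config.prior_shape if config.prior_shape is not None else 2.0
        if config.prior_scale is not None:
            scales0 = (config.prior_scale, config.prior_scale)
        else:
            scales0 = (max(ml_results.q01, 1e-4) / shape0,
                       max(ml_results.q10, 1e-4) / shape0)
        hyper_scale_max = None
        if config.hyperprior:
            hyper_scale_max = (2.0 * max(ml_results.q01, 1e-4),
                               2.0 * max(ml_results.q10, 1e-4))
        seed = config.seed if config.seed is not None else 0

        if mode == "global":
            post, rates, acc, ess = self._run_chain(
                np.arange(len(self.families)), target_idx, config,
                shape0, scales0, hyper_scale_max, np.random.default_rng(seed))
            posteriors = pd.Series(post, index=self.families, name="posterior")
            rate_means = pd.DataFrame([rates], columns=["q01", "q10"])
        else:
            ss = np.random.SeedSequence(seed).spawn(len(self.families))
            ps, rms = [], []
            acc_all, ess_all = [], []
            for i, fam_ss in enumerate(ss):
                post, rates, acc, ess = self._run_chain(
                    np.array([i]), target_idx, config,
                    shape0, scales0, hyper_scale_max, np.random.default_rng(fam_ss))
                ps.append(post[0])
                rms.append(rates)
                acc_all.append(acc)
                ess_all.append(min(ess.values()))
            posteriors = pd.Series(ps, index=self.families, name="posterior")
            rate_means = pd.DataFrame(rms, columns=["q01", "q10"], index=self.families)
            acc = float(np.mean(acc_all))
            ess = {"min_over_families": float(np.min(ess_all))}
        return AncestralResults(self, target_label, config, posteriors, rate_means,
                                acc, ess, mode)

    def _run_chain(self, rows, target_idx, config, shape0, scales0, hyper_scale_max, rng):
        """One Metropolis chain over (log q01, log q10[, gamma hyperparams])."""
        sym = self.model == "symmetric"
        lo, hi = self._LOG_BOUNDS

        def log_prior(q, shape, scale):
            # gamma density in q plus log-scale Jacobian: q^shape e^{-q/scale}
            return (shape * math.log(q) - q / scale
                    - scipy.special.gammaln(shape) - shape * math.log(scale))

        lq = np.array([math.log(shape0 * scales0[0]),
                       math.log(shape0 * scales0[1])])
        shapes = np.array([shape0, shape0])
        scales = np.array(scales0)
        ll_sum = float(self.loglik(math.exp(lq[0]), math.exp(lq[1]), rows=rows).sum())
        lp = sum(log_prior(math.exp(lq[i]), shapes[i], scales[i]) for i in range(2))
        n_kept = 0
        post_acc = np.zeros(len(rows))
        rate_acc = np.zeros(2)
        n_accept = 0
        step = config.step
        trace_q = []
        for it in range(config.iterations):
            # move 1: random walk on the log rates, prior parameters fixed
            prop = lq + rng.normal(0.0, step, size=2)
            if sym:
                prop[1] = prop[0]
            accepted = False
            if np.all(prop >= lo) and np.all(prop <= hi):
                q01p, q10p = math.exp(prop[0]), math.exp(prop[1])
                llp_sum = float(self.loglik(q01p, q10p, rows=rows).sum())
                lpp = sum(log_prior(math.exp(prop[i]), shapes[i], scales[i])
                          for i in range(2))
                if np.isfinite(llp_sum) and \
                        math.log(rng.uniform()) < (llp_sum + lpp) - (ll_sum + lp):
                    lq, ll_sum, lp = prop, llp_sum, lpp
                    accepted = True
                    n_accept += 1
            if config.adapt and it < config.burnin and (it + 1) % 50 == 0:
                # Robbins–Monro tuning toward ~30% acceptance during burn-in
                rate_so_far = n_accept / (it + 1)
                step *= math.exp(0.5 * (rate_so_far - 0.3))
                step = min(max(step, 1e-3), 5.0)
            # move 2 (hyperprior): resample the gamma parameters given the rates
            if hyper_scale_max is not None:
                new_shapes = rng.uniform(0.05, config.hyper_shape_max, size=2)
                new_scales = np.array([rng.uniform(1e-6, hyper_scale_max[0]),
                                       rng.uniform(1e-6, hyper_scale_max[1])])
                lpp = sum(log_prior(math.exp(lq[i]), new_shapes[i], new_scales[i])
                          for i in range(2))
                if math.log(rng.uniform()) < lpp - lp:
                    lp = lpp
                    shapes, scales = new_shapes, new_scales
            if it >= config.burnin and (it - config.burnin) % config.thinning == 0:
                q01c, q10c = math.exp(lq[0]), math.exp(lq[1])
                l0 = self.loglik(q01c, q10c, rows=rows, clamp=(target_idx, 0))
                l1 = self.loglik(q01c, q10c, rows=rows, clamp=(target_idx, 1))
                m = np.maximum(l0, l1)
                p1 = np.where(
                    np.isfinite(m),
                    np.exp(l1 - m) / (np.exp(l0 - m) + np.exp(l1 - m)),
                    0.5)
                post_acc += p1
                rate_acc += (q01c, q10c)
                trace_q.append((q01c, q10c))
                n_kept += 1
        if n_kept == 0:
            raise RuntimeError("no retained MCMC cycles")
        trace = np.asarray(trace_q)
        ess = {"q01": _ess(trace[:, 0]), "q10": _ess(trace[:, 1])}
        return (post_acc / n_kept, rate_acc / n_kept,
                n_accept / config.iterations, ess)


# ---------------------------------------------------------------------------
# genome-size extrapolation
# ---------------------------------------------------------------------------

@dataclass
class GenomeSizeFit:
    """OLS extrapolation of gene count and genome size from a family count."""

    ancestor_family_count: int
    gene_prediction: float
    gene_interval: tuple[float, float]
    size_prediction: float
    size_interval: tuple[float, float]
    gene_params: tuple[float, float]   # intercept, slope
    size_params: tuple[float, float]
    gene_r2: float
    size_r2: float

    def summary(self) -> str:
        g, s = self.gene_params, self.size_params
        return "\n".join([
            "Genome-size extrapolation (OLS, 95% prediction intervals)",
            "=" * 58,
            f"ancestor family count: {self.ancestor_family_count}",
            f"genes ~ families:  intercept {g[0]:.3f}  slope {g[1]:.4f}  R² {self.gene_r2:.4f}",
            f"  predicted genes: {self.gene_prediction:.0f} "
            f"[{self.gene_interval[0]:.0f}, {self.gene_interval[1]:.0f}]",
            f"Mb ~ families:     intercept {s[0]:.4f}  slope {s[1]:.6f}  R² {self.size_r2:.4f}",
            f"  predicted size:  {self.size_prediction:.2f} Mb "
            f"[{self.size_interval[0]:.2f}, {self.size_interval[1]:.2f}]",
        ])


def _ols_predict(x: np.ndarray, y: np.ndarray, x0: float):
    Xd = sm.add_constant(x)
    fit = sm.OLS(y, Xd).fit()
    pred = fit.get_prediction([1.0, x0]).summary_frame(alpha=0.05)
    lo, hi = float(pred["obs_ci_lower"].iloc[0]), float(pred["obs_ci_upper"].iloc[0])
    mean = float(pred["mean"].iloc[0])
    if np.allclose(fit.resid, 0, atol=1e-9):  # perfectly collinear input
        lo = hi = mean
    return mean, (lo, hi), (float(fit.params[0]), float(fit.params[1])), float(fit.rsquared)


def genome_size_regression(extant: pd.DataFrame, ancestor_family_count: int) -> GenomeSizeFit:
    """Predict the ancestral gene count and genome size by linear extrapolation.

    ``extant`` needs columns ``family_count``, ``gene_count`` and
    ``genome_size_mb`` for at least three genomes with variable family counts.
    Two OLS fits (genes ~ families, Mb ~ families) are evaluated at
    ``ancestor_family_count`` with 95% prediction intervals.
    """
    required = {"family_count", "gene_count", "genome_size_mb"}
    missing = required - set(extant.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(extant) < 3:
        raise ValueError("at least 3 extant genomes required")
    x = extant["family_count"].to_numpy(dtype=float)
    if np.isclose(np.var(x), 0):
        raise ValueError("zero variance in family counts")
    gm, gi, gp, gr2 = _ols_predict(x, extant["gene_count"].to_numpy(dtype=float),
                                   ancestor_family_count)
    sm_, si, sp, sr2 = _ols_predict(x, extant["genome_size_mb"].to_numpy(dtype=float),
                                    ancestor_family_count)
    return GenomeSizeFit(ancestor_family_count, gm, gi, sm_, si, gp, sp, gr2, sr2)
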