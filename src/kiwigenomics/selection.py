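"""Branch-model selection analysis: likelihood, fitting, LRT, Ka/Ks, dating.

Implements the classic foreground/background branch test: a one-ratio null
(single dN/dS for the whole tree) against a two-ratio alternative where
tagged branches carry their own omega, contrasted by a chi-square(1)
likelihood-ratio test. Also the two-taxon ML Ka/Ks estimator and the
closed-form dating of a loss of selective constraint from a branch's
averaged omega.

The likelihood is Felsenstein pruning over site patterns, with analytic
branch-length gradients via an inside-outside pass (rate parameters use
forward differences); optimization is bounded quasi-Newton in log space.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codon_alignment import CodonAlignment, f3x4_frequencies
from .codon_model import (
    BACKGROUND,
    FOREGROUND,
    CodonModelParams,
    SpectralCodonMatrix,
    build_rate_matrix,
)
from .genetics import GeneticCode, UNIVERSAL_CODE
from .phylo import PhyloTree

ONE_RATIO = "one-ratio"
TWO_RATIO = "two-ratio"

_T_MIN, _T_MAX = 1e-7, 30.0
_KAPPA_BOUNDS = (0.05, 100.0)
_OMEGA_BOUNDS = (1e-4, 50.0)


@dataclass(frozen=True)
class FitConfig:
    """Settings for branch-model optimization.

    freq_mode: 'f3x4' (positional nucleotide counts, the usual default),
    'uniform', or 'empirical' (observed codon proportions).
    n_starts: deterministic multi-starts; the first uses the heuristic
    initialization, later ones perturb it by fixed factors.
    """

    freq_mode: str = "f3x4"
    n_starts: int = 3
    kappa_init: float = 2.0
    omega_init: float = 0.3
    t_init: float = 0.1
    ftol: float = 1e-10
    maxiter: int = 500


@dataclass
class BranchModelFit:
    """A fitted branch codon model."""

    model_id: str
    params: CodonModelParams
    lnL: float
    tree: PhyloTree
    converged: bool
    n_evaluations: int
    data_hash: str

    @property
    def omega_background(self):
        return self.params.omega_background

    @property
    def omega_foreground(self):
        return self.params.omega_foreground

    def to_record(self) -> dict:
        return {
            "model_id": self.model_id,
            "kappa": float(self.params.kappa),
            "omega_background": float(self.params.omega_background),
            "omega_foreground": float(self.params.omega_foreground),
            "lnL": float(self.lnL),
            "converged": bool(self.converged),
            "tree_length": float(
                sum(self.tree.lengths[e] for e in self.tree.edges())
            ),
        }


@dataclass
class LRTResult:
    """One-degree-of-freedom likelihood-ratio test of the branch model."""

    statistic: float
    df: int
    pvalue: float
    significant: bool
    alpha: float
    critical_value: float


@dataclass
class KaKsResult:
    ka: float
    ks: float
    omega: float
    t: float
    kappa: float
    undefined: bool  # Ks ~ 0, so the ratio is flagged rather than reported


@dataclass
class LossDatingInput:
    """Inputs to the loss-of-constraint dating closed form.

    omega_obs: fitted omega on the focal branch (its time average).
    omega_constrained: omega of the constrained era, e.g. the average over
    background lineages for the same gene.
    duration_my: total time span of the focal branch in million years.
    """

    omega_obs: float
    omega_constrained: float
    duration_my: float

    def __post_init__(self):
        if not (0.0 <= self.omega_constrained <= 1.0):
            raise ValueError("omega_constrained must lie in [0, 1]")
        if self.omega_obs < 0:
            raise ValueError("omega_obs must be nonnegative")
        if self.duration_my <= 0:
            raise ValueError("branch duration must be positive")


# --------------------------------------------------------------------------
# likelihood core


def _states_for_tree(aln: CodonAlignment, tree: PhyloTree) -> np.ndarray:
    if set(aln.taxa) != set(tree.taxa):
        raise ValueError(
            f"taxon mismatch: alignment {sorted(aln.taxa)} vs tree {sorted(tree.taxa)}"
        )
    states = aln.state_matrix()
    order = [aln.taxa.index(t) for t in tree.taxa]
    return states[order]


def _patterns(states: np.ndarray):
    if states.shape[1] == 0:
        raise ValueError("no usable codon columns (all contain gaps/ambiguity)")
    pats, counts = np.unique(states.T, axis=0, return_counts=True)
    return pats.T.copy(), counts.astype(float)


def _data_hash(tree_taxa, states) -> str:
    h = hashlib.sha1()
    h.update("|".join(tree_taxa).encode())
    h.update(np.ascontiguousarray(states).tobytes())
    return h.hexdigest()


class _LikelihoodEngine:
    """Pruning likelihood + branch-length gradient for one dataset/tree."""

    def __init__(self, tree: PhyloTree, patterns, weights, pi, code: GeneticCode):
        self.tree = tree
        self.patterns = patterns
        self.weights = weights
        self.pi = pi
        self.code = code
        self.n = len(pi)
        self.npat = patterns.shape[1]
        self.postorder = tree.postorder()
        self.edges = tree.edges()
        self.fg_edges = [e for e in self.edges if tree.foreground[e]]
        self.eye = np.eye(self.n)
        self._decomp_cache = {}

    def decomps(self, kappa, omega_bg, omega_fg):
        key = (kappa, omega_bg, omega_fg)
        hit = self._decomp_cache.get(key)
        if hit is not None:
            return hit
        params = CodonModelParams(
            kappa=kappa, omega_background=omega_bg, omega_foreground=omega_fg,
            pi=self.pi, code=self.code,
        )
        bg = SpectralCodonMatrix(build_rate_matrix(params, self.code, BACKGROUND), self.pi)
        if omega_fg == omega_bg:
            fg = bg
        else:
            fg = SpectralCodonMatrix(
                build_rate_matrix(params, self.code, FOREGROUND), self.pi
            )
        if len(self._decomp_cache) > 64:
            self._decomp_cache.clear()
        self._decomp_cache[key] = (bg, fg)
        return bg, fg

    def _edge_matrices(self, decomp_bg, decomp_fg, lengths, want_grad):
        P, dP = {}, {}
        for e in self.edges:
            d = decomp_fg if self.tree.foreground[e] else decomp_bg
            t = lengths[e]
            ex = np.exp(d.lam * t)
            P[e] = (d.left * ex) @ d.right
            if want_grad:
                dP[e] = (d.left * (d.lam * ex)) @ d.right
        return P, dP

    def _inside(self, P):
        tree = self.tree
        cond = [None] * tree.n_nodes
        msgs = [None] * tree.n_nodes
        for node in self.postorder:
            L = self.eye[:, self.patterns[node]].copy() if node < tree.n_leaves else None
            for c in tree.children[node]:
                msgs[c] = P[c] @ cond[c]
                L = msgs[c].copy() if L is None else L * msgs[c]
            cond[node] = L
        return cond, msgs

    def loglik(self, kappa, omega_bg, omega_fg, lengths):
        bg, fg = self.decomps(kappa, omega_bg, omega_fg)
        P, _ = self._edge_matrices(bg, fg, lengths, want_grad=False)
        cond, _ = self._inside(P)
        site = np.maximum(self.pi @ cond[self.tree.root], 1e-250)
        return float(self.weights @ np.log(site))

    def loglik_and_tgrad(self, kappa, omega_bg, omega_fg, lengths):
        """lnL and its gradient with respect to each edge's branch length."""
        tree = self.tree
        bg, fg = self.decomps(kappa, omega_bg, omega_fg)
        P, dP = self._edge_matrices(bg, fg, lengths, want_grad=True)
        cond, msgs = self._inside(P)
        site = np.maximum(self.pi @ cond[tree.root], 1e-250)
        lnL = float(self.weights @ np.log(site))
        wsite = self.weights / site

        # outside pass: E[c] is the conditional of everything above edge c,
        # evaluated at c's parent (parent's own tip state included)
        E = [None] * tree.n_nodes
        grad = np.zeros(tree.n_nodes)
        O_root = np.broadcast_to(self.pi[:, None], (self.n, self.npat))
        O = [None] * tree.n_nodes
        O[tree.root] = O_root
        for node in reversed(self.postorder):
            kids = tree.children[node]
            if not kids:
                continue
            own = self.eye[:, self.patterns[node]] if node < tree.n_leaves else None
            base = O[node] if own is None else O[node] * own
            m = len(kids)
            for idx, c in enumerate(kids):
                sib = base
                for jdx, s in enumerate(kids):
                    if jdx != idx:
                        sib = sib * msgs[s]
                E[c] = sib
                grad[c] = wsite @ ((E[c] * (dP[c] @ cond[c])).sum(axis=0))
                if tree.children[c]:
                    O[c] = P[c].T @ E[c]
        return lnL, grad


# --------------------------------------------------------------------------
# public operations


def log_likelihood(
    aln: CodonAlignment, tree: PhyloTree, params: CodonModelParams
) -> float:
    """Log-likelihood of the alignment on the tree under the branch model.

    Codon columns containing a gap or ambiguity in any taxon are excluded
    (complete-column analysis). Branch lengths are taken from the tree.
    """
    states = _states_for_tree(aln, tree)
    pats, counts = _patterns(states)
    eng = _LikelihoodEngine(tree, pats, counts, params.pi, params.code)
    return eng.loglik(
        params.kappa, params.omega_background, params.omega_foreground, tree.lengths
    )


def _equilibrium_frequencies(aln: CodonAlignment, mode) -> np.ndarray:
    if isinstance(mode, np.ndarray):
        return mode
    if mode == "f3x4":
        return f3x4_frequencies(aln)
    if mode == "uniform":
        n = aln.code.n_states
        return np.full(n, 1.0 / n)
    if mode == "empirical":
        states = aln.state_matrix()
        counts = np.bincount(states.ravel(), minlength=aln.code.n_states) + 0.5
        return counts / counts.sum()
    raise ValueError(f"unknown frequency mode {mode!r}")


def fit_model(
    aln: CodonAlignment,
    tree: PhyloTree,
    model_id: str = ONE_RATIO,
    config: FitConfig = None,
    init_fit: BranchModelFit = None,
) -> BranchModelFit:
    """Maximize the branch-model likelihood over kappa, omega(s) and all
    branch lengths.

    ``init_fit`` warm-starts the optimization (fitting the two-ratio model
    from the one-ratio optimum guarantees the nested lnL ordering).
    Deterministic multi-starts guard against local optima; a fit that fails
    line search even after a retry is returned with ``converged=False``
    rather than raised.
    """
    config = config or FitConfig()
    if model_id not in (ONE_RATIO, TWO_RATIO):
        raise ValueError(f"unknown model {model_id!r}")
    two = model_id == TWO_RATIO
    if two and tree.n_foreground == 0:
        raise ValueError("two-ratio model requires at least one foreground branch")

    states = _states_for_tree(aln, tree)
    pats, counts = _patterns(states)
    pi = _equilibrium_frequencies(aln, config.freq_mode)
    eng = _LikelihoodEngine(tree, pats, counts, pi, aln.code)
    edges = eng.edges
    n_rate = 2 + (1 if two else 0)
    n_evals = 0

    def unpack(x):
        kappa = np.exp(x[0])
        wb = np.exp(x[1])
        wf = np.exp(x[2]) if two else wb
        lengths = [0.0] * tree.n_nodes
        for k, e in enumerate(edges):
            lengths[e] = np.exp(x[n_rate + k])
        return kappa, wb, wf, lengths

    # optimizing the per-site average log-likelihood keeps gradients O(1),
    # which L-BFGS-B's line search needs to take sane first steps
    site_total = counts.sum()

    def objective(x):
        nonlocal n_evals
        kappa, wb, wf, lengths = unpack(x)
        lnL, tgrad = eng.loglik_and_tgrad(kappa, wb, wf, lengths)
        n_evals += 1
        g = np.zeros_like(x)
        # rate-parameter derivatives by forward difference in log space
        h = 1e-6
        lk = eng.loglik(kappa * np.exp(h), wb, wf, lengths)
        g[0] = (lk - lnL) / h
        lb = eng.loglik(kappa, wb * np.exp(h), wf if two else wb * np.exp(h), lengths)
        g[1] = (lb - lnL) / h
        if two:
            lf = eng.loglik(kappa, wb, wf * np.exp(h), lengths)
            g[2] = (lf - lnL) / h
        n_evals += n_rate
        for k, e in enumerate(edges):
            g[n_rate + k] = tgrad[e] * lengths[e]
        return -lnL / site_total, -g / site_total

    t0 = [
        tree.lengths[e] if tree.lengths[e] > 0 else config.t_init for e in edges
    ]
    starts = []
    if init_fit is not None:
        warm = [np.log(init_fit.params.kappa), np.log(max(init_fit.params.omega_background, 1e-4))]
        if two:
            warm.append(np.log(max(init_fit.params.omega_foreground, 1e-4)))
        warm += [np.log(np.clip(init_fit.tree.lengths[e], _T_MIN, _T_MAX)) for e in edges]
        starts.append(np.array(warm))
    k0, w0 = config.kappa_init, config.omega_init
    for fk, fw, ft in [(1.0, 1.0, 1.0), (2.5, 0.25, 0.5), (0.5, 3.0, 2.0)][: config.n_starts]:
        x = [np.log(k0 * fk), np.log(min(w0 * fw, _OMEGA_BOUNDS[1]))]
        if two:
            x.append(np.log(min(w0 * fw, _OMEGA_BOUNDS[1])))
        x += [np.log(np.clip(t * ft, _T_MIN, _T_MAX)) for t in t0]
        starts.append(np.array(x))

    bounds = (
        [tuple(np.log(_KAPPA_BOUNDS))]
        + [tuple(np.log(_OMEGA_BOUNDS))] * (n_rate - 1)
        + [tuple(np.log((_T_MIN, _T_MAX)))] * len(edges)
    )

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"ftol": config.ftol, "maxiter": config.maxiter},
        )
        if not res.success:  # one retry from where it stopped
            res = minimize(
                objective, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"ftol": config.ftol, "maxiter": config.maxiter},
            )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    kappa, wb, wf, lengths = unpack(best.x)
    params = CodonModelParams(
        kappa=kappa, omega_background=wb, omega_foreground=wf, pi=pi, code=aln.code
    )
    fit = BranchModelFit(
        model_id=model_id,
        params=params,
        lnL=-best.fun * site_total,
        tree=tree.with_lengths(lengths),
        converged=any_converged,
        n_evaluations=n_evals,
        data_hash=_data_hash(tree.taxa, states),
    )
    if not any_converged:
        warnings.warn("branch-model optimization did not report convergence", RuntimeWarning)
    return fit


def branch_lrt(fit0: BranchModelFit, fit1: BranchModelFit, alpha: float = 0.05) -> LRTResult:
    """Likelihood-ratio test of the two-ratio model against the one-ratio
    null, chi-square with one degree of freedom.

    At alpha = 0.05 the critical value is 3.84: a statistic above it flags
    the foreground branch as evolving at a significantly different rate.
    """
    if fit0.model_id != ONE_RATIO or fit1.model_id != TWO_RATIO:
        raise ValueError("branch_lrt expects (one-ratio fit, two-ratio fit)")
    if fit0.data_hash != fit1.data_hash:
        raise ValueError("fits come from different alignments")
    stat = 2.0 * (fit1.lnL - fit0.lnL)
    if stat < -1e-4:
        warnings.warn(
            f"two-ratio lnL below one-ratio by {-stat / 2:.2e}; optimizer noise, clamping",
            RuntimeWarning,
        )
    stat = max(stat, 0.0)
    df = 1
    crit = float(chi2.isf(alpha, df))
    return LRTResult(
        statistic=stat,
        df=df,
        pvalue=float(chi2.sf(stat, df)),
        significant=bool(stat > crit),
        alpha=alpha,
        critical_value=crit,
    )


def pairwise_kaks(
    seq_a: str,
    seq_b: str,
    code: GeneticCode = UNIVERSAL_CODE,
    config: FitConfig = None,
    names=("A", "B"),
) -> KaKsResult:
    """ML Ka/Ks for one sequence pair on a two-taxon tree.

    Sites are counted by mutational opportunity: the fraction of
    substitution flow that is nonsynonymous under the fitted kappa and pi
    with omega forced to 1 defines the nonsynonymous site proportion, as in
    the standard ML counting of codeml-style estimators.
    """
    aln = CodonAlignment(list(names), [seq_a, seq_b], code)
    tree = PhyloTree.from_newick(f"({names[0]}:0.05,{names[1]}:0.05);")
    fit = fit_model(aln, tree, ONE_RATIO, config or FitConfig(n_starts=2))
    t = sum(fit.tree.lengths[e] for e in fit.tree.edges())
    params = fit.params
    ii, jj, ts, ns = code.neighbor_table()

    def flows(omega):
        p = params.with_omega(background=omega, foreground=omega)
        Q = build_rate_matrix(p, code, BACKGROUND)
        flow = params.pi[ii] * Q[ii, jj]
        total = flow.sum()
        return flow[ns].sum() / total

    pN = flows(params.omega_background)
    pN1 = flows(1.0)
    at_floor = t <= 1e-5
    ka = 0.0 if at_floor else t * pN / (3.0 * pN1)
    ks = 0.0 if at_floor else t * (1.0 - pN) / (3.0 * (1.0 - pN1))
    undefined = ks < 1e-6
    return KaKsResult(
        ka=ka,
        ks=ks,
        omega=float("nan") if undefined else params.omega_background,
        t=t,
        kappa=params.kappa,
        undefined=undefined,
    )


def date_loss_of_function(inp: LossDatingInput) -> float:
    """Date a loss of selective constraint from a branch-averaged omega.

    Assumes the focal branch of duration T splits into a constrained era at
    omega_c followed by a neutral era at omega 1, so the branch average
    satisfies omega_obs * T = omega_c * (T - t_loss) + 1 * t_loss. Solving,

        t_loss = T * (omega_obs - omega_c) / (1 - omega_c),

    clamped to [0, T] and returned in million years before present.
    """
    if inp.omega_constrained >= 1.0:
        raise ValueError("omega_constrained = 1 is degenerate: no constraint to lose")
    if inp.omega_obs > 1.0:
        raise ValueError(
            "omega_obs > 1 is outside the constrained/neutral mixture model "
            "(positive selection cannot be dated this way)"
        )
    if inp.omega_obs < inp.omega_constrained:
        warnings.warn(
            "observed omega below the constrained-era omega; dating loss at 0 My",
            RuntimeWarning,
        )
        return 0.0
    t_loss = (
        inp.duration_my
        * (inp.omega_obs - inp.omega_constrained)
        / (1.0 - inp.omega_constrained)
    )
    return float(np.clip(t_loss, 0.0, inp.duration_my))
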