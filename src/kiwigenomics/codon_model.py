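"""Goldman-Yang 61-state codon substitution model.

The instantaneous rate from codon i to j is zero unless they differ at a
single position; otherwise it is proportional to the target codon's
equilibrium frequency pi_j, multiplied by kappa for transitions and by the
branch-class omega (dN/dS) for nonsynonymous changes. Each matrix is
rescaled so branch lengths are expected substitutions per codon. The model
is time-reversible, so P(t) is computed by symmetric eigendecomposition —
one decomposition per (kappa, omega, pi) serves every branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetics import GeneticCode, UNIVERSAL_CODE

BACKGROUND = "background"
FOREGROUND = "foreground"


@dataclass
class CodonModelParams:
    """Parameters of the branch codon model.

    kappa: transition/transversion rate ratio (> 0).
    omega_background / omega_foreground: dN/dS on the two branch classes
    (>= 0); under a one-ratio model they are equal.
    pi: equilibrium frequencies over the sense codons (sum to 1).
    """

    kappa: float
    omega_background: float
    omega_foreground: float = None
    pi: np.ndarray = None
    code: GeneticCode = field(default_factory=lambda: UNIVERSAL_CODE)

    def __post_init__(self):
        if self.omega_foreground is None:
            self.omega_foreground = self.omega_background
        self.kappa = float(self.kappa)
        self.omega_background = float(self.omega_background)
        self.omega_foreground = float(self.omega_foreground)
        if self.pi is None:
            n = self.code.n_states
            self.pi = np.full(n, 1.0 / n)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.omega_background < 0 or self.omega_foreground < 0:
            raise ValueError("omega must be nonnegative")
        if self.pi.shape != (self.code.n_states,):
            raise ValueError(
                f"pi must have {self.code.n_states} entries, got {self.pi.shape}"
            )
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be nonnegative and sum to 1")

    def omega(self, branch_class: str) -> float:
        if branch_class == BACKGROUND:
            return self.omega_background
        if branch_class == FOREGROUND:
            return self.omega_foreground
        raise ValueError(f"unknown branch class {branch_class!r}")

    def with_omega(self, background=None, foreground=None) -> "CodonModelParams":
        return replace(
            self,
            omega_background=self.omega_background if background is None else background,
            omega_foreground=self.omega_foreground if foreground is None else foreground,
        )


def build_rate_matrix(
    params: CodonModelParams,
    code: GeneticCode = None,
    branch_class: str = BACKGROUND,
) -> np.ndarray:
    """Scaled instantaneous rate matrix Q for one branch class.

    Rows sum to zero and sum_i pi_i * (-q_ii) = 1, so t is measured in
    expected substitutions per codon.
    """
    code = code or params.code
    omega = params.omega(branch_class)
    n = code.n_states
    ii, jj, ts, ns = code.neighbor_table()
    rates = params.pi[jj].copy()
    rates[ts] *= params.kappa
    rates[ns] *= omega
    Q = np.zeros((n, n))
    Q[ii, jj] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(params.pi * np.diag(Q)).sum()
    if mean_rate <= 0:
        raise ValueError("degenerate rate matrix: zero total substitution rate")
    return Q / mean_rate


class SpectralCodonMatrix:
    """Eigendecomposed reversible Q for cheap P(t) at many branch lengths.

    Q = D^{-1/2} (D^{1/2} Q D^{-1/2}) D^{1/2} with the inner matrix
    symmetric for a reversible chain; eigh gives orthonormal U so
    P(t) = D^{-1/2} U exp(L t) U' D^{1/2}.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        mask = pi > 0
        if not mask.all():
            raise ValueError("spectral decomposition requires strictly positive pi")
        sq = np.sqrt(pi)
        sym = (Q * sq[:, None]) / sq[None, :]
        sym = 0.5 * (sym + sym.T)  # enforce exact symmetry against roundoff
        lam, U = np.linalg.eigh(sym)
        self.lam = lam
        self.left = U / sq[:, None]          # D^{-1/2} U
        self.right = (U * sq[:, None]).T     # U' D^{1/2}
        self.pi = pi

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probabilities(Q: np.ndarray, t: float, pi: np.ndarray = None) -> np.ndarray:
    """P(t) = expm(Q t), row-stochastic with tiny negatives clamped.

    When ``pi`` is supplied the reversible spectral route is used;
    otherwise falls back to scipy's expm.
    """
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if pi is not None:
        return SpectralCodonMatrix(Q, pi).transition_matrix(t)
    from scipy.linalg import expm

    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P
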