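"""Core state space and transition structure of the IWE-SSE methylation model.

A CpG site is in one of three states — unmethylated ``u``, partially
methylated ``p``, methylated ``m`` — and evolves by *single-site events*
(SSEs): at rate ``R`` the site redraws its state from the equilibrium
triple ``(pi_u, pi_p, pi_m)`` of its CpG island, possibly redrawing the
same state.  This is an F81-type process on three states, so transition
probabilities over an interval have a closed form.

*Island-wide events* (IWEs) replace the island's equilibrium triple with a
fresh one and simultaneously move every site by a minimal-motion stochastic
matrix ``M`` chosen so that the expected state frequencies match the new
triple immediately after the event.

Per-site rate factors follow an invariant+gamma mixture: ``R = 0`` with
probability ``r``, otherwise one of three discretized-gamma categories of
mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "STATE_CODES",
    "STATE_LABELS",
    "MISSING",
    "N_STATES",
    "validate_triple",
    "random_triple",
    "sse_rate_matrix",
    "sse_transition_matrix",
    "iwe_transition_matrix",
    "discretize_gamma",
    "RateModel",
    "GlobalParams",
    "compose_interval_transition",
    "silent_sse_fraction",
]

#: Integer codes of the methylation states.
STATE_CODES = {"u": 0, "p": 1, "m": 2, "missing": 3}
STATE_LABELS = ("u", "p", "m")
#: Code for an unobserved/missing state (only produced by data readers).
MISSING = 3
N_STATES = 3

_TRIPLE_FLOOR = 1e-12
_SIMPLEX_TOL = 1e-9


def validate_triple(pi, *, strict: bool = False) -> np.ndarray:
    """Validate an equilibrium triple ``(pi_u, pi_p, pi_m)``.

    Parameters
    ----------
    pi : array-like of 3 floats
        Point on the 2-simplex.
    strict : bool
        Require every component to exceed a small floor (needed wherever a
        component appears in a divisor, e.g. IWE transition matrices).

    Returns
    -------
    numpy.ndarray of shape (3,)
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (3,):
        raise ValueError(f"equilibrium triple must have 3 components, got shape {pi.shape}")
    if not np.all(np.isfinite(pi)):
        raise ValueError(f"equilibrium triple has non-finite components: {pi}")
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError(f"equilibrium triple components must lie in [0, 1]: {pi}")
    if abs(pi.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError(f"equilibrium triple must sum to 1 (got sum {pi.sum()!r})")
    if strict and np.any(pi < _TRIPLE_FLOOR):
        raise ValueError(
            f"degenerate equilibrium triple (component below {_TRIPLE_FLOOR}): {pi}"
        )
    return pi


def random_triple(rng: np.random.Generator) -> np.ndarray:
    """Draw an equilibrium triple uniformly on the simplex, i.e. Dirichlet(1,1,1)."""
    return rng.dirichlet(np.ones(3))


def sse_rate_matrix(pi, R: float) -> np.ndarray:
    """Rate matrix of the single-site event process.

    Off-diagonal entry ``(i, j)`` is ``R * pi_j``: at rate ``R`` the site
    redraws its state from the island's equilibrium triple.  ``pi`` is a
    stationary left eigenvector.
    """
    pi = validate_triple(pi)
    if R < 0:
        raise ValueError(f"rate factor must be nonnegative, got {R}")
    Q = np.tile(pi, (3, 1)) * R
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def sse_transition_matrix(pi, R: float, dt: float) -> np.ndarray:
    """Closed-form transition probabilities of the SSE process over time ``dt``.

    Equals ``expm(Q dt)`` for the F81-type rate matrix: with
    ``e = exp(-R dt)``, entry ``(i, j)`` is ``(1-e) pi_j`` for ``j != i``
    and ``pi_i + (1-pi_i) e`` on the diagonal.
    """
    pi = validate_triple(pi)
    if R < 0:
        raise ValueError(f"rate factor must be nonnegative, got {R}")
    if dt < 0:
        raise ValueError(f"duration must be nonnegative, got {dt}")
    e = np.exp(-R * dt)
    P = (1.0 - e) * np.tile(pi, (3, 1))
    P[np.diag_indices(3)] += e
    return P


def iwe_transition_matrix(pi_old, pi_new) -> np.ndarray:
    """Minimal-motion stochastic matrix applied to every site at an IWE.

    States whose equilibrium frequency decreases keep their state with
    probability ``pi'_s / pi_s`` and move to increasing states with the
    complementary mass, split proportionally to the frequency gains; states
    whose frequency does not decrease stay put.  This yields
    ``pi_old @ M == pi_new`` and moves as little probability as possible.

    States with ``pi'_s == pi_s`` have an identity row, which makes the two
    w.l.o.g. case matrices (one state gains / one state loses) coincide with
    this single rule.
    """
    pi_old = validate_triple(pi_old, strict=True)
    pi_new = validate_triple(pi_new, strict=True)
    M = np.eye(3)
    gain = np.clip(pi_new - pi_old, 0.0, None)
    total_gain = gain.sum()
    if total_gain <= 0.0:
        return M
    for a in range(3):
        if pi_new[a] < pi_old[a]:
            move = pi_old[a] - pi_new[a]
            M[a, a] = pi_new[a] / pi_old[a]
            for b in range(3):
                if b != a and gain[b] > 0.0:
                    M[a, b] = (move / pi_old[a]) * (gain[b] / total_gain)
    return M


def discretize_gamma(alpha: float, K: int = 3) -> np.ndarray:
    """Discretize a mean-1 gamma distribution into ``K`` equal-probability rates.

    Each rate is the conditional mean of Gamma(shape=``alpha``, mean=1) on one
    of ``K`` equal-probability quantile slices, renormalized so the category
    mean is exactly 1.

    Returns the rates sorted ascending.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"gamma shape must be positive and finite, got {alpha}")
    if K < 1:
        raise ValueError("need at least one category")
    probs = np.arange(K + 1) / K
    # Quantile boundaries of Gamma(alpha, rate=alpha).
    bounds = special.gammaincinv(alpha, probs) / alpha
    # E[X; X in (a,b)] for X ~ Gamma(alpha, rate=alpha) is
    # P(alpha+1, alpha*b) - P(alpha+1, alpha*a); slice probability is 1/K.
    upper = special.gammainc(alpha + 1, alpha * bounds[1:])
    lower = special.gammainc(alpha + 1, alpha * bounds[:-1])
    rates = K * (upper - lower)
    rates = rates / rates.mean()
    return rates


@dataclass(frozen=True)
class RateModel:
    """Invariant+gamma mixture of per-site rate factors.

    ``R = 0`` with probability ``r``; with probability ``1 - r`` it takes one
    of three discretized-gamma values of mean 1 (probability ``(1-r)/3``
    each), so ``E[R | R > 0] = 1`` and overall ``E[R] = 1 - r``.
    """

    r: float
    alpha: float
    n_gamma_categories: int = 3

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"invariant fraction must lie in [0, 1], got {self.r}")
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"gamma shape must be positive, got {self.alpha}")

    @property
    def rates(self) -> np.ndarray:
        """Rate values, invariant category first: ``[0, g1, g2, g3]``."""
        return np.concatenate([[0.0], discretize_gamma(self.alpha, self.n_gamma_categories)])

    @property
    def weights(self) -> np.ndarray:
        """Category probabilities ``[r, (1-r)/K, ...]``."""
        K = self.n_gamma_categories
        return np.concatenate([[self.r], np.full(K, (1.0 - self.r) / K)])


@dataclass(frozen=True)
class GlobalParams:
    """Global model parameters ``(r, alpha, mu)``.

    ``r``: invariant site fraction; ``alpha``: gamma shape of rate
    heterogeneity; ``mu``: IWE rate per island per SSE time unit.
    """

    r: float
    alpha: float
    mu: float

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r must lie in [0, 1], got {self.r}")
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.mu < 0:
            raise ValueError(f"mu must be nonnegative, got {self.mu}")

    @property
    def rate_model(self) -> RateModel:
        return RateModel(self.r, self.alpha)


def compose_interval_transition(P0: np.ndarray, events) -> np.ndarray:
    """Transition matrix across a branch interval carrying IWEs.

    ``P0`` is the SSE transition matrix of the segment before the first IWE;
    ``events`` is a sequence of ``(M_k, P_k)`` pairs, one per IWE, where
    ``M_k`` is the IWE transition matrix and ``P_k`` the SSE matrix of the
    segment that follows.  Returns ``P0 @ prod_k (M_k @ P_k)``.
    """
    out = np.asarray(P0, dtype=float)
    _check_stochastic(out)
    for M, P in events:
        _check_stochastic(M)
        _check_stochastic(P)
        out = out @ M @ P
    return out


def _check_stochastic(A: np.ndarray) -> None:
    A = np.asarray(A)
    if A.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {A.shape}")
    if np.any(A < -1e-12) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("matrix is not row-stochastic")


def silent_sse_fraction(pi) -> float:
    """Expected fraction of SSEs that do not change the state: ``sum pi_s^2``.

    Minimized at the simplex center with value 1/3 (squared distance from the
    origin to the plane ``pi_u + pi_p + pi_m = 1``).
    """
    pi = validate_triple(pi)
    return float(np.dot(pi, pi))
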