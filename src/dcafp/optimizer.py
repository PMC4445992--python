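"""Alternating constrained optimization of the co-clustering objective.

The method seeks a pairwise co-clustering likelihood matrix W ∈ [0,1]^{n×n}
and per-protein functional-preference vectors r_i (nonnegative, summing to 1
over the three GO aspects) maximizing

    J(W, R) = Tr((W_T)ᵀ W_D W_T) + β Tr(Σ_m Wᵀ S_m) − ‖W‖_F² − ‖R‖_F²

where W_T = T∘W, W_D = D∘W and S_m = [a_ij^m r_im]. The first term rewards
placing pairs with many shared, co-clustered interaction partners together
(density); the second rewards co-clustering pairs that are functionally
similar in the aspects the proteins prefer; the Frobenius terms regularize.

Each outer iteration updates every preference row by a primal–dual
active-set step on the 3-simplex, then refreshes every likelihood entry
simultaneously (a Jacobi sweep) from its per-entry concave subproblem,
clipping to [0, 1]. Iteration stops when |J^{(l+1)} − J^{(l)}| ≤ δ or after
l_max iterations.

Two computation modes are provided. ``"as-printed"`` (the default) applies
the update formulas of the original method description verbatim: the
preference gradient carries coefficient −1 on r_im and the likelihood
stationary point is used without the 1/2 factor. ``"corrected-gradient"``
uses the analytically exact derivatives of J (coefficient −2 r_im, β on the
functional sum, and the stationary point halved), which makes the updates
consistent with finite differences and per-entry grid maximization. Both
modes keep all iterates feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PPINetwork
from .similarity import SimilarityBundle

MODES = ("as-printed", "corrected-gradient")

#: number of functional categories (the three GO aspects)
N_CATEGORIES = 3

#: a preference component at or below this value with an inward-pushing
#: direction is treated as an active nonnegativity constraint
ACTIVE_TOL = 1e-12

#: row-sum drift beyond this triggers renormalization back onto the simplex
_DRIFT_TOL = 1e-9


@dataclass
class OptParams:
    """Knobs of the alternating optimization.

    l_max and delta default to the recommended operating point (100
    iterations, absolute objective change ≤ 1); beta weights the functional
    term and defaults to 1, which makes the trace form of the objective and
    its expanded form coincide.
    """

    l_max: int = 100
    delta: float = 1.0
    beta: float = 1.0
    seed: int | None = None
    mode: str = "as-printed"
    active_tol: float = ACTIVE_TOL

    def __post_init__(self) -> None:
        if self.l_max < 1:
            raise ValueError("l_max must be >= 1")
        if self.delta < 0 or self.beta < 0:
            raise ValueError("delta and beta must be nonnegative")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class OptState:
    """Result of :func:`optimize`: final W*, R*, the objective trace and
    bookkeeping. ``renormalizations`` counts preference rows whose sum
    drifted off 1 by more than 1e−9 after a step and were renormalized."""

    W: np.ndarray
    R: np.ndarray
    J_trace: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False
    renormalizations: int = 0


def _check_shapes(W: np.ndarray, R: np.ndarray, n: int) -> None:
    if W.shape != (n, n):
        raise ValueError(f"W must be {n}x{n}, got {W.shape}")
    if R.shape != (n, N_CATEGORIES):
        raise ValueError(f"R must be {n}x{N_CATEGORIES}, got {R.shape}")


def _triangle_matrix(W: np.ndarray, T: np.ndarray) -> np.ndarray:
    """M[i, j] = Σ_k w_ik w_jk t_ik t_jk — the common-neighbor co-clustering
    mass of the pair, computed as (W∘T)(W∘T)ᵀ."""
    WT = W * T
    return WT @ WT.T


def _functional_pair_scores(A_stack: np.ndarray, R: np.ndarray) -> np.ndarray:
    """F[i, j] = Σ_m a_ij^m r_im (the row protein's preferences weight the
    aspect similarities; F is not symmetric in general)."""
    return np.einsum("mij,im->ij", A_stack, R)


def objective(
    W: np.ndarray,
    R: np.ndarray,
    T: np.ndarray,
    D: np.ndarray,
    A_bundle: SimilarityBundle,
    beta: float = 1.0,
) -> float:
    """Evaluate J(W, R). Diagonal pairs contribute nothing because T, D and
    every A_m have zero diagonals and W's diagonal is held at 0."""
    n = T.shape[0]
    _check_shapes(W, R, n)
    M = _triangle_matrix(W, T)
    density_term = float(np.sum(D * W * M))
    functional_term = beta * float(
        np.sum(W * _functional_pair_scores(A_bundle.functional_stack, R))
    )
    return density_term + functional_term - float(np.sum(W * W)) - float(np.sum(R * R))


def _gradient_matrix(
    W: np.ndarray, A_bundle: SimilarityBundle, R: np.ndarray, beta: float, mode: str
) -> np.ndarray:
    """Per-row preference gradients, stacked: G[i, m] = ∂J(r_i|W)/∂r_im."""
    A_stack = A_bundle.functional_stack
    # F[i, m] = Σ_j w_ij a_ij^m
    F = np.einsum("ij,mij->im", W, A_stack)
    if mode == "as-printed":
        return -R + F
    return -2.0 * R + beta * F


def preference_gradient(
    i: int,
    W: np.ndarray,
    A_bundle: SimilarityBundle,
    R: np.ndarray,
    beta: float = 1.0,
    mode: str = "as-printed",
) -> np.ndarray:
    """Gradient of the restricted objective J(r_i | W) at the current r_i."""
    return _gradient_matrix(W, A_bundle, R, beta, mode)[i]


def max_step(r: np.ndarray, delta_r: np.ndarray) -> float:
    """Largest step λ ∈ (0, 1] along ``delta_r`` keeping every component of
    ``r + λ·delta_r`` nonnegative (1 caps the step for the equality
    constraint's sake)."""
    neg = delta_r < 0
    if not np.any(neg):
        return 1.0
    return float(min(1.0, np.min(r[neg] / (-delta_r[neg]))))


def _step_direction(g: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Active-set step: zero on active constraints, otherwise the gradient
    recentred by the mean-like correction with denominator
    n_Λ − n_P + 1."""
    n_p = int(active.sum())
    correction = g[~active].sum() / (N_CATEGORIES - n_p + 1)
    delta = g - correction
    delta[active] = 0.0
    return delta


def _update_row(
    r: np.ndarray, g: np.ndarray, active_tol: float
) -> tuple[np.ndarray, float, bool]:
    """One active-set step for a single preference row.

    Returns (new row, λ, renormalized?). A nonnegativity constraint is active
    when the component sits at (numerically) zero and the tentative
    unconstrained direction would push it negative.
    """
    tentative = _step_direction(g, np.zeros(N_CATEGORIES, dtype=bool))
    active = (r <= active_tol) & (tentative < 0)
    delta = _step_direction(g, active) if active.any() else tentative
    if np.all(delta == 0.0):
        return r, 1.0, False
    lam = max_step(r, delta)
    r_new = np.maximum(r + lam * delta, 0.0)
    s = float(r_new.sum())
    if s <= 1e-12:  # degenerate: direction annihilated the row
        return np.full(N_CATEGORIES, 1.0 / N_CATEGORIES), lam, True
    if abs(s - 1.0) > _DRIFT_TOL:
        return r_new / s, lam, True
    return r_new, lam, False


def update_preference_vector(
    i: int,
    R: np.ndarray,
    W: np.ndarray,
    A_bundle: SimilarityBundle,
    beta: float = 1.0,
    mode: str = "as-printed",
    active_tol: float = ACTIVE_TOL,
) -> tuple[np.ndarray, float]:
    """Update the preference row of protein ``i``; returns (new r_i, λ_i)."""
    g = preference_gradient(i, W, A_bundle, R, beta=beta, mode=mode)
    r_new, lam, _ = _update_row(R[i].copy(), g, active_tol)
    return r_new, lam


def update_R(
    R: np.ndarray,
    W: np.ndarray,
    A_bundle: SimilarityBundle,
    beta: float = 1.0,
    mode: str = "as-printed",
    active_tol: float = ACTIVE_TOL,
) -> np.ndarray:
    """Update every preference row; the rows are independent subproblems."""
    R_new, _ = _update_R_counted(R, W, A_bundle, beta, mode, active_tol)
    return R_new


def _update_R_counted(
    R: np.ndarray,
    W: np.ndarray,
    A_bundle: SimilarityBundle,
    beta: float,
    mode: str,
    active_tol: float,
) -> tuple[np.ndarray, int]:
    G = _gradient_matrix(W, A_bundle, R, beta, mode)
    R_new = np.empty_like(R)
    n_renorm = 0
    for i in range(R.shape[0]):
        R_new[i], _, renormed = _update_row(R[i].copy(), G[i], active_tol)
        n_renorm += renormed
    return R_new, n_renorm


def update_W(
    W: np.ndarray,
    R: np.ndarray,
    T: np.ndarray,
    D: np.ndarray,
    A_bundle: SimilarityBundle,
    beta: float = 1.0,
    mode: str = "as-printed",
) -> np.ndarray:
    """Simultaneous (Jacobi) refresh of every likelihood entry.

    The unconstrained optimum of the per-entry concave subproblem is
    w* = d_ij Σ_k w_ik w_jk t_ik t_jk + β Σ_m a_ij^m r_im (halved in
    corrected mode); the constrained update clips it to [0, 1]. All
    right-hand-side W values are the incoming iterate, so the sweep is
    order-free and equivariant under protein relabeling.
    """
    n = T.shape[0]
    _check_shapes(W, R, n)
    W_star = D * _triangle_matrix(W, T) + beta * _functional_pair_scores(
        A_bundle.functional_stack, R
    )
    if mode == "corrected-gradient":
        W_star = W_star / 2.0
    np.fill_diagonal(W_star, 0.0)
    return np.clip(W_star, 0.0, 1.0)


def initialize(
    n_V: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random starting point: W off-diagonal ~ U(0,1); preference rows at the
    simplex barycenter with ±0.01 uniform jitter, clipped and renormalized."""
    W = rng.uniform(0.0, 1.0, size=(n_V, n_V))
    np.fill_diagonal(W, 0.0)
    R = 1.0 / N_CATEGORIES + rng.uniform(-0.01, 0.01, size=(n_V, N_CATEGORIES))
    R = np.maximum(R, 0.0)
    R /= R.sum(axis=1, keepdims=True)
    return W, R


def optimize(
    network: PPINetwork,
    sims: SimilarityBundle,
    params: OptParams | None = None,
) -> OptState:
    """Run the alternating optimization to convergence.

    Records J after every full (R then W) iteration, starting with the
    objective of the random initial point; stops when the absolute change in
    J drops to ``params.delta`` or at ``params.l_max`` iterations.
    Non-convergence at l_max is flagged on the returned state, not an error.
    """
    params = params or OptParams()
    rng = np.random.default_rng(params.seed)
    T = network.T
    W, R = initialize(network.n_V, rng)
    state = OptState(W=W, R=R)
    state.J_trace.append(objective(W, R, T, sims.D, sims, params.beta))
    for _ in range(params.l_max):
        R, n_renorm = _update_R_counted(
            R, W, sims, params.beta, params.mode, params.active_tol
        )
        state.renormalizations += n_renorm
        W = update_W(W, R, T, sims.D, sims, params.beta, params.mode)
        state.iterations_run += 1
        state.J_trace.append(objective(W, R, T, sims.D, sims, params.beta))
        if abs(state.J_trace[-1] - state.J_trace[-2]) <= params.delta:
            state.converged = True
            break
    state.W, state.R = W, R
    return state
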