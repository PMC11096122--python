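"""MityBayes: binomial-mixture clonal assignment from mtDNA variant counts.

Cells are assigned to clones using both the presence and the heteroplasmy
level of mtDNA variants. The alternate read count of variant v in cell c is
Binomial(n = total reads, p = clone-specific heteroplasmy P_kv), cells are
exchangeable draws from clone fractions pi, and the fit maximizes the
marginal MAP objective

    sum_c log sum_k pi_k prod_v Binom(a_cv | t_cv, P_kv)  +  log prior

with Dirichlet(alpha) prior on pi and Beta(a, b) priors on each P_kv. Two
backends optimize the same objective: EM (default; exactly monotone) and a
gradient ascent on softmax/sigmoid-parameterized (pi, P) with backtracking
line search — a point-mass (MAP) treatment of the latent parameters, so both
backends agree at the optimum. An exhaustive-enumeration oracle
(:func:`exact_posterior`) provides ground truth on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp, softmax

P_EPS = 1e-6  # heteroplasmy clipped to [P_EPS, 1 - P_EPS] for stable logs


@dataclass
class Priors:
    """Hyperparameters: Dirichlet concentration for pi, Beta(a, b) for each P."""

    alpha: float = 1.0
    a: float = 1.0
    b: float = 1.0
    K_prior: int | None = None

    def __post_init__(self) -> None:
        if min(self.alpha, self.a, self.b) <= 0:
            raise ValueError("all prior hyperparameters must be positive")


@dataclass
class CloneModel:
    """A fitted clone model.

    ``pi`` (K,) clone fractions; ``P`` (K, V) clone heteroplasmy; ``gamma``
    (cells, K) assignment probabilities; ``contribution`` (V,) per-variant
    informativeness in [0, 1]; ``elbo_trace`` the objective per iteration.
    """

    K: int
    pi: np.ndarray
    P: np.ndarray
    gamma: np.ndarray
    contribution: np.ndarray
    elbo_trace: np.ndarray
    converged: bool
    seed: int
    backend: str = "em"
    data_loglik: float = float("nan")
    objective: float = float("nan")
    n_restarts: int = 1


def _validate(
    alt: np.ndarray, total: np.ndarray, K: int, allow_empty_clones: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(alt, dtype=float)
    T = np.asarray(total, dtype=float)
    if A.shape != T.shape or A.ndim != 2:
        raise ValueError("alt and total must be 2-D arrays of equal shape (cells x variants)")
    if (A < 0).any() or (T < 0).any() or (A > T).any():
        raise ValueError("require 0 <= alt <= total elementwise")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > A.shape[0] and not allow_empty_clones:
        raise ValueError(f"K={K} exceeds the number of cells ({A.shape[0]})")
    return A, T


def _binom_const(A: np.ndarray, T: np.ndarray) -> float:
    return float(np.sum(gammaln(T + 1) - gammaln(A + 1) - gammaln(T - A + 1)))


def _loglik_matrix(A: np.ndarray, T: np.ndarray, P: np.ndarray) -> np.ndarray:
    """(cells x K) binomial log likelihood, excluding the combinatorial constant."""
    logP = np.log(P)
    log1mP = np.log1p(-P)
    return A @ logP.T + (T - A) @ log1mP.T


def _objective(
    A: np.ndarray, T: np.ndarray, pi: np.ndarray, P: np.ndarray, priors: Priors, const: float
) -> tuple[float, np.ndarray, float]:
    """Returns (MAP objective, responsibilities gamma, data log-likelihood)."""
    L = _loglik_matrix(A, T, P)
    logpost = L + np.log(np.clip(pi, 1e-300, None))
    lse = logsumexp(logpost, axis=1)
    gamma = np.exp(logpost - lse[:, None])
    data_ll = float(lse.sum() + const)
    prior = float(
        (priors.alpha - 1.0) * np.sum(np.log(np.clip(pi, 1e-300, None)))
        + (priors.a - 1.0) * np.sum(np.log(P))
        + (priors.b - 1.0) * np.sum(np.log1p(-P))
    )
    return data_ll + prior, gamma, data_ll


def _init_P(A: np.ndarray, T: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Initialize clone heteroplasmy from K random cells' observed fractions."""
    C = A.shape[0]
    idx = rng.choice(C, size=K, replace=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(T[idx] > 0, A[idx] / np.maximum(T[idx], 1), 0.5)
    jitter = rng.uniform(-0.05, 0.05, size=frac.shape)
    return np.clip(frac + jitter, P_EPS, 1 - P_EPS)


def _em_fit(A, T, K, priors, rel_tol, max_iter, rng) -> dict:
    C, V = A.shape
    const = _binom_const(A, T)
    pi = np.full(K, 1.0 / K)
    P = _init_P(A, T, K, rng)
    trace = []
    converged = False
    obj, gamma, data_ll = _objective(A, T, pi, P, priors, const)
    for _ in range(max_iter):
        # M-step (MAP updates)
        Nk = gamma.sum(axis=0)
        pi = np.clip(Nk + priors.alpha - 1.0, 0.0, None)
        pi = pi / pi.sum() if pi.sum() > 0 else np.full(K, 1.0 / K)
        num = gamma.T @ A + priors.a - 1.0
        den = gamma.T @ T + priors.a + priors.b - 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        P = np.clip(P, P_EPS, 1 - P_EPS)
        new_obj, gamma, data_ll = _objective(A, T, pi, P, priors, const)
        trace.append(new_obj)
        if abs(new_obj - obj) <= rel_tol * max(abs(obj), 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    return dict(pi=pi, P=P, gamma=gamma, trace=np.array(trace), converged=converged,
                objective=obj, data_loglik=data_ll)


def _grad_fit(A, T, K, priors, lr, rel_tol, max_iter, rng) -> dict:
    """Gradient ascent on (softmax(s), sigmoid(Q)) with backtracking line search.

    Optimizes the identical MAP objective as EM; backtracking guarantees a
    monotone objective trace.
    """
    const = _binom_const(A, T)

    def unpack(s, Q):
        pi = softmax(s)
        P = np.clip(1.0 / (1.0 + np.exp(-Q)), P_EPS, 1 - P_EPS)
        return pi, P

    s = np.zeros(K)
    Q = rng.normal(0.0, 0.5, size=(K, A.shape[1]))
    pi, P = unpack(s, Q)
    obj, gamma, data_ll = _objective(A, T, pi, P, priors, const)
    trace = [obj]
    converged = False
    for _ in range(max_iter):
        # gradients at current point
        gP = (gamma.T @ A) * (1 - P) - (gamma.T @ (T - A)) * P
        gP += (priors.a - 1.0) * (1 - P) - (priors.b - 1.0) * P
        gs = (gamma.sum(axis=0) - gamma.shape[0] * pi) + (priors.alpha - 1.0) * (1.0 - K * pi)
        step = lr
        improved = False
        for _ in range(40):
            s_new, Q_new = s + step * gs, Q + step * gP
            pi_new, P_new = unpack(s_new, Q_new)
            new_obj, new_gamma, new_data_ll = _objective(A, T, pi_new, P_new, priors, const)
            if new_obj >= obj:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True
            break
        s, Q, pi, P, gamma = s_new, Q_new, pi_new, P_new, new_gamma
        rel = abs(new_obj - obj) / max(abs(obj), 1.0)
        obj, data_ll = new_obj, new_data_ll
        trace.append(obj)
        if rel < rel_tol:
            converged = True
            break
    return dict(pi=pi, P=P, gamma=gamma, trace=np.array(trace), converged=converged,
                objective=obj, data_loglik=data_ll)


def _variant_contribution(A, T, gamma, P) -> np.ndarray:
    """Informativeness: expected log-likelihood gain of clone-specific over
    pooled heteroplasmy, per variant, rescaled to [0, 1]."""
    tot = T.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(tot > 0, A.sum(axis=0) / np.maximum(tot, 1), 0.5)
    pooled = np.clip(pooled, P_EPS, 1 - P_EPS)
    # per (cell, clone, variant) log-likelihood difference; binomial constants cancel
    ll_clone = (
        A[:, None, :] * np.log(P)[None, :, :] + (T - A)[:, None, :] * np.log1p(-P)[None, :, :]
    )
    ll_pool = A * np.log(pooled) + (T - A) * np.log1p(-pooled)
    diff = (gamma[:, :, None] * (ll_clone - ll_pool[:, None, :])).sum(axis=(0, 1))
    raw = np.clip(diff, 0.0, None)
    mx = raw.max()
    return raw / mx if mx > 0 else raw


def fit(
    alt,
    total,
    K: int,
    priors: Priors | None = None,
    backend: str = "em",
    lr: float = 0.1,
    rel_tol: float = 1e-5,
    max_iter: int = 500,
    n_restarts: int = 8,
    seed: int = 0,
) -> CloneModel:
    """Fit the clone model, keeping the best of ``n_restarts`` random starts.

    ``backend`` is ``"em"`` (default) or ``"map_grad"``; both maximize the
    same MAP objective and agree at the optimum. Deterministic given ``seed``.
    Raises on K exceeding the cell count; a non-finite objective raises a
    numerical error naming the iteration.
    """
    priors = priors or Priors()
    A, T = _validate(alt, total, K)
    if backend not in ("em", "map_grad"):
        raise ValueError(f"unknown backend {backend!r}")
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    best: dict | None = None
    for s in seeds:
        rng = np.random.default_rng(s)
        if backend == "em":
            res = _em_fit(A, T, K, priors, rel_tol, max_iter, rng)
        else:
            res = _grad_fit(A, T, K, priors, lr, rel_tol, max_iter, rng)
        if not np.isfinite(res["objective"]):
            bad = int(np.flatnonzero(~np.isfinite(res["trace"]))[0]) if len(res["trace"]) else 0
            raise FloatingPointError(f"non-finite objective at iteration {bad}")
        if best is None or res["objective"] > best["objective"]:
            best = res
    contribution = _variant_contribution(A, T, best["gamma"], best["P"])
    return CloneModel(
        K=K,
        pi=best["pi"],
        P=best["P"],
        gamma=best["gamma"],
        contribution=contribution,
        elbo_trace=best["trace"],
        converged=bool(best["converged"]),
        seed=seed,
        backend=backend,
        data_loglik=best["data_loglik"],
        objective=best["objective"],
        n_restarts=n_restarts,
    )


def assign_clones(model: CloneModel, min_prob: float = 0.9) -> list:
    """Hard labels: argmax_k gamma (ties to the lowest clone index), or
    ``"unassigned"`` when the maximum falls below ``min_prob``."""
    labels = []
    for row in model.gamma:
        k = int(np.argmax(row))
        labels.append(k if row[k] >= min_prob else "unassigned")
    return labels


def variant_contribution(model: CloneModel) -> np.ndarray:
    """Per-variant informativeness weight in [0, 1] (computed at fit time)."""
    return model.contribution


@dataclass
class ExactPosterior:
    map_assignment: tuple
    map_P: np.ndarray
    map_score: float
    marginals: np.ndarray
    coassignment: np.ndarray
    pi_mode: str = "profile"


def exact_posterior(
    alt,
    total,
    K: int,
    priors: Priors | None = None,
    grid: np.ndarray | None = None,
    pi_mode: str = "profile",
    max_cells: int = 8,
    max_variants: int = 4,
    max_k: int = 3,
) -> ExactPosterior:
    """Exhaustive-enumeration oracle for :func:`fit` on tiny instances.

    Enumerates all K^cells assignments; for each, the heteroplasmy of every
    (clone, variant) is profiled over a grid (default 0.01 steps) — exact
    because the likelihood factorizes over (clone, variant) given the
    assignment — and clone fractions are either profiled at their MAP
    (``pi_mode="profile"``) or held uniform. Returns the global MAP
    assignment and grid-P, per-cell assignment marginals, and the
    co-assignment matrix P(z_i = z_j) from profiled-score weights. Raw
    marginals are label-symmetric under exchangeable priors; comparisons to
    a mixture fit should use the MAP partition and the co-assignment matrix.
    Refuses instances above the size caps.
    """
    priors = priors or Priors()
    A, T = _validate(alt, total, K, allow_empty_clones=True)
    C, V = A.shape
    if C > max_cells or V > max_variants or K > max_k:
        raise ValueError(
            f"instance ({C} cells, {V} variants, K={K}) exceeds oracle caps "
            f"({max_cells}, {max_variants}, {max_k})"
        )
    if grid is None:
        grid = np.arange(0.01, 1.0, 0.01)
    grid = np.asarray(grid, float)
    const = _binom_const(A, T)

    Z = np.array(list(itertools.product(range(K), repeat=C)), dtype=int)  # (N, C)
    onehot = np.eye(K)[Z]  # (N, C, K)
    SA = np.einsum("nck,cv->nkv", onehot, A)
    ST = np.einsum("nck,cv->nkv", onehot, T)
    logg = np.log(grid)
    log1mg = np.log1p(-grid)
    prior_g = (priors.a - 1.0) * logg + (priors.b - 1.0) * log1mg
    # (N, K, V, G) profiled per (clone, variant)
    scores_g = SA[..., None] * logg + (ST - SA)[..., None] * log1mg + prior_g
    best_idx = scores_g.argmax(axis=-1)
    lik = np.take_along_axis(scores_g, best_idx[..., None], axis=-1)[..., 0].sum(axis=(1, 2))
    nk = onehot.sum(axis=1)  # (N, K)
    if pi_mode == "uniform":
        pi_term = -C * np.log(K) * np.ones(len(Z))
    elif pi_mode == "profile":
        pi_hat = (nk + priors.alpha - 1.0) / (C + K * (priors.alpha - 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            logpi = np.log(np.clip(pi_hat, 1e-300, None))
        pi_term = (nk * logpi).sum(axis=1) + (priors.alpha - 1.0) * np.where(
            pi_hat > 0, logpi, 0.0
        ).sum(axis=1)
    else:
        raise ValueError(f"unknown pi_mode {pi_mode!r}")
    S = lik + pi_term + const

    i_map = int(np.argmax(S))
    map_P = grid[best_idx[i_map]]
    w = softmax(S)
    marginals = np.einsum("n,nck->ck", w, onehot)
    coassign = np.einsum("n,nik,njk->ij", w, onehot, onehot)
    return ExactPosterior(
        map_assignment=tuple(int(z) for z in Z[i_map]),
        map_P=map_P,
        map_score=float(S[i_map]),
        marginals=marginals,
        coassignment=coassign,
        pi_mode=pi_mode,
    )


def coassignment_matrix(model: CloneModel) -> np.ndarray:
    """P(two cells share a clone) implied by the fit's soft assignments."""
    M = model.gamma @ model.gamma.T
    np.fill_diagonal(M, 1.0)
    return M


def select_k(
    alt,
    total,
    K_grid,
    priors: Priors | None = None,
    seed: int = 0,
    n_restarts: int = 8,
    backend: str = "em",
    **fit_kwargs,
) -> tuple[int, "pd.DataFrame"]:
    """Choose the clone count by BIC over a grid of K.

    Each K is fitted with multiple restarts; the penalized objective is
    -2 x data log-likelihood + n_params x log(cells) with
    n_params = (K - 1) + K x V. Returns the minimizing K and the full table
    so users can override.
    """
    import pandas as pd

    K_grid = list(K_grid)
    if not K_grid:
        raise ValueError("K_grid must be nonempty")
    A = np.asarray(alt)
    C, V = A.shape
    rows = []
    models = {}
    for i, K in enumerate(sorted(set(K_grid))):
        model = fit(alt, total, K, priors=priors, seed=seed + 7919 * i,
                    n_restarts=n_restarts, backend=backend, **fit_kwargs)
        n_params = (K - 1) + K * V
        bic = -2.0 * model.data_loglik + n_params * np.log(C)
        rows.append({"K": K, "objective": model.objective, "data_loglik": model.data_loglik,
                     "n_params": n_params, "bic": bic})
        models[K] = model
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["bic"].idxmin(), "K"])
    return best_k, table
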