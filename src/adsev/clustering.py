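"""From-scratch K-means (Lloyd) and fuzzy C-means on generic feature vectors.

Both algorithms minimize a squared-Euclidean intra-cluster objective:

* K-means: J = sum_j ||x_j - v_{label(j)}||^2, alternating nearest-center
  assignment and mean updates; multi-restart with greedy distance-weighted
  (k-means++ style) seeding, best restart by final J.
* Fuzzy C-means: J_m = sum_i sum_j u_ij^m ||x_j - v_i||^2 with
  row-stochastic memberships U, fuzziness exponent m > 1, updates
  u_ij = 1 / sum_k (d_ij/d_kj)^{2/(m-1)} and
  v_i = sum_j u_ij^m x_j / sum_j u_ij^m.

Both objectives are provably non-increasing across iterations; the
per-iteration trajectory is recorded and asserted on every run.
Equidistant points break ties toward the lowest center index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ClusterResult", "kmeans", "fcm"]


@dataclass
class ClusterResult:
    """Outcome of one clustering run.

    ``memberships`` is None for K-means; for FCM ``labels`` is the
    argmax-hardened assignment.  ``diagnostics`` records per-iteration
    contract checks (e.g. FCM membership row-sum deviation).
    """

    method: str
    centers: np.ndarray  # (c, d)
    labels: np.ndarray  # (n,)
    memberships: np.ndarray | None  # (n, c) for FCM
    objective_trajectory: np.ndarray
    n_iter: int
    converged: bool
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "method": self.method,
            "centers": self.centers.tolist(),
            "labels": self.labels.tolist(),
            "memberships": None if self.memberships is None
            else self.memberships.tolist(),
            "objective_trajectory": self.objective_trajectory.tolist(),
            "n_iter": self.n_iter,
            "converged": bool(self.converged),
            "seed": self.seed,
        }


def _check_X(X: np.ndarray, k: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("X must be an (n, d) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n; got k={k}, n={n}")
    return X


def _sq_dists(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(n, c) squared Euclidean distances, clipped at 0 against roundoff."""
    d2 = (
        np.einsum("nd,nd->n", X, X)[:, None]
        - 2.0 * X @ centers.T
        + np.einsum("cd,cd->c", centers, centers)[None, :]
    )
    return np.clip(d2, 0.0, None)


def _plusplus_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted (k-means++) seeding.

    The first center is a uniform draw; each subsequent center is
    greedily sampled with probability proportional to the squared
    distance to the nearest already-chosen center.  (The multi-candidate
    "greedy k-means++" variant was deliberately not used: picking the
    potential-minimizing candidate concentrates every restart on the
    same seeding and measurably hurts global-optimum coverage of the
    multi-restart scheme on small instances.)
    """
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = _sq_dists(X, centers[:1]).ravel()
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centers[i] = X[rng.integers(n)]
            continue
        centers[i] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, _sq_dists(X, centers[i: i + 1]).ravel())
    return centers


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, tol: float,
           max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool]:
    centers = _plusplus_init(X, k, rng)
    labels = np.full(X.shape[0], -1)
    trajectory: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(X, centers)
        new_labels = np.argmin(d2, axis=1)  # ties -> lowest index
        trajectory.append(float(d2[np.arange(X.shape[0]), new_labels].sum()))
        new_centers = centers.copy()
        for c in range(k):
            members = new_labels == c
            if members.any():
                new_centers[c] = X[members].mean(axis=0)
            else:
                # empty cluster: re-seed to the point farthest from its center
                residual = d2[np.arange(X.shape[0]), new_labels]
                new_centers[c] = X[np.argmax(residual)]
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        stable = (new_labels == labels).all()
        centers, labels = new_centers, new_labels
        if shift < tol or stable:
            converged = True
            break
    return centers, labels, np.asarray(trajectory), it, converged


def kmeans(X: np.ndarray, k: int, seed: int = 0, n_init: int = 10,
           tol: float = 1e-6, max_iter: int = 300) -> ClusterResult:
    """Multi-restart Lloyd K-means; returns the restart with lowest final J."""
    X = _check_X(X, k)
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    child_seeds = np.random.SeedSequence(seed).spawn(n_init)
    best: tuple | None = None
    for child in child_seeds:
        rng = np.random.default_rng(child)
        run = _lloyd(X, k, rng, tol, max_iter)
        trajectory = run[2]
        if np.any(np.diff(trajectory) > 1e-8 * max(trajectory[0], 1.0)):
            raise AssertionError("K-means objective increased across iterations")
        if best is None or trajectory[-1] < best[2][-1]:
            best = run
    centers, labels, trajectory, n_iter, converged = best
    return ClusterResult(
        method="kmeans", centers=centers, labels=labels, memberships=None,
        objective_trajectory=trajectory, n_iter=n_iter, converged=converged,
        seed=seed, diagnostics={"n_init": n_init},
    )


def fcm(X: np.ndarray, c: int, m: float = 2.0, seed: int = 0,
        tol: float = 1e-6, max_iter: int = 300) -> ClusterResult:
    """Fuzzy C-means from a seeded Dirichlet membership initialization.

    Stops when the largest membership change falls below ``tol``.  A point
    coincident with a center receives membership 1 there (lowest such
    center index on ties) and 0 elsewhere.
    """
    X = _check_X(X, c)
    if m <= 1:
        raise ValueError(f"fuzziness m must be > 1, got {m}")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(c), size=n)  # row-stochastic init

    trajectory: list[float] = []
    row_dev: list[float] = []
    converged = False
    it = 0
    exponent = 1.0 / (m - 1.0)
    for it in range(1, max_iter + 1):
        Um = U ** m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = _sq_dists(X, centers)
        zero_rows = d2 <= 0.0
        with np.errstate(divide="ignore"):
            inv = (1.0 / d2) ** exponent
        U_new = np.empty_like(U)
        finite_mask = ~zero_rows.any(axis=1)
        U_new[finite_mask] = inv[finite_mask] / inv[finite_mask].sum(
            axis=1, keepdims=True)
        for j in np.nonzero(~finite_mask)[0]:
            U_new[j] = 0.0
            U_new[j, int(np.argmax(zero_rows[j]))] = 1.0
        trajectory.append(float((U_new ** m * d2).sum()))
        row_dev.append(float(np.abs(U_new.sum(axis=1) - 1.0).max()))
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta < tol:
            converged = True
            break

    trajectory_arr = np.asarray(trajectory)
    if np.any(np.diff(trajectory_arr) > 1e-8 * max(trajectory_arr[0], 1.0)):
        raise AssertionError("FCM objective increased across iterations")
    if max(row_dev) > 1e-9:
        raise AssertionError("FCM membership rows drifted from sum 1")
    labels = np.argmax(U, axis=1)  # ties -> lowest index
    return ClusterResult(
        method="fcm", centers=centers, labels=labels, memberships=U,
        objective_trajectory=trajectory_arr, n_iter=it, converged=converged,
        seed=seed,
        diagnostics={"m": m, "max_row_sum_deviation": max(row_dev),
                     "row_sum_deviation_trajectory": row_dev},
    )
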