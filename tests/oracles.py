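"""Independent reference implementations used only as test oracles.

Each function here deliberately takes a different algorithmic route from
the package code it cross-checks: quaternion-eigenvalue superposition vs
SVD Kabsch, bisection equilibrium solving vs the closed-form quadratic,
binless MBAR-style reweighting vs binned direct-iteration WHAM, and
exhaustive enumeration vs greedy medoid updates.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD via Horn's quaternion eigenvalue method."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    n = len(P)
    sq = (np.sum(P ** 2) + np.sum(Q ** 2) - 2.0 * lam_max) / n
    return float(np.sqrt(max(sq, 0.0)))


def bound_ligand_bisection(n: float, K: float, M_t: float, L_t: float) -> float:
    """Bound-ligand concentration by bisection on free ligand.

    Mass balance: L_free + n*M_t*theta = L_t with theta = K Lf/(1+K Lf).
    """

    def residual(Lf):
        theta = K * Lf / (1.0 + K * Lf)
        return Lf + n * M_t * theta - L_t

    if residual(0.0) >= 0:
        return 0.0
    Lf = brentq(residual, 0.0, L_t, xtol=1e-18, rtol=1e-15)
    return L_t - Lf


def mbar_pmf(windows, bin_edges, kT, subsample: int = 1):
    """Binless MBAR (UWHAM) free-energy profile, via the convex
    Shirts-Chodera objective minimised with BFGS.

    Returns (bin_centers, F) with F referenced to its minimum; bins with
    no samples get NaN.
    """
    xs = []
    origins = []
    for i, w in enumerate(windows):
        s = w.samples[::subsample]
        xs.append(s)
        origins.append(np.full(len(s), i))
    x = np.concatenate(xs)
    N = np.array([len(s) for s in xs], dtype=float)
    W = len(windows)
    # reduced bias energies u[i, n] in kT units
    u = np.stack(
        [0.5 * w.force_const * (x - w.center) ** 2 / kT for w in windows]
    )

    logN = np.log(N)
    frac = N / N.sum()

    def objective_and_grad(f):
        # (1/Ntot) sum_n logsumexp_j (logN_j + f_j - u_jn) - sum_j (N_j/Ntot) f_j
        terms = logN[:, None] + f[:, None] - u
        a = logsumexp(terms, axis=0)
        soft = np.exp(terms - a)        # (W, Nsamples) softmax weights
        return a.mean() - np.dot(frac, f), soft.mean(axis=1) - frac

    res = minimize(
        objective_and_grad, np.zeros(W), jac=True, method="BFGS",
        options={"gtol": 1e-12},
    )
    f = res.x
    log_denom = logsumexp(logN[:, None] + f[:, None] - u, axis=0)
    log_w = -log_denom   # unnormalised sample weights
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    F = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers))
    idx = np.digitize(x, bin_edges) - 1
    for b in range(len(centers)):
        sel = idx == b
        counts[b] = sel.sum()
        if sel.any():
            F[b] = -kT * logsumexp(log_w[sel])
    return centers, F - np.nanmin(F), counts


def exhaustive_medoid_cost(X: np.ndarray, assignments: np.ndarray, rmsd_fn):
    """Brute-force optimal within-cluster RMSD sums for fixed assignments.

    Returns the list of per-cluster minimal summed RMSD over every
    possible medoid choice.
    """
    costs = []
    for ci in np.unique(assignments):
        members = np.flatnonzero(assignments == ci)
        best = np.inf
        for m in members:
            cost = sum(rmsd_fn(X[m], X[j]) for j in members)
            best = min(best, cost)
        costs.append(best)
    return costs
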