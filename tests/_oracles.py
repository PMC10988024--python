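"""Independent oracles used by the test suite.

These deliberately take different computational routes from the library code
they check: numerical black-box maximization instead of eigen-decomposition,
whitened-SVD CCA, enumeration-style Benjamini-Hochberg, and loop-based ANOVA
sums of squares.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def sumcorr_objective(ws, within, cross):
    """Sum over pairs of component correlations implied by filters."""
    M = len(ws)
    var = [ws[i] @ within[i] @ ws[i] for i in range(M)]
    s = 0.0
    for i in range(M):
        for j in range(i + 1, M):
            s += ws[i] @ cross[i][j] @ ws[j] / np.sqrt(var[i] * var[j])
    return s


def brute_force_sumcorr(within, cross, n_restarts=50, rng=None):
    """Black-box maximization of the sum of pairwise correlations over filters.

    BFGS from random restarts on the unconstrained parametrization (the
    objective is scale-invariant per subject). Returns the best objective.
    """
    rng = rng or np.random.default_rng(0)
    M, C = len(within), within[0].shape[0]

    def neg(theta):
        ws = list(theta.reshape(M, C))
        return -sumcorr_objective(ws, within, cross)

    best = np.inf
    for _ in range(n_restarts):
        res = optimize.minimize(neg, rng.standard_normal(M * C), method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return -best


def classical_cca_first_corr(X1, X2):
    """First canonical correlation of two standardized datasets via whitened SVD."""
    T = X1.shape[1]
    C11 = X1 @ X1.T / T
    C22 = X2 @ X2.T / T
    C12 = X1 @ X2.T / T
    W1 = np.linalg.inv(np.linalg.cholesky(C11))
    W2 = np.linalg.inv(np.linalg.cholesky(C22))
    s = np.linalg.svd(W1 @ C12 @ W2.T, compute_uv=False)
    return float(s[0])


def bh_stepup(pvals, alpha=None):
    """Benjamini-Hochberg adjusted p-values by explicit step-up enumeration."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        candidate = min(1.0, p[idx] * m / rank_from_top)
        running_min = min(running_min, candidate)
        adj[idx] = running_min
    return adj


def splitplot_ss(Y, groups):
    """Split-plot ANOVA sums of squares by naive per-observation loops."""
    Y = np.asarray(Y, dtype=float)
    groups = list(groups)
    N, t = Y.shape
    labels = sorted(set(groups), key=groups.index)
    grand = Y.mean()
    ss = {"total": 0.0, "group": 0.0, "subj_within": 0.0, "time": 0.0,
          "inter": 0.0, "error": 0.0}
    group_mean = {lab: np.mean([Y[i] for i in range(N) if groups[i] == lab]) for lab in labels}
    time_mean = [np.mean(Y[:, j]) for j in range(t)]
    cell_mean = {(lab, j): np.mean([Y[i, j] for i in range(N) if groups[i] == lab])
                 for lab in labels for j in range(t)}
    for i in range(N):
        lab = groups[i]
        subj_mean = Y[i].mean()
        for j in range(t):
            y = Y[i, j]
            ss["total"] += (y - grand) ** 2
            ss["group"] += (group_mean[lab] - grand) ** 2
            ss["subj_within"] += (subj_mean - group_mean[lab]) ** 2
            ss["time"] += (time_mean[j] - grand) ** 2
            ss["inter"] += (cell_mean[(lab, j)] - group_mean[lab] - time_mean[j] + grand) ** 2
            ss["error"] += (y - subj_mean - cell_mean[(lab, j)] + group_mean[lab]) ** 2
    return ss


def splitplot_f_bruteforce(Y, groups):
    """F statistics for group, time and interaction from the naive SS."""
    Y = np.asarray(Y, dtype=float)
    N, t = Y.shape
    labels = sorted(set(groups), key=list(groups).index)
    g = len(labels)
    ss = splitplot_ss(Y, groups)
    ms = {
        "group": ss["group"] / (g - 1),
        "subj_within": ss["subj_within"] / (N - g),
        "time": ss["time"] / (t - 1),
        "inter": ss["inter"] / ((g - 1) * (t - 1)),
        "error": ss["error"] / ((N - g) * (t - 1)),
    }
    return {
        "group": ms["group"] / ms["subj_within"],
        "time": ms["time"] / ms["error"],
        "inter": ms["inter"] / ms["error"],
    }
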