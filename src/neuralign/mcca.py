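"""Multiset canonical correlation analysis (MCCA) across subjects.

Given M subjects' standardized channels × samples matrices, MCCA finds one
spatial filter per subject so that the filtered component time-series are
maximally correlated *between* subjects. With C channels per subject, stack
the per-subject filters into v = (w_1, ..., w_M); the fit solves the
generalized eigenproblem

    R v = λ D v

where R is the (MC × MC) block matrix of all within- and cross-covariance
blocks and D is the block diagonal of (ridge-regularized) within-subject
covariances. With each filter normalized to unit component variance, the
eigenvalue relates to the mean pairwise component correlation ρ̄ through
λ = 1 + (M − 1)·ρ̄; for M = 2 this is classical CCA and ρ̄ its first
canonical correlation.

Because the eigenproblem maximizes the sum of pairwise *covariances* under a
summed-variance constraint, its optimum can sit slightly off the maximizer of
the sum of pairwise *correlations* (per-subject unit variance). The top
component is therefore refined by Horst fixed-point iteration, which
converges to the sum-of-correlations (SUMCOR) optimum from the eigenvector
initialization.

The companion of a (backward-model) spatial filter w is its activation
pattern a ∝ C_within·w — the sensor topography of the component, which is the
object one would localize anatomically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "CovarianceStructure",
    "compute_covariances",
    "MCCA",
    "MCCAResults",
    "fit_mcca",
    "activation_pattern",
    "sum_pairwise_correlations",
]


@dataclass
class CovarianceStructure:
    """Second-order statistics of one group's multi-subject data.

    ``within[i]`` is subject i's raw C × C covariance (1/T) X_i X_iᵀ,
    ``within_reg[i]`` the same plus the ridge γ·tr(·)/C·I, and
    ``cross[i, j]`` the cross-covariance (1/T) X_i X_jᵀ.
    """

    within: np.ndarray  # (M, C, C)
    within_reg: np.ndarray  # (M, C, C)
    cross: np.ndarray  # (M, M, C, C); cross[i, i] == within[i]
    gamma: float

    @property
    def n_subjects(self) -> int:
        return self.within.shape[0]

    @property
    def n_channels(self) -> int:
        return self.within.shape[1]


def compute_covariances(group_data: Sequence[np.ndarray], gamma: float = 0.0) -> CovarianceStructure:
    """Within- and cross-covariances of all subjects, with ridge fraction γ.

    All subjects must share the sample count; inputs are expected standardized
    (no mean subtraction is performed here).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    Xs = [np.asarray(X, dtype=float) for X in group_data]
    T = {X.shape[1] for X in Xs}
    if len(T) != 1:
        raise ValueError(f"mismatched sample counts across subjects: {sorted(T)}")
    T = T.pop()
    M, C = len(Xs), Xs[0].shape[0]
    cross = np.empty((M, M, C, C))
    for i in range(M):
        for j in range(i, M):
            cij = Xs[i] @ Xs[j].T / T
            cross[i, j] = cij
            cross[j, i] = cij.T
    within = np.array([cross[i, i] for i in range(M)])
    within_reg = within + gamma * (
        np.trace(within, axis1=1, axis2=2)[:, None, None] / C
    ) * np.eye(C)
    return CovarianceStructure(within=within, within_reg=within_reg, cross=cross, gamma=gamma)


def sum_pairwise_correlations(filters: Sequence[np.ndarray], cov: CovarianceStructure) -> float:
    """Sum over subject pairs of the component correlations implied by filters."""
    M = cov.n_subjects
    w = [np.asarray(f, dtype=float) for f in filters]
    var = [w[i] @ cov.within[i] @ w[i] for i in range(M)]
    s = 0.0
    for i in range(M):
        for j in range(i + 1, M):
            s += w[i] @ cov.cross[i, j] @ w[j] / np.sqrt(var[i] * var[j])
    return float(s)


def _horst_refine(
    w0: list[np.ndarray], cov: CovarianceStructure, max_iter: int = 2000, tol: float = 1e-14
) -> list[np.ndarray]:
    """SUMCOR refinement: fixed-point iteration on the stationarity conditions.

    Each sweep sets w_i ∝ W_i⁻¹ Σ_{j≠i} C_ij w_j with unit component variance
    in the regularized within metric; monotone in the objective.
    """
    M = cov.n_subjects
    ws = []
    for i, w in enumerate(w0):
        n = np.sqrt(w @ cov.within_reg[i] @ w)
        ws.append(w / n if n > 0 else w)
    solves = [linalg.cho_factor(cov.within_reg[i]) for i in range(M)]
    for _ in range(max_iter):
        new = []
        for i in range(M):
            b = np.zeros(cov.n_channels)
            for j in range(M):
                if j != i:
                    b += cov.cross[i, j] @ ws[j]
            w = linalg.cho_solve(solves[i], b)
            n = np.sqrt(w @ cov.within_reg[i] @ w)
            new.append(w / n if n > 0 else ws[i])
        delta = max(np.linalg.norm(a - b) for a, b in zip(ws, new))
        ws = new
        if delta < tol:
            break
    return ws


@dataclass
class MCCAResults:
    """Fitted spatial filters, eigenvalues and activation patterns.

    ``filters[i, :, k]`` is subject i's filter for component k (unit component
    variance in the regularized within metric); components are ordered by
    decreasing eigenvalue. ``implied_correlation(k)`` maps the eigenvalue to
    the mean pairwise train correlation via ρ̄ = (λ − 1)/(M − 1).
    """

    filters: np.ndarray  # (M, C, K)
    eigenvalues: np.ndarray  # (K,)
    patterns: np.ndarray  # (M, C, K), unit-norm columns
    n_subjects: int
    gamma: float

    @property
    def n_components(self) -> int:
        return self.filters.shape[2]

    def implied_correlation(self, k: int | None = None) -> np.ndarray | float:
        rho = (self.eigenvalues - 1.0) / (self.n_subjects - 1)
        return rho if k is None else float(rho[k])

    def transform(self, group_data: Sequence[np.ndarray], k: int = 0) -> np.ndarray:
        """Per-subject component time-series y_i = w_{i,k}ᵀ X_i, standardized.

        Series with (numerically) zero variance are degenerate — e.g. a filter
        orthogonal to the data subspace — and are returned as all-NaN with a
        warning so downstream stages can treat them as missing.
        """
        Y = np.array([self.filters[i, :, k] @ np.asarray(X, float) for i, X in enumerate(group_data)])
        Y = Y - Y.mean(axis=1, keepdims=True)
        sd = Y.std(axis=1)
        bad = sd <= 1e-12 * np.sqrt(Y.shape[1])
        if np.any(bad):
            warnings.warn(
                f"degenerate (zero-variance) component series for subjects {np.flatnonzero(bad).tolist()}",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            Y = Y / sd[:, None]
        Y[bad] = np.nan
        return Y

    def summary(self) -> str:
        lines = [
            "Multiset CCA results",
            f"  subjects: {self.n_subjects}   channels: {self.filters.shape[1]}   "
            f"components: {self.n_components}   ridge gamma: {self.gamma:g}",
            "  comp   eigenvalue   implied mean pairwise r",
        ]
        rho = self.implied_correlation()
        for k in range(self.n_components):
            lines.append(f"  {k:4d}   {self.eigenvalues[k]:10.4f}   {rho[k]:>12.4f}")
        return "\n".join(lines)


def activation_pattern(filt: np.ndarray, within: np.ndarray) -> np.ndarray:
    """Forward-model activation pattern a ∝ C·w, normalized to unit norm."""
    a = np.asarray(within, float) @ np.asarray(filt, float)
    n = np.linalg.norm(a)
    return a / n if n > 0 else a


def _solve_eigproblem(cov: CovarianceStructure, K: int):
    M, C = cov.n_subjects, cov.n_channels
    R = cov.cross.transpose(0, 2, 1, 3).reshape(M * C, M * C)
    D = linalg.block_diag(*cov.within_reg)
    try:
        evals, evecs = linalg.eigh(R, D)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "within-covariance block is singular; raise the ridge fraction gamma "
            "or reduce rank with per-subject PCA (pca_var)"
        ) from err
    order = np.argsort(evals)[::-1][:K]
    return evals[order], evecs[:, order]


class MCCA:
    """Multiset CCA model over one group's standardized multi-subject data.

    Parameters
    ----------
    group_data : sequence of (C, T) arrays
        One standardized channels × samples matrix per subject.
    gamma : float
        Ridge fraction added to each within-subject covariance,
        γ·tr(C)/C·I. Needed whenever channels outnumber the effective rank
        of band-limited data.
    n_components : int
        Number of components K to extract (capped at the channel count).
    pca_var : float or None
        If set (e.g. 0.99), reduce each subject to the leading principal
        components explaining this variance fraction before solving, as an
        alternative conditioning route to the ridge.
    """

    def __init__(
        self,
        group_data: Sequence[np.ndarray],
        gamma: float = 0.05,
        n_components: int = 10,
        pca_var: float | None = None,
    ) -> None:
        self.group_data = [np.asarray(X, dtype=float) for X in group_data]
        if len(self.group_data) < 2:
            raise ValueError("MCCA needs at least two subjects")
        self.gamma = float(gamma)
        self.n_components = int(min(n_components, self.group_data[0].shape[0]))
        self.pca_var = pca_var

    def fit(self, refine_top: bool = True) -> MCCAResults:
        """Fit spatial filters; optionally refine the top component to the
        sum-of-pairwise-correlations (SUMCOR) optimum."""
        if self.pca_var is not None:
            return self._fit_pca_reduced(refine_top)
        cov = compute_covariances(self.group_data, self.gamma)
        return fit_mcca(cov, self.n_components, refine_top=refine_top)

    def _fit_pca_reduced(self, refine_top: bool) -> MCCAResults:
        cov_full = compute_covariances(self.group_data, gamma=0.0)
        M, C = cov_full.n_subjects, cov_full.n_channels
        bases = []
        for i in range(M):
            evals, evecs = np.linalg.eigh(cov_full.within[i])
            evals, evecs = evals[::-1], evecs[:, ::-1]
            frac = np.cumsum(evals) / np.sum(evals)
            r = int(np.searchsorted(frac, self.pca_var) + 1)
            bases.append(evecs[:, :r])
        reduced = [U.T @ X for U, X in zip(bases, self.group_data)]
        # ranks may differ across subjects; pad filters back to channel space
        r_min = min(U.shape[1] for U in bases)
        K = min(self.n_components, r_min)
        cov_red = compute_covariances(
            [Y[: U.shape[1]] for Y, U in zip(reduced, bases)], self.gamma
        )
        # blocks of unequal size: fall back to generic block assembly
        res_red = _fit_mcca_blocks(cov_red, bases, K, refine_top)
        return res_red


def _per_subject_normalize(ws: list[np.ndarray], cov: CovarianceStructure) -> list[np.ndarray]:
    out = []
    for i, w in enumerate(ws):
        n = np.sqrt(w @ cov.within_reg[i] @ w)
        out.append(w / n if n > 1e-300 else w)
    return out


def _rayleigh(ws: list[np.ndarray], cov: CovarianceStructure) -> float:
    """λ = vᵀRv / vᵀDv for per-subject unit-variance filters: 1 + 2S/M form."""
    M = cov.n_subjects
    num = 0.0
    for i in range(M):
        num += ws[i] @ cov.within[i] @ ws[i]
        for j in range(M):
            if j != i:
                num += ws[i] @ cov.cross[i, j] @ ws[j]
    den = sum(ws[i] @ cov.within_reg[i] @ ws[i] for i in range(M))
    return float(num / den)


def _fix_signs(ws_per_comp: list[list[np.ndarray]], cov: CovarianceStructure) -> None:
    """Flip each subject's filter so its series correlates positively with the
    across-subject mean series; then fix the global sign deterministically."""
    M = cov.n_subjects
    for ws in ws_per_comp:
        for _ in range(2):  # one or two sweeps suffice
            for i in range(M):
                c = sum(ws[i] @ cov.cross[i, j] @ ws[j] for j in range(M) if j != i)
                if c < 0:
                    ws[i] = -ws[i]
        lead = ws[0][np.argmax(np.abs(ws[0]))]
        if lead < 0:
            for i in range(M):
                ws[i] = -ws[i]


def fit_mcca(cov: CovarianceStructure, K: int, refine_top: bool = True) -> MCCAResults:
    """Solve the multiset-CCA generalized eigenproblem for K components.

    Components are eigenvectors of R v = λ D v in descending eigenvalue
    order, re-normalized to unit component variance per subject; eigenvalues
    are recomputed as Rayleigh quotients of the normalized filters so that
    ρ̄ = (λ − 1)/(M − 1) is exactly the mean pairwise train correlation at
    γ = 0. With ``refine_top``, the leading component is pushed to the SUMCOR
    optimum by Horst iteration.
    """
    M, C = cov.n_subjects, cov.n_channels
    K = int(min(K, C))
    evals, evecs = _solve_eigproblem(cov, K)
    ws_per_comp = []
    for k in range(K):
        v = evecs[:, k]
        ws = [v[i * C : (i + 1) * C].copy() for i in range(M)]
        ws = _per_subject_normalize(ws, cov)
        ws_per_comp.append(ws)
    if refine_top and K > 0:
        ws_per_comp[0] = _horst_refine(ws_per_comp[0], cov)
    _fix_signs(ws_per_comp, cov)
    lam = np.array([_rayleigh(ws, cov) for ws in ws_per_comp])
    # refinement can only raise the top quotient; keep descending order
    filters = np.empty((M, C, K))
    patterns = np.empty((M, C, K))
    for k, ws in enumerate(ws_per_comp):
        for i in range(M):
            filters[i, :, k] = ws[i]
            patterns[i, :, k] = activation_pattern(ws[i], cov.within[i])
    return MCCAResults(
        filters=filters, eigenvalues=lam, patterns=patterns, n_subjects=M, gamma=cov.gamma
    )


def _fit_mcca_blocks(
    cov_red: CovarianceStructure, bases: list[np.ndarray], K: int, refine_top: bool
) -> MCCAResults:
    """Eigenproblem in per-subject PCA spaces, mapped back to channel space."""
    # equal reduced dimension is required by the dense solver; truncate to min rank
    r = min(U.shape[1] for U in bases)
    M = cov_red.n_subjects
    sub = CovarianceStructure(
        within=cov_red.within[:, :r, :r].copy(),
        within_reg=cov_red.within_reg[:, :r, :r].copy(),
        cross=cov_red.cross[:, :, :r, :r].copy(),
        gamma=cov_red.gamma,
    )
    res = fit_mcca(sub, K, refine_top=refine_top)
    C = bases[0].shape[0]
    filters = np.empty((M, C, res.n_components))
    patterns = np.empty((M, C, res.n_components))
    for i in range(M):
        U = bases[i][:, :r]
        full_within = U @ sub.within[i] @ U.T
        for k in range(res.n_components):
            w = U @ res.filters[i, :, k]
            filters[i, :, k] = w
            patterns[i, :, k] = activation_pattern(w, full_within)
    return MCCAResults(
        filters=filters,
        eigenvalues=res.eigenvalues,
        patterns=patterns,
        n_subjects=M,
        gamma=cov_red.gamma,
    )
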