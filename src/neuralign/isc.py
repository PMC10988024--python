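"""Cross-validated intersubject correlation (ISC) and circular-bootstrap inference.

The group-level alignment statistic is the mean pairwise Pearson correlation
between subjects' component time-series. To keep model selection honest, the
spatial filters are fitted with contiguous-in-time k-fold cross-validation
(default 3 folds): filters learned on two thirds of a timeslot are applied to
the held-out third, and the component is selected by mean *test* ISC.

Significance is assessed nonparametrically: each subject's component series
is circularly rotated by an independent uniform random nonzero offset, which
preserves its mean, variance and circular autocorrelation while destroying
cross-subject alignment; the p-value is the (+1-corrected) fraction of null
ISC samples at or above the observed one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mcca import MCCA

__all__ = [
    "ISCResult",
    "BootstrapResult",
    "pairwise_isc",
    "pairwise_matrix",
    "circular_shift",
    "crossval_isc",
    "bootstrap_isc",
    "bootstrap_crossval_isc",
]

logger = logging.getLogger(__name__)


def pairwise_matrix(timecourses: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of M equal-length series (M × M).

    Rows containing NaN (degenerate/missing series) yield NaN entries.
    """
    Y = np.asarray(timecourses, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("need an (M >= 2) × T array of time-courses")
    ok = ~np.isnan(Y).any(axis=1)
    sd = np.zeros(Y.shape[0])
    sd[ok] = Y[ok].std(axis=1)
    if np.any(ok & (sd <= 0)):
        raise ValueError("constant series: Pearson correlation undefined")
    R = np.full((Y.shape[0], Y.shape[0]), np.nan)
    if ok.sum() >= 2:
        R_ok = np.corrcoef(Y[ok])
        idx = np.flatnonzero(ok)
        R[np.ix_(idx, idx)] = R_ok
    return R


def pairwise_isc(timecourses: np.ndarray) -> float:
    """Mean of the M(M−1)/2 pairwise Pearson correlations."""
    R = pairwise_matrix(timecourses)
    iu = np.triu_indices_from(R, k=1)
    vals = R[iu]
    return float(np.nanmean(vals))


def circular_shift(series: np.ndarray, offset: int) -> np.ndarray:
    """Rotate a series: out[t] = in[(t − offset) mod T]."""
    x = np.asarray(series)
    T = x.shape[-1]
    return np.roll(x, offset % T, axis=-1)


@dataclass
class ISCResult:
    """Cross-validated ISC for one (group, band, timeslot) analysis cell.

    ``per_fold``/``train_isc`` are fold × component matrices of held-out and
    training ISC. ``individual_isc`` is each subject's mean pairwise
    correlation with the others (so that its subject-mean equals
    ``group_isc`` identically); ``individual_isc_ovr`` is the one-vs-rest
    variant, corr(y_i, mean of the other subjects' series).
    """

    per_fold: np.ndarray  # (n_folds, K) test ISC
    train_isc: np.ndarray  # (n_folds, K)
    selected_component: int
    group_isc: float
    individual_isc: np.ndarray  # (M,) mean-pairwise-involving-i
    individual_isc_ovr: np.ndarray  # (M,) one-vs-rest
    test_series: np.ndarray = field(repr=False)  # (M, T_test_total) selected comp, concatenated folds
    n_folds: int = 3

    @property
    def n_components(self) -> int:
        return self.per_fold.shape[1]

    @property
    def mean_test_isc(self) -> np.ndarray:
        return np.nanmean(self.per_fold, axis=0)

    def summary(self) -> str:
        lines = [
            "Cross-validated ISC",
            f"  folds: {self.n_folds}   components: {self.n_components}   "
            f"subjects: {len(self.individual_isc)}",
            f"  selected component: {self.selected_component}   "
            f"group ISC (mean test): {self.group_isc:.4f}",
            "  comp   mean train ISC   mean test ISC",
        ]
        mtr = np.nanmean(self.train_isc, axis=0)
        mte = self.mean_test_isc
        for k in range(self.n_components):
            lines.append(f"  {k:4d}   {mtr[k]:14.4f}   {mte[k]:13.4f}")
        return "\n".join(lines)


def _fold_slices(T: int, n_folds: int) -> list[slice]:
    edges = [round(i * T / n_folds) for i in range(n_folds + 1)]
    return [slice(edges[i], edges[i + 1]) for i in range(n_folds)]


def crossval_isc(
    slot_data: list[np.ndarray],
    K: int = 10,
    n_folds: int = 3,
    gamma: float = 0.05,
    pca_var: float | None = None,
    min_fold_samples: int = 100,
) -> ISCResult:
    """Contiguous k-fold cross-validated MCCA/ISC on one timeslot.

    For each fold, MCCA is fitted on the remaining folds and the held-out
    fold is projected; the component with the highest mean test ISC is
    selected. Subjects whose held-out projection is degenerate (zero
    variance) contribute NaN to that fold and are excluded from the means.
    """
    M = len(slot_data)
    T = slot_data[0].shape[1]
    if T < n_folds * min_fold_samples:
        raise ValueError(
            f"{T} samples cannot support {n_folds} folds of >= {min_fold_samples} samples"
        )
    K = int(min(K, slot_data[0].shape[0]))
    folds = _fold_slices(T, n_folds)
    per_fold = np.full((n_folds, K), np.nan)
    train_isc = np.full((n_folds, K), np.nan)
    pair_sum = np.zeros((M, M))
    pair_cnt = np.zeros((M, M))
    ovr = np.full((n_folds, M), np.nan)
    test_series = []
    for f, test_sl in enumerate(folds):
        train = [np.concatenate([X[:, s] for i, s in enumerate(folds) if i != f], axis=1)
                 for X in slot_data]
        test = [X[:, test_sl] for X in slot_data]
        res = MCCA(train, gamma=gamma, n_components=K, pca_var=pca_var).fit()
        for k in range(res.n_components):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Y_te = res.transform(test, k)
                Y_tr = res.transform(train, k)
            if np.isnan(Y_te).any():
                logger.warning(
                    "fold %d comp %d: degenerate held-out projection for subjects %s",
                    f, k, np.flatnonzero(np.isnan(Y_te).any(axis=1)).tolist(),
                )
            per_fold[f, k] = pairwise_isc(Y_te)
            train_isc[f, k] = pairwise_isc(Y_tr)
        test_series.append((res, test))
    selected = int(np.argmax(np.nanmean(per_fold, axis=0)))
    series = []
    for f, (res, test) in enumerate(test_series):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Y = res.transform(test, selected)
        R = pairwise_matrix(Y)
        valid = ~np.isnan(R)
        np.fill_diagonal(valid, False)
        pair_sum[valid] += R[valid]
        pair_cnt += valid
        ok = ~np.isnan(Y).any(axis=1)
        for i in range(M):
            others = ok.copy()
            others[i] = False
            if ok[i] and others.sum() >= 1:
                rest = Y[others].mean(axis=0)
                if rest.std() > 0:
                    ovr[f, i] = np.corrcoef(Y[i], rest)[0, 1]
        series.append(Y)
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_mean = pair_sum / pair_cnt
    individual = np.array([np.nanmean(pair_mean[i, np.arange(M) != i]) for i in range(M)])
    iu = np.triu_indices(M, k=1)
    group_isc = float(np.nanmean(pair_mean[iu]))
    return ISCResult(
        per_fold=per_fold,
        train_isc=train_isc,
        selected_component=selected,
        group_isc=group_isc,
        individual_isc=individual,
        individual_isc_ovr=np.nanmean(ovr, axis=0),
        test_series=np.concatenate(series, axis=1),
        n_folds=n_folds,
    )


@dataclass
class BootstrapResult:
    """Observed ISC against a circular-shift null distribution."""

    observed: float
    null_samples: np.ndarray
    p_value: float

    def summary(self) -> str:
        return (
            f"circular-bootstrap ISC test: observed={self.observed:.4f}, "
            f"B={len(self.null_samples)}, null mean={self.null_samples.mean():.4f}, "
            f"p={self.p_value:.4g}"
        )


def _null_isc_once(Y: np.ndarray, rng: np.random.Generator) -> float:
    T = Y.shape[1]
    offsets = rng.integers(1, T, size=Y.shape[0])
    shifted = np.array([circular_shift(y, int(o)) for y, o in zip(Y, offsets)])
    return pairwise_isc(shifted)


def bootstrap_isc(timecourses: np.ndarray, B: int = 1000, seed: int = 0) -> BootstrapResult:
    """Circular-shift bootstrap of the mean pairwise ISC.

    Each null sample rotates every subject's series by an independent uniform
    nonzero offset. p = (1 + #{null ≥ observed}) / (B + 1): never exactly 0.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a usable null distribution")
    Y = np.asarray(timecourses, dtype=float)
    ok = ~np.isnan(Y).any(axis=1)
    Y = Y[ok]
    if Y.shape[0] < 2:
        raise ValueError("need at least two non-degenerate series")
    # standardize once: circular shifts preserve mean/variance, so pairwise
    # correlations of shifted series reduce to dot products
    Z = (Y - Y.mean(axis=1, keepdims=True)) / Y.std(axis=1, keepdims=True)
    M, T = Z.shape
    observed = pairwise_isc(Y)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    iu = np.triu_indices(M, k=1)
    for b in range(B):
        offsets = rng.integers(1, T, size=M)
        S = np.array([np.roll(Z[i], int(offsets[i])) for i in range(M)])
        R = (S @ S.T) / T
        null[b] = R[iu].mean()
    p = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    return BootstrapResult(observed=observed, null_samples=null, p_value=float(p))


def bootstrap_crossval_isc(
    slot_data: list[np.ndarray],
    B: int = 200,
    seed: int = 0,
    K: int = 10,
    n_folds: int = 3,
    gamma: float = 0.05,
) -> BootstrapResult:
    """Bootstrap that re-fits MCCA inside every replicate (``--refit-null``).

    The null rotates each subject's *sensor* data by an independent offset and
    reruns the full cross-validated ISC, accounting for selection optimism at
    considerable cost; the default test (:func:`bootstrap_isc`) instead shifts
    the held-out component series with filters held fixed.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a usable null distribution")
    observed_res = crossval_isc(slot_data, K=K, n_folds=n_folds, gamma=gamma)
    observed = observed_res.group_isc
    rng = np.random.default_rng(seed)
    T = slot_data[0].shape[1]
    null = np.empty(B)
    for b in range(B):
        offsets = rng.integers(1, T, size=len(slot_data))
        shifted = [np.roll(X, int(o), axis=1) for X, o in zip(slot_data, offsets)]
        null[b] = crossval_isc(shifted, K=K, n_folds=n_folds, gamma=gamma).group_isc
    p = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    return BootstrapResult(observed=observed, null_samples=null, p_value=float(p))
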