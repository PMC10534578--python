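"""Psychometric statistics for instrument validation, implemented from first
principles on top of numpy (scipy is used only for distribution tail areas).

Covers the full validation toolkit: Spearman rank correlation, Cronbach's
alpha, ROC curves with trapezoidal AUC, the Youden optimal cut-off,
confusion-table sensitivity/specificity, the Kaiser–Meyer–Olkin sampling
adequacy measure, Bartlett's sphericity test, PCA-based exploratory factor
analysis with the Kaiser retention rule, and varimax rotation via pairwise
Jacobi sweeps.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "ConfusionTable",
    "RocCurve",
    "FactorSolution",
    "spearman_rho",
    "cronbach_alpha",
    "roc_curve",
    "auc",
    "youden_optimal_cutoff",
    "sensitivity_specificity",
    "kmo",
    "bartlett_sphericity",
    "pca_efa",
    "varimax",
    "count_kaiser_factors",
]


class DegenerateDataError(ValueError):
    """The statistic is undefined on this input (constant data, one class...)."""


# ---------------------------------------------------------------------------
# Rank correlation


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties receive the mean of their positions."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sorted_x = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    return float(xc @ yc) / denom


def _exact_spearman_pvalue(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    """Two-sided permutation p-value by full enumeration of rank orderings.

    Intended for n ≤ 10 (10! ≈ 3.6M permutations, enumerated in chunks).
    """
    n = len(rx)
    rx_c = rx - rx.mean()
    sx = float(rx_c @ rx_c)
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []
    chunk_size = 40_000
    ry_arr = np.asarray(ry)

    def flush(chunk: list[tuple[int, ...]]) -> int:
        perms = ry_arr[np.array(chunk)]
        pc = perms - perms.mean(axis=1, keepdims=True)
        sy = np.einsum("ij,ij->i", pc, pc)
        rhos = (pc @ rx_c) / np.sqrt(sx * sy)
        return int(np.sum(np.abs(rhos) >= abs(observed) - 1e-12))

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            count += flush(chunk)
            total += len(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
        total += len(chunk)
    return count / total


def spearman_rho(x, y, *, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman's rank correlation with a two-sided p-value.

    The coefficient is the Pearson correlation of midranks (ties averaged).
    The p-value uses the t approximation ``t = rho·sqrt((n−2)/(1−rho²))`` on
    n−2 degrees of freedom; for n ≤ ``exact_max_n`` an exact permutation
    p-value is computed by full enumeration instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    rho = _pearson(rx, ry)
    rho = max(-1.0, min(1.0, rho))
    if n <= exact_max_n:
        p = _exact_spearman_pvalue(rx, ry, rho)
    elif abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(_stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


# ---------------------------------------------------------------------------
# Reliability


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha, ``(k/(k−1))·(1 − Σ s²_i / s²_total)``.

    Variances are sample variances (n−1 denominator).  Rows are subjects,
    columns are items; no missing values allowed.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("item matrix must be n×k with n ≥ 2 and k ≥ 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("item matrix contains missing/non-finite values")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise DegenerateDataError("alpha undefined: total-score variance is zero")
    return (k / (k - 1)) * (1.0 - float(item_vars.sum()) / float(total_var))


# ---------------------------------------------------------------------------
# ROC / Youden


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 table of predicted dependence × true dependence."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, predicted: np.ndarray, truth: np.ndarray) -> "ConfusionTable":
        predicted = np.asarray(predicted, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        return cls(
            tp=int(np.sum(predicted & truth)),
            fp=int(np.sum(predicted & ~truth)),
            fn=int(np.sum(~predicted & truth)),
            tn=int(np.sum(~predicted & ~truth)),
        )


def sensitivity_specificity(table: ConfusionTable) -> tuple[float, float]:
    """(sensitivity, specificity) = (tp/(tp+fn), tn/(tn+fp))."""
    if table.tp + table.fn == 0:
        raise DegenerateDataError("sensitivity undefined: no dependent subjects")
    if table.tn + table.fp == 0:
        raise DegenerateDataError("specificity undefined: no independent subjects")
    return table.tp / (table.tp + table.fn), table.tn / (table.tn + table.fp)


@dataclass(frozen=True)
class RocCurve:
    """ROC curve under the 'score ≥ threshold → predicted dependent' rule.

    ``points`` run from the +∞ sentinel (sens 0, spec 1) down to the −∞
    sentinel (sens 1, spec 0); thresholds sit at unique observed scores
    (or adjacent-score midpoints when ``midpoint`` placement is used).
    Higher score means more dependent.
    """

    thresholds: np.ndarray  # descending; ±inf sentinels at the ends
    sensitivity: np.ndarray
    specificity: np.ndarray
    higher_is_dependent: bool = True

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity


def roc_curve(scores, truth, *, midpoint: bool = False) -> RocCurve:
    """ROC curve of a dependence score against binary dependence truth.

    ``truth`` is boolean (True = dependent).  One candidate threshold per
    unique score, plus ±∞ sentinels; with ``midpoint=True`` thresholds are
    placed halfway between adjacent unique scores instead (the +∞ sentinel
    and the finite thresholds still classify by the ≥ rule).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D vectors")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("ROC needs both dependent and independent subjects")

    uniq = np.unique(scores)[::-1]  # descending
    if midpoint and len(uniq) > 1:
        candidates = 0.5 * (uniq[:-1] + uniq[1:])
        candidates = np.concatenate(([uniq[0] + 1.0], candidates))
    else:
        candidates = uniq
    thresholds = np.concatenate(([np.inf], candidates, [-np.inf]))

    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        predicted = scores >= thr
        sens[i] = np.sum(predicted & truth) / n_pos
        spec[i] = np.sum(~predicted & ~truth) / n_neg
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve (equals the Mann–Whitney
    probability of concordance with ties counted 1/2)."""
    order = np.argsort(curve.fpr, kind="mergesort")
    return float(np.trapezoid(curve.sensitivity[order], curve.fpr[order]))


def youden_optimal_cutoff(curve: RocCurve) -> tuple[float, float]:
    """Threshold maximising J = sensitivity + specificity − 1.

    Ties on J resolve to the smallest finite threshold (most sensitive).
    The −∞ sentinel is excluded as a cut-off candidate; if the curve carries
    no finite thresholds the input was degenerate.
    """
    finite = np.isfinite(curve.thresholds) | (curve.thresholds == np.inf)
    j = curve.sensitivity + curve.specificity - 1.0
    candidates = np.flatnonzero(finite)
    if len(candidates) <= 1:
        raise DegenerateDataError("degenerate ROC curve: no usable thresholds")
    j_cand = j[candidates]
    best_j = float(j_cand.max())
    # thresholds are descending: the last argmax is the smallest threshold
    best_idx = candidates[np.flatnonzero(j_cand >= best_j - 1e-12)[-1]]
    return float(curve.thresholds[best_idx]), best_j


# ---------------------------------------------------------------------------
# Factorability diagnostics


def _check_correlation_matrix(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] < 2:
        raise ValueError("need a p×p correlation matrix with p ≥ 2")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    return R


def kmo(correlation_matrix) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = Σr²/(Σr² + Σq²) over off-diagonal entries, where q_ij are the
    anti-image partial correlations −s_ij/√(s_ii s_jj) with S = R⁻¹.
    """
    R = _check_correlation_matrix(correlation_matrix)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or logdet < math.log(1e-12):
        raise DegenerateDataError("correlation matrix is singular or not positive-definite")
    S = np.linalg.inv(R)
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = float(np.sum(R[off] ** 2))
    q2 = float(np.sum(Q[off] ** 2))
    if r2 + q2 == 0.0:
        raise DegenerateDataError("KMO undefined for an identity correlation matrix")
    return r2 / (r2 + q2)


def bartlett_sphericity(correlation_matrix, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi² = −(n − 1 − (2p+5)/6)·ln det R on p(p−1)/2 degrees of freedom.
    """
    R = _check_correlation_matrix(correlation_matrix)
    p = R.shape[0]
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise DegenerateDataError("non-positive determinant: matrix not positive-definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(_stats.chi2.sf(chi2, df))
    return float(chi2), df, pval


# ---------------------------------------------------------------------------
# PCA-based EFA and varimax


@dataclass(frozen=True)
class FactorSolution:
    """Eigenstructure of a correlation matrix with PCA loadings.

    ``loadings`` are the unrotated component loadings (eigenvector ×
    √eigenvalue) for the retained components; ``rotated`` the varimax-rotated
    loadings (equal to ``loadings`` when fewer than two components are
    retained).  ``variance_pct`` is eigenvalue/p × 100 per component.
    """

    eigenvalues: np.ndarray  # length p, descending
    loadings: np.ndarray  # p × k, unrotated, retained components
    rotated: np.ndarray  # p × k after varimax
    variance_pct: np.ndarray  # length p
    cumulative_pct: np.ndarray  # length p
    n_retained: int
    n_obs: int = 0
    item_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def dominant_factor(self) -> np.ndarray:
        """Index of the rotated factor with the largest |loading| per item."""
        return np.abs(self.rotated).argmax(axis=1)


def count_kaiser_factors(eigenvalues) -> int:
    """Number of components retained by the Kaiser rule (eigenvalue > 1)."""
    return int(np.sum(np.asarray(eigenvalues, dtype=float) > 1.0))


def _fix_signs(L: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's largest-magnitude loading is positive."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = np.abs(L[:, j]).argmax()
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def pca_efa(item_matrix, *, n_factors: int | None = None, item_names=None) -> FactorSolution:
    """Exploratory factor analysis by principal components.

    Eigendecomposition of the sample correlation matrix; loadings are
    eigenvector × √eigenvalue.  ``n_factors=None`` retains by the Kaiser
    rule (eigenvalue > 1, strict).  When at least two components are
    retained the solution carries their varimax rotation.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("item matrix must be 2-D (subjects × items)")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more subjects than items (n={n}, p={p})")
    if np.any(X.std(axis=0) == 0):
        raise DegenerateDataError("constant item column: correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    k = count_kaiser_factors(eigval) if n_factors is None else int(n_factors)
    k = max(k, 1)
    loadings = _fix_signs(eigvec[:, :k] * np.sqrt(eigval[:k]))
    # rotation is meaningful only for a proper subset of ≥2 components
    rotated = varimax(loadings) if 2 <= k < p else loadings.copy()

    variance_pct = eigval / p * 100.0
    return FactorSolution(
        eigenvalues=eigval,
        loadings=loadings,
        rotated=rotated,
        variance_pct=variance_pct,
        cumulative_pct=np.cumsum(variance_pct),
        n_retained=k,
        n_obs=n,
        item_names=tuple(item_names) if item_names is not None else tuple(),
    )


class VarimaxConvergenceError(RuntimeError):
    def __init__(self, trace: list[float]):
        super().__init__(
            f"varimax failed to converge in {len(trace)} sweeps; criterion trace tail: "
            f"{trace[-5:]}"
        )
        self.trace = trace


def _varimax_criterion(L: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    sq = L**2
    return float(np.sum(sq.var(axis=0)))


def varimax(
    loadings,
    *,
    kaiser_normalize: bool = True,
    tol: float = 1e-8,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Varimax rotation by iterative pairwise (Jacobi) plane rotations.

    Maximises the varimax criterion — the total variance of squared
    loadings per factor — over orthogonal rotations, so row communalities
    are preserved.  With ``kaiser_normalize`` rows are scaled to unit
    communality during rotation (Kaiser's normalisation, the common
    default).  Columns of the result are sign-fixed (largest |loading|
    positive) and ordered by explained variance.
    """
    L = np.asarray(loadings, dtype=float).copy()
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("need a p×k loading matrix with k ≥ 2")
    p, k = L.shape
    if p <= k:
        raise ValueError("need more items than factors")

    comm = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        nonzero = comm > 0
        W = L.copy()
        W[nonzero] = L[nonzero] / comm[nonzero, None]
    else:
        W = L.copy()

    trace = [_varimax_criterion(W)]
    converged = False
    for _ in range(max_sweeps):
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = W[:, a], W[:, b]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = float(u @ u - v @ v)
                D = 2.0 * float(u @ v)
                num = D - 2.0 * A * B / p
                den = C - (A**2 - B**2) / p
                phi = 0.25 * math.atan2(num, den)
                if abs(phi) > 1e-12:
                    c, s = math.cos(phi), math.sin(phi)
                    W[:, a], W[:, b] = c * x + s * y, -s * x + c * y
        trace.append(_varimax_criterion(W))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        raise VarimaxConvergenceError(trace)

    if kaiser_normalize:
        W[nonzero] = W[nonzero] * comm[nonzero, None]
    order = np.argsort(-(W**2).sum(axis=0), kind="mergesort")
    return _fix_signs(W[:, order])
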