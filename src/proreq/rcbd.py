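"""Randomized-complete-block statistics for treatment-comparison tables.

The experimental model is the RCBD general linear model

    Y_ij = mu + B_i + T_j + e_ij

optionally extended with a centred covariate (ANCOVA),

    Y_ij = mu + B_i + T_j + beta * (X_ij - x_bar) + e_ij.

Sums of squares are the sequential (type-I) decomposition, which on a
balanced complete design is unique and orthogonal.  Treatment structure
over the quantitative CP levels is probed with orthogonal polynomial
contrasts built from the actual (unequally spaced) level values, and
pairwise mean separation uses Duncan's new multiple range test with its
span-dependent protection level 1 - (1-alpha)^(p-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaTerm",
    "AnovaResult",
    "DesignError",
    "rcbd_anova",
    "ancova_rcbd",
    "polynomial_contrasts",
    "orthogonal_poly_coefficients",
    "duncan_mrt",
    "pooled_sem",
    "lsd_threshold",
]


class DesignError(ValueError):
    """Raised when the block x treatment layout is not complete/balanced."""


@dataclass
class AnovaTerm:
    source: str
    ss: float
    df: int
    ms: float
    f: Optional[float]
    p: Optional[float]


@dataclass
class AnovaResult:
    """RCBD/ANCOVA decomposition plus the derived comparison statistics."""

    terms: list[AnovaTerm]
    grand_mean: float
    treatment_means: dict[str, float]
    adjusted_treatment_means: dict[str, float]
    mse: float
    error_df: int
    n_per_mean: int
    pooled_sem: float
    contrast_p: dict[str, float] = field(default_factory=dict)
    contrasts: dict[str, dict[str, float]] = field(default_factory=dict)
    duncan_letters: dict[str, str] = field(default_factory=dict)
    covariate_slope: Optional[float] = None

    @property
    def ss_total(self) -> float:
        return sum(t.ss for t in self.terms)

    def term(self, source: str) -> AnovaTerm:
        for t in self.terms:
            if t.source == source:
                return t
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": t.source, "SS": t.ss, "df": t.df, "MS": t.ms, "F": t.f, "p": t.p}
                for t in self.terms
            ]
        )


def _dummies(codes: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded indicator columns (first level dropped)."""
    levels = pd.unique(codes)
    return np.column_stack([(codes == lev).astype(float) for lev in levels[1:]])


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _check_design(blocks: np.ndarray, treatments: np.ndarray) -> tuple[int, int, int]:
    b_levels, b_codes = np.unique(blocks, return_inverse=True)
    t_levels, t_codes = np.unique(treatments, return_inverse=True)
    if len(b_levels) < 2 or len(t_levels) < 2:
        raise DesignError("need at least 2 blocks and 2 treatments")
    counts = np.zeros((len(b_levels), len(t_levels)), dtype=int)
    np.add.at(counts, (b_codes, t_codes), 1)
    if (counts == 0).any():
        missing = [
            (str(b_levels[i]), str(t_levels[j]))
            for i, j in zip(*np.nonzero(counts == 0))
        ]
        raise DesignError(f"incomplete design; missing block x treatment cells: {missing}")
    if counts.std() > 0:
        raise DesignError("unbalanced design: unequal cell counts")
    return len(b_levels), len(t_levels), int(counts[0, 0])


def rcbd_anova(
    y: Sequence[float],
    block_ids: Sequence,
    treatment_ids: Sequence,
    treatment_levels: Mapping | None = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """Exact least-squares RCBD decomposition with F-tests against MSE.

    ``treatment_levels`` optionally maps treatment label -> numeric level
    (e.g. dietary CP %); when given, linear and quadratic orthogonal
    polynomial contrasts and Duncan letters are filled in.
    """
    y = np.asarray(y, dtype=float)
    blocks = np.asarray(block_ids)
    treatments = np.asarray(treatment_ids)
    if not (len(y) == len(blocks) == len(treatments)):
        raise ValueError("y, block_ids and treatment_ids must have equal length")
    n_b, n_t, reps = _check_design(blocks, treatments)
    n = len(y)

    ones = np.ones((n, 1))
    Xb = np.column_stack([ones, _dummies(blocks)])
    Xbt = np.column_stack([Xb, _dummies(treatments)])
    rss0 = _rss(y, ones)
    rss_b = _rss(y, Xb)
    rss_bt = _rss(y, Xbt)

    # snap numerically-zero SS to zero (constant response gives ~1e-28)
    tol = 1e-12 * max(rss0, 1.0)
    ss_block = max(rss0 - rss_b, 0.0) if rss0 - rss_b > tol else 0.0
    ss_treat = max(rss_b - rss_bt, 0.0) if rss_b - rss_bt > tol else 0.0
    ss_error = rss_bt if rss_bt > tol else 0.0
    df_block, df_treat = n_b - 1, n_t - 1
    df_error = n - 1 - df_block - df_treat
    mse = ss_error / df_error if df_error > 0 else 0.0

    def term(name, ss, df):
        ms = ss / df if df > 0 else 0.0
        if mse > 0 and df > 0:
            f = ms / mse
            p = float(stats.f.sf(f, df, df_error))
        else:
            f = p = None
        return AnovaTerm(name, ss, df, ms, f, p)

    terms = [
        term("block", ss_block, df_block),
        term("treatment", ss_treat, df_treat),
        AnovaTerm("error", ss_error, df_error, mse, None, None),
    ]

    t_labels = list(pd.unique(treatments))
    means = {str(t): float(y[treatments == t].mean()) for t in t_labels}
    n_per_mean = n // n_t
    result = AnovaResult(
        terms=terms,
        grand_mean=float(y.mean()),
        treatment_means=means,
        adjusted_treatment_means=dict(means),
        mse=mse,
        error_df=df_error,
        n_per_mean=n_per_mean,
        pooled_sem=pooled_sem(mse, n_per_mean),
    )
    _fill_comparisons(result, treatment_levels, alpha)
    return result


def ancova_rcbd(
    y: Sequence[float],
    block_ids: Sequence,
    treatment_ids: Sequence,
    covariate: Sequence[float],
    treatment_levels: Mapping | None = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """RCBD analysis of covariance with one centred numeric covariate.

    Sequential decomposition: block, covariate, treatment (adjusted for
    the covariate), error.  Reduces to :func:`rcbd_anova` when the
    covariate is constant.  Treatment means are adjusted to the grand
    covariate mean: ``adj_j = mean_j - beta * (xbar_j - xbar)``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariate, dtype=float)
    blocks = np.asarray(block_ids)
    treatments = np.asarray(treatment_ids)
    if np.ptp(x) == 0:
        return rcbd_anova(y, blocks, treatments, treatment_levels, alpha)
    n_b, n_t, _ = _check_design(blocks, treatments)
    n = len(y)
    xc = (x - x.mean()).reshape(-1, 1)

    ones = np.ones((n, 1))
    Xb = np.column_stack([ones, _dummies(blocks)])
    Xbc = np.column_stack([Xb, xc])
    Xfull = np.column_stack([Xbc, _dummies(treatments)])
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise ValueError("covariate is collinear with block/treatment structure")

    rss0 = _rss(y, ones)
    rss_b = _rss(y, Xb)
    rss_bc = _rss(y, Xbc)
    rss_full = _rss(y, Xfull)

    tol = 1e-12 * max(rss0, 1.0)
    ss_block = max(rss0 - rss_b, 0.0) if rss0 - rss_b > tol else 0.0
    ss_cov = max(rss_b - rss_bc, 0.0) if rss_b - rss_bc > tol else 0.0
    ss_treat = max(rss_bc - rss_full, 0.0) if rss_bc - rss_full > tol else 0.0
    ss_error = rss_full if rss_full > tol else 0.0
    df_block, df_cov, df_treat = n_b - 1, 1, n_t - 1
    df_error = n - 1 - df_block - df_cov - df_treat
    mse = ss_error / df_error if df_error > 0 else 0.0

    def term(name, ss, df):
        ms = ss / df if df > 0 else 0.0
        if mse > 0 and df > 0:
            f = ms / mse
            p = float(stats.f.sf(f, df, df_error))
        else:
            f = p = None
        return AnovaTerm(name, ss, df, ms, f, p)

    terms = [
        term("block", ss_block, df_block),
        term("covariate", ss_cov, df_cov),
        term("treatment", ss_treat, df_treat),
        AnovaTerm("error", ss_error, df_error, mse, None, None),
    ]

    beta_full, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    slope = float(beta_full[Xbc.shape[1] - 1])

    t_labels = list(pd.unique(treatments))
    means = {str(t): float(y[treatments == t].mean()) for t in t_labels}
    xbar = x.mean()
    adjusted = {
        str(t): float(y[treatments == t].mean() - slope * (x[treatments == t].mean() - xbar))
        for t in t_labels
    }
    n_per_mean = n // n_t
    result = AnovaResult(
        terms=terms,
        grand_mean=float(y.mean()),
        treatment_means=means,
        adjusted_treatment_means=adjusted,
        mse=mse,
        error_df=df_error,
        n_per_mean=n_per_mean,
        pooled_sem=pooled_sem(mse, n_per_mean),
        covariate_slope=slope,
    )
    _fill_comparisons(result, treatment_levels, alpha, use_adjusted=True)
    return result


def _fill_comparisons(
    result: AnovaResult,
    treatment_levels: Mapping | None,
    alpha: float,
    use_adjusted: bool = False,
) -> None:
    means = result.adjusted_treatment_means if use_adjusted else result.treatment_means
    if result.mse > 0 and result.error_df > 0:
        result.duncan_letters = duncan_mrt(
            means, result.mse, result.n_per_mean, result.error_df, alpha
        )
    else:
        # zero error variance: identical means share a letter by convention
        result.duncan_letters = {k: "a" for k in means}
    if treatment_levels is not None and len(treatment_levels) >= 3:
        levels = np.array([treatment_levels[k] for k in means])
        m = np.array([means[k] for k in means])
        if result.mse > 0:
            contrasts = polynomial_contrasts(
                levels, m, result.mse, result.n_per_mean, result.error_df
            )
            result.contrasts = contrasts
            result.contrast_p = {k: v["p"] for k, v in contrasts.items()}


# ---------------------------------------------------------------------------
# Orthogonal polynomial contrasts


def orthogonal_poly_coefficients(levels: Sequence[float], max_order: int = 2) -> np.ndarray:
    """Orthonormal polynomial contrast coefficients for arbitrary spacing.

    Returns an array of shape (max_order, m): row 0 is the linear
    contrast, row 1 the quadratic, ...  Rows are mutually orthogonal,
    orthogonal to the intercept, unit-norm, and signed so the
    highest-order coefficient is positive (matching the classical
    integer tables up to scale for equal spacing).
    """
    x = np.asarray(levels, dtype=float)
    m = len(x)
    if len(np.unique(x)) != m:
        raise ValueError("levels must be distinct")
    if max_order > m - 1:
        raise ValueError(f"cannot build order-{max_order} contrasts from {m} levels")
    V = np.vander(x, N=max_order + 1, increasing=True)  # [1, x, x^2, ...]
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1:].T
    for i in range(C.shape[0]):
        if C[i, -1] < 0:
            C[i] *= -1.0
    return C


def polynomial_contrasts(
    levels: Sequence[float],
    treatment_means: Sequence[float],
    mse: float,
    n_per_mean: int,
    error_df: int,
    orders: Sequence[str] = ("linear", "quadratic"),
) -> dict[str, dict[str, float]]:
    """Single-df polynomial trend tests over quantitative treatment levels.

    For orthonormal coefficients c, the contrast SS is n * (c . means)^2
    and F = SS/MSE with 1 numerator df.
    """
    means = np.asarray(treatment_means, dtype=float)
    if len(means) != len(levels):
        raise ValueError("means and levels must align")
    if mse <= 0:
        raise ValueError("MSE must be positive for contrast tests")
    C = orthogonal_poly_coefficients(levels, max_order=len(orders))
    out = {}
    for i, name in enumerate(orders):
        c = C[i]
        estimate = float(c @ means)
        ss = n_per_mean * estimate**2 / float(c @ c)
        f = ss / mse
        out[name] = {
            "estimate": estimate,
            "ss": ss,
            "F": f,
            "p": float(stats.f.sf(f, 1, error_df)),
        }
    return out


# ---------------------------------------------------------------------------
# Mean separation


def pooled_sem(mse: float, n_per_mean: int) -> float:
    """Pooled standard error of a treatment mean, sqrt(MSE/n)."""
    if mse < 0:
        raise ValueError("MSE must be non-negative")
    if n_per_mean < 1:
        raise ValueError("n per mean must be >= 1")
    return float(np.sqrt(mse / n_per_mean))


def lsd_threshold(mse: float, n_per_mean: int, error_df: int, alpha: float = 0.05) -> float:
    """Fisher's least-significant-difference threshold for two means."""
    if mse <= 0:
        raise ValueError("MSE must be positive")
    t = stats.t.ppf(1 - alpha / 2, error_df)
    return float(t * np.sqrt(2 * mse / n_per_mean))


@lru_cache(maxsize=4096)
def _duncan_q(span: int, error_df: int, alpha: float) -> float:
    # protection level 1-(1-alpha)^(span-1): quantile of the studentized
    # range at probability (1-alpha)^(span-1); cached — the ppf is costly
    return float(stats.studentized_range.ppf((1 - alpha) ** (span - 1), span, error_df))


def _duncan_critical_range(span: int, error_df: int, sem: float, alpha: float) -> float:
    return _duncan_q(span, error_df, alpha) * sem


def duncan_mrt(
    treatment_means: Mapping[str, float],
    mse: float,
    n_per_mean: int,
    error_df: int,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Duncan's new multiple range test: letter groupings of means.

    Means are sorted descending; a stretch of consecutive means is
    homogeneous when its extremes differ by less than the critical range
    for its span, R_p = q_p(protection, p, df) * sqrt(MSE/n).  Letters
    are assigned to the maximal homogeneous stretches in rank order
    (largest mean gets 'a').
    """
    if mse <= 0:
        raise ValueError("MSE must be positive")
    if n_per_mean < 2:
        raise ValueError("Duncan's test needs n per mean >= 2")
    labels = sorted(treatment_means, key=lambda k: treatment_means[k], reverse=True)
    m = len(labels)
    vals = np.array([treatment_means[k] for k in labels])
    sem = np.sqrt(mse / n_per_mean)

    ranges = {p: _duncan_critical_range(p, error_df, sem, alpha) for p in range(2, m + 1)}

    # maximal homogeneous stretches [i, j]
    stretches = []
    for i in range(m):
        j = i
        while j + 1 < m and (vals[i] - vals[j + 1]) < ranges[j + 2 - i]:
            j += 1
        stretches.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in stretches
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in stretches)
    ]
    maximal.sort()

    letters = {k: "" for k in labels}
    for idx, (i, j) in enumerate(maximal):
        letter = chr(ord("a") + idx)
        for k in range(i, j + 1):
            letters[labels[k]] += letter
    return letters
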