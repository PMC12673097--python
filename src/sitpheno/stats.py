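"""Group-level inference on the bidimensional feature space.

Two procedures: a one-way MANOVA summarised by Wilks' Lambda — does the
joint (time-metric, distance-metric) distribution differ between groups?
— and Spearman's rank correlation between the Social Engagement Index and
the ordinal nest-building score.

Wilks' Lambda is the determinant ratio Λ = det(W) / det(W + B), with W
and B the pooled within-group and between-group cross-product matrices of
the mean-centred features.  Its p-value uses Rao's F transformation,
which is exact for two features (the bidimensional case here).  Spearman's
rho is the Pearson correlation of midranked values, with the usual
t-distribution p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ManovaResult", "CorrResult", "manova_wilks", "spearman_rho"]


@dataclass(frozen=True)
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df1: float
    df2: float
    p: float

    def __str__(self) -> str:  # human-readable report line
        return (
            f"Wilks' Lambda = {self.wilks_lambda:.4f}, "
            f"F({self.df1:g}, {self.df2:g}) = {self.f_stat:.4f}, p = {self.p:.4g}"
        )


@dataclass(frozen=True)
class CorrResult:
    rho: float
    p: float
    n: int

    def __str__(self) -> str:
        return f"Spearman rho = {self.rho:.4f}, p = {self.p:.4g}, n = {self.n}"


def manova_wilks(features: np.ndarray, groups) -> ManovaResult:
    """One-way MANOVA via Wilks' Lambda with Rao's F approximation.

    Parameters
    ----------
    features : (n, p) array
        One row per animal; typically the two type-B ratios, or the raw
        (time in zone, mean POI distance) pair — configurable upstream.
    groups : length-n sequence
        Group label per animal (>= 2 groups, each with >= 2 members).

    Returns
    -------
    ManovaResult
        Λ ∈ (0, 1] (1 means identical group means), Rao's F statistic with
        its degrees of freedom, and the p-value.  Exact for p = 2 features.

    Raises
    ------
    ValueError
        Fewer than two groups, a group with fewer than two animals, too few
        animals overall, or a singular within-group matrix (a collinear
        feature).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (animals x features) array")
    labels = np.asarray(groups)
    if len(labels) != len(X):
        raise ValueError("groups length must match number of feature rows")
    uniq, counts = np.unique(labels, return_counts=True)
    g = len(uniq)
    n, p = X.shape
    if g < 2:
        raise ValueError(f"need >= 2 groups, got {g}")
    if counts.min() < 2:
        small = uniq[counts.argmin()]
        raise ValueError(f"group {small!r} has fewer than 2 animals")
    if n <= p + g:
        raise ValueError(
            f"need more animals ({n}) than features + groups ({p + g})"
        )

    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab, cnt in zip(uniq, counts):
        sub = X[labels == lab]
        mu = sub.mean(axis=0)
        dev = sub - mu
        W += dev.T @ dev
        d = (mu - grand)[:, None]
        B += cnt * (d @ d.T)

    det_w = np.linalg.det(W)
    det_t = np.linalg.det(W + B)
    if det_w <= 0 or not np.isfinite(det_w):
        # name the offending feature: smallest within-group variance
        j = int(np.argmin(np.diag(W)))
        raise ValueError(
            f"singular within-group matrix: feature column {j} is "
            "(near-)collinear or constant within groups"
        )
    lam = float(det_w / det_t)
    lam = min(lam, 1.0)

    # Rao's F transformation (exact when p <= 2 or g <= 2)
    nu_h = g - 1  # hypothesis df
    nu_e = n - g  # error df
    denom = p * p + nu_h * nu_h - 5
    t = math.sqrt((p * p * nu_h * nu_h - 4) / denom) if denom > 0 else 1.0
    df1 = p * nu_h
    w = nu_e + nu_h - (p + nu_h + 1) / 2.0
    df2 = w * t - (p * nu_h - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    if lam_t == 0:
        f_stat = math.inf
    else:
        f_stat = (1.0 - lam_t) / lam_t * (df2 / df1)
    p_val = float(sps.f.sf(f_stat, df1, df2)) if math.isfinite(f_stat) else 0.0
    return ManovaResult(wilks_lambda=lam, f_stat=float(f_stat), df1=df1, df2=df2, p=p_val)


def _midrank(v: np.ndarray) -> np.ndarray:
    """Average-assigned ranks (ties share their mean rank), 1-based."""
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), dtype=float)
    sv = v[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y, *, ordinal_range: tuple[int, int] | None = (1, 5)) -> CorrResult:
    """Spearman rank correlation between a continuous score and an ordinal one.

    Designed for the SEI-vs-nest-score association: ``y`` is an ordinal
    rating (default declared range 1–5) whose ties get midranks; the
    correlation is the Pearson correlation of the two rank vectors and the
    p-value comes from the t-distribution approximation with n − 2 degrees
    of freedom.

    Raises
    ------
    ValueError
        n < 3, ``y`` outside its declared ordinal range, or zero variance
        in either variable (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 pairs, got {n}")
    if ordinal_range is not None:
        lo, hi = ordinal_range
        if y.min() < lo or y.max() > hi:
            raise ValueError(
                f"ordinal scores outside declared range [{lo}, {hi}]: "
                f"min {y.min()}, max {y.max()}"
            )
    rx, ry = _midrank(x), _midrank(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in ranks: correlation undefined")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t_stat), n - 2))
    return CorrResult(rho=rho, p=p, n=n)
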