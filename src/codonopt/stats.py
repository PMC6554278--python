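"""Statistical analysis of feature–expression association.

Protein expression is recorded as ordinal scores (1 low/not detected,
2 medium, 3 high) assumed to discretize a latent Gaussian liability at
fixed cutpoints. The association between a continuous sequence feature x
and the scores y is measured by the polyserial correlation — the
correlation between x and the latent liability.

Two estimators are provided:

* ``two_step``: cutpoints tau_k from inverse-normal of the cumulative
  level proportions, then rho = r_xy * sd(y) / sum_k phi(tau_k) with y
  numerically coded 1..K (the classical ad-hoc estimator); p-value from
  the Fisher-z approximation.
* ``ml``: maximize the bivariate latent-Gaussian likelihood over
  (rho, cutpoints) with x standardized to sample moments; standard error
  from a finite-difference Hessian, p from a Wald z test of rho = 0.

Also here: the window scan over 5'-region definitions (which UTR suffix /
head length carries the expression signal) and the Mann–Whitney U group
comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .folding import HeadRegionSpec, dG_UH

__all__ = [
    "DegenerateDataError",
    "PolyserialResult",
    "ScanResult",
    "polyserial",
    "feature_expression_analysis",
    "window_scan",
    "group_compare",
]

MIN_N = 10


class DegenerateDataError(ValueError):
    """Data cannot support the estimator (single level, constant x, ...)."""


@dataclass(frozen=True)
class PolyserialResult:
    """Latent-correlation estimate between a feature and ordinal scores."""

    rho: float
    se: float
    p_value: float
    thresholds: tuple
    n: int
    estimator: str

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def _validate_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    if len(x) < MIN_N:
        raise ValueError(f"need at least {MIN_N} observations, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    levels = np.unique(y)
    if len(levels) < 2:
        raise DegenerateDataError("y has a single observed level")
    if np.std(x) == 0:
        raise DegenerateDataError("x is constant")
    # order-preserving recode to 1..K
    y_num = np.searchsorted(levels, y) + 1
    return x, y_num, len(levels)


def _two_step(x, y_num, K):
    n = len(x)
    cum = np.cumsum([np.mean(y_num == k) for k in range(1, K + 1)])[:-1]
    tau = sps.norm.ppf(cum)
    r = np.corrcoef(x, y_num)[0, 1]
    rho = r * np.std(y_num, ddof=1) / np.sum(sps.norm.pdf(tau))
    rho = float(np.clip(rho, -1.0, 1.0))
    # Fisher-z approximation on the estimate
    se_z = 1.0 / math.sqrt(n - 3)
    z = math.atanh(min(max(rho, -1 + 1e-12), 1 - 1e-12)) / se_z
    p = 2.0 * sps.norm.sf(abs(z))
    se = (1.0 - rho**2) * se_z
    return rho, se, p, tau


def _ml_negloglik(theta, z, y_num, K):
    t = theta[0]
    rho = math.tanh(t)
    tau = np.empty(K + 1)
    tau[0] = -np.inf
    tau[-1] = np.inf
    tau[1] = theta[1]
    for k in range(2, K):
        tau[k] = tau[k - 1] + math.exp(theta[k])
    s = math.sqrt(max(1.0 - rho * rho, 1e-12))
    upper = (tau[y_num] - rho * z) / s
    lower = (tau[y_num - 1] - rho * z) / s
    p = sps.norm.cdf(upper) - sps.norm.cdf(lower)
    return -np.sum(np.log(np.clip(p, 1e-300, None)))


def _ml(x, y_num, K):
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    rho0, _, _, tau0 = _two_step(x, y_num, K)
    rho0 = float(np.clip(rho0, -0.99, 0.99))
    theta0 = np.empty(K)
    theta0[0] = math.atanh(rho0)
    theta0[1] = tau0[0]
    for k in range(2, K):
        theta0[k] = math.log(max(tau0[k - 1] - tau0[k - 2], 1e-3))
    res = optimize.minimize(
        _ml_negloglik, theta0, args=(z, y_num, K), method="BFGS",
        options={"gtol": 1e-6, "maxiter": 200},
    )
    theta = res.x
    rho = math.tanh(theta[0])
    tau = [theta[1]]
    for k in range(2, K):
        tau.append(tau[-1] + math.exp(theta[k]))
    # finite-difference Hessian for the observed information
    eps = 1e-4
    m = len(theta)
    H = np.empty((m, m))
    f0 = _ml_negloglik(theta, z, y_num, K)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m)
            ej = np.zeros(m)
            ei[i] = eps
            ej[j] = eps
            fpp = _ml_negloglik(theta + ei + ej, z, y_num, K)
            fpm = _ml_negloglik(theta + ei - ej, z, y_num, K)
            fmp = _ml_negloglik(theta - ei + ej, z, y_num, K)
            fmm = _ml_negloglik(theta - ei - ej, z, y_num, K)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    try:
        cov = np.linalg.inv(H)
        se_t = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        se_t = math.sqrt(max(res.hess_inv[0, 0], 0.0))
    se = (1.0 - rho**2) * se_t  # delta method from the atanh scale
    if se > 0:
        zstat = rho / se
        p = 2.0 * sps.norm.sf(abs(zstat))
    else:
        p = float("nan")
    return rho, se, p, np.asarray(tau)


def polyserial(x, y, estimator: str = "two_step") -> PolyserialResult:
    """Polyserial correlation between continuous x and ordinal y."""
    x, y_num, K = _validate_xy(x, y)
    if estimator == "two_step":
        rho, se, p, tau = _two_step(x, y_num, K)
    elif estimator == "ml":
        rho, se, p, tau = _ml(x, y_num, K)
    else:
        raise ValueError(f"unknown estimator {estimator!r}; use 'two_step' or 'ml'")
    return PolyserialResult(
        rho=float(rho), se=float(se), p_value=float(p),
        thresholds=tuple(float(t) for t in tau), n=len(x), estimator=estimator,
    )


def feature_expression_analysis(
    features: pd.DataFrame,
    scores: Mapping[str, int] | pd.Series | Iterable,
    estimator: str = "two_step",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One polyserial correlation per feature column.

    ``features`` is gene x feature (index = gene_id); ``scores`` maps
    gene_id to the ordinal expression score. Genes are inner-joined on id.
    Returns a DataFrame (index = feature) with rho, se, p_value, n,
    estimator, and a ``significant`` flag at ``alpha``; degenerate columns
    (constant values) come back as NaN with a warning.
    """
    if not isinstance(scores, pd.Series):
        try:
            scores = pd.Series(dict(scores))
        except (TypeError, ValueError):
            scores = pd.Series(
                {r.gene_id: r.score for r in scores}  # ExpressionRecord-likes
            )
    common = features.index.intersection(scores.index)
    if len(common) == 0:
        raise ValueError("no genes shared between features and scores")
    if len(common) < MIN_N:
        raise ValueError(f"only {len(common)} genes after join; need >= {MIN_N}")
    feats = features.loc[common]
    y = scores.loc[common].to_numpy()
    rows = {}
    for col in feats.columns:
        x = feats[col].to_numpy(dtype=float)
        mask = np.isfinite(x)
        try:
            res = polyserial(x[mask], y[mask], estimator=estimator)
            rows[col] = {
                "rho": res.rho, "se": res.se, "p_value": res.p_value,
                "n": res.n, "estimator": estimator,
                "significant": res.p_value <= alpha,
            }
        except (DegenerateDataError, ValueError) as exc:
            warnings.warn(f"feature {col!r} degenerate: {exc}", stacklevel=2)
            rows[col] = {
                "rho": np.nan, "se": np.nan, "p_value": np.nan,
                "n": int(mask.sum()), "estimator": estimator, "significant": False,
            }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature"
    return out


@dataclass(frozen=True)
class ScanResult:
    """Polyserial correlation of dG_UH over a grid of 5'-region definitions."""

    grid: Mapping
    argmax_cell: tuple
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "utr_take": take, "head_nt": hnt,
                "rho": r.rho, "se": r.se, "p_value": r.p_value, "n": r.n,
            }
            for (take, hnt), r in self.grid.items()
        ]
        return pd.DataFrame(rows)


def window_scan(
    cds_set: Sequence,
    scores: Mapping[str, int] | pd.Series,
    utr: str,
    utr_takes: Iterable[int],
    head_nts: Iterable[int],
    backend=None,
    estimator: str = "two_step",
) -> ScanResult:
    """Scan 5'-region definitions: for every (UTR suffix length, head length)
    cell, fold each gene's region, correlate dG with the expression scores,
    and report the cell with the largest coefficient."""
    if not isinstance(scores, pd.Series):
        scores = pd.Series(dict(scores))
    seqs = {s.id: s for s in cds_set}
    common = [g for g in seqs if g in scores.index]
    if len(common) < MIN_N:
        raise ValueError(f"only {len(common)} genes with scores; need >= {MIN_N}")
    y = scores.loc[common].to_numpy()
    grid = {}
    cache: dict = {}
    for hnt in head_nts:
        if hnt % 3 != 0:
            raise ValueError(f"head_nt {hnt} is not a multiple of 3")
        for take in utr_takes:
            spec = HeadRegionSpec(utr=utr, head_nt=hnt, utr_take=take)
            dgs = np.empty(len(common))
            for i, g in enumerate(common):
                key = (g, take, hnt)
                if key not in cache:
                    cache[key] = dG_UH(seqs[g], spec, backend)
                dgs[i] = cache[key]
            grid[(take, hnt)] = polyserial(dgs, y, estimator=estimator)
    argmax_cell = max(grid, key=lambda cell: grid[cell].rho)
    return ScanResult(grid=grid, argmax_cell=argmax_cell, n=len(common))


def group_compare(values_a, values_b) -> dict:
    """Two-sided Mann–Whitney U test between two groups of feature values
    (exact for small tie-free samples, as scipy decides)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return {"U": float(res.statistic), "p_value": float(res.pvalue)}
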