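"""Goodness of fit between observed and null-expected gradients.

For each randomization iteration, the observed per-cell metric is
regressed (OLS) on the iteration's expected metric; the per-iteration
(r², intercept, slope) triples summarize how well random range
placement reproduces the empirical gradient. A mechanistically
sufficient null predicts intercept 0 and slope 1, so the ensemble of
(intercept, slope) pairs is tested against that point with a bivariate-
normal 95% probability-contour ellipse: the point is inside iff its
squared Mahalanobis distance from the sample mean, under the sample
covariance, is at most the chi-square(2) 0.95 quantile (5.9915).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CHI2_95_DF2 = float(stats.chi2.ppf(0.95, df=2))  # 5.9915


class DegenerateFitError(ValueError):
    """Too few complete cells, or an expected gradient without variance."""


@dataclass(frozen=True)
class FitResult:
    """One OLS fit of observed on expected values."""

    r2: float
    intercept: float
    slope: float
    n_cells: int


@dataclass
class EnsembleFit:
    """Per-iteration fits plus distribution summaries."""

    metric: str
    fits: list  # FitResult per retained iteration
    n_failed: int = 0

    def __len__(self) -> int:
        return len(self.fits)

    def triples(self) -> np.ndarray:
        return np.array([[f.r2, f.intercept, f.slope] for f in self.fits])

    def summary(self) -> dict:
        """Means plus 95% and 99% percentile intervals of each parameter."""
        arr = self.triples()
        out = {"metric": self.metric, "n_iterations": len(self.fits), "n_failed": self.n_failed}
        for k, name in enumerate(("r2", "intercept", "slope")):
            x = arr[:, k]
            out[f"mean_{name}"] = float(x.mean())
            for level in (95, 99):
                half = (100 - level) / 2
                lo, hi = np.percentile(x, [half, 100 - half])
                out[f"ci{level}_{name}"] = [float(lo), float(hi)]
        return out


@dataclass
class EllipseTest:
    """Bivariate-normal probability-contour containment test."""

    mean: np.ndarray          # (intercept, slope) sample mean
    cov: np.ndarray           # 2x2 sample covariance
    point: tuple
    mahalanobis_sq: float
    threshold: float
    inside: bool
    rank: int = 2

    def to_dict(self) -> dict:
        return {
            "mean_intercept": float(self.mean[0]),
            "mean_slope": float(self.mean[1]),
            "cov": [[float(v) for v in row] for row in self.cov],
            "point": [float(v) for v in self.point],
            "mahalanobis_sq": float(self.mahalanobis_sq),
            "threshold": float(self.threshold),
            "inside": bool(self.inside),
            "rank": int(self.rank),
        }


def regress_obs_on_exp(observed, expected) -> FitResult:
    """OLS of observed (dependent) on expected (independent) values.

    Cells where either value is missing are dropped; at least 3 complete
    cells and nonzero variance in the expected values are required.
    """
    obs = np.asarray(observed, dtype=float)
    exp_ = np.asarray(expected, dtype=float)
    if obs.shape != exp_.shape:
        raise ValueError("observed and expected must have equal length")
    ok = np.isfinite(obs) & np.isfinite(exp_)
    obs, exp_ = obs[ok], exp_[ok]
    if len(obs) < 3:
        raise DegenerateFitError(f"only {len(obs)} complete cells (need >= 3)")
    if np.ptp(exp_) == 0:
        raise DegenerateFitError("expected gradient has zero variance")
    res = stats.linregress(exp_, obs)
    r2 = 0.0 if math.isnan(res.rvalue) else float(res.rvalue**2)
    return FitResult(r2=r2, intercept=float(res.intercept), slope=float(res.slope), n_cells=len(obs))


def ensemble_fit(
    observed: pd.Series | np.ndarray,
    expected_tables: Sequence,
    metric: str | None = None,
) -> EnsembleFit:
    """One fit per randomization iteration of one metric.

    ``expected_tables`` may be metric DataFrames (the ``metric`` column
    is used) or per-cell vectors. Iterations whose fit is degenerate
    (e.g. nearly empty simulated cells everywhere) are excluded and
    counted in ``n_failed``.
    """
    obs = observed[metric] if isinstance(observed, pd.DataFrame) else observed
    obs = np.asarray(obs, dtype=float)
    fits, failed = [], 0
    for tab in expected_tables:
        exp_ = tab[metric] if isinstance(tab, pd.DataFrame) else tab
        try:
            fits.append(regress_obs_on_exp(obs, exp_))
        except DegenerateFitError:
            failed += 1
    if not fits:
        raise DegenerateFitError(f"all {failed} iterations degenerate for {metric!r}")
    return EnsembleFit(metric=metric or "metric", fits=fits, n_failed=failed)


def mahalanobis_sq(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of row vectors from ``mean`` under ``cov``."""
    diff = np.atleast_2d(points) - mean
    sol = np.linalg.solve(cov, diff.T)
    return (diff.T * sol).sum(axis=0)


def ellipse_test(
    ens: EnsembleFit | np.ndarray,
    point: tuple = (0.0, 1.0),
    level: float = 0.95,
    small_sample: bool = False,
) -> EllipseTest:
    """Is ``point`` inside the fitted probability-contour ellipse?

    The (intercept, slope) cloud is summarized by its sample mean and
    covariance; containment compares the point's squared Mahalanobis
    distance with the chi-square quantile at ``level`` (plug-in
    bivariate-normal contour; 5.9915 at the default level in the full-
    rank case). ``small_sample=True`` uses the F-distribution quantile
    ``2(n-1)/(n-2) F_{2,n-2}`` instead.

    The covariance can be exactly singular: when every regression uses
    the same cell set, exact range-size conservation fixes the expected
    gradient's mean, making intercept and slope perfectly collinear —
    and the test point lies on that same line whenever the observed and
    expected means coincide. The Mahalanobis distance is therefore
    computed on the covariance's numerical rank (eigenvalues above
    ``1e-9`` of the largest), with the chi-square threshold at that
    rank; displacement off the degenerate subspace, beyond rounding,
    puts the point outside outright.
    """
    if isinstance(ens, EnsembleFit):
        cloud = ens.triples()[:, 1:3]
    else:
        cloud = np.asarray(ens, dtype=float)
    n = cloud.shape[0]
    if n < 3:
        raise DegenerateFitError("need at least 3 iterations for the ellipse test")
    mean = cloud.mean(axis=0)
    cov = np.cov(cloud, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    scale = float(evals.max())
    if not np.isfinite(scale) or scale <= 0:
        raise DegenerateFitError(
            "the (intercept, slope) cloud has no spread at all; "
            "inspect the per-iteration fits"
        )
    diff = np.asarray(point, dtype=float) - mean
    d2 = 0.0
    rank = 0
    off_subspace = False
    for lam, v in zip(evals, evecs.T):
        proj = float(v @ diff)
        if lam > 1e-9 * scale:
            d2 += proj * proj / lam
            rank += 1
        elif abs(proj) > 1e-6 * math.sqrt(scale):
            off_subspace = True
    if small_sample and n > 4:
        thr = rank * (n - 1) / (n - rank) * float(stats.f.ppf(level, rank, n - rank))
    else:
        thr = float(stats.chi2.ppf(level, df=rank))
    if off_subspace:
        d2 = math.inf
    return EllipseTest(
        mean=mean, cov=cov, point=tuple(point),
        mahalanobis_sq=d2, threshold=thr, inside=d2 <= thr, rank=rank,
    )
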