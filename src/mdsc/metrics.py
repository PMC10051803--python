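"""Agreement statistics: Lin's concordance correlation coefficient, MAE,
RMSE, percentile-bootstrap confidence intervals, and GMFCS-stratified bias
diagnostics.

Lin's CCC is computed with n-divisor (biased) moments, following the
original definition:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2).

The divisor choice changes small-sample values, so it is fixed here and
documented rather than configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from mdsc.errors import ConfigurationError


def _paired(x, y, min_len: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-d vectors, got {x.shape} / {y.shape}")
    if len(x) < min_len:
        raise ValueError(f"need at least {min_len} pairs, got {len(x)}")
    return x, y


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient of two paired score vectors.

    Equals 1 iff ``y == x`` elementwise.  Degenerate cases: if both vectors
    are constant with equal means the coefficient is 0/0 and a ValueError
    is raised; if only the means differ, the zero covariance makes the
    coefficient exactly 0.
    """
    x, y = _paired(x, y, 2)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # n-divisor
    sxy = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both vectors constant with equal means (0/0)")
    return float(2.0 * sxy / denom)


def mae(x, y) -> float:
    """Mean absolute error between paired scores (GMFM-66 units)."""
    x, y = _paired(x, y, 1)
    return float(np.mean(np.abs(x - y)))


def rmse(x, y) -> float:
    """Root mean square error between paired scores (GMFM-66 units)."""
    x, y = _paired(x, y, 1)
    return float(np.sqrt(np.mean((x - y) ** 2)))


_METRICS: dict[str, Callable] = {"ccc": lin_ccc, "mae": mae, "rmse": rmse}


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile-bootstrap interval for one agreement metric.

    ``n_redrawn`` counts resamples discarded because the metric was
    undefined on them (e.g. a constant resample for the CCC).
    ``contains_point`` flags the rare percentile-method pathology where the
    interval excludes the point estimate.
    """

    lo: float
    hi: float
    point: float
    n_redrawn: int
    contains_point: bool


def bootstrap_ci(
    metric, x, y, reps: int = 2000, level: float = 0.95, seed: int = 0
) -> BootstrapCI:
    """Percentile bootstrap over whole patient pairs.

    ``metric`` is one of ``"ccc" | "mae" | "rmse"`` or a callable
    ``f(x, y) -> float``.  Deterministic given ``seed``.
    """
    if isinstance(metric, str):
        try:
            fn = _METRICS[metric]
        except KeyError:
            raise ConfigurationError(
                f"unknown metric {metric!r}; expected one of {sorted(_METRICS)}"
            ) from None
    else:
        fn = metric
    if reps < 100:
        raise ConfigurationError(f"reps must be >= 100, got {reps}")
    if not (0.0 < level < 1.0):
        raise ConfigurationError(f"level must be in (0, 1), got {level}")
    x, y = _paired(x, y, 2)
    point = fn(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    stats = np.empty(reps)
    redrawn = 0
    max_attempts = 50 * reps
    filled = 0
    attempts = 0
    while filled < reps:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "bootstrap failed: metric undefined on nearly every resample"
            )
        idx = rng.integers(0, n, size=n)
        try:
            stats[filled] = fn(x[idx], y[idx])
        except ValueError:
            redrawn += 1
            continue
        filled += 1
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    contains = bool(lo <= point <= hi)
    if not contains:
        warnings.warn(
            f"percentile interval ({lo:.4g}, {hi:.4g}) excludes the point "
            f"estimate {point:.4g}",
            stacklevel=2,
        )
    return BootstrapCI(float(lo), float(hi), float(point), redrawn, contains)


@dataclass(frozen=True)
class MetricsReport:
    """CCC / MAE / RMSE with 95% bootstrap intervals for one prediction run."""

    ccc: float
    ccc_ci: tuple[float, float]
    mae: float
    mae_ci: tuple[float, float]
    rmse: float
    rmse_ci: tuple[float, float]
    n: int
    bootstrap_reps: int
    seed: int


def evaluate_agreement(
    x, y, reps: int = 2000, level: float = 0.95, seed: int = 0
) -> MetricsReport:
    """Compute the full agreement report for paired (GMFM-66, MDS) scores."""
    x, y = _paired(x, y, 2)
    cis = {
        name: bootstrap_ci(name, x, y, reps=reps, level=level, seed=seed)
        for name in ("ccc", "mae", "rmse")
    }
    return MetricsReport(
        ccc=cis["ccc"].point,
        ccc_ci=(cis["ccc"].lo, cis["ccc"].hi),
        mae=cis["mae"].point,
        mae_ci=(cis["mae"].lo, cis["mae"].hi),
        rmse=cis["rmse"].point,
        rmse_ci=(cis["rmse"].lo, cis["rmse"].hi),
        n=len(x),
        bootstrap_reps=reps,
        seed=seed,
    )


def stratified_bias(x, y, strata) -> pd.DataFrame:
    """Per-GMFCS-level error diagnostics for the floor/ceiling analysis.

    Parameters
    ----------
    x, y : array-like
        True GMFM-66 scores and predicted Medical Device Scores.
    strata : array-like of int
        GMFCS level (1-5) per pair.

    Returns
    -------
    DataFrame indexed by level 1-5 with columns ``n``, ``mean_error``
    (mean of MDS - GMFM, signed), ``mean_abs_error``, and quartiles of both
    score sources.  Levels with no pairs get ``n = 0`` and NaN statistics.
    """
    x, y = _paired(x, y, 1)
    strata = np.asarray(strata, dtype=int)
    if strata.shape != x.shape:
        raise ValueError("strata must be one label per pair")
    rows = {}
    for level in (1, 2, 3, 4, 5):
        mask = strata == level
        n = int(mask.sum())
        if n == 0:
            rows[level] = {"n": 0}
            continue
        gx, gy = x[mask], y[mask]
        err = gy - gx
        row = {
            "n": n,
            "mean_error": float(err.mean()),
            "mean_abs_error": float(np.abs(err).mean()),
        }
        for tag, vals in (("gmfm", gx), ("mds", gy)):
            q25, q50, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
            row[f"{tag}_q25"], row[f"{tag}_q50"], row[f"{tag}_q75"] = (
                float(q25), float(q50), float(q75),
            )
        rows[level] = row
    df = pd.DataFrame.from_dict(rows, orient="index").reindex([1, 2, 3, 4, 5])
    df.index.name = "gmfcs"
    df["n"] = df["n"].fillna(0).astype(int)
    return df
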