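"""Maximum specific growth rate from plate-reader time series.

The maximum specific growth rate mu_max (1/h) of a well is the largest
slope of log biomass-proxy signal versus time.  It is estimated
nonparametrically with a cubic smoothing spline fitted to ln(signal),
its smoothness chosen by generalized cross-validation (GCV), and
mu_max taken as the maximum of the spline's first derivative over the
observed time interval.

Instrument noise is approximately additive on the *linear* signal scale,
which makes the log-transformed data heteroscedastic: Var[ln y] ~
sigma^2 / y^2.  By default the spline is therefore fitted with
variance-stabilising weights w ∝ yhat^2, where yhat is a pilot GCV
smooth of the linear-scale signal (``weighting="none"`` disables this
and reproduces a plain unweighted log-scale fit).

Quality and edge-case rules:

* a well whose signal never rises above ``growth_factor_threshold``
  times its initial level is scored as no growth, mu_max = 0;
* a fit whose log-scale coefficient of determination falls below
  ``r2_threshold`` (default 0.99) is rejected and mu_max is missing;
* too few points, non-increasing times, or non-positive raw signals
  make the curve invalid.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .core import PhenotypeMatrix

__all__ = [
    "GrowthCurve",
    "GrowthFitResult",
    "FitConfig",
    "fit_mu_max",
    "fit_plate",
    "results_to_matrix",
]

logger = logging.getLogger(__name__)

STATUS_FIT = "fit"
STATUS_NO_GROWTH = "no_growth"
STATUS_POOR_FIT = "poor_fit"
STATUS_INVALID = "invalid_input"

MIN_POINTS = 5
#: relative floor applied to post-blank signals before taking logs
LOG_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class GrowthCurve:
    """One well's biomass-proxy time series (times in hours)."""

    well_id: str
    strain_id: str
    condition_id: str
    replicate_id: str
    times: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))


@dataclass(frozen=True)
class GrowthFitResult:
    """mu_max estimate and fit diagnostics for one well.

    ``mu_max``, ``r_squared`` and ``t_mu_max`` are NaN when not
    applicable for the given status.
    """

    well_id: str
    strain_id: str
    condition_id: str
    replicate_id: str
    mu_max: float
    r_squared: float
    t_mu_max: float
    status: str


@dataclass(frozen=True)
class FitConfig:
    """Settings for the spline mu_max estimator.

    Parameters
    ----------
    r2_threshold
        Minimum log-scale R^2 for a fit to be accepted.
    growth_factor_threshold
        A well grows if max(signal) >= threshold x initial signal, where
        the initial signal is the mean of the first three points (robust
        to a single noisy reading).
    blank_value
        Per-plate blank subtracted from every signal before fitting.
    smoothness
        ``"auto"`` selects the spline penalty by GCV; a number fixes it
        (useful for exact reproducibility studies).
    weighting
        ``"signal"`` (default) fits ln(signal) with weights proportional
        to the squared pilot-smoothed signal; ``"none"`` fits unweighted.
    grid_points
        Resolution of the derivative-maximisation grid.
    """

    r2_threshold: float = 0.99
    growth_factor_threshold: float = 1.2
    blank_value: float = 0.0
    smoothness: str | float = "auto"
    weighting: str = "signal"
    grid_points: int = 2001

    def __post_init__(self) -> None:
        if self.weighting not in ("signal", "none"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if isinstance(self.smoothness, str) and self.smoothness != "auto":
            raise ValueError(f"smoothness must be 'auto' or a number, got {self.smoothness!r}")


def _invalid(curve: GrowthCurve) -> GrowthFitResult:
    return GrowthFitResult(
        curve.well_id, curve.strain_id, curve.condition_id, curve.replicate_id,
        math.nan, math.nan, math.nan, STATUS_INVALID,
    )


def fit_mu_max(curve: GrowthCurve, config: FitConfig | None = None) -> GrowthFitResult:
    """Estimate the maximum specific growth rate of one well.

    Returns a :class:`GrowthFitResult`; never raises on bad data, which
    is reported through the ``invalid_input`` status instead so that
    whole plates can be processed in one pass.
    """
    config = config or FitConfig()
    t = curve.times
    y_raw = curve.signals

    if (
        t.size != y_raw.size
        or t.size < MIN_POINTS
        or np.any(np.diff(t) <= 0)
        or np.any(~np.isfinite(t))
        or np.any(~np.isfinite(y_raw))
        or np.any(y_raw <= 0)
    ):
        return _invalid(curve)

    y = y_raw - config.blank_value
    ymax = float(y.max())
    if ymax <= 0:
        return _invalid(curve)
    y = np.clip(y, LOG_FLOOR_FRACTION * ymax, None)

    initial = float(y[:3].mean())
    if ymax < config.growth_factor_threshold * initial:
        return GrowthFitResult(
            curve.well_id, curve.strain_id, curve.condition_id, curve.replicate_id,
            0.0, math.nan, math.nan, STATUS_NO_GROWTH,
        )

    lam = None if config.smoothness == "auto" else float(config.smoothness)
    ly = np.log(y)

    w = None
    if config.weighting == "signal":
        pilot = make_smoothing_spline(t, y, lam=lam)
        yhat = np.clip(pilot(t), 1e-3 * ymax, None)
        w = yhat**2
        w = w / w.mean()  # normalised: estimates invariant to signal rescaling

    spline = make_smoothing_spline(t, ly, w=w, lam=lam)

    grid = np.linspace(t[0], t[-1], config.grid_points)
    deriv = spline.derivative()(grid)
    i = int(np.argmax(deriv))
    mu = max(float(deriv[i]), 0.0)
    t_mu = float(grid[i])

    pred = spline(t)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((ly - pred) ** 2)) / ss_tot

    if r2 < config.r2_threshold:
        return GrowthFitResult(
            curve.well_id, curve.strain_id, curve.condition_id, curve.replicate_id,
            math.nan, r2, math.nan, STATUS_POOR_FIT,
        )
    return GrowthFitResult(
        curve.well_id, curve.strain_id, curve.condition_id, curve.replicate_id,
        mu, r2, t_mu, STATUS_FIT,
    )


def fit_plate(
    curves: Sequence[GrowthCurve], config: FitConfig | None = None
) -> list[GrowthFitResult]:
    """Fit every well of a plate, preserving input order."""
    ids = [c.well_id for c in curves]
    dup = [w for w, n in Counter(ids).items() if n > 1]
    if dup:
        raise ValueError(f"duplicate well ids: {sorted(dup)}")
    results = [fit_mu_max(c, config) for c in curves]
    counts = Counter(r.status for r in results)
    logger.info("fit_plate: %d wells, status counts %s", len(results), dict(counts))
    return results


def results_to_matrix(
    results: Sequence[GrowthFitResult],
    condition_subsets: Mapping[str, Sequence[str]] | None = None,
) -> PhenotypeMatrix:
    """Assemble per-well mu_max estimates into a phenotype matrix.

    Accepted fits contribute their mu_max, no-growth wells contribute 0,
    and rejected or invalid wells become missing values.  When no
    subsets are given and the data span >= 2 conditions, a single
    subset named ``"ALL"`` covering every condition is declared.
    """
    import pandas as pd

    rows = []
    for r in results:
        if r.status == STATUS_FIT:
            value = r.mu_max
        elif r.status == STATUS_NO_GROWTH:
            value = 0.0
        else:
            value = math.nan
        rows.append((r.strain_id, r.condition_id, r.replicate_id, value))
    df = pd.DataFrame(rows, columns=["strain", "condition", "replicate", "value"])
    if condition_subsets is None:
        conds = sorted(df["condition"].unique())
        condition_subsets = {"ALL": conds} if len(conds) >= 2 else {}
    return PhenotypeMatrix(df, condition_subsets)
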