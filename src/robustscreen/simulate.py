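"""Synthetic screens, growth curves and annotations with known truth.

The generators emulate the statistical structure the analysis assumes:

* ``simulate_screen`` -- a deletion-library phenomics screen: a
  non-negative phenotype (normalized colony size or growth rate) per
  strain x condition x replicate, built from log-normal strain means,
  per-strain condition-to-condition dispersion, shared multiplicative
  condition effects, additive replicate noise, sporadic zero-growth
  cells, and a fraction of perfectly stable ("robust") strains.  Default
  dimensions follow the reference screen this pipeline targets: 4429
  mutants across 14 conditions, single observations per cell.
* ``simulate_plate`` -- logistic growth trajectories with additive
  Gaussian instrument noise and optional flat no-growth wells; the true
  maximum specific growth rate of a logistic curve is r(1 - y0/K).
* ``simulate_annotation`` -- random strain -> region labels with
  optionally planted per-region metric shifts, for power studies of the
  region deviation test.

Every generator is deterministic given its config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import PhenotypeMatrix
from .growth import GrowthCurve
from .screen import AnnotationTable

__all__ = [
    "ScreenSimConfig",
    "PlateSimConfig",
    "simulate_screen",
    "simulate_plate",
    "simulate_annotation",
    "logistic",
]


def _check(errors: list[str], ok: bool, msg: str) -> None:
    if not ok:
        errors.append(msg)


@dataclass(frozen=True)
class ScreenSimConfig:
    """Ground-truth model of a strain x condition x replicate screen.

    ``strain_mean_law`` is (median, log-scale sd) of the log-normal law
    of per-strain mean phenotype; ``strain_dispersion_law`` is (shape,
    scale) of the gamma law of each strain's coefficient of variation
    across conditions.  ``condition_effect_sd`` is the log-scale sd of
    multiplicative condition effects shared by all strains;
    ``replicate_noise_sd`` is additive, in phenotype units.
    """

    n_strains: int = 4429
    n_conditions: int = 14
    n_replicates: int = 1
    strain_mean_law: tuple[float, float] = (1.0, 0.2)
    strain_dispersion_law: tuple[float, float] = (2.0, 0.05)
    condition_effect_sd: float = 0.1
    replicate_noise_sd: float = 0.02
    zero_growth_fraction: float = 0.005
    robust_fraction: float = 0.015
    seed: int = 0

    def validate(self) -> None:
        e: list[str] = []
        _check(e, self.n_strains >= 1, "n_strains must be >= 1")
        _check(e, self.n_conditions >= 1, "n_conditions must be >= 1")
        _check(e, self.n_replicates >= 1, "n_replicates must be >= 1")
        _check(e, self.strain_mean_law[0] > 0, "strain_mean_law median must be > 0")
        _check(e, self.strain_mean_law[1] >= 0, "strain_mean_law spread must be >= 0")
        _check(e, all(p > 0 for p in self.strain_dispersion_law),
               "strain_dispersion_law parameters must be > 0")
        _check(e, self.condition_effect_sd >= 0, "condition_effect_sd must be >= 0")
        _check(e, self.replicate_noise_sd >= 0, "replicate_noise_sd must be >= 0")
        _check(e, 0 <= self.zero_growth_fraction <= 1, "zero_growth_fraction must be in [0,1]")
        _check(e, 0 <= self.robust_fraction <= 1, "robust_fraction must be in [0,1]")
        if e:
            raise ValueError("invalid ScreenSimConfig: " + "; ".join(e))


@dataclass(frozen=True)
class PlateSimConfig:
    """Ground-truth model of a plate of logistic growth curves.

    Parameter ranges are uniform per well.  ``noise_sd`` is the additive
    Gaussian noise sd as a fraction of that well's carrying capacity K.
    Start signals default to 5-15 % of K so that the inoculum is
    resolvable above instrument noise, and rates to 0.05-0.3 1/h, the
    span a budding-yeast screen in rich or inhibitor-supplemented media
    typically covers.
    """

    n_wells: int = 96
    y0_range: tuple[float, float] = (0.05, 0.15)
    K_range: tuple[float, float] = (0.8, 1.2)
    r_range: tuple[float, float] = (0.05, 0.3)
    noise_sd: float = 0.01
    sampling_interval_h: float = 0.5
    duration_h: float = 48.0
    no_growth_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        e: list[str] = []
        _check(e, self.n_wells >= 1, "n_wells must be >= 1")
        _check(e, 0 < self.y0_range[0] <= self.y0_range[1], "y0_range must be positive and ordered")
        _check(e, 0 < self.K_range[0] <= self.K_range[1], "K_range must be positive and ordered")
        _check(e, self.y0_range[1] < self.K_range[0], "y0 must stay below K")
        _check(e, 0 < self.r_range[0] <= self.r_range[1], "r_range must be positive and ordered")
        _check(e, self.noise_sd >= 0, "noise_sd must be >= 0")
        _check(e, self.sampling_interval_h > 0, "sampling_interval_h must be > 0")
        _check(e, self.duration_h >= 10 * self.sampling_interval_h,
               "duration must cover >= 10 sampling intervals")
        _check(e, 0 <= self.no_growth_fraction <= 1, "no_growth_fraction must be in [0,1]")
        if e:
            raise ValueError("invalid PlateSimConfig: " + "; ".join(e))


def logistic(t: np.ndarray, y0: float, K: float, r: float) -> np.ndarray:
    """Logistic trajectory y(t) = K / (1 + (K/y0 - 1) e^(-rt))."""
    return K / (1.0 + (K / y0 - 1.0) * np.exp(-r * np.asarray(t, dtype=float)))


def simulate_screen(
    config: ScreenSimConfig,
    region_shifts: Mapping[str, float] | None = None,
    annotation: AnnotationTable | None = None,
) -> tuple[PhenotypeMatrix, pd.DataFrame]:
    """Draw a screen and its per-strain ground truth.

    Returns ``(matrix, truth)`` where ``truth`` has one row per strain
    with the true mean, dispersion (variance/mean) and robustness R of
    the *expected* (noise-free, infinite-replicate) phenotype across the
    realized conditions.  Optionally, ``region_shifts`` multiplies the
    mean of strains whose ``annotation`` region is listed by
    ``exp(shift)``, planting region-level fitness effects for enrichment
    power studies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_strains - 1)))
    strains = [f"strain{i:0{width}d}" for i in range(config.n_strains)]
    conditions = [f"cond{j:02d}" for j in range(config.n_conditions)]
    replicates = [f"rep{k:02d}" for k in range(config.n_replicates)]

    median, spread = config.strain_mean_law
    strain_means = median * np.exp(rng.normal(0.0, spread, config.n_strains))
    if region_shifts and annotation is not None:
        shifts = np.array(
            [region_shifts.get(annotation.get(s) or "", 0.0) for s in strains]
        )
        strain_means = strain_means * np.exp(shifts)

    shape, scale = config.strain_dispersion_law
    cvs = rng.gamma(shape, scale, config.n_strains)
    robust = rng.random(config.n_strains) < config.robust_fraction
    cvs[robust] = 0.0

    cond_effects = np.exp(rng.normal(0.0, config.condition_effect_sd, config.n_conditions))

    # strain-by-condition interaction: log-normal with per-strain sd chosen
    # so the across-condition coefficient of variation is ~ cvs[s]
    sigma_s = np.sqrt(np.log1p(cvs**2))
    z = rng.normal(0.0, 1.0, (config.n_strains, config.n_conditions))
    interaction = np.exp(z * sigma_s[:, None])

    expected = strain_means[:, None] * cond_effects[None, :] * interaction
    zero_mask = rng.random((config.n_strains, config.n_conditions)) < config.zero_growth_fraction
    expected[zero_mask] = 0.0
    # maximally robust strains are emulated as exactly invariant, mirroring
    # screens where the most stable mutants show identical values in every
    # condition and form the R = 0 tie block
    expected[robust, :] = strain_means[robust, None]

    obs = np.repeat(expected[:, :, None], config.n_replicates, axis=2)
    if config.replicate_noise_sd > 0:
        noise = rng.normal(0.0, config.replicate_noise_sd, obs.shape)
        noise[robust, :, :] = 0.0
        obs = obs + noise
    obs = np.clip(obs, 0.0, None)

    s_idx, c_idx, r_idx = np.meshgrid(
        np.arange(config.n_strains),
        np.arange(config.n_conditions),
        np.arange(config.n_replicates),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "strain": np.array(strains)[s_idx.ravel()],
            "condition": np.array(conditions)[c_idx.ravel()],
            "replicate": np.array(replicates)[r_idx.ravel()],
            "value": obs.ravel(),
        }
    )
    matrix = PhenotypeMatrix(df, {"ALL": conditions})

    m_true = float(expected.mean())
    true_mean = expected.mean(axis=1)
    true_var = expected.var(axis=1, ddof=1) if config.n_conditions >= 2 else np.full(
        config.n_strains, math.nan
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        true_disp = np.where(true_mean > 0, true_var / true_mean, math.nan)
    true_r = np.where(np.isnan(true_disp), math.nan, -true_disp / m_true)
    truth = pd.DataFrame(
        {
            "strain": strains,
            "true_mean": true_mean,
            "true_dispersion": true_disp,
            "true_robustness": true_r,
            "is_robust": robust,
        }
    )
    return matrix, truth


def simulate_plate(config: PlateSimConfig) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Draw a plate of growth curves and the true mu_max per well."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.duration_h + 1e-9, config.sampling_interval_h)

    curves: list[GrowthCurve] = []
    rows = []
    for i in range(config.n_wells):
        y0 = rng.uniform(*config.y0_range)
        K = rng.uniform(*config.K_range)
        r = rng.uniform(*config.r_range)
        grows = rng.random() >= config.no_growth_fraction
        if grows:
            y = logistic(t, y0, K, r)
            true_mu = r * (1.0 - y0 / K)
        else:
            y = np.full_like(t, y0)
            true_mu = 0.0
        y = y + rng.normal(0.0, config.noise_sd * K, t.size)
        y = np.clip(y, 1e-4 * K, None)
        well = f"W{i:03d}"
        curves.append(
            GrowthCurve(
                well_id=well,
                strain_id=f"strain{i:03d}",
                condition_id="cond01",
                replicate_id="rep01",
                times=t,
                signals=y,
            )
        )
        rows.append((well, true_mu, y0, K, r, grows))
    truth = pd.DataFrame(
        rows, columns=["well", "true_mu_max", "y0", "K", "r", "grows"]
    )
    return curves, truth


def simulate_annotation(
    strain_ids: Sequence[str],
    region_labels: Sequence[str],
    planted_shifts: Mapping[str, float] | None = None,
    weights: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[AnnotationTable, dict[str, float]]:
    """Assign strains to regions at random (uniformly or by weights).

    Returns the annotation plus the truth map region -> planted metric
    shift (0 for regions without a planted effect); feeding the truth to
    :func:`simulate_screen` via ``region_shifts`` closes the loop for
    power studies.
    """
    if not region_labels:
        raise ValueError("region_labels must be non-empty")
    rng = np.random.default_rng(seed)
    p = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.size != len(region_labels) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, one per region, not all zero")
        p = w / w.sum()
    labels = rng.choice(list(region_labels), size=len(strain_ids), p=p)
    table = AnnotationTable({s: str(l) for s, l in zip(strain_ids, labels)})
    truth = {r: float((planted_shifts or {}).get(r, 0.0)) for r in region_labels}
    return table, truth
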