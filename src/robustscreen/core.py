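"""Fano-factor robustness of a phenotype across a perturbation space.

A strain's robustness over a set of cultivation conditions (the
"perturbation space") is scored as

    R = -(sigma^2 / xbar) * (1 / m)

where ``sigma^2`` and ``xbar`` are the variance and mean of the strain's
phenotype values across all conditions and replicates of the space, and
``m`` is the grand mean of the phenotype over *all* strains in the space.
The variance-to-mean ratio ``sigma^2/xbar`` is the index of dispersion
(Fano factor); dividing by ``m`` makes the score dimensionless, so that
screens measured in different units (normalized colony size, maximum
specific growth rate in 1/h) can be compared.  R is always <= 0 for
non-negative phenotypes with positive mean; R = 0 (zero dispersion) is
maximal robustness, and more negative values mean a less stable phenotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeMatrix",
    "RobustnessRecord",
    "StrainStats",
    "compute_grand_mean",
    "strain_robustness",
    "robustness_table",
    "rank_strains",
    "records_to_frame",
]

#: record statuses
STATUS_OK = "ok"
STATUS_TOO_FEW = "too_few_obs"
STATUS_ZERO_MEAN = "zero_mean"

OBS_COLUMNS = ("strain", "condition", "replicate", "value")


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Strain x condition x replicate phenotype observations.

    Parameters
    ----------
    observations
        Long-format table with columns ``strain, condition, replicate,
        value``.  Values are non-negative phenotype measurements (growth
        rate in 1/h, normalized colony size, ...); missing values are NaN.
    condition_subsets
        Named perturbation spaces, each a list of >= 2 condition ids drawn
        from the conditions present in ``observations``.
    """

    observations: pd.DataFrame
    condition_subsets: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.observations
        missing_cols = [c for c in OBS_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"observations lack columns {missing_cols}")
        vals = df["value"].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("phenotype values must be non-negative")
        dup = df.duplicated(subset=["strain", "condition", "replicate"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate observation for "
                f"({row['strain']}, {row['condition']}, {row['replicate']})"
            )
        universe = set(df["condition"].unique())
        for name, conds in self.condition_subsets.items():
            conds = list(conds)
            if len(set(conds)) < 2:
                raise ValueError(f"subset {name!r} needs >= 2 distinct conditions")
            unknown = set(conds) - universe
            if unknown:
                raise ValueError(f"subset {name!r} has unknown conditions {sorted(unknown)}")

    @property
    def strains(self) -> list[str]:
        return sorted(self.observations["strain"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.observations["condition"].unique())

    def subset_observations(self, subset: str | None = None) -> pd.DataFrame:
        """Observations restricted to a named perturbation space.

        ``subset=None`` returns all observations.
        """
        if subset is None:
            return self.observations
        if subset not in self.condition_subsets:
            raise KeyError(f"unknown condition subset {subset!r}")
        conds = set(self.condition_subsets[subset])
        return self.observations[self.observations["condition"].isin(conds)]

    def restrict(self, conditions: Iterable[str], name: str = "restricted") -> "PhenotypeMatrix":
        """New matrix containing only the given conditions (single subset)."""
        conds = list(conditions)
        df = self.observations[self.observations["condition"].isin(set(conds))]
        return PhenotypeMatrix(df.reset_index(drop=True), {name: conds})


@dataclass(frozen=True)
class RobustnessRecord:
    """Per-strain fitness and robustness over one perturbation space."""

    strain_id: str
    n_obs: int
    strain_mean: float
    strain_variance: float
    grand_mean: float
    robustness: float  # NaN when undefined
    status: str = STATUS_OK

    @property
    def fitness(self) -> float:
        """Fitness = the strain's mean phenotype across the space."""
        return self.strain_mean


@dataclass(frozen=True)
class StrainStats:
    strain_mean: float
    strain_variance: float
    robustness: float
    status: str


def compute_grand_mean(matrix: PhenotypeMatrix, subset: str | None = None) -> float:
    """Grand mean ``m``: arithmetic mean of every non-missing observation
    in the perturbation space, pooled over strains, conditions and
    replicates (unweighted)."""
    vals = matrix.subset_observations(subset)["value"].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no data in subset")
    return float(vals.mean())


def strain_robustness(
    values: Sequence[float], grand_mean: float, ddof: int = 1
) -> StrainStats:
    """Apply the robustness score to one strain's pooled observations.

    ``values`` are the strain's non-missing phenotype values across all
    conditions and replicates of the space.  ``ddof=1`` gives the sample
    variance (default); ``ddof=0`` the population variance.
    """
    if grand_mean <= 0 or not math.isfinite(grand_mean):
        raise ValueError(f"grand mean must be positive, got {grand_mean}")
    vals = np.asarray(values, dtype=float)
    if np.any(np.isnan(vals)):
        vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        return StrainStats(
            strain_mean=float(vals.mean()) if vals.size else math.nan,
            strain_variance=math.nan,
            robustness=math.nan,
            status=STATUS_TOO_FEW,
        )
    mean = float(vals.mean())
    var = float(vals.var(ddof=ddof))
    if mean == 0.0:
        # all-zero phenotype: the Fano factor is undefined; never report 0,
        # which would falsely read as maximal robustness
        return StrainStats(0.0, var, math.nan, STATUS_ZERO_MEAN)
    rob = -(var / mean) / grand_mean + 0.0  # + 0.0 avoids IEEE negative zero
    return StrainStats(mean, var, rob, STATUS_OK)


def robustness_table(
    matrix: PhenotypeMatrix,
    subset: str | None = None,
    min_obs: int = 2,
    ddof: int = 1,
) -> list[RobustnessRecord]:
    """Robustness of every strain in a perturbation space.

    All replicates of all conditions are pooled as individual observations
    before the score is computed; the grand mean is shared by every record
    of one call.  Returns one record per strain, sorted by strain id.
    Strains with fewer than ``min_obs`` usable values or an all-zero
    phenotype carry NaN robustness and a non-ok status.
    """
    df = matrix.subset_observations(subset)
    grand_mean = compute_grand_mean(matrix, subset)

    grouped = df.groupby("strain")["value"]
    n_obs = grouped.count()  # non-missing
    means = grouped.mean()
    variances = grouped.var(ddof=ddof)

    records: list[RobustnessRecord] = []
    for strain in sorted(n_obs.index):
        n = int(n_obs[strain])
        mean = float(means[strain]) if n > 0 else math.nan
        var = float(variances[strain]) if n >= 2 else math.nan
        if n < min_obs or n < 2:
            status, rob = STATUS_TOO_FEW, math.nan
        elif mean == 0.0:
            status, rob = STATUS_ZERO_MEAN, math.nan
        else:
            status = STATUS_OK
            rob = -(var / mean) / grand_mean + 0.0
        records.append(
            RobustnessRecord(
                strain_id=str(strain),
                n_obs=n,
                strain_mean=mean,
                strain_variance=var,
                grand_mean=grand_mean,
                robustness=rob,
                status=status,
            )
        )
    return records


def rank_strains(
    records: Sequence[RobustnessRecord],
    by: str = "robustness",
    direction: str = "descending",
) -> list[str]:
    """Strain ids ordered by fitness or robustness.

    Missing-valued records are placed last regardless of direction; ties
    are broken by strain id (lexicographic).  The sort is stable.
    """
    if by not in ("fitness", "robustness"):
        raise ValueError(f"unknown ranking criterion {by!r}")
    if direction not in ("ascending", "descending"):
        raise ValueError(f"unknown direction {direction!r}")
    if not records:
        raise ValueError("no records to rank")
    sign = -1.0 if direction == "descending" else 1.0

    def key(rec: RobustnessRecord):
        v = rec.fitness if by == "fitness" else rec.robustness
        missing = v is None or math.isnan(v)
        return (missing, sign * v if not missing else 0.0, rec.strain_id)

    return [r.strain_id for r in sorted(records, key=key)]


def records_to_frame(records: Sequence[RobustnessRecord]) -> pd.DataFrame:
    """Tabular view of robustness records (one row per strain)."""
    return pd.DataFrame(
        {
            "strain": [r.strain_id for r in records],
            "n_obs": [r.n_obs for r in records],
            "fitness": [r.fitness for r in records],
            "variance": [r.strain_variance for r in records],
            "grand_mean": [r.grand_mean for r in records],
            "robustness": [r.robustness for r in records],
            "status": [r.status for r in records],
        }
    )
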