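"""Readers, writers and the end-to-end pipeline runner.

Table dialects
--------------
* phenotype, long: CSV with header ``strain,condition,replicate,value``;
  missing as empty field or ``NA``.
* phenotype, wide: TSV, rows = strains (first column ``strain``),
  columns = conditions, one file per replicate.
* time series: CSV with header ``well,strain,condition,replicate,time_h,signal``.
* annotation: two-column TSV ``strain<TAB>region`` with header.

All writers emit deterministic output: rows sorted, floats printed with
6 significant digits, missing values as ``NA``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core, growth, screen
from .core import PhenotypeMatrix, RobustnessRecord, robustness_table
from .growth import FitConfig, GrowthCurve, GrowthFitResult, fit_plate, results_to_matrix
from .screen import (
    AnnotationTable,
    ClassificationSets,
    RegionEnrichment,
    VennSummary,
    VENN_CATEGORIES,
    attach_regions,
    classify_percentiles,
    region_deviation_test,
    venn_overlaps,
)

__all__ = [
    "read_phenotype_table",
    "read_growth_csv",
    "read_annotation",
    "read_robustness_table",
    "write_robustness_table",
    "write_fit_results",
    "write_growth_csv",
    "write_phenotype_long",
    "write_classification",
    "write_venn",
    "write_enrichment",
    "RunConfig",
    "load_run_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

NA = "NA"


def _fmt(x: float) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return NA
    return f"{x:.6g}"


def _parse_value(raw: str, row_no: int) -> float:
    raw = raw.strip()
    if raw == "" or raw.upper() == NA:
        return math.nan
    try:
        v = float(raw)
    except ValueError as exc:
        raise ValueError(f"row {row_no}: cannot parse value {raw!r}") from exc
    if v < 0:
        raise ValueError(f"row {row_no}: negative phenotype value {v}")
    return v


def read_phenotype_table(
    path: str | Path,
    dialect: str = "long",
    condition_subsets: Mapping[str, Sequence[str]] | None = None,
    replicate_id: str = "rep01",
) -> PhenotypeMatrix:
    """Read a phenotype table into a :class:`PhenotypeMatrix`.

    ``dialect="long"`` expects CSV ``strain,condition,replicate,value``;
    ``dialect="wide"`` expects a strains-by-conditions TSV whose single
    replicate is labelled ``replicate_id``.
    """
    path = Path(path)
    rows: list[tuple[str, str, str, float]] = []
    if dialect == "long":
        with path.open() as fh:
            header = fh.readline().strip().split(",")
            if header[:4] != ["strain", "condition", "replicate", "value"]:
                raise ValueError(f"malformed long header {header!r}")
            for row_no, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split(",")
                if len(parts) != 4:
                    raise ValueError(f"row {row_no}: expected 4 fields, got {len(parts)}")
                rows.append((parts[0], parts[1], parts[2], _parse_value(parts[3], row_no)))
    elif dialect == "wide":
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "strain" or len(header) < 2:
                raise ValueError(f"malformed wide header {header!r}")
            conditions = header[1:]
            for row_no, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != len(header):
                    raise ValueError(
                        f"row {row_no}: expected {len(header)} fields, got {len(parts)}"
                    )
                for cond, raw in zip(conditions, parts[1:]):
                    rows.append((parts[0], cond, replicate_id, _parse_value(raw, row_no)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.DataFrame(rows, columns=["strain", "condition", "replicate", "value"])
    dup = df.duplicated(subset=["strain", "condition", "replicate"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        r = df.iloc[i]
        raise ValueError(
            f"duplicate observation ({r['strain']}, {r['condition']}, {r['replicate']})"
        )
    if condition_subsets is None:
        conds = sorted(df["condition"].unique())
        condition_subsets = {"ALL": conds} if len(conds) >= 2 else {}
    return PhenotypeMatrix(df, condition_subsets)


def write_phenotype_long(matrix: PhenotypeMatrix, path: str | Path) -> None:
    df = matrix.observations.sort_values(["strain", "condition", "replicate"])
    with Path(path).open("w") as fh:
        fh.write("strain,condition,replicate,value\n")
        for _, r in df.iterrows():
            fh.write(f"{r['strain']},{r['condition']},{r['replicate']},{_fmt(r['value'])}\n")


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    """Read long-format plate-reader series, one curve per well."""
    df = pd.read_csv(path, dtype={"well": str, "strain": str, "condition": str, "replicate": str})
    expected = ["well", "strain", "condition", "replicate", "time_h", "signal"]
    if list(df.columns[:6]) != expected:
        raise ValueError(f"malformed time-series header {list(df.columns)!r}")
    curves = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                well_id=str(well),
                strain_id=str(grp["strain"].iloc[0]),
                condition_id=str(grp["condition"].iloc[0]),
                replicate_id=str(grp["replicate"].iloc[0]),
                times=grp["time_h"].to_numpy(dtype=float),
                signals=grp["signal"].to_numpy(dtype=float),
            )
        )
    return curves


def write_growth_csv(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("well,strain,condition,replicate,time_h,signal\n")
        for c in sorted(curves, key=lambda c: c.well_id):
            for t, y in zip(c.times, c.signals):
                fh.write(
                    f"{c.well_id},{c.strain_id},{c.condition_id},{c.replicate_id},"
                    f"{_fmt(t)},{_fmt(y)}\n"
                )


def write_fit_results(results: Sequence[GrowthFitResult], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("well\tstrain\tcondition\treplicate\tmu_max\tr_squared\tt_mu_max\tstatus\n")
        for r in sorted(results, key=lambda r: r.well_id):
            fh.write(
                f"{r.well_id}\t{r.strain_id}\t{r.condition_id}\t{r.replicate_id}\t"
                f"{_fmt(r.mu_max)}\t{_fmt(r.r_squared)}\t{_fmt(r.t_mu_max)}\t{r.status}\n"
            )


def write_robustness_table(records: Sequence[RobustnessRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("strain\tn_obs\tfitness\tvariance\tgrand_mean\trobustness\tstatus\n")
        for r in sorted(records, key=lambda r: r.strain_id):
            fh.write(
                f"{r.strain_id}\t{r.n_obs}\t{_fmt(r.fitness)}\t{_fmt(r.strain_variance)}\t"
                f"{_fmt(r.grand_mean)}\t{_fmt(r.robustness)}\t{r.status}\n"
            )


def read_robustness_table(path: str | Path) -> list[RobustnessRecord]:
    df = pd.read_csv(path, sep="\t", na_values=[NA], dtype={"strain": str})
    records = []
    for _, r in df.iterrows():
        records.append(
            RobustnessRecord(
                strain_id=str(r["strain"]),
                n_obs=int(r["n_obs"]),
                strain_mean=float(r["fitness"]) if pd.notna(r["fitness"]) else math.nan,
                strain_variance=float(r["variance"]) if pd.notna(r["variance"]) else math.nan,
                grand_mean=float(r["grand_mean"]),
                robustness=float(r["robustness"]) if pd.notna(r["robustness"]) else math.nan,
                status=str(r["status"]),
            )
        )
    return records


def read_annotation(path: str | Path) -> AnnotationTable:
    """Two-column TSV ``strain<TAB>region`` with a header line."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"malformed annotation header {header!r}")
        for row_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"row {row_no}: expected 2 fields")
            if parts[0] in mapping:
                raise ValueError(f"row {row_no}: duplicate strain {parts[0]!r}")
            mapping[parts[0]] = parts[1]
    return AnnotationTable(mapping)


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("strain\tregion\n")
        for s in sorted(table.mapping):
            fh.write(f"{s}\t{table.mapping[s]}\n")


def write_classification(
    sets: ClassificationSets, records: Sequence[RobustnessRecord], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("strain\tfitness\trobustness\tin_HF\tin_LF\tin_HR\tin_LR\n")
        for r in sorted(records, key=lambda r: r.strain_id):
            s = r.strain_id
            fh.write(
                f"{s}\t{_fmt(r.fitness)}\t{_fmt(r.robustness)}\t"
                f"{int(s in sets.HF)}\t{int(s in sets.LF)}\t"
                f"{int(s in sets.HR)}\t{int(s in sets.LR)}\n"
            )


def write_venn(summary: VennSummary, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("category\tcount\tpercent\n")
        for cat in VENN_CATEGORIES:
            fh.write(f"{cat}\t{summary.counts[cat]}\t{_fmt(summary.percentages[cat])}\n")


def write_enrichment(enrichments: Sequence[RegionEnrichment], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("region\tmetric\tn\tregion_median\tbackground_median\tp\tp_adj\n")
        for e in sorted(enrichments, key=lambda e: (e.metric, e.region)):
            fh.write(
                f"{e.region}\t{e.metric}\t{e.n_region}\t{_fmt(e.region_median)}\t"
                f"{_fmt(e.background_median)}\t{_fmt(e.p_value)}\t{_fmt(e.p_adjusted)}\n"
            )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration of the four-stage pipeline.

    Exactly one of ``phenotype_table`` (pre-computed phenotype values) or
    ``timeseries`` (plate-reader curves, fitted first) must be given.
    ``condition_subsets`` names the perturbation spaces; when more than
    one is declared, their union is analysed as the additional combined
    space ``COMBINED``.
    """

    outdir: str
    phenotype_table: str | None = None
    dialect: str = "long"
    timeseries: str | None = None
    annotation: str | None = None
    condition_subsets: dict[str, list[str]] | None = None
    fit: FitConfig = field(default_factory=FitConfig)
    low_pct: float = 10.0
    high_pct: float = 90.0
    min_obs: int = 2
    ddof: int = 1
    enrich_metrics: tuple[str, ...] = ("fitness", "robustness")
    min_region_size: int = 3
    seed: int = 0

    def validate(self) -> None:
        if (self.phenotype_table is None) == (self.timeseries is None):
            raise ValueError("exactly one of phenotype_table or timeseries is required")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration (keys mirror :class:`RunConfig`)."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    fit = FitConfig(**raw.pop("fit", {}))
    subsets = raw.pop("condition_subsets", None)
    if subsets is not None:
        subsets = {str(k): [str(c) for c in v] for k, v in subsets.items()}
    metrics = raw.pop("enrich_metrics", None)
    cfg = RunConfig(fit=fit, condition_subsets=subsets, **raw)
    if metrics is not None:
        cfg.enrich_metrics = tuple(metrics)
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run fit -> robustness -> classification -> enrichment, write all
    stage outputs under ``config.outdir`` and return the JSON summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if config.timeseries is not None:
            stage = "fit-growth"
            curves = read_growth_csv(config.timeseries)
            results = fit_plate(curves, config.fit)
            write_fit_results(results, outdir / "growth_fits.tsv")
            matrix = results_to_matrix(results, config.condition_subsets)
        else:
            stage = "read-phenotypes"
            matrix = read_phenotype_table(
                config.phenotype_table, config.dialect, config.condition_subsets
            )

        subsets = dict(matrix.condition_subsets)
        if len(subsets) > 1:
            union = sorted({c for conds in subsets.values() for c in conds})
            subsets["COMBINED"] = union
            matrix = PhenotypeMatrix(matrix.observations, subsets)

        annotation = read_annotation(config.annotation) if config.annotation else None

        summary: dict = {"subsets": {}, "n_strains": len(matrix.strains)}
        for name in sorted(subsets):
            stage = f"robustness[{name}]"
            records = robustness_table(matrix, name, config.min_obs, config.ddof)
            write_robustness_table(records, outdir / f"robustness_{name}.tsv")

            stage = f"classify[{name}]"
            sets = classify_percentiles(records, config.low_pct, config.high_pct)
            write_classification(sets, records, outdir / f"classification_{name}.tsv")
            venn = venn_overlaps(sets)
            write_venn(venn, outdir / f"venn_{name}.tsv")

            sub_summary = {
                "n_strains": len(records),
                "n_ok": sum(r.status == core.STATUS_OK for r in records),
                "n_max_robustness": sum(
                    r.status == core.STATUS_OK and r.robustness == 0.0 for r in records
                ),
                "grand_mean": records[0].grand_mean if records else math.nan,
                "thresholds": {
                    "q_low_fitness": sets.q_low_fitness,
                    "q_high_fitness": sets.q_high_fitness,
                    "q_low_robustness": sets.q_low_robustness,
                    "q_high_robustness": sets.q_high_robustness,
                },
                "set_sizes": {
                    "HF": len(sets.HF), "LF": len(sets.LF),
                    "HR": len(sets.HR), "LR": len(sets.LR),
                },
                "venn_universe": venn.universe_size,
                "HR_strains": sorted(sets.HR),
            }

            if annotation is not None:
                stage = f"enrich[{name}]"
                annotated = attach_regions(records, annotation)
                for metric in config.enrich_metrics:
                    enr = region_deviation_test(
                        annotated, metric, config.min_region_size
                    )
                    write_enrichment(enr, outdir / f"enrichment_{name}_{metric}.tsv")
                sub_summary["n_annotated"] = len(annotated)

            summary["subsets"][name] = sub_summary

        stage = "summary"
        with (outdir / "summary.json").open("w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception:
        logger.error("pipeline failed at stage %s", stage)
        raise
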