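"""Percentile classification, Venn overlaps, and functional-region tests.

Strains are split into the tails of the fitness and robustness
distributions (high fitness HF, low fitness LF, high robustness HR, low
robustness LR) at configurable percentiles (default 10th/90th).  The
overlap structure of the four sets is summarised as the eight mutually
exclusive Venn categories.  Strains carry functional-region annotations
(e.g. SAFE network regions of the yeast genetic-interaction similarity
network; "unknown" is itself a valid region), and each region is tested
for deviation of its fitness or robustness from the overall distribution
with a two-sided Wilcoxon rank-sum (Mann-Whitney) test, with
Benjamini-Hochberg adjustment reported alongside the raw p-values.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import STATUS_OK, RobustnessRecord

__all__ = [
    "ClassificationSets",
    "VennSummary",
    "AnnotationTable",
    "AnnotatedRecord",
    "RegionEnrichment",
    "classify_percentiles",
    "venn_overlaps",
    "attach_regions",
    "top_regions",
    "region_deviation_test",
    "VENN_CATEGORIES",
]

logger = logging.getLogger(__name__)

#: the eight mutually exclusive Venn categories (HF/LF and HR/LR are
#: disjoint by construction, so membership is one of 3 x 3 - 1 patterns)
VENN_CATEGORIES = (
    "HF_only",
    "LF_only",
    "HR_only",
    "LR_only",
    "HF_HR",
    "HF_LR",
    "LF_HR",
    "LF_LR",
)


@dataclass(frozen=True)
class ClassificationSets:
    """Percentile thresholds and the four tail sets of strain ids."""

    q_low_fitness: float
    q_high_fitness: float
    q_low_robustness: float
    q_high_robustness: float
    HF: frozenset[str]
    LF: frozenset[str]
    HR: frozenset[str]
    LR: frozenset[str]
    low_pct: float
    high_pct: float
    degenerate_fitness: bool = False
    degenerate_robustness: bool = False


@dataclass(frozen=True)
class VennSummary:
    universe_size: int
    counts: Mapping[str, int]
    percentages: Mapping[str, float]
    empty: bool = False


@dataclass(frozen=True)
class AnnotationTable:
    """strain id (or gene name) -> functional-region label."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = [s for s, r in self.mapping.items() if not str(r).strip()]
        if bad:
            raise ValueError(f"empty region label for strains {bad[:5]}")

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, strain_id: str) -> str | None:
        return self.mapping.get(strain_id)


@dataclass(frozen=True)
class AnnotatedRecord:
    record: RobustnessRecord
    region: str

    @property
    def strain_id(self) -> str:
        return self.record.strain_id


@dataclass(frozen=True)
class RegionEnrichment:
    region: str
    metric: str
    n_region: int
    region_median: float
    background_median: float
    p_value: float
    p_adjusted: float


def _metric_value(record: RobustnessRecord, metric: str) -> float:
    if metric == "fitness":
        return record.fitness
    if metric == "robustness":
        return record.robustness if record.status == STATUS_OK else math.nan
    raise ValueError(f"unknown metric {metric!r}")


def classify_percentiles(
    records: Sequence[RobustnessRecord],
    low_pct: float = 10.0,
    high_pct: float = 90.0,
) -> ClassificationSets:
    """Extract the strains at or beyond the low/high percentiles.

    Thresholds are linear-interpolation (type-7) quantiles over the
    non-missing values of each metric; membership is inclusive
    (``<= q_low`` / ``>= q_high``) so that ties at the threshold -- e.g.
    a block of strains at the maximal robustness R = 0 -- are all kept.
    Strains with a missing metric are excluded from that metric's sets.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")

    out: dict[str, object] = {"low_pct": low_pct, "high_pct": high_pct}
    for metric, lo_name, hi_name, lo_set, hi_set, flag in (
        ("fitness", "q_low_fitness", "q_high_fitness", "LF", "HF", "degenerate_fitness"),
        ("robustness", "q_low_robustness", "q_high_robustness", "LR", "HR", "degenerate_robustness"),
    ):
        pairs = [
            (r.strain_id, _metric_value(r, metric))
            for r in records
            if not math.isnan(_metric_value(r, metric))
        ]
        if len(pairs) < 10:
            raise ValueError(f"need >= 10 records with non-missing {metric}")
        values = np.array([v for _, v in pairs])
        q_lo = float(np.quantile(values, low_pct / 100.0, method="linear"))
        q_hi = float(np.quantile(values, high_pct / 100.0, method="linear"))
        degenerate = q_lo == q_hi
        if degenerate:
            warnings.warn(
                f"degenerate {metric} distribution: low and high thresholds "
                f"coincide at {q_lo:g}; tail sets overlap",
                stacklevel=2,
            )
        out[lo_name] = q_lo
        out[hi_name] = q_hi
        out[lo_set] = frozenset(s for s, v in pairs if v <= q_lo)
        out[hi_set] = frozenset(s for s, v in pairs if v >= q_hi)
        out[flag] = degenerate
    return ClassificationSets(**out)  # type: ignore[arg-type]


def venn_overlaps(sets: ClassificationSets) -> VennSummary:
    """Mutually exclusive category counts over the union of the four sets.

    Percentages use the union as denominator and sum to 100 up to
    rounding.  An empty universe yields all-zero counts with a flag.
    """
    if sets.HF & sets.LF:
        raise ValueError("HF and LF overlap; cannot form Venn categories")
    if sets.HR & sets.LR:
        raise ValueError("HR and LR overlap; cannot form Venn categories")

    universe = sets.HF | sets.LF | sets.HR | sets.LR
    n = len(universe)
    counts = dict.fromkeys(VENN_CATEGORIES, 0)
    for s in universe:
        f = "HF" if s in sets.HF else ("LF" if s in sets.LF else "")
        r = "HR" if s in sets.HR else ("LR" if s in sets.LR else "")
        key = f"{f}_{r}" if f and r else f"{f or r}_only"
        counts[key] += 1
    if n == 0:
        return VennSummary(0, counts, dict.fromkeys(VENN_CATEGORIES, 0.0), empty=True)
    pct = {k: 100.0 * v / n for k, v in counts.items()}
    return VennSummary(n, counts, pct)


def attach_regions(
    records: Sequence[RobustnessRecord], annotation: AnnotationTable
) -> list[AnnotatedRecord]:
    """Merge region labels onto robustness records.

    Strains absent from the annotation are dropped (with a logged count);
    the label ``"unknown"`` is ordinary data, not a missing marker.
    """
    if len(annotation) == 0:
        warnings.warn("empty annotation table: no records annotated", stacklevel=2)
        return []
    annotated = []
    dropped = 0
    for rec in records:
        region = annotation.get(rec.strain_id)
        if region is None:
            dropped += 1
        else:
            annotated.append(AnnotatedRecord(rec, region))
    if dropped:
        logger.info("attach_regions: dropped %d strains without annotation", dropped)
    return annotated


def top_regions(
    annotated: Sequence[AnnotatedRecord],
    members: set[str] | frozenset[str],
    k: int = 5,
) -> list[tuple[str, int]]:
    """The k regions most prevalent within a strain set.

    Ranked by member count, descending; ties broken alphabetically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = Counter(a.region for a in annotated if a.strain_id in members)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


def region_deviation_test(
    annotated: Sequence[AnnotatedRecord],
    metric: str,
    min_region_size: int = 3,
    include_region: bool = True,
    method: str = "auto",
) -> list[RegionEnrichment]:
    """Test each region's metric values against the overall distribution.

    Each region is compared by a two-sided Wilcoxon rank-sum
    (Mann-Whitney) test against the distribution of *all* annotated
    strains -- including the region itself, which is how the deviation is
    framed in screen practice; ``include_region=False`` switches to the
    more conventional region-vs-complement comparison.

    ``method="auto"`` uses the exact null distribution when both samples
    have n < 25 and there are no ties, and the tie-corrected normal
    approximation otherwise; ``"exact"``/``"asymptotic"`` force a choice.
    Benjamini-Hochberg-adjusted p-values are reported alongside the raw
    ones across the regions of one call.
    """
    if metric not in ("fitness", "robustness"):
        raise ValueError(f"unknown metric {metric!r}")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")

    by_region: dict[str, list[float]] = {}
    all_values: list[float] = []
    for a in annotated:
        v = _metric_value(a.record, metric)
        if math.isnan(v):
            continue
        by_region.setdefault(a.region, []).append(v)
        all_values.append(v)
    if len(by_region) < 2:
        raise ValueError("need >= 2 regions with data")
    background = np.asarray(all_values)

    tested: list[tuple[str, int, float, float, float]] = []
    for region in sorted(by_region):
        x = np.asarray(by_region[region])
        if x.size < min_region_size:
            logger.info(
                "region_deviation_test: skipping %r (n=%d < %d)",
                region, x.size, min_region_size,
            )
            continue
        if include_region:
            y = background
        else:
            y = np.asarray(
                [v for r, vals in by_region.items() if r != region for v in vals]
            )
        if method == "auto":
            pooled = np.concatenate([x, y])
            no_ties = np.unique(pooled).size == pooled.size
            mw_method = "exact" if (x.size < 25 and y.size < 25 and no_ties) else "asymptotic"
        else:
            mw_method = method
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=mw_method)
        tested.append(
            (region, x.size, float(np.median(x)), float(np.median(y)), min(float(p), 1.0))
        )

    pvals = np.array([t[4] for t in tested])
    p_adj = stats.false_discovery_control(pvals, method="bh") if len(pvals) else pvals
    return [
        RegionEnrichment(region, metric, n, med, bg_med, p, min(float(pa), 1.0))
        for (region, n, med, bg_med, p), pa in zip(tested, p_adj)
    ]
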