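"""Temperature-series assembly and per-temperature genotype comparisons.

Replicate structure follows the acquisition design: technical replicates
nested inside biological replicates.  Aggregation averages technical
values within each biological replicate first, then reports mean ± SE
(sample SD/√n) across biological means.

Comparisons are classical pooled-variance two-sample Student t-tests,
two-sided, run separately for each measurement temperature, with
significance declared at p ≤ α (default α = 0.05).  No multiple-testing
correction is applied across measurement temperatures — each temperature
is reported as its own contrast, so interpret the per-temperature
asterisks accordingly.  Letter-group labels follow the convention that
two groups share a letter iff they do not differ significantly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeriesPoint",
    "TemperatureSeries",
    "ComparisonResult",
    "aggregate_replicates",
    "compare_genotypes",
    "paired_condition_compare",
    "pooled_t_test",
]


@dataclass
class SeriesPoint:
    """Replicate values of one metric at one measurement temperature."""

    temperature_C: float
    values: list[float]
    bio_ids: Optional[list] = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"empty point at {self.temperature_C} °C")
        if self.bio_ids is not None and len(self.bio_ids) != len(self.values):
            raise ValueError("bio_ids must align with values")

    def biological_means(self) -> list[float]:
        if self.bio_ids is None:
            return list(self.values)
        means: dict = {}
        for bid, v in zip(self.bio_ids, self.values):
            means.setdefault(bid, []).append(v)
        return [float(np.mean(vs)) for _, vs in sorted(means.items(), key=lambda kv: str(kv[0]))]


@dataclass
class TemperatureSeries:
    """One genotype × growth temperature series of a chosen metric."""

    genotype: str
    growth_temperature_C: float
    metric: str
    points: list[SeriesPoint] = field(default_factory=list)

    def temperatures(self) -> list[float]:
        return [p.temperature_C for p in self.points]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, genotype: str, growth_temperature_C: float, metric: str
    ) -> "TemperatureSeries":
        """Build from a long table (genotype, growth_T, measure_T, bio_rep, value, metric)."""
        sel = df[
            (df["genotype"] == genotype)
            & (df["growth_T"] == growth_temperature_C)
            & (df["metric"] == metric)
        ]
        points = []
        for temp, group in sel.groupby("measure_T", sort=True):
            values = group["value"].astype(float).tolist()
            bio = group["bio_rep"].tolist() if "bio_rep" in group else None
            points.append(SeriesPoint(float(temp), values, bio))
        return cls(genotype, growth_temperature_C, metric, points)


@dataclass
class ComparisonResult:
    """Pooled-t contrast of two groups at one measurement temperature."""

    measurement_temperature_C: Optional[float]
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    degenerate: bool = False
    letters: tuple[str, str] = ("a", "a")


def _mean_se(values: Sequence[float]) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean, se, n


def aggregate_replicates(series: TemperatureSeries) -> pd.DataFrame:
    """Per-temperature mean ± SE over biological replicates.

    Technical replicates are averaged within their biological replicate
    first; SE is the sample SD of the biological means over √n (0 when a
    single biological replicate is available).
    """
    rows = []
    for point in series.points:
        mean, se, n = _mean_se(point.biological_means())
        rows.append(
            {"measurement_temperature_C": point.temperature_C, "mean": mean, "se": se, "n": n}
        )
    return pd.DataFrame(rows)


def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, bool]:
    """Classical (pooled-variance, two-sided) Student t-test.

    Returns (t, p, degenerate).  With zero pooled variance the test is
    degenerate: equal means give (0, 1), unequal means (±inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("pooled t-test requires at least 2 values per group")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, True
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), False


def _compare(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float,
    temperature: Optional[float],
) -> ComparisonResult:
    mean_a, se_a, _ = _mean_se(a)
    mean_b, se_b, _ = _mean_se(b)
    t, p, degenerate = pooled_t_test(a, b)
    significant = bool(p <= alpha)
    letters = ("a", "b") if significant else ("a", "a")
    return ComparisonResult(
        measurement_temperature_C=temperature,
        mean_a=mean_a,
        mean_b=mean_b,
        se_a=se_a,
        se_b=se_b,
        t_statistic=t,
        p_value=p,
        significant=significant,
        alpha=alpha,
        degenerate=degenerate,
        letters=letters,
    )


def compare_genotypes(
    series_a: TemperatureSeries,
    series_b: TemperatureSeries,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Pooled-t contrast of two series at every shared measurement temperature.

    The two series must cover identical temperature grids; comparisons
    use the biological means, require ≥ 2 per side, and are returned
    ordered by temperature.  Excluding flagged values (e.g. out-of-range
    S) is the caller's responsibility when assembling the series.
    """
    grid_a, grid_b = series_a.temperatures(), series_b.temperatures()
    if sorted(grid_a) != sorted(grid_b):
        raise ValueError(
            f"temperature grid mismatch: {sorted(grid_a)} vs {sorted(grid_b)}"
        )
    by_temp_b = {p.temperature_C: p for p in series_b.points}
    results = []
    for point_a in sorted(series_a.points, key=lambda p: p.temperature_C):
        point_b = by_temp_b[point_a.temperature_C]
        results.append(
            _compare(
                point_a.biological_means(),
                point_b.biological_means(),
                alpha,
                point_a.temperature_C,
            )
        )
    return results


def paired_condition_compare(
    values_t1: Sequence[float], values_t2: Sequence[float], alpha: float = 0.05
) -> ComparisonResult:
    """Contrast one genotype across two growth conditions (same t machinery)."""
    return _compare(values_t1, values_t2, alpha, temperature=None)


def comparisons_to_dataframe(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measurement_temperature_C": r.measurement_temperature_C,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "se_a": r.se_a,
                "se_b": r.se_b,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "degenerate": r.degenerate,
                "letter_a": r.letters[0],
                "letter_b": r.letters[1],
            }
            for r in results
        ]
    )
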