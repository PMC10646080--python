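"""Culture-condition analytics: growth curves, viability correlation, subculture timing.

Per-image summaries taken daily become Day-1-relative growth curves
(replicates normalized individually, then mean ± SD across replicates).
Image-derived parameters are ranked by their Pearson correlation against a
viability readout, and the first day on which relative growth slows below a
threshold is flagged as the time point to subculture.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import AgreementStats, ccc, linregress_r2, pearson

__all__ = [
    "relative_series",
    "relative_growth_table",
    "correlate_parameters",
    "subculture_timepoint",
]

#: Per-image parameters used as growth read-outs.
GROWTH_PARAMETERS = ["total_area", "total_perimeter", "count", "mean_eccentricity"]


def relative_series(values_by_day: Mapping[int, float]) -> dict[int, float]:
    """Normalize a per-day series to a relative value of one on Day 1.

    Days are sorted before normalizing; the earliest day acts as Day 1 and
    must be positive.
    """
    if not values_by_day:
        raise ValueError("empty series")
    days = sorted(values_by_day)
    if len(days) != len(set(days)):
        raise ValueError("duplicate days")
    base = values_by_day[days[0]]
    if not base > 0:
        raise ValueError(f"Day-1 value must be > 0, got {base}")
    return {d: values_by_day[d] / base for d in days}


def relative_growth_table(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD Day-1-relative curves across replicate wells.

    ``records`` needs columns ``day``, ``well``, ``parameter``, ``value``
    (one row per well/day/parameter).  Each replicate is normalized to its
    own Day-1 value, then mean and SD are taken across replicates.
    """
    required = {"day", "well", "parameter", "value"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    rows = []
    for (param, well), grp in records.groupby(["parameter", "well"]):
        series = dict(zip(grp["day"], grp["value"]))
        for day, rel in relative_series(series).items():
            rows.append({"parameter": param, "well": well, "day": day, "relative": rel})
    rel = pd.DataFrame(rows)
    out = (
        rel.groupby(["parameter", "day"])["relative"]
        .agg(mean_relative="mean", sd_relative="std")
        .reset_index()
    )
    return out


def correlate_parameters(
    summaries: pd.DataFrame, viability: Sequence[float]
) -> dict[str, AgreementStats]:
    """Pearson correlation of each image parameter against viability.

    ``summaries`` has one row per well/image with the parameter columns
    (any of ``total_area``, ``total_perimeter``, ``count``,
    ``mean_eccentricity`` that are present); ``viability`` is the matching
    per-well readout.  Returns per-parameter agreement statistics, ordered
    by descending r, so the best-correlated culture parameter comes first.
    """
    v = np.asarray(viability, dtype=float)
    if len(summaries) != len(v):
        raise ValueError("one viability value per summary row required")
    if len(v) < 3:
        raise ValueError("need at least 3 wells")
    out: dict[str, AgreementStats] = {}
    for param in GROWTH_PARAMETERS:
        if param not in summaries.columns:
            continue
        x = summaries[param].to_numpy(dtype=float)
        r, p = pearson(x, v)
        rho_c, ci = ccc(x, v)
        slope, intercept, r2, _ = linregress_r2(x, v)
        out[param] = AgreementStats(rho_c, ci, r, p, slope, intercept, r2)
    return dict(sorted(out.items(), key=lambda kv: kv[1].pearson_r, reverse=True))


def subculture_timepoint(
    relative: Mapping[int, float] | Sequence[float],
    slowdown_fraction: float = 0.10,
) -> int | None:
    """First day whose relative growth over the previous day falls below
    ``slowdown_fraction`` — the flag that the culture is due for subculture.

    Accepts a day->relative-value mapping or a plain sequence (taken as days
    1..D).  Returns the day number, or ``None`` if growth never slows.
    """
    if isinstance(relative, Mapping):
        days = sorted(relative)
        if len(days) != len(set(days)):
            raise ValueError("duplicate days")
        values = [relative[d] for d in days]
    else:
        values = list(relative)
        days = list(range(1, len(values) + 1))
    if len(values) < 3:
        raise ValueError("need at least 3 days")
    for i in range(1, len(values)):
        prev = values[i - 1]
        if prev <= 0:
            raise ValueError("relative values must be positive")
        if (values[i] - prev) / prev < slowdown_fraction:
            return days[i]
    return None
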