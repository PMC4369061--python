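"""Calibrated green area, NGA and RGR analytics.

The three per-view projected areas are combined as the Euclidean norm
``A = sqrt(Ax^2 + Ay^2 + Az^2)``, a proxy for shoot biomass.  Two growth
statistics are derived from the per-plant area time series:

* **NGA** (normalized green area): each day's area divided by the area on
  the first measuring day, so plants of different initial size compare on
  a common fold-change scale.
* **RGR** (relative growth rate): ``(mean(ln W2) - mean(ln W1)) / (t2 - t1)``,
  the difference of group means of log areas per unit time.  The mean is
  taken over log-areas, not the log of mean areas.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .segmentation import VIEWS

logger = logging.getLogger(__name__)


def calibrate(
    reference_measurements: Iterable[tuple[str, float, float]],
) -> dict[str, float]:
    """Per-view mm²-per-pixel factors from reference objects of known area.

    Each reference is ``(view, px_count, known_mm2)`` — e.g. a bar covered
    by millimeter paper segmented in that view.  The factor for a view is
    the mean of ``known_mm2 / px_count`` over its references.
    """
    ratios: dict[str, list[float]] = {}
    for view, px_count, known_mm2 in reference_measurements:
        if view not in VIEWS:
            raise ValueError(f"unknown view {view!r}")
        if px_count <= 0 or known_mm2 <= 0:
            raise ValueError("px_count and known_mm2 must be positive")
        ratios.setdefault(view, []).append(known_mm2 / px_count)
    if not ratios:
        raise ValueError("no reference measurements given")
    return {view: float(np.mean(r)) for view, r in ratios.items()}


def total_green_area(a_x: float, a_y: float, a_z: float) -> float:
    """Euclidean combination of the three projected areas (same units).

    A missing view may be passed as ``None``; it counts as zero projection
    and is logged, which biases the total low but keeps it defined.
    """
    areas = []
    for name, a in zip("xyz", (a_x, a_y, a_z)):
        if a is None or (isinstance(a, float) and np.isnan(a)):
            logger.warning("missing %s projection treated as 0", name)
            a = 0.0
        if a < 0:
            raise ValueError(f"negative projected area A_{name}={a}")
        areas.append(float(a))
    return float(np.sqrt(sum(a * a for a in areas)))


def normalized_green_area(days: np.ndarray, areas: np.ndarray) -> np.ndarray:
    """NGA: area on each day divided by the first-day area."""
    days = np.asarray(days, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if days.size == 0:
        raise ValueError("empty series")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if areas[0] <= 0:
        raise ValueError("first-day area must be positive to define NGA")
    return areas / areas[0]


def relative_growth_rate(
    areas_t1: np.ndarray, areas_t2: np.ndarray, t1: float, t2: float
) -> float:
    """RGR per day between two group samples of areas."""
    a1 = np.asarray(areas_t1, dtype=float)
    a2 = np.asarray(areas_t2, dtype=float)
    if a1.size == 0 or a2.size == 0:
        raise ValueError("empty area sample")
    if np.any(a1 <= 0) or np.any(a2 <= 0):
        raise ValueError("areas must be positive for log growth rates")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return float((np.mean(np.log(a2)) - np.mean(np.log(a1))) / (t2 - t1))


def areas_to_mm2(
    table: pd.DataFrame, calibration: Mapping[str, float]
) -> pd.DataFrame:
    """Calibrate a long table (plant_id, day, view, area_px) and combine views.

    Returns a tidy per-plant table (plant_id, day, A_total_mm2, NGA).
    Views absent from the calibration raise; views absent from a plant/day
    row count as zero projection (logged by :func:`total_green_area`).
    """
    required = {"plant_id", "day", "view", "area_px"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"area table missing column(s): {sorted(missing)}")
    used_views = sorted(table["view"].unique())
    for view in used_views:
        if view not in calibration:
            raise ValueError(f"no calibration factor for view {view!r}")

    records = []
    for (plant, day), grp in table.groupby(["plant_id", "day"], sort=True):
        per_view = {
            row["view"]: row["area_px"] * calibration[row["view"]]
            for _, row in grp.iterrows()
        }
        total = total_green_area(
            per_view.get("top"), per_view.get("front"), per_view.get("side")
        )
        records.append({"plant_id": plant, "day": day, "A_total_mm2": total})
    tidy = pd.DataFrame.from_records(records).sort_values(["plant_id", "day"])

    ngas = []
    for _, grp in tidy.groupby("plant_id", sort=False):
        ngas.append(
            pd.Series(
                normalized_green_area(
                    grp["day"].to_numpy(), grp["A_total_mm2"].to_numpy()
                ),
                index=grp.index,
            )
        )
    tidy["NGA"] = pd.concat(ngas)
    return tidy.reset_index(drop=True)


def group_rgr_table(
    tidy: pd.DataFrame, anchored: bool = False
) -> pd.DataFrame:
    """Per-interval RGR over a group of plants.

    ``tidy`` is the output of :func:`areas_to_mm2` (columns plant_id, day,
    A_total_mm2).  By default each interval spans consecutive measuring
    days; with ``anchored=True`` every interval starts at the first day.
    Returns columns (day_start, day_end, RGR_per_day, n).
    """
    days = sorted(tidy["day"].unique())
    if len(days) < 2:
        raise ValueError("need at least two measuring days for RGR")
    by_day = {d: tidy.loc[tidy["day"] == d, "A_total_mm2"].to_numpy() for d in days}
    rows = []
    for i in range(1, len(days)):
        d1 = days[0] if anchored else days[i - 1]
        d2 = days[i]
        rows.append(
            {
                "day_start": d1,
                "day_end": d2,
                "RGR_per_day": relative_growth_rate(by_day[d1], by_day[d2], d1, d2),
                "n": min(len(by_day[d1]), len(by_day[d2])),
            }
        )
    return pd.DataFrame(rows)
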