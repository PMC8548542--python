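"""Region-level aggregation of occupation measures.

Regional income security and work-from-home capability are occupation-count
weighted averages of the per-occupation measures, with weights equal to the
fraction of employed residents in each occupation.  Occupations without a
measure trigger weight renormalisation over the covered ones (never zero
imputation, which would bias regions with rare occupations downward); the
covered fraction is reported per region.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd

__all__ = ["regional_weighted_averages", "classify_by_median", "to_geojson"]

logger = logging.getLogger(__name__)


def regional_weighted_averages(occupation_counts: pd.DataFrame,
                               measures: pd.DataFrame,
                               value_cols: tuple[str, ...] = (
                                   "income_security", "wfh_fraction"),
                               ) -> pd.DataFrame:
    """Occupation-distribution weighted regional means.

    Parameters
    ----------
    occupation_counts
        Long table ``region_id, occupation_code, count`` (counts >= 0).
    measures
        Per-occupation table with ``occupation_code`` and the columns named
        in ``value_cols``.
    value_cols
        Measure columns to aggregate (each must exist in ``measures``).

    Returns
    -------
    One row per region: the weighted mean of each measure over covered
    occupations (weights renormalised when some occupations carry no
    measure), ``coverage`` = covered count / total count, and ``covered`` =
    False for regions with zero covered employment (their means are NaN and
    they should be excluded from association analyses).
    """
    if (occupation_counts["count"] < 0).any():
        raise ValueError("occupation counts must be >= 0")
    merged = occupation_counts.merge(
        measures[["occupation_code", *value_cols]],
        on="occupation_code", how="left")

    totals = occupation_counts.groupby("region_id", sort=True)["count"].sum()
    if (totals <= 0).any():
        raise ValueError("every region needs a positive total count")

    covered_mask = merged[list(value_cols)].notna().all(axis=1)
    cov = merged[covered_mask]
    covered_totals = cov.groupby("region_id", sort=True)["count"].sum()

    rows = []
    for region_id, total in totals.items():
        c_total = covered_totals.get(region_id, 0)
        row: dict[str, object] = {
            "region_id": region_id,
            "coverage": c_total / total,
            "covered": c_total > 0,
        }
        if c_total > 0:
            g = cov[cov["region_id"] == region_id]
            w = g["count"].to_numpy() / c_total
            for col in value_cols:
                row[col] = float(w @ g[col].to_numpy())
        else:
            for col in value_cols:
                row[col] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    n_flagged = int((~out["covered"]).sum())
    if n_flagged:
        logger.warning("%d regions have zero covered employment", n_flagged)
    return out[["region_id", *value_cols, "coverage", "covered"]]


def classify_by_median(values: pd.Series) -> tuple[pd.Series, float]:
    """Split regions at the sample median of a measure.

    Returns ``(above, median)`` where ``above`` is a boolean Series (ties at
    the median go to the lower group).  Emits a warning when all values are
    equal, in which case every region lands in the lower group.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("need at least 2 regions to split at the median")
    med = float(values.median())
    if values.nunique() == 1:
        warnings.warn("all values equal; every region is in the lower group",
                      stacklevel=2)
    return values > med, med


def to_geojson(regional: pd.DataFrame, path,
               geometries: dict[str, list] | None = None,
               grid_cols: tuple[str, str] = ("grid_x", "grid_y")) -> None:
    """Write regional measures as a GeoJSON FeatureCollection.

    ``geometries`` maps region_id to polygon coordinate rings; when omitted
    and grid coordinates are present, unit squares at the grid positions are
    used so synthetic scenarios can be mapped directly.
    """
    features = []
    for _, row in regional.iterrows():
        rid = row["region_id"]
        if geometries is not None:
            coords = geometries[rid]
        elif all(c in row for c in grid_cols):
            x, y = float(row[grid_cols[0]]), float(row[grid_cols[1]])
            coords = [[[x, y], [x + 1, y], [x + 1, y + 1], [x, y + 1], [x, y]]]
        else:
            raise ValueError("no geometry available for region "
                             f"{rid!r}: supply `geometries`")
        props = {k: (v.item() if isinstance(v, np.generic) else v)
                 for k, v in row.items() if k != "region_id"}
        features.append({
            "type": "Feature",
            "id": rid,
            "geometry": {"type": "Polygon", "coordinates": coords},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
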