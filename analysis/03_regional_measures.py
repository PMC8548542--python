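"""Aggregate occupation measures to regions and split at the median.

Computes occupation-count weighted regional income security and WFH
fractions, reports the median split used for mapping, and exports a
GeoJSON choropleth layer on the synthetic grid.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _scenario import INPUTS, RESULTS

from homenet.regions import (
    classify_by_median,
    regional_weighted_averages,
    to_geojson,
)


def main() -> None:
    counts = pd.read_csv(INPUTS / "region_occupation_counts.csv",
                         dtype={"region_id": str, "occupation_code": str})
    covariates = pd.read_csv(INPUTS / "region_covariates.csv",
                             dtype={"region_id": str})
    measures = pd.read_csv(RESULTS / "occupation_measures.csv",
                           dtype={"occupation_code": str})

    regional = regional_weighted_averages(counts, measures)
    regional = regional.merge(covariates, on="region_id")
    above, median = classify_by_median(regional["income_security"])
    regional["above_median_security"] = above

    regional.to_csv(RESULTS / "regional_measures.csv", index=False)
    to_geojson(regional, RESULTS / "regional_measures.geojson")

    print(f"{len(regional)} regions; median income security {median:.4f}")
    print(f"coverage: min {regional['coverage'].min():.3f}, "
          f"mean {regional['coverage'].mean():.3f}")
    print(f"above-median regions: {int(above.sum())} / {len(regional)}")


if __name__ == "__main__":
    main()
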