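"""Association battery over the merged regional analysis table.

Censored Pearson correlations between income security, the WFH fraction,
the children covariate and the traffic changes; the between-city t-test;
Moran's I of the spatially varying measures; and the 3-variable PCA.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _scenario import INPUTS, RESULTS, SCENARIO

from homenet.stats import censored_pearson, morans_i, pca_three_vars, two_sample_t


def main() -> None:
    regional = pd.read_csv(RESULTS / "regional_measures.csv",
                           dtype={"region_id": str})
    changes = pd.read_csv(RESULTS / "changes_wave1.csv",
                          dtype={"region_id": str})
    adjacency = pd.read_csv(INPUTS / "adjacency.csv",
                            dtype={"region_id": str, "neighbour_id": str})
    base = pd.read_csv(RESULTS / "period_metrics_baseline.csv",
                       dtype={"region_id": str})

    up = (changes[changes["direction"] == "upload"]
          .set_index("region_id")["daytime_avg_abs_change"]
          .rename("upload_change"))
    down_base = (base[base["direction"] == "download"]
                 .set_index("region_id")["daytime_avg"]
                 .rename("download_baseline"))
    df = regional.set_index("region_id").join([up, down_base])

    pairs = [("income_security", "wfh_fraction"),
             ("income_security", "prop_families_children"),
             ("income_security", "upload_change"),
             ("prop_families_children", "download_baseline")]
    out = {}
    print("censored Pearson correlations (95% CI):")
    for x, y in pairs:
        r = censored_pearson(df[x], df[y])
        out[f"{x}~{y}"] = {"rho": r.rho, "ci": [r.ci_low, r.ci_high],
                           "n": r.n_used, "censored": r.n_censored}
        print(f"  {x} ~ {y}: rho={r.rho:.3f} [{r.ci_low:.3f}, {r.ci_high:.3f}]"
              f" (n={r.n_used}, censored {r.n_censored})")

    groups = [g["income_security"] for _, g in df.groupby("city")]
    tt = two_sample_t(*groups)
    out["city_ttest"] = {"t": tt.statistic, "p": tt.pvalue}
    print(f"between-city t-test: t={tt.statistic:.3f}, p={tt.pvalue:.3f}")

    print("Moran's I (999 permutations):")
    out["morans_i"] = {}
    for var in ("income_security", "upload_change"):
        mi = morans_i(df[var].dropna(), adjacency, 999, seed=SCENARIO.seed)
        out["morans_i"][var] = {"I": mi.I, "p": mi.p_permutation}
        print(f"  {var}: I={mi.I:.3f} (E[I]={mi.expected_I:.4f}), "
              f"p={mi.p_permutation:.3f}")

    pca = pca_three_vars(df[["income_security", "prop_families_children",
                             "upload_change"]])
    out["pca_variance_explained"] = [float(v) for v in pca.variance_explained]
    print("PCA variance explained:",
          [round(float(v), 3) for v in pca.variance_explained])

    with open(RESULTS / "associations.json", "w") as fh:
        json.dump(out, fh, indent=2, default=float)


if __name__ == "__main__":
    main()
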