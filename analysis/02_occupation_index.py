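"""Compute per-occupation income security and work-from-home fractions.

Re-derives the income security index (proportion securely employed x
earnings rescaled to the sample maximum) from the individual employment
records, propagates the binary WFH classification through the taxonomy
crosswalk, and writes the occupation measures table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _scenario import INPUTS, RESULTS

from homenet.occupations import income_security_index, propagate_wfh


def main() -> None:
    records = pd.read_csv(INPUTS / "employment_records.csv",
                          dtype={"occupation_code": str})
    earnings = pd.read_csv(INPUTS / "occupation_earnings.csv",
                           dtype={"occupation_code": str})
    crosswalk = pd.read_csv(INPUTS / "wfh_crosswalk.csv",
                            dtype={"source_code": str, "target_code": str})
    overrides = pd.read_csv(INPUTS / "wfh_overrides.csv",
                            dtype={"occupation_code": str})

    measures = income_security_index(records, earnings)
    wfh, unlinked = propagate_wfh(crosswalk, overrides,
                                  all_codes=measures["occupation_code"])
    measures = measures.merge(wfh, on="occupation_code", how="left")

    RESULTS.mkdir(parents=True, exist_ok=True)
    measures.to_csv(RESULTS / "occupation_measures.csv", index=False)

    lo = measures.loc[measures["income_security"].idxmin()]
    hi = measures.loc[measures["income_security"].idxmax()]
    print(f"{len(measures)} occupations; {len(unlinked)} without WFH linkage")
    print(f"index range: {lo['income_security']:.4f} (code {lo['occupation_code']}) "
          f"to {hi['income_security']:.4f} (code {hi['occupation_code']})")
    print(f"mean WFH fraction: {measures['wfh_fraction'].mean():.3f}")


if __name__ == "__main__":
    main()
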