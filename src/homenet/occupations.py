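"""Per-occupation income security and work-from-home measures.

The income security index of an occupation is the product of the proportion
of its respondents in secure employment (permanent or fixed-term contracts)
and its average weekly earnings rescaled to the sample maximum; it lies in
[0, 1], with 0 for occupations with no securely employed respondents and 1
for a fully secure occupation at the sample-maximum wage.

Note on coding: survey conventions often code the categorical variable as
0 = secure / 1 = insecure; this module returns secure = 1 throughout to keep
the index a product of two "goods".  The inversion is deliberate and local
to the security *status*; the index itself is unaffected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "SECURE_CONTRACTS",
    "CONTRACT_TYPES",
    "classify_secure",
    "income_security_index",
    "propagate_wfh",
]

logger = logging.getLogger(__name__)

SECURE_CONTRACTS = frozenset({"permanent", "fixed_term"})
CONTRACT_TYPES = frozenset({"permanent", "fixed_term", "casual", "other_insecure"})


def classify_secure(contract_type: str) -> int:
    """Return 1 for secure employment (permanent or fixed-term), else 0.

    Fixed-term contracts count as secure: their conditions resemble
    permanent employment far more than casual work.
    """
    if contract_type not in CONTRACT_TYPES:
        raise ValueError(
            f"unknown contract type {contract_type!r}; accepted labels are "
            f"{sorted(CONTRACT_TYPES)}")
    return int(contract_type in SECURE_CONTRACTS)


def income_security_index(records: pd.DataFrame,
                          earnings: pd.DataFrame) -> pd.DataFrame:
    """Compute per-occupation income security from individual records.

    Parameters
    ----------
    records
        Individual employment records with columns ``occupation_code`` and
        ``contract_type`` (one of permanent / fixed_term / casual /
        other_insecure).
    earnings
        Per-occupation table with columns ``occupation_code`` and
        ``avg_weekly_earnings`` (> 0).

    Returns
    -------
    DataFrame with one row per occupation present in ``records``:
    ``occupation_code, n_respondents, prop_secure, avg_weekly_earnings,
    income_security``, where ``income_security = prop_secure x earnings /
    max(earnings over the sample)``.

    Occupations listed in ``earnings`` but with zero respondents are
    excluded with a logged warning; occupations in ``records`` without an
    earnings entry raise, naming the codes.
    """
    bad = set(records["contract_type"]) - CONTRACT_TYPES
    if bad:
        raise ValueError(
            f"unknown contract types {sorted(bad)}; accepted labels are "
            f"{sorted(CONTRACT_TYPES)}")

    secure = records["contract_type"].isin(SECURE_CONTRACTS)
    grouped = (records.assign(secure=secure.astype(int))
               .groupby("occupation_code", sort=True)["secure"]
               .agg(n_respondents="size", n_secure="sum")
               .reset_index())
    grouped["prop_secure"] = grouped["n_secure"] / grouped["n_respondents"]

    earn = earnings[["occupation_code", "avg_weekly_earnings"]].drop_duplicates(
        "occupation_code")
    if (earn["avg_weekly_earnings"] <= 0).any():
        raise ValueError("avg_weekly_earnings must be > 0")
    missing = set(grouped["occupation_code"]) - set(earn["occupation_code"])
    if missing:
        raise KeyError(
            f"no earnings entry for occupation codes {sorted(missing)}")
    zero_resp = set(earn["occupation_code"]) - set(grouped["occupation_code"])
    if zero_resp:
        logger.warning("excluding %d occupations with zero respondents",
                       len(zero_resp))

    out = grouped.merge(earn, on="occupation_code", how="left")
    out["income_security"] = (out["prop_secure"] * out["avg_weekly_earnings"]
                              / out["avg_weekly_earnings"].max())
    return out.drop(columns=["n_secure"])


def propagate_wfh(crosswalk: pd.DataFrame,
                  unlinked_overrides: pd.DataFrame | None = None,
                  all_codes=None,
                  weights: str | None = None
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Aggregate 6-digit binary WFH flags to 4-digit fractions.

    Parameters
    ----------
    crosswalk
        Rows linking a foreign-taxonomy ``source_code`` to a 6-digit
        ``target_code`` with a binary ``wfh_flag``.  4-digit codes are the
        first four characters of the target code.
    unlinked_overrides
        Manually determined flags (``occupation_code``, ``wfh_flag``) for
        4-digit codes with no linked entries.
    all_codes
        Optional iterable of 4-digit codes expected to be covered; codes
        with neither linked entries nor an override are returned in the
        unlinked listing rather than silently dropped.
    weights
        Optional crosswalk column for employment-weighted aggregation;
        the default is the unweighted mean of the linked binary flags.

    Returns
    -------
    ``(table, unlinked)`` where ``table`` has ``occupation_code`` (4-digit)
    and ``wfh_fraction`` in [0, 1], and ``unlinked`` lists uncovered codes.
    """
    if not crosswalk["wfh_flag"].isin((0, 1)).all():
        raise ValueError("wfh_flag must be binary")
    xw = crosswalk.assign(
        occupation_code=crosswalk["target_code"].astype(str).str[:4])
    if weights is None:
        frac = xw.groupby("occupation_code", sort=True)["wfh_flag"].mean()
    else:
        num = (xw[weights] * xw["wfh_flag"]).groupby(xw["occupation_code"]).sum()
        den = xw.groupby("occupation_code", sort=True)[weights].sum()
        frac = num / den
    table = frac.rename("wfh_fraction").reset_index()
    table = table.rename(columns={table.columns[0]: "occupation_code"})

    if unlinked_overrides is not None and len(unlinked_overrides):
        extra = unlinked_overrides.rename(columns={"wfh_flag": "wfh_fraction"})
        extra = extra[~extra["occupation_code"].isin(table["occupation_code"])]
        table = pd.concat([table, extra[["occupation_code", "wfh_fraction"]]],
                          ignore_index=True)
        table = table.sort_values("occupation_code").reset_index(drop=True)

    unlinked: list[str] = []
    if all_codes is not None:
        unlinked = sorted(set(map(str, all_codes)) - set(table["occupation_code"]))
        if unlinked:
            logger.warning("%d occupation codes have no WFH linkage: %s",
                           len(unlinked), unlinked[:10])
    table["wfh_fraction"] = table["wfh_fraction"].astype(float)
    return table, unlinked
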