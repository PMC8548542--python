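"""Small published reference tables used as analysis inputs."""

from __future__ import annotations

from .stats import ContingencyTable

__all__ = ["victorian_wfh_survey"]


def victorian_wfh_survey() -> ContingencyTable:
    """Published 2x2 counts from a September 2020 survey of 875 Victorian
    adults: responses to "Have you personally experienced a change in work
    environment (working from home) because of COVID-19?", split by annual
    household income above vs at-or-below the sample median bracket
    (AUD 60,000-69,999).

    Rows: above-median income (144 yes / 267 no), at-or-below median
    (93 yes / 371 no).
    """
    return ContingencyTable(a=144, b=267, c=93, d=371)
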