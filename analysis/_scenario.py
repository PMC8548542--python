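"""Shared study scenario and paths for the numbered analysis drivers.

The drivers run the analysis at a desk-scale synthetic study: 100
SA2-style regions, 150 occupation groups, a 14-day baseline window and a
7-day lockdown window.  Large intermediates (telemetry) live under
``scratch/``; small result tables go to ``results/analysis/``.
"""

from pathlib import Path

from homenet.config import ScenarioConfig

SCENARIO = ScenarioConfig(seed=2026, n_regions=100, n_occupations=150,
                          baseline_days=14, wave_days=7)

ROOT = Path(__file__).resolve().parent.parent
INPUTS = ROOT / "scratch" / "analysis" / "inputs"
RESULTS = ROOT / "results" / "analysis"
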