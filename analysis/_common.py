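"""Shared paths and run conditions for the numbered analysis drivers."""

from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
SCRATCH = REPO / "scratch" / "analysis"     # large intermediates (not tracked)
RESULTS = REPO / "results"                  # small summary tables
DEFAULT_SEED = 1

COHORT_IDS = ["c1", "c2", "c3", "c4", "c5"]


def outdirs():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    return SCRATCH, RESULTS
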