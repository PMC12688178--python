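"""Shared fixtures: scaled-down study configs and one cached full run."""

from __future__ import annotations

from dataclasses import replace

import pytest

import metscreen as ms


@pytest.fixture(scope="session")
def default_run():
    """One full default-condition screen run (seed 1), shared read-only."""
    return ms.run_screen(ms.PipelineConfig(), seed=1, with_enrichment=True)


@pytest.fixture()
def small_sim() -> ms.SimConfig:
    """Reduced cohort sizes / gene count for fast structural tests."""
    return replace(
        ms.SimConfig(),
        n_genes=200,
        samples_per_group=((10, 40, 10), (12, 50, 12), (8, 36, 10), (10, 44, 10), (8, 30, 12)),
    )


@pytest.fixture()
def null_sim() -> ms.SimConfig:
    """No planted structure at all: every gene is a null gene."""
    return replace(
        ms.SimConfig(),
        frac_prognostic_up=0.0, frac_prognostic_down=0.0,
        frac_met_up=0.0, frac_met_down=0.0, frac_initiation=0.0,
        n_ar_genes=0,
    )
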