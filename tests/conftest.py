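"""Shared fixtures: session-scoped simulations reused across test modules."""

import numpy as np
import pytest

import mmphys as m


@pytest.fixture(scope="session")
def steady_run():
    """Default-condition mother-machine ensemble with frame sampling.

    20 lineages x 60 generations (~1,100 analyzable generations after the
    3-h equilibration cut) — large enough for the statistical recovery and
    CV-hierarchy checks, small enough to simulate in a few seconds.
    """
    return m.simulate_steady_state(m.DEFAULT_CONDITION, m.SamplingConfig(),
                                   n_generations=60, n_lineages=20, seed=11)


@pytest.fixture(scope="session")
def steady_analysis(steady_run):
    """Filtered per-generation records with cell-cycle assignments."""
    records = m.build_generations(steady_run.frames)
    records, events, _ = m.assign_cell_cycles(records, steady_run.initiations)
    kept, report = m.filter_outliers(records)
    return {"records": records, "events": events, "kept": kept,
            "report": report}


@pytest.fixture(scope="session")
def shift_run():
    """Up-then-down nutrient shift (doubling time 65 -> 30 -> 65 min).

    Upshift at t = 360 min (after a 4-h minimal-medium baseline) and
    downshift 12 h later, with a 60-120 min growth/fork pause at the
    downshift; 64 lineages yield > 1,500 initiation events.
    """
    minimal = m.CONDITIONS["succinate_minimal"]
    rich = m.CONDITIONS["succinate_rich"]
    schedule = m.ShiftSchedule(
        segments=((0.0, minimal), (360.0, rich), (1080.0, minimal)),
        pause_after_downshift=(60.0, 120.0),
    )
    res = m.simulate_shift(schedule, sampling=None, total_duration=1560.0,
                           n_lineages=64, seed=5)
    return {"result": res, "t_up": 360.0, "t_down": 1080.0}


@pytest.fixture(scope="session")
def noiseless_slow():
    """Noiseless slow-growth condition with C + D < tau (no overlap)."""
    cond = m.GrowthCondition(name="slow", tau_mean=60.0, C_mean=35.0,
                             D_mean=15.0, width_mean=0.9,
                             si_mean=1.2).noiseless()
    return m.simulate_steady_state(cond, None, n_generations=30, seed=2)
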