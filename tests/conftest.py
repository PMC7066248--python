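"""Shared fixtures: baseline parameters and the frequently used trajectories.

Trajectories are session-scoped because several test modules interrogate the
same runs (the toxin-free cycle, the asymmetric r11=1/r21=10 run, and the
severe equal-intensity run).
"""

import pytest

from mplv import (
    SolverSettings,
    baseline_parameters,
    make_condition,
    paper_campaign,
    run_campaign,
    run_scenario,
)


@pytest.fixture(scope="session")
def baseline():
    """The study's printed parameter table and initial state."""
    return baseline_parameters()


@pytest.fixture(scope="session")
def condition_a_run():
    """Toxin-free reference run: (trajectory, stats) over 10 months."""
    return run_scenario(make_condition("a"))


@pytest.fixture(scope="session")
def asymmetric_run():
    """r11=1, r21=10 run (prey weakly, predator strongly responsive)."""
    return run_scenario(make_condition("c", (1.0, 10.0)))


@pytest.fixture(scope="session")
def severe_run():
    """r11=r21=10 run (severe equal response intensities)."""
    return run_scenario(make_condition("b", (10.0, 10.0)))


@pytest.fixture(scope="session")
def campaign_result():
    """Summaries for the full named-condition registry at default settings."""
    return run_campaign(paper_campaign())
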