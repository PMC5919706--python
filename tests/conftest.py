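"""Shared fixtures: toy geography and seeded synthetic study scenarios.

Scenario fixtures are session-scoped: generating events and building the
IT-Matrices is the expensive part of the suite, and every consumer only
reads from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import cdrmobility as cm


@dataclass
class PipelineRun:
    """A generated scenario with its regularized matrices."""

    scenario: cm.SyntheticScenario
    daily_raw: cm.ITMatrix
    daily: cm.ITMatrix              # interpolated, region level
    mpl: cm.ITMatrix                # monthly, zone level


def _run(spec: cm.ScenarioSpec) -> PipelineRun:
    sc = cm.generate(spec)
    daily_raw = cm.daily_preferential(sc.events, sc.calendar, sc.partition)
    daily = cm.interpolate_missing(daily_raw)
    mpl = cm.aggregate_space(cm.aggregate_time(daily, "monthly"),
                             sc.partition)
    return PipelineRun(sc, daily_raw, daily, mpl)


@pytest.fixture(scope="session")
def calendar() -> cm.StudyCalendar:
    return cm.StudyCalendar(2013)


@pytest.fixture(scope="session")
def toy_partition() -> cm.RegionPartition:
    """Four regions in two zones, centroids a few km apart."""
    return cm.RegionPartition(
        region_ids=["A", "B", "C", "D"],
        lat=[14.00, 14.05, 14.50, 14.55],
        lon=[-16.00, -16.05, -16.50, -16.55],
        zone_ids=[1, 1, 2, 2],
        urban=np.array([True, False, False, False]),
    )


@pytest.fixture(scope="session")
def clustering_run() -> PipelineRun:
    """Three planted profile groups (100 users each, flip noise 0.05)."""
    return _run(cm.clustering_scenario(seed=7))


@pytest.fixture(scope="session")
def occupancy_run() -> PipelineRun:
    """2,000 visitors of one zone: 10% occasional, 40% moving, 50% permanent."""
    return _run(cm.occupancy_scenario(seed=11, n_users=2000))


@pytest.fixture(scope="session")
def alignment_run() -> PipelineRun:
    """Rural out-migration departing at the rainfall onset month."""
    return _run(cm.alignment_scenario(seed=5))


@pytest.fixture(scope="session")
def conservation_run() -> PipelineRun:
    """1,000 users mixing permanent, seasonal and occasional behaviors."""
    groups = (
        cm.permanent_group("perm_z4", 400, 4),
        cm.seasonal_group("seasonal", 400, home=10, dest=1, depart_month=6,
                          return_month=10),
        cm.occasional_group("occasional", 200, home=3, visit_zone=10,
                            visit_month=2),
    )
    return _run(cm.ScenarioSpec(groups=groups, seed=3))


@pytest.fixture(scope="session")
def clustering_selection(clustering_run):
    """Selection + binarization of the planted clustering scenario.

    The planted migrants each make one long home↔destination displacement,
    so the regular-traveler ratio threshold is set to 1 for this scenario
    (a two-location trajectory always has a move at least twice its radius
    of gyration, so the filter keeps all planted movers).
    """
    run = clustering_run
    cfg = cm.SelectionConfig(target_zone=11, rog_ratio_threshold=1.0)
    sel = cm.select_users(run.mpl, run.daily, run.scenario.partition, cfg)
    B = cm.binarize(run.mpl, sel, run.scenario.partition)
    return sel, B
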