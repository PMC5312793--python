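"""Shared fixtures: reduced-scale simulated worlds for pipeline testing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dynconn as dc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def clique(regions: list[int]) -> list[tuple[int, int]]:
    """All pairs among a region set (shared-modulator coupling is clique-wide)."""
    return [(a, b) for i, a in enumerate(regions) for b in regions[i + 1 :]]


def acceptance_networks() -> list[dc.NetworkDefinition]:
    """Two task-locked planted networks and one tonic (non-task) control.

    Coupling amplitude 0.4 puts envelope-correlation modulations on the
    order of the window noise sigma(r) ~ 0.1 — the realistic regime.
    """
    return [
        dc.NetworkDefinition(
            edges=clique([0, 1, 2]),
            modulation=dc.boxcar_modulation(-1.0, 3.0, amplitude=0.4),
            label="taskA",
        ),
        dc.NetworkDefinition(
            edges=clique([4, 5, 6]),
            modulation=dc.boxcar_modulation(3.0, 7.0, amplitude=0.4),
            label="taskB",
        ),
        dc.NetworkDefinition(
            edges=clique([7, 8, 9]), tonic_level=0.4, label="control"
        ),
    ]


def acceptance_params(seed: int, with_networks: bool = True) -> dc.SimulationParams:
    """Reduced-scale stated world: 10 regions, 14 subjects, 10 trials.

    Band 8-25 Hz keeps the paper's beta bandwidth Bw = 17 Hz at a sampling
    rate (100 Hz) that makes repeated end-to-end runs affordable.
    """
    return dc.SimulationParams(
        n_regions=10,
        sampling_rate=100.0,
        band=(8.0, 25.0),
        n_subjects=14,
        n_trials_per_subject=10,
        trial_spacing=20.0,
        padding_s=15.0,
        planted_networks=acceptance_networks() if with_networks else [],
        leakage_strength=0.0,
        noise_sd=0.1,
        modulation_scale_sd=0.2,
        seed=seed,
    )


def acceptance_model(ts_list, events, n_components: int = 8) -> dc.DynamicNetworkModel:
    return dc.DynamicNetworkModel(
        ts_list,
        events,
        band=(8.0, 25.0),
        window_width=6.0,
        window_shift=2.0,
        epoch_start=-8.0,
        epoch_end=8.0,
        n_components=n_components,
    )


def match_component(A: np.ndarray, net: dc.NetworkDefinition, nn: int) -> tuple[int, float]:
    """Best-matching component for a planted network by spatial correlation.

    Matching uses the maximal absolute correlation between |mixing column|
    and the planted edge-indicator vector, so assertions are invariant to
    component order and sign.
    """
    iu = np.triu_indices(nn, k=1)
    M = np.zeros((nn, nn))
    for j, k in net.edges:
        M[j, k] = M[k, j] = 1.0
    v = M[iu]
    cors = [
        abs(np.corrcoef(np.abs(A[:, j]), v)[0, 1]) for j in range(A.shape[1])
    ]
    jbest = int(np.argmax(cors))
    return jbest, float(cors[jbest])


@pytest.fixture(scope="session")
def small_world():
    """A tiny simulated dataset (3 subjects) for fast structural tests."""
    params = dc.SimulationParams(
        n_regions=6,
        sampling_rate=80.0,
        band=(8.0, 24.0),
        n_subjects=3,
        n_trials_per_subject=4,
        trial_spacing=14.0,
        padding_s=8.0,
        planted_networks=[
            dc.NetworkDefinition(
                edges=clique([0, 1, 2]),
                modulation=dc.boxcar_modulation(-1.0, 3.0, amplitude=0.4),
                label="task",
            )
        ],
        noise_sd=0.1,
        seed=123,
    )
    ts_list, events, truth = dc.simulate_dataset(params)
    return params, ts_list, events, truth


@pytest.fixture(scope="session")
def fitted_small(small_world):
    """A fitted model on the tiny dataset, reused across structural tests."""
    _, ts_list, events, _ = small_world
    model = dc.DynamicNetworkModel(
        ts_list,
        events,
        band=(8.0, 24.0),
        window_width=4.0,
        window_shift=2.0,
        epoch_start=-4.0,
        epoch_end=4.0,
        n_components=3,
    )
    return model, model.fit(seed=0)
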