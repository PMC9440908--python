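"""Shared synthetic experiments (session-scoped: simulations are reused)."""

from __future__ import annotations

import numpy as np
import pytest

from cicada_dh import preprocess_traces, run_pipeline
from cicada_dh.synth import (
    CellSpec,
    PopulationConfig,
    ProtocolConfig,
    generate_experiment,
)


@pytest.fixture(scope="session")
def detection_run():
    """Grid-only experiment with suprathreshold (2.0 dF/F) static drive.

    40 cells x 128 grid events; used for detection sensitivity/specificity
    and receptive-field recovery against the generator's injected truth.
    """
    rng = np.random.default_rng(42)
    proto = ProtocolConfig(
        include_capsaicin=False, include_ligands=False,
        include_dynamic=False, include_thermal=False,
    )
    cells = [
        CellSpec(
            lt_amp=2.0, ht_amp=2.0,
            rf_center=(rng.uniform(0.5, 2.5), rng.uniform(0.5, 2.5)),
            rf_radius=1.2,
        )
        for _ in range(40)
    ]
    traces, timeline, rois, truth = generate_experiment(cells, proto, seed=5)
    dffset = preprocess_traces(traces)
    return traces, timeline, rois, truth, dffset


@pytest.fixture(scope="session")
def mixed_run():
    """Mixed-archetype experiment with LT gain 3 planted in Ex5 only.

    200 cells through the full protocol (shortened ligand washes); the full
    pipeline result is attached.  Ex5's static-LT amplitude sits below the
    responder threshold pre (0.9) and above it post (2.7), so the planted
    sensitization should appear as a Δ% LT responders in Ex5 alone.
    """
    proto = ProtocolConfig(ligand_wash_s=60.0)
    pop = PopulationConfig(lt_gain={"Ex5": 3.0}, rf_expansion={})
    traces, timeline, rois, truth = generate_experiment(200, proto, pop, seed=7)
    result = run_pipeline(traces, timeline, rois)
    return traces, timeline, rois, truth, result


@pytest.fixture(scope="session")
def capsaicin_run():
    """500 cells, half capsaicin-direct (2x activity), injection-only protocol."""
    proto = ProtocolConfig(
        include_dynamic=False, include_thermal=False, include_grid=False,
        include_post_block=False, include_ligands=False,
    )
    n = 500
    cells = [CellSpec(capsaicin_direct=(i < n // 2)) for i in range(n)]
    traces, timeline, rois, truth = generate_experiment(cells, proto, seed=3)
    dffset = preprocess_traces(traces)
    return cells, traces, timeline, truth, dffset


@pytest.fixture(scope="session")
def rf_expansion_run():
    """200 compact-RF cells with a 4x receptive-field area expansion planted."""
    rng = np.random.default_rng(99)
    proto = ProtocolConfig(
        include_dynamic=False, include_thermal=False, include_ligands=False,
    )
    cells = [
        CellSpec(
            lt_amp=2.0, ht_amp=2.0,
            rf_center=(rng.uniform(0.5, 2.5), rng.uniform(0.5, 2.5)),
            rf_radius=0.9, rf_expansion=4.0,
        )
        for _ in range(200)
    ]
    traces, timeline, rois, truth = generate_experiment(cells, proto, seed=9)
    dffset = preprocess_traces(traces)
    return cells, traces, timeline, truth, dffset


@pytest.fixture(scope="session")
def ligand_archetype_run():
    """300 cells in 3 well-separated ligand archetypes, ligand-only protocol."""
    rng = np.random.default_rng(7)
    proto = ProtocolConfig(
        include_dynamic=False, include_thermal=False, include_grid=False,
        include_capsaicin=False, ligand_wash_s=60.0,
    )
    # one-hot principal ligands: SP (0), taltirelin (4), NKB (7)
    cells = []
    planted = []
    for i in range(300):
        a = i % 3
        planted.append(a)
        ligs = np.zeros(8)
        ligs[(0, 4, 7)[a]] = max(0.5, 2.0 + 0.1 * rng.standard_normal())
        cells.append(CellSpec(ligand_amps=ligs))
    traces, timeline, rois, truth = generate_experiment(cells, proto, seed=11)
    dffset = preprocess_traces(traces)
    return np.array(planted), traces, timeline, truth, dffset
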