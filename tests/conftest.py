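import numpy as np
import pandas as pd
import pytest

from psifactor import (
    JunctionCountTable,
    SimulationConfig,
    SpliceEvent,
    simulate_factorial_experiment,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Default-structure synthetic dataset, small enough for fast tests."""
    cfg = SimulationConfig(n_events=300, n_genes=80, seed=42)
    return simulate_factorial_experiment(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """No-effect dataset: every event truly null."""
    cfg = SimulationConfig(
        n_events=200,
        n_genes=50,
        frac_mut_sensitive=0.0,
        frac_drug_sensitive=0.0,
        frac_interacting=0.0,
        frac_de_genes=0.0,
        seed=7,
    )
    return simulate_factorial_experiment(cfg)


def make_table(inc, skp, samples=None, conditions=None, event_type="SE"):
    """Tiny JunctionCountTable from raw integer arrays (events x samples)."""
    inc = np.atleast_2d(np.asarray(inc))
    skp = np.atleast_2d(np.asarray(skp))
    n_ev, n_s = inc.shape
    samples = samples or [f"s{i}" for i in range(n_s)]
    events = [
        SpliceEvent(
            event_id=f"e{i}",
            gene_id=f"g{i}",
            event_type=event_type,
            coordinates=(0, 10, 20, 30) if event_type == "SE" else (0, 10),
        )
        for i in range(n_ev)
    ]
    return JunctionCountTable(
        events=events,
        inclusion_counts=pd.DataFrame(inc, index=[e.event_id for e in events], columns=samples),
        skipping_counts=pd.DataFrame(skp, index=[e.event_id for e in events], columns=samples),
        sample_conditions=conditions or {},
    )
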