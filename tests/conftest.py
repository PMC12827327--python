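import numpy as np
import pytest

from actokin import (
    BulkCondition,
    NucleationParams,
    simulate_spontaneous_assembly,
)


@pytest.fixture(scope="session")
def default_assembly():
    """Noiseless reference ODE run: 2 µM actin, spontaneous nucleation."""
    return simulate_spontaneous_assembly(
        BulkCondition(a_total=2.0), t_end=2000.0, n_points=400
    )


@pytest.fixture(scope="session")
def fast_assembly():
    """Noiseless run with doubled nucleation for ordering comparisons."""
    return simulate_spontaneous_assembly(
        BulkCondition(a_total=2.0),
        nuc=NucleationParams(k_nuc_base=4e-6),
        t_end=2000.0,
        n_points=400,
    )
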