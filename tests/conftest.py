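import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from v1l4sim import connectome, geometry


def make_cells(spec):
    """Hand-built cell table: spec is a list of (cell_type, x, y, theta)."""
    rows = []
    for i, (ct, x, y, theta) in enumerate(spec):
        rows.append(dict(cell_id=i, cell_type=ct,
                         ei_class=geometry.EI_CLASS[ct],
                         x=float(x), y=float(y), z=50.0,
                         is_core=ct in geometry.CORE_TYPES,
                         theta_assigned=float(theta)))
    cells = pd.DataFrame(rows)
    cells["cell_type"] = cells["cell_type"].astype("category")
    cells["ei_class"] = cells["ei_class"].astype("category")
    return cells


@pytest.fixture
def two_cell_pair():
    return make_cells([("Scnn1a", 0, 0, 0), ("Scnn1a", 10, 0, 0)])


@pytest.fixture(scope="session")
def small_cells():
    """A placed-and-tuned population at 2% scale (900 cells)."""
    census = {t: max(1, int(round(n * 0.02)))
              for t, n in geometry.DEFAULT_CENSUS.items()}
    geom = geometry.Geometry(core_radius=400 * np.sqrt(0.02),
                             outer_radius=845 * np.sqrt(0.02))
    return geometry.assign_tuning(
        geometry.place_cells(census, geom, seed=11))


def external_from_events(events, n_sources=None, weight=1.2, n_syn=1,
                         kind="lgn"):
    """One-source-per-target external input from (target, [times]) pairs."""
    from v1l4sim import netsim
    targets = [t for t, _ in events]
    conns = connectome.ConnectionSet(
        np.arange(len(events), dtype=np.int32),
        np.asarray(targets, dtype=np.int32),
        np.full(len(events), n_syn, dtype=np.int16),
        np.full(len(events), weight, dtype=np.float32),
        kind=kind)
    spikes = [np.asarray(t_list, dtype=float) for _, t_list in events]
    return netsim.ExternalInput(kind, conns, spikes)
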