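"""Cell population of the layer-4 model: census, cylindrical placement, assigned tuning.

The model plane is the cortical surface (x, y in micrometres); z spans the
100-um-thick layer-4 slab.  Five "core" cell types (Scnn1a, Rorb, Nr5a1
excitatory; PV1, PV2 inhibitory) occupy an inner cylinder and two generic
LIF types (one excitatory, one inhibitory) fill the surrounding annulus to
suppress boundary artefacts.  Every neuron carries an assigned preferred
direction used by the functional connectivity rules and by the
thalamocortical wiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: cell types in canonical ID order; cell_ids are contiguous blocks per type
CELL_TYPES = ("Scnn1a", "Rorb", "Nr5a1", "PV1", "PV2", "LIF_exc", "LIF_inh")

#: default per-type census of the 45,000-neuron model
DEFAULT_CENSUS = {
    "Scnn1a": 3700,
    "Rorb": 3300,
    "Nr5a1": 1500,
    "PV1": 800,
    "PV2": 700,
    "LIF_exc": 29750,
    "LIF_inh": 5250,
}

#: excitatory / inhibitory class per type
EI_CLASS = {
    "Scnn1a": "E",
    "Rorb": "E",
    "Nr5a1": "E",
    "PV1": "I",
    "PV2": "I",
    "LIF_exc": "E",
    "LIF_inh": "I",
}

#: types placed in the inner cylinder (the analogue of the biophysical core)
CORE_TYPES = ("Scnn1a", "Rorb", "Nr5a1", "PV1", "PV2")


@dataclass(frozen=True)
class Geometry:
    """Cylinder/annulus dimensions of the cell slab, in micrometres."""

    core_radius: float = 400.0
    outer_radius: float = 845.0
    height: float = 100.0

    def __post_init__(self):
        if self.core_radius <= 0 or self.outer_radius <= 0:
            raise ValueError("radii must be positive")
        if self.core_radius >= self.outer_radius:
            raise ValueError("core radius must be smaller than outer radius")
        if self.height <= 0:
            raise ValueError("height must be positive")


DEFAULT_GEOMETRY = Geometry()


def _sample_disc(rng: np.random.Generator, n: int, r_min: float, r_max: float):
    """Uniform-per-area samples in the annulus r_min < r <= r_max."""
    u = rng.random(n)
    r = np.sqrt(r_min ** 2 + u * (r_max ** 2 - r_min ** 2))
    phi = rng.random(n) * 2.0 * np.pi
    return r * np.cos(phi), r * np.sin(phi)


def place_cells(census: dict | None = None,
                geometry: Geometry = DEFAULT_GEOMETRY,
                seed: int = 0) -> pd.DataFrame:
    """Instantiate the cell table.

    Core types are placed uniformly (per volume) inside the inner cylinder,
    LIF types in the annulus between the core and outer radii; z is uniform
    over the slab height.  Positions are reproducible for a given seed.

    Returns a DataFrame with columns
    ``cell_id, cell_type, ei_class, x, y, z, is_core`` (``theta_assigned``
    is added by :func:`assign_tuning`).
    """
    if census is None:
        census = DEFAULT_CENSUS
    unknown = set(census) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"unknown cell types in census: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    frames = []
    next_id = 0
    for ct in CELL_TYPES:
        n = int(census.get(ct, 0))
        if n < 0:
            raise ValueError("census counts must be nonnegative")
        if n == 0:
            continue
        core = ct in CORE_TYPES
        if core:
            x, y = _sample_disc(rng, n, 0.0, geometry.core_radius)
        else:
            x, y = _sample_disc(rng, n, geometry.core_radius,
                                geometry.outer_radius)
        z = rng.random(n) * geometry.height
        frames.append(pd.DataFrame({
            "cell_id": np.arange(next_id, next_id + n),
            "cell_type": ct,
            "ei_class": EI_CLASS[ct],
            "x": x, "y": y, "z": z,
            "is_core": core,
        }))
        next_id += n
    if not frames:
        return pd.DataFrame(columns=["cell_id", "cell_type", "ei_class",
                                     "x", "y", "z", "is_core"])
    cells = pd.concat(frames, ignore_index=True)
    cells["cell_type"] = cells["cell_type"].astype("category")
    cells["ei_class"] = cells["ei_class"].astype("category")
    return cells


def assign_tuning(cells: pd.DataFrame) -> pd.DataFrame:
    """Assign a preferred direction to every neuron.

    Within each type, the assigned direction tiles [0, 360) linearly over the
    type's ID order: the first ID of a type gets 0 degrees and the step is
    360/n.  The assigned *orientation* is the direction modulo 180.
    """
    cells = cells.copy()
    theta = np.zeros(len(cells))
    for ct in CELL_TYPES:
        mask = (cells["cell_type"] == ct).to_numpy()
        n = int(mask.sum())
        if n:
            theta[mask] = 360.0 * np.arange(n) / n
    cells["theta_assigned"] = theta
    return cells


def delta_direction(theta_a, theta_b):
    """Absolute direction difference folded into [0, 180]."""
    d = np.abs(np.asarray(theta_a) - np.asarray(theta_b)) % 360.0
    return np.minimum(d, 360.0 - d)


def delta_orientation(theta_a, theta_b):
    """Orientation difference folded into [0, 90].

    Directions 180 degrees apart share an orientation, so the direction
    difference is first reduced modulo 180 and then folded about 90.
    """
    d = np.abs(np.asarray(theta_a) - np.asarray(theta_b)) % 180.0
    return np.minimum(d, 180.0 - d)


def save_cells_csv(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def load_cells_csv(path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    cells["cell_type"] = cells["cell_type"].astype("category")
    cells["ei_class"] = cells["ei_class"].astype("category")
    return cells
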