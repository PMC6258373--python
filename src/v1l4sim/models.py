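"""Assembly of complete model instances, including matched-density reductions.

A :class:`Network` bundles the cell table, recurrent connectivity, LGN
filter bank with its feedforward wiring, and background generators.  The
``scale`` argument shrinks the model while preserving areal cell density,
filter density per square degree of visual space, and all local wiring
rules: cell counts scale by ``scale``, radii by ``sqrt(scale)``, and the
LGN field by ``sqrt(scale)`` with filter count tracking its area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import background as bg
from . import connectome, geometry, lgn, netsim
from .stimuli import StimulusMovie

#: default feedforward weights per target cell type (calibration starting
#: points, model activation units)
DEFAULT_LGN_W = {t: 0.003 for t in geometry.CELL_TYPES}
DEFAULT_BKG_W = {t: 0.003 for t in geometry.CELL_TYPES}


@dataclass
class Network:
    cells: pd.DataFrame
    recurrent: connectome.ConnectionSet
    filter_bank: pd.DataFrame
    lgn_conns: connectome.ConnectionSet
    generators: np.ndarray
    bkg_conns: connectome.ConnectionSet
    rule: str
    seed: int
    scale: float = 1.0

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def scaled_census(scale: float) -> dict:
    return {t: int(round(n * scale))
            for t, n in geometry.DEFAULT_CENSUS.items()}


def scaled_geometry(scale: float) -> geometry.Geometry:
    s = np.sqrt(scale)
    return geometry.Geometry(core_radius=400.0 * s, outer_radius=845.0 * s)


def scaled_field(scale: float) -> tuple:
    s = np.sqrt(scale)
    return (lgn.DEFAULT_FIELD[0] * s, lgn.DEFAULT_FIELD[1] * s)


def build_network(rule: str = "LL", seed: int = 0, scale: float = 1.0,
                  class_matrix: dict | None = None,
                  lgn_w: dict | None = None,
                  bkg_w: dict | None = None,
                  ranges: lgn.FilterParamRanges = lgn.DEFAULT_PARAM_RANGES
                  ) -> Network:
    """Build a complete model instance (cells, recurrent, LGN, background)."""
    geom = scaled_geometry(scale)
    cells = geometry.assign_tuning(
        geometry.place_cells(scaled_census(scale), geom, seed=seed))
    rec = connectome.build_recurrent(cells, rule=rule, seed=seed + 1)
    rec = connectome.assign_weights(rec, cells, class_matrix, rule=rule)
    field_deg = scaled_field(scale)
    n_per_type = int(round(3000 * (field_deg[0] * field_deg[1])
                           / (lgn.DEFAULT_FIELD[0] * lgn.DEFAULT_FIELD[1])))
    bank = lgn.place_filters(n_per_type=n_per_type, field=field_deg,
                             seed=seed + 2, ranges=ranges)
    lgn_conns = lgn.wire_lgn_to_l4(bank, cells, seed=seed + 3,
                                   weight_per_type=lgn_w or DEFAULT_LGN_W)
    gens = bg.place_generators(geom.outer_radius + bg.GENERATOR_MARGIN_UM,
                               seed=seed + 4)
    bkg_conns = bg.wire_background(cells, gens, seed=seed + 5,
                                   weight_per_type=bkg_w or DEFAULT_BKG_W)
    return Network(cells, rec, bank, lgn_conns, gens, bkg_conns,
                   rule, seed, scale)


def scale_feedforward(conns: connectome.ConnectionSet, cells: pd.DataFrame,
                      weight_per_type: dict) -> connectome.ConnectionSet:
    """Re-issue a feedforward ConnectionSet with new per-type weights."""
    ctype = cells.set_index("cell_id")["cell_type"].astype(str)
    w = ctype.reindex(conns.target).map(weight_per_type).to_numpy()
    return connectome.ConnectionSet(conns.source, conns.target, conns.n_syn,
                                    w.astype(np.float32), conns.delay,
                                    conns.rule_tag, conns.seed, conns.kind)


def lgn_input(net: Network, movie: StimulusMovie, seed: int,
              rates: np.ndarray | None = None) -> netsim.ExternalInput:
    """LGN spikes for one trial of ``movie``, wired onto the network.

    Pass precomputed ``rates`` (from :func:`lgn.bank_rates`) to amortise the
    deterministic front end across trials.
    """
    if rates is None:
        rates = lgn.bank_rates(net.filter_bank, movie)
    spikes = lgn.generate_spikes(rates, seed=seed)
    return netsim.ExternalInput("lgn", net.lgn_conns, spikes)


def background_input(net: Network, t_max_ms: float, seed: int,
                     match_duty_window: tuple | None = None,
                     duty_rel_tol: float = 0.1,
                     max_tries: int = 200) -> netsim.ExternalInput:
    """A fresh traveling-wave background trial wired onto the network.

    With ``match_duty_window=(t0, t1)`` the schedule seed is advanced until
    the generators' ON fraction over that window is within ``duty_rel_tol``
    of its long-run expectation - used for calibration training trials,
    whose short windows would otherwise over- or under-sample the waves.
    """
    geom = scaled_geometry(net.scale)
    r_f = geom.outer_radius + bg.GENERATOR_MARGIN_UM
    target = bg.expected_duty(footprint_radius=r_f)
    sched = None
    for tri in range(max_tries):
        cand = bg.generate_waves(t_max_ms, seed=seed + 7919 * tri,
                                 footprint_radius=r_f)
        if match_duty_window is None:
            sched = cand
            break
        duty = bg.schedule_duty(cand, net.generators, *match_duty_window)
        if abs(duty - target) <= duty_rel_tol * target:
            sched = cand
            break
    if sched is None:
        raise RuntimeError("no duty-matched wave schedule found")
    spikes = bg.generator_spikes(sched, net.generators, t_max_ms,
                                 seed=seed + 1)
    return netsim.ExternalInput("background", net.bkg_conns, spikes)
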