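"""Recurrent layer-4 connectivity under the four functional-rule variants.

A rule tag is a two-letter code.  The first letter selects the *connection
probability* rule and the second the *synaptic weight* rule; "L" means
like-to-like (dependent on the difference of assigned preferred
orientations) and "R" means random (tuning-independent).  So LL is
like-to-like in both probability and weight, RR in neither, and RL/LR mix.

Connection probability is a product of a linear distance term and (for
E-to-E pairs under "L" probability rules) a linear orientation term.
Like-to-like weights multiply the class base weight by
``F_w = exp(-dtheta^2 / sigma_theta^2)`` with sigma_theta = 50 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import delta_orientation

RULES = ("LL", "LR", "RL", "RR")

#: peak connection probability at zero distance, keyed (src_class, tgt_class);
#: E-to-E and E-to-I depend on the probability rule letter
_PEAK_P = {
    "L": {("E", "E"): 0.34, ("E", "I"): 0.26, ("I", "E"): 1.0, ("I", "I"): 1.0},
    "R": {("E", "E"): 0.255, ("E", "I"): 0.255, ("I", "E"): 1.0, ("I", "I"): 1.0},
}

#: distance (um) at which the probability reaches zero, keyed by source class
_CUTOFF = {"E": 300.0, "I": 160.0}

#: like-to-like weight width (degrees)
SIGMA_THETA = 50.0

#: synapses per recurrent connection: uniform integer in [3, 7]
N_SYN_RANGE = (3, 7)

#: default recurrent conduction delay (ms); nonzero for causal event ordering
DEFAULT_DELAY_MS = 1.0

#: default base weights (model activation units, threshold-normalised LIF)
#: keyed (source class, target class); starting points for calibration
DEFAULT_CLASS_MATRIX = {
    ("E", "E"): 0.002, ("E", "I"): 0.002,
    ("I", "E"): -0.006, ("I", "I"): -0.006,
}


@dataclass
class ConnectionSet:
    """Flat directed edge list with per-edge synapse count and weight.

    Edge arrays are parallel and sorted by target for gather efficiency.
    ``weight`` is the per-synapse weight; the total per-event contribution in
    the simulator is ``weight * n_syn``.
    """

    source: np.ndarray          # int32 cell/filter ids
    target: np.ndarray          # int32 cell ids
    n_syn: np.ndarray           # int16
    weight: np.ndarray          # float32, signed (E positive, I negative)
    delay: float = DEFAULT_DELAY_MS
    rule_tag: str | None = None
    seed: int | None = None
    kind: str = "recurrent"     # recurrent | lgn | background

    def __post_init__(self):
        n = len(self.source)
        if not (len(self.target) == len(self.n_syn) == len(self.weight) == n):
            raise ValueError("edge arrays must have equal length")

    def __len__(self):
        return len(self.source)

    def sort_by_target(self) -> "ConnectionSet":
        order = np.argsort(self.target, kind="stable")
        return ConnectionSet(self.source[order], self.target[order],
                             self.n_syn[order], self.weight[order],
                             self.delay, self.rule_tag, self.seed, self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "source": self.source, "target": self.target,
            "n_syn": self.n_syn, "weight": self.weight,
        })


def connection_probability(src_class, tgt_class, distance, delta_ori,
                           rule: str):
    """Probability of a directed connection (vectorised).

    ``distance`` is the planar intersomatic distance in micrometres and
    ``delta_ori`` the assigned orientation difference in [0, 90] degrees.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise ValueError("distance must be nonnegative")
    delta_ori = np.asarray(delta_ori, dtype=float)
    peak = _PEAK_P[rule[0]][(src_class, tgt_class)]
    cutoff = _CUTOFF[src_class]
    p = peak * np.clip(1.0 - distance / cutoff, 0.0, None)
    if src_class == "E" and tgt_class == "E" and rule[0] == "L":
        p = p * (1.0 - 0.5 * delta_ori / 90.0)
    return np.clip(p, 0.0, 1.0)


def build_recurrent(cells: pd.DataFrame, rule: str = "LL", seed: int = 0,
                    chunk: int = 1024) -> ConnectionSet:
    """Draw the recurrent connectivity by independent Bernoulli trials.

    Every ordered pair within the 300-um source cutoff is a candidate; the
    draw is independent per direction.  Distances are computed in the x-y
    plane.  Per-edge synapse counts are uniform integers in [3, 7].  Edges
    carry a unit placeholder weight until :func:`assign_weights` runs.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    xy = cells[["x", "y"]].to_numpy()
    n = len(cells)
    is_e = (cells["ei_class"] == "E").to_numpy()
    theta = cells["theta_assigned"].to_numpy()
    tree = cKDTree(xy)
    r_max = _CUTOFF["E"]

    src_out, tgt_out, p_cache = [], [], []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        neigh = tree.query_ball_point(xy[start:stop], r_max,
                                      return_sorted=False)
        counts = np.fromiter((len(a) for a in neigh), dtype=np.int64,
                             count=stop - start)
        src = np.concatenate([np.asarray(a, dtype=np.int64) for a in neigh]) \
            if counts.sum() else np.empty(0, dtype=np.int64)
        tgt = np.repeat(np.arange(start, stop, dtype=np.int64), counts)
        keep = src != tgt           # no self-edges
        src, tgt = src[keep], tgt[keep]
        d = np.hypot(xy[src, 0] - xy[tgt, 0], xy[src, 1] - xy[tgt, 1])

        p = np.zeros(len(src))
        se, te = is_e[src], is_e[tgt]
        for sc_mask, sc in ((se, "E"), (~se, "I")):
            for tc_mask, tc in ((te, "E"), (~te, "I")):
                m = sc_mask & tc_mask
                if not m.any():
                    continue
                if sc == "E" and tc == "E" and rule[0] == "L":
                    dori = delta_orientation(theta[src[m]], theta[tgt[m]])
                else:
                    dori = 0.0
                p[m] = connection_probability(sc, tc, d[m], dori, rule)
        hit = rng.random(len(p)) < p
        src_out.append(src[hit].astype(np.int32))
        tgt_out.append(tgt[hit].astype(np.int32))

    source = np.concatenate(src_out) if src_out else np.empty(0, np.int32)
    target = np.concatenate(tgt_out) if tgt_out else np.empty(0, np.int32)
    n_syn = rng.integers(N_SYN_RANGE[0], N_SYN_RANGE[1] + 1,
                         size=len(source)).astype(np.int16)
    weight = np.ones(len(source), dtype=np.float32)
    conns = ConnectionSet(source, target, n_syn, weight,
                          rule_tag=rule, seed=seed, kind="recurrent")
    return conns.sort_by_target()


def assign_weights(conns: ConnectionSet, cells: pd.DataFrame,
                   class_matrix: dict | None = None,
                   rule: str | None = None,
                   sigma_theta: float = SIGMA_THETA) -> ConnectionSet:
    """Set per-edge weights from the class matrix and the weight rule.

    Base weight depends on (source class, target class).  For E-to-E edges
    under like-to-like *weight* rules (second letter "L": LL and RL) the base
    is multiplied by ``F_w = exp(-dtheta^2 / sigma_theta^2)`` with dtheta the
    assigned orientation difference folded into [0, 90] degrees.
    """
    if class_matrix is None:
        class_matrix = DEFAULT_CLASS_MATRIX
    rule = rule if rule is not None else conns.rule_tag
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    is_e = (cells["ei_class"] == "E").to_numpy()
    theta = cells["theta_assigned"].to_numpy()
    se, te = is_e[conns.source], is_e[conns.target]
    w = np.empty(len(conns), dtype=np.float32)
    for sc_mask, sc in ((se, "E"), (~se, "I")):
        for tc_mask, tc in ((te, "E"), (~te, "I")):
            m = sc_mask & tc_mask
            if (sc, tc) not in class_matrix:
                if m.any():
                    raise KeyError(f"class matrix missing entry {(sc, tc)}")
                continue
            w[m] = class_matrix[(sc, tc)]
    if rule[1] == "L":
        m = se & te
        dtheta = delta_orientation(theta[conns.source[m]],
                                   theta[conns.target[m]])
        w[m] *= np.exp(-(dtheta / sigma_theta) ** 2).astype(np.float32)
    return ConnectionSet(conns.source, conns.target, conns.n_syn, w,
                         conns.delay, rule, conns.seed, conns.kind)


def degree_summary(conns: ConnectionSet, cells: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of distinct in/out partners and incoming synapse totals.

    Returned per ei_class and per cell_type, plus "core E"/"core I" rows
    restricted to the inner-cylinder population (whose neighbourhoods are
    unaffected by the outer model boundary).
    """
    n = len(cells)
    in_deg = np.bincount(conns.target, minlength=n)
    out_deg = np.bincount(conns.source, minlength=n)
    in_syn = np.bincount(conns.target, weights=conns.n_syn, minlength=n)
    groups = {}
    ei = cells["ei_class"].to_numpy()
    core = cells["is_core"].to_numpy()
    for cls in ("E", "I"):
        groups[cls] = ei == cls
        groups[f"core {cls}"] = (ei == cls) & core
    for ct in cells["cell_type"].cat.categories:
        groups[ct] = (cells["cell_type"] == ct).to_numpy()
    rows = []
    for name, mask in groups.items():
        if not mask.any():
            rows.append({"group": name, "n_cells": 0, "in_mean": 0.0,
                         "in_sd": 0.0, "out_mean": 0.0, "out_sd": 0.0,
                         "in_syn_mean": 0.0})
            continue
        rows.append({
            "group": name,
            "n_cells": int(mask.sum()),
            "in_mean": float(in_deg[mask].mean()),
            "in_sd": float(in_deg[mask].std()),
            "out_mean": float(out_deg[mask].mean()),
            "out_sd": float(out_deg[mask].std()),
            "in_syn_mean": float(in_syn[mask].mean()),
        })
    return pd.DataFrame(rows).set_index("group")
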