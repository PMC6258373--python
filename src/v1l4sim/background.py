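"""Traveling-wave background drive standing in for the rest of the brain.

Plane waves of elevated Poisson rate sweep across the cortical sheet,
producing alternating quiescent and depolarised epochs analogous to cortical
state fluctuations.  3,000 Poisson generators tile the model footprint; each
cortical cell listens to 18-24 nearby generators through a per-cell synapse
multiplier drawn from a long-tailed distribution, which is what makes the
spontaneous firing-rate distribution across cells long-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .connectome import ConnectionSet

N_GENERATORS = 3000
CONNECT_RADIUS_UM = 150.0
N_CONN_RANGE = (18, 24)
WAVE_WIDTH_UM = 2000.0
DURATION_RANGE_MS = (200.0, 1200.0)
GAP_RANGE_MS = (250.0, 1750.0)
AMPLITUDE_RANGE_HZ = (5.0, 15.0)
MAX_SYN_PER_CONN = 16
#: success parameter of the truncated-geometric synapse multiplier
SYN_GEOM_P = 0.5
#: generators extend this margin (um) beyond the outer cell radius so that
#: edge cells keep full candidate pools
GENERATOR_MARGIN_UM = 150.0


@dataclass
class WaveSchedule:
    """Sequential, non-overlapping waves plus generator positions."""

    onset: np.ndarray       # ms
    duration: np.ndarray    # ms
    direction: np.ndarray   # degrees
    amplitude: np.ndarray   # Hz
    footprint_radius: float # um, disc covered by generators
    width: float = WAVE_WIDTH_UM

    def __len__(self):
        return len(self.onset)


def place_generators(footprint_radius: float, seed: int = 0,
                     n: int = N_GENERATORS) -> np.ndarray:
    """Uniform generator positions over the footprint disc; (n, 2) um."""
    rng = np.random.default_rng(seed)
    r = footprint_radius * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2.0 * np.pi
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def generate_waves(total_time_ms: float, seed: int = 0,
                   footprint_radius: float = 845.0 + GENERATOR_MARGIN_UM
                   ) -> WaveSchedule:
    """Draw a sequential wave schedule covering [0, total_time_ms).

    The schedule alternates gaps (U[250, 1750] ms) and waves (U[200, 1200]
    ms, amplitude U[5, 15] Hz, direction U[0, 360)), starting with a gap, so
    short windows may contain no wave at all.
    """
    if total_time_ms <= 0:
        raise ValueError("total_time_ms must be positive")
    rng = np.random.default_rng(seed)
    onsets, durations, directions, amplitudes = [], [], [], []
    t = rng.uniform(*GAP_RANGE_MS)
    while t < total_time_ms:
        dur = rng.uniform(*DURATION_RANGE_MS)
        onsets.append(t)
        durations.append(dur)
        directions.append(rng.uniform(0.0, 360.0))
        amplitudes.append(rng.uniform(*AMPLITUDE_RANGE_HZ))
        t += dur + rng.uniform(*GAP_RANGE_MS)
    return WaveSchedule(np.asarray(onsets), np.asarray(durations),
                        np.asarray(directions), np.asarray(amplitudes),
                        footprint_radius)


def wave_rate(schedule: WaveSchedule, x_um, y_um, t_ms: float):
    """Instantaneous generator rate (Hz) at position(s) (x, y) and time t.

    The active wave is a rectangular band of the wave's amplitude, 2,000 um
    wide along its direction of motion and unbounded perpendicular to it.
    Each wave traverses the whole footprint within its duration: its speed is
    (footprint diameter + width) / duration, with the leading edge entering
    at the upstream footprint rim at onset.
    """
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    out = np.zeros(np.broadcast(x, y).shape)
    i = np.searchsorted(schedule.onset, t_ms, side="right") - 1
    if i < 0 or t_ms >= schedule.onset[i] + schedule.duration[i]:
        return out if out.shape else float(out)
    r_f = schedule.footprint_radius
    speed = (2.0 * r_f + schedule.width) / schedule.duration[i]
    phi = np.deg2rad(schedule.direction[i])
    u = x * np.cos(phi) + y * np.sin(phi)
    lead = -r_f + speed * (t_ms - schedule.onset[i])
    inside = (u > lead - schedule.width) & (u <= lead)
    out = np.where(inside, schedule.amplitude[i], 0.0)
    return out if out.shape else float(out)


def generator_spikes(schedule: WaveSchedule, positions: np.ndarray,
                     total_time_ms: float, seed: int,
                     dt_ms: float = 1.0) -> list[np.ndarray]:
    """Poisson spike trains (per-bin Bernoulli) for every generator.

    Exploits the rectangular wave profile: for each wave, each generator's
    rate is the wave amplitude over a contiguous crossing interval.
    """
    rng = np.random.default_rng(seed)
    n = len(positions)
    n_bins = int(round(total_time_ms / dt_ms))
    rate = np.zeros((n, n_bins), dtype=np.float32)
    r_f = schedule.footprint_radius
    for onset, dur, direc, amp in zip(schedule.onset, schedule.duration,
                                      schedule.direction, schedule.amplitude):
        speed = (2.0 * r_f + schedule.width) / dur
        phi = np.deg2rad(direc)
        u = positions[:, 0] * np.cos(phi) + positions[:, 1] * np.sin(phi)
        # band occupies u in (lead - width, lead]; invert for time interval
        t_in = onset + (u + r_f) / speed
        t_out = onset + (u + r_f + schedule.width) / speed
        lo = np.clip((t_in / dt_ms).astype(int), 0, n_bins)
        hi = np.clip(np.ceil(t_out / dt_ms).astype(int), 0, n_bins)
        hi = np.minimum(hi, int(np.ceil((onset + dur) / dt_ms)))
        for g in range(n):
            if hi[g] > lo[g]:
                rate[g, lo[g]:hi[g]] = amp
    p = rate * (dt_ms / 1000.0)
    hits = rng.random(rate.shape) < p
    return [(np.nonzero(h)[0] + 0.5) * dt_ms for h in hits]


def schedule_duty(schedule: WaveSchedule, positions: np.ndarray,
                  t_start_ms: float, t_stop_ms: float) -> float:
    """Mean ON fraction of the generators over [t_start, t_stop)."""
    on = 0.0
    r_f = schedule.footprint_radius
    for onset, dur, direc in zip(schedule.onset, schedule.duration,
                                 schedule.direction):
        speed = (2.0 * r_f + schedule.width) / dur
        phi = np.deg2rad(direc)
        u = positions[:, 0] * np.cos(phi) + positions[:, 1] * np.sin(phi)
        t_in = onset + (u + r_f) / speed
        t_out = np.minimum(onset + (u + r_f + schedule.width) / speed,
                           onset + dur)
        on += np.clip(np.minimum(t_out, t_stop_ms)
                      - np.maximum(t_in, t_start_ms), 0.0, None).sum()
    return float(on / (len(positions) * (t_stop_ms - t_start_ms)))


def expected_duty(schedule_width: float = WAVE_WIDTH_UM,
                  footprint_radius: float = 845.0 + GENERATOR_MARGIN_UM
                  ) -> float:
    """Long-run ON fraction implied by the wave statistics."""
    mean_dur = np.mean(DURATION_RANGE_MS)
    mean_gap = np.mean(GAP_RANGE_MS)
    traversal = schedule_width / (2.0 * footprint_radius + schedule_width)
    return float(mean_dur * traversal / (mean_dur + mean_gap))


def sample_syn_multiplier(rng: np.random.Generator, n: int,
                          p: float = SYN_GEOM_P,
                          max_syn: int = MAX_SYN_PER_CONN) -> np.ndarray:
    """Truncated geometric on {1..max_syn}, heavily weighted towards 1."""
    m = np.arange(1, max_syn + 1)
    pmf = p * (1 - p) ** (m - 1)
    pmf /= pmf.sum()
    return rng.choice(m, size=n, p=pmf)


def wire_background(cells: pd.DataFrame, generators: np.ndarray,
                    seed: int = 0,
                    weight_per_type: dict | None = None) -> ConnectionSet:
    """Connect each cell to 18-24 generators within 150 um.

    All background edges of one cell share a single synapse multiplier m in
    {1..16}, drawn per cell from a truncated geometric distribution, so a
    small fraction of cells receives much stronger background drive.
    """
    rng = np.random.default_rng(seed)
    if weight_per_type is None:
        weight_per_type = {}
    tree = cKDTree(generators)
    xy = cells[["x", "y"]].to_numpy()
    neigh = tree.query_ball_point(xy, CONNECT_RADIUS_UM)
    n_conn = rng.integers(N_CONN_RANGE[0], N_CONN_RANGE[1] + 1,
                          size=len(cells))
    m = sample_syn_multiplier(rng, len(cells))
    ctype = cells["cell_type"].astype(str).to_numpy()
    cell_ids = cells["cell_id"].to_numpy()
    src_list, tgt_list, syn_list, w_list = [], [], [], []
    for j, cand in enumerate(neigh):
        if len(cand) < N_CONN_RANGE[0]:
            raise ValueError(
                f"cell {cell_ids[j]} has only {len(cand)} generators within "
                f"{CONNECT_RADIUS_UM} um; generator density too low")
        k = min(n_conn[j], len(cand))
        sel = rng.choice(np.asarray(cand), size=k, replace=False)
        src_list.append(sel.astype(np.int32))
        tgt_list.append(np.full(k, cell_ids[j], dtype=np.int32))
        syn_list.append(np.full(k, m[j], dtype=np.int16))
        w_list.append(np.full(k, weight_per_type.get(ctype[j], 1.0),
                              dtype=np.float32))
    return ConnectionSet(np.concatenate(src_list), np.concatenate(tgt_list),
                         np.concatenate(syn_list), np.concatenate(w_list),
                         seed=seed, kind="background").sort_by_target()
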