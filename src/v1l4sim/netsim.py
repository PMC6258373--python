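"""Fixed-step point-neuron (LIF) network simulation with two synapse models.

Membrane potential is threshold-normalised: threshold 1, reset 0, absolute
refractory period 3 ms.  Two synapse dynamics are offered:

* ``instantaneous`` - each arriving event dumps ``weight * n_syn`` directly
  onto the membrane, which otherwise decays with the membrane time constant.
* ``kinetic`` - excitatory events feed a single-exponential drive (tau_E)
  and inhibitory events a difference-of-exponentials drive (rise tau_I1,
  decay tau_I2, peak-normalised); the membrane integrates both drives
  leakily.  The per-step state update uses the exact matrix exponential of
  the linear cascade, so subthreshold trajectories match the closed-form
  solution to machine precision.

Inputs arriving during the refractory period are discarded, not queued.
External spike trains (LGN, background, optogenetic silencing sources) are
binned at 1 ms; recurrent spikes propagate with the connection delay on the
0.1 ms integration grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .connectome import ConnectionSet

REFRACTORY_MS = 3.0

#: kinetic synaptic time constants per target class: (tau_e, tau_i1, tau_i2)
KINETIC_TAUS = {"E": (1.0, 4.0, 17.0), "I": (7.0, 1.0, 8.0)}

#: default membrane time constants (ms) per ei class; calibration inputs
#: standing in for the per-type averages of the detailed counterpart cells
DEFAULT_TAU_M = {"E": 15.0, "I": 10.0}

#: silencing-synapse weight corresponding to the "-100 pA" label
OPTO_REFERENCE_WEIGHT = 0.3
OPTO_POISSON_RATE_HZ = 100.0


@dataclass(frozen=True)
class PointNeuronParams:
    tau_m: dict = field(default_factory=lambda: dict(DEFAULT_TAU_M))
    refractory_ms: float = REFRACTORY_MS
    synapse_model: str = "instantaneous"      # or "kinetic"
    kinetic_taus: dict = field(default_factory=lambda: dict(KINETIC_TAUS))

    def __post_init__(self):
        if self.synapse_model not in ("instantaneous", "kinetic"):
            raise ValueError(f"unknown synapse model {self.synapse_model!r}")
        if self.refractory_ms < 0:
            raise ValueError("refractory period must be nonnegative")


@dataclass
class ExternalInput:
    """A population of external spike sources wired onto the network.

    ``spikes`` holds one spike-time array (ms) per source id; ``conns``
    edges use those source ids.
    """

    label: str                      # "lgn" | "background" | "opto"
    conns: ConnectionSet
    spikes: list


@dataclass
class Perturbation:
    kind: str                       # "silence_population" | "silence_lgn"
    target_type: str | None = None
    fraction: float = 1.0
    strength_pa: float = 100.0      # current-injection label, magnitude used
    onset_ms: float = 1000.0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.kind not in ("silence_population", "silence_lgn"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


@dataclass
class SpikeData:
    """Spike times plus per-cell synaptic-input accumulators.

    ``acc`` maps label -> per-cell summed arriving weight (weight * n_syn
    per event, every arrival counted whether or not the target was
    refractory): keys "lgn_exc", "all_exc", "all_inh".  ``audit`` carries
    event-conservation totals (applied + discarded external drive).
    """

    cell_ids: np.ndarray
    times: np.ndarray
    n_cells: int
    t_max_ms: float
    trial: int = 0
    acc: dict = field(default_factory=dict)
    audit: dict = field(default_factory=dict)

    def rates_hz(self, t_start_ms: float = 0.0,
                 t_stop_ms: float | None = None) -> np.ndarray:
        t_stop = self.t_max_ms if t_stop_ms is None else t_stop_ms
        m = (self.times >= t_start_ms) & (self.times < t_stop)
        counts = np.bincount(self.cell_ids[m], minlength=self.n_cells)
        return counts / ((t_stop - t_start_ms) / 1000.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "time_ms": self.times,
                             "trial": self.trial})


def _csr_by_source(conns: ConnectionSet, n_sources: int):
    """Edge arrays grouped by source: (indptr, targets, w_syn)."""
    order = np.argsort(conns.source, kind="stable")
    src = conns.source[order]
    tgt = conns.target[order]
    w = (conns.weight[order] * conns.n_syn[order]).astype(np.float64)
    indptr = np.searchsorted(src, np.arange(n_sources + 1))
    return indptr, tgt, w


def bin_external_drive(external: list[ExternalInput], n_cells: int,
                       t_max_ms: float):
    """Dense per-ms drive matrices (T x N): excitatory, inhibitory, LGN-only.

    Each external spike deposits weight * n_syn on every target of its
    source at the spike's 1-ms bin.
    """
    n_bins = int(np.ceil(t_max_ms))
    drive_e = np.zeros((n_bins, n_cells), dtype=np.float64)
    drive_i = np.zeros((n_bins, n_cells), dtype=np.float64)
    drive_lgn = np.zeros(n_cells, dtype=np.float64)
    for ext in external:
        n_src = int(ext.conns.source.max()) + 1 if len(ext.conns) else 0
        n_src = max(n_src, len(ext.spikes))
        indptr, tgt, w = _csr_by_source(ext.conns, n_src)
        for s, st in enumerate(ext.spikes):
            st = np.asarray(st)
            st = st[(st >= 0) & (st < t_max_ms)]
            if len(st) == 0 or indptr[s] == indptr[s + 1]:
                continue
            bins = st.astype(np.int64)
            e_tgt = tgt[indptr[s]:indptr[s + 1]]
            e_w = w[indptr[s]:indptr[s + 1]]
            t_rep = np.repeat(bins, len(e_tgt))
            tgt_rep = np.tile(e_tgt, len(bins))
            w_rep = np.tile(e_w, len(bins))
            pos = w_rep > 0
            np.add.at(drive_e, (t_rep[pos], tgt_rep[pos]), w_rep[pos])
            if not pos.all():
                np.add.at(drive_i, (t_rep[~pos], tgt_rep[~pos]), w_rep[~pos])
            if ext.label == "lgn":
                np.add.at(drive_lgn, tgt_rep[pos], w_rep[pos])
    return drive_e, drive_i, drive_lgn


def _kinetic_coeffs(tau_m: float, taus: tuple, dt: float) -> np.ndarray:
    """One-step transition matrix of the (V, ge, gi1, gi2) linear cascade."""
    tau_e, tau_i1, tau_i2 = taus
    tp = np.log(tau_i2 / tau_i1) * tau_i1 * tau_i2 / (tau_i2 - tau_i1)
    norm = 1.0 / (np.exp(-tp / tau_i2) - np.exp(-tp / tau_i1))
    A = np.array([
        [-1.0 / tau_m, 1.0 / tau_m, -norm / tau_m, norm / tau_m],
        [0.0, -1.0 / tau_e, 0.0, 0.0],
        [0.0, 0.0, -1.0 / tau_i1, 0.0],
        [0.0, 0.0, 0.0, -1.0 / tau_i2],
    ])
    return expm(A * dt)


def simulate(cells: pd.DataFrame, recurrent: ConnectionSet | None,
             external: list[ExternalInput],
             params: PointNeuronParams = PointNeuronParams(),
             t_max_ms: float = 3000.0, dt_ms: float = 0.1,
             perturbation: Perturbation | None = None,
             seed: int = 0, trial: int = 0) -> SpikeData:
    """Run the network for ``t_max_ms`` and return spikes + accumulators."""
    if dt_ms > 1.0:
        raise ValueError("dt must be at most 1 ms")
    n = len(cells)
    if recurrent is not None and len(recurrent):
        if recurrent.target.max() >= n or recurrent.source.max() >= n:
            raise ValueError("recurrent edges reference unknown cell ids")
    if perturbation is not None:
        external = apply_perturbation(cells, external, perturbation,
                                      t_max_ms, seed=seed + 900_001)

    ei = (cells["ei_class"] == "E").to_numpy()
    tau_m = np.where(ei, params.tau_m["E"], params.tau_m["I"])
    steps_per_ms = int(round(1.0 / dt_ms))
    n_steps = int(round(t_max_ms / dt_ms))
    refr_steps = int(round(params.refractory_ms / dt_ms))

    drive_e, drive_i, drive_lgn = bin_external_drive(external, n, t_max_ms)

    acc_exc = drive_e.sum(axis=0)
    acc_inh = drive_i.sum(axis=0)
    acc_lgn = drive_lgn
    ext_total = float(drive_e.sum() + drive_i.sum())
    applied_ext = 0.0

    kinetic = params.synapse_model == "kinetic"
    if recurrent is not None and len(recurrent):
        indptr, r_tgt, r_w = _csr_by_source(recurrent, n)
        delay_steps = max(1, int(round(recurrent.delay / dt_ms)))
    else:
        indptr = None
        delay_steps = 1
    buf_len = delay_steps + 1
    rec_buf_e = np.zeros((buf_len, n))
    rec_buf_i = np.zeros((buf_len, n))

    V = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    if kinetic:
        ge = np.zeros(n)
        gi1 = np.zeros(n)
        gi2 = np.zeros(n)
        Me = _kinetic_coeffs(params.tau_m["E"], params.kinetic_taus["E"], dt_ms)
        Mi = _kinetic_coeffs(params.tau_m["I"], params.kinetic_taus["I"], dt_ms)
        c = {k: np.where(ei, Me[i, j], Mi[i, j])
             for k, (i, j) in {"vv": (0, 0), "ve": (0, 1), "v1": (0, 2),
                               "v2": (0, 3)}.items()}
        dec_e = np.where(ei, Me[1, 1], Mi[1, 1])
        dec_1 = np.where(ei, Me[2, 2], Mi[2, 2])
        dec_2 = np.where(ei, Me[3, 3], Mi[3, 3])
    else:
        decay = np.exp(-dt_ms / tau_m)

    spike_cells, spike_times = [], []
    for step in range(n_steps):
        cur = step % buf_len
        inc_e = rec_buf_e[cur].copy()
        inc_i = rec_buf_i[cur].copy()
        rec_buf_e[cur] = 0.0
        rec_buf_i[cur] = 0.0
        active = refr <= 0
        if step % steps_per_ms == 0:
            ms = step // steps_per_ms
            inc_e += drive_e[ms]
            inc_i += drive_i[ms]
            if active.all():
                applied_ext += float(drive_e[ms].sum() + drive_i[ms].sum())
            else:
                applied_ext += float(drive_e[ms][active].sum()
                                     + drive_i[ms][active].sum())
        if not active.all():
            refr[~active] -= 1
            inc_e = np.where(active, inc_e, 0.0)
            inc_i = np.where(active, inc_i, 0.0)
        if kinetic:
            V = c["vv"] * V + c["ve"] * ge + c["v1"] * gi1 + c["v2"] * gi2
            ge = dec_e * ge + inc_e
            gi1 = dec_1 * gi1 + inc_i
            gi2 = dec_2 * gi2 + inc_i
            V = np.where(active, V, 0.0)
        else:
            V = V * decay + inc_e + inc_i
            V = np.where(active, V, 0.0)
        if not np.all(np.isfinite(V)):
            raise FloatingPointError(
                f"non-finite membrane state at step {step}")
        fired = V >= 1.0
        if fired.any():
            ids = np.nonzero(fired)[0]
            V[ids] = 0.0
            refr[ids] = refr_steps
            t_ms = (step + 1) * dt_ms
            spike_cells.append(ids.astype(np.int32))
            spike_times.append(np.full(len(ids), t_ms))
            if indptr is not None:
                starts, stops = indptr[ids], indptr[ids + 1]
                if np.any(stops > starts):
                    tgt_all = np.concatenate(
                        [r_tgt[a:b] for a, b in zip(starts, stops)])
                    w_all = np.concatenate(
                        [r_w[a:b] for a, b in zip(starts, stops)])
                    slot = (step + delay_steps) % buf_len
                    pos = w_all > 0
                    np.add.at(rec_buf_e[slot], tgt_all[pos], w_all[pos])
                    np.add.at(rec_buf_i[slot], tgt_all[~pos], w_all[~pos])
                    np.add.at(acc_exc, tgt_all[pos], w_all[pos])
                    np.add.at(acc_inh, tgt_all[~pos], w_all[~pos])

    cell_ids = (np.concatenate(spike_cells) if spike_cells
                else np.empty(0, dtype=np.int32))
    times = (np.concatenate(spike_times) if spike_times
             else np.empty(0, dtype=float))
    order = np.argsort(times, kind="stable")
    # external drive audit: applied (delivered to non-refractory cells) plus
    # discarded must equal the binned total
    discarded_ext = ext_total - applied_ext
    return SpikeData(cell_ids[order], times[order], n, t_max_ms, trial,
                     acc={"lgn_exc": acc_lgn, "all_exc": acc_exc,
                          "all_inh": acc_inh},
                     audit={"ext_total": ext_total,
                            "ext_applied": applied_ext,
                            "ext_discarded": discarded_ext})


def poisson_train(rate_hz: float, t_max_ms: float, rng: np.random.Generator,
                  dt_ms: float = 1.0) -> np.ndarray:
    n = int(np.ceil(t_max_ms / dt_ms))
    hits = rng.random(n) < rate_hz * dt_ms / 1000.0
    return (np.nonzero(hits)[0] + 0.5) * dt_ms


def apply_perturbation(cells: pd.DataFrame, external: list[ExternalInput],
                       perturbation: Perturbation, t_max_ms: float,
                       seed: int = 0) -> list[ExternalInput]:
    """Return a modified copy of the external inputs.

    ``silence_lgn`` removes every LGN spike at or after the onset time.
    ``silence_population`` attaches one inhibitory synapse, driven by an
    independent 100 Hz Poisson train, to the selected fraction of the target
    type; its weight scales linearly with the current-injection label
    (|strength| / 100 pA times the reference weight).
    """
    rng = np.random.default_rng(seed)
    if perturbation.kind == "silence_lgn":
        out = []
        for ext in external:
            if ext.label == "lgn":
                spikes = [np.asarray(st)[np.asarray(st)
                                         < perturbation.onset_ms]
                          for st in ext.spikes]
                out.append(ExternalInput(ext.label, ext.conns, spikes))
            else:
                out.append(ext)
        return out

    mask = (cells["cell_type"] == perturbation.target_type).to_numpy()
    if not mask.any():
        raise ValueError(
            f"unknown or empty target type {perturbation.target_type!r}")
    ids = cells.loc[mask, "cell_id"].to_numpy()
    n_sel = int(round(perturbation.fraction * len(ids)))
    if n_sel == 0:
        return list(external)
    sel = rng.choice(ids, size=n_sel, replace=False)
    w = -OPTO_REFERENCE_WEIGHT * abs(perturbation.strength_pa) / 100.0
    conns = ConnectionSet(
        source=np.arange(n_sel, dtype=np.int32),
        target=sel.astype(np.int32),
        n_syn=np.ones(n_sel, dtype=np.int16),
        weight=np.full(n_sel, w, dtype=np.float32),
        kind="opto")
    spikes = [poisson_train(OPTO_POISSON_RATE_HZ, t_max_ms, rng)
              for _ in range(n_sel)]
    return list(external) + [ExternalInput("opto", conns, spikes)]
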