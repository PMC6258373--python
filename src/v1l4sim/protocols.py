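"""End-to-end experiment pipelines: build, calibrate, stimulate, measure.

These functions chain the package's modules into the standard in-silico
physiology workflows - a calibrated model instance, a grating battery with
per-cell tuning and input accounting, the spontaneous-activity protocol,
LGN silencing, and multi-unit spectra - so scripts and tests run the same
code paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis, calibrate, connectome, models, netsim
from . import lgn as lgn_mod
from .stimuli import GRATING_DIRECTIONS, make_grating, make_gray


@dataclass
class CalibratedModel:
    """A network instance with frozen calibrated weights."""

    net: models.Network
    calib: calibrate.CalibrationResult
    recurrent: connectome.ConnectionSet
    lgn_conns: connectome.ConnectionSet
    bkg_conns: connectome.ConnectionSet
    params: netsim.PointNeuronParams

    @property
    def cells(self):
        return self.net.cells

    def is_exc(self):
        return (self.net.cells["ei_class"] == "E").to_numpy()

    def external_inputs(self, movie, seed, bank_rates=None):
        if bank_rates is None:
            bank_rates = lgn_mod.bank_rates(self.net.filter_bank, movie)
        lgn_in = netsim.ExternalInput(
            "lgn", self.lgn_conns,
            lgn_mod.generate_spikes(bank_rates, seed=seed))
        bkg_in = netsim.ExternalInput(
            "background", self.bkg_conns,
            models.background_input(self.net, movie.duration_ms,
                                    seed=seed + 1).spikes)
        return [lgn_in, bkg_in]


def calibrated_network(rule: str = "LL", scale: float = 0.1, seed: int = 0,
                       params: netsim.PointNeuronParams | None = None,
                       calib: calibrate.CalibrationResult | None = None
                       ) -> CalibratedModel:
    """Build a model instance and run (or reuse) the calibration protocol.

    Passing a ``calib`` result from another instance reuses its weight
    scales - used for the rule-variant comparisons, where all four variants
    share one calibration so that differences are attributable to the
    wiring rules alone.
    """
    params = params or netsim.PointNeuronParams()
    net = models.build_network(rule=rule, seed=seed, scale=scale)
    if calib is None:
        calib = calibrate.calibrate_all(net, params=params, seed=seed)
    rec = connectome.assign_weights(net.recurrent, net.cells,
                                    calib.class_matrix, rule=rule)
    lgn_conns = models.scale_feedforward(net.lgn_conns, net.cells,
                                         calib.lgn_w)
    bkg_conns = models.scale_feedforward(net.bkg_conns, net.cells,
                                         calib.bkg_w)
    return CalibratedModel(net, calib, rec, lgn_conns, bkg_conns, params)


def grating_battery(model: CalibratedModel, tf_hz: float = 2.0,
                    sf_cpd: float = 0.05,
                    directions=GRATING_DIRECTIONS,
                    duration_ms: int = 2500, seed: int = 0):
    """One trial per direction; returns (rates, lgn_fracs, spike_data).

    ``rates`` and ``lgn_fracs`` are (n_directions, n_cells): trial rate over
    the grating presentation and the per-cell LGN share of excitatory input.
    """
    R, F, spikes = [], [], []
    for i, d in enumerate(directions):
        movie = make_grating(d, sf_cpd, tf_hz, duration_ms=duration_ms)
        bank_rates = lgn_mod.bank_rates(model.net.filter_bank, movie)
        ext = model.external_inputs(movie, seed=seed + 13 * i,
                                    bank_rates=bank_rates)
        sd = netsim.simulate(model.cells, model.recurrent, ext, model.params,
                             t_max_ms=movie.duration_ms,
                             seed=seed + 17 * i, trial=i)
        R.append(sd.rates_hz(500.0, movie.duration_ms))
        with np.errstate(invalid="ignore", divide="ignore"):
            F.append(np.where(sd.acc["all_exc"] > 0,
                              sd.acc["lgn_exc"]
                              / np.where(sd.acc["all_exc"] > 0,
                                         sd.acc["all_exc"], 1.0),
                              np.nan))
        spikes.append(sd)
    return np.stack(R), np.stack(F), spikes


def preferred_orientation_lgn_fraction(rates: np.ndarray,
                                       fracs: np.ndarray) -> np.ndarray:
    """Per-cell LGN input fraction at each cell's preferred direction."""
    pref = rates.argmax(axis=0)
    return fracs[pref, np.arange(fracs.shape[1])]


def spont_protocol(model: CalibratedModel, n_trials: int = 20,
                   seed: int = 1000):
    """Gray-screen trials (1,000 ms each); returns per-cell rates."""
    gray = make_gray(1000)
    bank_rates = lgn_mod.bank_rates(model.net.filter_bank, gray)
    trials = []
    for tr in range(n_trials):
        ext = model.external_inputs(gray, seed=seed + 10 * tr,
                                    bank_rates=bank_rates)
        trials.append(netsim.simulate(model.cells, model.recurrent, ext,
                                      model.params, t_max_ms=1000.0,
                                      seed=seed + tr, trial=tr))
    return analysis.spont_rate(trials, model.net.n_cells), trials


def lgn_silencing_run(model: CalibratedModel, onset_ms: float = 1000.0,
                      tf_hz: float = 4.0, duration_ms: int = 1500,
                      seed: int = 0):
    """Paired grating runs with and without LGN silencing at ``onset_ms``.

    Returns (baseline SpikeData, silenced SpikeData, background-only
    SpikeData) sharing identical input realisations where applicable.
    """
    movie = make_grating(0.0, 0.05, tf_hz, duration_ms=duration_ms)
    ext = model.external_inputs(movie, seed=seed)
    base = netsim.simulate(model.cells, model.recurrent, ext, model.params,
                           t_max_ms=movie.duration_ms, seed=seed)
    pert = netsim.Perturbation(kind="silence_lgn", onset_ms=onset_ms)
    silenced = netsim.simulate(model.cells, model.recurrent, ext,
                               model.params, t_max_ms=movie.duration_ms,
                               perturbation=pert, seed=seed)
    bkg_only = netsim.simulate(model.cells, model.recurrent, [ext[1]],
                               model.params, t_max_ms=movie.duration_ms,
                               seed=seed)
    return base, silenced, bkg_only


def mua_low_gamma_prominence(model: CalibratedModel, n_trials: int = 8,
                             tf_hz: float = 4.0, seed: int = 0,
                             band=(10.0, 20.0),
                             edges=((7.0, 9.5), (21.0, 26.0))):
    """Mean elevation of the 10-20 Hz multi-unit power above its spectral
    floor, from grating trials.

    Stimulus-locked harmonics of the drift frequency are masked out, the
    spectrum is lightly smoothed, and the floor under the band is the
    log-linear interpolation between the median power in the two flanking
    ``edges`` windows.  A value near 1 means no band-limited oscillation;
    a genuine low-gamma rhythm elevates the whole band above its floor.
    """
    movie = make_grating(0.0, 0.05, tf_hz, duration_ms=2500)
    bank_rates = lgn_mod.bank_rates(model.net.filter_bank, movie)
    trials = []
    for tr in range(n_trials):
        ext = model.external_inputs(movie, seed=seed + 10 * tr,
                                    bank_rates=bank_rates)
        trials.append(netsim.simulate(model.cells, model.recurrent, ext,
                                      model.params,
                                      t_max_ms=movie.duration_ms,
                                      seed=seed + tr, trial=tr))
    freqs, power = analysis.mua_spectrum(trials, model.cells)
    harm = np.min(np.abs(freqs[:, None]
                         - tf_hz * np.arange(1, 51)[None, :]),
                  axis=1) < 0.75
    smooth = np.convolve(power, np.ones(3) / 3.0, mode="same")
    lo = np.median(smooth[(freqs >= edges[0][0]) & (freqs <= edges[0][1])
                          & ~harm])
    hi = np.median(smooth[(freqs >= edges[1][0]) & (freqs <= edges[1][1])
                          & ~harm])
    m = (freqs >= band[0]) & (freqs <= band[1]) & ~harm
    floor = np.exp(np.interp(freqs[m],
                             [np.mean(edges[0]), np.mean(edges[1])],
                             [np.log(lo), np.log(hi)]))
    return float(np.mean(smooth[m] / floor))


def mean_exc_osi(model: CalibratedModel, tf_hz: float = 4.0,
                 duration_ms: int = 1500, seed: int = 0) -> float:
    """Population-mean OSI of excitatory cells from one battery pass."""
    rates, _, _ = grating_battery(model, tf_hz=tf_hz,
                                  duration_ms=duration_ms, seed=seed)
    osis = analysis.osi(np.asarray(GRATING_DIRECTIONS), rates.T)
    return float(np.nanmean(osis[model.is_exc()]))
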