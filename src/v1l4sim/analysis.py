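"""Response metrics for simulated (or recorded) spike trains.

Conventions shared by all metrics: the first 500 ms of every trial is an
equilibration period and is discarded; degenerate denominators yield NaN
("undefined") rather than zero so population summaries can exclude them
explicitly.

Implemented metrics: spontaneous rate, tuning curves and Rmax, OSI (one
minus circular variance), DSI, F0/F1 of cycle-averaged responses, lifetime
sparsity, CV of inter-spike intervals, Fano factor, signal/noise
correlations, optogenetic modulation index, rate-distribution skewness,
inverse-distance-weighted multi-unit activity spectra, LGN input fraction,
LGN convergence of connected pairs, and linear amplification fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DISCARD_MS = 500.0

# ---------------------------------------------------------------------------
# rates and tuning


def trial_rates(spike_list, n_cells: int, t_start_ms: float,
                t_stop_ms: float) -> np.ndarray:
    """Trial-averaged firing rate (Hz) per cell over [t_start, t_stop)."""
    acc = np.zeros(n_cells)
    for sd in spike_list:
        acc += sd.rates_hz(t_start_ms, t_stop_ms)
    return acc / len(spike_list)


def spont_rate(gray_trials, n_cells: int,
               window_ms: tuple = (500.0, 1000.0)) -> np.ndarray:
    """Spontaneous rate from gray-screen trials (second 500 ms of each).

    With 20 trials of 500 ms the smallest resolvable nonzero rate is 0.1 Hz.
    """
    if not gray_trials:
        raise ValueError("no gray-screen trials supplied")
    return trial_rates(gray_trials, n_cells, *window_ms)


@dataclass
class TuningCurve:
    """Per-cell direction tuning at the preferred SF/TF, plus Rmax."""

    directions: np.ndarray          # degrees, shape (n_dir,)
    rates: np.ndarray               # Hz, (n_cells, n_dir), preferred SF/TF
    rmax: np.ndarray                # Hz, (n_cells,), max over all conditions
    pref_dir: np.ndarray            # degrees (NaN where response all zero)


def tuning_and_rmax(rates_by_condition: pd.DataFrame) -> TuningCurve:
    """Summarise grating responses into tuning curves and Rmax.

    ``rates_by_condition`` has columns ``direction, sf, tf`` and one rate
    column per cell... practical layout: index = (direction, sf, tf),
    values = (n_conditions, n_cells) array in column "rates".  Preferred
    direction is the argmax of the SF/TF-averaged response; preferred SF/TF
    maximise the response at that direction; Rmax is the maximum over all
    conditions.
    """
    dirs = np.sort(rates_by_condition["direction"].unique())
    mats = np.stack(rates_by_condition["rates"].to_numpy())  # (n_cond, n_cells)
    n_cells = mats.shape[1]
    rmax = mats.max(axis=0)
    by_dir = np.stack([
        mats[(rates_by_condition["direction"] == d).to_numpy()].mean(axis=0)
        for d in dirs])                                       # (n_dir, n_cells)
    pref_idx = by_dir.argmax(axis=0)
    pref_dir = dirs[pref_idx].astype(float)
    pref_dir[by_dir.max(axis=0) <= 0] = np.nan

    curve = np.empty((n_cells, len(dirs)))
    dir_arr = rates_by_condition["direction"].to_numpy()
    sf_arr = rates_by_condition["sf"].to_numpy()
    tf_arr = rates_by_condition["tf"].to_numpy()
    for c in range(n_cells):
        if np.isnan(pref_dir[c]):
            curve[c] = by_dir[:, c]
            continue
        at_pref = dir_arr == pref_dir[c]
        best = np.argmax(mats[at_pref, c])
        sf_b, tf_b = sf_arr[at_pref][best], tf_arr[at_pref][best]
        sel = (sf_arr == sf_b) & (tf_arr == tf_b)
        sub_dirs = dir_arr[sel]
        order = np.argsort(sub_dirs)
        curve[c] = np.interp(dirs, sub_dirs[order], mats[sel, c][order])
    return TuningCurve(dirs, curve, rmax, pref_dir)


def osi(directions_deg: np.ndarray, rates: np.ndarray):
    """Orientation selectivity index: |sum f e^{2i theta} / sum f|.

    Equals one minus the circular variance in orientation space.  ``rates``
    may be (n_dir,) or (n_cells, n_dir).  NaN where the summed rate is zero.
    """
    th = np.deg2rad(np.asarray(directions_deg, dtype=float))
    f = np.atleast_2d(np.asarray(rates, dtype=float))
    denom = f.sum(axis=1)
    num = np.abs((f * np.exp(2j * th)).sum(axis=1))
    out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return out[0] if np.ndim(rates) == 1 else out


def dsi(directions_deg: np.ndarray, rates: np.ndarray):
    """Direction selectivity index (f_pref - f_null)/(f_pref + f_null)."""
    d = np.asarray(directions_deg, dtype=float) % 360.0
    f = np.atleast_2d(np.asarray(rates, dtype=float))
    pref_idx = f.argmax(axis=1)
    null_dir = (d[pref_idx] + 180.0) % 360.0
    null_idx = np.argmin(np.abs((d[None, :] - null_dir[:, None] + 180.0)
                                % 360.0 - 180.0), axis=1)
    fp = f[np.arange(len(f)), pref_idx]
    fn = f[np.arange(len(f)), null_idx]
    denom = fp + fn
    out = np.where(denom > 0, (fp - fn) / np.where(denom > 0, denom, 1.0),
                   np.nan)
    return out[0] if np.ndim(rates) == 1 else out


def f0_f1(signal: np.ndarray, freq_hz: float, dt_ms: float = 1.0,
          convention: str = "fourier_abs"):
    """F0 and F1 of a cycle-averaged periodic response.

    The trial-averaged signal is folded at the stimulus period; F0 is the
    cycle mean.  Two F1 conventions are in circulation and both are exposed:
    ``fourier_abs`` returns |b| for a + b sin(wt) (the Fourier amplitude at
    the stimulus frequency) and ``fit_2b`` returns 2|b| (peak-to-trough of
    the fitted sinusoid).
    """
    if convention not in ("fourier_abs", "fit_2b"):
        raise ValueError(f"unknown F1 convention {convention!r}")
    period = 1000.0 / freq_hz / dt_ms
    n_cycles = int(len(signal) / period)
    if n_cycles < 1:
        raise ValueError("signal shorter than one stimulus cycle")
    n_bin = int(round(period))
    folded = np.zeros(n_bin)
    counts = np.zeros(n_bin)
    idx = (np.arange(int(n_cycles * period)) % period).astype(int) % n_bin
    np.add.at(folded, idx, np.asarray(signal)[:len(idx)])
    np.add.at(counts, idx, 1.0)
    cyc = folded / np.maximum(counts, 1.0)
    f0 = float(cyc.mean())
    ph = 2.0 * np.pi * np.arange(n_bin) / n_bin
    b = 2.0 * np.sqrt(np.mean(cyc * np.cos(ph)) ** 2
                      + np.mean(cyc * np.sin(ph)) ** 2)
    f1 = abs(b) if convention == "fourier_abs" else 2.0 * abs(b)
    return f0, f1


def sparsity(binned_rates: np.ndarray):
    """Lifetime sparsity S = [1 - (mean f)^2 / mean(f^2)] / (1 - 1/n).

    ``binned_rates`` is (n_bins,) or (n_cells, n_bins) of trial-averaged
    rates in 33.3 ms bins; NaN where the response is identically zero.
    """
    f = np.atleast_2d(np.asarray(binned_rates, dtype=float))
    n = f.shape[1]
    if n < 2:
        raise ValueError("sparsity needs at least two bins")
    sum_sq = (f ** 2).mean(axis=1)
    ok = sum_sq > 0
    val = (1.0 - f.mean(axis=1) ** 2 / np.where(ok, sum_sq, 1.0)) \
        / (1.0 - 1.0 / n)
    out = np.where(ok, val, np.nan)
    return out[0] if np.ndim(binned_rates) == 1 else out


def bin_spike_counts(sd, bin_ms: float, t_start_ms: float = DISCARD_MS,
                     t_stop_ms: float | None = None) -> np.ndarray:
    """(n_cells, n_bins) spike counts in non-overlapping windows."""
    t_stop = sd.t_max_ms if t_stop_ms is None else t_stop_ms
    n_bins = int((t_stop - t_start_ms) / bin_ms)
    edges = t_start_ms + np.arange(n_bins + 1) * bin_ms
    counts = np.zeros((sd.n_cells, n_bins))
    m = (sd.times >= edges[0]) & (sd.times < edges[-1])
    b = ((sd.times[m] - t_start_ms) / bin_ms).astype(int)
    np.add.at(counts, (sd.cell_ids[m], b), 1.0)
    return counts


# ---------------------------------------------------------------------------
# variability


def cv_isi(spike_times: np.ndarray, squared: bool = True):
    """Variation of inter-spike intervals: (sd/mean)^2 by default.

    The squared ratio is the convention used throughout this package's
    variability summaries; set ``squared=False`` for the conventional
    unsquared coefficient of variation.
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    isi = np.diff(st)
    if len(isi) < 2 or isi.mean() == 0:
        return np.nan
    r = isi.std() / isi.mean()
    return r ** 2 if squared else r


def fano_factor(trial_spike_list, n_cells: int,
                window_ms: float = 50.0, step_ms: float = 10.0,
                t_start_ms: float = DISCARD_MS,
                t_stop_ms: float | None = None) -> np.ndarray:
    """Per-cell Fano factor from sliding-window spike counts.

    Counts in 50 ms windows sliding by 10 ms are collected across trials;
    the Fano factor is the slope of the regression of count variance on
    count mean over the windows.
    """
    t_stop = trial_spike_list[0].t_max_ms if t_stop_ms is None else t_stop_ms
    starts = np.arange(t_start_ms, t_stop - window_ms + 1e-9, step_ms)
    n_w = len(starts)
    counts = np.zeros((len(trial_spike_list), n_cells, n_w))
    for i, sd in enumerate(trial_spike_list):
        for j, s in enumerate(starts):
            m = (sd.times >= s) & (sd.times < s + window_ms)
            counts[i, :, j] = np.bincount(sd.cell_ids[m], minlength=n_cells)
    mean_w = counts.mean(axis=0)            # (n_cells, n_w)
    var_w = counts.var(axis=0, ddof=1)
    out = np.full(n_cells, np.nan)
    for c in range(n_cells):
        x, y = mean_w[c], var_w[c]
        if np.ptp(x) == 0:
            continue
        out[c] = np.polyfit(x, y, 1)[0]
    return out


def signal_noise_correlations(counts_by_stim: np.ndarray):
    """Pairwise signal and noise correlations from per-stimulus counts.

    ``counts_by_stim`` has shape (n_stim, n_trials, n_cells).  Signal
    correlation: Pearson r between trial-averaged counts across stimuli.
    Noise correlation: Pearson r between single-trial counts within each
    stimulus, averaged over stimuli.  Returns (sig, noise) matrices with NaN
    for constant cells.
    """
    c = np.asarray(counts_by_stim, dtype=float)
    n_stim, n_trials, n_cells = c.shape
    mean_counts = c.mean(axis=1)                     # (n_stim, n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        sig = np.corrcoef(mean_counts.T)
        noise = np.zeros((n_cells, n_cells))
        valid = np.zeros((n_cells, n_cells))
        for s in range(n_stim):
            r = np.corrcoef(c[s].T)
            ok = np.isfinite(r)
            noise += np.where(ok, r, 0.0)
            valid += ok
        noise = np.where(valid > 0, noise / np.maximum(valid, 1), np.nan)
    return sig, noise


def omi(f_perturbed, f_control):
    """Optogenetic modulation index (f_p - f_c)/(f_p + f_c); NaN if both 0."""
    fp = np.asarray(f_perturbed, dtype=float)
    fc = np.asarray(f_control, dtype=float)
    denom = fp + fc
    out = np.where(denom > 0, (fp - fc) / np.where(denom > 0, denom, 1.0),
                   np.nan)
    return float(out) if out.ndim == 0 else out


def skewness(values: np.ndarray) -> float:
    """Third standardised moment of a sample (linear rate space)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3 or v.std() == 0:
        return np.nan
    return float(stats.skew(v, bias=True))


# ---------------------------------------------------------------------------
# population signals


def mua_spectrum(trial_spike_list, cells: pd.DataFrame,
                 center=(0.0, 0.0), bin_ms: float = 1.0,
                 t_start_ms: float = DISCARD_MS,
                 min_r_um: float = 1.0):
    """Trial-averaged power spectrum of inverse-distance-weighted activity.

    The signal is the 1 ms-binned population rate with each neuron weighted
    by 1/r (r = planar distance to the recording point, floored at 1 um to
    avoid the singularity).  Returns (freqs_hz, power).
    """
    r = np.hypot(cells["x"].to_numpy() - center[0],
                 cells["y"].to_numpy() - center[1])
    w = 1.0 / np.maximum(r, min_r_um)
    psd = None
    for sd in trial_spike_list:
        t_stop = sd.t_max_ms
        n_bins = int((t_stop - t_start_ms) / bin_ms)
        sig = np.zeros(n_bins)
        m = (sd.times >= t_start_ms) & (sd.times < t_start_ms + n_bins * bin_ms)
        b = ((sd.times[m] - t_start_ms) / bin_ms).astype(int)
        np.add.at(sig, b, w[sd.cell_ids[m]])
        spec = np.abs(np.fft.rfft(sig - sig.mean())) ** 2
        psd = spec if psd is None else psd + spec
    psd /= len(trial_spike_list)
    freqs = np.fft.rfftfreq(n_bins, d=bin_ms / 1000.0)
    return freqs, psd


def lgn_fraction(trial_spike_list, undefined_below: float = 0.0):
    """Per-cell LGN share of total excitatory synaptic input.

    Uses the simulator's per-trial input accumulators (summed arriving
    weights); fractions are averaged over trials.  NaN where a cell received
    no excitatory input at all.
    """
    lgn = np.zeros(trial_spike_list[0].n_cells)
    tot = np.zeros_like(lgn)
    for sd in trial_spike_list:
        lgn += sd.acc["lgn_exc"]
        tot += sd.acc["all_exc"]
    ok = tot > undefined_below
    return np.where(ok, lgn / np.where(ok, tot, 1.0), np.nan)


def lgn_convergence(pairs: np.ndarray, lgn_conns, recurrent_conns,
                    n_cells: int):
    """LGN convergence per cell pair, grouped by recurrent coupling.

    Convergence = |shared LGN sources| / (|sources of a| + |sources of b|);
    NaN when neither cell receives LGN input.  Returns a DataFrame with
    columns ``a, b, convergence, coupling`` where coupling is "none",
    "one_way" or "reciprocal".
    """
    from scipy import sparse
    lgn_sets = [set() for _ in range(n_cells)]
    for s, t in zip(lgn_conns.source, lgn_conns.target):
        lgn_sets[t].add(int(s))
    n_src = int(recurrent_conns.source.max()) + 1 if len(recurrent_conns) \
        else 1
    adj = sparse.csr_matrix(
        (np.ones(len(recurrent_conns), dtype=bool),
         (recurrent_conns.source, recurrent_conns.target)),
        shape=(max(n_cells, n_src), max(n_cells, n_src)))
    rows = []
    for a, b in pairs:
        sa, sb = lgn_sets[a], lgn_sets[b]
        denom = len(sa) + len(sb)
        conv = len(sa & sb) / denom if denom else np.nan
        ab = bool(adj[a, b])
        ba = bool(adj[b, a])
        coupling = ("reciprocal" if ab and ba
                    else "one_way" if ab or ba else "none")
        rows.append((a, b, conv, coupling))
    return pd.DataFrame(rows, columns=["a", "b", "convergence", "coupling"])


def amplification_fit(x: np.ndarray, y: np.ndarray):
    """OLS fit y = A x + B across conditions; returns (A, B, r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        return np.nan, np.nan, np.nan
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def flash_psth(trial_spike_list, cell_ids: np.ndarray, onset_ms: float,
               bin_ms: float = 2.0, smooth_ms: float = 10.0):
    """Population PSTH around a flash plus the first two peak latencies.

    Returns (t_centers_ms, psth_hz, peaks) where peaks is a list of up to
    two (latency_ms, magnitude_hz) tuples found as local maxima of the
    boxcar-smoothed PSTH after the flash onset; empty where no local maxima
    exist.
    """
    sel = np.zeros(trial_spike_list[0].n_cells, dtype=bool)
    sel[np.asarray(cell_ids)] = True
    t_max = trial_spike_list[0].t_max_ms
    n_bins = int(t_max / bin_ms)
    counts = np.zeros(n_bins)
    for sd in trial_spike_list:
        m = sel[sd.cell_ids]
        b = (sd.times[m] / bin_ms).astype(int)
        b = b[b < n_bins]
        np.add.at(counts, b, 1.0)
    n_norm = len(trial_spike_list) * sel.sum() * bin_ms / 1000.0
    psth = counts / n_norm
    t_centers = (np.arange(n_bins) + 0.5) * bin_ms
    k = max(1, int(round(smooth_ms / bin_ms)))
    kernel = np.ones(k) / k
    smooth = np.convolve(psth, kernel, mode="same")
    after = t_centers >= onset_ms
    s = smooth[after]
    t_a = t_centers[after]
    peaks = []
    for i in range(1, len(s) - 1):
        if s[i] > s[i - 1] and s[i] >= s[i + 1] and s[i] > 0:
            peaks.append((float(t_a[i] - onset_ms), float(s[i])))
            if len(peaks) == 2:
                break
    return t_centers, psth, peaks
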