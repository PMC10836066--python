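"""Stimulus-evoked PSC detection and per-event kinetic measurement.

Detection works on the polarity-rectified trace (inward events at -60 mV,
outward at 0 mV — at the AMPA reversal potential only chloride-mediated
currents remain): the trace is lightly smoothed, baseline noise is estimated
from the pre-stimulus segment, and candidate events are local maxima exceeding
``k`` × baseline SD.  Partially overlapping events within a compound PSC are
additionally split at secondary rising phases of the first derivative.  Each
event is then measured: onset by extrapolating the 20-80% rising chord to the
local baseline, 10-90% rise time by interpolated level crossings, amplitude as
signed peak minus local baseline, and decay by a least-squares
single-exponential fit from the peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from . import kernels


@dataclass
class Sweep:
    """One voltage-clamp sweep on a uniform time grid."""

    current: np.ndarray  # pA
    fs_khz: float
    stim_time: float  # ms
    holding: float  # mV
    sweep_id: int = 0

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.current.size) / self.fs_khz

    def __post_init__(self):
        if not 0.0 <= self.stim_time <= self.current.size / self.fs_khz:
            raise ValueError("stim_time outside sweep window")


@dataclass
class PSCEvent:
    """One detected post-synaptic current."""

    onset_latency: float  # ms from stimulus
    rise_10_90: float  # ms
    amplitude: float  # pA, signed (peak minus local baseline)
    tau_decay: float  # ms
    time_to_peak: float  # ms, onset to peak
    sweep_id: int = 0
    holding: float = -60.0
    fit_ok: bool = True  # decay fit converged


@dataclass(frozen=True)
class DetectParams:
    """Tunables of the detector (defaults standard for evoked PSC work)."""

    threshold_sd: float = 4.0  # k × baseline SD
    smooth_ms: float = 0.06  # gaussian smoothing sigma
    min_separation_ms: float = 0.4
    search_window_ms: float = 25.0  # post-stimulus window searched
    deriv_threshold_sd: float = 4.0  # for compound-event splitting
    baseline_margin_ms: float = 0.5


def _polarity(holding: float) -> float:
    """Sign that rectifies expected events to positive deflections."""
    return -1.0 if holding < -10.0 else 1.0


def _interp_crossing(t, y, level, i_hi):
    """Time where y crosses ``level`` moving backwards from index i_hi."""
    i = i_hi
    while i > 0 and y[i] > level:
        i -= 1
    if i == i_hi:
        return t[i_hi]
    frac = (level - y[i]) / (y[i + 1] - y[i]) if y[i + 1] != y[i] else 0.0
    return t[i] + frac * (t[i + 1] - t[i])


def fit_kinetics(segment: np.ndarray, fs_khz: float, polarity: float = -1.0,
                 baseline: float | None = None, noise_sd: float | None = None,
                 allow_offset: bool = False):
    """Measure one event contained in ``segment``.

    ``segment`` must start shortly before the event onset and extend at least
    about two decay constants beyond the peak.  Returns
    ``(rise_10_90, amplitude, tau_decay, time_to_peak, onset_time, fit_ok)``
    with times in ms relative to the start of the segment and amplitude signed
    as in the raw trace.
    """
    y = polarity * np.asarray(segment, float)
    t = np.arange(y.size) / fs_khz
    if y.size < max(8, int(0.3 * fs_khz)):
        raise ValueError("segment shorter than the fit window")
    if baseline is None:
        baseline = float(np.median(y[: max(3, int(0.1 * fs_khz))]))
    y = y - baseline

    # crossings and peak location on a lightly smoothed copy; amplitude as a
    # short average of the raw trace around the peak (the kernel is flat there)
    ys = ndimage.gaussian_filter1d(y, 1.5)
    i_peak = int(np.argmax(ys))
    lo, hi = max(i_peak - 2, 0), min(i_peak + 3, y.size)
    peak = float(np.mean(y[lo:hi]))
    if noise_sd is not None and peak <= 2.0 * noise_sd:
        raise ValueError("peak not beyond baseline noise")
    if peak <= 0:
        raise ValueError("no event deflection in segment")

    t10 = _interp_crossing(t, ys, 0.10 * peak, i_peak)
    t20 = _interp_crossing(t, ys, 0.20 * peak, i_peak)
    t80 = _interp_crossing(t, ys, 0.80 * peak, i_peak)
    t90 = _interp_crossing(t, ys, 0.90 * peak, i_peak)
    rise = max(t90 - t10, 1.0 / fs_khz)

    # onset: extrapolate the 20-80% chord back to the local baseline
    if t80 > t20:
        slope = 0.60 * peak / (t80 - t20)
        onset = t20 - 0.20 * peak / slope
    else:
        onset = t10
    onset = max(onset, 0.0)

    # decay: single-exponential least squares from the peak over a window of
    # ~3 decay constants (two passes: a first fit sets the window).  For
    # later events in a compound PSC (``allow_offset``) a bounded free
    # offset absorbs the decaying local baseline of the preceding event.
    tail = y[i_peak:]
    t_tail = t[i_peak:] - t[i_peak]
    fit_ok = True
    try:
        if allow_offset:
            tau = kernels.decay_tau_ls_offset(t_tail, tail, peak)
        else:
            tau = kernels.decay_tau_ls(t_tail, tail)
        if not math.isfinite(tau):
            raise RuntimeError
    except Exception:
        fit_ok = False
        # fallback: log-linear fit over the positive part of the tail
        pos = tail > max(0.05 * peak, 1e-12)
        if pos.sum() >= 3:
            coef = np.polyfit(t_tail[pos], np.log(tail[pos]), 1)
            tau = float(-1.0 / coef[0]) if coef[0] < 0 else float("nan")
        else:
            tau = float("nan")

    amplitude = polarity * peak
    return rise, amplitude, tau, t[i_peak] - onset, onset, fit_ok


def detect_events(sweep: Sweep, dp: DetectParams = DetectParams()) -> list[PSCEvent]:
    """Detect and measure all stimulus-evoked PSCs in one sweep."""
    pol = _polarity(sweep.holding)
    fs = sweep.fs_khz
    y_raw = pol * sweep.current
    sigma = max(dp.smooth_ms * fs, 1.0)
    y = ndimage.gaussian_filter1d(y_raw, sigma)

    i_stim = int(sweep.stim_time * fs)
    i_base_end = max(i_stim - int(dp.baseline_margin_ms * fs), 4)
    base = y_raw[:i_base_end]
    base_mean = float(np.median(base))
    noise_sd = float(np.std(base))
    if noise_sd == 0.0:
        noise_sd = 1e-9
    y = y - base_mean
    y_raw = y_raw - base_mean

    i_end = min(y.size, i_stim + int(dp.search_window_ms * fs))
    thr = dp.threshold_sd * noise_sd
    min_dist = max(int(dp.min_separation_ms * fs), 1)

    seg = y[i_stim:i_end]
    peaks, _ = signal.find_peaks(seg, height=thr, prominence=0.5 * thr,
                                 distance=min_dist)
    peaks = peaks + i_stim

    # compound-event splitting: secondary rising phases of the derivative
    dy = np.gradient(y) * fs  # pA/ms
    dnoise = float(np.std(np.gradient(ndimage.gaussian_filter1d(y_raw[:i_base_end], sigma)) * fs))
    if dnoise == 0.0:
        dnoise = 1e-9
    dpk, _ = signal.find_peaks(dy[i_stim:i_end],
                               height=dp.deriv_threshold_sd * dnoise,
                               distance=min_dist)
    dpk = dpk + i_stim

    # each derivative peak marks a rising phase; its event peak is the first
    # local maximum of y after it that clears threshold
    onsets_idx = set()
    for p in peaks:
        onsets_idx.add(int(p))
    cand_peaks = sorted(onsets_idx)
    for d in dpk:
        nxt = [p for p in cand_peaks if p >= d]
        prv = [p for p in cand_peaks if p < d]
        # a rising phase not explained by an already-found peak within the
        # separation window indicates a shoulder event
        if nxt and nxt[0] - d < 4 * min_dist:
            continue
        j = d
        while j + 1 < i_end and dy[j + 1] > 0:
            j += 1
        if y[j] > thr and all(abs(j - p) >= min_dist for p in cand_peaks):
            cand_peaks.append(j)
            cand_peaks.sort()

    # merge candidates not separated by a genuine valley (noise on the flat
    # top of a slow PSC can pass find_peaks twice): the dip between two real
    # events must fall well below the smaller peak
    merged = []
    for p in sorted(cand_peaks):
        if merged:
            q = merged[-1]
            dip = float(np.min(y[q:p + 1]))
            if dip > min(y[q], y[p]) - max(4.0 * noise_sd, 0.15 * min(y[q], y[p])):
                if y[p] > y[q]:
                    merged[-1] = p
                continue
        merged.append(p)
    cand_peaks = merged

    # valleys: smoothed-trace minima separating consecutive candidate events;
    # each event is measured on [its valley, the next valley] so that later
    # events in a compound PSC are referenced to their local baseline
    valleys = []
    prev = i_stim
    for p in cand_peaks:
        valleys.append(prev + int(np.argmin(y[prev:p + 1])))
        prev = p

    events: list[PSCEvent] = []
    for n, p in enumerate(cand_peaks):
        i0 = max(valleys[n] - 2, i_stim)
        if n > 0:
            i0 = max(i0, cand_peaks[n - 1] + 1)
        i1 = valleys[n + 1] if n + 1 < len(cand_peaks) else i_end
        i1 = min(max(i1, p + int(0.4 * fs)), y.size)
        local_base = float(np.median(y_raw[max(i0 - 2, 0):i0 + 3])) if n > 0 else 0.0
        try:
            rise, amp, tau, ttp, onset_rel, ok = fit_kinetics(
                y_raw[i0:i1], fs, polarity=1.0,
                baseline=local_base, noise_sd=noise_sd,
                allow_offset=(n > 0))
        except ValueError:
            continue
        onset_ms = i0 / fs + onset_rel - sweep.stim_time
        if onset_ms <= 0:
            continue
        events.append(PSCEvent(onset_latency=onset_ms, rise_10_90=rise,
                               amplitude=pol * amp, tau_decay=tau,
                               time_to_peak=ttp, sweep_id=sweep.sweep_id,
                               holding=sweep.holding, fit_ok=ok))
    events.sort(key=lambda e: e.onset_latency)

    # de-duplicate: flat-topped or shoulder-split candidates can resolve to
    # the same rising phase; keep the larger-amplitude measurement
    deduped: list[PSCEvent] = []
    for e in events:
        if deduped and e.onset_latency - deduped[-1].onset_latency < dp.min_separation_ms:
            if abs(e.amplitude) > abs(deduped[-1].amplitude):
                deduped[-1] = e
            continue
        deduped.append(e)
    return deduped


def events_to_frame(events: list[PSCEvent]) -> "pd.DataFrame":
    """Event table with one row per PSC (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([vars(e) for e in events],
                        columns=["onset_latency", "rise_10_90", "amplitude",
                                 "tau_decay", "time_to_peak", "sweep_id",
                                 "holding", "fit_ok"])
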