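"""Difference-of-exponentials synaptic event kernels.

Detected PSCs are summarised by *measured* parameters — 10–90% rise time and
the time constant of a single-exponential fit to the decay from the peak —
whereas the generative waveform is a difference of two exponentials

    g(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / norm,   t >= 0,

normalised to unit peak.  The pair (tau_r, tau_d) is therefore solved
numerically so that the realised measurements match requested values.
"""

from __future__ import annotations

import functools
import math

import numpy as np
from scipy import optimize


def peak_time(tau_r: float, tau_d: float) -> float:
    """Time of the kernel peak for tau_r < tau_d."""
    return tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)


def evaluate(t, tau_r: float, tau_d: float):
    """Unit-peak difference-of-exponentials kernel; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    tp = peak_time(tau_r, tau_d)
    norm = math.exp(-tp / tau_d) - math.exp(-tp / tau_r)
    out = np.where(t >= 0.0, np.exp(-t / tau_d) - np.exp(-t / tau_r), 0.0)
    return out / norm


def rise_10_90(tau_r: float, tau_d: float) -> float:
    """Realised 10–90% rise time of the unit-peak kernel."""
    tp = peak_time(tau_r, tau_d)

    def f(t, level):
        return evaluate(t, tau_r, tau_d) - level

    t10 = optimize.brentq(f, 1e-9, tp, args=(0.1,))
    t90 = optimize.brentq(f, t10, tp, args=(0.9,))
    return t90 - t10


def fitted_decay_tau(tau_r: float, tau_d: float) -> float:
    """Single-exponential decay constant fitted from the kernel peak.

    Matches the estimator the event detector applies to isolated events:
    an initial constant from the 1/e-decay crossing, then two least-squares
    refinements of ``a * exp(-(t - t_peak)/tau)`` over a window of three
    decay constants, evaluated here on a dense noiseless grid.
    """
    tp = peak_time(tau_r, tau_d)
    t = np.linspace(tp, tp + 8.0 * tau_d, 2000)
    y = evaluate(t, tau_r, tau_d)
    tau = decay_tau_ls(t - tp, y)
    if not math.isfinite(tau):  # pragma: no cover
        raise RuntimeError("decay fit failed on noiseless kernel")
    return tau


def decay_tau_ls(t_tail, y_tail) -> float:
    """Shared decay-constant estimator (tail measured from its peak).

    tau0 from the interpolated 1/e crossing of the tail, then two
    least-squares single-exponential fits over [0, 3 tau] windows.
    """
    t_tail = np.asarray(t_tail, float)
    y_tail = np.asarray(y_tail, float)
    peak = y_tail[0]
    level = peak / math.e
    below = np.flatnonzero(y_tail <= level)
    if below.size and below[0] > 0:
        i = below[0]
        frac = (y_tail[i - 1] - level) / max(y_tail[i - 1] - y_tail[i], 1e-12)
        tau = t_tail[i - 1] + frac * (t_tail[i] - t_tail[i - 1])
    else:
        tau = t_tail[-1] / 3.0 if t_tail[-1] > 0 else 1.0
    for _ in range(2):
        n_win = int(np.searchsorted(t_tail, 3.0 * tau))
        n_win = max(min(n_win, len(t_tail)), 8)
        tt, yy = t_tail[:n_win], y_tail[:n_win]
        popt, _ = optimize.curve_fit(
            lambda x, a, tau_: a * np.exp(-x / tau_), tt, yy,
            p0=(peak, max(tau, 1e-3)),
            bounds=((0.0, 1e-3), (np.inf, 1e3)), maxfev=4000)
        tau = float(popt[1])
    return tau


def decay_tau_ls_offset(t_tail, y_tail, peak_bound: float) -> float:
    """Decay estimator with a bounded free offset (compound-event variant)."""
    t_tail = np.asarray(t_tail, float)
    y_tail = np.asarray(y_tail, float)
    peak = y_tail[0]
    tau = max(t_tail[-1] / 6.0, 1e-3)
    for _ in range(2):
        n_win = int(np.searchsorted(t_tail, 3.0 * tau))
        n_win = max(min(n_win, len(t_tail)), 8)
        tt, yy = t_tail[:n_win], y_tail[:n_win]
        popt, _ = optimize.curve_fit(
            lambda x, a, tau_, c: a * np.exp(-x / tau_) + c, tt, yy,
            p0=(peak, max(tau, 1e-3), 0.0),
            bounds=((0.0, 1e-3, -0.6 * peak_bound),
                    (np.inf, 1e3, 0.6 * peak_bound)), maxfev=4000)
        tau = float(popt[1])
    return tau


@functools.lru_cache(maxsize=512)
def solve_taus(rise: float, tau: float) -> tuple[float, float]:
    """Find (tau_r, tau_d) whose realised (10–90 rise, fitted decay tau)
    equal ``(rise, tau)``.

    Requires rise < tau.  Parametrised in logs with tau_d = tau_r * (1 + e^u)
    to keep the ordering constraint implicit.
    """
    if not rise < tau:
        raise ValueError(f"rise ({rise}) must be smaller than tau ({tau})")

    def tr_for_rise(td: float) -> float:
        """Rise time is monotone increasing in tau_r at fixed tau_d."""
        lo, hi = 1e-4 * td, 0.999 * td
        if rise_10_90(hi, td) < rise:
            raise ValueError("requested rise not achievable at this tau_d")
        return optimize.brentq(lambda tr: rise_10_90(tr, td) - rise, lo, hi,
                               xtol=1e-10)

    def tau_residual(td: float) -> float:
        try:
            return fitted_decay_tau(tr_for_rise(td), td) - tau
        except ValueError:
            # tau_d too small to realise the requested rise at all: the
            # kernel is certainly too fast, so report a negative residual
            return -tau

    # fitted decay tau is monotone increasing in tau_d; bracket around tau
    lo, hi = 0.5 * tau, 2.0 * tau
    while tau_residual(hi) < 0:  # pragma: no cover - very skewed kernels
        hi *= 1.5
    while tau_residual(lo) > 0:
        lo *= 0.7
    td = optimize.brentq(tau_residual, lo, hi, xtol=1e-9)
    tr = tr_for_rise(td)
    res = (rise_10_90(tr, td) - rise, fitted_decay_tau(tr, td) - tau)
    if abs(res[0]) > 0.02 * rise or abs(res[1]) > 0.02 * tau:
        raise RuntimeError(f"kernel solve failed for rise={rise}, tau={tau}: residual {res}")
    return tr, td


def event_waveform(t, onset: float, amplitude: float, tau_r: float, tau_d: float):
    """Signed event waveform on time grid ``t`` (ms): amplitude × unit kernel."""
    return amplitude * evaluate(np.asarray(t) - onset, tau_r, tau_d)
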