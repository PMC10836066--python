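"""Conductance-based single MOC neuron model.

A compact compartmental model (soma + four equivalent dendritic cables) with
auditory-brainstem-style channel kinetics: fast transient Na, a high-threshold
delayed-rectifier (Kv3-like, needed for >300 Hz firing), a low-threshold K
current, a slow spike-triggered AHP-like K component, and leak.  Synapses are
difference-of-exponentials conductances with reversal 0 mV (AMPA-like
excitation) and -74 mV (glycine/GABA with physiological low intracellular
chloride).  Integration is fixed-step exponential Euler (default dt 0.02 ms),
deterministic, and numba-accelerated when numba is importable.

The channel *kinetics* are standard published forms (Rothman & Manis 2003
ventral-cochlear-nucleus formulations, temperature-scaled); the *densities*
and synaptic weights are free parameters fixed by a calibration contract:
reproduce the packaged synthetic mini-PSP templates and the train-response
endpoints (first-AP latency with and without inhibition, E-only AP rate) for
100 Hz, 20-pulse synaptic trains at the midline-derived E-I latency
difference of +2.8 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kernels

try:  # numba is optional; the pure-python path is identical but slower
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]
    _HAVE_NUMBA = False


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronModelSpec:
    """Geometry, passive properties and channel densities."""

    soma_diam_um: float = 25.0
    n_dend: int = 4
    dend_len_um: float = 200.0
    dend_diam_um: float = 2.0
    nseg_dend: int = 2
    cm_uf_cm2: float = 1.0
    ra_ohm_cm: float = 150.0
    e_leak_mv: float = -65.0
    e_na_mv: float = 55.0
    e_k_mv: float = -70.0
    # somatic densities, mS/cm^2 (dendrites carry leak only)
    g_na: float = 250.0
    g_kht: float = 60.0
    g_klt: float = 0.5
    g_ahp: float = 0.4
    g_leak: float = 0.06
    temperature_c: float = 35.0
    # Na inactivation slowed relative to the delayed-rectifier time scale so
    # that slow synaptic summation can reach threshold before accommodating
    tauh_scale: float = 2.6
    # slow decay of the spike-triggered AHP-like K conductance
    ahp_tau_ms: float = 4.0

    def __post_init__(self):
        for name in ("g_na", "g_kht", "g_klt", "g_ahp", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SynapseSpec:
    """Double-exponential conductance synapse (somatic by default)."""

    kind: str  # "E" | "I"
    reversal_mv: float
    tau_rise_ms: float
    tau_decay_ms: float
    g_peak_ns: float  # unitary (mini) peak conductance
    location: str = "soma"


# unitary peak conductances frozen by calibration against the packaged
# mini-PSP templates (mEPSP +1.1 mV, mIPSP -0.75 mV at the soma)
DEFAULT_E_SYNAPSE = SynapseSpec("E", 0.0, 0.8, 3.0, 0.3492424)
DEFAULT_I_SYNAPSE = SynapseSpec("I", -74.0, 0.5, 3.5, 1.8484817)

# evoked (compound) synaptic weights frozen by calibration against the
# train-response contract (see `calibrate`)
DEFAULT_EVOKED_WEIGHT_E = 5.0349
DEFAULT_EVOKED_WEIGHT_I = 0.3787


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation protocol for the model neuron."""

    mode: str = "train"  # "single_psp" | "train"
    rate_hz: float = 100.0
    n_pulses: int = 20
    ei_latency_difference_ms: float = 2.8  # I onset minus E onset
    include_e: bool = True
    include_i: bool = True
    ipsp_scale: float = 1.0  # 0.51 mimics depressed inhibition
    duration_ms: float = 260.0
    dt_ms: float = 0.02
    stim_start_ms: float = 10.0

    def __post_init__(self):
        if self.dt_ms > 0.025:
            raise ValueError("dt must be <= 0.025 ms")
        if not -10.0 <= self.ei_latency_difference_ms <= 10.0:
            raise ValueError("E-I latency difference outside the +/-10 ms grid")


@dataclass
class SimResult:
    time_ms: np.ndarray
    v_soma_mv: np.ndarray
    ap_times_ms: np.ndarray  # AP peak times
    first_ap_latency_ms: float  # from the first stimulus (nan if no APs)
    ap_rate_hz: float  # over the train window n_pulses/rate
    ap_rate_sweep_hz: float  # over the full simulated sweep
    psp_peak_mv: float  # max depolarisation from rest (subthreshold measure)
    n_aps: int = 0


# --------------------------------------------------------------------------
# integrator core
# --------------------------------------------------------------------------

@njit(cache=False)
def _simulate(dt, n_steps, v, C, gL, eL, gNa, eNa, gKht, gKlt, gAhp, eK,
              parent, g_ax, phi, tauh_scale, ahp_tau,
              inc_e, inc_i, tr_e, td_e, tr_i, td_i, norm_e, norm_i,
              e_rev, i_rev, inj, soma, v_out, stride):
    nc = v.shape[0]
    # gate initial values at v0
    V = v[soma]
    m = 1.0 / (1.0 + math.exp(-(V + 38.0) / 7.0))
    h = 1.0 / (1.0 + math.exp((V + 65.0) / 6.0))
    n = (1.0 / (1.0 + math.exp(-(V + 15.0) / 5.0))) ** 0.5
    p = 1.0 / (1.0 + math.exp(-(V + 23.0) / 6.0))
    w = (1.0 / (1.0 + math.exp(-(V + 48.0) / 6.0))) ** 0.25
    z = 0.5 + 0.5 / (1.0 + math.exp((V + 71.0) / 10.0))
    q = 0.0
    aE = 0.0
    bE = 0.0
    aI = 0.0
    bI = 0.0
    dec_are = math.exp(-dt / tr_e)
    dec_bde = math.exp(-dt / td_e)
    dec_ari = math.exp(-dt / tr_i)
    dec_bdi = math.exp(-dt / td_i)
    out_i = 0
    for step in range(n_steps):
        if step % stride == 0 and out_i < v_out.shape[0]:
            v_out[out_i] = v[soma]
            out_i += 1
        # synaptic states
        aE = aE * dec_are + inc_e[step]
        bE = bE * dec_bde + inc_e[step]
        aI = aI * dec_ari + inc_i[step]
        bI = bI * dec_bdi + inc_i[step]
        gE = (bE - aE) / norm_e
        gI = (bI - aI) / norm_i

        V = v[soma]
        # gates (exponential Euler), temperature-scaled rates
        minf = 1.0 / (1.0 + math.exp(-(V + 38.0) / 7.0))
        taum = (10.0 / (5.0 * math.exp((V + 60.0) / 18.0)
                        + 36.0 * math.exp(-(V + 60.0) / 25.0)) + 0.04) / phi
        hinf = 1.0 / (1.0 + math.exp((V + 65.0) / 6.0))
        tauh = (100.0 / (7.0 * math.exp((V + 60.0) / 11.0)
                         + 10.0 * math.exp(-(V + 60.0) / 25.0)) + 0.6) \
            * tauh_scale / phi
        ninf = (1.0 / (1.0 + math.exp(-(V + 15.0) / 5.0))) ** 0.5
        taun = (100.0 / (11.0 * math.exp((V + 60.0) / 24.0)
                         + 21.0 * math.exp(-(V + 60.0) / 23.0)) + 0.7) / phi
        pinf = 1.0 / (1.0 + math.exp(-(V + 23.0) / 6.0))
        taup = (100.0 / (4.0 * math.exp((V + 60.0) / 32.0)
                         + 5.0 * math.exp(-(V + 60.0) / 22.0)) + 5.0) / phi
        winf = (1.0 / (1.0 + math.exp(-(V + 48.0) / 6.0))) ** 0.25
        tauw = (100.0 / (6.0 * math.exp((V + 60.0) / 6.0)
                         + 16.0 * math.exp(-(V + 60.0) / 45.0)) + 1.5) / phi
        zinf = 0.5 + 0.5 / (1.0 + math.exp((V + 71.0) / 10.0))
        tauz = (1000.0 / (math.exp((V + 60.0) / 20.0)
                          + math.exp(-(V + 60.0) / 8.0)) + 50.0) / phi
        # slow AHP-like K gate: activates only at spike-level voltages,
        # decays slowly below them
        qinf = 1.0 / (1.0 + math.exp(-(V + 10.0) / 4.0))
        tauq = 0.8 + (ahp_tau - 0.8) / (1.0 + math.exp((V + 30.0) / 4.0))

        m += (minf - m) * (1.0 - math.exp(-dt / taum))
        h += (hinf - h) * (1.0 - math.exp(-dt / tauh))
        n += (ninf - n) * (1.0 - math.exp(-dt / taun))
        p += (pinf - p) * (1.0 - math.exp(-dt / taup))
        w += (winf - w) * (1.0 - math.exp(-dt / tauw))
        z += (zinf - z) * (1.0 - math.exp(-dt / tauz))
        q += (qinf - q) * (1.0 - math.exp(-dt / tauq))

        # voltage update, exponential Euler with frozen neighbour voltages
        for i in range(nc):
            g_tot = gL[i]
            gE_sum = gL[i] * eL
            if i == soma:
                gna = gNa * m * m * m * h
                gkht = gKht * (0.85 * n * n + 0.15 * p)
                gklt = gKlt * (w ** 4) * z
                gahp = gAhp * q
                g_tot += gna + gkht + gklt + gahp + gE + gI
                gE_sum += (gna * eNa + (gkht + gklt + gahp) * eK
                           + gE * e_rev + gI * i_rev + inj[step])
            if parent[i] >= 0:
                g_tot += g_ax[i]
                gE_sum += g_ax[i] * v[parent[i]]
            for j in range(nc):
                if parent[j] == i:
                    g_tot += g_ax[j]
                    gE_sum += g_ax[j] * v[j]
            e_eff = gE_sum / g_tot
            v[i] = e_eff + (v[i] - e_eff) * math.exp(-dt * g_tot / C[i])
    return v_out


# --------------------------------------------------------------------------
# model object
# --------------------------------------------------------------------------

class MOCModel:
    """Integrable model instance derived from a NeuronModelSpec."""

    def __init__(self, spec: NeuronModelSpec,
                 e_syn: SynapseSpec = DEFAULT_E_SYNAPSE,
                 i_syn: SynapseSpec = DEFAULT_I_SYNAPSE,
                 evoked_weight_e: float = DEFAULT_EVOKED_WEIGHT_E,
                 evoked_weight_i: float = DEFAULT_EVOKED_WEIGHT_I):
        self.spec = spec
        self.e_syn = e_syn
        self.i_syn = i_syn
        # evoked (compound) synaptic events as multiples of the unitary g
        self.evoked_weight_e = evoked_weight_e
        self.evoked_weight_i = evoked_weight_i
        self._build()

    def _build(self):
        s = self.spec
        nc = 1 + s.n_dend * s.nseg_dend
        soma_area = math.pi * (s.soma_diam_um * 1e-4) ** 2  # sphere, cm^2
        seg_len_cm = s.dend_len_um * 1e-4 / s.nseg_dend
        seg_area = math.pi * (s.dend_diam_um * 1e-4) * seg_len_cm
        r_cm = s.dend_diam_um * 1e-4 / 2.0
        g_axial_ns = math.pi * r_cm ** 2 / (s.ra_ohm_cm * seg_len_cm) * 1e9

        self.C = np.empty(nc)
        self.gL = np.empty(nc)
        self.parent = np.full(nc, -1, dtype=np.int64)
        self.g_ax = np.zeros(nc)
        self.C[0] = s.cm_uf_cm2 * soma_area * 1e6  # pF
        self.gL[0] = s.g_leak * soma_area * 1e6  # nS
        idx = 1
        for d in range(s.n_dend):
            for k in range(s.nseg_dend):
                self.C[idx] = s.cm_uf_cm2 * seg_area * 1e6
                self.gL[idx] = s.g_leak * seg_area * 1e6
                self.parent[idx] = 0 if k == 0 else idx - 1
                self.g_ax[idx] = g_axial_ns
                idx += 1
        self.gNa = s.g_na * soma_area * 1e6
        self.gKht = s.g_kht * soma_area * 1e6
        self.gKlt = s.g_klt * soma_area * 1e6
        self.gAhp = s.g_ahp * soma_area * 1e6
        self.phi = 3.0 ** ((s.temperature_c - 22.0) / 10.0)
        self.norm_e = self._kernel_norm(self.e_syn)
        self.norm_i = self._kernel_norm(self.i_syn)

    @staticmethod
    def _kernel_norm(syn: SynapseSpec) -> float:
        tp = kernels.peak_time(syn.tau_rise_ms, syn.tau_decay_ms)
        return math.exp(-tp / syn.tau_decay_ms) - math.exp(-tp / syn.tau_rise_ms)

    def run(self, events_e, events_i, duration_ms: float, dt_ms: float = 0.02,
            record_stride: int = 5, v0: float | None = None,
            inj_pa: float = 0.0, inj_window_ms: tuple[float, float] | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
        """Integrate with the given synaptic event lists.

        ``events_e``/``events_i`` are sequences of (time_ms, weight) where the
        weight multiplies the unitary peak conductance.  ``inj_pa`` injects a
        somatic current step over ``inj_window_ms``.  Returns
        (time_ms, v_soma_mv) at ``record_stride`` x dt resolution.
        """
        n_steps = int(round(duration_ms / dt_ms))
        inc_e = np.zeros(n_steps)
        inc_i = np.zeros(n_steps)
        inj = np.zeros(n_steps)
        if inj_pa and inj_window_ms is not None:
            a = max(int(inj_window_ms[0] / dt_ms), 0)
            b = min(int(inj_window_ms[1] / dt_ms), n_steps)
            inj[a:b] = inj_pa
        for t, wgt in events_e:
            k = int(round(t / dt_ms))
            if 0 <= k < n_steps:
                inc_e[k] += wgt * self.e_syn.g_peak_ns
        for t, wgt in events_i:
            k = int(round(t / dt_ms))
            if 0 <= k < n_steps:
                inc_i[k] += wgt * self.i_syn.g_peak_ns
        nc = self.C.shape[0]
        v = np.full(nc, self.spec.e_leak_mv if v0 is None else v0)
        n_out = (n_steps + record_stride - 1) // record_stride
        v_out = np.empty(n_out)
        _simulate(dt_ms, n_steps, v, self.C, self.gL, self.spec.e_leak_mv,
                  self.gNa, self.spec.e_na_mv, self.gKht, self.gKlt, self.gAhp,
                  self.spec.e_k_mv, self.parent, self.g_ax, self.phi,
                  self.spec.tauh_scale, self.spec.ahp_tau_ms,
                  inc_e, inc_i,
                  self.e_syn.tau_rise_ms, self.e_syn.tau_decay_ms,
                  self.i_syn.tau_rise_ms, self.i_syn.tau_decay_ms,
                  self.norm_e, self.norm_i,
                  self.e_syn.reversal_mv, self.i_syn.reversal_mv,
                  inj, 0, v_out, record_stride)
        t_out = np.arange(n_out) * dt_ms * record_stride
        return t_out, v_out

    def resting_potential(self, duration_ms: float = 300.0) -> float:
        t, v = self.run([], [], duration_ms)
        return float(v[-1])


def build_model(spec: NeuronModelSpec, **kwargs) -> MOCModel:
    """Construct and sanity-check an integrable model.

    Raises if the parameter set is unstable (divergent voltage) or
    spontaneously active at rest.
    """
    model = MOCModel(spec, **kwargs)
    t, v = model.run([], [], 300.0)
    if not np.all(np.isfinite(v)):
        raise RuntimeError("unstable parameter set: voltage diverged at rest")
    if v[-1] > -40.0 or _ap_peaks(t, v).size:
        raise RuntimeError(
            f"parameter set is spontaneously active (rest {v[-1]:.1f} mV)")
    if abs(v[-1] - v[len(v) // 2]) > 0.5:
        raise RuntimeError("resting potential did not settle within 300 ms")
    return model


# --------------------------------------------------------------------------
# protocols
# --------------------------------------------------------------------------

def _ap_peaks(t: np.ndarray, v: np.ndarray, threshold: float = 0.0,
              refractory_ms: float = 1.0) -> np.ndarray:
    """AP peak times from upward threshold crossings."""
    above = v >= threshold
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    peaks = []
    last = -np.inf
    for i in idx:
        if t[i] - last < refractory_ms:
            continue
        j = i
        while j + 1 < len(v) and v[j + 1] >= v[j]:
            j += 1
        peaks.append(t[j])
        last = t[i]
    return np.asarray(peaks)


def protocol_events(model: MOCModel, protocol: ProtocolSpec):
    """Synaptic event lists (deterministic, no release failures)."""
    d = protocol.ei_latency_difference_ms
    n = 1 if protocol.mode == "single_psp" else protocol.n_pulses
    isi = 1000.0 / protocol.rate_hz
    ev_e, ev_i = [], []
    for k in range(n):
        t_e = protocol.stim_start_ms + k * isi
        if protocol.include_e:
            ev_e.append((t_e, model.evoked_weight_e))
        if protocol.include_i:
            ev_i.append((t_e + d, model.evoked_weight_i * protocol.ipsp_scale))
    return ev_e, ev_i


def simulate_protocol(model: MOCModel, protocol: ProtocolSpec) -> SimResult:
    """Run one protocol and extract AP/PSP metrics.

    The first-AP latency and the train-window AP rate are measured from the
    first (excitatory-train) stimulus time; the train window is
    n_pulses/rate.
    """
    ev_e, ev_i = protocol_events(model, protocol)
    duration = protocol.duration_ms
    if protocol.mode == "train":
        duration = max(duration,
                       protocol.stim_start_ms + protocol.n_pulses
                       * 1000.0 / protocol.rate_hz + 50.0)
    t, v = model.run(ev_e, ev_i, duration, protocol.dt_ms)
    aps = _ap_peaks(t, v)
    t0 = protocol.stim_start_ms
    train_win = protocol.n_pulses * 1000.0 / protocol.rate_hz
    in_train = aps[(aps >= t0) & (aps < t0 + train_win)] if len(aps) else aps
    rest = v[int(0.9 * t0 / (t[1] - t[0]))] if t0 > 0 else v[0]
    return SimResult(
        time_ms=t, v_soma_mv=v, ap_times_ms=aps,
        first_ap_latency_ms=float(aps[0] - t0) if len(aps) else float("nan"),
        ap_rate_hz=len(in_train) / (train_win / 1000.0) if train_win else 0.0,
        ap_rate_sweep_hz=len(aps) / (t[-1] / 1000.0),
        psp_peak_mv=float(v.max() - rest), n_aps=len(aps))


def sweep_ei_latency(model: MOCModel, grid=None, ipsp_scale: float = 1.0,
                     rate_hz: float = 100.0, n_pulses: int = 20,
                     dt_ms: float = 0.02) -> pd.DataFrame:
    """Fig-8C-style sweep: one train per E-I latency difference grid point."""
    if grid is None:
        grid = np.arange(-10, 11)
    rows = []
    for d in sorted(grid):
        if not -10 <= d <= 10:
            raise ValueError("grid outside [-10, +10] ms")
        res = simulate_protocol(model, ProtocolSpec(
            mode="train", rate_hz=rate_hz, n_pulses=n_pulses,
            ei_latency_difference_ms=float(d), ipsp_scale=ipsp_scale,
            dt_ms=dt_ms))
        rows.append(dict(ei_diff_ms=float(d),
                         first_ap_latency_ms=res.first_ap_latency_ms,
                         ap_rate_hz=res.ap_rate_hz, n_aps=res.n_aps))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# calibration contract
# --------------------------------------------------------------------------

def mpsp_templates(dt_ms: float = 0.02, duration_ms: float = 60.0):
    """Packaged synthetic mini-PSP target waveforms (labelled synthetic).

    Difference-of-exponentials voltage waveforms standing in for recorded
    mini-EPSP/mini-IPSP averages: mEPSP +1.1 mV peak (rise ~1.4 ms, decay
    ~12 ms), mIPSP -0.75 mV peak (rise ~2 ms, decay ~15 ms).
    """
    t = np.arange(int(duration_ms / dt_ms)) * dt_ms
    e = 1.1 * kernels.evaluate(t - 5.0, 1.0, 12.0)
    i = -0.75 * kernels.evaluate(t - 5.0, 1.5, 15.0)
    return dict(time_ms=t, mepsp_mv=e, mipsp_mv=i)


@dataclass
class CalibrationReport:
    mepsp_peak_mv: float
    mipsp_peak_mv: float
    mepsp_target_mv: float
    mipsp_target_mv: float
    mepsp_rms_mv: float
    mipsp_rms_mv: float
    control_first_ap_ms: float
    eonly_first_ap_ms: float
    eonly_rate_hz: float
    targets: dict
    within_tolerance: bool


TRAIN_TARGETS = dict(control_first_ap_ms=38.5, eonly_first_ap_ms=24.4,
                     eonly_rate_hz=31.5)


def _mini_psp(model: MOCModel, kind: str, dt=0.02):
    ev = [(20.0, 1.0)]
    t, v = model.run(ev if kind == "E" else [], [] if kind == "E" else ev,
                     90.0, dt)
    rest = v[int(15.0 / (t[1] - t[0]))]
    dev = v - rest
    return t, dev if kind == "E" else dev


def calibrate(model: MOCModel, targets: dict | None = None,
              tol_mpsp: float = 0.10, tol_train: float = 0.10) -> tuple[MOCModel, CalibrationReport]:
    """Tune synaptic conductances against the calibration contract.

    1. Unitary E/I peak conductances are scaled (bisection) until the model's
       mini-PSP peaks match the packaged templates.
    2. The evoked excitatory weight is tuned so the E-only 100 Hz train first
       AP matches its target; the evoked inhibitory weight so the control
       train (E-I difference +2.8 ms) first AP matches its target.

    Failure to reach tolerance is reported, not raised: the report carries
    the residuals and ``within_tolerance``.
    """
    targets = dict(TRAIN_TARGETS, **(targets or {}))
    tmpl = mpsp_templates()
    te = float(np.max(tmpl["mepsp_mv"]))
    ti = float(np.min(tmpl["mipsp_mv"]))

    def mini_peak(m, kind):
        t, dev = _mini_psp(m, kind)
        return float(dev.max() if kind == "E" else dev.min())

    m = model
    # 1. unitary conductances (mini peaks scale monotonically with g_peak)
    for kind, target in (("E", te), ("I", ti)):
        lo, hi = 0.01, 50.0
        for _ in range(40):
            mid = math.sqrt(lo * hi)
            syn = replace(m.e_syn if kind == "E" else m.i_syn, g_peak_ns=mid)
            mm = MOCModel(m.spec,
                          e_syn=syn if kind == "E" else m.e_syn,
                          i_syn=syn if kind == "I" else m.i_syn,
                          evoked_weight_e=m.evoked_weight_e,
                          evoked_weight_i=m.evoked_weight_i)
            peak = mini_peak(mm, kind)
            if abs(peak) < abs(target):
                lo = mid
            else:
                hi = mid
        m = mm

    # 2a. evoked excitatory weight: bisection on the E-only first-AP latency
    # (monotone: stronger excitation -> earlier first AP)
    def eonly_first_ap(we):
        mm = MOCModel(m.spec, m.e_syn, m.i_syn, we, m.evoked_weight_i)
        res = simulate_protocol(mm, ProtocolSpec(include_i=False))
        return res.first_ap_latency_ms, mm

    lo, hi = 0.3 / m.e_syn.g_peak_ns, 40.0 / m.e_syn.g_peak_ns
    for _ in range(28):
        mid = math.sqrt(lo * hi)
        lat, mm = eonly_first_ap(mid)
        if math.isnan(lat) or lat > targets["eonly_first_ap_ms"]:
            lo = mid  # too weak -> later (or no) first AP
        else:
            hi = mid
    m = mm

    # 2b. evoked inhibitory weight: deterministic grid search choosing the
    # candidate closest to the control first-AP target among those that keep
    # the E-I latency sweep in its contracted regime (min 4 / max 5 APs over
    # the 200 ms train window).  The first-AP latency is not monotone in the
    # inhibitory weight once spike/stimulus lockings rearrange, so a bounded
    # grid is more robust than bisection here.
    t_ctrl = targets["control_first_ap_ms"]
    best = None
    for g_abs in np.arange(0.40, 1.00, 0.02):
        wi = float(g_abs) / m.i_syn.g_peak_ns
        mm = MOCModel(m.spec, m.e_syn, m.i_syn, m.evoked_weight_e, wi)
        lat = simulate_protocol(mm, ProtocolSpec()).first_ap_latency_ms
        if math.isnan(lat) or abs(lat - t_ctrl) > 0.1 * t_ctrl:
            continue
        counts = sweep_ei_latency(mm).n_aps.values
        if counts.min() != 4 or counts.max() != 5:
            continue
        score = abs(lat - t_ctrl)
        if best is None or score < best[0]:
            best = (score, mm)
    if best is not None:
        m = best[1]
    else:  # fall back to plain bisection on the control latency
        lo, hi = 0.05 / m.i_syn.g_peak_ns, 5.0 / m.i_syn.g_peak_ns
        for _ in range(28):
            mid = math.sqrt(lo * hi)
            mm = MOCModel(m.spec, m.e_syn, m.i_syn, m.evoked_weight_e, mid)
            lat = simulate_protocol(mm, ProtocolSpec()).first_ap_latency_ms
            if math.isnan(lat) or lat > t_ctrl:
                hi = mid
            else:
                lo = mid
        m = mm

    # residual report
    t_e, dev_e = _mini_psp(m, "E")
    t_i, dev_i = _mini_psp(m, "I")
    n = min(len(dev_e), len(tmpl["mepsp_mv"]))
    # align template (event at 5 ms) to model (event at 20 ms)
    shift = int(15.0 / (t_e[1] - t_e[0]))
    me = dev_e[shift:shift + n - shift]
    mi = dev_i[shift:shift + n - shift]
    ke = tmpl["mepsp_mv"][:len(me)]
    ki = tmpl["mipsp_mv"][:len(mi)]
    res_c = simulate_protocol(m, ProtocolSpec())
    res_e = simulate_protocol(m, ProtocolSpec(include_i=False))
    rep = CalibrationReport(
        mepsp_peak_mv=float(dev_e.max()), mipsp_peak_mv=float(dev_i.min()),
        mepsp_target_mv=te, mipsp_target_mv=ti,
        mepsp_rms_mv=float(np.sqrt(np.mean((me - ke) ** 2))),
        mipsp_rms_mv=float(np.sqrt(np.mean((mi - ki) ** 2))),
        control_first_ap_ms=res_c.first_ap_latency_ms,
        eonly_first_ap_ms=res_e.first_ap_latency_ms,
        eonly_rate_hz=res_e.ap_rate_hz,
        targets=targets,
        within_tolerance=bool(
            abs(dev_e.max() - te) <= tol_mpsp * abs(te)
            and abs(dev_i.min() - ti) <= tol_mpsp * abs(ti)
            and abs(res_c.first_ap_latency_ms - targets["control_first_ap_ms"])
            <= tol_train * targets["control_first_ap_ms"]
            and abs(res_e.first_ap_latency_ms - targets["eonly_first_ap_ms"])
            <= tol_train * targets["eonly_first_ap_ms"]
            and abs(res_e.ap_rate_hz - targets["eonly_rate_hz"])
            <= tol_train * targets["eonly_rate_hz"]))
    return m, rep
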