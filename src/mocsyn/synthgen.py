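"""Synthetic voltage-clamp, current-clamp and calcium data with ground truth.

The generator emulates the statistical structure of evoked synaptic recordings
from MOC neurons: stimulus-locked PSC trains organised in latency clusters with
Gaussian onset jitter, difference-of-exponentials event kinetics, per-cluster
release probability, chloride-reversal-dependent polarity across holding
potentials (-60 vs 0 mV), current-clamp PSP summation with a threshold-crossing
spike surrogate, and stimulus-locked calcium transients with pharmacological
suppression.  Every generator is fully determined by its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kernels, params
from .detect import Sweep


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """Generative parameters of one latency-defined PSC cluster."""

    kind: str  # "excitatory" | "inhibitory"
    latency_mean: float  # ms from stimulus
    latency_sd: float  # ms onset jitter
    rise_mean: float  # ms 10-90%
    tau_mean: float  # ms fitted decay constant
    amp_mean: float  # pA at -60 mV (negative = inward)
    amp_cv: float
    probability: float  # per-sweep release probability
    kinetics_cv: float = 0.10  # event-to-event scaling of rise & tau

    def __post_init__(self):
        if self.kind not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown cluster kind {self.kind!r}")
        if self.latency_mean <= 0:
            raise ValueError("latency_mean must be positive")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if not self.rise_mean < self.tau_mean:
            raise ValueError("rise_mean must be smaller than tau_mean")
        if self.amp_cv < 0:
            raise ValueError("amp_cv must be non-negative")


@dataclass(frozen=True)
class RecordingSpec:
    """One synthetic voltage-clamp session (one cell)."""

    clusters: tuple[ClusterSpec, ...]
    n_sweeps: int = params.MDL_N_SWEEPS
    stim_time: float = params.STIM_TIME_MS
    holding_potentials: tuple[float, ...] = (-60.0, 0.0)
    noise_sd: float = params.NOISE_SD_PA
    ecl: float = params.ECL_MV
    seed: int = 0
    duration_ms: float = params.SWEEP_DURATION_MS
    fs_khz: float = params.FS_KHZ

    def __post_init__(self):
        if len(self.clusters) == 0:
            raise ValueError("cluster list must not be empty")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if not 0.0 < self.stim_time < self.duration_ms:
            raise ValueError("stim_time must lie inside the sweep window")
        if not set(self.holding_potentials) <= {-60.0, 0.0}:
            raise ValueError("holding potentials must be a subset of {-60, 0} mV")


@dataclass(frozen=True)
class TrainSpec:
    """Current-clamp stimulus-train protocol."""

    rates: tuple[float, ...] = (10.0, 50.0, 100.0, 200.0)
    n_pulses: int = 20
    with_inhibition: bool = True
    n_repeats: int = 5

    def __post_init__(self):
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be positive")
        if self.n_pulses < 0:
            raise ValueError("n_pulses must be >= 0")


@dataclass(frozen=True)
class PSPParams:
    """Kernel amplitudes/kinetics for the current-clamp PSP surrogate."""

    epsp_amp: float = 5.0  # mV
    epsp_rise: float = 1.0  # ms
    epsp_tau: float = 25.0  # ms
    ipsp_amp: float = -1.3  # mV
    ipsp_rise: float = 1.5  # ms
    ipsp_tau: float = 30.0  # ms
    ei_latency_difference: float = 2.8  # ms, IPSP onset lag after EPSP
    rest_mv: float = -60.0
    threshold_mv: float = -47.0
    refractory_ms: float = 5.0
    noise_sd_mv: float = 0.4


@dataclass(frozen=True)
class CalciumSpec:
    """Synthetic ROI-fluorescence experiment (control / drug / wash)."""

    n_rois: int = 50
    baseline_f: float = 100.0  # a.u.
    evoked_dff: float = 0.4
    drug_scale: float = 0.32  # fraction of the control response left in drug
    active_fraction: float = 227 / 388
    noise_sd: float = 1.0  # a.u.
    seed: int = 0
    n_bouts: int = 3
    fs_hz: float = 30.0
    duration_s: float = 30.0
    decay_s: float = 0.6  # GCaMP6f-like transient decay
    rise_s: float = 0.07

    def __post_init__(self):
        if not 0.0 <= self.drug_scale <= 1.0:
            raise ValueError("drug_scale must lie in [0, 1]")
        if self.baseline_f <= 0:
            raise ValueError("baseline_f must be positive")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CellInput:
    """One cohort cell: archetype bookkeeping plus its recording spec."""

    cell_id: str
    archetype: str
    age_days: int
    stim_site: str  # "MdL" | "AN"
    spec: RecordingSpec


MIN_LATENCY_MS = 0.1  # physiological floor; negative draws are resampled


# --------------------------------------------------------------------------
# voltage clamp
# --------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, low):
    """Draw one Normal(mean, sd) sample, resampling below ``low``."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= low:
            return x
    return low


def generate_voltage_clamp(spec: RecordingSpec):
    """Generate sweep sets per holding potential plus ground truth.

    Returns ``(sweeps, truth)`` where ``sweeps`` maps holding potential (mV)
    to a list of :class:`~mocsyn.detect.Sweep` and ``truth`` is a DataFrame
    with one row per emitted event (sweep, holding, cluster, kind, onset,
    amplitude).  At 0 mV — the AMPA reversal potential — excitatory clusters
    emit nothing and inhibitory events are outward, scaled by the chloride
    driving force (V - E_Cl)/(-60 - E_Cl).
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration_ms * spec.fs_khz))
    t = np.arange(n_samples) / spec.fs_khz

    taus = [kernels.solve_taus(c.rise_mean, c.tau_mean) for c in spec.clusters]

    sweeps: dict[float, list[Sweep]] = {}
    rows = []
    for holding in spec.holding_potentials:
        drive = (holding - spec.ecl) / (-60.0 - spec.ecl)
        hv = []
        for s in range(spec.n_sweeps):
            current = rng.normal(0.0, spec.noise_sd, n_samples)
            for ci, (c, (tr, td)) in enumerate(zip(spec.clusters, taus)):
                if holding == 0.0 and c.kind == "excitatory":
                    continue  # invisible at the AMPA reversal potential
                if rng.random() >= c.probability:
                    continue
                onset = _truncated_normal(rng, c.latency_mean, c.latency_sd, MIN_LATENCY_MS)
                if c.amp_cv > 0:
                    sigma = math.sqrt(math.log(1.0 + c.amp_cv**2))
                    amp_scale = rng.lognormal(-sigma**2 / 2.0, sigma)
                else:
                    amp_scale = 1.0
                kin_scale = rng.lognormal(0.0, c.kinetics_cv) if c.kinetics_cv > 0 else 1.0
                amp = c.amp_mean * amp_scale * drive
                current += kernels.event_waveform(
                    t, spec.stim_time + onset, amp, tr * kin_scale, td * kin_scale)
                rows.append(dict(sweep_id=s, holding=holding, cluster_id=ci,
                                 kind=c.kind, onset=onset, amplitude=amp))
            hv.append(Sweep(current=current, fs_khz=spec.fs_khz,
                            stim_time=spec.stim_time, holding=holding, sweep_id=s))
        sweeps[holding] = hv

    truth = pd.DataFrame(rows, columns=["sweep_id", "holding", "cluster_id",
                                        "kind", "onset", "amplitude"])
    return sweeps, truth


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def _truncnorm_interval(rng, mean, sd, low, high):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return x
    return min(max(mean, low), high)


def _cluster(kind: str, latency: float, kin: params.KineticsRow) -> ClusterSpec:
    return ClusterSpec(kind=kind, latency_mean=max(latency, MIN_LATENCY_MS + 0.2),
                       latency_sd=kin.latency_sd, rise_mean=kin.rise_mean,
                       tau_mean=kin.tau_mean, amp_mean=kin.amp_mean,
                       amp_cv=kin.amp_cv, probability=kin.probability)


def sample_archetype_clusters(archetype: str, stim_site: str, rng) -> tuple[ClusterSpec, ...]:
    """Draw the cluster set of one cell of the given archetype.

    MdL archetypes: ``e_only``, ``i_only``, ``mixed`` (one E + one I separated
    by the E-I latency difference), ``complex`` (2 E + 2 I).  AN archetypes:
    ``complex_both``, ``complex_e``, ``e_only``, ``i_only``; for AN cells the
    *earlier* first cluster carries the 5.51 ms pathway latency and the E-I
    difference (I - E, positive = excitation leads) decides which class leads.
    """
    if stim_site == "MdL":
        E, I = params.MDL_KINETICS["E"], params.MDL_KINETICS["I"]
        base = _truncated_normal(rng, params.MDL_E_LATENCY_MEAN,
                                 params.CELL_LATENCY_SD, 0.8)
        if archetype == "e_only":
            return (_cluster("excitatory", base, E),)
        if archetype == "i_only":
            lat = _truncated_normal(rng, params.MDL_I_ONLY_LATENCY,
                                    params.CELL_LATENCY_SD, 0.8)
            return (_cluster("inhibitory", lat, I),)
        diff = _truncated_normal(rng, params.MDL_EI_DIFF_MEAN, params.MDL_EI_DIFF_SD, 0.8)
        if archetype == "mixed":
            return (_cluster("excitatory", base, E),
                    _cluster("inhibitory", base + diff, I))
        if archetype == "complex":
            return (_cluster("excitatory", base, E),
                    _cluster("excitatory", base + params.MDL_SECOND_E_OFFSET, E),
                    _cluster("inhibitory", base + diff, I),
                    _cluster("inhibitory", base + diff + params.MDL_SECOND_I_OFFSET, I))
        raise ValueError(f"unknown MdL archetype {archetype!r}")

    if stim_site == "AN":
        E, I = params.AN_KINETICS["E"], params.AN_KINETICS["I"]
        first = _truncated_normal(rng, params.AN_FIRST_LATENCY_MEAN,
                                  params.AN_FIRST_LATENCY_SD, 2.0)
        if archetype == "e_only":
            return (_cluster("excitatory", first, E),)
        if archetype == "i_only":
            return (_cluster("inhibitory", first, I),)
        if archetype == "complex_e":
            return (_cluster("excitatory", first, E),
                    _cluster("excitatory", first + params.AN_SECOND_OFFSET, E))
        if archetype == "complex_both":
            lo, hi = params.AN_EI_DIFF_RANGE
            diff = _truncnorm_interval(rng, params.AN_EI_DIFF_MEAN,
                                       params.AN_EI_DIFF_SD, lo, hi)
            e1 = first if diff >= 0 else first + abs(diff)
            i1 = first + diff if diff >= 0 else first
            return (_cluster("excitatory", e1, E),
                    _cluster("inhibitory", i1, I),
                    _cluster("excitatory", e1 + params.AN_SECOND_OFFSET, E),
                    _cluster("inhibitory", i1 + params.AN_SECOND_OFFSET + 0.4, I))
        raise ValueError(f"unknown AN archetype {archetype!r}")

    raise ValueError(f"unknown stim site {stim_site!r}")


def generate_cohort(population_table, n_cells: int, seed: int, *,
                    stim_site: str = "MdL",
                    n_sweeps: int | None = None,
                    holding_potentials: tuple[float, ...] = (-60.0, 0.0),
                    noise_sd: float = params.NOISE_SD_PA) -> list[CellInput]:
    """Draw ``n_cells`` independent recording sessions from an archetype table.

    ``population_table`` is a sequence of :class:`~mocsyn.params.ArchetypeRow`
    (or (name, frequency) pairs); frequencies must sum to 1.  Each cell gets an
    independent child seed so that per-cell generation streams are disjoint
    while the archetype bookkeeping depends only on (table, n_cells, seed).
    """
    names = [r.name if hasattr(r, "name") else r[0] for r in population_table]
    freqs = np.array([r.frequency if hasattr(r, "frequency") else r[1]
                      for r in population_table], float)
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError(f"archetype frequencies must sum to 1 (got {freqs.sum()})")

    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(names), size=n_cells, p=freqs)
    ages = rng.integers(params.AGE_RANGE_DAYS[0], params.AGE_RANGE_DAYS[1] + 1,
                        size=n_cells)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_cells)

    if n_sweeps is None:
        n_sweeps = params.MDL_N_SWEEPS if stim_site == "MdL" else params.AN_N_SWEEPS

    duration = params.SWEEP_DURATION_MS if stim_site == "MdL" else params.SWEEP_DURATION_MS + 10.0
    cells = []
    for i in range(n_cells):
        cell_rng = np.random.default_rng(int(child_seeds[i]))
        clusters = sample_archetype_clusters(names[assignment[i]], stim_site, cell_rng)
        spec = RecordingSpec(clusters=clusters, n_sweeps=n_sweeps,
                             holding_potentials=holding_potentials,
                             noise_sd=noise_sd,
                             seed=int(cell_rng.integers(0, 2**31 - 1)),
                             duration_ms=duration)
        cells.append(CellInput(cell_id=f"{stim_site}_{i:03d}",
                               archetype=names[assignment[i]],
                               age_days=int(ages[i]), stim_site=stim_site,
                               spec=spec))
    return cells


# --------------------------------------------------------------------------
# current clamp
# --------------------------------------------------------------------------

def generate_current_clamp(train: TrainSpec, psp: PSPParams = PSPParams(), seed: int = 0):
    """Stimulus-locked PSP-train voltage sweeps with a spike surrogate.

    EPSP (and optionally IPSP) difference-of-exponentials kernels are summed
    linearly on a 20 kHz grid; whenever the subthreshold sum crosses
    ``psp.threshold_mv`` outside the refractory window a stereotyped AP
    waveform is superimposed and the crossing time recorded as ground truth.

    Returns ``(sweeps, truth)``: ``sweeps`` maps rate (Hz) to a list of
    ``(time_ms, voltage_mv)`` arrays, ``truth`` maps rate to a list (per
    repeat) of injected AP times (ms).
    """
    rng = np.random.default_rng(seed)
    fs = 20.0  # kHz
    e_tr, e_td = kernels.solve_taus(psp.epsp_rise, psp.epsp_tau)
    i_tr, i_td = kernels.solve_taus(psp.ipsp_rise, psp.ipsp_tau)

    sweeps: dict[float, list[tuple[np.ndarray, np.ndarray]]] = {}
    truth: dict[float, list[list[float]]] = {}
    stim0 = 10.0
    for rate in train.rates:
        isi = 1000.0 / rate
        duration = stim0 + max(train.n_pulses, 1) * isi + 100.0
        n = int(duration * fs)
        t = np.arange(n) / fs
        stim_times = stim0 + np.arange(train.n_pulses) * isi
        sweeps[rate] = []
        truth[rate] = []
        for _ in range(train.n_repeats):
            # smoothed noise resembling membrane noise (reflect padding keeps
            # the sweep edges artifact-free)
            from scipy import ndimage
            noise = ndimage.gaussian_filter1d(
                rng.normal(0.0, psp.noise_sd_mv, n), 2.0, mode="reflect")
            v = psp.rest_mv + noise
            for st in stim_times:
                a = psp.epsp_amp * rng.lognormal(0.0, 0.1)
                v += kernels.event_waveform(t, st, a, e_tr, e_td)
                if train.with_inhibition:
                    ai = psp.ipsp_amp * rng.lognormal(0.0, 0.1)
                    v += kernels.event_waveform(
                        t, st + psp.ei_latency_difference, ai, i_tr, i_td)
            # refractory-limited tonic firing while the subthreshold sum sits
            # above threshold (integrate-and-fire-like surrogate)
            ap_times = []
            last = -np.inf
            for idx in np.flatnonzero(v >= psp.threshold_mv):
                tt = t[idx]
                if tt - last < psp.refractory_ms:
                    continue
                last = tt
                ap_times.append(float(tt))
            for tt in ap_times:
                # stereotyped spike: fast gaussian to +25 mV
                v += (25.0 - psp.threshold_mv) * np.exp(-0.5 * ((t - tt) / 0.25) ** 2)
            sweeps[rate].append((t, v))
            truth[rate].append(ap_times)
    return sweeps, truth


# --------------------------------------------------------------------------
# calcium
# --------------------------------------------------------------------------

def generate_calcium(spec: CalciumSpec) -> pd.DataFrame:
    """ROI fluorescence traces for conditions control / drug / wash.

    Active ROIs carry stimulus-locked transients of peak amplitude
    ``evoked_dff × baseline_f`` in control and wash, scaled by ``drug_scale``
    in the drug condition; inactive ROIs carry noise only.  Returns a tidy
    DataFrame (roi_id, condition, active_true, time_s, fluorescence) plus
    stimulus epochs in ``df.attrs['epochs']``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration_s * spec.fs_hz)
    t = np.arange(n) / spec.fs_hz
    bout_starts = np.linspace(8.0, spec.duration_s - 8.0, spec.n_bouts)
    epochs = [(s, s + 2.0) for s in bout_starts]

    active = rng.random(spec.n_rois) < spec.active_fraction
    # GCaMP-like transient: fast rise, slower decay, unit peak
    tr, td = kernels.solve_taus(spec.rise_s, spec.decay_s)

    frames = []
    for cond, scale in (("control", 1.0), ("drug", spec.drug_scale), ("wash", 1.0)):
        for roi in range(spec.n_rois):
            f0 = spec.baseline_f * rng.lognormal(0.0, 0.05)
            f = f0 + rng.normal(0.0, spec.noise_sd, n)
            if active[roi]:
                amp = spec.evoked_dff * f0 * scale * rng.lognormal(0.0, 0.1)
                for start, _ in epochs:
                    f += amp * kernels.event_waveform(t, start + 0.1, 1.0, tr, td)
            frames.append(pd.DataFrame(dict(
                roi_id=roi, condition=cond, active_true=bool(active[roi]),
                time_s=t, fluorescence=f)))
    df = pd.concat(frames, ignore_index=True)
    df.attrs["epochs"] = epochs
    return df
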