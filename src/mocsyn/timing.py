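"""E-I timing statistics, nonparametric comparisons, and AP metrics.

Sign convention (fixed and used everywhere): the E-I latency difference is

    ei_latency_difference = first_I_latency - first_E_latency,

so a *positive* value means excitation precedes inhibition.  With midline
stimulation the mono-synaptic excitatory pathway always leads (differences
near +2.8 ms); with auditory-nerve stimulation the fast cochlear-nucleus
inhibitory circuitry compensates for its extra synapse and differences
straddle zero (negative values = inhibition first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import PSCCluster, RecordingSession


@dataclass
class CellTimingSummary:
    """First-cluster timing statistics of one cell."""

    cell_id: str
    stim_site: str
    first_e_latency: float  # ms (nan if no excitatory cluster)
    first_i_latency: float  # ms (nan if no inhibitory cluster)
    ei_latency_difference: float  # ms, I - E (nan if either missing)
    first_e_jitter: float
    first_i_jitter: float
    first_e_prob: float
    first_i_prob: float


@dataclass
class APMetrics:
    """Spike metrics of one train-stimulation sweep set."""

    ap_probability: float  # fraction of sweeps with >= 1 AP
    ap_rate: float  # Hz, mean APs per sweep / train window
    n_stims_to_first_ap: float  # mean over AP-bearing sweeps
    first_ap_latency: float  # ms from first stimulus, mean over AP-bearing sweeps
    n_sweeps: int = 0
    ap_times: list = None  # per sweep


def ei_latency_difference(first_e_latency: float, first_i_latency: float) -> float:
    """I minus E first-cluster latency; positive = excitation leads."""
    if not (np.isfinite(first_e_latency) and np.isfinite(first_i_latency)):
        return float("nan")
    return first_i_latency - first_e_latency


def summarize_cell(session: RecordingSession, holding: float = -60.0) -> CellTimingSummary:
    """First-E / first-I cluster latencies, jitters and probabilities."""
    clusters = session.clusters.get(holding, [])
    # micro-clusters cannot anchor a first-latency estimate
    solid = [c for c in clusters if len(c.member_ids) >= 3] or clusters
    first = {}
    for kind in ("excitatory", "inhibitory"):
        cands = [c for c in solid if c.label == kind]
        first[kind] = min(cands, key=lambda c: c.latency_mu) if cands else None
    e, i = first["excitatory"], first["inhibitory"]
    return CellTimingSummary(
        cell_id=session.cell_id, stim_site=session.stim_site,
        first_e_latency=e.latency_mu if e else float("nan"),
        first_i_latency=i.latency_mu if i else float("nan"),
        ei_latency_difference=ei_latency_difference(
            e.latency_mu if e else float("nan"),
            i.latency_mu if i else float("nan")),
        first_e_jitter=e.onset_jitter if e else float("nan"),
        first_i_jitter=i.onset_jitter if i else float("nan"),
        first_e_prob=e.probability if e else float("nan"),
        first_i_prob=i.probability if i else float("nan"))


def population_table(summaries: list[CellTimingSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


# --------------------------------------------------------------------------
# nonparametric comparisons
# --------------------------------------------------------------------------

def compare_groups(sample_a, sample_b=None, test: str = "mann_whitney_u"):
    """Two-sided nonparametric comparison; exact methods where available.

    ``mann_whitney_u``: independent samples a vs b.
    ``wilcoxon_one_sample``: a against zero (b ignored); an all-zero sample
    degenerates — reported as (0, 1.0) with a flag in the third return slot.
    ``friedman``: repeated measures, ``sample_a`` is an (n_subjects, k) array.

    Returns (statistic, p, flag) where flag marks degenerate inputs.
    """
    a = np.asarray(sample_a, dtype=float)
    if test == "mann_whitney_u":
        b = np.asarray(sample_b, dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise ValueError("need n >= 3 per group")
        method = "exact" if max(len(a), len(b)) <= 25 else "auto"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue), False
    if test == "wilcoxon_one_sample":
        if len(a) < 3:
            raise ValueError("need n >= 3")
        nz = a[a != 0]
        if len(nz) == 0:
            return 0.0, 1.0, True  # all-zero differences: test degenerates
        res = stats.wilcoxon(a, alternative="two-sided",
                             method="exact" if len(a) <= 25 else "auto",
                             zero_method="wilcox")
        return float(res.statistic), float(res.pvalue), False
    if test == "friedman":
        mat = np.atleast_2d(a)
        if mat.shape[0] < 3 or mat.shape[1] < 3:
            raise ValueError("friedman needs >= 3 subjects and >= 3 conditions")
        res = stats.friedmanchisquare(*(mat[:, j] for j in range(mat.shape[1])))
        return float(res.statistic), float(res.pvalue), False
    raise ValueError(f"unknown test {test!r}")


# --------------------------------------------------------------------------
# AP metrics from current-clamp trains
# --------------------------------------------------------------------------

def detect_aps(time_ms: np.ndarray, v_mv: np.ndarray, threshold: float = 0.0,
               refractory_ms: float = 1.0) -> np.ndarray:
    """AP peak times: upward threshold crossings (refractory-gated), each
    resolved to the following local voltage maximum."""
    above = v_mv >= threshold
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    out = []
    last = -np.inf
    for i in idx:
        if time_ms[i] - last < refractory_ms:
            continue
        last = time_ms[i]
        j = i
        while j + 1 < len(v_mv) and v_mv[j + 1] >= v_mv[j]:
            j += 1
        out.append(time_ms[j])
    return np.asarray(out)


def ap_metrics(sweeps, stim_times_ms, rate_hz: float, n_pulses: int, *,
               threshold: float = 0.0, refractory_ms: float = 1.0,
               window: str = "train") -> APMetrics:
    """Spike metrics over a train-stimulation sweep set.

    ``sweeps`` is a list of (time_ms, voltage_mv) arrays.  ``window`` chooses
    the AP-rate denominator: "train" = n_pulses/rate starting at the first
    stimulus (default), "sweep" = the full sweep duration.
    """
    stim_times_ms = np.asarray(stim_times_ms, dtype=float)
    t0 = stim_times_ms[0] if stim_times_ms.size else 0.0
    train_win_ms = n_pulses * 1000.0 / rate_hz if rate_hz > 0 else 0.0

    all_counts, first_lats, first_nstims, per_sweep = [], [], [], []
    for time_ms, v in sweeps:
        aps = detect_aps(np.asarray(time_ms), np.asarray(v), threshold, refractory_ms)
        per_sweep.append(aps)
        if window == "train" and train_win_ms > 0:
            in_win = aps[(aps >= t0) & (aps < t0 + train_win_ms)]
            denom_s = train_win_ms / 1000.0
        else:
            in_win = aps
            denom_s = (time_ms[-1] - time_ms[0]) / 1000.0
        all_counts.append(len(in_win) / denom_s if denom_s > 0 else 0.0)
        if len(aps):
            first_lats.append(aps[0] - t0)
            first_nstims.append(int(np.sum(stim_times_ms <= aps[0])))
    n = len(sweeps)
    with_ap = len(first_lats)
    return APMetrics(
        ap_probability=with_ap / n if n else 0.0,
        ap_rate=float(np.mean(all_counts)) if all_counts else 0.0,
        n_stims_to_first_ap=float(np.mean(first_nstims)) if first_nstims else float("nan"),
        first_ap_latency=float(np.mean(first_lats)) if first_lats else float("nan"),
        n_sweeps=n, ap_times=per_sweep)
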