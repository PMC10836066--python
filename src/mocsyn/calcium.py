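"""ROI calcium-fluorescence analysis: dF/F, activity, pharmacological suppression.

Used to verify that electrical stimulation of the auditory nerve root excites
cochlear-nucleus bushy cells synaptically (glutamate-receptor blockers should
suppress the stimulus-locked somatic calcium signal) rather than electrically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class CalciumParams:
    active_threshold_sd: float = 3.0  # k x baseline dF/F SD
    evoked_mode: str = "peak"  # "peak" | "mean" within the epoch
    # light enough not to attenuate a GCaMP6f-speed transient peak
    smooth_s: float = 0.04
    baseline_window_s: float = 4.0  # pre-epoch window for F0


def dff(time_s: np.ndarray, f: np.ndarray, epoch: tuple[float, float],
        p: CalciumParams = CalciumParams()) -> float:
    """(F_evoked - F0) / F0 for one stimulus epoch.

    F0 is the mean over ``baseline_window_s`` immediately before the epoch;
    F_evoked is the peak (default) or mean of the lightly smoothed trace
    within the epoch.
    """
    time_s = np.asarray(time_s, float)
    f = np.asarray(f, float)
    start, end = epoch
    if start <= time_s[0]:
        raise ValueError("no pre-epoch baseline available")
    base_mask = (time_s >= start - p.baseline_window_s) & (time_s < start)
    f0 = float(np.mean(f[base_mask]))
    if f0 <= 0:
        raise ValueError("non-positive baseline fluorescence")
    dt = np.median(np.diff(time_s))
    fs = ndimage.gaussian_filter1d(f, max(p.smooth_s / dt, 1e-9))
    ep = fs[(time_s >= start) & (time_s <= end)]
    evoked = float(ep.max() if p.evoked_mode == "peak" else ep.mean())
    return (evoked - f0) / f0


def roi_dff_table(traces: pd.DataFrame, epochs=None,
                  p: CalciumParams = CalciumParams()) -> pd.DataFrame:
    """Per-ROI, per-condition mean dF/F over stimulation bouts.

    ``traces`` is tidy (roi_id, condition, time_s, fluorescence) with stimulus
    epochs either passed explicitly or read from ``traces.attrs['epochs']``.
    Also returns the per-ROI baseline dF/F SD (noise floor for the activity
    criterion) estimated from bout-free segments.
    """
    if epochs is None:
        epochs = traces.attrs.get("epochs")
    if not epochs:
        raise ValueError("no stimulus epochs given")
    rows = []
    for (roi, cond), g in traces.groupby(["roi_id", "condition"], sort=True):
        t = g["time_s"].to_numpy()
        f = g["fluorescence"].to_numpy()
        vals = [dff(t, f, ep, p) for ep in epochs]
        # noise floor: apply the same evoked measure to sham epochs carved
        # out of the stimulus-free head of the trace
        f0 = float(np.mean(f[t < epochs[0][0]]))
        dt = np.median(np.diff(t))
        fsm = ndimage.gaussian_filter1d(f, max(p.smooth_s / dt, 1e-9))
        pre = fsm[t < epochs[0][0] - 1.0]
        nwin = max(int((epochs[0][1] - epochs[0][0]) / dt), 1)
        nseg = len(pre) // nwin
        sham = np.array([(pre[i * nwin:(i + 1) * nwin].max() - f0) / f0
                         for i in range(nseg)])
        rows.append(dict(roi_id=roi, condition=cond,
                         dff=float(np.mean(vals)),
                         baseline_dff_mean=float(sham.mean()) if nseg else np.nan,
                         baseline_dff_sd=float(sham.std(ddof=1)) if nseg >= 2 else np.nan))
    return pd.DataFrame(rows)


def classify_active(dff_control: float, baseline_dff_sd: float,
                    k: float = 3.0, baseline_dff_mean: float = 0.0) -> bool:
    """Active iff the control response clears the sham-epoch level by
    k x the baseline dF/F noise (the evoked measure is a within-epoch peak,
    so it must be referenced to the sham mean, not to zero)."""
    return bool(dff_control - baseline_dff_mean > k * baseline_dff_sd)


def percent_suppression(dff_control: float, dff_drug: float) -> float:
    """100 x (1 - drug/control); negative values (facilitation) kept as-is."""
    if dff_control <= 0:
        raise ValueError("ROI not active in control (non-positive dF/F)")
    return 100.0 * (1.0 - dff_drug / dff_control)


def suppression_table(traces: pd.DataFrame, epochs=None,
                      p: CalciumParams = CalciumParams()) -> pd.DataFrame:
    """Full analysis: dF/F per condition, activity flag, suppression/recovery.

    Returns one row per ROI with columns dff_control, dff_drug, dff_wash,
    active, percent_suppression (control vs drug) and percent_recovery
    (wash vs drug, relative to control).  ROIs inactive in control get NaN
    suppression; the cohort median over active ROIs is the headline statistic.
    """
    table = roi_dff_table(traces, epochs, p)
    wide = table.pivot(index="roi_id", columns="condition", values="dff")
    ctrl = table[table.condition == "control"].set_index("roi_id")
    noise = ctrl["baseline_dff_sd"]
    sham_mean = ctrl["baseline_dff_mean"]
    # pool the (few-sample) per-ROI noise SDs across the field of view
    sd_pool = float(np.nanmedian(noise))
    out = []
    for roi in wide.index:
        c, d, w = (wide.loc[roi].get(k, np.nan) for k in ("control", "drug", "wash"))
        active = classify_active(c, max(noise.loc[roi], sd_pool),
                                 p.active_threshold_sd, sham_mean.loc[roi])
        supp = percent_suppression(c, d) if active and c > 0 else np.nan
        rec = percent_suppression(c, w) if active and c > 0 else np.nan
        out.append(dict(roi_id=roi, dff_control=c, dff_drug=d, dff_wash=w,
                        baseline_dff_sd=noise.loc[roi], active=active,
                        percent_suppression=supp, percent_recovery_deficit=rec))
    return pd.DataFrame(out)
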