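"""Latency clustering of detected PSCs and excitatory/inhibitory labeling.

PSCs recorded at one holding potential are grouped per cell with k-means.
By default clustering runs on the standardized onset latency alone: in
compound responses the kinetic measurements (rise, decay tau) of overlapping
events are corrupted by truncated fit windows and moving local baselines, and
empirically they destroy the partition that is plainly visible in the latency
histogram.  ``features="full"`` switches to standardized (onset latency,
rise, tau); amplitude is always excluded so that the chloride driving force
cannot leak into the grouping.  The number of clusters is chosen by mean
silhouette over k = 2..k_max, with a seeded parametric-bootstrap
multimodality test deciding whether k = 1 is adequate (observed k=2
silhouette compared with its null distribution under a single Gaussian).

Clusters observed at both -60 mV and 0 mV holding potentials are labeled
inhibitory (only chloride-mediated currents remain visible at the AMPA
reversal potential); clusters observed only at -60 mV are labeled excitatory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .detect import PSCEvent


@dataclass
class PSCCluster:
    """A latency-defined group of PSCs across sweeps of one cell."""

    member_ids: list[int]  # indices into the event table
    latency_mu: float  # ms, Gaussian mean of member onset latencies
    latency_sigma: float  # ms
    onset_jitter: float  # ms, SD of member onsets (nan if single member)
    peak_jitter: float  # ms, SD of member absolute peak times
    probability: float  # fraction of sweeps containing a member
    label: str = "unknown"  # excitatory | inhibitory | unknown
    label_source: str = "none"  # holding | classifier | none
    rank: int = 0  # order by latency_mu
    low_n: bool = False


@dataclass
class RecordingSession:
    """All sweeps, events and clusters of one cell."""

    cell_id: str
    stim_site: str  # MdL | AN
    age_days: int
    sweeps: dict  # holding -> list[Sweep]
    events: dict  # holding -> list[PSCEvent]
    clusters: dict  # holding -> list[PSCCluster]


FEATURES = ("onset_latency", "rise_10_90", "tau_decay")


def _feature_matrix(events: list[PSCEvent]) -> np.ndarray:
    X = np.array([[e.onset_latency, e.rise_10_90, e.tau_decay] for e in events])
    # decay fits can fail on truncated compound events; impute with the median
    for j in range(X.shape[1]):
        bad = ~np.isfinite(X[:, j])
        if bad.any():
            X[bad, j] = np.nanmedian(np.where(np.isfinite(X[:, j]), X[:, j], np.nan))
    return X


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _quantile_init(Z: np.ndarray, k: int) -> np.ndarray:
    """Deterministic centroid seeding: events at latency quantiles."""
    order = np.argsort(Z[:, 0], kind="stable")
    qs = (np.arange(k) + 0.5) / k
    idx = order[np.clip((qs * len(order)).astype(int), 0, len(order) - 1)]
    return Z[idx]

def _kmeans(Z: np.ndarray, k: int) -> np.ndarray:
    km = KMeans(n_clusters=k, init=_quantile_init(Z, k), n_init=1, random_state=0)
    return km.fit_predict(Z)


def multimodality_pvalue(Z: np.ndarray, n_boot: int = 100, seed: int = 0) -> float:
    """Parametric-bootstrap test of unimodality of the feature cloud.

    The observed k=2 silhouette is compared against its distribution under a
    single multivariate Gaussian fitted to the data; the p-value is the
    fraction of bootstrap samples whose silhouette is at least as large.
    """
    n = len(Z)
    if n < 8:
        return 1.0
    obs = silhouette_score(Z, _kmeans(Z, 2))
    mean = Z.mean(axis=0)
    cov = np.cov(Z.T) + 1e-9 * np.eye(Z.shape[1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_boot):
        sim = rng.multivariate_normal(mean, cov, size=n)
        if silhouette_score(sim, _kmeans(sim, 2)) >= obs:
            hits += 1
    return (hits + 1) / (n_boot + 1)


def cluster_events(events: list[PSCEvent], k_max: int = 5, *,
                   n_sweeps: int | None = None, alpha: float = 0.05,
                   seed: int = 0, features: str = "latency") -> list[PSCCluster]:
    """Group one cell's PSCs (one holding potential) into latency clusters.

    Fewer than 3 events yield a single cluster flagged ``low_n``.  Otherwise
    k-means runs on standardized (onset, rise, tau); k=1 is kept when the
    multimodality test is not significant at ``alpha``, else k maximises the
    mean silhouette over 2..k_max.  Clusters are ordered (``rank``) by their
    fitted Gaussian latency mean.
    """
    if len(events) == 0:
        return []
    if n_sweeps is None:
        n_sweeps = len({e.sweep_id for e in events})

    if len(events) < 3:
        cl = _make_cluster(list(range(len(events))), events, n_sweeps)
        cl.low_n = True
        return [cl]

    X = _feature_matrix(events)
    if features == "latency":
        X = X[:, :1]
    elif features != "full":
        raise ValueError("features must be 'latency' or 'full'")
    Z = _standardize(X)
    # below ~a dozen events a multimodality claim cannot be supported and
    # k-means happily carves noise into micro-clusters
    if len(events) < 12 or multimodality_pvalue(Z, seed=seed) >= alpha:
        labels = np.zeros(len(events), dtype=int)
        k = 1
    else:
        best_k, best_s, best_labels = 2, -np.inf, None
        for k in range(2, min(k_max, len(events) - 1) + 1):
            lab = _kmeans(Z, k)
            if len(np.unique(lab)) < k:
                continue
            s = silhouette_score(Z, lab)
            if s > best_s:
                best_k, best_s, best_labels = k, s, lab
        labels, k = best_labels, best_k

    # absorb micro-clusters (fewer than 3 members) into the nearest cluster
    groups = [sorted(np.flatnonzero(labels == c).tolist()) for c in range(k)]
    groups = [g for g in groups if g]
    changed = True
    while changed and len(groups) > 1:
        changed = False
        mus = [float(np.mean([events[i].onset_latency for i in g])) for g in groups]
        for gi, g in enumerate(groups):
            if len(g) < 3:
                others = [j for j in range(len(groups)) if j != gi]
                tgt = min(others, key=lambda j: abs(mus[j] - mus[gi]))
                groups[tgt] = sorted(groups[tgt] + g)
                groups.pop(gi)
                changed = True
                break

    clusters = [_make_cluster(g, events, n_sweeps) for g in groups]
    clusters.sort(key=lambda cl: cl.latency_mu)
    for r, cl in enumerate(clusters):
        cl.rank = r
    return clusters


def _make_cluster(members: list[int], events: list[PSCEvent],
                  n_sweeps: int) -> PSCCluster:
    onsets = np.array([events[i].onset_latency for i in members])
    peaks = np.array([events[i].onset_latency + events[i].time_to_peak
                      for i in members])
    mu, sigma = stats.norm.fit(onsets)
    jit, pjit = cluster_stats_arrays(onsets, peaks)
    prob = len({events[i].sweep_id for i in members}) / n_sweeps
    return PSCCluster(member_ids=members, latency_mu=float(mu),
                      latency_sigma=float(sigma),
                      onset_jitter=jit, peak_jitter=pjit, probability=prob)


def cluster_stats_arrays(onsets: np.ndarray, peaks: np.ndarray):
    """(onset jitter, peak jitter) as sample SDs; nan for single members."""
    if len(onsets) < 2:
        return float("nan"), float("nan")
    return float(np.std(onsets, ddof=1)), float(np.std(peaks, ddof=1))


def cluster_stats(cluster: PSCCluster, events: list[PSCEvent],
                  n_sweeps: int) -> tuple[float, float, float]:
    """Recompute (onset_jitter, peak_jitter, probability) for one cluster."""
    if not cluster.member_ids:
        raise ValueError("cluster is empty")
    onsets = np.array([events[i].onset_latency for i in cluster.member_ids])
    peaks = np.array([events[i].onset_latency + events[i].time_to_peak
                      for i in cluster.member_ids])
    jit, pjit = cluster_stats_arrays(onsets, peaks)
    prob = len({events[i].sweep_id for i in cluster.member_ids}) / n_sweeps
    return jit, pjit, prob


def label_by_holding(clusters_minus60: list[PSCCluster],
                     clusters_0mv: list[PSCCluster],
                     tolerance_ms: float = 1.0) -> list[PSCCluster]:
    """Label -60 mV clusters by presence of a 0 mV (chloride-only) partner.

    A -60 mV cluster is inhibitory iff some 0 mV cluster lies within
    ``tolerance_ms`` of its latency mean (each 0 mV cluster matched at most
    once, nearest first); otherwise excitatory.  With no 0 mV recording the
    labels stay unknown and are left to the classifier.
    """
    if clusters_0mv is None:
        for cl in clusters_minus60:
            cl.label, cl.label_source = "unknown", "none"
        return clusters_minus60

    taken: set[int] = set()
    pairs = sorted(
        ((abs(cl.latency_mu - z.latency_mu), i, j)
         for i, cl in enumerate(clusters_minus60)
         for j, z in enumerate(clusters_0mv)),
        key=lambda t: t[0])
    matched: set[int] = set()
    for d, i, j in pairs:
        if d > tolerance_ms or i in matched or j in taken:
            continue
        matched.add(i)
        taken.add(j)
    for i, cl in enumerate(clusters_minus60):
        cl.label = "inhibitory" if i in matched else "excitatory"
        cl.label_source = "holding"
    return clusters_minus60


def clusters_to_frame(clusters: list[PSCCluster]) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        rows.append(dict(rank=cl.rank, latency_mu=cl.latency_mu,
                         latency_sigma=cl.latency_sigma,
                         onset_jitter=cl.onset_jitter, peak_jitter=cl.peak_jitter,
                         probability=cl.probability, n_members=len(cl.member_ids),
                         label=cl.label, label_source=cl.label_source,
                         low_n=cl.low_n))
    return pd.DataFrame(rows, columns=["rank", "latency_mu", "latency_sigma",
                                       "onset_jitter", "peak_jitter", "probability",
                                       "n_members", "label", "label_source", "low_n"])
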