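"""RandomForest excitatory/inhibitory classification of PSCs.

The classifier is trained on PSCs whose identity is known from the
holding-potential criterion (clusters present at 0 mV are inhibitory) —
available with midline stimulation — and is then applied to PSCs whose
identity is unknown (auditory-nerve stimulation without 0 mV data).  Each PSC
contributes event-level features (amplitude, time to peak, decay tau, age)
plus its cluster's statistics (onset jitter, peak jitter, probability).
Evaluation artifacts mirror standard RandomForest practice: out-of-bag
accuracy, permutation-stable feature importances, a proximity matrix embedded
in 2-D by metric MDS, and a ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import MDS
from sklearn.metrics import roc_auc_score, roc_curve

from .cluster import RecordingSession

# default follows the figure convention (time-to-peak); rise time can be
# swapped in by config
DEFAULT_FEATURES = ("amplitude", "time_to_peak", "tau_decay", "onset_jitter",
                    "peak_jitter", "probability", "age")
ALT_FEATURES = ("amplitude", "rise_10_90", "tau_decay", "onset_jitter",
                "peak_jitter", "probability", "age")


def build_features(session: RecordingSession, holding: float = -60.0) -> pd.DataFrame:
    """One row per PSC: event kinetics + its cluster's statistics.

    Events whose cluster has undefined jitter (single-member clusters) are
    excluded; the count is recorded in ``df.attrs['n_excluded']``.
    """
    events = session.events.get(holding, [])
    clusters = session.clusters.get(holding, [])
    rows, n_excluded = [], 0
    for cl in clusters:
        if not np.isfinite(cl.onset_jitter):
            n_excluded += len(cl.member_ids)
            continue
        for i in cl.member_ids:
            e = events[i]
            rows.append(dict(
                cell_id=session.cell_id, event_id=i, cluster_rank=cl.rank,
                amplitude=e.amplitude, time_to_peak=e.time_to_peak,
                rise_10_90=e.rise_10_90, tau_decay=e.tau_decay,
                onset_latency=e.onset_latency,
                onset_jitter=cl.onset_jitter, peak_jitter=cl.peak_jitter,
                probability=cl.probability, age=session.age_days,
                label=cl.label))
    cols = ["cell_id", "event_id", "cluster_rank", "amplitude", "time_to_peak",
            "rise_10_90", "tau_decay", "onset_latency", "onset_jitter",
            "peak_jitter", "probability", "age", "label"]
    df = pd.DataFrame(rows, columns=cols)
    # decay-fit failures leave nan taus; impute with the session median
    if len(df) and df["tau_decay"].isna().any():
        df["tau_decay"] = df["tau_decay"].fillna(df["tau_decay"].median())
    df.attrs["n_excluded"] = n_excluded
    return df


@dataclass
class TrainedClassifier:
    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    oob_accuracy: float
    importances: pd.Series
    proximity: np.ndarray  # on the (possibly subsampled) training rows
    proximity_rows: np.ndarray  # indices of rows used for proximity
    seed: int


def _proximity_matrix(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees in which two samples share a leaf."""
    leaves = model.apply(X)  # (n, n_trees)
    n = X.shape[0]
    prox = np.zeros((n, n))
    for t in range(leaves.shape[1]):
        col = leaves[:, t]
        prox += col[:, None] == col[None, :]
    return prox / leaves.shape[1]


def train(features: pd.DataFrame, seed: int = 0, *,
          feature_names: tuple[str, ...] = DEFAULT_FEATURES,
          n_estimators: int = 500, max_proximity_rows: int = 400) -> TrainedClassifier:
    """Fit a RandomForest on labeled PSC rows (labels 'excitatory'/'inhibitory')."""
    labeled = features[features["label"].isin(["excitatory", "inhibitory"])]
    y = labeled["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    X = labeled.loc[:, list(feature_names)].to_numpy(dtype=float)
    model = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", oob_score=True,
        random_state=seed, n_jobs=1)
    model.fit(X, y)
    rng = np.random.default_rng(seed)
    rows = np.arange(len(X))
    if len(rows) > max_proximity_rows:
        rows = np.sort(rng.choice(rows, size=max_proximity_rows, replace=False))
    prox = _proximity_matrix(model, X[rows])
    return TrainedClassifier(
        model=model, feature_names=tuple(feature_names),
        classes=tuple(model.classes_), oob_accuracy=float(model.oob_score_),
        importances=pd.Series(model.feature_importances_, index=feature_names)
                      .sort_values(ascending=False),
        proximity=prox, proximity_rows=rows, seed=seed)


def predict(clf: TrainedClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Per-PSC excitatory probability and hard label (ties -> 'unknown')."""
    missing = [c for c in clf.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X = features.loc[:, list(clf.feature_names)].to_numpy(dtype=float)
    proba = clf.model.predict_proba(X)
    p_e = proba[:, list(clf.classes).index("excitatory")]
    out = features.copy()
    out["probability_excitatory"] = p_e
    out["predicted_label"] = np.where(
        p_e > 0.5, "excitatory", np.where(p_e < 0.5, "inhibitory", "unknown"))
    return out


def evaluate(clf: TrainedClassifier, features: pd.DataFrame, seed: int = 0):
    """ROC + AUC, 2-D MDS embedding of (1 - proximity), importance ranking.

    Returns a dict with keys roc (DataFrame fpr/tpr/threshold), auc, mds
    (DataFrame dim1/dim2/label), mds_stress, importances.
    """
    labeled = features[features["label"].isin(["excitatory", "inhibitory"])]
    pred = predict(clf, labeled)
    y = (labeled["label"] == "excitatory").to_numpy()
    p = pred["probability_excitatory"].to_numpy()
    fpr, tpr, thr = roc_curve(y, p)
    auc = roc_auc_score(y, p)

    dist = 1.0 - clf.proximity
    np.fill_diagonal(dist, 0.0)
    mds = MDS(n_components=2, dissimilarity="precomputed", random_state=seed,
              normalized_stress=False)
    emb = mds.fit_transform(dist)
    # labels of the proximity rows, via the training subset used in train()
    lab_rows = labeled.iloc[clf.proximity_rows]["label"].to_numpy() \
        if len(labeled) >= len(clf.proximity_rows) else None

    return dict(
        roc=pd.DataFrame(dict(fpr=fpr, tpr=tpr, threshold=thr)),
        auc=float(auc),
        mds=pd.DataFrame(dict(dim1=emb[:, 0], dim2=emb[:, 1],
                              label=lab_rows if lab_rows is not None else "n/a")),
        mds_stress=float(mds.stress_),
        importances=clf.importances)
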