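"""End-to-end workflows.

Two cohort workflows mirror the train/apply asymmetry of the analysis: the
midline (MdL) workflow produces holding-potential-labeled PSCs and trains the
RandomForest; the auditory-nerve (AN) workflow produces unlabeled PSCs and
classifies them with the trained forest.  A third workflow runs the
conductance-model experiment suite (mini-PSP checks, control/E-only/I-only
trains, the 21-point E-I latency sweep at full and depressed IPSP amplitude).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, cluster, detect, io, mocmodel, params, synthgen, timing

log = logging.getLogger("mocsyn")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | None = None  # None -> keep results in memory only
    n_cells_mdl: int = 21
    n_cells_an: int = 11
    n_sweeps: int | None = None  # None -> per-site default
    noise_sd: float = params.NOISE_SD_PA
    detect_params: detect.DetectParams = field(default_factory=detect.DetectParams)
    cluster_alpha: float = 0.05
    label_tolerance_ms: float = 1.0
    classifier_seed: int | None = None  # None -> derived from seed
    sweep_dt_ms: float = 0.02
    ipsp_scales: tuple[float, ...] = (1.0, 0.51)

    def hash(self) -> str:
        return io.config_hash(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a configuration from a YAML mapping (unknown keys rejected)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "detect_params" in raw:
            raw["detect_params"] = detect.DetectParams(**raw["detect_params"])
        return cls(**raw)


@dataclass
class RunReport:
    name: str
    tables: dict
    warnings: list
    provenance: str

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, df in self.tables.items():
            io.write_table(df, outdir / f"{self.name}_{key}.csv", self.provenance)


def _analyze_cell(cell: synthgen.CellInput, cfg: PipelineConfig) -> tuple[cluster.RecordingSession, pd.DataFrame]:
    """synthgen -> detect -> cluster (-> holding labels) for one cell."""
    sweeps, truth = synthgen.generate_voltage_clamp(cell.spec)
    events, clusters = {}, {}
    for holding, sws in sweeps.items():
        evs = [e for sw in sws for e in detect.detect_events(sw, cfg.detect_params)]
        events[holding] = evs
        clusters[holding] = cluster.cluster_events(
            evs, n_sweeps=cell.spec.n_sweeps, alpha=cfg.cluster_alpha,
            seed=cell.spec.seed)
    if -60.0 in clusters:
        cluster.label_by_holding(clusters[-60.0], clusters.get(0.0),
                                 cfg.label_tolerance_ms)
    session = cluster.RecordingSession(
        cell_id=cell.cell_id, stim_site=cell.stim_site, age_days=cell.age_days,
        sweeps=sweeps, events=events, clusters=clusters)
    return session, truth


def run_mdl_workflow(cfg: PipelineConfig):
    """MdL cohort: detect, cluster, label by holding, train classifier, timing.

    Returns ``(report, classifier, sessions)``.
    """
    cells = synthgen.generate_cohort(
        params.MDL_ARCHETYPES, cfg.n_cells_mdl, cfg.seed, stim_site="MdL",
        n_sweeps=cfg.n_sweeps, noise_sd=cfg.noise_sd)
    warnings_, sessions, features, truths = [], [], [], []
    for cell in cells:
        session, truth = _analyze_cell(cell, cfg)
        sessions.append(session)
        truths.append(truth.assign(cell_id=cell.cell_id))
        features.append(classify.build_features(session))
    feat = pd.concat(features, ignore_index=True) if features else pd.DataFrame()

    clf = None
    if len(feat) and feat["label"].nunique() >= 2:
        clf_seed = cfg.classifier_seed if cfg.classifier_seed is not None else cfg.seed
        clf = classify.train(feat, seed=clf_seed)
    else:
        warnings_.append("classifier not trained: fewer than two PSC classes")

    summaries = [timing.summarize_cell(s) for s in sessions]
    pop = timing.population_table(summaries)
    cluster_rows = []
    for s in sessions:
        df = cluster.clusters_to_frame(s.clusters.get(-60.0, []))
        df.insert(0, "cell_id", s.cell_id)
        cluster_rows.append(df)
    event_rows = []
    for s in sessions:
        for holding, evs in s.events.items():
            df = detect.events_to_frame(evs)
            df.insert(0, "cell_id", s.cell_id)
            event_rows.append(df)

    tables = dict(
        events=pd.concat(event_rows, ignore_index=True) if event_rows else pd.DataFrame(),
        clusters=pd.concat(cluster_rows, ignore_index=True) if cluster_rows else pd.DataFrame(),
        features=feat,
        timing=pop,
        truth=pd.concat(truths, ignore_index=True) if truths else pd.DataFrame())
    if clf is not None:
        tables["importances"] = clf.importances.rename_axis("feature").rename("importance").reset_index()
        tables["oob"] = pd.DataFrame([dict(oob_accuracy=clf.oob_accuracy)])
    report = RunReport("mdl", tables, warnings_, cfg.hash())
    if cfg.outdir:
        report.save(cfg.outdir)
    return report, clf, sessions


def run_an_workflow(cfg: PipelineConfig, clf: classify.TrainedClassifier):
    """AN cohort (no 0 mV data): detect, cluster, classify, timing.

    Cluster labels are assigned by the mean classifier probability of their
    member events.  Returns ``(report, sessions)``.
    """
    if clf is None:
        raise ValueError("AN workflow needs a trained classifier")
    cells = synthgen.generate_cohort(
        params.AN_ARCHETYPES, cfg.n_cells_an, cfg.seed + 1, stim_site="AN",
        n_sweeps=cfg.n_sweeps, holding_potentials=(-60.0,),
        noise_sd=cfg.noise_sd)
    warnings_, sessions, preds, truths = [], [], [], []
    if cfg.n_cells_an == 0:
        warnings_.append("empty AN cohort requested")
    for cell in cells:
        session, truth = _analyze_cell(cell, cfg)
        feat = classify.build_features(session)
        if len(feat):
            pred = classify.predict(clf, feat)
            # label clusters by the mean probability of their events
            for cl in session.clusters[-60.0]:
                rows = pred[pred["cluster_rank"] == cl.rank]
                if len(rows) == 0:
                    continue
                p = rows["probability_excitatory"].mean()
                cl.label = "excitatory" if p > 0.5 else "inhibitory"
                cl.label_source = "classifier"
            preds.append(pred.assign(cell_id=cell.cell_id))
        sessions.append(session)
        truths.append(truth.assign(cell_id=cell.cell_id))
    summaries = [timing.summarize_cell(s) for s in sessions]
    pop = timing.population_table(summaries)
    tables = dict(
        predictions=pd.concat(preds, ignore_index=True) if preds else pd.DataFrame(),
        timing=pop,
        truth=pd.concat(truths, ignore_index=True) if truths else pd.DataFrame())
    report = RunReport("an", tables, warnings_, cfg.hash())
    if cfg.outdir:
        report.save(cfg.outdir)
    return report, sessions


def run_model_suite(cfg: PipelineConfig):
    """Calibrate the neuron model and run the full protocol suite."""
    model = mocmodel.build_model(mocmodel.NeuronModelSpec())
    model, cal = mocmodel.calibrate(model)
    warnings_ = []
    if not cal.within_tolerance:
        warnings_.append("calibration outside tolerance; endpoints still emitted")

    protos = dict(
        control=mocmodel.ProtocolSpec(dt_ms=cfg.sweep_dt_ms),
        e_only=mocmodel.ProtocolSpec(include_i=False, dt_ms=cfg.sweep_dt_ms),
        i_only=mocmodel.ProtocolSpec(include_e=False, dt_ms=cfg.sweep_dt_ms))
    endpoint_rows = []
    for name, proto in protos.items():
        res = mocmodel.simulate_protocol(model, proto)
        endpoint_rows.append(dict(
            protocol=name, first_ap_latency_ms=res.first_ap_latency_ms,
            ap_rate_hz=res.ap_rate_hz, ap_rate_sweep_hz=res.ap_rate_sweep_hz,
            n_aps=res.n_aps, psp_peak_mv=res.psp_peak_mv))

    sweep_tables = {}
    for scale in cfg.ipsp_scales:
        sw = mocmodel.sweep_ei_latency(model, ipsp_scale=scale,
                                       dt_ms=cfg.sweep_dt_ms)
        sw.insert(0, "ipsp_scale", scale)
        sweep_tables[f"sweep_scale_{scale:g}"] = sw

    tables = dict(
        calibration=pd.DataFrame([{k: v for k, v in vars(cal).items()
                                   if k != "targets"}]),
        endpoints=pd.DataFrame(endpoint_rows),
        **sweep_tables)
    report = RunReport("model", tables, warnings_, cfg.hash())
    if cfg.outdir:
        report.save(cfg.outdir)
    return report, model
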