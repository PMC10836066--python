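import warnings

import numpy as np
import pytest

from mocsyn import synthgen

warnings.filterwarnings("ignore", message=".*Covariance of the parameters.*")


@pytest.fixture(scope="session")
def mixed_cell():
    """One mixed E+I cell (E at 1.9 ms, I at 4.7 ms), both holdings."""
    spec = synthgen.RecordingSpec(
        clusters=(
            synthgen.ClusterSpec("excitatory", 1.9, 0.28, 0.30, 1.2, -60.0, 0.3, 0.85),
            synthgen.ClusterSpec("inhibitory", 4.7, 0.45, 0.60, 4.5, -55.0, 0.3, 0.6),
        ),
        n_sweeps=30, noise_sd=4.0, seed=7)
    sweeps, truth = synthgen.generate_voltage_clamp(spec)
    return spec, sweeps, truth


@pytest.fixture(scope="session")
def calibrated_model():
    """Calibrated conductance model (expensive; shared across tests)."""
    from mocsyn import mocmodel

    model = mocmodel.build_model(mocmodel.NeuronModelSpec())
    model, report = mocmodel.calibrate(model)
    return model, report


@pytest.fixture(scope="session")
def ei_sweep(calibrated_model):
    from mocsyn import mocmodel

    model, _ = calibrated_model
    full = mocmodel.sweep_ei_latency(model, ipsp_scale=1.0)
    weak = mocmodel.sweep_ei_latency(model, ipsp_scale=0.51)
    return full, weak


@pytest.fixture(scope="session")
def mdl_run():
    """Full MdL workflow on the packaged table (shared)."""
    from mocsyn.pipeline import PipelineConfig, run_mdl_workflow

    cfg = PipelineConfig(seed=1)
    report, clf, sessions = run_mdl_workflow(cfg)
    return cfg, report, clf, sessions


@pytest.fixture(scope="session")
def an_run(mdl_run):
    from mocsyn.pipeline import run_an_workflow

    cfg, _, clf, _ = mdl_run
    report, sessions = run_an_workflow(cfg, clf)
    return report, sessions
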