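# mocsyn

Synaptic integration analysis for medial olivocochlear (MOC) neurons — the
brainstem efferent cells that inhibit cochlear outer hair cells and thereby
turn down the gain of the cochlear amplifier.

MOC neurons receive fast ascending excitation (cochlear-nucleus T-stellate
cells) and fast di-synaptic inhibition (globular bushy cell → MNTB). Although
individually capable of firing above 300 Hz in vitro, MOC neurons respond to
sound slowly and variably in vivo. A central quantity for understanding this
is the **E–I latency difference** of a cell,

```
Δ_EI = L_I − L_E          (first inhibitory minus first excitatory latency;
                           positive ⇒ excitation leads)
```

With electrical stimulation at the brainstem midline (MdL, bypassing the
cochlear nucleus) excitation always leads (Δ_EI ≈ +2.8 ms); with stimulation
of the auditory nerve root (AN, engaging the full cochlear nucleus) the
unusually fast inhibitory pathway catches up (Δ_EI ≈ 0, sometimes negative).
Closely timed inhibition turns out to be the most effective at delaying and
slowing MOC spiking.

`mocsyn` implements the full analysis chain as a tested pipeline:

| module     | role |
|------------|------|
| `synthgen` | synthetic voltage-clamp / current-clamp / calcium data with ground truth (no raw recordings are publicly deposited; the generator encodes the published summary statistics) |
| `detect`   | PSC detection in sweeps; onset latency, 10–90% rise, amplitude, decay τ |
| `cluster`  | per-cell k-means latency clustering, jitter/probability statistics, E/I labeling via the 0 mV holding-potential criterion (only chloride-mediated currents remain at the AMPA reversal potential) |
| `classify` | RandomForest trained on holding-potential-labeled MdL PSCs, applied to unlabeled AN PSCs; OOB accuracy, importances, proximity/MDS, ROC |
| `timing`   | E–I latency differences, onset jitter, PSC probability, AP metrics, exact nonparametric tests |
| `mocmodel` | conductance-based MOC neuron (soma + 4 dendritic cables; Na, Kv3-like high-threshold K, low-threshold K, slow AHP-like K, leak; double-exponential conductance synapses at 0 / −74 mV) |
| `calcium`  | ΔF/F quantification, activity classification, % suppression under glutamate-receptor blockade |
| `pipeline` | the two cohort workflows (MdL-train, AN-predict) and the model experiment suite |

## Worked example

Calibrate the neuron model against the packaged mini-PSP templates and
train-response contract, then run 100 Hz, 20-pulse synaptic trains:

```
$ mocsyn model run                  # control: EPSPs + IPSPs, Δ_EI = +2.8 ms
first AP latency: 35.90 ms; AP rate (train window): 20.00 Hz; APs: 4

$ mocsyn model run --no-inhibition  # EPSPs only
first AP latency: 24.50 ms; AP rate (train window): 30.00 Hz; APs: 6
```

Removing inhibition moves the first spike earlier by ~11 ms and raises the
AP rate — fast MNTB inhibition delays and slows MOC output. Sweeping the E–I
latency difference (`mocsyn model sweep`) shows inhibition is most effective
when it arrives within about a millisecond of excitation (rate ≈ 20 Hz at
Δ_EI −10/−1/+9 ms) and least effective mid-cycle (≈ 25 Hz near −5/+5 ms);
halving the IPSP amplitude (`--ipsp-scale 0.51`, mimicking synaptic
depression) weakens the suppression at every grid point.

The cohort workflows run from Python:

```python
from mocsyn.pipeline import PipelineConfig, run_mdl_workflow, run_an_workflow

cfg = PipelineConfig(seed=1, outdir="out")
mdl_report, classifier, sessions = run_mdl_workflow(cfg)   # detect → cluster → label → train
an_report, an_sessions = run_an_workflow(cfg, classifier)  # detect → cluster → predict
print(mdl_report.tables["timing"].ei_latency_difference.mean())  # ≈ +2.8 ms
```

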