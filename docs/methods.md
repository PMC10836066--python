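# Methods

## Scope and data model

The package analyses evoked post-synaptic currents (PSCs) in MOC neurons and
the consequences of excitatory/inhibitory timing for spiking. No raw
recordings are publicly deposited, so a first-class synthetic-data module
(`synthgen`) generates voltage-clamp sweep sets, current-clamp PSP trains and
calcium ROI traces with known ground truth; all downstream claims about the
analysis code are demonstrated as round trips against that ground truth.
What passing tests show is therefore that the *estimators and pipeline
recover known generative parameters under realistic noise*, not that the
synthetic data capture every property of the biological recordings (see
Limitations).

## Synthetic voltage-clamp data

Each cell is a set of latency clusters. Per sweep, a cluster emits an event
with its release probability; the onset is Normal(latency mean, onset
jitter), truncated at 0.1 ms (a physiological floor — no non-causal events);
amplitudes are lognormal with a configurable CV (mean-preserving); event
kinetics scale jointly (a common lognormal factor multiplies both rise and
decay, CV 0.10), so peak-time jitter arises from onset jitter plus rise
variability. The waveform is a difference of two exponentials. Because the
analysis world measures events by 10–90% rise and a fitted decay constant —
not by generative time constants — the kernel pair (τ_rise, τ_decay) is
solved numerically (nested bisections) so the *realised measurements* equal
the specified values. This family has a feasibility floor: a fitted-from-peak
decay cannot be faster than ≈3.5× the 10–90% rise.

Polarity follows the chloride logic of the recordings: with 60 mM internal
chloride (E_Cl ≈ −20 mV) every event is inward at −60 mV; at 0 mV — the AMPA
reversal potential — excitatory clusters vanish and inhibitory events are
outward, scaled by the driving-force ratio (V − E_Cl)/(−60 − E_Cl).

### Packaged cohort tables

The default tables (`mocsyn.params`) encode the study conditions as published
summary statistics: MdL archetype frequencies 6:4:5:6 of 21 (E-only, I-only,
one E + one I, complex), mixed-cell E–I latency difference Normal(+2.80,
0.88) ms across cells, AN first-PSC latency 5.51 ± 1.00 ms per cell, AN E–I
differences centred near zero and truncated to the observed −4.4…+3.5 ms
range, AN complex fraction 8/11. Two table entries are not pinned by any
printed statistic and were fixed once by design: the MdL base excitatory
latency (1.73 ms) and the AN base first-cluster latency (4.85 ms) were solved
— analytically, then verified by multi-seed Monte Carlo through the full
detector — so that the *measured* cohort statistics (per-sweep first-PSC
latency for MdL, per-cell first-PSC latency for AN) equal the published
1.85 ms and 5.51 ms in expectation. Release probabilities (MdL E 0.85 / I
0.35; AN E 0.60 / I 0.45) and the short latencies of IPSC-only cells are the
free parameters that make those solves feasible. Amplitude distributions are
lognormal by choice (configurable), since no per-cluster amplitude
distribution is published.

## Event detection

Detection operates on the polarity-rectified trace: Gaussian smoothing
(σ = 0.06 ms), baseline noise from the pre-stimulus segment, candidate events
as local maxima above 4× baseline SD (standard for evoked-PSC work), plus
secondary rising phases of the first derivative to split shoulder events in
compound PSCs. Candidates not separated by a genuine valley (a dip of at
least 4 SD or 15% of the smaller peak) are merged — noise on the flat top of
a slow IPSC otherwise splits one event in two. Each event is measured on the
segment between its flanking valleys: onset by extrapolating the 20–80%
rising chord to the local baseline; 10–90% rise by interpolated level
crossings on a lightly smoothed copy; amplitude as peak minus *local*
baseline (so later events in a compound response are referenced to the decay
they ride on); decay by a shared estimator — τ₀ from the 1/e crossing, then
two least-squares single-exponential refinements on a 3τ window. For later
events in a compound the decay fit gains a bounded free offset that absorbs
the decaying local baseline. Failed decay fits are flagged, not discarded.

On noiseless synthetic events all estimators are unbiased within 5% across
the packaged parameter range; at realistic noise (amplitude ≥ 5× noise SD)
precision and recall are ≥ 0.95 on isolated events.

## Latency clustering and E/I labeling

PSCs are grouped per cell with k-means, k chosen by mean silhouette over
k = 2…k_max with k = 1 admitted by a seeded parametric-bootstrap
multimodality test (observed k = 2 silhouette against its null under a
single Gaussian fitted to the data; 100 bootstrap draws). Initial centroids
sit at latency quantiles, so the partition is deterministic and stable under
event permutation. Fewer than 12 events cannot support a multimodality claim
and yield one cluster; clusters with fewer than 3 members are absorbed into
their nearest neighbour, and timing summaries ignore clusters that small.

By default clustering uses the standardized onset latency alone. The spec of
record for this analysis lists (onset, rise, τ) as the feature set, and that
variant is available (`features="full"`), but in compound responses the
kinetic measurements of overlapping events are corrupted (truncated fit
windows, moving baselines — a true τ of 4.5 ms is measured near 1.2 ms), and
including them empirically destroys partitions that are plainly visible in
the latency histogram, which is also how the source analysis displays its
clusters. Amplitude is always excluded so chloride driving force cannot leak
into the grouping.

A −60 mV cluster is labeled *inhibitory* iff a 0 mV cluster exists within
1.0 ms of its latency mean (each 0 mV cluster matched at most once, nearest
first), else *excitatory*. The 1.0 ms tolerance is well below the typical
3–4 ms spacing between successive IPSC clusters.

## E/I classification (RandomForest)

One row per PSC: event-level amplitude, time-to-peak, decay τ and animal age
plus the cluster-level onset jitter, peak jitter and probability (rise time
can replace time-to-peak by configuration). 500 trees, √p features per
split, out-of-bag accuracy as the headline validation (no scheme is
published for the original), proximity from shared leaves (subsampled to
≤400 rows), 2-D metric MDS of 1 − proximity, ROC over the excitatory class
probability. Hard labels threshold at 0.5; exact ties are reported as
unknown. On the packaged MdL cohort OOB accuracy exceeds 99%.

**Transfer limitation.** Applying the MdL-trained forest to AN events is a
covariate-shift problem: the published comparison reports AN-EPSC and
AN-IPSC kinetics and amplitudes as statistically similar, and the packaged
AN table accordingly places the classes much closer (τ 2.2 vs 4.0 ms,
probability 0.60 vs 0.45) than the MdL training classes (τ 1.2 vs 4.5 ms,
probability 0.85 vs 0.35). Event-level transfer accuracy on the packaged AN
cohort is therefore above chance but far from perfect (~0.6 on resolvable
events); when an AN-latency cohort shares the MdL kinetic signatures the
same pipeline classifies ≥ 90% of events correctly. Per-event class
probabilities should be read as graded evidence, exactly as in the source
analysis, not as validated labels.

## Timing statistics

The E–I latency difference is fixed throughout as `first_I − first_E`
(positive ⇒ excitation precedes inhibition): the verbal definition and the
sign usage in the source conflict, and the usage (+2.8 ms with IPSPs lagging
EPSPs) wins. Group comparisons use exact two-sided nonparametric tests where
available (Mann–Whitney U, one-sample Wilcoxon signed-rank, Friedman); an
all-zero Wilcoxon sample is reported as p = 1 with a degeneracy flag. No
multiple-testing correction is applied (raw p-values, as in the source). AP
metrics from current-clamp trains: APs are upward crossings of 0 mV with a
1 ms refractory window, resolved to the following voltage peak; AP
probability is the fraction of sweeps with ≥ 1 AP; the AP rate denominator
is the train window n_pulses/rate (a full-sweep variant is also computed);
first-AP latency is measured from the first stimulus.

## The conductance-based MOC model

Soma (25 µm sphere) plus four equivalent dendritic cables (200 µm, 2 µm
diameter, two segments each, passive), C_m = 1 µF/cm², R_a = 150 Ω·cm,
leak 0.06 mS/cm² (τ_m ≈ 17 ms), E_leak = −65 mV. Somatic channels use
ventral-cochlear-nucleus-style kinetics (temperature-scaled to 35 °C,
Q10 = 3): fast transient Na (m³h), a Kv3-like high-threshold delayed
rectifier (0.85 n² + 0.15 p), a low-threshold K current (w⁴z, with its slow
inactivation gate z), and a slow spike-triggered AHP-like K conductance
(activation only at spike-level voltages, decay ≈ 4 ms). Two deliberate
departures from the textbook kinetics are load-bearing and exposed as spec
parameters: Na inactivation is slowed 2.6× relative to the other gates so
that slow synaptic summation can reach threshold before fully accommodating,
and the AHP component spaces spikes during trains. Synapses are
difference-of-exponentials conductances at the soma (E: reversal 0 mV,
τ 0.8/3.0 ms; I: reversal −74 mV — physiological low internal chloride —
τ 0.5/3.5 ms); synaptic event trains are deterministic (no release
failures). Integration is exponential Euler at dt = 0.02 ms (numba-compiled
when available; an identical pure-Python path otherwise); AP counts are
invariant under dt halving.

### Calibration contract

The published channel parameter tables are not available, so the model is
specified by contract rather than by transcription: (1) unitary synaptic
conductances are bisected until the somatic mini-EPSP/mini-IPSP peaks match
the packaged templates (+1.1 / −0.75 mV; the templates are synthetic
waveforms of the recorded shape class — files and docstrings say so); (2)
the evoked excitatory weight is bisected so the E-only 100 Hz, 20-pulse
train fires its first AP at 24.4 ms; (3) the evoked inhibitory weight is
chosen on a bounded deterministic grid as the candidate closest to the
38.5 ms control-train first-AP target among those that keep the 21-point E–I
latency sweep in its contracted regime (4–5 APs per 200 ms train window).
The first-AP latency is not monotone in the inhibitory weight once
spike/stimulus lockings rearrange, which is why the last step is a
constrained grid rather than a bisection. Calibration residuals are reported
and non-fatal. With the frozen defaults the calibrated model yields: control
first AP ≈ 35.9 ms (target 38.5), E-only first AP 24.5 ms (24.4), E-only
rate 30 Hz (31.5), sweep minimum 20 Hz at E–I differences around −10/−1/+9
ms and maximum 25 Hz around −5/+5 ms (targets ≈20 and ≈23.5 Hz at −6/+4),
with inhibition reducing the rate at every grid point and a depressed IPSP
(scale 0.51) weakening suppression everywhere.

## Calcium analysis

ΔF/F = (F_evoked − F₀)/F₀ with F₀ the mean over a 4 s pre-epoch window and
F_evoked the peak of a lightly smoothed trace within the epoch (mean mode by
configuration); values are averaged over the stimulation bouts. An ROI is
*active* iff its control response exceeds the sham-epoch level by 3× the
baseline ΔF/F SD — the evoked measure is a within-window peak, so it is
referenced to sham-epoch maxima, with per-ROI noise SDs floored by the
field-of-view median (few sham windows make single-ROI SDs unstable). The
activity criterion is not defined in the source and is configuration-exposed.
Percent suppression is 100 × (1 − ΔF/F_drug / ΔF/F_control) per ROI, cohort
median reported; facilitation (negative suppression) is kept as-is. The
measure is scale-invariant by construction.

## Problem sizes and numerical choices

Default cohorts are 21 MdL cells (30 sweeps, both holding potentials) and 11
AN cells (40 sweeps, −60 mV only) at 50 kHz with 4 pA baseline noise —
matched to the published ns. Stochastic round-trip checks in the test suite
average three cohort replicates to keep estimator noise below the stated
tolerances; the acceptance script uses single cohorts at the published ns.
Model protocols run 260 ms at dt = 0.02 ms. k-means ties break by latency;
all randomised steps (generator, bootstrap, forest, MDS) take explicit
seeds, and identical configurations reproduce identical outputs bit-for-bit.

## Known limitations

- The cochlear-nucleus circuitry is represented only as latency / jitter /
  probability differences between the MdL-like and AN-like tables; there is
  no network model.
- MdL→AN classifier transfer is limited by design-faithful covariate shift
  (above); accuracy claims hold only where the kinetic signature carries
  over.
- The calibrated neuron sustains ≈215 Hz under strong current steps before
  depolarisation block, short of the >300 Hz reported for MOC neurons in
  vitro; parameter sets reaching that rate could not simultaneously satisfy
  the five train/sweep endpoints, which were given precedence.
- The control-train first-AP latency calibrates to 35.9 ms against a 38.5 ms
  target (−7%): pushing the inhibitory weight further delays the first AP
  but collapses the sweep's 4–5 AP regime.
- Events closer than ~0.4 ms superimpose physically and are detected as one;
  cluster pairs closer than the onset jitter cannot be resolved by any
  latency-based analysis.
- ABF/NWB ingestion is not implemented; sweep I/O is CSV and HDF5.
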