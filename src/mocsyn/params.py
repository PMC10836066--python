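"""Packaged synthetic-cohort parameter tables.

These tables define the default study conditions for the synthetic cohorts:
per-pathway PSC kinetics and per-cell cluster archetypes for midline (MdL)
stimulation — which bypasses cochlear-nucleus circuitry and yields short-latency,
excitation-leading responses — and auditory-nerve (AN) stimulation, which engages
the full cochlear nucleus and yields longer-latency responses in which fast
di-synaptic inhibition can precede excitation.

Summary statistics transcribed into the tables (population values the cohorts
are built to reproduce in expectation): MdL per-sweep first-PSC latency
1.85 ± 0.53 ms; MdL mixed-cell E–I latency difference +2.80 ± 0.88 ms;
AN per-cell first-PSC latency 5.51 ± 1.00 ms; AN E–I latency difference
0.14 ± 2.87 ms ranging −4.4 … +3.5 ms; MdL archetype frequencies 6:4:5:6 /21
(EPSC-only, IPSC-only, one E + one I, complex); AN complex fraction 8/11.

Because no printed statistic pins down the latency of IPSC-only cells or of
complex-cell inhibitory clusters, those entries are free parameters; they were
chosen, together with the excitatory/inhibitory event probabilities, so that
the expected per-sweep first-PSC latency of the full MdL cohort equals 1.85 ms
(solved once, analytically — see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class KineticsRow:
    """Per-pathway, per-kind PSC kinetics and release statistics."""

    rise_mean: float  # ms, 10-90%
    tau_mean: float  # ms, single-exponential decay
    amp_mean: float  # pA at -60 mV (negative = inward)
    amp_cv: float
    probability: float  # per-sweep release probability of the cluster
    latency_sd: float  # ms, onset jitter within a cluster


# MdL pathway: mono-synaptic excitation is fast and temporally precise; the
# di-synaptic MNTB inhibition is slower-rising, slower-decaying and has more
# onset jitter.  Probabilities differ (0.85 vs 0.35); the recorded E/I
# probability contrast was the least constrained of the printed statistics.
MDL_KINETICS: dict[str, KineticsRow] = {
    "E": KineticsRow(rise_mean=0.30, tau_mean=1.2, amp_mean=-60.0, amp_cv=0.30,
                     probability=0.85, latency_sd=0.28),
    "I": KineticsRow(rise_mean=0.60, tau_mean=4.5, amp_mean=-55.0, amp_cv=0.30,
                     probability=0.35, latency_sd=0.45),
}

# AN pathway: all latencies are longer, kinetics of E and I converge, and both
# pathways have lower per-sweep probability than with MdL stimulation.
AN_KINETICS: dict[str, KineticsRow] = {
    "E": KineticsRow(rise_mean=0.45, tau_mean=2.2, amp_mean=-45.0, amp_cv=0.35,
                     probability=0.60, latency_sd=0.50),
    "I": KineticsRow(rise_mean=0.60, tau_mean=4.0, amp_mean=-48.0, amp_cv=0.35,
                     probability=0.45, latency_sd=0.50),
}


@dataclass(frozen=True)
class ArchetypeRow:
    """One cluster-pattern archetype and its cohort frequency."""

    name: str
    frequency: float
    # cluster template: list of (kind, latency offset rule) interpreted by
    # synthgen.sample_archetype_clusters
    has_e: bool
    has_i: bool
    complex_pattern: bool


# --- MdL cohort -----------------------------------------------------------
# Base excitatory latency per cell ~ Normal(MDL_E_LATENCY_MEAN, CELL_LATENCY_SD);
# mixed/complex inhibitory latency = E + Normal(2.80, 0.88) (the E-I latency
# difference); complex cells add a second E cluster at +1.1 ms and a second I
# cluster a further +3.2 ms after the first (the ~3-4 ms spacing seen between
# successive IPSC clusters).  IPSC-only cells sit at ~2.0 ms.
MDL_E_LATENCY_MEAN = 1.73  # ms; solved so the cohort per-sweep first-PSC mean is 1.85
MDL_I_ONLY_LATENCY = 2.00  # ms
MDL_EI_DIFF_MEAN = 2.80  # ms
MDL_EI_DIFF_SD = 0.88  # ms, across cells
MDL_SECOND_E_OFFSET = 1.1  # ms
MDL_SECOND_I_OFFSET = 3.2  # ms
CELL_LATENCY_SD = 0.35  # ms, across-cell scatter of the base latency

MDL_ARCHETYPES = [
    ArchetypeRow("e_only", 6 / 21, True, False, False),
    ArchetypeRow("i_only", 4 / 21, False, True, False),
    ArchetypeRow("mixed", 5 / 21, True, True, False),
    ArchetypeRow("complex", 6 / 21, True, True, True),
]

# --- AN cohort ------------------------------------------------------------
# Per cell the latency of the *earlier* of the first E / first I cluster is
# Normal(AN_FIRST_LATENCY_MEAN, AN_FIRST_LATENCY_SD); the other class follows
# at |diff| where diff = I - E ~ Normal(0.14, 2.2) truncated to [-4.4, +3.5].
# Complex cells add later clusters ~3.3 ms after each first cluster.
AN_FIRST_LATENCY_MEAN = 4.85  # ms; solved so measured per-cell first-PSC mean is 5.51
AN_FIRST_LATENCY_SD = 0.90  # ms
AN_EI_DIFF_MEAN = 0.14  # ms
AN_EI_DIFF_SD = 2.2  # ms (generative; truncation narrows the realised SD)
AN_EI_DIFF_RANGE = (-4.4, 3.5)  # ms
AN_SECOND_OFFSET = 3.3  # ms
AN_CELL_LATENCY_SD = AN_FIRST_LATENCY_SD

AN_ARCHETYPES = [
    ArchetypeRow("complex_both", 7 / 11, True, True, True),
    ArchetypeRow("complex_e", 1 / 11, True, False, True),
    ArchetypeRow("e_only", 2 / 11, True, False, False),
    ArchetypeRow("i_only", 1 / 11, False, True, False),
]

# --- recording defaults ---------------------------------------------------
MDL_N_SWEEPS = 30
AN_N_SWEEPS = 40
STIM_TIME_MS = 5.0
SWEEP_DURATION_MS = 50.0
FS_KHZ = 50.0
NOISE_SD_PA = 4.0
ECL_MV = -20.0  # 60 mM internal chloride
AGE_RANGE_DAYS = (14, 19)
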