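"""Synthetic-data generator: determinism, polarity, ground-truth statistics."""

import numpy as np
import pandas as pd
import pytest

from mocsyn import params, synthgen, timing


def _one_cluster_spec(prob=1.0, n_sweeps=20, seed=0,
                      holding_potentials=(-60.0, 0.0), **cluster_kw):
    defaults = dict(kind="excitatory", latency_mean=2.0, latency_sd=0.3,
                    rise_mean=0.3, tau_mean=1.2, amp_mean=-60.0, amp_cv=0.3,
                    probability=prob)
    defaults.update(cluster_kw)
    return synthgen.RecordingSpec(clusters=(synthgen.ClusterSpec(**defaults),),
                                  n_sweeps=n_sweeps, seed=seed,
                                  holding_potentials=holding_potentials)


class TestVoltageClamp:
    def test_probability_one_and_excitatory_invisible_at_0mv(self):
        sweeps, truth = synthgen.generate_voltage_clamp(_one_cluster_spec())
        assert (truth.holding == -60.0).sum() == 20  # every sweep has its event
        assert (truth.holding == 0.0).sum() == 0  # AMPA reversal hides E

    def test_polarity_law(self, mixed_cell):
        _, _, truth = mixed_cell
        assert (truth.loc[truth.holding == -60.0, "amplitude"] < 0).all()
        assert (truth.loc[truth.holding == 0.0, "amplitude"] > 0).all()
        assert (truth.loc[truth.holding == 0.0, "kind"] == "inhibitory").all()

    def test_determinism_byte_identical(self):
        spec = _one_cluster_spec(seed=42)
        s1, t1 = synthgen.generate_voltage_clamp(spec)
        s2, t2 = synthgen.generate_voltage_clamp(spec)
        pd.testing.assert_frame_equal(t1, t2)
        for h in s1:
            for a, b in zip(s1[h], s2[h]):
                np.testing.assert_array_equal(a.current, b.current)

    def test_onset_statistics_law_of_large_numbers(self):
        # 10,000 events: sample mean/SD of true onsets within 2% of the spec
        spec = _one_cluster_spec(n_sweeps=10_000, seed=3,
                                 holding_potentials=(-60.0,))
        _, truth = synthgen.generate_voltage_clamp(spec)
        assert truth.onset.mean() == pytest.approx(2.0, rel=0.02)
        assert truth.onset.std() == pytest.approx(0.3, rel=0.02)

    def test_latency_floor(self):
        spec = _one_cluster_spec(latency_mean=0.15, latency_sd=0.5, seed=5,
                                 n_sweeps=200, holding_potentials=(-60.0,))
        _, truth = synthgen.generate_voltage_clamp(spec)
        assert (truth.onset >= synthgen.MIN_LATENCY_MS).all()

    def test_empty_cluster_list_rejected(self):
        with pytest.raises(ValueError):
            synthgen.RecordingSpec(clusters=())

    def test_invalid_cluster_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthgen.ClusterSpec("excitatory", 2.0, 0.3, 0.3, 1.2, -60.0, 0.3, 1.5)
        with pytest.raises(ValueError):
            synthgen.ClusterSpec("excitatory", 2.0, 0.3, 2.0, 1.2, -60.0, 0.3, 0.5)
        with pytest.raises(ValueError):
            synthgen.ClusterSpec("other", 2.0, 0.3, 0.3, 1.2, -60.0, 0.3, 0.5)


class TestCohort:
    def test_archetype_proportions_within_binomial_ci(self):
        cells = synthgen.generate_cohort(params.MDL_ARCHETYPES, 210, seed=0)
        counts = pd.Series([c.archetype for c in cells]).value_counts()
        for row in params.MDL_ARCHETYPES:
            p = row.frequency
            se = np.sqrt(p * (1 - p) / 210)
            assert abs(counts.get(row.name, 0) / 210 - p) < 3.5 * se

    def test_single_cell_single_archetype(self):
        table = [r for r in params.MDL_ARCHETYPES if r.name == "mixed"]
        table = [synthgen.params.ArchetypeRow("mixed", 1.0, True, True, False)]
        cells = synthgen.generate_cohort(table, 1, seed=0)
        assert len(cells) == 1 and cells[0].archetype == "mixed"

    def test_seeds_give_disjoint_streams_same_bookkeeping(self):
        a = synthgen.generate_cohort(params.MDL_ARCHETYPES, 10, seed=1)
        b = synthgen.generate_cohort(params.MDL_ARCHETYPES, 10, seed=2)
        a2 = synthgen.generate_cohort(params.MDL_ARCHETYPES, 10, seed=1)
        assert [c.archetype for c in a] == [c.archetype for c in a2]
        assert [c.spec.seed for c in a] == [c.spec.seed for c in a2]
        assert [c.spec.seed for c in a] != [c.spec.seed for c in b]

    def test_frequencies_must_sum_to_one(self):
        bad = [("a", 0.5), ("b", 0.3)]
        with pytest.raises(ValueError):
            synthgen.generate_cohort(bad, 5, seed=0)

    def test_mixed_archetype_carries_ei_difference(self):
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(200):
            cl = synthgen.sample_archetype_clusters("mixed", "MdL", rng)
            e = [c for c in cl if c.kind == "excitatory"][0]
            i = [c for c in cl if c.kind == "inhibitory"][0]
            diffs.append(i.latency_mean - e.latency_mean)
        assert np.mean(diffs) == pytest.approx(params.MDL_EI_DIFF_MEAN, abs=0.2)
        assert np.std(diffs) == pytest.approx(params.MDL_EI_DIFF_SD, rel=0.3)


class TestCurrentClamp:
    def test_zero_pulses_flat_no_aps(self):
        sw, truth = synthgen.generate_current_clamp(
            synthgen.TrainSpec(rates=(100.0,), n_pulses=0, n_repeats=2), seed=0)
        t, v = sw[100.0][0]
        assert truth[100.0] == [[], []]
        assert v.max() < -40.0

    def test_ap_metric_code_recovers_injected_aps(self):
        tsp = synthgen.TrainSpec(rates=(100.0,), with_inhibition=False, n_repeats=5)
        sw, truth = synthgen.generate_current_clamp(tsp, seed=2)
        for (t, v), aps in zip(sw[100.0], truth[100.0]):
            det = timing.detect_aps(t, v, threshold=-20.0)
            assert len(det) == len(aps)

    def test_blocking_inhibition_increases_ap_bearing_sweeps(self):
        kw = dict(rates=(100.0,), n_repeats=8)
        sw_c, tr_c = synthgen.generate_current_clamp(
            synthgen.TrainSpec(with_inhibition=True, **kw), seed=2)
        sw_n, tr_n = synthgen.generate_current_clamp(
            synthgen.TrainSpec(with_inhibition=False, **kw), seed=2)
        n_c = sum(len(a) > 0 for a in tr_c[100.0])
        n_n = sum(len(a) > 0 for a in tr_n[100.0])
        assert n_n > n_c


class TestCalciumGenerator:
    def test_inactive_rois_are_noise_only(self):
        spec = synthgen.CalciumSpec(n_rois=10, active_fraction=0.0, seed=1)
        df = synthgen.generate_calcium(spec)
        base = df[df.condition == "control"].groupby("roi_id").fluorescence
        assert (base.std() < 3 * spec.noise_sd).all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            synthgen.CalciumSpec(drug_scale=1.5)
        with pytest.raises(ValueError):
            synthgen.CalciumSpec(baseline_f=0.0)
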