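"""Latency clustering, cluster statistics, and E/I labeling by holding."""

import numpy as np
import pytest

from mocsyn import cluster, detect, synthgen
from mocsyn.detect import PSCEvent


def _events(onsets, sweep_ids=None, rise=0.3, tau=1.2):
    if sweep_ids is None:
        sweep_ids = range(len(onsets))
    return [PSCEvent(onset_latency=o, rise_10_90=rise, amplitude=-50.0,
                     tau_decay=tau, time_to_peak=0.5, sweep_id=s)
            for o, s in zip(onsets, sweep_ids)]


def _detected(spec):
    sweeps, truth = synthgen.generate_voltage_clamp(spec)
    out = {}
    for h, sws in sweeps.items():
        out[h] = [e for sw in sws for e in detect.detect_events(sw)]
    return out, truth


class TestClusterEvents:
    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(0)
        onsets = np.r_[rng.normal(2.0, 0.2, 40), rng.normal(5.0, 0.2, 40)]
        cls = cluster.cluster_events(_events(onsets, sweep_ids=list(range(40)) * 2),
                                     n_sweeps=40)
        assert len(cls) == 2
        assert cls[0].latency_mu == pytest.approx(2.0, abs=0.1)
        assert cls[1].latency_mu == pytest.approx(5.0, abs=0.1)

    def test_single_cluster_gives_k1(self):
        rng = np.random.default_rng(1)
        cls = cluster.cluster_events(_events(rng.normal(2.0, 0.3, 50)), n_sweeps=50)
        assert len(cls) == 1

    def test_fewer_than_three_events_low_n(self):
        cls = cluster.cluster_events(_events([2.0, 2.1]), n_sweeps=10)
        assert len(cls) == 1 and cls[0].low_n

    def test_complex_cell_four_clusters(self):
        spec = synthgen.RecordingSpec(
            clusters=(
                synthgen.ClusterSpec("excitatory", 1.7, 0.28, 0.30, 1.2, -60.0, 0.3, 0.85),
                synthgen.ClusterSpec("excitatory", 2.8, 0.28, 0.30, 1.2, -60.0, 0.3, 0.85),
                synthgen.ClusterSpec("inhibitory", 4.5, 0.45, 0.60, 4.5, -55.0, 0.3, 0.35),
                synthgen.ClusterSpec("inhibitory", 7.7, 0.45, 0.60, 4.5, -55.0, 0.3, 0.35)),
            n_sweeps=40, noise_sd=4.0, seed=11, holding_potentials=(-60.0,))
        evs, _ = _detected(spec)
        cls = cluster.cluster_events(evs[-60.0], n_sweeps=40)
        assert len(cls) == 4
        mus = [c.latency_mu for c in cls]
        for got, want in zip(mus, (1.7, 2.8, 4.5, 7.7)):
            assert got == pytest.approx(want, abs=0.3)

    def test_order_stable_under_event_permutation(self):
        rng = np.random.default_rng(2)
        onsets = np.r_[rng.normal(2.0, 0.2, 30), rng.normal(5.0, 0.2, 30)]
        evs = _events(onsets, sweep_ids=list(range(30)) * 2)
        cls1 = cluster.cluster_events(evs, n_sweeps=30)
        perm = rng.permutation(len(evs))
        cls2 = cluster.cluster_events([evs[i] for i in perm], n_sweeps=30)
        assert [round(c.latency_mu, 6) for c in cls1] == \
               [round(c.latency_mu, 6) for c in cls2]

    def test_roundtrip_latency_and_probability_recovery(self, mixed_cell):
        spec, _, _ = mixed_cell
        evs, _ = _detected(spec)
        cls = cluster.cluster_events(evs[-60.0], n_sweeps=spec.n_sweeps)
        assert len(cls) == 2
        for cl, true in zip(cls, spec.clusters):
            assert cl.latency_mu == pytest.approx(true.latency_mean, abs=0.2)
            assert cl.probability == pytest.approx(true.probability, abs=0.08)


class TestClusterStats:
    def test_hand_computed_oracle(self):
        evs = _events([2.0, 2.2, 1.8], sweep_ids=[0, 1, 2])
        cl = cluster.cluster_events(evs, n_sweeps=4)[0]
        jit, pjit, prob = cluster.cluster_stats(cl, evs, n_sweeps=4)
        assert jit == pytest.approx(0.2)
        assert prob == pytest.approx(0.75)

    def test_identical_onsets_zero_jitter(self):
        evs = _events([2.0, 2.0, 2.0], sweep_ids=[0, 1, 2])
        cl = cluster.cluster_events(evs, n_sweeps=3)[0]
        jit, _, _ = cluster.cluster_stats(cl, evs, n_sweeps=3)
        assert jit == pytest.approx(0.0)

    def test_single_member_jitter_undefined(self):
        jit, pjit = cluster.cluster_stats_arrays(np.array([2.0]), np.array([2.5]))
        assert np.isnan(jit) and np.isnan(pjit)

    def test_empty_cluster_raises(self):
        cl = cluster.PSCCluster([], 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            cluster.cluster_stats(cl, [], 10)

    def test_synthetic_jitter_probability_recovery(self):
        spec = synthgen.RecordingSpec(
            clusters=(synthgen.ClusterSpec("excitatory", 2.5, 0.3, 0.30, 1.2,
                                           -60.0, 0.3, 0.8),),
            n_sweeps=80, noise_sd=3.0, seed=6, holding_potentials=(-60.0,))
        evs, _ = _detected(spec)
        cls = cluster.cluster_events(evs[-60.0], n_sweeps=80)
        assert len(cls) == 1
        assert cls[0].onset_jitter == pytest.approx(0.3, abs=0.05)
        assert cls[0].probability == pytest.approx(0.8, abs=0.05)


class TestLabelByHolding:
    def _cl(self, mu, n=10):
        return cluster.PSCCluster(list(range(n)), mu, 0.2, 0.2, 0.3, 0.8)

    def test_paired_cluster_is_inhibitory(self):
        minus60 = [self._cl(1.9), self._cl(4.7)]
        zero = [self._cl(4.7)]
        out = cluster.label_by_holding(minus60, zero)
        assert [c.label for c in out] == ["excitatory", "inhibitory"]

    def test_no_0mv_clusters_all_excitatory(self):
        out = cluster.label_by_holding([self._cl(2.0), self._cl(5.0)], [])
        assert all(c.label == "excitatory" for c in out)

    def test_missing_0mv_recording_labels_unknown(self):
        out = cluster.label_by_holding([self._cl(2.0)], None)
        assert out[0].label == "unknown"

    def test_each_0mv_cluster_matched_once(self):
        minus60 = [self._cl(4.5), self._cl(4.9)]
        zero = [self._cl(4.7)]
        out = cluster.label_by_holding(minus60, zero)
        assert sorted(c.label for c in out) == ["excitatory", "inhibitory"]

    def test_cohort_label_accuracy_at_low_jitter(self, mixed_cell):
        spec, _, _ = mixed_cell
        evs, _ = _detected(spec)
        c60 = cluster.cluster_events(evs[-60.0], n_sweeps=spec.n_sweeps)
        c0 = cluster.cluster_events(evs[0.0], n_sweeps=spec.n_sweeps)
        out = cluster.label_by_holding(c60, c0)
        assert [c.label for c in out] == ["excitatory", "inhibitory"]
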