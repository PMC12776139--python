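"""Explore/retreat detection and signal-conditioned event probability."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from conftest import make_ztrace
from sertflow.actions import (
    conditional_event_probability,
    detect_transitions,
    initiation_signal,
    TransitionEvents,
)
from sertflow.synth import simulate_actions
from sertflow.types import ValidationError, ZoneSeries


def zone_series_from_schedule(schedule, fs=30.0):
    """Build a zone series from (label, duration_s) segments."""
    labels = []
    for label, dur in schedule:
        labels.extend([label] * int(round(dur * fs)))
    return ZoneSeries(t=np.arange(len(labels)) / fs, zone=np.array(labels, dtype=object))


class TestDetectTransitions:
    def test_basic_explore_and_retreat(self):
        zones = zone_series_from_schedule(
            [("closed", 5.0), ("center", 2.0), ("open", 3.0), ("center", 3.0)])
        ev = detect_transitions(zones, min_commit=1.0)
        assert len(ev.explores) == 1 and len(ev.retreats) == 1
        assert ev.explores[0] == pytest.approx(7.0, abs=1 / 30)
        assert ev.retreats[0] == pytest.approx(10.0, abs=1 / 30)

    def test_subthreshold_excursion_ignored(self):
        zones = zone_series_from_schedule(
            [("center", 5.0), ("open", 0.4), ("center", 5.0)])
        ev = detect_transitions(zones, min_commit=1.0)
        assert len(ev.explores) == 0 and len(ev.retreats) == 0

    def test_session_start_in_open_allows_retreat(self):
        # the animal is placed in the open arm at session start
        zones = zone_series_from_schedule([("open", 4.0), ("center", 4.0)])
        ev = detect_transitions(zones, min_commit=1.0)
        assert len(ev.explores) == 0 and len(ev.retreats) == 1

    def test_brief_center_dip_blocks_retreat(self):
        zones = zone_series_from_schedule(
            [("center", 3.0), ("open", 3.0), ("center", 0.4), ("open", 3.0), ("center", 3.0)])
        ev = detect_transitions(zones, min_commit=1.0)
        # the 0.4 s dip is not a committed retreat; explore fires on both entries
        assert len(ev.retreats) == 1
        assert ev.retreats[0] == pytest.approx(9.4, abs=2 / 30)

    def test_schedule_round_trip(self):
        # known crossing times are recovered exactly at matching min_commit
        rng = np.random.default_rng(4)
        schedule = [("closed", 10.0)]
        expected_explores, expected_retreats = [], []
        t = 10.0
        for _ in range(6):
            c = float(rng.uniform(2.0, 5.0))
            o = float(rng.uniform(2.0, 5.0))
            schedule.append(("center", c))
            t += c
            expected_explores.append(t)
            schedule.append(("open", o))
            t += o
            expected_retreats.append(t)
        schedule.append(("center", 5.0))
        zones = zone_series_from_schedule(schedule)
        ev = detect_transitions(zones, min_commit=1.0)
        np.testing.assert_allclose(ev.explores, expected_explores, atol=2 / 30)
        np.testing.assert_allclose(ev.retreats[:-1], expected_retreats[:-1], atol=2 / 30)

    def test_empty_series(self):
        ev = detect_transitions(ZoneSeries(t=np.array([]), zone=np.array([], dtype=object)))
        assert len(ev.explores) == 0 and len(ev.retreats) == 0


class TestInitiationSignal:
    def test_constant_signal(self):
        z = make_ztrace(np.full(3000, 0.7))
        ev = TransitionEvents(explores=[10.0, 40.0], retreats=[20.0], min_commit=1.0)
        table, dropped = initiation_signal(z, ev, window=(0.0, 2.0))
        assert dropped == 0
        np.testing.assert_allclose(table["mean_z"], 0.7)

    def test_step_at_retreat_only(self):
        fs = 30.0
        t = np.arange(3000) / fs
        retreats = [30.0, 60.0]
        z = np.zeros_like(t)
        for r in retreats:
            z[(t >= r) & (t < r + 2.0)] = 1.0
        ev = TransitionEvents(explores=[10.0, 45.0], retreats=retreats, min_commit=1.0)
        table, _ = initiation_signal(make_ztrace(z, fs=fs), ev, window=(0.0, 2.0))
        by_type = table.groupby("event_type")["mean_z"].mean()
        assert by_type["retreat"] == pytest.approx(1.0)
        assert by_type["explore"] == pytest.approx(0.0)

    def test_no_events_gives_empty_frame(self):
        z = make_ztrace(np.zeros(300))
        ev = TransitionEvents(explores=[], retreats=[], min_commit=1.0)
        table, dropped = initiation_signal(z, ev)
        assert len(table) == 0 and dropped == 0

    def test_event_near_session_end_dropped(self):
        z = make_ztrace(np.zeros(300))  # 10 s at 30 Hz
        ev = TransitionEvents(explores=[9.5], retreats=[], min_commit=1.0)
        table, dropped = initiation_signal(z, ev, window=(0.0, 2.0))
        assert dropped == 1 and len(table) == 0


def all_zone(n, fs, label):
    return ZoneSeries(t=np.arange(n) / fs, zone=np.array([label] * n, dtype=object))


class TestConditionalProbability:
    def test_events_only_at_negative_z(self):
        fs = 10.0
        n = 6000
        rng = np.random.default_rng(0)
        z = rng.normal(0, 1, n)
        t = np.arange(n) / fs
        zones = all_zone(n, fs, "center")
        event_times = t[(z < -1.0)][::5]
        curve = conditional_event_probability(
            make_ztrace(z, fs=fs), zones, event_times, "explore", horizon=0.05,
            bin_edges=np.array([-5.0, 0.0, 5.0]))
        assert curve.p[1] == 0.0

    def test_horizon_zero_probability_zero(self):
        fs = 10.0
        n = 1000
        zones = all_zone(n, fs, "center")
        z = make_ztrace(np.random.default_rng(1).normal(0, 1, n), fs=fs)
        curve = conditional_event_probability(z, zones, np.array([10.0, 20.0]), "explore",
                                              horizon=0.0, n_bins=4)
        assert np.nansum(curve.p) == 0.0

    def test_counts_conserve_eligible_samples(self):
        fs = 10.0
        n = 6000
        rng = np.random.default_rng(2)
        labels = np.where(rng.random(n) < 0.5, "center", "closed").astype(object)
        zones = ZoneSeries(t=np.arange(n) / fs, zone=labels)
        z = make_ztrace(rng.normal(0, 1, n), fs=fs)
        horizon = 10.0
        curve = conditional_event_probability(z, zones, np.array([50.0]), "explore",
                                              horizon=horizon, n_bins=5)
        step = int(round(fs / 1.0))
        cand = np.arange(0, n, step)
        cand = cand[labels[cand] == "center"]
        cand = cand[z.t[cand] + horizon <= z.t[-1] + 1 / fs]
        assert curve.n.sum() == len(cand)

    def test_directionality_and_oracle_recovery(self):
        # generator hazards with opposite slopes produce opposite monotone
        # curves, each within a design-effect-adjusted binomial CI of the
        # exact survival oracle
        fs, dur, horizon = 10.0, 600.0, 10.0
        n = int(dur * fs)
        t = np.arange(n) / fs
        H = int(horizon * fs)
        results = {"explore": [], "retreat": []}
        ci_ok, ci_total = 0, 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            z = np.cumsum(rng.normal(0, 1, n))
            z = (z - z.mean()) / z.std()
            for etype, (b0, b1) in (("explore", (-4.0, -1.0)), ("retreat", (-4.0, 1.0))):
                zone_label = "center" if etype == "explore" else "open"
                zones = all_zone(n, fs, zone_label)
                log = simulate_actions(zones, z, {etype: (b0, b1)}, seed=seed + 100)
                times = np.array([a for a, _ in log.for_label(etype)])
                curve = conditional_event_probability(
                    make_ztrace(z, fs=fs), zones, times, etype, horizon=horizon, n_bins=5,
                    eligible_zone=zone_label)
                rho, _ = spearmanr(np.arange(len(curve.p)), curve.p)
                results[etype].append(rho)
                # exact oracle: P(>=1 event in (t, t+H]) from the hazard survival
                p = expit(b0 + b1 * z)
                S = np.concatenate([[0.0], np.cumsum(np.log1p(-p))])
                step = int(fs)
                cand = np.arange(0, n, step)
                cand = cand[t[cand] + horizon <= t[-1] + 1 / fs]
                upper = np.minimum(cand + H, n - 1) + 1  # draws exist up to sample n-1
                po = 1.0 - np.exp(S[upper] - S[cand + 1])
                which = np.clip(np.digitize(z[cand], curve.bin_edges) - 1, 0, len(curve.p) - 1)
                po_bin = np.array([po[which == b].mean() for b in range(len(curve.p))])
                deff = horizon * 1.0  # overlapping 10 s horizons sampled at 1 Hz
                se = np.sqrt(po_bin * (1 - po_bin) * deff / np.maximum(curve.n, 1))
                ok = np.abs(curve.p - po_bin) <= 3 * se + 1.0 / np.maximum(curve.n, 1)
                ci_ok += int(ok.sum())
                ci_total += len(ok)
        assert np.mean(np.array(results["explore"]) < 0) >= 0.95
        assert np.mean(np.array(results["retreat"]) > 0) >= 0.95
        assert ci_ok / ci_total >= 0.95

    def test_quantile_bins_invariant_to_affine_rescaling(self):
        fs = 10.0
        n = 3000
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, n)
        zones = all_zone(n, fs, "center")
        times = np.sort(rng.uniform(0, n / fs, 30))
        a = conditional_event_probability(make_ztrace(z, fs=fs), zones, times, "explore", n_bins=5)
        b = conditional_event_probability(make_ztrace(2.0 * z + 3.0, fs=fs), zones, times,
                                          "explore", n_bins=5)
        np.testing.assert_allclose(a.p, b.p)
        np.testing.assert_array_equal(a.n, b.n)

    def test_empty_eligible_set(self):
        fs = 10.0
        zones = all_zone(100, fs, "closed")
        z = make_ztrace(np.zeros(100), fs=fs)
        curve = conditional_event_probability(z, zones, np.array([1.0]), "explore")
        assert len(curve.p) == 0
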