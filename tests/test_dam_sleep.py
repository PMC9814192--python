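"""Sleep-bout scoring, architecture, dead-fly filtering, rebound, DAM i/o."""

import math
from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from mamsleep.dam_sleep import (
    DAY_MIN,
    HALF_DAY_MIN,
    ActivityTrace,
    baseline_average,
    filter_dead,
    profile_30min,
    read_dam,
    rebound_analysis,
    records_to_frame,
    score_sleep,
    sleep_architecture,
    stability,
    write_dam,
)
from mamsleep.errors import FormatError

START = datetime(2023, 1, 9, 8, 0, 0)


def trace_from(counts, fly_id="f1", genotype="ctrl"):
    return ActivityTrace(fly_id, genotype, START, np.asarray(counts, dtype=int))


def day_counts(sleep_plan):
    """Build one 1440-min day: sleep_plan is a list of (start, length) zero
    runs; all other minutes get activity 1."""
    counts = np.ones(DAY_MIN, dtype=int)
    for start, length in sleep_plan:
        counts[start:start + length] = 0
    return counts


class TestScoreSleep:
    def test_five_zero_minutes_are_one_bout(self):
        counts = [1] * 10 + [0] * 5 + [1] * 10
        sleep, bouts = score_sleep(trace_from(counts))
        assert sleep.sum() == 5
        assert [b for b in bouts if b.is_sleep] == [(10, 5, True)]

    def test_four_zero_minutes_are_not_sleep(self):
        counts = [1] * 10 + [0] * 4 + [1] * 10
        sleep, bouts = score_sleep(trace_from(counts))
        assert sleep.sum() == 0
        assert all(not b.is_sleep for b in bouts)

    def test_interrupted_inactivity_gives_two_bouts(self):
        counts = [0] * 7 + [2] + [0] * 6
        sleep, bouts = score_sleep(trace_from(counts))
        assert sleep.sum() == 13
        assert [(b.start, b.length) for b in bouts if b.is_sleep] == [(0, 7), (8, 6)]

    def test_conservation_sleep_plus_wake(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 3, size=DAY_MIN)
        tr = trace_from(counts)
        sleep, bouts = score_sleep(tr)
        total = sum(b.length for b in bouts)
        assert total == DAY_MIN
        assert sleep.sum() + sum(b.length for b in bouts if not b.is_sleep) == DAY_MIN

    def test_splitting_property_under_perturbation(self):
        """Waking one minute inside a sleep bout of length L leaves sleep
        runs totalling L-1, minus any fragment shorter than 5 min."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            L = int(rng.integers(5, 60))
            pos = int(rng.integers(0, L))
            counts = np.ones(L + 20, dtype=int)
            counts[10:10 + L] = 0
            base_sleep, _ = score_sleep(trace_from(counts))
            counts[10 + pos] = 3
            new_sleep, _ = score_sleep(trace_from(counts))
            left, right = pos, L - pos - 1
            expected = (left if left >= 5 else 0) + (right if right >= 5 else 0)
            assert base_sleep.sum() == L
            assert new_sleep.sum() == expected


class TestArchitecture:
    def test_boundary_spanning_bout_split_for_totals_counted_by_onset(self):
        # 20-min bout centred on lights-off: 10 light + 10 dark minutes,
        # counted once as a light-period bout
        plan = [(HALF_DAY_MIN - 10, 20), (100, 30)]
        rec = sleep_architecture(trace_from(day_counts(plan)), 0)
        assert rec.sleep_light_min == 10 + 30
        assert rec.sleep_dark_min == 10
        assert rec.n_bouts == 2
        assert rec.n_bouts_light == 2
        assert rec.n_bouts_dark == 0

    def test_stability_sign_conventions(self):
        # max sleep 120, max wake 300 -> methods convention: +180 (wakeful)
        plan = [(0, 120), (420, 60)]
        rec = sleep_architecture(trace_from(day_counts(plan)), 0)
        assert rec.max_sleep_bout_min == 120
        assert rec.max_wake_bout_min == DAY_MIN - 480
        assert stability(rec, "methods") == rec.max_wake_bout_min - 120
        assert stability(rec, "figure") == -(rec.max_wake_bout_min - 120)
        rec2 = sleep_architecture(
            trace_from(np.concatenate([
                day_counts([(0, 120)])[:720],
                day_counts([(0, 300)])[:720],
            ])), 0)
        assert rec2.stability_min == pytest.approx(
            rec2.max_wake_bout_min - rec2.max_sleep_bout_min
        )

    def test_latency_from_lights_off(self):
        # first dark sleep bout starts 37 min after lights-off
        plan = [(HALF_DAY_MIN + 37, 25)]
        rec = sleep_architecture(trace_from(day_counts(plan)), 0)
        assert rec.latency_min == 37

    def test_incomplete_day_is_an_error(self):
        tr = trace_from(np.ones(1000, dtype=int))
        with pytest.raises(ValueError):
            sleep_architecture(tr, 0)

    def test_light_dark_totals_sum_to_24h(self, fly_batch):
        traces, _ = fly_batch
        for tr in traces:
            rec = sleep_architecture(tr, 0)
            assert rec.sleep_light_min + rec.sleep_dark_min == rec.sleep_total_min


class TestBaselineAverage:
    def test_identical_days(self):
        counts = np.tile(day_counts([(800, 100)]), 4)
        tr = trace_from(counts)
        recs = [sleep_architecture(tr, d) for d in range(4)]
        avg = baseline_average(recs)
        assert avg.sleep_total_min == recs[0].sleep_total_min

    def test_mean_of_varying_days(self):
        days = [day_counts([(800, t)]) for t in (500, 520, 540, 560)]
        tr = trace_from(np.concatenate(days))
        recs = [sleep_architecture(tr, d) for d in range(4)]
        assert baseline_average(recs).sleep_total_min == 530

    def test_missing_day_is_an_error(self):
        counts = np.tile(day_counts([(800, 100)]), 4)
        tr = trace_from(counts)
        recs = [sleep_architecture(tr, d) for d in range(3)]
        with pytest.raises(ValueError, match="3"):
            baseline_average(recs)


class TestFilterDead:
    def test_terminal_immobility_removes_fly(self):
        counts = np.concatenate([np.ones(600, dtype=int), np.zeros(18 * 60, dtype=int)])
        survivors, log = filter_dead([trace_from(counts)])
        assert survivors == []
        assert log["death_onset_bin"].iloc[0] == 600

    def test_long_sleep_below_threshold_is_kept(self):
        counts = np.concatenate([np.ones(600, dtype=int), np.zeros(11 * 60, dtype=int)])
        survivors, log = filter_dead([trace_from(counts)])
        assert len(survivors) == 1 and log.empty

    def test_all_active_empty_log(self):
        survivors, log = filter_dead([trace_from(np.ones(2000, dtype=int))])
        assert len(survivors) == 1 and log.empty


class TestRebound:
    def _records(self, totals):
        recs = {}
        for fly_id, t in totals.items():
            recs[fly_id] = None
            recs[fly_id] = _mk_record(fly_id, t)
        return recs

    def test_no_change_gives_zero_deltas(self):
        base = {f"f{i}": _mk_record(f"f{i}", 600.0) for i in range(6)}
        post = {f"f{i}": _mk_record(f"f{i}", 600.0) for i in range(6)}
        genotypes = {f"f{i}": "g1" if i < 3 else "g2" for i in range(6)}
        df, comps = rebound_analysis(base, post, genotypes, n_boot=0)
        assert (df["delta_min"] == 0).all()
        assert comps[0].p_value > 0.9

    def test_percent_delta(self):
        base = {"f0": _mk_record("f0", 600.0), "f1": _mk_record("f1", 600.0)}
        post = {"f0": _mk_record("f0", 660.0), "f1": _mk_record("f1", 660.0)}
        df, _ = rebound_analysis(base, post, {"f0": "g", "f1": "g"}, n_boot=0)
        assert df["delta_pct"].iloc[0] == pytest.approx(10.0)

    def test_unmatched_ids_raise(self):
        base = {"f0": _mk_record("f0", 600.0), "f1": _mk_record("f1", 600.0)}
        post = {"f0": _mk_record("f0", 660.0)}
        with pytest.raises(ValueError, match="f1"):
            rebound_analysis(base, post, {"f0": "g"}, n_boot=0)


class TestProfile:
    def test_all_sleep_trace(self):
        tr = trace_from(np.zeros(DAY_MIN, dtype=int))
        prof = profile_30min([tr], [0])
        assert (prof["mean_sleep_min"] == 30).all()

    def test_all_wake_trace(self):
        tr = trace_from(np.ones(DAY_MIN, dtype=int))
        prof = profile_30min([tr], [0])
        assert (prof["mean_sleep_min"] == 0).all()


class TestDamIO:
    def test_round_trip(self, tmp_path, fly_batch):
        traces, _ = fly_batch
        path = tmp_path / "monitor.txt"
        write_dam(path, traces)
        cmap = pd.DataFrame({
            "channel": range(1, len(traces) + 1),
            "fly_id": [t.fly_id for t in traces],
            "genotype": [t.genotype for t in traces],
        })
        again = read_dam(path, channel_map=cmap)
        assert len(again) == 32
        for orig, back in zip(traces, again):
            assert back.fly_id == orig.fly_id
            np.testing.assert_array_equal(back.counts, orig.counts)
            assert back.lights_on_offset == 0

    def test_three_rows_give_32_short_traces(self, tmp_path):
        path = tmp_path / "m.txt"
        tr = [ActivityTrace(f"f{i}", "g", START, np.array([1, 0, 2])) for i in range(32)]
        write_dam(path, tr)
        traces = read_dam(path)
        assert len(traces) == 32
        assert all(t.counts.size == 3 for t in traces)

    def test_error_status_row_flags_bins(self, tmp_path):
        path = tmp_path / "m.txt"
        tr = [ActivityTrace(f"f{i}", "g", START, np.array([1, 1, 1])) for i in range(32)]
        write_dam(path, tr)
        lines = path.read_text().splitlines()
        parts = lines[1].split("\t")
        parts[3] = "51"  # monitor error status
        lines[1] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        traces = read_dam(path)
        assert not traces[0].valid[1]
        assert traces[0].counts[1] == 1  # counts retained

    def test_timestamp_gap_is_an_error(self, tmp_path):
        path = tmp_path / "m.txt"
        tr = [ActivityTrace(f"f{i}", "g", START, np.array([1, 1, 1])) for i in range(32)]
        write_dam(path, tr)
        lines = path.read_text().splitlines()
        path.write_text("\n".join([lines[0], lines[2]]) + "\n")
        with pytest.raises(FormatError, match="gap"):
            read_dam(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "m.txt"
        tr = [ActivityTrace(f"f{i}", "g", START, np.array([1, 1])) for i in range(32)]
        write_dam(path, tr)
        with open(path, "a") as fh:
            fh.write("garbage line\n")
        with pytest.raises(FormatError, match=":3"):
            read_dam(path)


def _mk_record(fly_id, total):
    from mamsleep.dam_sleep import SleepRecord

    return SleepRecord(
        fly_id=fly_id, genotype="g", day=0.0,
        sleep_total_min=total, sleep_light_min=total / 3, sleep_dark_min=2 * total / 3,
        n_bouts=20.0, n_bouts_light=8.0, n_bouts_dark=12.0,
        mean_bout_min=total / 20, mean_bout_light_min=10.0, mean_bout_dark_min=30.0,
        max_sleep_bout_min=90.0, max_wake_bout_min=60.0,
        stability_min=-30.0, latency_min=15.0,
    )
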