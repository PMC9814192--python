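"""Drosophila sleep scoring from 1-min activity-monitor counts.

Sleep is five or more consecutive minutes of zero beam-crossing counts.
A day runs lights-on to lights-on (12 h light, 12 h dark).  Bouts that
span a light/dark (or day) boundary contribute their minutes to each
window but are counted once, in the window containing their onset.
Sleep stability is ``max wake bout - max sleep bout`` (positive = more
wakeful); the opposite sign convention is available via
``stability_convention="figure"``.  Latency is measured from lights-off to
the onset of the first sleep bout starting in the dark period.

Monitor rows whose status is not OK are treated as missing: they break
bout runs and are excluded from totals; days with more than 5 % missing
bins should be excluded upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from datetime import datetime, timedelta
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError
from . import stats as mstats

MIN_SLEEP_BOUT = 5          # minutes of inactivity defining sleep
DAY_MIN = 1440
HALF_DAY_MIN = 720
DEAD_IMMOBILE_MIN = 720     # terminal immobility (>= 12 h) marking a dead fly
DAM_META_COLS = 10          # reading idx, date, time, status, 6 bookkeeping
DAM_CHANNELS = 32
OK_STATUS = 1


@dataclass
class ActivityTrace:
    """One fly's 1-min activity counts with its light schedule.

    ``lights_on_offset`` is the index of the first bin of the first full
    light period; daily summaries use whole days from that bin on.
    ``valid`` marks bins with an OK monitor status.
    """

    fly_id: str
    genotype: str
    start: datetime
    counts: np.ndarray
    lights_on_offset: int = 0
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError(f"{self.fly_id}: negative activity counts")
        if self.valid is None:
            self.valid = np.ones(self.counts.size, dtype=bool)

    @property
    def n_days(self) -> int:
        return (self.counts.size - self.lights_on_offset) // DAY_MIN

    def day_slice(self, day: int) -> slice:
        start = self.lights_on_offset + day * DAY_MIN
        stop = start + DAY_MIN
        if stop > self.counts.size:
            raise ValueError(f"{self.fly_id}: day {day} is incomplete")
        return slice(start, stop)


class Bout(NamedTuple):
    """A maximal sleep or wake run (indices into the trace, minutes)."""

    start: int
    length: int
    is_sleep: bool


@dataclass
class SleepRecord:
    """Sleep architecture of one fly over one 24-h day."""

    fly_id: str
    genotype: str
    day: float
    sleep_total_min: float
    sleep_light_min: float
    sleep_dark_min: float
    n_bouts: float
    n_bouts_light: float
    n_bouts_dark: float
    mean_bout_min: float
    mean_bout_light_min: float
    mean_bout_dark_min: float
    max_sleep_bout_min: float
    max_wake_bout_min: float
    stability_min: float
    latency_min: float

    _NUMERIC = (
        "day", "sleep_total_min", "sleep_light_min", "sleep_dark_min",
        "n_bouts", "n_bouts_light", "n_bouts_dark",
        "mean_bout_min", "mean_bout_light_min", "mean_bout_dark_min",
        "max_sleep_bout_min", "max_wake_bout_min", "stability_min", "latency_min",
    )


def score_sleep(trace: ActivityTrace) -> tuple[np.ndarray, list[Bout]]:
    """Boolean per-bin sleep vector plus the list of sleep/wake bouts.

    Sleep bins are exactly the bins inside maximal runs of >= 5 consecutive
    valid zero-count bins.  Invalid bins break runs and belong to no bout.
    """
    zero = (trace.counts == 0) & trace.valid
    sleep = np.zeros_like(zero)
    bouts: list[Bout] = []
    n = zero.size
    # maximal zero-runs
    padded = np.concatenate([[False], zero, [False]])
    starts = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)
    ends = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)
    for s, e in zip(starts, ends):
        if e - s >= MIN_SLEEP_BOUT:
            sleep[s:e] = True
    # wake bouts: maximal valid non-sleep runs
    awake = trace.valid & ~sleep
    padded = np.concatenate([[False], awake, [False]])
    w_starts = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == 1)
    w_ends = np.flatnonzero(padded[1:].astype(int) - padded[:-1].astype(int) == -1)
    all_bouts = [Bout(int(s), int(e - s), True) for s, e in zip(starts, ends) if e - s >= MIN_SLEEP_BOUT]
    all_bouts += [Bout(int(s), int(e - s), False) for s, e in zip(w_starts, w_ends)]
    all_bouts.sort(key=lambda b: b.start)
    return sleep, all_bouts


def _overlap(bout_start: int, bout_len: int, win: slice) -> int:
    return max(0, min(bout_start + bout_len, win.stop) - max(bout_start, win.start))


def sleep_architecture(trace: ActivityTrace, day: int) -> SleepRecord:
    """Score one complete 24-h day of one fly (day 0 = first full day)."""
    win = trace.day_slice(day)  # raises on incomplete day
    light = slice(win.start, win.start + HALF_DAY_MIN)
    dark = slice(win.start + HALF_DAY_MIN, win.stop)
    sleep_vec, bouts = score_sleep(trace)

    sleep_total = int(sleep_vec[win].sum())
    sleep_light = int(sleep_vec[light].sum())
    sleep_dark = int(sleep_vec[dark].sum())

    def onset_in(b: Bout, w: slice) -> bool:
        return w.start <= b.start < w.stop

    sleep_day = [b for b in bouts if b.is_sleep and onset_in(b, win)]
    sleep_l = [b for b in sleep_day if onset_in(b, light)]
    sleep_d = [b for b in sleep_day if onset_in(b, dark)]
    wake_day = [b for b in bouts if not b.is_sleep and onset_in(b, win)]

    def mean_len(bs: list[Bout]) -> float:
        return sum(b.length for b in bs) / len(bs) if bs else math.nan

    max_sleep = max((b.length for b in sleep_day), default=0)
    max_wake = max((b.length for b in wake_day), default=0)
    first_dark_sleep = next((b for b in sleep_d), None)
    latency = float(first_dark_sleep.start - dark.start) if first_dark_sleep else math.nan

    return SleepRecord(
        fly_id=trace.fly_id,
        genotype=trace.genotype,
        day=float(day),
        sleep_total_min=float(sleep_total),
        sleep_light_min=float(sleep_light),
        sleep_dark_min=float(sleep_dark),
        n_bouts=float(len(sleep_day)),
        n_bouts_light=float(len(sleep_l)),
        n_bouts_dark=float(len(sleep_d)),
        mean_bout_min=mean_len(sleep_day),
        mean_bout_light_min=mean_len(sleep_l),
        mean_bout_dark_min=mean_len(sleep_d),
        max_sleep_bout_min=float(max_sleep),
        max_wake_bout_min=float(max_wake),
        stability_min=float(max_wake - max_sleep),
        latency_min=latency,
    )


def stability(record: SleepRecord, convention: str = "methods") -> float:
    """Sleep stability under either published sign convention:
    ``methods`` = max wake - max sleep (positive = wakeful);
    ``figure`` = max sleep - max wake."""
    if convention == "methods":
        return record.stability_min
    if convention == "figure":
        return -record.stability_min
    raise ValueError(f"unknown stability convention {convention!r}")


def baseline_average(records: Iterable[SleepRecord], n_days: int = 4) -> SleepRecord:
    """Per-fly arithmetic mean of each field over the baseline days."""
    records = list(records)
    days = sorted(r.day for r in records)
    if len(records) != n_days:
        raise ValueError(
            f"expected {n_days} baseline days, found {len(records)} (days {days})"
        )
    first = records[0]
    means = {}
    for name in SleepRecord._NUMERIC:
        vals = [getattr(r, name) for r in records]
        finite = [v for v in vals if not math.isnan(v)]
        means[name] = sum(finite) / len(finite) if finite else math.nan
    return SleepRecord(fly_id=first.fly_id, genotype=first.genotype, **means)


def filter_dead(traces: list[ActivityTrace]) -> tuple[list[ActivityTrace], pd.DataFrame]:
    """Remove flies immobile for >= 12 consecutive hours ending at the
    final bin; returns survivors plus a removal log with the estimated
    death-onset bin."""
    survivors, log_rows = [], []
    for tr in traces:
        nz = np.flatnonzero(tr.counts)
        last_active = int(nz[-1]) if nz.size else -1
        terminal_zero = tr.counts.size - 1 - last_active
        if terminal_zero >= DEAD_IMMOBILE_MIN:
            log_rows.append({"fly_id": tr.fly_id, "genotype": tr.genotype,
                             "death_onset_bin": last_active + 1,
                             "terminal_immobile_min": terminal_zero})
        else:
            survivors.append(tr)
    return survivors, pd.DataFrame(log_rows, columns=["fly_id", "genotype",
                                                      "death_onset_bin",
                                                      "terminal_immobile_min"])


def records_to_frame(records: Iterable[SleepRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(SleepRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)


def rebound_analysis(
    baseline: dict[str, SleepRecord],
    post_sd: dict[str, SleepRecord],
    genotypes: dict[str, str],
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[mstats.GroupComparison]]:
    """Per-fly sleep rebound and its group statistics.

    Rebound is (post-SD day total sleep) - (baseline mean total sleep) per
    fly, also as percent of baseline.  The genotype effect is tested with
    Kruskal-Wallis + Dunn on the deltas; baseline-vs-after within each
    genotype with Bonferroni-corrected paired Wilcoxon tests.
    """
    missing = sorted(set(baseline) ^ set(post_sd))
    if missing:
        raise ValueError(f"unmatched fly ids between baseline and post-SD: {missing}")
    rows = []
    for fly_id in sorted(baseline):
        b = baseline[fly_id].sleep_total_min
        p = post_sd[fly_id].sleep_total_min
        rows.append({
            "fly_id": fly_id,
            "genotype": genotypes[fly_id],
            "baseline_sleep_min": b,
            "post_sd_sleep_min": p,
            "delta_min": p - b,
            "delta_pct": (p - b) / b * 100.0 if b > 0 else math.nan,
        })
    df = pd.DataFrame(rows)
    groups = {g: sub["delta_min"].to_numpy() for g, sub in df.groupby("genotype")}
    paired = {
        g: (sub["baseline_sleep_min"].to_numpy(), sub["post_sd_sleep_min"].to_numpy())
        for g, sub in df.groupby("genotype")
    }
    if len(groups) >= 2:
        comparisons = mstats.compare_multi(
            groups, posthoc="dunn", paired_followup="wilcoxon", paired=paired,
            metric="rebound_delta_sleep_min", n_boot=n_boot, seed=seed,
        )
    else:  # single genotype: only the within-group baseline-vs-after contrast
        comparisons = mstats.compare_multi(
            dict(groups, _pool=df["baseline_sleep_min"].to_numpy()),
            posthoc="none", paired_followup="wilcoxon", paired=paired,
            metric="rebound_delta_sleep_min", n_boot=n_boot, seed=seed,
        )[1:]
    return df, comparisons


def profile_30min(traces: list[ActivityTrace], days: Iterable[int]) -> pd.DataFrame:
    """Group mean minutes asleep per 30-min bin across 24 h, with SEM.

    Bins are aligned to lights-on; each fly contributes its across-day
    mean per bin, so the SEM is over flies.
    """
    days = list(days)
    rows = []
    per_group: dict[str, list[np.ndarray]] = {}
    for tr in traces:
        sleep_vec, _ = score_sleep(tr)
        day_profiles = []
        for d in days:
            win = tr.day_slice(d)
            day_sleep = sleep_vec[win].astype(float)
            day_profiles.append(day_sleep.reshape(48, 30).sum(axis=1))
        per_group.setdefault(tr.genotype, []).append(np.mean(day_profiles, axis=0))
    for genotype, profiles in per_group.items():
        arr = np.asarray(profiles)
        mean = arr.mean(axis=0)
        sem = arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(48)
        for b in range(48):
            rows.append({"genotype": genotype, "bin": b, "t_min": b * 30,
                         "mean_sleep_min": mean[b], "sem": sem[b],
                         "n_flies": arr.shape[0]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trikinetics DAM text i/o
# ---------------------------------------------------------------------------

def read_dam(
    path,
    lights_on: str = "08:00:00",
    channel_map: pd.DataFrame | None = None,
) -> list[ActivityTrace]:
    """Parse a Trikinetics DAM monitor text file into 32 activity traces.

    Rows are tab-delimited: reading index, date (``%d %b %y``), time,
    monitor status (1 = OK), six bookkeeping fields, then 32 per-channel
    counts at 1-min bins.  Rows with a non-OK status keep their counts but
    are flagged invalid.  Raises :class:`FormatError` on malformed lines or
    a broken/non-monotonic 1-min timestamp grid.

    ``channel_map`` (columns ``channel``, ``fly_id``, ``genotype``) assigns
    identities; unmapped channels get ``<stem>_chNN`` ids.
    """
    timestamps: list[datetime] = []
    status: list[int] = []
    counts: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != DAM_META_COLS + DAM_CHANNELS:
                raise FormatError(
                    f"{path}:{lineno}: expected {DAM_META_COLS + DAM_CHANNELS} "
                    f"tab-separated fields, got {len(parts)}"
                )
            try:
                ts = datetime.strptime(f"{parts[1]} {parts[2]}", "%d %b %y %H:%M:%S")
                st = int(parts[3])
                row = [int(v) for v in parts[DAM_META_COLS:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line ({exc})") from exc
            timestamps.append(ts)
            status.append(st)
            counts.append(row)
    if not timestamps:
        raise FormatError(f"{path}: empty DAM file")
    for i in range(1, len(timestamps)):
        if timestamps[i] - timestamps[i - 1] != timedelta(minutes=1):
            raise FormatError(
                f"{path}: timestamp gap or non-monotonic step at row {i + 1} "
                f"({timestamps[i - 1]} -> {timestamps[i]})"
            )
    arr = np.asarray(counts, dtype=int)
    valid = np.asarray(status) == OK_STATUS
    start = timestamps[0]
    lights = datetime.strptime(lights_on, "%H:%M:%S").time()
    lights_dt = datetime.combine(start.date(), lights)
    offset = int((lights_dt - start).total_seconds() // 60) % DAY_MIN

    mapping = {}
    if channel_map is not None:
        for _, row in channel_map.iterrows():
            mapping[int(row["channel"])] = (str(row["fly_id"]), str(row["genotype"]))
    from pathlib import Path

    stem = Path(path).stem
    traces = []
    for ch in range(DAM_CHANNELS):
        fly_id, genotype = mapping.get(ch + 1, (f"{stem}_ch{ch + 1:02d}", ""))
        traces.append(
            ActivityTrace(
                fly_id=fly_id, genotype=genotype, start=start,
                counts=arr[:, ch], lights_on_offset=offset, valid=valid.copy(),
            )
        )
    return traces


def write_dam(path, traces: list[ActivityTrace], start: datetime | None = None) -> None:
    """Write up to 32 traces as a DAM monitor text file (inverse of
    :func:`read_dam`; traces must share length and start)."""
    if not traces or len(traces) > DAM_CHANNELS:
        raise ValueError("need 1-32 traces")
    n = traces[0].counts.size
    start = start or traces[0].start
    arr = np.zeros((n, DAM_CHANNELS), dtype=int)
    for ch, tr in enumerate(traces):
        if tr.counts.size != n:
            raise ValueError("traces must have equal length")
        arr[:, ch] = tr.counts
    with open(path, "w") as fh:
        for i in range(n):
            ts = start + timedelta(minutes=i)
            meta = [str(i + 1), ts.strftime("%d %b %y"), ts.strftime("%H:%M:%S"),
                    str(OK_STATUS)] + ["0"] * 6
            fh.write("\t".join(meta + [str(v) for v in arr[i]]) + "\n")
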