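"""Raw bilateral CBFV recordings -> per-task laterality indices.

The pipeline follows the fixed stage order

    downsample -> segment into epochs -> spike repair/reject -> normalize
    -> heart-cycle integrate -> range check -> baseline correct -> LI

with these rules:

* down-sampling 100 -> 25 Hz keeps every fourth sample starting at index 0;
* epochs span [-7, 26) s around each trial marker (825 samples at 25 Hz);
* spiking/dropout samples are those strictly outside the per-channel
  [0.0001, 0.9999] empirical quantiles of the whole session; one flagged
  sample in an epoch is repaired (replaced by the epoch-channel mean over
  the remaining samples), two or more reject the epoch;
* each channel is normalized to mean 100 (session-level mean by default);
* heart-cycle integration replaces samples within each cardiac cycle by the
  cycle mean, with cycle boundaries shared between channels;
* epochs containing any normalized sample below 60 or above 140 are
  rejected (evaluated on the mean-100 scale, before baseline subtraction);
* baseline correction subtracts the per-channel mean over [-5, 2) s;
* the laterality index is the time-average of the across-epoch mean
  left-minus-right difference over the period of interest (6-23 s, or
  6-17 s for the overt-report tasks A and D); positive = left dominant;
* a task with fewer than 12 acceptable epochs (of 15) is excluded; a
  subject with more than one excluded task in a session loses the session.

The legacy peak-based LI (absolute peak of the difference wave, averaged
over a 2 s window centred on it) is provided alongside the mean-based LI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

ACCEPTED = "accepted"
REPAIRED = "repaired_then_accepted"
REJECTED_SPIKE = "rejected_spike"
REJECTED_RANGE = "rejected_range"


@dataclass
class SignalRecording:
    """One session's bilateral CBFV time series plus trial markers.

    ``markers`` holds (sample_index, task_label) pairs with strictly
    increasing indices, one per trial onset ('CLEAR' stimulus).
    """

    sampling_rate: float
    left: np.ndarray
    right: np.ndarray
    markers: list[tuple[int, str]]
    subject: str = "S001"
    session: int = 1
    artifact_log: list | None = None

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left and right channels must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        idx = [m[0] for m in self.markers]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("marker indices must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class PreprocessConfig:
    """All thresholds and windows of the preprocessing pipeline (seconds/Hz)."""

    downsample_factor: int = 4
    epoch_start_s: float = -7.0
    epoch_length_s: float = 33.0
    spike_screening: bool = True
    spike_quantiles: tuple[float, float] = (0.0001, 0.9999)
    normalization_target: float = 100.0
    normalization_scope: str = "session"          # or "epoch"
    baseline_window_s: tuple[float, float] = (-5.0, 2.0)
    range_limits_pct: tuple[float, float] = (60.0, 140.0)
    poi_decision_s: tuple[float, float] = (6.0, 23.0)
    poi_generation_s: tuple[float, float] = (6.0, 17.0)
    generation_tasks: tuple[str, ...] = ("A", "D")
    min_acceptable_epochs: int = 12
    trials_per_task: int = 15
    heart_cycle_integration: bool = True
    min_beat_interval_s: float = 0.5
    peak_window_s: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.spike_quantiles
        if not (0 < lo < hi < 1):
            raise ValueError("spike quantiles must satisfy 0 < lo < hi < 1")
        rlo, rhi = self.range_limits_pct
        if not (0 < rlo < self.normalization_target < rhi):
            raise ValueError("range limits must bracket the normalization target")
        for w in (self.baseline_window_s, self.poi_decision_s, self.poi_generation_s):
            if not (self.epoch_start_s <= w[0] < w[1]
                    <= self.epoch_start_s + self.epoch_length_s):
                raise ValueError(f"window {w} outside the epoch")
        if self.normalization_scope not in ("session", "epoch"):
            raise ValueError("normalization_scope must be 'session' or 'epoch'")

    def poi_for(self, task: str) -> tuple[float, float]:
        if task in self.generation_tasks:
            return self.poi_generation_s
        return self.poi_decision_s


@dataclass
class TrialEpoch:
    """One trial's left/right series on the peristimulus grid."""

    task: str
    trial_index: int
    times: np.ndarray          # peristimulus seconds, window-start aligned
    left: np.ndarray
    right: np.ndarray
    status: str = ACCEPTED
    n_flagged: int = 0

    @property
    def accepted(self) -> bool:
        return self.status in (ACCEPTED, REPAIRED)

    def difference(self) -> np.ndarray:
        return self.left - self.right


@dataclass
class TaskLI:
    """Laterality index for one subject/task/session cell."""

    subject: str
    task: str
    session: int
    li: float
    se: float
    n_accepted_epochs: int
    method: str = "mean"
    li_peak: float = np.nan
    trial_lis: tuple[float, ...] = ()
    excluded: bool = False
    reason: str = ""

    def exclude(self, reason: str) -> None:
        if not reason:
            raise ValueError("exclusion reason must be non-empty")
        self.excluded = True
        self.reason = reason


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def downsample(series: np.ndarray, factor: int) -> np.ndarray:
    """Keep every ``factor``-th sample starting at index 0."""
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("cannot downsample an empty series")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return series[::factor]


def downsample_recording(recording: SignalRecording,
                         factor: int) -> SignalRecording:
    """Downsample both channels; marker indices are floor-divided."""
    return SignalRecording(
        sampling_rate=recording.sampling_rate / factor,
        left=downsample(recording.left, factor),
        right=downsample(recording.right, factor),
        markers=[(i // factor, task) for i, task in recording.markers],
        subject=recording.subject,
        session=recording.session,
    )


def flag_extreme_points(recording: SignalRecording,
                        config: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample spike/dropout masks, one per channel.

    A sample is flagged when it lies strictly outside the channel's empirical
    [lo, hi] quantile interval computed over the whole session (linearly
    interpolated order statistics).
    """
    if recording.n_samples == 0:
        raise ValueError("empty recording")
    lo, hi = config.spike_quantiles
    masks = []
    for ch in (recording.left, recording.right):
        qlo, qhi = np.quantile(ch, [lo, hi])
        masks.append((ch < qlo) | (ch > qhi))
    return masks[0], masks[1]


def segment_epochs(recording: SignalRecording, config: PreprocessConfig,
                   masks: tuple[np.ndarray, np.ndarray] | None = None
                   ) -> list[TrialEpoch]:
    """Cut one epoch per marker; markers too close to an edge are dropped.

    Epochs are half-open [epoch_start, epoch_start + epoch_length) around
    each marker, 825 samples at 25 Hz.  When ``masks`` are given, the flagged
    samples falling in each epoch are counted into ``n_flagged`` (used by the
    repair-or-reject rule).
    """
    fs = recording.sampling_rate
    n_ep = int(round(config.epoch_length_s * fs))
    offset = int(round(config.epoch_start_s * fs))
    times = config.epoch_start_s + np.arange(n_ep) / fs

    trial_counter: dict[str, int] = {}
    epochs = []
    for marker, task in recording.markers:
        trial_counter[task] = trial_counter.get(task, 0) + 1
        start = marker + offset
        stop = start + n_ep
        if start < 0 or stop > recording.n_samples:
            logger.warning("marker at sample %d (%s) too close to the edge; "
                           "trial dropped", marker, task)
            continue
        n_flagged = 0
        if masks is not None:
            n_flagged = int(masks[0][start:stop].sum()
                            + masks[1][start:stop].sum())
        epochs.append(TrialEpoch(
            task=task, trial_index=trial_counter[task], times=times.copy(),
            left=recording.left[start:stop].copy(),
            right=recording.right[start:stop].copy(),
            n_flagged=n_flagged,
        ))
    return epochs


def repair_or_reject(epoch: TrialEpoch,
                     mask_left: np.ndarray,
                     mask_right: np.ndarray) -> TrialEpoch:
    """Single flagged sample -> repaired; two or more -> epoch rejected.

    The repair replaces the flagged sample (in its own channel) with the mean
    of that channel over the remaining samples of the epoch — the spike does
    not contribute to its own replacement value.
    """
    total = int(mask_left.sum() + mask_right.sum())
    epoch.n_flagged = total
    if total == 0:
        return epoch
    if total >= 2:
        epoch.status = REJECTED_SPIKE
        return epoch
    for mask, channel in ((mask_left, epoch.left), (mask_right, epoch.right)):
        if mask.any():
            i = int(np.flatnonzero(mask)[0])
            keep = np.ones(len(channel), dtype=bool)
            keep[i] = False
            channel[i] = channel[keep].mean()
    epoch.status = REPAIRED
    return epoch


def normalize(series: np.ndarray, target: float = 100.0,
              mean: float | None = None) -> np.ndarray:
    """Scale a channel so its mean is ``target`` (divide by mean, times 100).

    ``mean`` overrides the divisor, used to normalize an epoch slice by the
    whole-session channel mean.  A non-positive mean signals a dead probe.
    """
    series = np.asarray(series, dtype=float)
    m = float(series.mean()) if mean is None else float(mean)
    if m <= 0:
        raise ValueError("channel mean is non-positive (dead probe?)")
    return series / m * target


def heart_cycle_integrate(left: np.ndarray, right: np.ndarray,
                          sampling_rate: float,
                          min_beat_interval_s: float = 0.5
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Replace samples within each cardiac cycle by the cycle mean.

    Cycle boundaries are detected once, by systolic peak-picking on the sum
    of the two channels with a minimum inter-beat interval, and shared by
    both channels; cycles span peak to peak, with the partial segments before
    the first and after the last peak averaged as their own segments (this
    preserves each channel's overall mean exactly).  Constant inputs pass
    through unchanged; a non-constant signal without detectable cycles
    raises.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    combined = left + right
    if np.ptp(combined) == 0 and np.ptp(left) == 0:
        return left.copy(), right.copy()
    distance = max(1, int(round(min_beat_interval_s * sampling_rate)))
    peaks, _ = find_peaks(combined, distance=distance)
    if len(peaks) < 2:
        raise ValueError("no detectable cardiac cycles (fewer than 2 peaks); "
                         "check the signal or disable heart-cycle integration")
    bounds = np.concatenate(([0], peaks, [len(left)]))
    bounds = np.unique(bounds)
    out_l, out_r = left.copy(), right.copy()
    for a, b in zip(bounds[:-1], bounds[1:]):
        out_l[a:b] = left[a:b].mean()
        out_r[a:b] = right[a:b].mean()
    return out_l, out_r


def _window_slice(times: np.ndarray, window: tuple[float, float],
                  sampling_rate: float) -> slice:
    """Sample slice for [w0, w1): start inclusive, end exclusive."""
    t0 = times[0]
    i0 = int(round((window[0] - t0) * sampling_rate))
    i1 = int(round((window[1] - t0) * sampling_rate))
    return slice(max(i0, 0), min(i1, len(times)))


def baseline_correct(epoch: TrialEpoch, config: PreprocessConfig,
                     sampling_rate: float = 25.0) -> TrialEpoch:
    """Subtract each channel's mean over the baseline window (default -5..2 s)."""
    sl = _window_slice(epoch.times, config.baseline_window_s, sampling_rate)
    epoch.left = epoch.left - epoch.left[sl].mean()
    epoch.right = epoch.right - epoch.right[sl].mean()
    return epoch


def range_check(epoch: TrialEpoch, config: PreprocessConfig) -> str:
    """Reject the epoch if either channel leaves [60, 140] on the mean-100 scale.

    Must run before baseline subtraction, where the percent thresholds still
    refer to the normalized flow level.
    """
    lo, hi = config.range_limits_pct
    for ch in (epoch.left, epoch.right):
        if (ch < lo).any() or (ch > hi).any():
            epoch.status = REJECTED_RANGE
            return epoch.status
    return epoch.status


def compute_task_li(epochs: Sequence[TrialEpoch], config: PreprocessConfig,
                    sampling_rate: float = 25.0,
                    subject: str = "", session: int = 1) -> TaskLI:
    """Mean-based LI over the accepted epochs of one task/session.

    The across-epoch mean left-minus-right difference wave is averaged over
    the task's period of interest.  With complete epochs this equals the mean
    of the per-trial LIs, which are retained for the trial standard error.
    """
    accepted = [e for e in epochs if e.accepted]
    if not accepted:
        raise ValueError("no accepted epochs for this task")
    task = accepted[0].task
    if any(e.task != task for e in accepted):
        raise ValueError("epochs from multiple tasks passed to compute_task_li")
    poi = _window_slice(accepted[0].times, config.poi_for(task), sampling_rate)
    trial_lis = tuple(float(e.difference()[poi].mean()) for e in accepted)
    mean_diff = np.mean([e.difference() for e in accepted], axis=0)
    li = float(mean_diff[poi].mean())
    return TaskLI(subject=subject, task=task, session=session, li=li,
                  se=trial_se(trial_lis), n_accepted_epochs=len(accepted),
                  method="mean", trial_lis=trial_lis)


def compute_peak_li(epochs: Sequence[TrialEpoch], config: PreprocessConfig,
                    sampling_rate: float = 25.0,
                    subject: str = "", session: int = 1) -> TaskLI:
    """Legacy peak-based LI.

    Locates the sample of maximum absolute across-epoch mean difference
    within the period of interest, then averages the difference over a 2 s
    window centred there, clipped to the POI edges.
    """
    accepted = [e for e in epochs if e.accepted]
    if not accepted:
        raise ValueError("no accepted epochs for this task")
    task = accepted[0].task
    poi = _window_slice(accepted[0].times, config.poi_for(task), sampling_rate)
    mean_diff = np.mean([e.difference() for e in accepted], axis=0)
    seg = mean_diff[poi]
    peak = int(np.argmax(np.abs(seg)))
    half = int(round(config.peak_window_s / 2 * sampling_rate))
    w0 = max(peak - half, 0)
    w1 = min(peak + half + 1, len(seg))
    li = float(seg[w0:w1].mean())
    trial_lis = tuple(float(e.difference()[poi][w0:w1].mean()) for e in accepted)
    return TaskLI(subject=subject, task=task, session=session, li=li,
                  se=trial_se(trial_lis), n_accepted_epochs=len(accepted),
                  method="peak", trial_lis=trial_lis)


def trial_se(trial_lis: Sequence[float]) -> float:
    """Standard error of the per-trial LIs: sample s.d. / sqrt(n); NaN if n < 2."""
    vals = np.asarray(trial_lis, dtype=float)
    if vals.size < 2:
        return np.nan
    return float(vals.std(ddof=1) / np.sqrt(vals.size))


def apply_epoch_count_rule(task_lis: Iterable[TaskLI],
                           config: PreprocessConfig) -> list[TaskLI]:
    """Exclude tasks with < 12 acceptable epochs; > 1 such task drops the session.

    Mutates and returns the TaskLI set for one subject/session.
    """
    task_lis = list(task_lis)
    short = [t for t in task_lis
             if t.n_accepted_epochs < config.min_acceptable_epochs]
    for t in short:
        t.exclude(f"fewer_than_{config.min_acceptable_epochs}_epochs")
    if len(short) > 1:
        for t in task_lis:
            if not t.excluded:
                t.exclude("participant_excluded_multiple_tasks")
    return task_lis


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    task_lis: list[TaskLI]
    epochs: list[TrialEpoch]
    log: dict

    def as_records(self) -> list[dict]:
        return [
            {"subject": t.subject, "task": t.task, "session": t.session,
             "li_mean": t.li, "li_peak": t.li_peak, "se": t.se,
             "n_epochs": t.n_accepted_epochs, "excluded": t.excluded,
             "reason": t.reason}
            for t in self.task_lis
        ]


def preprocess_recording(recording: SignalRecording,
                         config: PreprocessConfig = PreprocessConfig()
                         ) -> PreprocessResult:
    """Run the full stage pipeline on one session's recording."""
    ds = downsample_recording(recording, config.downsample_factor)
    fs = ds.sampling_rate
    if config.spike_screening:
        mask_l, mask_r = flag_extreme_points(ds, config)
    else:
        # screening off (e.g. signals known clean): the quantile rule always
        # flags the extreme tail of the empirical distribution, even when
        # every sample is physiological
        mask_l = np.zeros(ds.n_samples, dtype=bool)
        mask_r = np.zeros(ds.n_samples, dtype=bool)
    session_mean_l = float(ds.left.mean())
    session_mean_r = float(ds.right.mean())

    n_ep = int(round(config.epoch_length_s * fs))
    offset = int(round(config.epoch_start_s * fs))
    epochs = segment_epochs(ds, config)
    counters = {"rejected_spike": 0, "repaired": 0, "rejected_range": 0}

    # align each epoch with its mask slice for the repair/reject rule
    kept: list[TrialEpoch] = []
    marker_iter = [m for m in ds.markers
                   if m[0] + offset >= 0 and m[0] + offset + n_ep <= ds.n_samples]
    for epoch, (marker, _task) in zip(epochs, marker_iter):
        start = marker + offset
        sl = slice(start, start + n_ep)
        repair_or_reject(epoch, mask_l[sl], mask_r[sl])
        if epoch.status == REJECTED_SPIKE:
            counters["rejected_spike"] += 1
            kept.append(epoch)
            continue
        if epoch.status == REPAIRED:
            counters["repaired"] += 1
        if config.normalization_scope == "session":
            epoch.left = normalize(epoch.left, config.normalization_target,
                                   mean=session_mean_l)
            epoch.right = normalize(epoch.right, config.normalization_target,
                                    mean=session_mean_r)
        else:
            epoch.left = normalize(epoch.left, config.normalization_target)
            epoch.right = normalize(epoch.right, config.normalization_target)
        if config.heart_cycle_integration:
            epoch.left, epoch.right = heart_cycle_integrate(
                epoch.left, epoch.right, fs, config.min_beat_interval_s)
        if range_check(epoch, config) == REJECTED_RANGE:
            counters["rejected_range"] += 1
            kept.append(epoch)
            continue
        baseline_correct(epoch, config, fs)
        kept.append(epoch)

    by_task: dict[str, list[TrialEpoch]] = {}
    for e in kept:
        by_task.setdefault(e.task, []).append(e)

    task_lis = []
    for task, eps in by_task.items():
        accepted = [e for e in eps if e.accepted]
        if accepted:
            t = compute_task_li(accepted, config, fs,
                                subject=recording.subject,
                                session=recording.session)
            t.li_peak = compute_peak_li(accepted, config, fs).li
        else:
            t = TaskLI(subject=recording.subject, task=task,
                       session=recording.session, li=np.nan, se=np.nan,
                       n_accepted_epochs=0)
        task_lis.append(t)
    task_lis = apply_epoch_count_rule(task_lis, config)

    log = {"subject": recording.subject, "session": recording.session,
           "n_markers": len(recording.markers), "n_epochs": len(kept),
           **counters,
           "excluded_tasks": [t.task for t in task_lis if t.excluded]}
    return PreprocessResult(task_lis=task_lis, epochs=kept, log=log)
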