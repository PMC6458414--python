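"""Generative models for laterality data, at two levels.

1.  LI level: draws subject x condition laterality-index tables from the
    additive family

        LI_ij = a + t_i + p_j + x_ij + e_ij

    where ``a`` is a population bias, ``t_i`` a task effect, ``p_j`` a stable
    person effect (constant across tasks and sessions), ``x_ij`` a
    task-by-person interaction (constant across sessions within a
    subject-task), and ``e_ij`` independent measurement error.  Zeroing the
    standard deviation of a term removes it exactly, which yields the nested
    Population Bias, Task Effect and Person Effect models as special cases.

2.  Signal level: synthesizes raw bilateral cerebral blood-flow-velocity
    (CBFV) recordings with the study trial structure (six tasks, 15 trials of
    33 s each), cardiac pulsatility, a task-locked lateralized evoked
    response, and optional spike/dropout artifacts, so that the preprocessing
    pipeline can be exercised against known ground truth.

All randomness flows through explicit integer seeds; there is no hidden
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import LateralityTable, condition_label, condition_labels

TASKS = ("A", "B", "C", "D", "E", "F")


# ---------------------------------------------------------------------------
# LI-level generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the additive LI generator (all in LI units).

    ``interaction_structure`` optionally replaces the independent
    task-by-person term with a second latent factor: task i receives
    ``x_ij = g_i * q_j`` with per-task loadings ``g_i`` and a per-subject
    score ``q_j ~ N(0, sd_interaction^2)``.  This is the configuration used
    for one-factor versus two-factor power simulation.
    """

    intercept: float = 1.0
    task_effects: tuple[float, ...] = (0.0,) * 6
    sd_person: float = 1.0
    sd_interaction: float = 0.0
    sd_error: float = 1.0
    interaction_structure: Mapping[str, float] | None = None
    tasks: tuple[str, ...] = TASKS
    n_sessions: int = 2

    def __post_init__(self) -> None:
        for name in ("sd_person", "sd_interaction", "sd_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.task_effects) != len(self.tasks):
            raise ValueError("task_effects length must equal number of tasks")
        if self.interaction_structure is not None:
            unknown = set(self.interaction_structure) - set(self.tasks)
            if unknown:
                raise ValueError(f"interaction_structure names unknown tasks: {unknown}")

    # Convenience constructors for the four canonical scenarios.  Task
    # effects follow the worked example (a lateralized and a non-lateralized
    # task differing by about one LI unit, spread about one unit).
    @classmethod
    def population_bias(cls, **kw) -> "GenerativeParams":
        return cls(intercept=1.0, sd_person=0.0, sd_interaction=0.0,
                   sd_error=1.0, **kw)

    @classmethod
    def task_effect(cls, **kw) -> "GenerativeParams":
        return cls(intercept=1.0, task_effects=(0.0, 0.5, 1.0, 1.5, 1.0, 0.5),
                   sd_person=0.0, sd_interaction=0.0, sd_error=1.0, **kw)

    @classmethod
    def person_effect(cls, sd_person: float = 1.0, sd_error: float = 1.0,
                      **kw) -> "GenerativeParams":
        return cls(intercept=1.0, task_effects=(0.0, 0.5, 1.0, 1.5, 1.0, 0.5),
                   sd_person=sd_person, sd_interaction=0.0,
                   sd_error=sd_error, **kw)

    @classmethod
    def task_by_person(cls, sd_person: float = 1.0, sd_interaction: float = 1.0,
                       sd_error: float = 1.0, **kw) -> "GenerativeParams":
        return cls(intercept=1.0, task_effects=(0.0, 0.5, 1.0, 1.5, 1.0, 0.5),
                   sd_person=sd_person, sd_interaction=sd_interaction,
                   sd_error=sd_error, **kw)


@dataclass
class SimulatedLIDataset:
    """A simulated LI table together with the latent draws that produced it."""

    table: LateralityTable
    person: pd.Series                 # p_j per subject
    interaction: pd.DataFrame         # x_ij per subject x task
    error: pd.DataFrame               # e_ij per subject x condition
    params: GenerativeParams
    seed: int

    def reconstruct(self) -> pd.DataFrame:
        """Rebuild the LI table from stored truth terms (exact)."""
        out = pd.DataFrame(index=self.table.li.index,
                           columns=self.table.li.columns, dtype=float)
        teff = dict(zip(self.params.tasks, self.params.task_effects))
        for cond in out.columns:
            task = cond[:-1]
            out[cond] = (self.params.intercept + teff[task]
                         + self.person + self.interaction[task]
                         + self.error[cond])
        return out


def simulate_li_dataset(params: GenerativeParams, n_subjects: int,
                        seed: int) -> SimulatedLIDataset:
    """Draw an LI table from the additive generative model.

    The person term is constant within subject across tasks and sessions; the
    interaction term is constant within subject-task across sessions; errors
    are independent per cell.  All terms are Gaussian.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    conds = condition_labels(params.tasks, range(1, params.n_sessions + 1))

    person = pd.Series(rng.normal(0.0, params.sd_person, n_subjects),
                       index=subjects, name="person")
    if params.interaction_structure is not None:
        q = rng.normal(0.0, params.sd_interaction, n_subjects)
        inter = pd.DataFrame(
            {t: params.interaction_structure.get(t, 0.0) * q
             for t in params.tasks}, index=subjects)
    else:
        inter = pd.DataFrame(
            rng.normal(0.0, params.sd_interaction, (n_subjects, len(params.tasks))),
            index=subjects, columns=list(params.tasks))
    error = pd.DataFrame(
        rng.normal(0.0, params.sd_error, (n_subjects, len(conds))),
        index=subjects, columns=conds)

    teff = dict(zip(params.tasks, params.task_effects))
    li = pd.DataFrame(index=subjects, columns=conds, dtype=float)
    for cond in conds:
        task = cond[:-1]
        li[cond] = (params.intercept + teff[task] + person + inter[task]
                    + error[cond])

    table = LateralityTable(li=li)
    return SimulatedLIDataset(table=table, person=person, interaction=inter,
                              error=error, params=params, seed=seed)


# ---------------------------------------------------------------------------
# Signal-level generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArtifactSpec:
    """Ground-truth artifact plan: spikes and dropouts to superimpose.

    ``spikes``: (time_s, channel, amplitude_cm_s) — a single-sample deflection
    added to the named channel ("left" or "right").
    ``dropouts``: (start_s, duration_s, channel or "both") — the signal is
    collapsed to near zero over the interval.
    """

    spikes: tuple[tuple[float, str, float], ...] = ()
    dropouts: tuple[tuple[float, float, str], ...] = ()


@dataclass(frozen=True)
class RecordingPlan:
    """Design of a synthetic fTCD session.

    Amplitudes of the evoked left-minus-right differential are expressed in
    normalized units (percent of mean CBFV), the scale on which laterality
    indices are read out after mean-100 normalization.  The cardiac waveform
    is a sum of harmonics of a configurable heart rate; its exact morphology
    is irrelevant to the pipeline contracts and only needs to exercise
    heart-cycle integration.
    """

    tasks: tuple[str, ...] = TASKS
    trials_per_task: int = 15
    trial_length_s: float = 33.0
    sampling_rate_hz: float = 100.0
    task_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.5, "B": 2.0, "C": 2.5,
                                 "D": 4.0, "E": 2.5, "F": 0.5})
    baseline_left_cm_s: float = 55.0
    baseline_right_cm_s: float = 50.0
    cardiac_rate_hz: float = 1.17
    cardiac_rel_amplitude: float = 0.15
    cardiac_harmonics: tuple[float, ...] = (1.0, 0.4, 0.15)
    common_evoked_pct: float = 3.0
    evoked_window_s: tuple[float, float] = (3.0, 24.48)
    noise_sd_cm_s: float = 0.5
    lead_in_s: float = 10.0
    lead_out_s: float = 30.0
    artifacts: ArtifactSpec = ArtifactSpec()

    def __post_init__(self) -> None:
        if self.trials_per_task < 1:
            raise ValueError("trials_per_task must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.noise_sd_cm_s < 0:
            raise ValueError("noise_sd_cm_s must be non-negative")
        missing = set(self.tasks) - set(self.task_amplitudes)
        if missing:
            raise ValueError(f"task_amplitudes missing tasks: {missing}")
        w0, w1 = self.evoked_window_s
        if not (0 <= w0 < w1 <= self.trial_length_s):
            raise ValueError("evoked window must lie inside the trial")

    @property
    def n_trials(self) -> int:
        return len(self.tasks) * self.trials_per_task

    @property
    def duration_s(self) -> float:
        return (self.lead_in_s + self.n_trials * self.trial_length_s
                + self.lead_out_s)

    def trial_onsets(self) -> list[tuple[float, str]]:
        """(onset_s, task) per trial; tasks run in contiguous blocks."""
        onsets = []
        t = self.lead_in_s
        for task in self.tasks:
            for _ in range(self.trials_per_task):
                onsets.append((t, task))
                t += self.trial_length_s
        return onsets


def _evoked_profile(plan: RecordingPlan, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Boxcar profiles (common, differential) in normalized units, mean-removed.

    Removing the session mean of each profile keeps both channels' session
    means exactly at their baseline levels, so that mean-100 normalization is
    exactly linear in the evoked differential (baseline correction later
    restores the boxcar's zero reference).
    """
    fs = plan.sampling_rate_hz
    common = np.zeros(n)
    diff = np.zeros(n)
    w0, w1 = plan.evoked_window_s
    for onset, task in plan.trial_onsets():
        i0 = int(round((onset + w0) * fs))
        i1 = int(round((onset + w1) * fs))
        common[i0:i1] += plan.common_evoked_pct
        diff[i0:i1] += plan.task_amplitudes[task]
    common -= common.mean()
    diff -= diff.mean()
    return common, diff


def simulate_recording(plan: RecordingPlan, seed: int,
                       subject: str = "SIM", session: int = 1):
    """Synthesize one session's bilateral CBFV recording.

    Each channel is ``baseline * (1 + cardiac + common_evoked +/- diff/2)``
    plus white noise, with the cardiac component shared between channels and
    constructed with exactly zero session mean.  The marker channel encodes
    trial onsets ('CLEAR' stimulus onset) and task labels.
    """
    from .preprocess import SignalRecording  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    fs = plan.sampling_rate_hz
    n = int(round(plan.duration_s * fs))
    t = np.arange(n) / fs

    # Snap the heart rate to an integer number of cycles per session so the
    # waveform averages to zero on the session grid (and on any integer
    # decimation of it); the adjustment is below 1/(2T) Hz and keeps the
    # session means of both channels exactly at their baseline levels.
    cardiac = np.zeros(n)
    if plan.cardiac_rel_amplitude > 0:
        f0 = max(2, round(plan.cardiac_rate_hz * n / fs)) * fs / n
        phases = rng.uniform(0, 2 * np.pi, len(plan.cardiac_harmonics))
        for k, (amp, ph) in enumerate(zip(plan.cardiac_harmonics, phases),
                                      start=1):
            cardiac += amp * np.cos(2 * np.pi * k * f0 * t + ph)
        cardiac *= plan.cardiac_rel_amplitude / np.max(np.abs(cardiac))
        cardiac -= cardiac.mean()

    common, diff = _evoked_profile(plan, n)
    left = plan.baseline_left_cm_s * (1 + cardiac + (common + diff / 2) / 100.0)
    right = plan.baseline_right_cm_s * (1 + cardiac + (common - diff / 2) / 100.0)
    if plan.noise_sd_cm_s > 0:
        left = left + rng.normal(0, plan.noise_sd_cm_s, n)
        right = right + rng.normal(0, plan.noise_sd_cm_s, n)

    markers = [(int(round(onset * fs)), task)
               for onset, task in plan.trial_onsets()]
    return SignalRecording(sampling_rate=fs, left=left, right=right,
                           markers=markers, subject=subject, session=session)


def inject_artifacts(recording, plan: RecordingPlan, seed: int = 0):
    """Superimpose the plan's spikes and dropouts on a recording.

    Returns a new recording carrying a ground-truth ``artifact_log``.  An
    artifact placed outside the recording raises.  An empty spec returns an
    identical copy.
    """
    fs = recording.sampling_rate
    n = len(recording.left)
    left = recording.left.copy()
    right = recording.right.copy()
    log = []

    for time_s, channel, amplitude in plan.artifacts.spikes:
        i = int(round(time_s * fs))
        if not 0 <= i < n:
            raise ValueError(f"spike at {time_s}s outside recording")
        target = left if channel == "left" else right
        target[i] += amplitude
        log.append({"kind": "spike", "time_s": time_s, "channel": channel,
                    "amplitude": amplitude, "sample": i})

    for start_s, dur_s, channel in plan.artifacts.dropouts:
        i0 = int(round(start_s * fs))
        i1 = int(round((start_s + dur_s) * fs))
        if not (0 <= i0 < i1 <= n):
            raise ValueError(f"dropout at {start_s}s outside recording")
        for name, arr in (("left", left), ("right", right)):
            if channel in (name, "both"):
                arr[i0:i1] *= 0.02
        log.append({"kind": "dropout", "start_s": start_s,
                    "duration_s": dur_s, "channel": channel,
                    "samples": [i0, i1]})

    out = replace_recording(recording, left=left, right=right)
    out.artifact_log = log
    return out


def replace_recording(recording, **kw):
    from .preprocess import SignalRecording

    fields = dict(sampling_rate=recording.sampling_rate, left=recording.left,
                  right=recording.right, markers=list(recording.markers),
                  subject=recording.subject, session=recording.session)
    fields.update(kw)
    return SignalRecording(**fields)
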