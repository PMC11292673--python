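"""Seeded generation of oddball experimental designs.

The paradigm: runs of tone-sequence trials, each trial an 8-tone stream in
which a single deviant tone occurs at position 4, 5 or 6.  Because the
deviant must occur at one of those positions, its conditional probability
rises along the sequence (1/3 at position 4, 1/2 at position 5 given it has
not yet occurred, 1 at position 6), which is the expectancy manipulation the
downstream analyses quantify.  Silent trials of the same duration are
interleaved to provide a baseline, and inter-trial intervals are jittered to
decorrelate trial onsets from the volume acquisition grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigurationError, TimingError

#: canonical region-of-interest labels along the auditory pathway
ROIS = ("IC", "MGB", "AC", "STG")

#: condition labels of the oddball first-level model
ODDBALL_CONDITIONS = ("std0", "std1", "dev4", "dev5", "dev6", "std2")

#: condition labels of the periodicity (phase-flip) manipulation
PHASEFLIP_CONDITIONS = ("control", "inphase", "antiphase")


@dataclass(frozen=True)
class DesignParams:
    """Timing and counting parameters of one oddball session.

    ``isi`` is the offset-to-onset gap between successive tones, so the
    stimulus-onset asynchrony is ``tone_duration + isi``.
    """

    tone_duration: float = 0.25
    isi: float = 0.70
    tones_per_sequence: int = 8
    deviant_positions: tuple[int, ...] = (4, 5, 6)
    iti_min: float = 1.5
    iti_max: float = 11.0
    iti_mean: float = 5.0
    blocks_per_run: int = 6
    trials_per_block: int = 9
    silent_trials_per_run: int = 21
    n_runs: int = 4
    tr: float = 1.53

    @property
    def soa(self) -> float:
        """Onset-to-onset interval between tones in a sequence."""
        return self.tone_duration + self.isi

    @property
    def tone_trials_per_run(self) -> int:
        return self.blocks_per_run * self.trials_per_block

    @property
    def sequence_duration(self) -> float:
        return (self.tones_per_sequence - 1) * self.soa + self.tone_duration

    def validate(self) -> None:
        n_pos = len(self.deviant_positions)
        if self.tone_trials_per_run % n_pos != 0:
            raise ConfigurationError(
                f"{self.tone_trials_per_run} tone trials cannot be split "
                f"evenly over {n_pos} deviant positions"
            )
        if self.isi < 0 or self.tone_duration <= 0:
            raise TimingError("tone duration must be positive, ISI non-negative")
        if not (0 < self.iti_min <= self.iti_mean <= self.iti_max):
            raise ConfigurationError("ITI bounds must satisfy min <= mean <= max")
        if max(self.deviant_positions) > self.tones_per_sequence:
            raise ConfigurationError("deviant position beyond sequence length")


@dataclass(frozen=True)
class TrialEvent:
    """A single stimulus event within a run."""

    onset: float
    duration: float
    trial_type: str
    modulator: Optional[int] = None
    block_condition: Optional[str] = None


@dataclass(frozen=True)
class Trial:
    """One trial slot of a run: a tone sequence or a silent gap."""

    index: int
    onset: float
    block: Optional[int]
    deviant_position: Optional[int]
    events: tuple[TrialEvent, ...]

    @property
    def is_silent(self) -> bool:
        return self.deviant_position is None


@dataclass(frozen=True)
class RunDesign:
    run: int
    params: DesignParams
    trials: tuple[Trial, ...]
    block_conditions: Optional[tuple[str, ...]] = None

    @property
    def tone_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if not t.is_silent)

    @property
    def silent_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if t.is_silent)

    def deviant_position_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {p: 0 for p in self.params.deviant_positions}
        for t in self.tone_trials:
            counts[t.deviant_position] += 1
        return counts

    @property
    def duration(self) -> float:
        last = self.trials[-1]
        return last.onset + max(e.onset - last.onset + e.duration for e in last.events)

    @property
    def n_volumes(self) -> int:
        """Volumes needed to cover the last event plus a 32 s response tail."""
        last_event_onset = max(e.onset for t in self.trials for e in t.events)
        return int(np.ceil((last_event_onset + 32.0) / self.params.tr))

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            for e in t.events:
                rows.append(
                    dict(
                        onset=e.onset,
                        duration=e.duration,
                        trial_type=e.trial_type,
                        modulator=e.modulator,
                        block_condition=e.block_condition,
                        trial=t.index,
                        block=t.block,
                    )
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExperimentDesign:
    """A full session: several runs sharing one parameter set."""

    runs: tuple[RunDesign, ...]
    params: DesignParams

    def events_frame(self) -> pd.DataFrame:
        frames = []
        for r in self.runs:
            f = r.events_frame()
            f.insert(0, "run", r.run)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


@lru_cache(maxsize=16)
def _truncexp_rate(lo: float, hi: float, mean: float) -> float:
    """Rate of a truncated exponential on [lo, hi] with the given mean.

    The mean of Exp(rate) truncated to [lo, hi] decreases monotonically in the
    rate from (lo+hi)/2 (rate -> 0) towards lo, so a root exists whenever
    lo < mean < (lo+hi)/2.
    """
    if not (lo < mean < (lo + hi) / 2.0):
        raise ConfigurationError(
            f"truncated-exponential mean {mean} unreachable on [{lo}, {hi}]"
        )

    def trunc_mean(rate: float) -> float:
        # E[T | lo <= T <= hi] for T ~ Exp(rate)
        a, b = rate * lo, rate * hi
        z = np.exp(-a) - np.exp(-b)
        return (lo * np.exp(-a) - hi * np.exp(-b)) / z + 1.0 / rate

    return brentq(lambda r: trunc_mean(r) - mean, 1e-6, 50.0, xtol=1e-12)


def draw_itis(rng: np.random.Generator, n: int, params: DesignParams) -> np.ndarray:
    """Jittered inter-trial intervals: truncated exponential via inverse CDF."""
    rate = _truncexp_rate(params.iti_min, params.iti_max, params.iti_mean)
    u = rng.random(n)
    a, b = np.exp(-rate * params.iti_min), np.exp(-rate * params.iti_max)
    itis = -np.log(a - u * (a - b)) / rate
    return np.clip(itis, params.iti_min, params.iti_max)


def _sequence_events(
    trial_onset: float, deviant_position: int, params: DesignParams
) -> tuple[TrialEvent, ...]:
    events = []
    for pos in range(1, params.tones_per_sequence + 1):
        onset = trial_onset + (pos - 1) * params.soa
        if pos == 1:
            ttype, mod = "std0", None
        elif pos < deviant_position:
            ttype, mod = "std1", pos
        elif pos == deviant_position:
            ttype, mod = f"dev{deviant_position}", None
        else:
            ttype, mod = "std2", pos
        events.append(TrialEvent(onset, params.tone_duration, ttype, mod))
    return tuple(events)


def generate_run_design(
    seed: int | np.random.Generator,
    params: DesignParams = DesignParams(),
    run: int = 0,
) -> RunDesign:
    """Generate one run satisfying the exact design counts.

    Deviant positions are a seeded permutation of an exactly balanced multiset
    (18 per position under the defaults); silent trials are interleaved at
    seeded random slots among all trial slots; ITIs follow the truncated
    exponential jitter law clipped to the configured bounds.
    """
    params.validate()
    rng = np.random.default_rng(seed)

    n_tone = params.tone_trials_per_run
    per_pos = n_tone // len(params.deviant_positions)
    positions = np.repeat(params.deviant_positions, per_pos)
    positions = rng.permutation(positions)

    n_total = n_tone + params.silent_trials_per_run
    silent_slots = set(
        rng.choice(n_total, size=params.silent_trials_per_run, replace=False).tolist()
    )

    itis = draw_itis(rng, n_total, params)
    trials = []
    onset = itis[0]
    tone_i = 0
    for slot in range(n_total):
        if slot in silent_slots:
            ev = (TrialEvent(onset, params.sequence_duration, "silent"),)
            trials.append(Trial(slot, onset, None, None, ev))
        else:
            d = int(positions[tone_i])
            block = tone_i // params.trials_per_block
            trials.append(Trial(slot, onset, block, d, _sequence_events(onset, d, params)))
            tone_i += 1
        if slot + 1 < n_total:
            gap = itis[slot + 1] if slot + 1 < len(itis) else params.iti_mean
            next_onset = onset + params.sequence_duration + gap
            if next_onset <= onset:
                raise TimingError("non-increasing trial onsets")
            onset = next_onset
    return RunDesign(run=run, params=params, trials=tuple(trials))


def generate_experiment(
    seed: int, params: DesignParams = DesignParams()
) -> ExperimentDesign:
    """Generate all runs of a session from one master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(params.n_runs)
    runs = tuple(
        generate_run_design(np.random.default_rng(c), params, run=i)
        for i, c in enumerate(children)
    )
    return ExperimentDesign(runs=runs, params=params)


def assign_block_conditions(
    design: ExperimentDesign, seed: int
) -> ExperimentDesign:
    """Randomly and evenly assign each run's blocks to the periodicity conditions.

    With 6 blocks per run each of control / inphase / antiphase occurs exactly
    twice, in seeded random order; tone events inherit their block's label.
    """
    n_blocks = design.params.blocks_per_run
    n_cond = len(PHASEFLIP_CONDITIONS)
    if n_blocks % n_cond != 0:
        raise ConfigurationError(
            f"{n_blocks} blocks cannot be split evenly over {n_cond} conditions"
        )
    rng = np.random.default_rng(seed)
    new_runs = []
    for r in design.runs:
        labels = np.repeat(PHASEFLIP_CONDITIONS, n_blocks // n_cond)
        labels = tuple(rng.permutation(labels).tolist())
        new_trials = []
        for t in r.trials:
            if t.is_silent:
                new_trials.append(t)
                continue
            cond = labels[t.block]
            events = tuple(replace(e, block_condition=cond) for e in t.events)
            new_trials.append(replace(t, events=events))
        new_runs.append(replace(r, trials=tuple(new_trials), block_conditions=labels))
    return ExperimentDesign(runs=tuple(new_runs), params=design.params)


def deviant_hazard(design: ExperimentDesign | RunDesign) -> dict[int, float]:
    """Empirical conditional probability of the deviant at each position.

    P(pos 4), P(pos 5 | not at 4), P(pos 6 | not at 4 or 5).  Balanced designs
    give exactly 1/3, 1/2, 1.
    """
    runs = design.runs if isinstance(design, ExperimentDesign) else (design,)
    pos = np.array([t.deviant_position for r in runs for t in r.tone_trials])
    out: dict[int, float] = {}
    remaining = np.ones(len(pos), dtype=bool)
    for p in sorted(set(pos.tolist())):
        here = pos == p
        out[p] = float(here[remaining].mean())
        remaining &= ~here
    return out
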