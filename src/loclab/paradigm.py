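"""Trial, block, and run timing for blocked reading-localizer paradigms.

Implements three task versions of the language-network localizer family:

* ``standard`` — sentences vs. pronounceable nonwords, rapid serial visual
  presentation at 450 ms per word, 6-s trials, 18-s blocks;
* ``speeded`` — identical design at 200 ms per word, 3-s trials, 9-s blocks;
* ``spatialWM`` — a hard vs. easy spatial working-memory task used to
  localize the domain-general Multiple Demand network, 8-s trials,
  32-s blocks.

All three are blocked designs: experimental blocks of a single condition
interleaved with passive-fixation blocks, with a condition order
counterbalanced across the two runs each participant completes.

All onsets and durations are computed on an integer millisecond clock and
only converted to float seconds at the boundary, so run durations are exact
(358 s, 214 s, 448 s for the three versions) with no floating-point drift.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TaskVersion",
    "TimedEvent",
    "RunSchedule",
    "StimulusItem",
    "StimulusMaterials",
    "STANDARD",
    "SPEEDED",
    "SPATIAL_WM",
    "VERSIONS",
    "FIXATION",
    "InvalidStimulusError",
    "BalanceError",
    "ExhaustionError",
    "build_localizer_trial",
    "build_run_schedule",
    "build_wm_run_schedule",
    "counterbalance_orders",
    "generate_placeholder_materials",
    "write_events",
]

FIXATION = "fixation"

#: per-trial framing around the word stream, milliseconds
_PRE_BLANK_MS = 100
_CUE_MS = 400
_POST_BLANK_MS = 100
_WORDS_PER_STIMULUS = 12


class InvalidStimulusError(ValueError):
    """Stimulus does not have the required token structure."""


class BalanceError(ValueError):
    """A condition order is not balanced (or cannot be balanced)."""


class ExhaustionError(RuntimeError):
    """Not enough unused stimuli remain for a subject's runs of a version."""


@dataclass(frozen=True)
class TaskVersion:
    """Static timing parameters of one task version.

    Durations are stored in seconds but are exact decimals representable
    on a millisecond grid.
    """

    name: str
    word_duration_ms: int | None
    trial_duration_s: float
    block_duration_s: float
    fixation_block_s: float
    n_experimental_blocks: int
    n_fixation_blocks: int
    trials_per_block: int
    conditions: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError("a task version has exactly two conditions")
        expected = self.trials_per_block * self.trial_duration_s
        if abs(self.block_duration_s - expected) > 1e-9:
            raise ValueError(
                f"block_duration_s={self.block_duration_s} != "
                f"trials_per_block × trial_duration_s = {expected}"
            )

    @property
    def run_duration_s(self) -> float:
        return _ms_to_s(
            self.n_experimental_blocks * _s_to_ms(self.block_duration_s)
            + self.n_fixation_blocks * _s_to_ms(self.fixation_block_s)
        )


STANDARD = TaskVersion(
    name="standard",
    word_duration_ms=450,
    trial_duration_s=6.0,
    block_duration_s=18.0,
    fixation_block_s=14.0,
    n_experimental_blocks=16,
    n_fixation_blocks=5,
    trials_per_block=3,
    conditions=("sentences", "nonwords"),
)

SPEEDED = TaskVersion(
    name="speeded",
    word_duration_ms=200,
    trial_duration_s=3.0,
    block_duration_s=9.0,
    fixation_block_s=14.0,
    n_experimental_blocks=16,
    n_fixation_blocks=5,
    trials_per_block=3,
    conditions=("sentences", "nonwords"),
)

SPATIAL_WM = TaskVersion(
    name="spatialWM",
    word_duration_ms=None,
    trial_duration_s=8.0,
    block_duration_s=32.0,
    fixation_block_s=16.0,
    n_experimental_blocks=12,
    n_fixation_blocks=4,
    trials_per_block=4,
    conditions=("hard", "easy"),
)

VERSIONS = {v.name: v for v in (STANDARD, SPEEDED, SPATIAL_WM)}


@dataclass(frozen=True)
class TimedEvent:
    """One timed presentation event within a run (run-relative onset)."""

    onset_s: float
    duration_s: float
    condition: str
    block_index: int
    trial_index: int | None = None
    stimulus_id: str | None = None

    @property
    def offset_s(self) -> float:
        return _ms_to_s(_s_to_ms(self.onset_s) + _s_to_ms(self.duration_s))


@dataclass(frozen=True)
class RunSchedule:
    """Ordered, gap-free event timeline for one run of one task version."""

    version: TaskVersion
    run_index: int
    events: tuple[TimedEvent, ...]
    total_duration_s: float

    def validate(self) -> None:
        clock = 0
        blocks_seen: dict[int, str] = {}
        for ev in self.events:
            onset_ms = _s_to_ms(ev.onset_s)
            if onset_ms != clock:
                raise ValueError(
                    f"event at {ev.onset_s}s overlaps or leaves a gap "
                    f"(expected onset {_ms_to_s(clock)}s)"
                )
            clock += _s_to_ms(ev.duration_s)
            prev = blocks_seen.setdefault(ev.block_index, ev.condition)
            if prev != ev.condition:
                raise ValueError(f"block {ev.block_index} mixes conditions")
        if clock != _s_to_ms(self.total_duration_s):
            raise ValueError("total_duration_s does not equal summed durations")
        n_fix = sum(1 for c in blocks_seen.values() if c == FIXATION)
        n_exp = len(blocks_seen) - n_fix
        if n_exp != self.version.n_experimental_blocks:
            raise ValueError("experimental block count mismatch")
        if n_fix != self.version.n_fixation_blocks:
            raise ValueError("fixation block count mismatch")
        per_cond: dict[str, int] = {}
        for c in blocks_seen.values():
            if c != FIXATION:
                per_cond[c] = per_cond.get(c, 0) + 1
        half = self.version.n_experimental_blocks // 2
        if any(n != half for n in per_cond.values()) or len(per_cond) != 2:
            raise ValueError("conditions do not split the blocks equally")

    def condition_blocks(self) -> list[str]:
        """Condition labels of the experimental blocks, in run order."""
        out: list[tuple[int, str]] = []
        seen: set[int] = set()
        for ev in self.events:
            if ev.condition != FIXATION and ev.block_index not in seen:
                seen.add(ev.block_index)
                out.append((ev.block_index, ev.condition))
        return [c for _, c in sorted(out)]


@dataclass(frozen=True)
class StimulusItem:
    item_id: str
    condition: str
    tokens: tuple[str, ...]


@dataclass(frozen=True)
class StimulusMaterials:
    """Five material sets of 48 sentence and 48 nonword items each.

    Item text is opaque: only token counts and identities matter for the
    downstream timing/GLM machinery.
    """

    sets: tuple[tuple[StimulusItem, ...], ...]

    def __post_init__(self) -> None:
        if len(self.sets) != 5:
            raise ValueError("materials must contain exactly 5 sets")
        for s in self.sets:
            for cond in ("sentences", "nonwords"):
                n = sum(1 for it in s if it.condition == cond)
                if n != 48:
                    raise ValueError(f"each set needs 48 {cond} items, got {n}")
            for it in s:
                if len(it.tokens) != _WORDS_PER_STIMULUS:
                    raise ValueError(f"item {it.item_id} has {len(it.tokens)} tokens")

    def items(self, set_index: int, condition: str) -> list[StimulusItem]:
        return [it for it in self.sets[set_index] if it.condition == condition]


def _s_to_ms(x: float) -> int:
    ms = round(x * 1000)
    if abs(ms - x * 1000) > 1e-6:
        raise ValueError(f"duration {x}s is not on the millisecond grid")
    return int(ms)


def _ms_to_s(ms: int) -> float:
    return ms / 1000.0


def build_localizer_trial(
    version: TaskVersion, stimulus: StimulusItem, onset_s: float = 0.0,
    block_index: int = 0, trial_index: int = 0,
) -> list[TimedEvent]:
    """Expand one reading trial into its contiguous sub-events.

    A trial is a 100 ms blank, 12 words/nonwords at the version's rate,
    a 400 ms button-press cue, and a final 100 ms blank.  All sub-events
    carry the trial's condition label (the GLM models whole blocks).
    """
    if version.word_duration_ms is None:
        raise InvalidStimulusError(f"version {version.name!r} has no word stream")
    if len(stimulus.tokens) != _WORDS_PER_STIMULUS:
        raise InvalidStimulusError(
            f"stimulus {stimulus.item_id!r} has {len(stimulus.tokens)} tokens, "
            f"expected {_WORDS_PER_STIMULUS}"
        )
    durations_ms = (
        [_PRE_BLANK_MS]
        + [version.word_duration_ms] * _WORDS_PER_STIMULUS
        + [_CUE_MS, _POST_BLANK_MS]
    )
    events = []
    clock = _s_to_ms(onset_s)
    for d in durations_ms:
        events.append(
            TimedEvent(
                onset_s=_ms_to_s(clock),
                duration_s=_ms_to_s(d),
                condition=stimulus.condition,
                block_index=block_index,
                trial_index=trial_index,
                stimulus_id=stimulus.item_id,
            )
        )
        clock += d
    assert clock - _s_to_ms(onset_s) == _s_to_ms(version.trial_duration_s)
    return events


def _fixation_layout(n_exp: int, n_fix: int) -> list[str]:
    """Interleave block kinds: fixation at run start/end, the rest spaced
    as evenly as possible between equal groups of experimental blocks."""
    if n_fix < 2:
        raise ValueError("need at least 2 fixation blocks (run start and end)")
    n_gaps = n_fix - 1
    if n_exp % n_gaps:
        raise ValueError(
            f"{n_exp} experimental blocks cannot be split evenly into {n_gaps} groups"
        )
    group = n_exp // n_gaps
    layout = ["F"]
    for _ in range(n_gaps):
        layout.extend(["E"] * group)
        layout.append("F")
    return layout


def counterbalance_orders(
    n_blocks: int,
    conditions: Sequence[str],
    scheme: str = "reversal",
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Balanced per-run condition orders, counterbalanced across two runs.

    Under the default ``reversal`` scheme run 1 is a seeded balanced
    pseudo-random order and run 2 is its reverse, which cancels linear
    time-in-run confounds between conditions.
    """
    if n_blocks % 2:
        raise BalanceError(f"n_blocks={n_blocks} is odd; conditions cannot balance")
    if len(set(conditions)) != 2:
        raise BalanceError("exactly two distinct conditions are required")
    if scheme != "reversal":
        raise ValueError(f"unknown counterbalancing scheme {scheme!r}")
    half = n_blocks // 2
    rng = np.random.default_rng(seed)
    run1 = [conditions[0]] * half + [conditions[1]] * half
    run1 = [run1[i] for i in rng.permutation(n_blocks)]
    run2 = list(reversed(run1))
    return run1, run2


def _check_balanced(order: Sequence[str], version: TaskVersion) -> None:
    if len(order) != version.n_experimental_blocks:
        raise BalanceError(
            f"condition order has {len(order)} blocks, "
            f"expected {version.n_experimental_blocks}"
        )
    half = version.n_experimental_blocks // 2
    for cond in version.conditions:
        n = sum(1 for c in order if c == cond)
        if n != half:
            raise BalanceError(f"condition {cond!r} appears in {n} blocks, expected {half}")


def _subject_stimuli(
    materials: StimulusMaterials,
    version: TaskVersion,
    run_index: int,
    subject_seed: int,
) -> dict[str, list[StimulusItem]]:
    """Deterministic per-subject stimulus draw: one material set per subject,
    a per-(subject, version) permutation, runs take disjoint slices."""
    set_index = subject_seed % len(materials.sets)
    version_code = sorted(VERSIONS).index(version.name)
    per_run = version.trials_per_block * (version.n_experimental_blocks // 2)
    out: dict[str, list[StimulusItem]] = {}
    for ci, cond in enumerate(version.conditions):
        pool = materials.items(set_index, cond)
        lo, hi = (run_index - 1) * per_run, run_index * per_run
        if hi > len(pool):
            raise ExhaustionError(
                f"run {run_index} needs items {lo}..{hi} of {len(pool)} "
                f"available {cond!r} stimuli in set {set_index}"
            )
        rng = np.random.default_rng([subject_seed, version_code, ci])
        order = rng.permutation(len(pool))
        out[cond] = [pool[i] for i in order[lo:hi]]
    return out


def _assemble_run(
    version: TaskVersion,
    run_index: int,
    condition_order: Sequence[str],
    stimuli: dict[str, list[StimulusItem]] | None,
) -> RunSchedule:
    layout = _fixation_layout(version.n_experimental_blocks, version.n_fixation_blocks)
    events: list[TimedEvent] = []
    clock = 0
    block_index = 0
    exp_cursor = 0
    consumed = {c: 0 for c in version.conditions}
    for kind in layout:
        if kind == "F":
            events.append(
                TimedEvent(
                    onset_s=_ms_to_s(clock),
                    duration_s=version.fixation_block_s,
                    condition=FIXATION,
                    block_index=block_index,
                )
            )
            clock += _s_to_ms(version.fixation_block_s)
        else:
            cond = condition_order[exp_cursor]
            for t in range(version.trials_per_block):
                if stimuli is None:
                    events.append(
                        TimedEvent(
                            onset_s=_ms_to_s(clock),
                            duration_s=version.trial_duration_s,
                            condition=cond,
                            block_index=block_index,
                            trial_index=t,
                        )
                    )
                    clock += _s_to_ms(version.trial_duration_s)
                else:
                    item = stimuli[cond][consumed[cond]]
                    consumed[cond] += 1
                    trial = build_localizer_trial(
                        version, item, onset_s=_ms_to_s(clock),
                        block_index=block_index, trial_index=t,
                    )
                    events.extend(trial)
                    clock += _s_to_ms(version.trial_duration_s)
            exp_cursor += 1
        block_index += 1
    sched = RunSchedule(
        version=version,
        run_index=run_index,
        events=tuple(events),
        total_duration_s=_ms_to_s(clock),
    )
    sched.validate()
    return sched


def build_run_schedule(
    version: TaskVersion,
    run_index: int,
    condition_order: Sequence[str],
    materials: StimulusMaterials,
    subject_seed: int,
) -> RunSchedule:
    """Assemble a full localizer run for one subject.

    Stimuli come from the subject's single material set, permuted once per
    (subject, version) so no item repeats across that subject's two runs
    of the same version.
    """
    if version.name not in ("standard", "speeded"):
        raise ValueError("build_run_schedule is for the reading localizer versions")
    if run_index not in (1, 2):
        raise ValueError("run_index must be 1 or 2")
    _check_balanced(condition_order, version)
    stimuli = _subject_stimuli(materials, version, run_index, subject_seed)
    return _assemble_run(version, run_index, condition_order, stimuli)


def build_wm_run_schedule(
    run_index: int, condition_order: Sequence[str]
) -> RunSchedule:
    """Assemble a spatial working-memory run.

    Trial-internal dynamics (fixation cross, location flashes, choice,
    feedback) are collapsed into one fixed 8-s event per trial, since the
    GLM models whole condition blocks.
    """
    if run_index not in (1, 2):
        raise ValueError("run_index must be 1 or 2")
    _check_balanced(condition_order, SPATIAL_WM)
    return _assemble_run(SPATIAL_WM, run_index, condition_order, None)


_VOWELS = "aeiou"
_ONSETS = [c for c in string.ascii_lowercase if c not in _VOWELS + "qxy"]


def _pseudoword(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(1, 4))
    return "".join(
        _ONSETS[int(rng.integers(len(_ONSETS)))] + _VOWELS[int(rng.integers(5))]
        for _ in range(n_syll)
    )


def generate_placeholder_materials(seed: int = 0) -> StimulusMaterials:
    """Deterministic opaque stimulus text: 5 sets × (48 sentences + 48
    nonword sequences), 12 pseudo-tokens each.

    Stands in for the corpus-sampled sentences and phonotactically legal
    nonwords of the real paradigm; only timing and condition labels enter
    the analysis, so the text itself is arbitrary.
    """
    rng = np.random.default_rng(seed)
    sets = []
    for s in range(5):
        items = []
        for cond, tag in (("sentences", "S"), ("nonwords", "N")):
            for i in range(48):
                tokens = tuple(_pseudoword(rng) for _ in range(_WORDS_PER_STIMULUS))
                items.append(
                    StimulusItem(
                        item_id=f"set{s}_{tag}{i:02d}",
                        condition=cond,
                        tokens=tokens,
                    )
                )
        sets.append(tuple(items))
    return StimulusMaterials(sets=tuple(sets))


def write_events(schedule: RunSchedule, path: str | Path) -> None:
    """Serialize a schedule as a BIDS-events-style TSV (onset/duration in
    seconds, 0-based, period decimal separator)."""
    lines = ["onset\tduration\ttrial_type\tstimulus_id"]
    for ev in schedule.events:
        sid = ev.stimulus_id if ev.stimulus_id is not None else "n/a"
        lines.append(f"{ev.onset_s:.3f}\t{ev.duration_s:.3f}\t{ev.condition}\t{sid}")
    Path(path).write_text("\n".join(lines) + "\n")
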