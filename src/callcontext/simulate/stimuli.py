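"""Stimulus assembly and playback-session scheduling.

A stimulus is three consecutive calls of one condition (grunt or one of
the three yawn contexts) separated by two randomized pauses of 5-10 s,
with the three calls' peak amplitudes equalized.  Reuse rules mirror a
field playback protocol: each call appears in at most two stimuli and
never twice in the same three-call combination; each subject hears a
given call at most once; every subject receives all 4 conditions x 2
receiver contexts = 8 sessions, at most one session per day per subject,
at least one day between a subject's sessions, and a global cap of three
playbacks per day.

``validate_design`` re-checks every invariant independently of the
scheduler and returns the list of violations (empty on success).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "StimulusSequence",
    "PlaybackDesign",
    "InfeasibleDesignError",
    "assemble_stimuli",
    "schedule_playbacks",
    "validate_design",
]

CONDITIONS: tuple[str, ...] = ("grunt", "high_social", "low_social", "non_social")
RECEIVER_CONTEXTS: tuple[str, ...] = ("social", "non_social")

PAUSE_RANGE_S = (5.0, 10.0)
MAX_USES_PER_CALL = 2
CALLS_PER_STIMULUS = 3
SESSIONS_PER_SUBJECT = 8
MAX_PLAYBACKS_PER_DAY = 3


class InfeasibleDesignError(RuntimeError):
    """Raised when reuse/scheduling constraints cannot be satisfied;
    the message names the binding rule."""


@dataclass(frozen=True)
class StimulusSequence:
    """Three calls of one condition with randomized inter-call pauses."""

    stimulus_id: str
    condition: str
    call_ids: tuple[str, str, str]
    call_durations_s: tuple[float, float, float]
    pause_s: tuple[float, float]
    gains: tuple[float, float, float]  # per-call scale equalizing peak amplitude

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.call_ids) != CALLS_PER_STIMULUS:
            raise ValueError("a stimulus holds exactly 3 calls")
        if len(set(self.call_ids)) != CALLS_PER_STIMULUS:
            raise ValueError("calls within a stimulus must be distinct")
        for p in self.pause_s:
            if not (PAUSE_RANGE_S[0] <= p <= PAUSE_RANGE_S[1]):
                raise ValueError(f"pause {p:.2f}s outside {PAUSE_RANGE_S}")

    @property
    def total_duration_s(self) -> float:
        return float(sum(self.call_durations_s) + sum(self.pause_s))


@dataclass
class PlaybackDesign:
    """Subjects plus the per-session schedule (one row per playback)."""

    subjects: pd.DataFrame  # columns: subject_id, sex
    sessions: pd.DataFrame  # columns: subject_id, day_index, condition,
    #          receiver_context, stimulus_id, trial_order


def assemble_stimuli(
    manifest: pd.DataFrame,
    n_per_condition: Mapping[str, int],
    seed: int = 0,
) -> list[StimulusSequence]:
    """Build stimulus sequences from a call manifest.

    ``manifest`` needs columns ``call_id, context, duration_s, peak_amp``
    (grunts carry context ``"grunt"``).  Calls are drawn without caller
    repetition inside a stimulus when a ``caller_id`` column is present,
    each call is used at most twice overall, and no three-call
    combination repeats.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    out: list[StimulusSequence] = []
    uses: dict[str, int] = {}
    combos: set[frozenset[str]] = set()
    sid = 0
    for condition, n_needed in n_per_condition.items():
        pool = manifest[manifest["context"] == condition]
        if len(pool) < CALLS_PER_STIMULUS:
            raise InfeasibleDesignError(
                f"condition {condition!r}: pool has {len(pool)} calls, need >= {CALLS_PER_STIMULUS} per stimulus"
            )
        capacity = (MAX_USES_PER_CALL * len(pool)) // CALLS_PER_STIMULUS
        if n_needed > capacity:
            raise InfeasibleDesignError(
                f"condition {condition!r}: {n_needed} stimuli requested but reuse<= {MAX_USES_PER_CALL} "
                f"on {len(pool)} calls caps the count at {capacity}"
            )
        for _ in range(n_needed):
            avail = pool[pool["call_id"].map(lambda c: uses.get(c, 0) < MAX_USES_PER_CALL)]
            # prefer fresh calls so stimuli stay disjoint while the pool lasts,
            # which maximizes how many times the set can be played downstream
            min_use = min((uses.get(c, 0) for c in avail["call_id"]), default=0)
            fresh = avail[avail["call_id"].map(lambda c: uses.get(c, 0) == min_use)]
            chosen = _pick_combo(fresh if len(fresh) >= CALLS_PER_STIMULUS else avail, combos, rng)
            if chosen is None and len(fresh) >= CALLS_PER_STIMULUS:
                chosen = _pick_combo(avail, combos, rng)
            if chosen is None:
                raise InfeasibleDesignError(
                    f"condition {condition!r}: no unused 3-call combination left "
                    f"(reuse <= {MAX_USES_PER_CALL}, combinations must be unique)"
                )
            ids = tuple(chosen["call_id"])
            durs = tuple(float(d) for d in chosen["duration_s"])
            peaks = np.asarray(chosen["peak_amp"], dtype=float)
            target = peaks.max()
            gains = tuple(float(target / p) if p > 0 else 1.0 for p in peaks)
            pauses = tuple(rng.uniform(*PAUSE_RANGE_S, size=2))
            out.append(
                StimulusSequence(
                    stimulus_id=f"stim{sid:03d}",
                    condition=condition,
                    call_ids=ids,  # type: ignore[arg-type]
                    call_durations_s=durs,  # type: ignore[arg-type]
                    pause_s=pauses,  # type: ignore[arg-type]
                    gains=gains,  # type: ignore[arg-type]
                )
            )
            sid += 1
            combos.add(frozenset(ids))
            for c in ids:
                uses[c] = uses.get(c, 0) + 1
    return out


def _pick_combo(
    avail: pd.DataFrame, combos: set[frozenset[str]], rng: np.random.Generator, tries: int = 200
) -> pd.DataFrame | None:
    if len(avail) < CALLS_PER_STIMULUS:
        return None
    distinct_callers = "caller_id" in avail.columns and avail["caller_id"].nunique() >= CALLS_PER_STIMULUS
    for _ in range(tries):
        if distinct_callers:
            callers = rng.choice(avail["caller_id"].unique(), size=CALLS_PER_STIMULUS, replace=False)
            rows = [avail[avail["caller_id"] == c].sample(1, random_state=int(rng.integers(2**31 - 1))) for c in callers]
            pick = pd.concat(rows)
        else:
            pick = avail.sample(CALLS_PER_STIMULUS, random_state=int(rng.integers(2**31 - 1)))
        if frozenset(pick["call_id"]) not in combos:
            return pick
    # deterministic fallback: exhaustive search over index triples
    for trio in itertools.combinations(range(len(avail)), CALLS_PER_STIMULUS):
        pick = avail.iloc[list(trio)]
        if frozenset(pick["call_id"]) not in combos:
            if not distinct_callers or pick["caller_id"].nunique() == CALLS_PER_STIMULUS:
                return pick
    return None


def schedule_playbacks(
    subjects: Sequence[tuple[str, str]],
    stimuli: Sequence[StimulusSequence],
    seed: int = 0,
    max_attempts: int = 50,
) -> PlaybackDesign:
    """Assign 8 sessions (4 conditions x 2 receiver contexts) per subject.

    Greedy randomized construction with restarts: days advance while each
    subject still owes sessions; per day at most three playbacks overall
    and at most one per subject.  Stimulus choice tracks uses per call id
    (not per stimulus) and never exposes the same subject to the same
    call twice.
    """
    by_condition: dict[str, list[StimulusSequence]] = {}
    for s in stimuli:
        by_condition.setdefault(s.condition, []).append(s)
    for cond in CONDITIONS:
        need = 2 * len(subjects)  # each subject meets the condition in both receiver contexts
        pool = by_condition.get(cond, [])
        if MAX_USES_PER_CALL * len(pool) < need:
            raise InfeasibleDesignError(
                f"condition {cond!r}: {len(pool)} stimuli cannot cover {need} sessions "
                f"with call reuse <= {MAX_USES_PER_CALL}"
            )

    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    last_err = "unknown"
    for _ in range(max_attempts):
        result = _try_schedule(subjects, by_condition, rng)
        if isinstance(result, PlaybackDesign):
            violations = validate_design(result, stimuli)
            if violations:  # pragma: no cover - scheduler bug guard
                raise AssertionError(f"scheduler produced invalid design: {violations}")
            return result
        last_err = result
    raise InfeasibleDesignError(f"scheduling failed after {max_attempts} restarts; binding constraint: {last_err}")


def _try_schedule(
    subjects: Sequence[tuple[str, str]],
    by_condition: Mapping[str, Sequence[StimulusSequence]],
    rng: np.random.Generator,
) -> PlaybackDesign | str:
    pending: dict[str, list[tuple[str, str]]] = {
        sid: [(c, r) for c in CONDITIONS for r in RECEIVER_CONTEXTS] for sid, _ in subjects
    }
    call_uses: dict[str, int] = {}
    heard: dict[str, set[str]] = {sid: set() for sid, _ in subjects}
    trial_order: dict[str, int] = {sid: 0 for sid, _ in subjects}
    rows = []
    day = 0
    stall = 0
    while any(pending.values()):
        day += 1
        if stall > 6:
            return "no admissible stimulus for remaining subject/condition pairs (call reuse or repeat-exposure)"
        todays = 0
        order = list(pending)
        rng.shuffle(order)
        progressed = False
        for sid in order:
            if todays >= MAX_PLAYBACKS_PER_DAY or not pending[sid]:
                continue
            slots = pending[sid][:]
            rng.shuffle(slots)
            placed = False
            for cond, rc in slots:
                options = [
                    s
                    for s in by_condition.get(cond, [])
                    if all(call_uses.get(c, 0) < MAX_USES_PER_CALL for c in s.call_ids)
                    and not (set(s.call_ids) & heard[sid])
                ]
                if not options:
                    continue
                stim = options[int(rng.integers(len(options)))]
                trial_order[sid] += 1
                rows.append(
                    {
                        "subject_id": sid,
                        "day_index": day,
                        "condition": cond,
                        "receiver_context": rc,
                        "stimulus_id": stim.stimulus_id,
                        "trial_order": trial_order[sid],
                    }
                )
                pending[sid].remove((cond, rc))
                for c in stim.call_ids:
                    call_uses[c] = call_uses.get(c, 0) + 1
                heard[sid].update(stim.call_ids)
                todays += 1
                placed = True
                progressed = True
                break
            if placed:
                continue
        stall = 0 if progressed else stall + 1
    subj_df = pd.DataFrame(subjects, columns=["subject_id", "sex"])
    return PlaybackDesign(subjects=subj_df, sessions=pd.DataFrame(rows))


def validate_design(design: PlaybackDesign, stimuli: Sequence[StimulusSequence]) -> list[str]:
    """Independent re-check of every scheduling invariant; returns violations."""
    v: list[str] = []
    stim_map = {s.stimulus_id: s for s in stimuli}
    sess = design.sessions
    for sid, grp in sess.groupby("subject_id"):
        if len(grp) != SESSIONS_PER_SUBJECT:
            v.append(f"{sid}: {len(grp)} sessions, expected {SESSIONS_PER_SUBJECT}")
        combos = set(zip(grp["condition"], grp["receiver_context"]))
        if len(combos) != SESSIONS_PER_SUBJECT:
            v.append(f"{sid}: conditions x receiver contexts not fully crossed")
        for day, dgrp in grp.groupby("day_index"):
            if dgrp["condition"].duplicated().any():
                v.append(f"{sid} day {day}: same condition twice in one day")
        days = np.sort(grp["day_index"].to_numpy())
        if len(days) > 1 and np.min(np.diff(days)) < 1:
            v.append(f"{sid}: sessions closer than one day apart")
        # call-level repeat exposure
        heard: list[str] = []
        for stim_id in grp["stimulus_id"]:
            heard.extend(stim_map[stim_id].call_ids)
        dup = {c for c in heard if heard.count(c) > 1}
        if dup:
            v.append(f"{sid}: heard call(s) {sorted(dup)} more than once")
    for day, dgrp in sess.groupby("day_index"):
        if len(dgrp) > MAX_PLAYBACKS_PER_DAY:
            v.append(f"day {day}: {len(dgrp)} playbacks exceed the {MAX_PLAYBACKS_PER_DAY}/day cap")
    all_calls: list[str] = []
    for stim_id in sess["stimulus_id"]:
        all_calls.extend(stim_map[stim_id].call_ids)
    overused = {c for c in set(all_calls) if all_calls.count(c) > MAX_USES_PER_CALL}
    if overused:
        v.append(f"call(s) used more than {MAX_USES_PER_CALL} times: {sorted(overused)}")
    return v
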