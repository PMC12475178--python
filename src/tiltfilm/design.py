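"""Counterbalanced trial schedules for the film-adaptation experiment.

The experiment has three sessions per participant: a baseline session
(practice + 600 baseline trials, no film) and two adaptation sessions, one
with a cardinal adaptor (0 or 90 deg) and one with an oblique adaptor (45 or
135 deg).  In adaptation sessions, 600 trials are split into 120 blocks of
five, each block preceded by a 22.40 s orientation-filtered film clip, for
44.80 min of viewing per session.  Each participant judges test gratings
against two standard orientations chosen to be equidistant from both of
their adaptors, so that only the adaptor changes between sessions.

Trial tables are plain pandas DataFrames with one row per trial (columns in
``SCHEDULE_COLUMNS``); the baseline condition carries the adaptor sentinel
``BASELINE`` (-999), the coding used on disk as well.
"""

from __future__ import annotations

import itertools
import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BASELINE",
    "STANDARD_SET",
    "DesignSpec",
    "assign_standards",
    "build_baseline_schedule",
    "build_adaptation_schedule",
    "build_practice_schedule",
    "build_participant_schedule",
    "counterbalance",
    "relative_standard",
    "fold_deg",
    "angular_distance",
]

#: Sentinel adaptor code for baseline (no-adaptor) trials, as stored on disk.
BASELINE = -999.0

#: The four possible standard-bar orientations (deg from vertical).
STANDARD_SET = (-67.5, -22.5, 22.5, 67.5)

CARDINALS = (0.0, 90.0)
OBLIQUES = (45.0, 135.0)

SCHEDULE_COLUMNS = [
    "participant", "session", "phase", "block", "trial_index",
    "adaptor_deg", "standard_deg", "offset_deg", "feedback",
    "include_in_baseline", "response",
]

SESSIONS = ("baseline", "adapt1", "adapt2")


def fold_deg(theta):
    """Fold an orientation (deg) to (-90, 90] under 180-deg periodicity."""
    wrapped = -np.mod(-np.asarray(theta, dtype=float) + 90.0, 180.0) + 90.0
    if np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


def angular_distance(a, b):
    """Unsigned orientation distance in degrees, folded to [0, 90]."""
    d = np.abs(fold_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
    return np.minimum(d, 180.0 - d) if np.ndim(d) else min(d, 180.0 - d)


@dataclass
class DesignSpec:
    """All tunable design parameters, defaulting to the study's values.

    ``baseline_counts`` maps |offset| -> trials per (standard, offset) cell
    in the baseline (and, by the same scheme, adaptation) sessions; the
    default 20/40/60 scheme concentrates trials at small offsets and sums to
    300 trials per standard per session.
    """

    offsets: tuple = (-10.0, -5.0, -2.5, 0.0, 2.5, 5.0, 10.0)
    baseline_counts: dict = field(
        default_factory=lambda: {10.0: 20, 5.0: 40, 2.5: 60, 0.0: 60})
    clips_per_session: int = 120
    trials_per_block: int = 5
    clip_seconds: float = 22.40
    n_sessions_adapt: int = 2
    # session-1 practice: doubled-offset feedback phase, then standard-offset
    # feedback phase; sessions 2-3: short feedback phase + no-feedback phase
    # folded into the baseline dataset.
    practice1_doubled: int = 84
    practice1_standard: int = 504
    practice23_feedback: int = 14
    practice23_nofeedback: int = 196

    def __post_init__(self) -> None:
        offs = np.asarray(self.offsets, dtype=float)
        if not np.allclose(np.sort(offs), np.sort(-offs)):
            raise ValueError("offsets must be symmetric about 0")
        for o in offs:
            if abs(o) not in self.baseline_counts:
                raise ValueError(f"no baseline count for offset {o}")

    def cell_counts(self) -> dict:
        """Trials per (standard x offset) cell in an experimental session."""
        return {o: self.baseline_counts[abs(o)] for o in self.offsets}

    @property
    def trials_per_session(self) -> int:
        return 2 * sum(self.cell_counts().values())

    @property
    def viewing_minutes_per_session(self) -> float:
        return self.clips_per_session * self.clip_seconds / 60.0


def assign_standards(adaptor_pair) -> tuple[float, float]:
    """The unique standard pair equidistant from both adaptors.

    Each of the two standards is individually equidistant (orientation
    distance folded to [0, 90]) from the two adaptors, and per adaptor one
    standard lies 22.5 deg away and the other 67.5 deg.  E.g. adaptors
    {0, 135} give standards (67.5, -22.5).
    """
    pair = tuple(float(a) for a in adaptor_pair)
    if len(pair) != 2 or not (
            (pair[0] in CARDINALS and pair[1] in OBLIQUES)
            or (pair[0] in OBLIQUES and pair[1] in CARDINALS)):
        raise ValueError(
            f"adaptor pair must contain one cardinal and one oblique, got {pair}")
    a1, a2 = pair
    hits = []
    for s1, s2 in itertools.combinations(STANDARD_SET, 2):
        if angular_distance(s1, a1) != angular_distance(s1, a2):
            continue
        if angular_distance(s2, a1) != angular_distance(s2, a2):
            continue
        dists = sorted((angular_distance(s1, a1), angular_distance(s2, a1)))
        if dists == [22.5, 67.5]:
            hits.append((s1, s2))
    if len(hits) != 1:  # impossible for valid cardinal+oblique pairs
        raise ValueError(f"no unique standard pair for adaptors {pair}: {hits}")
    s1, s2 = hits[0]
    # deterministic presentation order: larger magnitude first, to match the
    # (67.5, -22.5) phrasing of the worked example
    return tuple(sorted(hits[0], key=lambda s: (-abs(s), s)))


def relative_standard(S: float, F: float) -> float:
    """Standard orientation re-coded relative to the adaptor, in (-90, 90]."""
    if F == BASELINE:
        raise ValueError("relative_standard undefined for the baseline condition")
    return fold_deg(S - F)


def _empty_schedule(n: int) -> pd.DataFrame:
    return pd.DataFrame({c: [np.nan] * n for c in SCHEDULE_COLUMNS})


def _assemble(participant, session, phase, adaptor, standards, offsets,
              feedback, include_in_baseline, rng, spec) -> pd.DataFrame:
    """Shuffle (standard, offset) cells into a trial table."""
    n = len(standards)
    order = rng.permutation(n)
    df = _empty_schedule(n)
    df["participant"] = participant
    df["session"] = session
    df["phase"] = phase
    df["trial_index"] = np.arange(n)
    df["block"] = np.arange(n) // spec.trials_per_block
    df["adaptor_deg"] = adaptor
    df["standard_deg"] = np.asarray(standards, dtype=float)[order]
    df["offset_deg"] = np.asarray(offsets, dtype=float)[order]
    df["feedback"] = bool(feedback)
    df["include_in_baseline"] = bool(include_in_baseline)
    df["response"] = np.nan
    return df


def _cells(standards, counts) -> tuple[list, list]:
    ss, oo = [], []
    for s in standards:
        for off, k in counts.items():
            ss += [s] * k
            oo += [off] * k
    return ss, oo


def build_baseline_schedule(spec: DesignSpec, participant, standards,
                            seed: int) -> pd.DataFrame:
    """600 baseline trials: 20/40/60 per offset magnitude per standard."""
    rng = np.random.default_rng(seed)
    ss, oo = _cells(standards, spec.cell_counts())
    return _assemble(participant, "baseline", "main", BASELINE, ss, oo,
                     feedback=False, include_in_baseline=True, rng=rng,
                     spec=spec)


def build_adaptation_schedule(spec: DesignSpec, participant, session: str,
                              adaptor: float, standards,
                              seed: int) -> pd.DataFrame:
    """600 adaptation trials in 120 blocks of five, one clip per block.

    Per-cell counts reuse the baseline 20/40/60 scheme (the totals match:
    300 trials per standard per session).
    """
    if session not in ("adapt1", "adapt2"):
        raise ValueError(f"session must be adapt1/adapt2, got {session}")
    rng = np.random.default_rng(seed)
    ss, oo = _cells(standards, spec.cell_counts())
    return _assemble(participant, session, "main", float(adaptor), ss, oo,
                     feedback=False, include_in_baseline=False, rng=rng,
                     spec=spec)


def build_practice_schedule(spec: DesignSpec, participant, session: str,
                            standards, seed: int) -> pd.DataFrame:
    """Practice trials preceding each session's experimental trials.

    Session 1: 84 feedback trials at doubled offsets, then 504 feedback
    trials at standard offsets.  Sessions 2-3: 14 feedback trials (one per
    standard x offset cell) then 196 no-feedback trials (14 per cell) that
    are flagged for inclusion in the baseline dataset.
    """
    if session not in SESSIONS:
        raise ValueError(f"unknown session {session}")
    rng = np.random.default_rng(seed)
    offsets = np.asarray(spec.offsets, dtype=float)
    n_cells = 2 * len(offsets)
    if session == "baseline":
        reps1 = spec.practice1_doubled // n_cells
        ss1, oo1 = _cells(standards, {2 * o: reps1 for o in offsets})
        part1 = _assemble(participant, session, "practice_doubled", BASELINE,
                          ss1, oo1, True, False, rng, spec)
        reps2 = spec.practice1_standard // n_cells
        ss2, oo2 = _cells(standards, {o: reps2 for o in offsets})
        part2 = _assemble(participant, session, "practice", BASELINE,
                          ss2, oo2, True, False, rng, spec)
        out = pd.concat([part1, part2], ignore_index=True)
    else:
        ss1, oo1 = _cells(standards, {o: 1 for o in offsets})
        part1 = _assemble(participant, session, "practice", BASELINE,
                          ss1, oo1, True, False, rng, spec)
        reps = spec.practice23_nofeedback // n_cells
        ss2, oo2 = _cells(standards, {o: reps for o in offsets})
        part2 = _assemble(participant, session, "practice", BASELINE,
                          ss2, oo2, False, True, rng, spec)
        out = pd.concat([part1, part2], ignore_index=True)
    out["trial_index"] = np.arange(len(out))
    out["block"] = out["trial_index"] // spec.trials_per_block
    return out


def counterbalance(participants, seed: int = 0) -> pd.DataFrame:
    """Assign (cardinal, oblique, order) cells to participants.

    The 8 cells (4 cardinal x oblique pairs x 2 session orders) are cycled
    in a seeded random order, so any multiple of 8 participants uses every
    cell equally often.  Returns one row per participant with the adaptor
    shown in each adaptation session and the shared standard pair.
    """
    participants = list(participants)
    if len(participants) % 8 != 0:
        warnings.warn(
            f"{len(participants)} participants: counterbalance cells will be "
            "unequally used (8 cells)", stacklevel=2)
    cells = [(c, o, order) for c in CARDINALS for o in OBLIQUES
             for order in ("cardinal_first", "oblique_first")]
    rng = np.random.default_rng(seed)
    cells = [cells[i] for i in rng.permutation(len(cells))]
    rows = []
    for i, p in enumerate(participants):
        cardinal, oblique, order = cells[i % len(cells)]
        first, second = ((cardinal, oblique) if order == "cardinal_first"
                         else (oblique, cardinal))
        s1, s2 = assign_standards((cardinal, oblique))
        rows.append({"participant": p, "adaptor_adapt1": first,
                     "adaptor_adapt2": second, "standard_1": s1,
                     "standard_2": s2, "order": order})
    return pd.DataFrame(rows)


def build_participant_schedule(spec: DesignSpec, assignment_row,
                               seed: int) -> pd.DataFrame:
    """All three sessions (practice + experimental trials) for one participant."""
    p = assignment_row["participant"]
    standards = (assignment_row["standard_1"], assignment_row["standard_2"])
    # stable per-participant stream (zlib.crc32 is deterministic across runs,
    # unlike the builtin str hash)
    ss = np.random.SeedSequence([int(seed), zlib.crc32(str(p).encode())])
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]
    parts = [
        build_practice_schedule(spec, p, "baseline", standards, seeds[0]),
        build_baseline_schedule(spec, p, standards, seeds[1]),
        build_practice_schedule(spec, p, "adapt1", standards, seeds[2]),
        build_adaptation_schedule(spec, p, "adapt1",
                                  assignment_row["adaptor_adapt1"], standards,
                                  seeds[3]),
        build_practice_schedule(spec, p, "adapt2", standards, seeds[4]),
        build_adaptation_schedule(spec, p, "adapt2",
                                  assignment_row["adaptor_adapt2"], standards,
                                  seeds[5]),
    ]
    out = pd.concat(parts, ignore_index=True)
    # renumber so trial_index is the within-session presentation order
    # (practice precedes the experimental trials it belongs to)
    out["trial_index"] = out.groupby("session").cumcount()
    return out


def build_cohort_schedule(spec: DesignSpec, participants, seed: int) -> pd.DataFrame:
    """Counterbalanced schedules for a whole cohort, one table."""
    table = counterbalance(participants, seed)
    frames = [build_participant_schedule(spec, row, seed)
              for _, row in table.iterrows()]
    df = pd.concat(frames, ignore_index=True)
    logger.info("built schedule: %d participants, %d trials",
                len(participants), len(df))
    return df
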