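"""Forward/reverse cumulative response-bias traces with permutation bands.

Response bias in a stratum (session x adaptor-relative standard
orientation) is the mean of +-1-coded clockwise/counterclockwise responses.
To ask whether bias differs between the start and end of a session, the
running mean is computed forward from trial 1 and in reverse from the last
trial, per participant, and the two aggregate traces are compared against a
permutation null in which the direction of accumulation carries no
information: for each permutation, every participant's trace value at every
trial index is randomly taken from their forward or reverse accumulation
before averaging across participants.  The per-trial 2.5% and 97.5%
quantiles of the permuted aggregates form a 95% confidence band; aggregate
trace points strictly outside the band are flagged as significant
start-vs-end differences.

Because forward and reverse traces share the full-sample mean at their far
end, the null is exactly a sign-flip distribution on the per-participant
half-differences, giving nominal pointwise coverage under a stationary
observer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BASELINE, relative_standard

logger = logging.getLogger(__name__)

__all__ = ["AccumulationResult", "code_responses", "cumulative_trace",
           "aggregate_traces", "permutation_band", "flag_divergence",
           "fold_absolute_standard", "analyze_stratum", "sequential_analysis"]


@dataclass
class AccumulationResult:
    """Forward/reverse accumulation traces and permutation band for a stratum."""

    rel_standard: float
    forward: np.ndarray          # aggregate forward trace, length n
    reverse: np.ndarray          # aggregate reverse trace (same 1..n axis)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    flags: np.ndarray            # True where a trace exits the band
    n_perm: int
    seed: int
    participant_forward: np.ndarray  # (n_participants, n) per-trace matrices
    participant_reverse: np.ndarray
    folded: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.forward)


def code_responses(trials: pd.DataFrame) -> np.ndarray:
    """+-1-coded responses in strict trial order for one stratum slice.

    'right' (1) -> +1, 'left' (0) -> -1.  Raises if any response is missing.
    """
    missing = trials.loc[trials["response"].isna()]
    if len(missing):
        raise ValueError(
            f"missing responses for trials {missing.index.tolist()[:10]}")
    ordered = trials.sort_values("trial_index")
    return (2.0 * ordered["response"].to_numpy(dtype=float) - 1.0)


def cumulative_trace(coded: np.ndarray, direction: str = "forward"
                     ) -> np.ndarray:
    """Running mean of a +-1 sequence, forward or from the tail.

    forward[k] is the mean of the first k entries; reverse[k] the mean of
    the LAST k entries, so both are indexed on the same 1..n axis and agree
    at k = n (the grand mean).
    """
    coded = np.asarray(coded, dtype=float)
    if coded.size == 0:
        raise ValueError("empty response sequence")
    if direction == "reverse":
        coded = coded[::-1]
    elif direction != "forward":
        raise ValueError(f"unknown direction {direction!r}")
    return np.cumsum(coded) / np.arange(1, coded.size + 1)


def aggregate_traces(traces: np.ndarray) -> np.ndarray:
    """Pointwise mean across participants of equal-length traces."""
    if isinstance(traces, (list, tuple)):
        rows = [np.asarray(t, dtype=float) for t in traces]
    else:
        arr = np.atleast_2d(np.asarray(traces, dtype=float))
        rows = list(arr)
    lengths = {r.shape[-1] for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"trace length mismatch: {sorted(lengths)}")
    return np.vstack(rows).mean(axis=0)


def permutation_band(fwd: np.ndarray, rev: np.ndarray, n_perm: int = 1000,
                     seed: int = 0, level: str = "participant"
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial 95% band of the direction-randomised null.

    ``fwd``/``rev`` are (n_participants, n_trials) per-participant trace
    matrices.  level="participant" (default): each permutation picks, per
    participant and per trial, the forward or reverse value before
    averaging — the sign-flip null on half-differences.  level="aggregate"
    randomises the already-aggregated value pair instead (a degenerate
    two-point null, kept for comparison only).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; quantiles will be coarse",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    fwd = np.atleast_2d(fwd)
    rev = np.atleast_2d(rev)
    if level == "participant":
        mid = (fwd + rev) / 2.0          # (P, n)
        half = (fwd - rev) / 2.0
        # permuted aggregate = mean_p(mid) + mean_p(s * half), s = +-1
        signs = rng.choice([-1.0, 1.0], size=(n_perm,) + fwd.shape)
        null = mid.mean(axis=0)[None, :] + np.einsum(
            "qpn,pn->qn", signs, half) / fwd.shape[0]
    elif level == "aggregate":
        fa, ra = fwd.mean(axis=0), rev.mean(axis=0)
        pick = rng.random((n_perm, fa.size)) < 0.5
        null = np.where(pick, fa[None, :], ra[None, :])
    else:
        raise ValueError(f"unknown level {level!r}")
    ci_lo = np.quantile(null, 0.025, axis=0)
    ci_hi = np.quantile(null, 0.975, axis=0)
    return ci_lo, ci_hi


def flag_divergence(result: AccumulationResult) -> np.ndarray:
    """True where the forward or reverse aggregate lies strictly outside the band."""
    out_f = (result.forward < result.ci_lo) | (result.forward > result.ci_hi)
    out_r = (result.reverse < result.ci_lo) | (result.reverse > result.ci_hi)
    return out_f | out_r


def analyze_stratum(sequences: dict, rel_standard: float, n_perm: int = 1000,
                    seed: int = 0, level: str = "participant"
                    ) -> AccumulationResult:
    """Full accumulation analysis for one stratum.

    ``sequences`` maps participant id -> +-1-coded response array (equal
    lengths).  Traces are computed per participant, averaged, and compared
    to the permutation band.
    """
    pids = sorted(sequences, key=str)
    fwd = np.vstack([cumulative_trace(sequences[p], "forward") for p in pids])
    rev = np.vstack([cumulative_trace(sequences[p], "reverse") for p in pids])
    ci_lo, ci_hi = permutation_band(fwd, rev, n_perm=n_perm, seed=seed,
                                    level=level)
    result = AccumulationResult(
        rel_standard=rel_standard,
        forward=aggregate_traces(fwd), reverse=aggregate_traces(rev),
        ci_lo=ci_lo, ci_hi=ci_hi, flags=np.zeros(fwd.shape[1], dtype=bool),
        n_perm=n_perm, seed=seed,
        participant_forward=fwd, participant_reverse=rev)
    result.flags = flag_divergence(result)
    return result


def fold_absolute_standard(res_pos: AccumulationResult,
                           res_neg: AccumulationResult,
                           ) -> AccumulationResult:
    """Combine +-S strata into one absolute-standard result.

    Traces from the negative stratum are sign-reversed (a leftward bias at
    -S is the mirror of a rightward bias at +S) and pooled with the
    positive-stratum participants before aggregation and band construction.
    Refolding an already-folded result is an error.
    """
    if res_pos.folded or res_neg.folded:
        raise ValueError("inputs already folded; folding is not idempotent")
    if res_pos.n_trials != res_neg.n_trials:
        raise ValueError("strata have different trial counts")
    if abs(res_pos.rel_standard) != abs(res_neg.rel_standard):
        raise ValueError("strata are not a +-S pair")
    fwd = np.vstack([res_pos.participant_forward,
                     -res_neg.participant_forward])
    rev = np.vstack([res_pos.participant_reverse,
                     -res_neg.participant_reverse])
    ci_lo, ci_hi = permutation_band(fwd, rev, n_perm=res_pos.n_perm,
                                    seed=res_pos.seed)
    result = AccumulationResult(
        rel_standard=abs(res_pos.rel_standard),
        forward=aggregate_traces(fwd), reverse=aggregate_traces(rev),
        ci_lo=ci_lo, ci_hi=ci_hi, flags=np.zeros(fwd.shape[1], dtype=bool),
        n_perm=res_pos.n_perm, seed=res_pos.seed,
        participant_forward=fwd, participant_reverse=rev, folded=True)
    result.flags = flag_divergence(result)
    return result


def stratum_sequences(trials: pd.DataFrame) -> dict:
    """Group adaptation main trials into per-stratum coded sequences.

    Returns {(session, rel_standard): {participant: +-1 array}}, with the
    standard re-coded relative to the session's adaptor so attraction and
    repulsion read consistently across adaptor conditions.
    """
    df = trials.loc[(trials["adaptor_deg"] != BASELINE)]
    if "phase" in df.columns:
        df = df.loc[df["phase"] == "main"]
    df = df.copy()
    df["rel_standard"] = [relative_standard(s, f) for s, f in
                          zip(df["standard_deg"], df["adaptor_deg"])]
    out: dict = {}
    for (session, rel, pid), grp in df.groupby(
            ["session", "rel_standard", "participant"]):
        out.setdefault((session, rel), {})[pid] = code_responses(grp)
    return out


def sequential_analysis(trials: pd.DataFrame, n_perm: int = 1000,
                        seed: int = 0, collapse_sessions: bool = True,
                        level: str = "participant") -> dict:
    """Accumulation analysis for every adaptor-relative standard stratum.

    With ``collapse_sessions`` (matching the presentation of results
    collapsed across adaptor conditions), the two adaptation sessions'
    sequences enter the same relative-standard stratum as separate
    participant-session traces.  Returns {stratum key: AccumulationResult}.
    """
    seqs = stratum_sequences(trials)
    if collapse_sessions:
        merged: dict = {}
        for (session, rel), d in seqs.items():
            slot = merged.setdefault(rel, {})
            for pid, arr in d.items():
                slot[(pid, session)] = arr
        seqs = merged
        return {rel: analyze_stratum(d, rel, n_perm=n_perm, seed=seed,
                                     level=level)
                for rel, d in sorted(seqs.items())}
    return {key: analyze_stratum(d, key[1], n_perm=n_perm, seed=seed,
                                 level=level)
            for key, d in sorted(seqs.items())}


def result_table(result: AccumulationResult) -> pd.DataFrame:
    """Tidy per-trial table of one stratum's accumulation analysis."""
    n = result.n_trials
    return pd.DataFrame({
        "trial": np.arange(1, n + 1),
        "forward": result.forward, "reverse": result.reverse,
        "ci_lo": result.ci_lo, "ci_hi": result.ci_hi,
        "flag": result.flags,
    })
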