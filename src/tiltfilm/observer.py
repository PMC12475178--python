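"""Parametric synthetic observer generating binary tilt judgements.

The observer answers "is the test grating clockwise of the standard?" with

    P(right) = (1 - lapse) * Phi(slope * (T + b)) + lapse / 2

where T is the test offset in degrees, Phi the standard normal CDF, and the
bias b (degrees) is the sum of a baseline anisotropy term tied to the
standard orientation, an adaptor-relative tilt-aftereffect term that may
build up over trials, an optional per-(adaptor, standard)-cell injected bias,
and a participant-level random perturbation.  The probit core mirrors the
analysis model, so injected biases are recoverable in expectation and the
whole pipeline can be validated by parameter recovery.

The tilt-aftereffect profile is the classic odd-symmetric shape: repulsion
for test orientations within ~50 deg of the adaptor, attraction beyond, zero
at 0 and 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import BASELINE, fold_deg, relative_standard

__all__ = ["ObserverParams", "tae_profile", "respond", "simulate_cohort",
           "simulate_trials"]


@dataclass
class ObserverParams:
    """Ground-truth data-generating parameters for one synthetic observer.

    Parameters
    ----------
    slope : float
        Probit-scale sensitivity per degree of offset.  0.3/deg puts the
        ~84% point at +3.3 deg, a realistic psychometric width for this task.
    baseline_bias : dict
        Standard orientation (deg) -> baseline bias (deg); models the
        cardinal-repulsion anisotropy.  Missing standards mean zero bias.
    tae_amplitude : float
        Peak tilt-aftereffect magnitude in degrees.  Conventional aftereffects
        peak at 1-3 deg; default 2.
    tae_crossover : float
        Adaptor-relative orientation (deg) at which the aftereffect switches
        from repulsion to attraction (default 50).
    buildup_tau : float
        Trial-scale time constant of the saturating build-up
        b(t) = b_inf * (1 - exp(-t / tau)); ``inf`` = instantaneous.
    condition_bias : dict
        Optional (adaptor_deg, standard_deg) -> extra bias in degrees,
        applied only in adaptation sessions; used to inject known effects
        for recovery studies.
    lapse : float
        Probability of a uniformly random response, in [0, 0.5].
    participant_bias_sd : float
        SD (deg) of a per-participant additive bias perturbation, matching
        the analysis model's random-intercept assumption.
    """

    slope: float = 0.3
    baseline_bias: dict = field(default_factory=dict)
    tae_amplitude: float = 2.0
    tae_crossover: float = 50.0
    buildup_tau: float = np.inf
    condition_bias: dict = field(default_factory=dict)
    lapse: float = 0.0
    participant_bias_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ValueError("slope must be > 0")
        if not (0 <= self.lapse <= 0.5):
            raise ValueError("lapse must be in [0, 0.5]")
        if not (0 < self.tae_crossover < 90):
            raise ValueError("tae_crossover must be in (0, 90)")


def tae_profile(delta, params: ObserverParams):
    """Signed tilt-aftereffect bias (deg) at adaptor-relative orientation delta.

    Odd in delta, zero at 0 and +-90 deg, positive (repulsive) for
    |delta| below ``tae_crossover`` and negative (attractive) beyond, with
    peak magnitude ``tae_amplitude``.  Implemented as a two-harmonic odd
    series a*[sin(2d) + c*sin(4d)] whose zero crossing is pinned at the
    crossover and whose peak is normalised to the amplitude.
    """
    d = np.radians(np.asarray(fold_deg(delta), dtype=float))
    cross = np.radians(params.tae_crossover)
    grid = np.radians(np.linspace(-90, 90, 3601))
    if abs(np.cos(2.0 * cross)) < 1e-9:
        # crossover at exactly 45 deg: the first harmonic drops out
        raw = np.sin(4 * d)
        peak = 1.0
    else:
        c = -1.0 / (2.0 * np.cos(2.0 * cross))  # zero of 1+2c*cos(2d) at cross
        raw = np.sin(2 * d) + c * np.sin(4 * d)
        # normalise peak |raw| on a fine grid (shape depends only on crossover)
        peak = np.max(np.abs(np.sin(2 * grid) + c * np.sin(4 * grid)))
    out = params.tae_amplitude * raw / peak
    return out if out.ndim else float(out)


def _buildup(t, tau):
    """Saturating build-up factor in [0, 1) as a function of trial index."""
    t = np.asarray(t, dtype=float)
    if np.isinf(tau):
        out = np.ones_like(t)
    else:
        out = 1.0 - np.exp(-(t + 1.0) / tau)
    return out


def trial_bias(adaptor, standard, trial_index, params: ObserverParams,
               participant_offset: float = 0.0):
    """Total bias b (deg) entering the probit for each trial (vectorised)."""
    adaptor = np.asarray(adaptor, dtype=float)
    standard = np.asarray(standard, dtype=float)
    b = np.zeros_like(standard)
    for s, v in params.baseline_bias.items():
        b = b + np.where(standard == float(s), v, 0.0)
    adapted = adaptor != BASELINE
    if adapted.any():
        rel = fold_deg(np.where(adapted, standard - adaptor, 0.0))
        tae = tae_profile(rel, params) * _buildup(trial_index, params.buildup_tau)
        b = b + np.where(adapted, tae, 0.0)
        for (f, s), v in params.condition_bias.items():
            b = b + np.where(adapted & (adaptor == float(f))
                             & (standard == float(s)), v, 0.0)
    return b + participant_offset


def response_probability(offset, bias, params: ObserverParams):
    """P(respond 'right') under the probit-with-lapse observer."""
    p = norm.cdf(params.slope * (np.asarray(offset, float) + bias))
    return (1 - params.lapse) * p + params.lapse / 2.0


def respond(trial, params: ObserverParams, t: int, rng=None,
            participant_offset: float = 0.0) -> int:
    """Binary response for one trial record (mapping-like row).

    ``t`` is the within-session trial index driving aftereffect build-up.
    """
    rng = np.random.default_rng(rng)
    b = trial_bias(trial["adaptor_deg"], trial["standard_deg"], t, params,
                   participant_offset)
    p = response_probability(trial["offset_deg"], b, params)
    return int(rng.random() < p)


def simulate_trials(schedule: pd.DataFrame, params: ObserverParams,
                    seed, participant_offset: float = 0.0) -> pd.DataFrame:
    """Fill responses for one participant's schedule (vectorised, seeded).

    Build-up time is the trial's position within its session's main phase;
    practice/baseline trials carry no aftereffect term by construction
    (their adaptor is the baseline sentinel).
    """
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    t = out.groupby(["session", "phase"]).cumcount().to_numpy()
    b = trial_bias(out["adaptor_deg"].to_numpy(),
                   out["standard_deg"].to_numpy(), t, params,
                   participant_offset)
    p = response_probability(out["offset_deg"].to_numpy(), b, params)
    out["response"] = (rng.random(len(out)) < p).astype(float)
    return out


def simulate_cohort(schedule: pd.DataFrame, params: ObserverParams,
                    seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every participant in a cohort schedule.

    Participant-level bias offsets are drawn from
    N(0, participant_bias_sd^2) and returned in a ground-truth table for
    recovery scoring.  Fully reproducible from ``seed``.
    """
    pids = list(pd.unique(schedule["participant"]))
    root = np.random.SeedSequence(seed)
    offset_rng = np.random.default_rng(root.spawn(1)[0])
    offsets = offset_rng.normal(0.0, params.participant_bias_sd, len(pids))
    completed, truth = [], []
    for child, pid, off in zip(root.spawn(len(pids) + 1)[1:], pids, offsets):
        sub = schedule[schedule["participant"] == pid]
        completed.append(simulate_trials(sub, params,
                                         np.random.default_rng(child), off))
        truth.append({"participant": pid, "participant_bias_deg": off,
                      "slope": params.slope,
                      "tae_amplitude": params.tae_amplitude})
    return (pd.concat(completed, ignore_index=True),
            pd.DataFrame(truth))
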