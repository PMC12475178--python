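import numpy as np
import pandas as pd
import pytest

from tiltfilm import glmm
from tiltfilm.design import DesignSpec, build_cohort_schedule
from tiltfilm.frames import FrameImage
from tiltfilm.observer import ObserverParams, simulate_cohort


@pytest.fixture(scope="session")
def reduced_spec():
    """Study design at one tenth the trial counts (30 per standard/session)."""
    return DesignSpec(baseline_counts={10.0: 2, 5.0: 4, 2.5: 6, 0.0: 6},
                      clips_per_session=12,
                      practice1_doubled=14, practice1_standard=14,
                      practice23_feedback=14, practice23_nofeedback=28)


def make_cohort(spec, n_participants, params, seed):
    pids = [f"p{i:02d}" for i in range(n_participants)]
    schedule = build_cohort_schedule(spec, pids, seed)
    completed, truth = simulate_cohort(schedule, params, seed + 1)
    return completed, truth


@pytest.fixture(scope="session")
def null_cohort(reduced_spec):
    """8 unbiased observers (random participant intercepts only)."""
    params = ObserverParams(slope=0.3, tae_amplitude=0.0,
                            participant_bias_sd=0.5)
    completed, _ = make_cohort(reduced_spec, 8, params, seed=11)
    return completed

@pytest.fixture(scope="session")
def null_fit(null_cohort):
    return glmm.fit_bias_model(null_cohort)


@pytest.fixture()
def texture_frame():
    """Seeded 64x64 pseudo-natural texture (1/f-filtered noise + gradient)."""
    rng = np.random.default_rng(7)
    n = 64
    white = rng.standard_normal((n, n))
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    f = np.hypot(fx, fy)
    f[0, 0] = 1.0
    spec = np.fft.fft2(white) / f
    img = np.fft.ifft2(spec).real
    img = (img - img.min()) / np.ptp(img)
    return FrameImage(0.1 + 0.8 * img, ppd=16.0)
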