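import numpy as np
import pytest

from engramkit import synthetic_data as syn
from engramkit.synthetic_data import _poisson_times, calcium_kernel

SHORT_PLAN = [
    ("A", "awake", 120.0),
    ("B", "NREM", 30.0),
    ("C", "NREM", 30.0),
    ("D", "REM", 30.0),
    ("E", "awake", 60.0),
    ("F", "awake", 60.0),
]


@pytest.fixture(scope="session")
def small_experiment():
    """Scaled-down six-session experiment with planted engram fates."""
    cfg = syn.SynthConfig(
        n_cells=120,
        engram_fraction=1 / 6,
        n_engram_patterns=4,
        n_nonengram_patterns=3,
        session_plan=list(SHORT_PLAN),
        pattern_activation_rate_hz=0.3,
        seed=3,
    )
    return cfg, *syn.generate_experiment(cfg)


def make_session_matrix(
    vectors: np.ndarray,
    n_frames: int = 400,
    seed: int = 0,
    rate_hz: float = 0.4,
    frame_rate_hz: float = 20.0,
    noise_sd: float = 0.02,
) -> np.ndarray:
    """Single-group session matrix: planted synchronous patterns + clipped noise."""
    rng = np.random.default_rng(seed)
    kern = calcium_kernel(0.05, 0.5, frame_rate_hz)
    n = vectors.shape[1]
    D = np.zeros((n, n_frames))
    for v in vectors:
        for t in _poisson_times(rng, rate_hz, n_frames, frame_rate_hz):
            D[:, t] += v * rng.uniform(0.9, 1.1)
    D = np.apply_along_axis(lambda r: np.convolve(r, kern)[:n_frames], 1, D)
    return np.clip(D + rng.normal(0, noise_sd, size=D.shape), 0, None)
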