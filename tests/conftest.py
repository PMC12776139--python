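import numpy as np
import pytest

from sertflow.arenas import epm_arena, oft_arena, rtpp_arena
from sertflow.types import PhotometrySession, ZScoredTrace


@pytest.fixture(scope="session")
def oft():
    return oft_arena()


@pytest.fixture(scope="session")
def epm():
    return epm_arena()


@pytest.fixture(scope="session")
def rtpp():
    return rtpp_arena()


def make_session(F=None, duration=120.0, fs=30.0, **kwargs):
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if F is None:
        F = np.full(n, 100.0)
    elif np.isscalar(F):
        F = np.full(n, float(F))
    defaults = dict(subject_id="s0", region="ACC", fs=fs)
    defaults.update(kwargs)
    return PhotometrySession(t=t, F=np.asarray(F, dtype=float), **defaults)


def make_ztrace(z, fs=30.0, t0=0.0):
    z = np.asarray(z, dtype=float)
    t = t0 + np.arange(len(z)) / fs
    return ZScoredTrace(t=t, z=z, fs=fs)


def random_session(rng, fs=30.0):
    """A random but valid photometry session for fuzz/round-trip tests (>= 60 s)."""
    n = int(rng.integers(2000, 5000))
    t = np.arange(n) / fs
    F = 50.0 + 200.0 * rng.random() + rng.normal(0, 5.0, n)
    return PhotometrySession(
        subject_id=f"m{rng.integers(1000):03d}",
        region=("ACC", "CeA")[int(rng.integers(2))],
        t=t,
        F=F,
        fs=fs,
        assay_label="fuzz",
        week=int(rng.integers(5)),
    )
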