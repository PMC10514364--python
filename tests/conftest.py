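import numpy as np
import pytest

from kcomplex.synth_eeg import SynthSpec, generate_recording, write_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def short_synth():
    """A 60-s synthetic recording with 8 annotated k-complexes."""
    spec = SynthSpec(duration_s=60.0, n_events=8, snr=8.0, seed=7)
    rec, ann = generate_recording(spec)
    return spec, rec, ann


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory, short_synth):
    """EDF + annotation text written by the synthetic generator."""
    _, rec, ann = short_synth
    out = tmp_path_factory.mktemp("fixtures")
    edf, annot = write_fixture(rec, ann, out)
    return edf, annot


def make_informative_matrix(n=200, n_noise=3, seed=0, shift=3.0):
    """Binary-labeled matrix: one shifted Gaussian feature + noise columns."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    good = rng.normal(0, 1, n) + shift * y
    noise = rng.normal(0, 1, (n, n_noise))
    X = np.column_stack([good, noise])
    names = ["good"] + [f"noise{i}" for i in range(n_noise)]
    return X, y, names
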