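import numpy as np
import pytest

from atacscore.pipeline import run_discovery, run_validation
from atacscore.simulate import SimulationConfig, simulate_cohort, simulate_validation
from atacscore.tracks import SignalTrack


@pytest.fixture(scope="session")
def discovery_bundle(tmp_path_factory):
    """Default synthetic discovery cohort (seed 0, 32 samples)."""
    return simulate_cohort(SimulationConfig(seed=0),
                           tmp_path_factory.mktemp("disc"))


@pytest.fixture(scope="session")
def discovery_out(tmp_path_factory):
    return tmp_path_factory.mktemp("disc_out")


@pytest.fixture(scope="session")
def discovery_result(discovery_bundle, discovery_out):
    """Full fitted pipeline on the discovery cohort."""
    return run_discovery(discovery_bundle, discovery_out)


@pytest.fixture(scope="session")
def validation_bundle(discovery_bundle, tmp_path_factory):
    """Held-out cohort drawn from the same generative truth (seed 2)."""
    return simulate_validation(discovery_bundle,
                               tmp_path_factory.mktemp("val"), seed=2)


@pytest.fixture(scope="session")
def validation_result(validation_bundle, discovery_result, discovery_out,
                      tmp_path_factory):
    return run_validation(validation_bundle, discovery_out,
                          tmp_path_factory.mktemp("val_out"))


def make_random_track(rng: np.random.Generator, chrom: str = "chr1",
                      n_runs: int = 30, span: int = 5000) -> SignalTrack:
    """Random run-length track with integer heights (possibly zero)."""
    cuts = np.sort(rng.choice(span, size=2 * n_runs, replace=False))
    runs = []
    for i in range(n_runs):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if s < e:
            runs.append((chrom, s, e, float(rng.integers(0, 6))))
    return SignalTrack.from_runs(runs)


def track_height_oracle(track: SignalTrack, chrom: str, start: int,
                        end: int) -> np.ndarray:
    """Materialize every base height in [start, end) — brute force."""
    return np.array([track.height_at(chrom, p) for p in range(start, end)])
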