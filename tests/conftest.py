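"""Shared fixtures: synthetic corpora, a trained classifier, small builders.

The session-scoped corpus fixtures define the study conditions for the
end-to-end checks: a 200-recording training corpus and a disjoint
100-recording evaluation corpus, both seeded, with buzz / non-buzz balanced
and non-buzz content cycling through search-phase, click and noise
subtypes.
"""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from batbuzz import FrequencyBand
from batbuzz.detector import Detection
from batbuzz.pipeline import classify_files, extract_features, train_from_features
from batbuzz.synth import synth_corpus

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TRAIN_SEED = 101
EVAL_SEED = 202
MODEL_SEED = 7


def make_detection(start_s, snr_db, freqs_hz, band=None, frame_step_s=8.6e-5,
                   end_s=None):
    """Build a Detection with a uniform frame grid for feature tests."""
    freqs = np.asarray(freqs_hz, dtype=float)
    times = start_s + np.arange(freqs.size) * frame_step_s
    band = band or FrequencyBand(15_000.0, 50_000.0)
    end = end_s if end_s is not None else times[-1] + frame_step_s
    return Detection(
        start_time=float(start_s),
        end_time=float(end),
        snr=float(snr_db),
        freq_track=freqs,
        amp_track=np.full(freqs.size, snr_db, dtype=float),
        frame_times=times,
        band=band,
    )


@pytest.fixture
def detection_factory():
    return make_detection


@pytest.fixture(scope="session")
def train_corpus(tmp_path_factory):
    d = tmp_path_factory.mktemp("train_corpus")
    manifest = synth_corpus(100, 100, d, seed=TRAIN_SEED)
    return d, manifest


@pytest.fixture(scope="session")
def eval_corpus(tmp_path_factory):
    d = tmp_path_factory.mktemp("eval_corpus")
    manifest = synth_corpus(50, 50, d, seed=EVAL_SEED)
    return d, manifest


@pytest.fixture(scope="session")
def train_windows(train_corpus):
    d, manifest = train_corpus
    labels = dict(zip(manifest.frame["path"], manifest.frame["label"]))
    return extract_features(sorted(Path(d).glob("*.wav")), labels=labels)


@pytest.fixture(scope="session")
def trained_bundle(train_windows):
    bundle, _ = train_from_features(train_windows, seed=MODEL_SEED)
    return bundle


@pytest.fixture(scope="session")
def eval_predictions(eval_corpus, trained_bundle):
    d, _ = eval_corpus
    return classify_files(sorted(Path(d).glob("*.wav")), trained_bundle)
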